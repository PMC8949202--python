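"""Solution arrays and angle lookup tables.

After a sensor's network is trained, every achievable raw value from
the flat-hand reading up to the 12-bit maximum (4095) is pushed through
the network once, producing a *solution array* of (raw, angle) pairs.
A smoothing pass discards entries beyond the joint's physical flexion
limit, and normalization re-keys the array by ``raw - flat_hand_raw``
so that the runtime lookup key for a live reading is a simple
subtraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bpnn import TrainedNetwork
from .sensors import RAW_MAX

__all__ = [
    "SolutionArray",
    "LookupTable",
    "TableBank",
    "build_solution_array",
    "predict_angles",
    "smooth",
    "normalize",
    "save_table",
    "load_table",
]

#: Tolerance on the key-0 (flat hand) angle, degrees.
KEY0_TOL = 0.5


@dataclass
class SolutionArray:
    """Raw values from the flat-hand reading to 4095, one angle each."""

    sensor_id: str
    flat_hand_raw: int
    raws: np.ndarray
    angles: np.ndarray | None = None
    truncated_at: int | None = None   # original index of first removed entry
    smoothed: bool = False
    theta_max: float | None = None

    def __len__(self) -> int:
        return self.raws.size


def build_solution_array(
    flat_hand_raw: int, max_raw: int = RAW_MAX, sensor_id: str = ""
) -> SolutionArray:
    """Initialize the raw axis: flat_hand_raw, flat_hand_raw+1, ..., max_raw."""
    if not 0 <= flat_hand_raw <= max_raw:
        raise ValueError("flat_hand_raw must be in [0, max_raw]")
    return SolutionArray(
        sensor_id=sensor_id,
        flat_hand_raw=int(flat_hand_raw),
        raws=np.arange(flat_hand_raw, max_raw + 1, dtype=np.int64),
    )


#: Width (degrees above the flat-hand prediction) over which the
#: zero-reference correction is tapered out.
ZERO_ANCHOR_SPAN_DEG = 5.0


def predict_angles(
    net: TrainedNetwork, arr: SolutionArray, zero_anchor: bool = True
) -> SolutionArray:
    """Fill the array: one network evaluation per raw value.

    The flat-hand reading defines the 0-degree minimum of the sensor's
    angle scale, so with ``zero_anchor`` (default) the network's small
    residual at the first entry is subtracted there and tapered out
    linearly over the first few degrees of the table — key 0 then reads
    exactly 0 while the rest of the table is untouched. Angles below
    0 deg are clamped to 0; angles above the joint limit are left for
    `smooth`.
    """
    if arr.angles is not None:
        raise ValueError("solution array already filled")
    if net.sensor_id and arr.sensor_id and net.sensor_id != arr.sensor_id:
        raise ValueError(
            f"network for {net.sensor_id!r} cannot fill array for "
            f"{arr.sensor_id!r}"
        )
    ang = np.asarray(net.predict_angle(arr.raws.astype(float)), dtype=float)
    if not np.all(np.isfinite(ang)):
        raise ValueError("network produced non-finite angles")
    if zero_anchor and ang[0] > 0:
        a0 = ang[0]
        above = np.nonzero(ang >= a0 + ZERO_ANCHOR_SPAN_DEG)[0]
        # a table that never rises above the flat-hand prediction carries
        # no angle information to re-reference; leave it untouched
        if above.size and above[0] > 0:
            k5 = int(above[0])
            k = np.arange(len(ang), dtype=float)
            taper = np.clip(1.0 - k / k5, 0.0, 1.0)
            ang = ang - a0 * taper  # adds an increasing ramp: stays monotone
    arr.angles = np.maximum(ang, 0.0)
    return arr


def smooth(arr: SolutionArray, theta_max: float) -> SolutionArray:
    """Discard entries beyond the joint's physical limit.

    Everything after the first entry whose angle exceeds ``theta_max``
    is removed (that first entry is kept, clamped to the limit); all
    retained angles are clamped into [0, theta_max].
    """
    if arr.angles is None:
        raise ValueError("predict angles before smoothing")
    over = np.nonzero(arr.angles > theta_max)[0]
    if over.size:
        cut = int(over[0]) + 1   # keep the first exceeder, clamped
        arr.truncated_at = cut if cut < len(arr.raws) else None
        arr.raws = arr.raws[:cut]
        arr.angles = arr.angles[:cut]
    arr.angles = np.clip(arr.angles, 0.0, theta_max)
    arr.smoothed = True
    arr.theta_max = float(theta_max)
    return arr


@dataclass
class LookupTable:
    """Angle per normalized key (raw - flat_hand_raw) for one sensor."""

    sensor_id: str
    flat_hand_raw: int
    theta_max: float
    angles: np.ndarray
    hand_size: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.angles.size == 0:
            raise ValueError("empty lookup table")
        if self.angles.size > RAW_MAX - self.flat_hand_raw + 1:
            raise ValueError("table longer than the available raw range")
        if abs(self.angles[0]) > KEY0_TOL:
            raise ValueError(
                f"key-0 angle {self.angles[0]:.2f} deg exceeds the "
                f"{KEY0_TOL} deg flat-hand tolerance"
            )
        if np.any(self.angles < 0) or np.any(self.angles > self.theta_max):
            raise ValueError("table angles must lie in [0, theta_max]")

    def __len__(self) -> int:
        return self.angles.size

    def is_monotone(self, tol: float = 0.0) -> bool:
        """Diagnostic: does the angle increase (within tol) with the key?"""
        return bool(np.all(np.diff(self.angles) >= -tol))


def normalize(arr: SolutionArray, hand_size: float | None = None,
              provenance: dict | None = None) -> LookupTable:
    """Re-key the smoothed array by raw - flat_hand_raw (key 0 = flat hand)."""
    if not arr.smoothed:
        raise ValueError("smooth the solution array before normalizing")
    return LookupTable(
        sensor_id=arr.sensor_id,
        flat_hand_raw=arr.flat_hand_raw,
        theta_max=float(arr.theta_max),
        angles=arr.angles.copy(),
        hand_size=hand_size,
        provenance=dict(provenance or {}),
    )


def save_table(table: LookupTable, path) -> None:
    doc = {
        "schema": "glovecal.table/1",
        "sensor_id": table.sensor_id,
        "hand_size": table.hand_size,
        "flat_hand_raw": table.flat_hand_raw,
        "theta_max": table.theta_max,
        "angles": [round(a, 4) for a in table.angles.tolist()],
        "provenance": table.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_table(path) -> LookupTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "glovecal.table/1":
        raise ValueError("unrecognized lookup-table file schema")
    return LookupTable(
        sensor_id=doc["sensor_id"],
        flat_hand_raw=doc["flat_hand_raw"],
        theta_max=doc["theta_max"],
        angles=np.array(doc["angles"]),
        hand_size=doc.get("hand_size"),
        provenance=doc.get("provenance", {}),
    )


class TableBank:
    """Lookup tables addressed by (hand_size, sensor_id).

    A full bank holds 10 tables for each of the four glove hand sizes.
    """

    def __init__(self, tables: dict | None = None):
        self._tables: dict[tuple[float, str], LookupTable] = dict(tables or {})

    def add(self, table: LookupTable) -> None:
        if table.hand_size is None:
            raise ValueError("table needs a hand_size to live in a bank")
        self._tables[(table.hand_size, table.sensor_id)] = table

    def get(self, hand_size: float, sensor_id: str) -> LookupTable:
        try:
            return self._tables[(hand_size, sensor_id)]
        except KeyError:
            raise KeyError(
                f"no table for hand size {hand_size}, sensor {sensor_id!r}"
            ) from None

    def for_hand(self, hand_size: float) -> dict[str, LookupTable]:
        return {
            sid: t for (hs, sid), t in self._tables.items() if hs == hand_size
        }

    def __len__(self) -> int:
        return len(self._tables)

    def __iter__(self):
        return iter(self._tables.values())

    def save(self, path) -> None:
        doc = {
            "schema": "glovecal.bank/1",
            "tables": [
                {
                    "sensor_id": t.sensor_id,
                    "hand_size": t.hand_size,
                    "flat_hand_raw": t.flat_hand_raw,
                    "theta_max": t.theta_max,
                    "angles": [round(a, 4) for a in t.angles.tolist()],
                    "provenance": t.provenance,
                }
                for t in self._tables.values()
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "TableBank":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema") != "glovecal.bank/1":
            raise ValueError("unrecognized table-bank file schema")
        bank = cls()
        for td in doc["tables"]:
            bank.add(
                LookupTable(
                    sensor_id=td["sensor_id"],
                    flat_hand_raw=td["flat_hand_raw"],
                    theta_max=td["theta_max"],
                    angles=np.array(td["angles"]),
                    hand_size=td["hand_size"],
                    provenance=td.get("provenance", {}),
                )
            )
        return bank
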