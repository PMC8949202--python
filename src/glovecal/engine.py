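"""Runtime angle computation from raw sensor frames.

Two routes from a 12-bit reading to a joint angle:

* **NN method** — subtract the stored flat-hand reading to form a
  lookup key and index the sensor's network-generated angle table.
  The only per-wearer step is capturing the flat-hand reading.
* **Linear method** — the traditional calibration baseline: flat-hand
  and fist poses give per-sensor (raw_min, raw_max), and the angle is
  min–max interpolation scaled by the joint limit, assuming the sensor
  responds linearly across its whole range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lut import LookupTable
from .sensors import RAW_MAX, theta_max_for
from .sim import Recording

__all__ = [
    "CalibrationState",
    "compute_lookup_key",
    "angle_nn",
    "calibrate_linear",
    "capture_flat_hand",
    "angle_linear",
    "process_recording",
]


@dataclass
class CalibrationState:
    """Per-sensor calibration constants for both methods."""

    flat_hand_raw: dict = field(default_factory=dict)   # NN method
    raw_min: dict = field(default_factory=dict)         # linear method
    raw_max: dict = field(default_factory=dict)
    theta_max: dict = field(default_factory=dict)

    def require_linear(self, sensor_id: str) -> tuple[int, int, float]:
        if sensor_id not in self.raw_min or sensor_id not in self.raw_max:
            raise KeyError(f"sensor {sensor_id!r} has no linear calibration")
        return (
            self.raw_min[sensor_id],
            self.raw_max[sensor_id],
            self.theta_max.get(sensor_id, theta_max_for(sensor_id)),
        )


def compute_lookup_key(raw: int, flat_hand_raw: int, table_len: int) -> int:
    """Key = raw - flat_hand_raw, clamped into the table.

    Clamping is deliberate: readings below the flat-hand value
    (hyperextension) map to key 0, readings beyond the table's end
    (over-flexion) to the last entry.
    """
    if not 0 <= raw <= RAW_MAX:
        raise ValueError(f"raw must be in [0, {RAW_MAX}]")
    if table_len < 1:
        raise ValueError("table_len must be >= 1")
    return int(np.clip(raw - flat_hand_raw, 0, table_len - 1))


def angle_nn(
    raw: int, table: LookupTable, flat_hand_raw: int | None = None
) -> float:
    """Angle from the lookup table; total over the full raw range.

    ``flat_hand_raw`` defaults to the table's own stored flat-hand
    value; pass the freshly captured one after re-donning the glove.
    """
    flat = table.flat_hand_raw if flat_hand_raw is None else flat_hand_raw
    key = compute_lookup_key(raw, flat, len(table))
    return float(table.angles[key])


def _segment_mean_raw(rec: Recording, labels: tuple[str, ...]) -> np.ndarray:
    frames = [
        rec.raw[s.start:s.stop] for s in rec.segments if s.label in labels
    ]
    if not frames:
        # no annotations: use every frame
        return rec.raw.astype(float).mean(axis=0)
    return np.vstack(frames).astype(float).mean(axis=0)


def capture_flat_hand(rec: Recording) -> dict[str, int]:
    """Mean raw over the flat-pose frames, rounded, per sensor."""
    means = _segment_mean_raw(rec, ("flat",))
    return {
        sid: int(round(means[j])) for j, sid in enumerate(rec.sensor_ids)
    }


def calibrate_linear(
    flat_recording: Recording, fist_recording: Recording
) -> CalibrationState:
    """Traditional two-pose calibration.

    raw_min is the mean raw over the flat pose, raw_max over the fist
    pose, both rounded to integers. A sensor whose fist reading does
    not exceed its flat reading cannot be calibrated linearly.
    """
    lo = _segment_mean_raw(flat_recording, ("flat",))
    hi = _segment_mean_raw(fist_recording, ("fist",))
    state = CalibrationState()
    for j, sid in enumerate(flat_recording.sensor_ids):
        rmin, rmax = int(round(lo[j])), int(round(hi[j]))
        if rmax <= rmin:
            raise ValueError(
                f"degenerate calibration for sensor {sid!r}: "
                f"fist reading {rmax} <= flat reading {rmin}"
            )
        state.raw_min[sid] = rmin
        state.raw_max[sid] = rmax
        state.flat_hand_raw[sid] = rmin
        state.theta_max[sid] = theta_max_for(sid)
    return state


def angle_linear(raw: int, state: CalibrationState, sensor_id: str) -> float:
    """Min–max interpolated angle, clamped to [0, theta_max]."""
    if not 0 <= raw <= RAW_MAX:
        raise ValueError(f"raw must be in [0, {RAW_MAX}]")
    rmin, rmax, tmax = state.require_linear(sensor_id)
    frac = (raw - rmin) / (rmax - rmin)
    return float(tmax * np.clip(frac, 0.0, 1.0))


def process_recording(
    rec: Recording,
    method: str,
    tables: dict[str, LookupTable] | None = None,
    state: CalibrationState | None = None,
    flat_hand: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert a raw recording to per-frame angles plus per-pose means.

    Parameters
    ----------
    method : {"nn", "linear"}
    tables : sensor_id -> LookupTable, required for the NN method.
    state : CalibrationState, required for the linear method.
    flat_hand : optional per-sensor flat-hand readings for the NN
        method (a re-donned glove should have them re-captured; omit to
        reuse each table's stored value, emulating a stale calibration).

    Returns
    -------
    angles : DataFrame with ``time_s`` and one ``<sensor>_deg`` column
        per sensor.
    segment_means : DataFrame of per-(segment, cycle, sensor) mean
        measured and true angles.
    """
    if method not in ("nn", "linear"):
        raise ValueError("method must be 'nn' or 'linear'")
    n, n_sens = rec.raw.shape
    out = np.empty((n, n_sens))
    for j, sid in enumerate(rec.sensor_ids):
        col = rec.raw[:, j]
        if method == "nn":
            if tables is None or sid not in tables:
                raise KeyError(f"no lookup table for sensor {sid!r}")
            table = tables[sid]
            flat = (
                flat_hand[sid] if flat_hand is not None else table.flat_hand_raw
            )
            keys = np.clip(col - flat, 0, len(table) - 1)
            out[:, j] = table.angles[keys]
        else:
            if state is None:
                raise ValueError("linear method requires a CalibrationState")
            rmin, rmax, tmax = state.require_linear(sid)
            frac = np.clip((col - rmin) / (rmax - rmin), 0.0, 1.0)
            out[:, j] = tmax * frac
    angles = pd.DataFrame({"time_s": rec.time_s})
    for j, sid in enumerate(rec.sensor_ids):
        angles[f"{sid}_deg"] = out[:, j]
    rows = []
    for seg in rec.segments:
        for j, sid in enumerate(rec.sensor_ids):
            rows.append(
                {
                    "segment": seg.label,
                    "cycle": seg.cycle,
                    "sensor_id": sid,
                    "mean_deg": float(out[seg.start:seg.stop, j].mean()),
                    "true_mean_deg": float(
                        rec.true_angles[seg.start:seg.stop, j].mean()
                    ),
                }
            )
    return angles, pd.DataFrame(rows)
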