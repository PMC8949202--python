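"""Synthetic bend-sensor glove.

Stands in for physical glove hardware: each simulated sensor converts a
joint angle into a 12-bit integer reading through a monotone, optionally
nonlinear transfer function, perturbed by how well the glove fits the
wearer's hand, additive Gaussian noise, and an offset that is re-drawn
every time the glove is put back on (donning/doffing drift).

The transfer function is

    raw(theta) = round(clamp(r_flat + fit_offset
                             + gain * fit_gain_scale * g(theta / theta_max; c)
                             + eps, 0, 4095))

with ``g(u; c) = (1 + c) u / (1 + c u)`` — a one-parameter saturating
map with g(0) = 0, g(1) = 1 that is the identity at curvature c = 0 and
increasingly front-loaded (fiber-optic-like saturation) as c grows —
and ``eps ~ Normal(0, noise_sd^2)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .bpnn import TrainingSet
from .sensors import (
    FRAME_RATE,
    RAW_MAX,
    SENSOR_IDS,
    grid_for,
    theta_max_for,
)

__all__ = [
    "SensorGroundTruth",
    "HandFitProfile",
    "Segment",
    "Recording",
    "response",
    "simulate_raw",
    "generate_training_samples",
    "generate_protocol",
    "default_sensor_bank",
    "save_profiles",
    "load_profiles",
]

#: Allowed hyperextension margin beyond theta_max (degrees).
HYPEREXTENSION_MARGIN = 15.0

PROTOCOL_IDS = ("A", "B", "C", "D", "E")
DEFAULT_CYCLES = {"A": 10, "B": 10, "C": 10, "D": 1, "E": 12}

#: Wooden-block angles visited by the accuracy protocol (degrees).
BLOCK_ANGLES = (0.0, 20.0, 45.0, 60.0, 70.0, 90.0)


def response(u, curvature: float):
    """Normalized sensor response g(u; c) = (1+c)u / (1+cu).

    Monotone on [0, 1] with g(0)=0 and g(1)=1 for any curvature >= 0;
    reduces to the identity at curvature 0.
    """
    if curvature < 0:
        raise ValueError("curvature must be >= 0")
    u = np.asarray(u, dtype=float)
    return (1.0 + curvature) * u / (1.0 + curvature * u)


@dataclass(frozen=True)
class SensorGroundTruth:
    """Hidden parameters of one simulated sensor.

    Parameters
    ----------
    sensor_id : str
        Joint label, e.g. ``"index_mcp"``.
    r_flat : int
        Raw reading at 0 deg (flat hand), in [0, 4095].
    gain : float
        Raw counts spanned between 0 deg and theta_max (before fit
        perturbation); must be > 0.
    curvature : float
        Nonlinearity of the transfer function; 0 = perfectly linear.
    noise_sd : float
        SD of additive raw-count noise per frame.
    theta_max : float
        Physical joint limit in degrees.
    """

    sensor_id: str
    r_flat: int
    gain: float
    curvature: float = 0.0
    noise_sd: float = 0.0
    theta_max: float = 0.0  # 0 -> resolve from sensor_id

    def __post_init__(self):
        if not 0 <= self.r_flat <= RAW_MAX:
            raise ValueError(f"r_flat must be in [0, {RAW_MAX}]")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.curvature < 0 or self.noise_sd < 0:
            raise ValueError("curvature and noise_sd must be >= 0")
        if self.theta_max <= 0:
            object.__setattr__(self, "theta_max", theta_max_for(self.sensor_id))


@dataclass(frozen=True)
class HandFitProfile:
    """How the glove sits on a particular hand.

    ``fit_offset`` (raw counts, additive) and ``fit_gain_scale``
    (multiplicative, > 0) perturb each sensor's transfer function;
    ``don_doff_sd`` is the SD of the fresh offset drawn each time the
    glove is re-donned.
    """

    hand_size: float
    fit_offset: dict = field(default_factory=dict)
    fit_gain_scale: dict = field(default_factory=dict)
    don_doff_sd: float = 0.0

    #: misfit scaling constants: raw-count offset SD and log-gain SD per
    #: inch of distance from the glove's design size (7.75 in).
    _OFFSET_SD_PER_INCH = 60.0
    _LOG_GAIN_SD_PER_INCH = 0.08

    def __post_init__(self):
        if self.hand_size not in (7.0, 7.5, 7.75, 8.0):
            raise ValueError("hand_size must be one of 7, 7.5, 7.75, 8 inches")
        for v in self.fit_gain_scale.values():
            if v <= 0:
                raise ValueError("fit_gain_scale must be > 0")
        if self.don_doff_sd < 0:
            raise ValueError("don_doff_sd must be >= 0")

    def offset(self, sensor_id: str) -> float:
        return self.fit_offset.get(sensor_id, 0.0)

    def gain_scale(self, sensor_id: str) -> float:
        return self.fit_gain_scale.get(sensor_id, 1.0)

    @classmethod
    def neutral(cls, hand_size: float = 7.75) -> "HandFitProfile":
        """Perfectly fitting glove: no offsets, unit gain scales."""
        return cls(hand_size=hand_size)

    @classmethod
    def for_hand_size(
        cls, hand_size: float, seed: int = 0, don_doff_sd: float = 0.0
    ) -> "HandFitProfile":
        """Draw a plausible fit for a hand of the given size.

        The glove is designed for a 7.75-inch hand; per-sensor offsets
        and gain perturbations grow with the distance from that size
        (the 7-inch hand is the worst fit, as a small hand in a medium
        glove leaves sensors loosely coupled to the joints).
        """
        rng = np.random.default_rng(seed)
        misfit = abs(hand_size - 7.75)
        off_sd = cls._OFFSET_SD_PER_INCH * misfit
        lg_sd = cls._LOG_GAIN_SD_PER_INCH * misfit
        offsets = {s: float(rng.normal(0.0, off_sd)) for s in SENSOR_IDS}
        gains = {s: float(np.exp(rng.normal(0.0, lg_sd))) for s in SENSOR_IDS}
        return cls(
            hand_size=hand_size,
            fit_offset=offsets,
            fit_gain_scale=gains,
            don_doff_sd=don_doff_sd,
        )


def _raw_values(
    angles: np.ndarray,
    truth: SensorGroundTruth,
    fit: HandFitProfile,
    rng: np.random.Generator | None,
    extra_offset: float = 0.0,
) -> np.ndarray:
    """Vectorized transfer function; returns quantized ints in [0, 4095]."""
    angles = np.asarray(angles, dtype=float)
    if np.any(angles < 0):
        raise ValueError("angle must be >= 0")
    if np.any(angles > truth.theta_max + HYPEREXTENSION_MARGIN):
        raise ValueError(
            f"angle exceeds theta_max + {HYPEREXTENSION_MARGIN} deg margin"
        )
    u = np.minimum(angles / truth.theta_max, 1.0)
    raw = (
        truth.r_flat
        + fit.offset(truth.sensor_id)
        + extra_offset
        + truth.gain * fit.gain_scale(truth.sensor_id) * response(u, truth.curvature)
    )
    if truth.noise_sd > 0:
        if rng is None:
            raise ValueError("a seeded generator is required when noise_sd > 0")
        raw = raw + rng.normal(0.0, truth.noise_sd, size=raw.shape)
    return np.clip(np.round(raw), 0, RAW_MAX).astype(np.int64)


def simulate_raw(
    angle: float,
    truth: SensorGroundTruth,
    fit: HandFitProfile | None = None,
    seed: int = 0,
) -> int:
    """One quantized sensor reading at a joint angle.

    Deterministic for a given seed; the seed only matters when the
    sensor has ``noise_sd > 0``.
    """
    fit = fit or HandFitProfile.neutral()
    rng = np.random.default_rng(seed)
    return int(_raw_values(np.array([angle]), truth, fit, rng)[0])


def generate_training_samples(
    truth: SensorGroundTruth,
    fit: HandFitProfile | None = None,
    angle_grid=None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> TrainingSet:
    """Calibration sample points (raw, angle) over a pose grid.

    Calibration poses are held static and averaged, so samples are
    noiseless by default; pass ``noise_sd`` to perturb them.
    """
    fit = fit or HandFitProfile.neutral()
    if angle_grid is None:
        angle_grid = grid_for(truth.sensor_id)
    grid = np.asarray(angle_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("angle_grid is empty")
    if grid[0] != 0:
        raise ValueError("angle_grid must start at 0 deg (flat hand)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("angle_grid must be sorted ascending without duplicates")
    t = truth if noise_sd == truth.noise_sd else replace(truth, noise_sd=noise_sd)
    raws = _raw_values(grid, t, fit, np.random.default_rng(seed))
    return TrainingSet(
        sensor_id=truth.sensor_id,
        hand_size=fit.hand_size,
        raws=raws,
        angles=grid,
    )


def default_sensor_bank(
    curvature: float = 0.0,
    noise_sd: float = 0.0,
    thumb_noise_scale: float = 3.0,
    seed: int | None = None,
) -> dict[str, SensorGroundTruth]:
    """Ten plausible sensors, keyed by sensor_id.

    Flat-hand values and gains are fixed round numbers spread over the
    12-bit range; pass ``seed`` to jitter them. Thumb sensors get
    ``thumb_noise_scale`` times the base noise to emulate the difficulty
    of holding the thumb still against a mold.
    """
    base = {
        "thumb_mcp": (900, 1700),
        "thumb_ip": (1100, 1650),
        "index_mcp": (1201, 1500),
        "index_pip": (1450, 1400),
        "middle_mcp": (1700, 1350),
        "middle_pip": (1900, 1300),
        "ring_mcp": (1300, 1600),
        "ring_pip": (1500, 1550),
        "little_mcp": (2200, 1100),
        "little_pip": (2500, 1000),
    }
    rng = np.random.default_rng(seed) if seed is not None else None
    bank = {}
    for sid, (r_flat, gain) in base.items():
        if rng is not None:
            r_flat = int(r_flat + rng.integers(-100, 101))
            gain = float(gain * rng.uniform(0.9, 1.1))
        sd = noise_sd * (thumb_noise_scale if sid.startswith("thumb") else 1.0)
        bank[sid] = SensorGroundTruth(
            sensor_id=sid, r_flat=r_flat, gain=gain,
            curvature=curvature, noise_sd=sd,
        )
    return bank


@dataclass(frozen=True)
class Segment:
    """A contiguous run of frames holding (or ramping through) one pose."""

    label: str
    cycle: int
    start: int  # first frame index
    stop: int   # one past last frame index


@dataclass
class Recording:
    """Timestamped frames of per-sensor raw readings from one protocol run."""

    protocol_id: str
    sensor_ids: tuple
    time_s: np.ndarray          # (n,)
    raw: np.ndarray             # (n, n_sensors) int
    true_angles: np.ndarray     # (n, n_sensors) float, degrees
    segments: tuple = ()        # Segment annotations
    rate: float = FRAME_RATE

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.raw = np.asarray(self.raw, dtype=np.int64)
        self.true_angles = np.asarray(self.true_angles, dtype=float)
        if self.raw.shape != self.true_angles.shape:
            raise ValueError("raw and true_angles shapes differ")
        if self.raw.shape[0] != self.time_s.shape[0]:
            raise ValueError("frame count mismatch")
        if np.any(np.diff(self.time_s) < 0):
            raise ValueError("frames must be time-ordered")
        if np.any((self.raw < 0) | (self.raw > RAW_MAX)):
            raise ValueError(f"raw values must be in [0, {RAW_MAX}]")

    @property
    def n_frames(self) -> int:
        return self.raw.shape[0]

    def sensor_index(self, sensor_id: str) -> int:
        return self.sensor_ids.index(sensor_id)

    def to_csv(self, path) -> None:
        """Write ``time_s, <raw cols>, true_<angle cols>, segment``."""
        labels = np.empty(self.n_frames, dtype=object)
        labels[:] = ""
        for seg in self.segments:
            labels[seg.start:seg.stop] = f"{seg.label}:{seg.cycle}"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["time_s", *self.sensor_ids]
                + [f"true_{s}" for s in self.sensor_ids]
                + ["segment"]
            )
            for i in range(self.n_frames):
                w.writerow(
                    [f"{self.time_s[i]:.3f}"]
                    + [int(v) for v in self.raw[i]]
                    + [f"{v:.3f}" for v in self.true_angles[i]]
                    + [labels[i]]
                )

    @classmethod
    def from_csv(cls, path, protocol_id: str = "?", rate: float = FRAME_RATE):
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = next(r)
            rows = list(r)
        has_seg = header[-1] == "segment"
        cols = header[1:-1] if has_seg else header[1:]
        n_sens = len(cols) // 2
        sensor_ids = tuple(cols[:n_sens])
        time_s = np.array([float(row[0]) for row in rows])
        raw = np.array([[int(v) for v in row[1:1 + n_sens]] for row in rows])
        ang = np.array(
            [[float(v) for v in row[1 + n_sens:1 + 2 * n_sens]] for row in rows]
        )
        segments = []
        if has_seg:
            labels = [row[-1] for row in rows]
            start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[start]:
                    if labels[start]:
                        lab, cyc = labels[start].rsplit(":", 1)
                        segments.append(Segment(lab, int(cyc), start, i))
                    start = i
        return cls(
            protocol_id=protocol_id,
            sensor_ids=sensor_ids,
            time_s=time_s,
            raw=raw,
            true_angles=ang,
            segments=tuple(segments),
            rate=rate,
        )


def _pose_angles(truths: dict, scale: float) -> np.ndarray:
    """Per-sensor angle at a fraction ``scale`` of each joint's limit."""
    return np.array([truths[s].theta_max * scale for s in truths])


def generate_protocol(
    protocol_id: str,
    truths: dict[str, SensorGroundTruth],
    fit: HandFitProfile | None = None,
    cycles: int | None = None,
    seed: int = 0,
    hold_s: float = 5.0,
    ramp_s: float = 2.0,
    rate: float = FRAME_RATE,
) -> Recording:
    """Simulate one run of a repeatability/accuracy test protocol.

    A — flat hand alternating with palm resting on a mold, glove kept on
        between cycles (repeatability of the flat pose).
    B — flat hand alternating with a full fist (material-stretch test).
    C — as B, but the glove is taken off and re-donned between cycles:
        each cycle gets a fresh per-sensor offset ~ Normal(0, don_doff_sd).
    D — each joint held on wooden blocks of 0/20/45/60/70/90 deg
        (accuracy against a known angle).
    E — 12 maximal flexion ramps (maximum range-of-motion test).
    """
    if protocol_id not in PROTOCOL_IDS:
        raise ValueError(f"unknown protocol {protocol_id!r}")
    fit = fit or HandFitProfile.neutral()
    if cycles is None:
        cycles = DEFAULT_CYCLES[protocol_id]
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if hold_s * rate < rate:  # < 1 s of frames per pose
        raise ValueError("hold_s must give at least 1 s of frames")
    rng = np.random.default_rng(seed)
    sensor_ids = tuple(truths)
    hold_n = int(round(hold_s * rate))
    ramp_n = int(round(ramp_s * rate))

    # Build (label, per-sensor angle trajectory (n_frames, n_sensors),
    # per-cycle extra offset) blocks.
    blocks: list[tuple[str, int, np.ndarray, np.ndarray]] = []
    n_sens = len(sensor_ids)
    zero_off = np.zeros(n_sens)
    flat = np.zeros((hold_n, n_sens))
    if protocol_id in ("A",):
        rest = np.zeros((hold_n, n_sens))
        for c in range(cycles):
            blocks.append(("flat", c, flat, zero_off))
            blocks.append(("rest", c, rest, zero_off))
    elif protocol_id in ("B", "C"):
        fist = np.tile(_pose_angles(truths, 1.0), (hold_n, 1))
        for c in range(cycles):
            off = (
                rng.normal(0.0, fit.don_doff_sd, size=n_sens)
                if protocol_id == "C" and fit.don_doff_sd > 0
                else zero_off
            )
            blocks.append(("flat", c, flat, off))
            blocks.append(("fist", c, fist, off))
    elif protocol_id == "D":
        for c in range(cycles):
            for a in BLOCK_ANGLES:
                pose = np.tile(
                    np.minimum(a, _pose_angles(truths, 1.0)), (hold_n, 1)
                )
                blocks.append((f"block_{a:g}", c, pose, zero_off))
    elif protocol_id == "E":
        limits = _pose_angles(truths, 1.0)
        up = np.linspace(0, 1, ramp_n)[:, None] * limits
        hold = np.tile(limits, (int(rate), 1))  # 1 s at maximum
        down = np.linspace(1, 0, ramp_n)[:, None] * limits
        for c in range(cycles):
            blocks.append(("ramp_up", c, up, zero_off))
            blocks.append(("max", c, hold, zero_off))
            blocks.append(("ramp_down", c, down, zero_off))

    segments, raw_parts, ang_parts = [], [], []
    pos = 0
    for label, cyc, traj, off in blocks:
        n = traj.shape[0]
        frame = np.empty((n, n_sens), dtype=np.int64)
        for j, sid in enumerate(sensor_ids):
            frame[:, j] = _raw_values(
                traj[:, j], truths[sid], fit, rng, extra_offset=off[j]
            )
        raw_parts.append(frame)
        ang_parts.append(traj)
        segments.append(Segment(label, cyc, pos, pos + n))
        pos += n

    raw = np.vstack(raw_parts)
    ang = np.vstack(ang_parts)
    time_s = np.arange(raw.shape[0]) / rate
    return Recording(
        protocol_id=protocol_id,
        sensor_ids=sensor_ids,
        time_s=time_s,
        raw=raw,
        true_angles=ang,
        segments=tuple(segments),
        rate=rate,
    )


def save_profiles(path, truths: dict, fit: HandFitProfile) -> None:
    """Persist a sensor bank plus fit profile as JSON keyed by sensor_id."""
    doc = {
        "sensors": {
            s: {
                "r_flat": t.r_flat,
                "gain": t.gain,
                "curvature": t.curvature,
                "noise_sd": t.noise_sd,
                "theta_max": t.theta_max,
            }
            for s, t in truths.items()
        },
        "fit": {
            "hand_size": fit.hand_size,
            "fit_offset": fit.fit_offset,
            "fit_gain_scale": fit.fit_gain_scale,
            "don_doff_sd": fit.don_doff_sd,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_profiles(path) -> tuple[dict, HandFitProfile]:
    with open(path) as fh:
        doc = json.load(fh)
    truths = {
        s: SensorGroundTruth(sensor_id=s, **p) for s, p in doc["sensors"].items()
    }
    f = doc["fit"]
    fit = HandFitProfile(
        hand_size=f["hand_size"],
        fit_offset=f.get("fit_offset", {}),
        fit_gain_scale=f.get("fit_gain_scale", {}),
        don_doff_sd=f.get("don_doff_sd", 0.0),
    )
    return truths, fit
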