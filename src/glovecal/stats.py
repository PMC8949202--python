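"""Repeatability and accuracy statistics, and the NN-vs-linear harness.

Implements the measures used to judge a glove calibration method:
test–retest repeatability (range and SD of per-cycle means), Pearson
correlation against reference angles, Bland–Altman limits of agreement
(mean difference ± 2·SD of paired differences), and mean difference
with a t-based 95% confidence interval for maximum range-of-motion
trials. `run_benchmark` wires these to the simulator: it trains a
table bank per seed and scores both the NN and the linear method over
the requested test protocols.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps

from . import engine, lut, sim
from .bpnn import NetworkConfig, train
from .sim import generate_protocol, generate_training_samples

__all__ = [
    "RepeatabilityResult",
    "AgreementResult",
    "repeatability",
    "pearson_r2",
    "bland_altman",
    "mean_diff_ci",
    "run_benchmark",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class RepeatabilityResult:
    """Spread of per-cycle means: range (max - min) and sample SD."""

    range: float
    sd: float
    n_cycles: int


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between two paired angle sequences."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r2: float
    n: int


def repeatability(cycle_means) -> RepeatabilityResult:
    """Range and sample SD (n-1 denominator) of per-cycle mean angles."""
    x = np.asarray(cycle_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cycles")
    return RepeatabilityResult(
        range=float(x.max() - x.min()),
        sd=float(x.std(ddof=1)),
        n_cycles=int(x.size),
    )


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation (coefficient of determination R^2)."""
    return pearson_r(x, y) ** 2


def bland_altman(a, b) -> AgreementResult:
    """Limits of agreement for paired measurements a and b.

    Differences d = a - b; limits are mean(d) ± 2·SD(d) (sample SD).
    The attached r^2 is the squared correlation of a with b when both
    vary, else NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r2 = pearson_r2(a, b)
    except ValueError:
        r2 = float("nan")
    return AgreementResult(
        mean_diff=md,
        sd_diff=sd,
        loa_low=md - 2 * sd,
        loa_high=md + 2 * sd,
        r2=r2,
        n=int(a.size),
    )


def mean_diff_ci(measurements, expected: float, confidence: float = 0.95):
    """Mean, mean difference from an expected value, and t-based CI.

    Returns ``(mean, mean_diff, ci_low, ci_high)`` where the CI is
    mean ± t_{(1+confidence)/2, n-1} · sd / sqrt(n). The t distribution
    is used because maximum-flexion trials are few (typically n = 12).
    """
    x = np.asarray(measurements, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 measurements")
    m = float(x.mean())
    half = float(
        sps.t.ppf((1 + confidence) / 2, x.size - 1)
        * x.std(ddof=1) / np.sqrt(x.size)
    )
    return m, m - expected, m - half, m + half


def bland_altman_plot(a, b, ax=None):
    """Bland–Altman chart: per-pair mean vs difference with LoA lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=12)
    ax.axhline(res.mean_diff, color="tab:blue", label="mean difference")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="gray", linestyle=":")
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("difference (deg)")
    return ax


# ---------------------------------------------------------------------------
# Benchmark harness

DEFAULT_SCENARIO = {
    "protocols": ["A", "D"],
    "hand_sizes": [7.0],
    "curvature": 3.0,
    "noise_sd": 4.0,
    "thumb_noise_scale": 3.0,
    "don_doff_sd": 0.0,
    "cycles": None,
    "epochs": 100_000,
    "sensors": None,          # None -> all ten
    "refresh_flat_hand": True,
    "hold_s": 5.0,
}


def _fit_and_tables(scn, hand_size, seed):
    """Train one table bank and linear calibration for a (seed, hand)."""
    bank = sim.default_sensor_bank(
        curvature=scn["curvature"],
        noise_sd=scn["noise_sd"],
        thumb_noise_scale=scn["thumb_noise_scale"],
    )
    if scn["sensors"]:
        bank = {s: bank[s] for s in scn["sensors"]}
    fit = sim.HandFitProfile.for_hand_size(
        hand_size, seed=seed, don_doff_sd=scn["don_doff_sd"]
    )
    tables = {}
    for j, (sid, truth) in enumerate(bank.items()):
        ts = generate_training_samples(truth, fit)   # static poses: noiseless
        cfg = NetworkConfig(seed=seed * 1009 + j, epochs=scn["epochs"])
        net = train(ts, cfg)
        arr = lut.build_solution_array(int(ts.raws[0]), sensor_id=sid)
        lut.predict_angles(net, arr)
        lut.smooth(arr, truth.theta_max)
        tables[sid] = lut.normalize(arr, hand_size=hand_size)
    # two-pose linear calibration from a one-cycle flat/fist recording
    calib_rec = generate_protocol(
        "B", bank, fit, cycles=1, seed=seed + 7919, hold_s=scn["hold_s"]
    )
    state = engine.calibrate_linear(calib_rec, calib_rec)
    flat_hand = engine.capture_flat_hand(calib_rec)
    return bank, fit, tables, state, flat_hand


def _score_protocol(rec, tables, state, flat_hand, refresh):
    out = {}
    for method in ("nn", "linear"):
        kwargs = {"tables": tables} if method == "nn" else {"state": state}
        if method == "nn" and refresh:
            kwargs["flat_hand"] = flat_hand
        _, seg = engine.process_recording(rec, method, **kwargs)
        per_sensor = {}
        if rec.protocol_id in ("A", "B", "C"):
            flat = seg[seg.segment == "flat"]
            for sid, grp in flat.groupby("sensor_id"):
                per_sensor[sid] = asdict(repeatability(grp.mean_deg.values))
        elif rec.protocol_id == "D":
            blocks = seg[seg.segment.str.startswith("block_")]
            for sid, grp in blocks.groupby("sensor_id"):
                meas = grp.mean_deg.values
                true = grp.true_mean_deg.values
                ba = bland_altman(meas, true)
                per_sensor[sid] = {
                    "mae": float(np.mean(np.abs(meas - true))),
                    "r": pearson_r(meas, true),
                    "r2": pearson_r2(meas, true),
                    **asdict(ba),
                }
        elif rec.protocol_id == "E":
            hold = seg[seg.segment == "max"]
            for sid, grp in hold.groupby("sensor_id"):
                expected = float(grp.true_mean_deg.mean())
                m, md, lo, hi = mean_diff_ci(grp.mean_deg.values, expected)
                per_sensor[sid] = {
                    "mean_max_rom": m,
                    "mean_diff": md,
                    "ci_low": lo,
                    "ci_high": hi,
                }
        out[method] = per_sensor
    return out


def run_benchmark(scenario: dict | None = None, seeds=20) -> dict:
    """Compare the NN and linear methods over simulated test protocols.

    Parameters
    ----------
    scenario : dict
        Overrides for `DEFAULT_SCENARIO`: protocols (subset of A–E),
        hand sizes, sensor curvature/noise, donning drift, training
        epoch budget, sensor subset, and whether the NN method
        re-captures the flat-hand reading per run.
    seeds : int or sequence of int
        Replicate seeds; an integer n means seeds 0..n-1.

    Returns
    -------
    dict with one entry per (protocol, hand_size, seed) of per-sensor,
    per-method statistics, JSON-serializable.
    """
    scn = dict(DEFAULT_SCENARIO)
    unknown = set(scenario or {}) - set(scn)
    if unknown:
        raise KeyError(f"unknown scenario keys: {sorted(unknown)}")
    scn.update(scenario or {})
    seed_list = list(range(seeds)) if isinstance(seeds, int) else list(seeds)
    runs = []
    for hand_size in scn["hand_sizes"]:
        for seed in seed_list:
            bank, fit, tables, state, flat_hand = _fit_and_tables(
                scn, hand_size, seed
            )
            for pid in scn["protocols"]:
                rec = generate_protocol(
                    pid, bank, fit,
                    cycles=scn["cycles"],
                    seed=seed * 31 + ord(pid),
                    hold_s=scn["hold_s"],
                )
                runs.append(
                    {
                        "protocol": pid,
                        "hand_size": hand_size,
                        "seed": seed,
                        "methods": _score_protocol(
                            rec, tables, state, flat_hand,
                            scn["refresh_flat_hand"],
                        ),
                    }
                )
    return {"scenario": scn, "seeds": seed_list, "runs": runs}


def summarize_benchmark(report: dict) -> dict:
    """Seed-averaged per-(protocol, method) summary of a benchmark report."""
    agg: dict[tuple, list] = {}
    for run in report["runs"]:
        for method, sensors in run["methods"].items():
            for sid, stats_d in sensors.items():
                for key, val in stats_d.items():
                    agg.setdefault((run["protocol"], method, key), []).append(val)
    return {
        f"{p}.{m}.{k}": float(np.mean(v))
        for (p, m, k), v in sorted(agg.items())
        if np.all(np.isfinite(v))
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
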