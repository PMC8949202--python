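"""Model/Results interface over the calibration pipeline.

`SensorCalibration` is constructed from calibration sample data for one
sensor; `fit()` trains the network, builds the smoothed lookup table,
and returns a `SensorCalibrationResults` carrying the estimates,
training diagnostics and a text `summary()`. `GloveCalibration` does
the same for a whole 10-sensor bank.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import lut
from .bpnn import NetworkConfig, TrainingSet, select_sample_subset, train

__all__ = ["SensorCalibration", "SensorCalibrationResults", "GloveCalibration"]


class SensorCalibration:
    """Network calibration model for a single glove sensor.

    Parameters
    ----------
    raws, angles : array-like
        Calibration sample points: 12-bit readings and the reference
        joint angles (degrees) they were captured at; the first sample
        must be the flat-hand 0-degree pose.
    sensor_id : str
        Joint label, e.g. ``"index_mcp"``; sets the joint limit.
    hand_size : float
        Glove hand size in inches the samples were captured for.
    config : NetworkConfig, optional
        Network hyperparameters; defaults follow the study conditions.
    """

    def __init__(self, raws, angles, sensor_id, hand_size=7.75, config=None):
        self.data = TrainingSet(
            sensor_id=sensor_id, hand_size=hand_size, raws=raws, angles=angles
        )
        self.config = config or NetworkConfig()

    @classmethod
    def from_training_set(cls, training: TrainingSet, config=None):
        m = cls.__new__(cls)
        m.data = training
        m.config = config or NetworkConfig()
        return m

    @classmethod
    def from_samples_csv(cls, path, sensor_id, hand_size=7.75, config=None):
        return cls.from_training_set(
            TrainingSet.from_csv(path, sensor_id, hand_size), config
        )

    @classmethod
    def from_simulation(cls, truth, fit=None, angle_grid=None, seed=0,
                        config=None):
        from .sim import generate_training_samples

        return cls.from_training_set(
            generate_training_samples(truth, fit, angle_grid, seed), config
        )

    def fit(self, subset_search: bool = False, epochs: int | None = None,
            backend: str = "numba") -> "SensorCalibrationResults":
        """Train the network and build the sensor's lookup table.

        With ``subset_search=True`` a leave-one-sample-out search (at
        the reduced ``config.subset_epochs`` budget) first picks the
        sample subset with the lowest MSE; the winner is then retrained
        at the full epoch budget.
        """
        training = self.data
        report = None
        if subset_search:
            training, report = select_sample_subset(
                training, self.config, backend=backend
            )
        net = train(training, self.config, backend=backend, epochs=epochs)
        flat = int(training.raws[0])
        arr = lut.build_solution_array(flat, sensor_id=training.sensor_id)
        lut.predict_angles(net, arr)
        theta_max = training.theta_max
        lut.smooth(arr, theta_max)
        table = lut.normalize(
            arr,
            hand_size=training.hand_size,
            provenance={
                "best_mse": net.best_mse,
                "grid": training.angles.tolist(),
                "seed": self.config.seed,
            },
        )
        return SensorCalibrationResults(self, training, net, table, report)


class SensorCalibrationResults:
    """Fitted calibration for one sensor."""

    def __init__(self, model, training, network, table, subset_report=None):
        self.model = model
        self.training = training
        self.network = network
        self.table = table
        self.subset_report = subset_report

    @property
    def best_mse(self) -> float:
        """Lowest per-epoch MSE reached (normalized scale)."""
        return self.network.best_mse

    @property
    def best_epoch(self) -> int:
        return self.network.best_epoch

    @property
    def fittedvalues(self) -> np.ndarray:
        """Table angles at the training raws (degrees)."""
        keys = np.clip(
            self.training.raws - self.table.flat_hand_raw,
            0, len(self.table) - 1,
        )
        return self.table.angles[keys]

    @property
    def resid(self) -> np.ndarray:
        """Training-point residuals, degrees (fitted - target)."""
        return self.fittedvalues - self.training.angles

    def predict(self, raws) -> np.ndarray:
        """Lookup-table angle for raw reading(s)."""
        raws = np.atleast_1d(np.asarray(raws, dtype=np.int64))
        keys = np.clip(
            raws - self.table.flat_hand_raw, 0, len(self.table) - 1
        )
        return self.table.angles[keys]

    def summary(self) -> str:
        t = self.training
        lines = [
            "Sensor calibration (back-propagation network)",
            "=" * 52,
            f"sensor:            {t.sensor_id}",
            f"hand size:         {t.hand_size} in",
            f"training samples:  {len(t)}",
            f"joint limit:       {t.theta_max:g} deg",
            f"flat-hand raw:     {self.table.flat_hand_raw}",
            f"table length:      {len(self.table)}",
            f"best epoch:        {self.best_epoch}",
            f"best MSE:          {self.best_mse:.3e}",
            f"max |residual|:    {np.abs(self.resid).max():.2f} deg",
            f"table monotone:    {self.table.is_monotone(tol=1e-9)}",
            "-" * 52,
            "  raw    target(deg)  fitted(deg)  resid(deg)",
        ]
        for r, a, f in zip(t.raws, t.angles, self.fittedvalues):
            lines.append(f"  {r:5d}  {a:10.1f}  {f:11.2f}  {f - a:9.2f}")
        return "\n".join(lines)

    def save(self, net_path=None, table_path=None) -> None:
        if net_path:
            self.network.to_json(net_path)
        if table_path:
            lut.save_table(self.table, table_path)


class GloveCalibration:
    """Calibration model for a whole sensor bank (one or more hand sizes)."""

    def __init__(self, training_sets: dict, config: NetworkConfig | None = None):
        """``training_sets`` maps sensor_id -> TrainingSet."""
        self.training_sets = dict(training_sets)
        self.config = config or NetworkConfig()

    @classmethod
    def from_simulation(cls, truths: dict, fit=None, seed=0, config=None):
        from .sim import generate_training_samples

        return cls(
            {
                sid: generate_training_samples(t, fit, seed=seed)
                for sid, t in truths.items()
            },
            config,
        )

    def fit(self, epochs: int | None = None, backend: str = "numba",
            subset_search: bool = False) -> "GloveCalibrationResults":
        results = {}
        for j, (sid, ts) in enumerate(self.training_sets.items()):
            cfg = replace(self.config, seed=self.config.seed * 1009 + j)
            results[sid] = SensorCalibration.from_training_set(ts, cfg).fit(
                epochs=epochs, backend=backend, subset_search=subset_search
            )
        return GloveCalibrationResults(self, results)


class GloveCalibrationResults:
    def __init__(self, model, per_sensor: dict):
        self.model = model
        self.per_sensor = per_sensor

    def __getitem__(self, sensor_id) -> SensorCalibrationResults:
        return self.per_sensor[sensor_id]

    @property
    def tables(self) -> lut.TableBank:
        bank = lut.TableBank()
        for res in self.per_sensor.values():
            bank.add(res.table)
        return bank

    def summary(self) -> str:
        lines = [
            "Glove calibration bank",
            "=" * 64,
            "sensor         hand  n  flat_raw  table  best MSE   max|res|",
        ]
        for sid, r in self.per_sensor.items():
            t = r.training
            lines.append(
                f"{sid:<13} {t.hand_size:>5} {len(t):>2} {r.table.flat_hand_raw:>9}"
                f" {len(r.table):>6}  {r.best_mse:.2e}  {np.abs(r.resid).max():7.2f}"
            )
        return "\n".join(lines)
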