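"""Per-sensor back-propagation network.

Each glove sensor gets its own small feed-forward network (1 input node
for the raw reading, 7 hidden sigmoid nodes, 2 sigmoid outputs: one
echoes the normalized raw value, one carries the joint angle). The
network is trained by batch gradient descent with momentum on a handful
of calibration sample points, and the weights of the epoch with the
lowest mean-squared error are kept — not the final epoch's.

Normalization: the raw input is min–max scaled over the training raws,
and both targets are mapped into the window [0.1, 0.9] of the sigmoid's
range. Sigmoid outputs approach 0 and 1 only asymptotically (the
derivative vanishes there), so placing the 0-degree and full-flexion
targets strictly inside the range is what lets gradient descent reach
them; predictions are mapped back through the inverse affine transform.

The epoch loop exists in two interchangeable implementations: a
numba-compiled one (default) and a plain-numpy one used as a reference
in tests and as a fallback. The gradient of the epoch loss
E = 1/2 * sum over samples and outputs of (output - target)^2
is also exposed standalone (`loss_and_grads`) so it can be verified
against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sensors import RAW_MAX, theta_max_for

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "NetworkConfig",
    "TrainingSet",
    "TrainedNetwork",
    "mse",
    "init_network",
    "forward",
    "train",
    "loss_and_grads",
    "select_sample_subset",
]

#: Target window inside the sigmoid's (0, 1) range.
TARGET_LO = 0.1
TARGET_HI = 0.9

#: Divergence guard: abort if epoch MSE exceeds this multiple of the
#: first epoch's MSE.
DIVERGENCE_FACTOR = 10.0


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def mse(predicted, target) -> float:
    """Mean squared difference of two equal-length sequences."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty sequences")
    return float(np.mean((p - t) ** 2))


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one sensor network.

    Defaults follow the study conditions: 7 hidden nodes, two outputs,
    learning rate and momentum 0.1, 100,000 epochs.
    """

    n_inputs: int = 1
    n_hidden: int = 7
    n_outputs: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.1
    epochs: int = 100_000
    seed: int = 0
    raw_scale: float = float(RAW_MAX)
    angle_scale: float | None = None  # None -> joint limit of the sensor
    input_scaling: str = "minmax"     # "minmax" | "fixed" (raw / raw_scale)
    update: str = "batch"             # "batch" | "online"
    subset_epochs: int = 10_000
    target_lo: float = TARGET_LO
    target_hi: float = TARGET_HI

    def __post_init__(self):
        if min(self.n_inputs, self.n_hidden, self.n_outputs) <= 0:
            raise ValueError("layer sizes must be positive")
        if not (0 < self.learning_rate <= 1) or not (0 <= self.momentum <= 1):
            raise ValueError("learning_rate in (0,1], momentum in [0,1]")
        if self.epochs < 1 or self.subset_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_scaling not in ("minmax", "fixed"):
            raise ValueError("input_scaling must be 'minmax' or 'fixed'")
        if self.update not in ("batch", "online"):
            raise ValueError("update must be 'batch' or 'online'")
        if not (0 <= self.target_lo < self.target_hi <= 1):
            raise ValueError("need 0 <= target_lo < target_hi <= 1")


@dataclass(frozen=True)
class TrainingSet:
    """Ordered (raw, angle) calibration sample points for one sensor."""

    sensor_id: str
    hand_size: float
    raws: np.ndarray
    angles: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "raws", np.asarray(self.raws, dtype=np.int64))
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if self.raws.shape != self.angles.shape or self.raws.ndim != 1:
            raise ValueError("raws and angles must be equal-length 1-d arrays")
        if self.raws.size == 0:
            raise ValueError("empty training set")
        if self.angles[0] != 0:
            raise ValueError("first sample must be the 0-degree (flat hand) pose")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(np.diff(self.raws) < 0):
            raise ValueError("raws must be non-decreasing")

    def __len__(self) -> int:
        return self.raws.size

    @property
    def theta_max(self) -> float:
        return theta_max_for(self.sensor_id)

    def subset(self, keep: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            sensor_id=self.sensor_id,
            hand_size=self.hand_size,
            raws=self.raws[keep],
            angles=self.angles[keep],
        )

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.raws, self.angles]),
            fmt=("%d", "%.4f"),
            delimiter=",",
            header=f"raw,angle_deg sensor={self.sensor_id} hand={self.hand_size}",
        )

    @classmethod
    def from_csv(cls, path, sensor_id: str, hand_size: float = 7.75):
        data = np.loadtxt(path, delimiter=",")
        data = np.atleast_2d(data)
        return cls(
            sensor_id=sensor_id,
            hand_size=hand_size,
            raws=data[:, 0],
            angles=data[:, 1],
        )


@dataclass
class TrainedNetwork:
    """Weights of the best epoch plus the training trace."""

    config: NetworkConfig
    sensor_id: str
    w1: np.ndarray            # (n_inputs, n_hidden)
    b1: np.ndarray            # (n_hidden,)
    w2: np.ndarray            # (n_hidden, n_outputs)
    b2: np.ndarray            # (n_outputs,)
    input_min: float = 0.0
    input_max: float = float(RAW_MAX)
    angle_scale: float = 95.0
    best_epoch: int = -1
    best_mse: float = float("inf")
    mse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def _scale_input(self, raw) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        span = self.input_max - self.input_min
        return (raw - self.input_min) / (span if span > 0 else 1.0)

    def forward_normalized(self, raw):
        """Sigmoid outputs (echoed raw, angle) on the [0, 1] scale."""
        raw = np.asarray(raw)
        if np.any((raw < 0) | (raw > RAW_MAX)):
            raise ValueError(f"raw must be in [0, {RAW_MAX}]")
        x = np.atleast_1d(self._scale_input(raw))[:, None]
        a1 = sigmoid(x @ self.w1 + self.b1)
        return sigmoid(a1 @ self.w2 + self.b2)

    def predict_angle(self, raw):
        """Angle in degrees for raw reading(s); may exceed [0, theta_max]
        near the ends of the raw range — clamping is the table builder's job."""
        a2 = self.forward_normalized(raw)
        lo, hi = self.config.target_lo, self.config.target_hi
        ang = (a2[:, -1] - lo) / (hi - lo) * self.angle_scale
        return ang if np.asarray(raw).ndim else float(ang[0])

    def to_json(self, path=None, trace_thin: int = 100):
        doc = {
            "schema": "glovecal.net/1",
            "sensor_id": self.sensor_id,
            "layer_sizes": [
                self.config.n_inputs, self.config.n_hidden, self.config.n_outputs
            ],
            "w1": self.w1.ravel().tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.ravel().tolist(),
            "b2": self.b2.tolist(),
            "input_min": self.input_min,
            "input_max": self.input_max,
            "angle_scale": self.angle_scale,
            "best_epoch": int(self.best_epoch),
            "best_mse": float(self.best_mse),
            "mse_trace_thin": trace_thin,
            "mse_trace": self.mse_trace[::trace_thin].tolist(),
            "config": {
                "learning_rate": self.config.learning_rate,
                "momentum": self.config.momentum,
                "epochs": self.config.epochs,
                "seed": self.config.seed,
                "input_scaling": self.config.input_scaling,
                "update": self.config.update,
                "target_lo": self.config.target_lo,
                "target_hi": self.config.target_hi,
            },
        }
        if path is None:
            return doc
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path_or_doc):
        if isinstance(path_or_doc, dict):
            doc = path_or_doc
        else:
            with open(path_or_doc) as fh:
                doc = json.load(fh)
        if doc.get("schema") != "glovecal.net/1":
            raise ValueError("unrecognized network file schema")
        ni, nh, no = doc["layer_sizes"]
        cfg = NetworkConfig(
            n_inputs=ni, n_hidden=nh, n_outputs=no, **doc["config"]
        )
        return cls(
            config=cfg,
            sensor_id=doc["sensor_id"],
            w1=np.array(doc["w1"]).reshape(ni, nh),
            b1=np.array(doc["b1"]),
            w2=np.array(doc["w2"]).reshape(nh, no),
            b2=np.array(doc["b2"]),
            input_min=doc["input_min"],
            input_max=doc["input_max"],
            angle_scale=doc["angle_scale"],
            best_epoch=doc["best_epoch"],
            best_mse=doc["best_mse"],
            mse_trace=np.array(doc["mse_trace"]),
        )


def init_network(config: NetworkConfig, sensor_id: str = "") -> TrainedNetwork:
    """Untrained network with small random weights, uniform on [-0.5, 0.5]."""
    rng = np.random.default_rng(config.seed)
    return TrainedNetwork(
        config=config,
        sensor_id=sensor_id,
        w1=rng.uniform(-0.5, 0.5, (config.n_inputs, config.n_hidden)),
        b1=rng.uniform(-0.5, 0.5, config.n_hidden),
        w2=rng.uniform(-0.5, 0.5, (config.n_hidden, config.n_outputs)),
        b2=rng.uniform(-0.5, 0.5, config.n_outputs),
    )


def forward(net: TrainedNetwork, raw):
    """Normalized network outputs for a raw reading (spec-level entry point)."""
    return net.forward_normalized(raw)


def loss_and_grads(w1, b1, w2, b2, X, T):
    """Epoch loss E = 1/2 sum (a2 - T)^2 and its analytic gradients.

    This is exactly the gradient the training loops apply; kept separate
    so it can be checked against central finite differences.
    """
    a1 = sigmoid(X @ w1 + b1)
    a2 = sigmoid(a1 @ w2 + b2)
    err = a2 - T
    loss = 0.5 * float(np.sum(err**2))
    d2 = err * a2 * (1.0 - a2)
    gw2 = a1.T @ d2
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ w2.T) * a1 * (1.0 - a1)
    gw1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return loss, gw1, gb1, gw2, gb2


@njit(cache=True)
def _train_loop_nb(X, T, w1, b1, w2, b2, epochs, lr, mom):  # pragma: no cover
    n = X.shape[0]
    ni = w1.shape[0]
    nh = w1.shape[1]
    no = w2.shape[1]
    dw1 = np.zeros_like(w1)
    db1 = np.zeros_like(b1)
    dw2 = np.zeros_like(w2)
    db2 = np.zeros_like(b2)
    bw1 = w1.copy()
    bb1 = b1.copy()
    bw2 = w2.copy()
    bb2 = b2.copy()
    best = 1e300
    best_ep = -1
    trace = np.empty(epochs)
    status = 0
    n_done = 0
    for ep in range(epochs):
        gw1 = np.zeros_like(w1)
        gb1 = np.zeros_like(b1)
        gw2 = np.zeros_like(w2)
        gb2 = np.zeros_like(b2)
        sse = 0.0
        for s in range(n):
            a1 = np.empty(nh)
            for h in range(nh):
                z = b1[h]
                for i in range(ni):
                    z += w1[i, h] * X[s, i]
                a1[h] = 1.0 / (1.0 + np.exp(-z))
            a2 = np.empty(no)
            d2 = np.empty(no)
            for o in range(no):
                z = b2[o]
                for h in range(nh):
                    z += w2[h, o] * a1[h]
                a2[o] = 1.0 / (1.0 + np.exp(-z))
                e = a2[o] - T[s, o]
                sse += e * e
                d2[o] = e * a2[o] * (1.0 - a2[o])
                gb2[o] += d2[o]
                for h in range(nh):
                    gw2[h, o] += a1[h] * d2[o]
            for h in range(nh):
                dh = 0.0
                for o in range(no):
                    dh += d2[o] * w2[h, o]
                dh *= a1[h] * (1.0 - a1[h])
                gb1[h] += dh
                for i in range(ni):
                    gw1[i, h] += X[s, i] * dh
        ep_mse = sse / (n * no)
        trace[ep] = ep_mse
        n_done = ep + 1
        if not np.isfinite(ep_mse):
            status = 2
            break
        if ep > 0 and ep_mse > DIVERGENCE_FACTOR * trace[0]:
            status = 1
            break
        if ep_mse < best:
            best = ep_mse
            best_ep = ep
            bw1[:] = w1
            bb1[:] = b1
            bw2[:] = w2
            bb2[:] = b2
        for h in range(nh):
            for i in range(ni):
                dw1[i, h] = -lr * gw1[i, h] + mom * dw1[i, h]
                w1[i, h] += dw1[i, h]
            db1[h] = -lr * gb1[h] + mom * db1[h]
            b1[h] += db1[h]
            for o in range(no):
                dw2[h, o] = -lr * gw2[h, o] + mom * dw2[h, o]
                w2[h, o] += dw2[h, o]
        for o in range(no):
            db2[o] = -lr * gb2[o] + mom * db2[o]
            b2[o] += db2[o]
    return bw1, bb1, bw2, bb2, best, best_ep, trace[:n_done], status


def _train_loop_np(X, T, w1, b1, w2, b2, epochs, lr, mom, online=False):
    """Reference epoch loop in plain numpy (identical update rule)."""
    dw1 = np.zeros_like(w1)
    db1 = np.zeros_like(b1)
    dw2 = np.zeros_like(w2)
    db2 = np.zeros_like(b2)
    best = np.inf
    best_ep = -1
    bw = None
    trace = np.empty(epochs)
    status = 0
    n_done = 0
    n, no = T.shape
    for ep in range(epochs):
        if online:
            sse = 0.0
            for s in range(n):
                loss, gw1, gb1, gw2, gb2 = loss_and_grads(
                    w1, b1, w2, b2, X[s:s + 1], T[s:s + 1]
                )
                sse += 2.0 * loss
                dw1 = -lr * gw1 + mom * dw1
                db1 = -lr * gb1 + mom * db1
                dw2 = -lr * gw2 + mom * dw2
                db2 = -lr * gb2 + mom * db2
                w1 = w1 + dw1
                b1 = b1 + db1
                w2 = w2 + dw2
                b2 = b2 + db2
            ep_mse = sse / (n * no)
        else:
            loss, gw1, gb1, gw2, gb2 = loss_and_grads(w1, b1, w2, b2, X, T)
            ep_mse = 2.0 * loss / (n * no)
        trace[ep] = ep_mse
        n_done = ep + 1
        if not np.isfinite(ep_mse):
            status = 2
            break
        if ep > 0 and ep_mse > DIVERGENCE_FACTOR * trace[0]:
            status = 1
            break
        if ep_mse < best:
            best = ep_mse
            best_ep = ep
            bw = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
        if not online:
            dw1 = -lr * gw1 + mom * dw1
            db1 = -lr * gb1 + mom * db1
            dw2 = -lr * gw2 + mom * dw2
            db2 = -lr * gb2 + mom * db2
            w1 = w1 + dw1
            b1 = b1 + db1
            w2 = w2 + dw2
            b2 = b2 + db2
    if bw is None:
        bw = (w1, b1, w2, b2)
    return (*bw, best, best_ep, trace[:n_done], status)


def _prepare(training: TrainingSet, config: NetworkConfig):
    raws = training.raws.astype(float)
    if config.input_scaling == "minmax":
        r0, r1 = float(raws.min()), float(raws.max())
        if r1 <= r0:
            raise ValueError("degenerate training raws: no raw-value spread")
    else:
        r0, r1 = 0.0, config.raw_scale
    x = (raws - r0) / (r1 - r0)
    angle_scale = (
        config.angle_scale if config.angle_scale is not None
        else training.theta_max
    )
    lo, hi = config.target_lo, config.target_hi
    t_echo = lo + (hi - lo) * x
    t_ang = lo + (hi - lo) * training.angles / angle_scale
    X = x[:, None]
    if config.n_outputs == 2:
        T = np.column_stack([t_echo, t_ang])
    elif config.n_outputs == 1:
        T = t_ang[:, None]
    else:
        raise ValueError("n_outputs must be 1 or 2")
    return X, T, r0, r1, angle_scale


def train(
    training: TrainingSet,
    config: NetworkConfig | None = None,
    backend: str = "numba",
    epochs: int | None = None,
) -> TrainedNetwork:
    """Train one sensor network and return the best-epoch weights.

    Per epoch every sample is presented; with ``config.update='batch'``
    (default) gradients are accumulated over the whole set before the
    single momentum update Δw(t) = -lr·∂E/∂w + momentum·Δw(t-1).
    The recorded epoch MSE is the mean over samples and outputs of the
    squared output error; the weights returned are those of the
    earliest epoch attaining the minimum MSE.
    """
    config = config or NetworkConfig()
    if len(training) < 2:
        raise ValueError("need at least 2 training samples")
    n_epochs = epochs if epochs is not None else config.epochs
    X, T, r0, r1, angle_scale = _prepare(training, config)
    net = init_network(config, sensor_id=training.sensor_id)
    w1, b1, w2, b2 = (a.copy() for a in (net.w1, net.b1, net.w2, net.b2))
    if backend == "numba" and _HAVE_NUMBA and config.update == "batch":
        out = _train_loop_nb(
            X, T, w1, b1, w2, b2, n_epochs,
            config.learning_rate, config.momentum,
        )
    elif backend in ("numba", "numpy"):
        out = _train_loop_np(
            X, T, w1, b1, w2, b2, n_epochs,
            config.learning_rate, config.momentum,
            online=(config.update == "online"),
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")
    bw1, bb1, bw2, bb2, best, best_ep, trace, status = out
    if status == 2:
        raise RuntimeError(
            f"training diverged to non-finite MSE at epoch {len(trace) - 1} "
            f"for sensor {training.sensor_id!r}"
        )
    if status == 1:
        raise RuntimeError(
            f"training diverged (MSE > {DIVERGENCE_FACTOR}x initial) at epoch "
            f"{len(trace) - 1} for sensor {training.sensor_id!r}"
        )
    return TrainedNetwork(
        config=config,
        sensor_id=training.sensor_id,
        w1=bw1, b1=bb1, w2=bw2, b2=bb2,
        input_min=r0, input_max=r1,
        angle_scale=angle_scale,
        best_epoch=int(best_ep),
        best_mse=float(best),
        mse_trace=np.asarray(trace),
    )


def select_sample_subset(
    training: TrainingSet,
    config: NetworkConfig | None = None,
    backend: str = "numba",
):
    """Leave-one-sample-out search for the lowest-MSE training subset.

    Trains once on the full set and once per leave-one-out subset
    (the 0-degree sample is never removed — it anchors the minimum
    angle), each at ``config.subset_epochs``. Returns the winning
    subset and the per-candidate report; ties go to the larger subset.
    """
    config = config or NetworkConfig()
    if len(training) < 3:
        raise ValueError("need at least 3 samples for a subset search")
    n = len(training)
    candidates: list[tuple[float | None, np.ndarray]] = [(None, np.arange(n))]
    for i in range(n):
        if training.angles[i] == 0:
            continue
        candidates.append(
            (float(training.angles[i]), np.delete(np.arange(n), i))
        )
    report = []
    best_i = 0
    best_mse_val = np.inf
    best_set = training
    for idx, (removed, keep) in enumerate(candidates):
        sub = training.subset(keep)
        net = train(sub, config, backend=backend, epochs=config.subset_epochs)
        report.append(
            {
                "removed_angle": removed,
                "n_samples": len(sub),
                "best_mse": net.best_mse,
            }
        )
        # strict < : the full set (listed first, largest) wins ties
        if net.best_mse < best_mse_val:
            best_mse_val = net.best_mse
            best_i = idx
            best_set = sub
    report[best_i]["selected"] = True
    return best_set, report
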