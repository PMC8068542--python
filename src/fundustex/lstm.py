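"""A gated recurrent sequence regressor, written directly in NumPy.

One standard four-gate LSTM layer (forget f, input i, output o, candidate
C-bar) followed by a single biased linear output neuron predicts a
segment's symptom score rho from the raw benchmark-correlation signals of
nearby segments:

    f_t = sigmoid(W_f^x x_t + W_f^h h_{t-1} + b_f)      (and likewise i, o)
    C-bar_t = tanh(W_c^x x_t + W_c^h h_{t-1} + b_c)
    C_t = C_{t-1} * f_t + i_t * C-bar_t
    h_t = tanh(C_t) * o_t

Separate input and recurrent weight matrices are used (the general
parameterization); with hidden = 100, per-step input dimension 3 and one
dense output neuron this network has 4*100*(100+3+1) + (100+1) = 41,701
trainable parameters. Training is full-batch-window truncated
backpropagation through time with Adam, hand-derived gradients, and a
fixed seed — runs are bit-reproducible.

Sequence encoding: segments are traversed in raster order; per segment a
raw signal s_t (its feature correlation against the ROI benchmark) is
computed, and the sample for segment t is a look_back-step sequence over
positions p = t-look_back+1 .. t whose step input is the 3-vector
[s_{p-2}, s_{p-1}, s_p], zero-padded before the start of the image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("fundustex")

CHECKPOINT_VERSION = 1


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class LstmCellParams:
    """Gate weights and biases; rows stacked in gate order f, i, o, c."""

    w_x: np.ndarray   # (4H, D) input weights
    w_h: np.ndarray   # (4H, H) recurrent weights
    b: np.ndarray     # (4H,)  gate biases
    hidden: int
    input_dim: int

    def __post_init__(self):
        H, D = self.hidden, self.input_dim
        if self.w_x.shape != (4 * H, D) or self.w_h.shape != (4 * H, H) \
                or self.b.shape != (4 * H,):
            raise ValueError("LSTM parameter shapes inconsistent with "
                             f"hidden={H}, input_dim={D}")
        for arr in (self.w_x, self.w_h, self.b):
            if not np.isfinite(arr).all():
                raise ValueError("LSTM parameters must be finite")


@dataclass
class LstmState:
    """Hidden output h and cell state C (each an H-vector)."""

    h: np.ndarray
    c: np.ndarray


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _split_gates(z, H):
    return z[..., 0:H], z[..., H:2 * H], z[..., 2 * H:3 * H], z[..., 3 * H:4 * H]


def cell_step(params: LstmCellParams, state: LstmState, x: np.ndarray) -> LstmState:
    """One LSTM cell update — the reference (non-batched) forward pass."""
    x = np.asarray(x, dtype=np.float64).ravel()
    h, c = np.asarray(state.h, dtype=np.float64), np.asarray(state.c, dtype=np.float64)
    H = params.hidden
    if x.shape != (params.input_dim,) or h.shape != (H,) or c.shape != (H,):
        raise ValueError("cell_step: input/state shapes inconsistent with params")
    z = params.w_x @ x + params.w_h @ h + params.b
    zf, zi, zo, zc = _split_gates(z, H)
    f, i, o = _sigmoid(zf), _sigmoid(zi), _sigmoid(zo)
    cbar = np.tanh(zc)
    c_new = c * f + i * cbar
    h_new = np.tanh(c_new) * o
    return LstmState(h_new, c_new)


def count_parameters(hidden: int, input_dim: int, dense_out: int = 1) -> int:
    """Trainable parameter count: four gates (input + recurrent weights and
    bias each) plus a biased dense output layer."""
    if hidden < 1 or input_dim < 1 or dense_out < 1:
        raise ValueError("hidden, input_dim and dense_out must all be >= 1")
    return 4 * hidden * (hidden + input_dim + 1) + dense_out * (hidden + 1)


class LstmRegressor:
    """LSTM-plus-dense scalar regressor with seeded initialization."""

    def __init__(self, hidden: int = 100, input_dim: int = 3,
                 look_back: int = 3, seed: int = 0):
        self.hidden = hidden
        self.input_dim = input_dim
        self.look_back = look_back
        self.seed = seed
        self.benchmark: np.ndarray | None = None
        self.scaler = None            # FeatureScaler fitted at training time
        self.trained = False
        rng = np.random.default_rng(seed)
        H, D = hidden, input_dim
        scale_x = 1.0 / np.sqrt(D)
        scale_h = 1.0 / np.sqrt(H)
        self.w_x = rng.normal(0.0, scale_x, size=(4 * H, D))
        self.w_h = rng.normal(0.0, scale_h, size=(4 * H, H))
        self.b = np.zeros(4 * H)
        self.b[0:H] = 1.0  # open forget gate at init
        self.dense_w = rng.normal(0.0, scale_h, size=H)
        self.dense_b = 0.0

    # -- parameter plumbing -------------------------------------------------

    @property
    def cell_params(self) -> LstmCellParams:
        return LstmCellParams(self.w_x, self.w_h, self.b,
                              self.hidden, self.input_dim)

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        return {"w_x": self.w_x, "w_h": self.w_h, "b": self.b,
                "dense_w": self.dense_w,
                "dense_b": np.atleast_1d(np.float64(self.dense_b))}

    def num_parameters(self) -> int:
        """Enumerate the stored weight arrays and count their entries."""
        return int(sum(a.size for a in self.parameter_arrays().values()))

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray):
        """Batched forward over (B, T, D) sequences; returns output and caches."""
        X = np.asarray(X, dtype=np.float64)
        B, T, D = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(T):
            x = X[:, t, :]
            z = x @ self.w_x.T + h @ self.w_h.T + self.b
            zf, zi, zo, zc = _split_gates(z, H)
            f, i, o = _sigmoid(zf), _sigmoid(zi), _sigmoid(zo)
            cbar = np.tanh(zc)
            c_new = c * f + i * cbar
            tanh_c = np.tanh(c_new)
            h_new = tanh_c * o
            caches.append((x, h, c, f, i, o, cbar, tanh_c))
            h, c = h_new, c_new
        y = h @ self.dense_w + self.dense_b
        return y, h, caches

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Predicted rho per sequence sample, clamped to [-1, 1]."""
        y, _, _ = self._forward(np.asarray(X, dtype=np.float64))
        return np.clip(y, -1.0, 1.0) if clamp else y

    def score_grid(self, grid) -> np.ndarray:
        """One predicted rho per segment of a feature-encoded grid.

        Raw signals are the segment-vs-benchmark correlations; the model
        must carry its training benchmark.
        """
        from .segments import score_grid_correlation

        if not self.trained:
            raise RuntimeError("model is untrained; train or load a checkpoint")
        if self.benchmark is None:
            raise RuntimeError("model carries no ROI benchmark vector")
        signals = score_grid_correlation(grid, self.benchmark, self.scaler)
        X = build_sequences(signals, self.look_back, for_training=False)
        return self.predict(X)

    # -- training -----------------------------------------------------------

    def _backward(self, X, targets, y, h_T, caches):
        """Hand-derived BPTT gradients of mean squared error."""
        B, T, D = X.shape
        H = self.hidden
        grads = {"w_x": np.zeros_like(self.w_x),
                 "w_h": np.zeros_like(self.w_h),
                 "b": np.zeros_like(self.b),
                 "dense_w": np.zeros_like(self.dense_w),
                 "dense_b": 0.0}
        dy = 2.0 * (y - targets) / B                     # (B,)
        grads["dense_w"] = h_T.T @ dy
        grads["dense_b"] = float(dy.sum())
        dh = dy[:, None] * self.dense_w[None, :]          # (B, H)
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, f, i, o, cbar, tanh_c = caches[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            df = dc * c_prev
            di = dc * cbar
            dcbar = dc * i
            dzf = df * f * (1.0 - f)
            dzi = di * i * (1.0 - i)
            dzo = do * o * (1.0 - o)
            dzc = dcbar * (1.0 - cbar ** 2)
            dz = np.concatenate([dzf, dzi, dzo, dzc], axis=1)  # (B, 4H)
            grads["w_x"] += dz.T @ x
            grads["w_h"] += dz.T @ h_prev
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.w_h
            dc = dc * f
        return grads

    def save(self, path) -> None:
        """Write a versioned flat checkpoint (named arrays + JSON header)."""
        meta = {"format_version": CHECKPOINT_VERSION, "hidden": self.hidden,
                "input_dim": self.input_dim, "look_back": self.look_back,
                "seed": self.seed, "trained": self.trained}
        arrays = {k: v for k, v in self.parameter_arrays().items()}
        if self.benchmark is not None:
            arrays["benchmark"] = np.asarray(self.benchmark, dtype=np.float64)
        if self.scaler is not None:
            arrays["feat_mean"] = np.asarray(self.scaler.mean, dtype=np.float64)
            arrays["feat_std"] = np.asarray(self.scaler.std, dtype=np.float64)
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "LstmRegressor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format_version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta.get('format_version')}"
                )
            model = cls(hidden=meta["hidden"], input_dim=meta["input_dim"],
                        look_back=meta["look_back"], seed=meta["seed"])
            model.w_x = data["w_x"]
            model.w_h = data["w_h"]
            model.b = data["b"]
            model.dense_w = data["dense_w"]
            model.dense_b = float(data["dense_b"][0])
            model.trained = bool(meta["trained"])
            if "benchmark" in data:
                model.benchmark = data["benchmark"]
            if "feat_mean" in data:
                from .segments import FeatureScaler
                model.scaler = FeatureScaler(data["feat_mean"], data["feat_std"])
        return model


def build_sequences(signals: np.ndarray, look_back: int = 3,
                    for_training: bool = True):
    """Encode a raster-order signal stream into look-back sequence samples.

    Each sample for target position t is a (look_back, 3) array whose step
    p carries [s_{p-2}, s_{p-1}, s_p] with zeros before position 0. For
    training only positions t >= look_back are kept (targets are
    ``signals[t]``); for prediction every position gets a sample.

    Returns (X, targets, positions) in training mode and X otherwise.
    """
    signals = np.asarray(signals, dtype=np.float64).ravel()
    n = signals.size

    def padded(p):
        return signals[p] if 0 <= p < n else 0.0

    def sample(t):
        steps = []
        for p in range(t - look_back + 1, t + 1):
            steps.append([padded(p - 2), padded(p - 1), padded(p)])
        return steps

    if for_training:
        positions = [t for t in range(look_back, n)]
        X = np.array([sample(t) for t in positions]) if positions else \
            np.zeros((0, look_back, 3))
        targets = signals[positions] if positions else np.zeros(0)
        return X, targets, positions
    X = np.array([sample(t) for t in range(n)]) if n else np.zeros((0, look_back, 3))
    return X


def train(model: LstmRegressor, X: np.ndarray, targets: np.ndarray,
          epochs: int = 100, seed: int = 0, learning_rate: float = 1e-3,
          batch_size: int = 32) -> list[float]:
    """Truncated BPTT with Adam; returns the per-epoch RMSE loss trace."""
    X = np.asarray(X, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64).ravel()
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValueError("training requires a non-empty (B, T, D) sample array")
    if X.shape[0] != targets.size:
        raise ValueError("one target per sample sequence is required")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    names = ["w_x", "w_h", "b", "dense_w", "dense_b"]
    m = {k: 0.0 for k in names}
    v = {k: 0.0 for k in names}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[float] = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, tb = X[idx], targets[idx]
            y, h_T, caches = model._forward(xb)
            err = y - tb
            sq_sum += float((err ** 2).sum())
            grads = model._backward(xb, tb, y, h_T, caches)
            step += 1
            for k in names:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * np.asarray(g)
                v[k] = beta2 * v[k] + (1 - beta2) * np.asarray(g) ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                update = learning_rate * mhat / (np.sqrt(vhat) + eps)
                if k == "dense_b":
                    model.dense_b -= float(update)
                else:
                    setattr(model, k, getattr(model, k) - update)
        rmse = float(np.sqrt(sq_sum / n))
        if not np.isfinite(rmse):
            raise DivergenceError(
                "training loss is non-finite; try a smaller learning rate"
            )
        trace.append(rmse)
    model.trained = True
    return trace


def predict_sequence(model: LstmRegressor, grid) -> np.ndarray:
    """Predicted rho per segment of ``grid`` in raster order, in [-1, 1]."""
    return model.score_grid(grid)
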