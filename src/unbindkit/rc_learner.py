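"""Learned linear reaction coordinates via a predictive encoder-decoder.

The reaction coordinate (RC) is the 1-D bottleneck of a small network
trained to predict the feature vector a short lag ahead: a linear encoder
``z = w . x`` followed by a decoder of two ELU layers of width K and a
linear output,

    h     = f(W2 f(W1 z + b1) + b2),      f = ELU
    x_hat = W3 h + b3,

minimising the (bias-reweighted) mean-square prediction error of
``x_{t+dt}``.  Because the encoder is a single inner product, the trained
``w`` is directly interpretable as a linear combination of the input
features; coefficients are reported rescaled to unit maximum magnitude and
rounded to one decimal.

Training data from metadynamics runs is reweighted per source frame with
``exp(beta V(t))`` — valid for short lags, hence the short default lag.
Forward/backward passes and the RMSprop optimiser are implemented directly
in numpy; the network is small enough that full-batch training is both fast
and exactly reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import TimeSeriesTable

__all__ = [
    "RCModel",
    "TrainingRecord",
    "encode",
    "decoder_forward",
    "reweighted_loss",
    "train_rc",
    "make_pairs",
]


# ======================================================================
# Model container
# ======================================================================

@dataclass
class RCModel:
    """Linear encoder coefficients plus decoder parameters and lag."""

    w: np.ndarray                 # (k,)
    W1: np.ndarray                # (K, 1)
    b1: np.ndarray                # (K,)
    W2: np.ndarray                # (K, K)
    b2: np.ndarray                # (K,)
    W3: np.ndarray                # (k, K)
    b3: np.ndarray                # (k,)
    lag: float = 2.0              # time units (ps)
    feature_names: list[str] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.w.size

    @property
    def K(self) -> int:
        return self.b1.size

    def standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return np.asarray(x, float)
        return (np.asarray(x, float) - self.feature_mean) / self.feature_std

    def reported_coefficients(self) -> np.ndarray:
        """w rescaled to unit max magnitude, largest coefficient positive,
        rounded to one decimal (the conventional reporting style)."""
        w = np.asarray(self.w, float)
        imax = int(np.argmax(np.abs(w)))
        scale = np.abs(w[imax])
        if scale == 0:
            raise ValueError("encoder is untrained (w = 0)")
        w = w / scale
        if w[imax] < 0:
            w = -w
        r = np.round(w, 1)
        return np.where(r == 0, 0.0, r)  # canonical zero, never -0.0

    # -- persistence: flat HDF5 container with a JSON header --------------

    def save(self, path: str | Path) -> None:
        import json

        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["header"] = json.dumps(
                {
                    "lag": self.lag,
                    "k": self.k,
                    "K": self.K,
                    "feature_names": self.feature_names,
                    "standardized": self.feature_mean is not None,
                }
            )
            for name in ("w", "W1", "b1", "W2", "b2", "W3", "b3"):
                f.create_dataset(name, data=getattr(self, name))
            if self.feature_mean is not None:
                f.create_dataset("feature_mean", data=self.feature_mean)
                f.create_dataset("feature_std", data=self.feature_std)

    @classmethod
    def load(cls, path: str | Path) -> "RCModel":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            hdr = json.loads(f.attrs["header"])
            kw = {n: f[n][...] for n in ("w", "W1", "b1", "W2", "b2", "W3", "b3")}
            if "feature_mean" in f:
                kw["feature_mean"] = f["feature_mean"][...]
                kw["feature_std"] = f["feature_std"][...]
        return cls(lag=hdr["lag"], feature_names=hdr["feature_names"], **kw)


@dataclass
class TrainingRecord:
    """Per-epoch loss trace with the fractional loss (relative to epoch 1)."""

    losses: np.ndarray
    epochs: int
    learning_rate: float
    seed: int

    @property
    def fractional_loss(self) -> np.ndarray:
        return self.losses / self.losses[0]


# ======================================================================
# Pure forward functions
# ======================================================================

def encode(x: np.ndarray, w: np.ndarray) -> float | np.ndarray:
    """Linear bottleneck z = w . x (rows of x encoded independently)."""
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    if x.shape[-1] != w.size:
        raise ValueError(f"feature length {x.shape[-1]} != len(w) {w.size}")
    z = x @ w
    return float(z) if z.ndim == 0 else z


def _elu(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a, np.expm1(np.clip(a, None, 0.0)))


def _elu_grad(a: np.ndarray, fa: np.ndarray) -> np.ndarray:
    return np.where(a > 0, 1.0, fa + 1.0)


def decoder_forward(z: float | np.ndarray, model: RCModel) -> np.ndarray:
    """Decoder map x_hat = W3 f(W2 f(W1 z + b1) + b2) + b3 with f = ELU."""
    z_arr = np.atleast_1d(np.asarray(z, float))
    a1 = z_arr[:, None] * model.W1[:, 0][None, :] + model.b1[None, :]
    h1 = _elu(a1)
    a2 = h1 @ model.W2.T + model.b2[None, :]
    h2 = _elu(a2)
    out = h2 @ model.W3.T + model.b3[None, :]
    return out[0] if np.ndim(z) == 0 else out


# ======================================================================
# Loss
# ======================================================================

def _bias_weights(bias_at_t: np.ndarray | None, beta: float, n: int) -> np.ndarray:
    if bias_at_t is None:
        v = np.zeros(n)
    else:
        v = np.asarray(bias_at_t, float)
        if v.shape != (n,):
            raise ValueError("one bias value per source frame required")
    a = beta * v
    w = np.exp(a - a.max())
    s = w.sum()
    if s <= 0:
        raise ValueError("all-zero reweighting weights")
    return w / s


def reweighted_loss(
    pairs: tuple[np.ndarray, np.ndarray],
    model: RCModel,
    bias_at_t: np.ndarray | None = None,
    beta: float = 1.0,
) -> float:
    """Bias-reweighted mean-square prediction error over a batch of pairs.

    Per-pair weights are proportional to exp(beta V(t)) of the source frame
    and normalised within the batch; zero bias reduces to the plain MSE.
    """
    x_t, x_lag = (np.atleast_2d(np.asarray(a, float)) for a in pairs)
    if x_t.shape != x_lag.shape:
        raise ValueError("pair arrays must have identical shape")
    wts = _bias_weights(bias_at_t, beta, x_t.shape[0])
    pred = decoder_forward(encode(x_t, model.w), model)
    err = ((np.atleast_2d(pred) - x_lag) ** 2).sum(axis=1)
    return float(wts @ err)


# ======================================================================
# Training
# ======================================================================

def make_pairs(
    table: TimeSeriesTable,
    lag: float,
    feature_columns: list[str],
    bias_column: str | None = "bias",
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(x_t, x_{t+lag}, bias_at_t) built at the given lag from one trajectory."""
    times = table.times
    if times.size < 2:
        raise ValueError("need at least 2 frames")
    dt = times[1] - times[0]
    shift = int(round(lag / dt))
    if shift < 1 or shift >= times.size:
        raise ValueError(f"lag {lag} not representable with frame spacing {dt}")
    x = table.values(feature_columns)
    bias = None
    if bias_column is not None and bias_column in table.columns:
        bias = table.column(bias_column)[:-shift]
    return x[:-shift], x[shift:], bias


class _RMSProp:
    """RMSprop with the standard accumulator: v <- rho v + (1-rho) g^2."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, rho: float = 0.9,
                 eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            v = self.v[k]
            v *= self.rho
            v += (1 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(v) + self.eps)


def train_rc(
    table: TimeSeriesTable,
    lag: float = 2.0,
    epochs: int = 5000,
    lr: float = 2e-4,
    K: int = 128,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    bias_column: str | None = "bias",
    beta: float = 1.0,
    reweight: bool = True,
    standardize: bool = True,
) -> tuple[RCModel, TrainingRecord]:
    """Train the predictive encoder-decoder on one trajectory.

    Features are standardised (zero mean, unit variance) before training;
    reported coefficients therefore refer to standardised features.  Biased
    input is reweighted per source frame with exp(beta V(t)) unless
    ``reweight`` is disabled.  Full-batch RMSprop; deterministic for a fixed
    seed.  Raises on non-finite loss (diverged training).
    """
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c != bias_column]
    x_t, x_lag, bias = make_pairs(table, lag, feature_columns, bias_column)
    if not reweight:
        bias = None
    n, k = x_t.shape
    if standardize:
        mu = x_t.mean(axis=0)
        sd = x_t.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = np.zeros(k)
        sd = np.ones(k)
    X = (x_t - mu) / sd
    Y = (x_lag - mu) / sd
    wts = _bias_weights(bias, beta, n)

    rng = np.random.default_rng(seed)
    params = {
        "w": rng.standard_normal(k) / math.sqrt(k),
        "W1": rng.standard_normal((K, 1)),
        "b1": np.zeros(K),
        "W2": rng.standard_normal((K, K)) / math.sqrt(K),
        "b2": np.zeros(K),
        "W3": rng.standard_normal((k, K)) / math.sqrt(K),
        "b3": np.zeros(k),
    }
    opt = _RMSProp(params, lr)
    losses = np.empty(epochs)
    wcol = wts[:, None]
    for ep in range(epochs):
        z = X @ params["w"]                                   # (n,)
        a1 = z[:, None] * params["W1"][:, 0][None, :] + params["b1"]
        h1 = _elu(a1)
        a2 = h1 @ params["W2"].T + params["b2"]
        h2 = _elu(a2)
        out = h2 @ params["W3"].T + params["b3"]
        diff = out - Y
        loss = float(wts @ (diff**2).sum(axis=1))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {ep}; lower the learning rate"
            )
        losses[ep] = loss

        dout = 2.0 * wcol * diff                              # (n, k)
        g_W3 = dout.T @ h2
        g_b3 = dout.sum(axis=0)
        dh2 = dout @ params["W3"]
        da2 = dh2 * _elu_grad(a2, h2)
        g_W2 = da2.T @ h1
        g_b2 = da2.sum(axis=0)
        dh1 = da2 @ params["W2"]
        da1 = dh1 * _elu_grad(a1, h1)
        g_W1 = (da1 * z[:, None]).sum(axis=0)[:, None]
        g_b1 = da1.sum(axis=0)
        dz = da1 @ params["W1"][:, 0]
        g_w = X.T @ dz
        opt.step(
            params,
            {"w": g_w, "W1": g_W1, "b1": g_b1, "W2": g_W2, "b2": g_b2,
             "W3": g_W3, "b3": g_b3},
        )

    model = RCModel(
        w=params["w"], W1=params["W1"], b1=params["b1"], W2=params["W2"],
        b2=params["b2"], W3=params["W3"], b3=params["b3"], lag=lag,
        feature_names=list(feature_columns),
        feature_mean=mu if standardize else None,
        feature_std=sd if standardize else None,
    )
    record = TrainingRecord(losses=losses, epochs=epochs, learning_rate=lr, seed=seed)
    return model, record
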