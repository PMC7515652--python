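"""Overdamped Langevin dynamics on analytic Gaussian-mixture landscapes.

This module stands in for the MD engine: it integrates Euler–Maruyama
overdamped Langevin dynamics on a free-energy surface defined as a Gaussian
mixture, optionally depositing well-tempered metadynamics hills along one or
two linear collective variables (CVs).  It supports infrequent-metadynamics
unbinding runs with an absorbing region in CV space, brute-force
first-passage sampling, and committor shooting.

Model
-----
The landscape is ``E(x) = -(1/beta) log sum_i w_i N(x; mu_i, Sigma_i)``.
The integrator is ``x <- x + (dt/gamma) F(x) + sqrt(2 dt/(beta gamma)) xi``
with friction ``gamma`` and standard-normal ``xi``; the invariant measure is
the Boltzmann density ``exp(-beta E)`` for any friction, which makes the
equilibrium statistics verifiable in closed form.

Well-tempered hills have effective height ``h exp(-V(s)/((gamma_wt-1) kT))``
where ``V(s)`` is the bias already accumulated at the walker's CV value; the
bias is accumulated on a cached grid over CV space (spacing <= width/5) so
per-step cost does not grow with the number of hills.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .io import TimeSeriesTable

__all__ = [
    "MixtureSurface",
    "MetadParams",
    "LinearCV",
    "UnbindingCriterion",
    "Box",
    "BiasedTrajectory",
    "UnbindingResult",
    "CommittorResult",
    "run_langevin",
    "run_metadynamics",
    "run_unbinding",
    "first_passage_times",
    "estimate_committor",
]


# ======================================================================
# Surfaces
# ======================================================================

class MixtureSurface:
    """Analytic (free-)energy surface defined by a Gaussian mixture.

    Parameters
    ----------
    components:
        Sequence of ``(weight, mean, covariance)`` triples.  Weights must be
        positive and sum to one; covariances symmetric positive definite.
    beta:
        Inverse temperature ``1/(k_b T)`` in inverse energy units.
    """

    def __init__(self, components: Sequence[tuple], beta: float = 1.0):
        if beta <= 0:
            raise ValueError("beta must be positive")
        if not components:
            raise ValueError("at least one component required")
        ws, mus, covs = [], [], []
        for w, mu, cov in components:
            mu = np.atleast_1d(np.asarray(mu, float))
            cov = np.atleast_2d(np.asarray(cov, float))
            if w <= 0:
                raise ValueError("component weights must be positive")
            if cov.shape != (mu.size, mu.size):
                raise ValueError("covariance shape inconsistent with mean")
            if not np.allclose(cov, cov.T):
                raise ValueError("covariance must be symmetric")
            np.linalg.cholesky(cov)  # SPD check
            ws.append(float(w)); mus.append(mu); covs.append(cov)
        w = np.asarray(ws, float)
        if not math.isclose(w.sum(), 1.0, rel_tol=1e-8):
            raise ValueError("weights must sum to 1")
        self.weights = w
        self.means = np.asarray(mus, float)
        self.covariances = np.asarray(covs, float)
        self.beta = float(beta)
        self.dimension = self.means.shape[1]
        # cached per-component precision and log-normalisation
        self.precisions = np.linalg.inv(self.covariances)
        sign, logdet = np.linalg.slogdet(self.covariances)
        if np.any(sign <= 0):
            raise ValueError("covariances must be positive definite")
        d = self.dimension
        self._lognorms = (
            np.log(self.weights) - 0.5 * (d * math.log(2 * math.pi) + logdet)
        )

    @property
    def components(self) -> list[tuple[float, np.ndarray, np.ndarray]]:
        return [
            (float(w), m.copy(), c.copy())
            for w, m, c in zip(self.weights, self.means, self.covariances)
        ]

    # -- densities and derivatives ------------------------------------

    def _log_terms(self, x: np.ndarray) -> np.ndarray:
        """Per-component log(w_i N_i) at points ``x`` of shape (n, D)."""
        dx = x[:, None, :] - self.means[None, :, :]          # (n, K, D)
        q = np.einsum("nkd,kde,nke->nk", dx, self.precisions, dx)
        return self._lognorms[None, :] - 0.5 * q

    def log_density(self, x: np.ndarray) -> np.ndarray:
        x2 = np.atleast_2d(np.asarray(x, float))
        out = logsumexp(self._log_terms(x2), axis=1)
        return out[0] if np.ndim(x) == 1 else out

    def energy(self, x: np.ndarray) -> np.ndarray:
        """E(x) = -(1/beta) log p(x); scalar for a single point."""
        return -self.log_density(x) / self.beta

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x2 = np.atleast_2d(np.asarray(x, float))
        lt = self._log_terms(x2)
        r = np.exp(lt - logsumexp(lt, axis=1, keepdims=True))  # responsibilities
        dx = x2[:, None, :] - self.means[None, :, :]
        g = np.einsum("nk,kde,nke->nd", r, self.precisions, dx)  # Σ r P (x-μ)
        g /= self.beta
        return g[0] if np.ndim(x) == 1 else g

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Hessian of the energy at a single point."""
        x = np.asarray(x, float)
        lt = self._log_terms(x[None, :])[0]
        r = np.exp(lt - logsumexp(lt))
        dx = x[None, :] - self.means                              # (K, D)
        g = np.einsum("kde,ke->kd", self.precisions, dx)          # P_i (x-μ_i)
        gbar = r @ g
        h = np.einsum("k,kde->de", r, self.precisions)
        h -= np.einsum("k,kd,ke->de", r, g, g)
        h += np.outer(gbar, gbar)
        return h / self.beta

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.gradient(x)

    def refine_minimum(self, x0: np.ndarray, tol: float = 1e-10) -> np.ndarray:
        """Polish a local minimum with a quasi-Newton search from ``x0``."""
        from scipy.optimize import minimize

        res = minimize(
            lambda x: self.energy(x), np.atleast_1d(np.asarray(x0, float)),
            jac=lambda x: self.gradient(x), method="BFGS",
            options={"gtol": tol},
        )
        return res.x

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSurface":
        comps = list(zip(d["weights"], d["means"], d["covariances"]))
        return cls(comps, beta=d["beta"])

    # -- stock toy landscapes ------------------------------------------

    @classmethod
    def double_well_1d(
        cls,
        separation: float = 2.0,
        sigma: float = 0.25,
        beta: float = 1.0,
        weights: tuple[float, float] = (0.5, 0.5),
    ) -> "MixtureSurface":
        """Two 1-D wells at ``+-separation/2`` of width ``sigma``.

        For equal weights the barrier at the midpoint is approximately
        ``(1/beta)(separation^2/(8 sigma^2) - log 2)``.
        """
        a = separation / 2.0
        return cls(
            [(weights[0], [-a], [[sigma**2]]), (weights[1], [a], [[sigma**2]])],
            beta=beta,
        )


# ======================================================================
# Parameter containers
# ======================================================================

@dataclass
class MetadParams:
    """Well-tempered metadynamics settings.

    ``temperature`` is expressed directly as an energy (``k_b T``); when
    ``None`` it defaults to ``1/beta`` of the surface the run uses, so the
    well-tempered schedule and the physical temperature agree.
    """

    hill_height: float = 0.5
    hill_width: float | tuple[float, ...] = 0.05
    bias_factor: float = 20.0
    deposition_interval: float = 25.0
    temperature: float | None = None
    grid_min: tuple[float, ...] = (-4.0,)
    grid_max: tuple[float, ...] = (4.0,)
    grid_spacing: float | None = None  # default: hill_width / 5

    def __post_init__(self) -> None:
        if self.hill_height < 0:
            raise ValueError("hill_height must be >= 0")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.deposition_interval <= 0:
            raise ValueError("deposition_interval must be positive")

    def widths(self, n_cv: int) -> np.ndarray:
        w = np.atleast_1d(np.asarray(self.hill_width, float))
        if w.size == 1:
            w = np.full(n_cv, w[0])
        if w.size != n_cv or np.any(w <= 0):
            raise ValueError("hill_width must be positive, one value per CV")
        return w


@dataclass
class LinearCV:
    """Linear projection CV: ``s = A x`` with ``A`` of shape (n_cv, D)."""

    matrix: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if self.matrix.shape[0] not in (1, 2):
            raise ValueError("only 1- or 2-dimensional CVs are supported")
        if self.names is None:
            self.names = [f"cv{i+1}" for i in range(self.matrix.shape[0])]

    @property
    def n_cv(self) -> int:
        return self.matrix.shape[0]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) @ self.matrix.T

    @classmethod
    def coordinate(cls, dim: int, index: int = 0) -> "LinearCV":
        a = np.zeros((1, dim))
        a[0, index] = 1.0
        return cls(a)


@dataclass
class UnbindingCriterion:
    """Absorbing region: first frame with ``cv[cv_index]`` beyond ``threshold``."""

    threshold: float
    cv_index: int = 0
    side: str = "above"  # 'above' -> cv > threshold absorbs, 'below' -> cv <

    def __post_init__(self) -> None:
        if self.side not in ("above", "below"):
            raise ValueError("side must be 'above' or 'below'")

    def satisfied(self, cv: np.ndarray) -> bool:
        v = float(np.atleast_1d(cv)[self.cv_index])
        return v > self.threshold if self.side == "above" else v < self.threshold


@dataclass
class Box:
    """Axis-aligned box region in position space."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.atleast_1d(np.asarray(self.lo, float))
        self.hi = np.atleast_1d(np.asarray(self.hi, float))
        if self.lo.shape != self.hi.shape or np.any(self.lo >= self.hi):
            raise ValueError("box needs lo < hi elementwise")

    def contains(self, x: np.ndarray) -> bool:
        x = np.atleast_1d(x)
        return bool(np.all(x >= self.lo) and np.all(x <= self.hi))

    def overlaps(self, other: "Box") -> bool:
        return bool(np.all(self.lo <= other.hi) and np.all(other.lo <= self.hi))


# ======================================================================
# Results
# ======================================================================

@dataclass
class BiasedTrajectory:
    """A (possibly biased) trajectory with its bias record and hill log."""

    table: TimeSeriesTable
    bias_at_frame: np.ndarray
    hill_log: np.ndarray          # rows (time, center..., effective height)
    seed: int
    cv_names: list[str] = field(default_factory=list)
    bias_grid: np.ndarray | None = None
    grid_lo: np.ndarray | None = None
    grid_dx: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.table.n_frames

    def positions(self) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("x")]
        return self.table.values(cols)

    def cv_values(self) -> np.ndarray:
        return self.table.values(self.cv_names) if self.cv_names else None

    def final_bias_at(self, s: np.ndarray) -> np.ndarray:
        """Final accumulated bias V(s, t_end) by interpolation on the grid."""
        if self.bias_grid is None:
            return np.zeros(np.atleast_2d(s).shape[0])
        s2 = np.atleast_2d(np.asarray(s, float))
        n1, n2 = self.bias_grid.shape
        u = np.clip((s2[:, 0] - self.grid_lo[0]) / self.grid_dx[0], 0, n1 - 1)
        i = np.clip(u.astype(int), 0, n1 - 2)
        fu = u - i
        if n2 == 1:
            g = self.bias_grid[:, 0]
            return (1 - fu) * g[i] + fu * g[i + 1]
        v = np.clip((s2[:, 1] - self.grid_lo[1]) / self.grid_dx[1], 0, n2 - 1)
        j = np.clip(v.astype(int), 0, n2 - 2)
        fv = v - j
        g = self.bias_grid
        return (
            (1 - fu) * (1 - fv) * g[i, j]
            + fu * (1 - fv) * g[i + 1, j]
            + (1 - fu) * fv * g[i, j + 1]
            + fu * fv * g[i + 1, j + 1]
        )


@dataclass
class UnbindingResult:
    trajectory: BiasedTrajectory
    stop_time: float | None
    censored: bool


@dataclass
class CommittorResult:
    """Committor estimate: fraction of shots reaching basin B first."""

    probability: float
    stderr: float
    n_to_a: int
    n_to_b: int
    n_unresolved: int


# ======================================================================
# numba kernels
# ======================================================================

@njit(cache=True)
def _force_into(x, means, precs, lognorms, beta, fout, a, pdx):
    """Physical force -dE/dx of the mixture surface, written into fout."""
    K, D = means.shape
    amax = -1.0e300
    for i in range(K):
        q = 0.0
        for d in range(D):
            acc = 0.0
            for e in range(D):
                acc += precs[i, d, e] * (x[e] - means[i, e])
            pdx[i, d] = acc
        for d in range(D):
            q += pdx[i, d] * (x[d] - means[i, d])
        a[i] = lognorms[i] - 0.5 * q
        if a[i] > amax:
            amax = a[i]
    ssum = 0.0
    for d in range(D):
        fout[d] = 0.0
    for i in range(K):
        r = np.exp(a[i] - amax)
        ssum += r
        for d in range(D):
            fout[d] -= r * pdx[i, d]
    for d in range(D):
        fout[d] /= ssum * beta


@njit(cache=True)
def _bias_eval(grid, g_lo, g_dx, s, grad_out):
    """Interpolated bias value and in-plane gradient; flat outside the grid."""
    n1, n2 = grid.shape
    u = (s[0] - g_lo[0]) / g_dx[0]
    in1 = 0.0 <= u <= n1 - 1.0
    if u < 0.0:
        u = 0.0
    if u > n1 - 1.0:
        u = n1 - 1.0
    i = int(u)
    if i > n1 - 2:
        i = n1 - 2
    fu = u - i
    if n2 == 1:
        val = (1.0 - fu) * grid[i, 0] + fu * grid[i + 1, 0]
        grad_out[0] = (grid[i + 1, 0] - grid[i, 0]) / g_dx[0] if in1 else 0.0
        return val
    v = (s[1] - g_lo[1]) / g_dx[1]
    in2 = 0.0 <= v <= n2 - 1.0
    if v < 0.0:
        v = 0.0
    if v > n2 - 1.0:
        v = n2 - 1.0
    j = int(v)
    if j > n2 - 2:
        j = n2 - 2
    fv = v - j
    g00 = grid[i, j]
    g10 = grid[i + 1, j]
    g01 = grid[i, j + 1]
    g11 = grid[i + 1, j + 1]
    val = (1 - fu) * (1 - fv) * g00 + fu * (1 - fv) * g10 \
        + (1 - fu) * fv * g01 + fu * fv * g11
    if in1 and in2:
        grad_out[0] = ((1 - fv) * (g10 - g00) + fv * (g11 - g01)) / g_dx[0]
        grad_out[1] = ((1 - fu) * (g01 - g00) + fu * (g11 - g10)) / g_dx[1]
    else:
        grad_out[0] = 0.0
        grad_out[1] = 0.0
    return val


@njit(cache=True)
def _deposit(grid, g_lo, g_dx, s, heff, widths):
    """Add a Gaussian hill of effective height heff at CV point s."""
    n1, n2 = grid.shape
    w0 = widths[0]
    j0 = int((s[0] - 5.0 * w0 - g_lo[0]) / g_dx[0])
    j1 = int((s[0] + 5.0 * w0 - g_lo[0]) / g_dx[0]) + 1
    if j0 < 0:
        j0 = 0
    if j1 > n1 - 1:
        j1 = n1 - 1
    if n2 == 1:
        for j in range(j0, j1 + 1):
            sj = g_lo[0] + j * g_dx[0]
            grid[j, 0] += heff * np.exp(-0.5 * ((sj - s[0]) / w0) ** 2)
    else:
        w1 = widths[1]
        k0 = int((s[1] - 5.0 * w1 - g_lo[1]) / g_dx[1])
        k1 = int((s[1] + 5.0 * w1 - g_lo[1]) / g_dx[1]) + 1
        if k0 < 0:
            k0 = 0
        if k1 > n2 - 1:
            k1 = n2 - 1
        for j in range(j0, j1 + 1):
            ej = np.exp(-0.5 * ((g_lo[0] + j * g_dx[0] - s[0]) / w0) ** 2)
            for k in range(k0, k1 + 1):
                ek = np.exp(-0.5 * ((g_lo[1] + k * g_dx[1] - s[1]) / w1) ** 2)
                grid[j, k] += heff * ej * ek


@njit(cache=True)
def _run_kernel(
    x0, dt, n_steps, stride, friction, beta,
    means, precs, lognorms,
    bias_on, A, widths, hill_h, wt_denom, dep_stride,
    g_lo, g_dx, grid,
    stop_on, stop_idx, stop_thr, stop_above,
    seed,
    out_pos, out_cv, out_bias,
    hill_t, hill_c, hill_heights,
):
    """Euler–Maruyama integration with optional WT-metadynamics and stop.

    Returns (n_frames_written, n_hills, stop_frame) where stop_frame is -1
    if the absorbing condition was never met.
    """
    np.random.seed(seed)
    D = x0.shape[0]
    c = A.shape[0]
    x = x0.copy()
    f = np.zeros(D)
    s = np.zeros(c)
    bgrad = np.zeros(c)
    a_buf = np.zeros(means.shape[0])
    pdx_buf = np.zeros(means.shape)
    noise_pref = np.sqrt(2.0 * dt / (beta * friction))
    mob = dt / friction

    # frame 0
    for d in range(D):
        out_pos[0, d] = x[d]
    for q in range(c):
        s[q] = 0.0
        for d in range(D):
            s[q] += A[q, d] * x[d]
        out_cv[0, q] = s[q]
    out_bias[0] = _bias_eval(grid, g_lo, g_dx, s, bgrad) if bias_on else 0.0
    frame = 1
    n_hills = 0
    stop_frame = -1
    if stop_on:
        v = out_cv[0, stop_idx]
        if (stop_above and v > stop_thr) or ((not stop_above) and v < stop_thr):
            return frame, n_hills, 0

    for k in range(1, n_steps + 1):
        _force_into(x, means, precs, lognorms, beta, f, a_buf, pdx_buf)
        if bias_on:
            for q in range(c):
                s[q] = 0.0
                for d in range(D):
                    s[q] += A[q, d] * x[d]
            _bias_eval(grid, g_lo, g_dx, s, bgrad)
            for d in range(D):
                for q in range(c):
                    f[d] -= A[q, d] * bgrad[q]
        for d in range(D):
            x[d] += mob * f[d] + noise_pref * np.random.standard_normal()
        if bias_on and hill_h > 0.0 and k % dep_stride == 0:
            for q in range(c):
                s[q] = 0.0
                for d in range(D):
                    s[q] += A[q, d] * x[d]
            v0 = _bias_eval(grid, g_lo, g_dx, s, bgrad)
            heff = hill_h * np.exp(-v0 / wt_denom)
            _deposit(grid, g_lo, g_dx, s, heff, widths)
            hill_t[n_hills] = k * dt
            for q in range(c):
                hill_c[n_hills, q] = s[q]
            hill_heights[n_hills] = heff
            n_hills += 1
        if k % stride == 0:
            for d in range(D):
                out_pos[frame, d] = x[d]
            for q in range(c):
                s[q] = 0.0
                for d in range(D):
                    s[q] += A[q, d] * x[d]
                out_cv[frame, q] = s[q]
            out_bias[frame] = _bias_eval(grid, g_lo, g_dx, s, bgrad) if bias_on else 0.0
            if stop_on:
                v = out_cv[frame, stop_idx]
                if (stop_above and v > stop_thr) or ((not stop_above) and v < stop_thr):
                    frame += 1
                    stop_frame = frame - 1
                    break
            frame += 1
    return frame, n_hills, stop_frame


@njit(cache=True)
def _committor_kernel(
    x_start, dt, max_steps, friction, beta,
    means, precs, lognorms,
    loA, hiA, loB, hiB, n_shots, seed,
):
    np.random.seed(seed)
    D = x_start.shape[0]
    f = np.zeros(D)
    a_buf = np.zeros(means.shape[0])
    pdx_buf = np.zeros(means.shape)
    noise_pref = np.sqrt(2.0 * dt / (beta * friction))
    mob = dt / friction
    nA = 0
    nB = 0
    nU = 0
    for _ in range(n_shots):
        x = x_start.copy()
        res = 0
        for _k in range(max_steps):
            _force_into(x, means, precs, lognorms, beta, f, a_buf, pdx_buf)
            for d in range(D):
                x[d] += mob * f[d] + noise_pref * np.random.standard_normal()
            inA = True
            inB = True
            for d in range(D):
                if x[d] < loA[d] or x[d] > hiA[d]:
                    inA = False
                if x[d] < loB[d] or x[d] > hiB[d]:
                    inB = False
            if inA:
                res = 1
                break
            if inB:
                res = 2
                break
        if res == 1:
            nA += 1
        elif res == 2:
            nB += 1
        else:
            nU += 1
    return nA, nB, nU


@njit(cache=True)
def _fpt_kernel(
    x0, dt, max_steps, friction, beta,
    means, precs, lognorms,
    A, stop_idx, stop_thr, stop_above,
    n_runs, seed,
):
    """Unbiased first-passage times to the absorbing CV region (nan = censored)."""
    np.random.seed(seed)
    D = x0.shape[0]
    c = A.shape[0]
    f = np.zeros(D)
    a_buf = np.zeros(means.shape[0])
    pdx_buf = np.zeros(means.shape)
    noise_pref = np.sqrt(2.0 * dt / (beta * friction))
    mob = dt / friction
    out = np.empty(n_runs)
    for r in range(n_runs):
        x = x0.copy()
        t = np.nan
        for k in range(1, max_steps + 1):
            _force_into(x, means, precs, lognorms, beta, f, a_buf, pdx_buf)
            for d in range(D):
                x[d] += mob * f[d] + noise_pref * np.random.standard_normal()
            v = 0.0
            for d in range(D):
                v += A[stop_idx, d] * x[d]
            if (stop_above and v > stop_thr) or ((not stop_above) and v < stop_thr):
                t = k * dt
                break
        out[r] = t
    return out


# ======================================================================
# public driver functions
# ======================================================================

def _dummy_grid() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.zeros(1), np.ones(1), np.zeros((2, 1))


def _make_grid(params: MetadParams, n_cv: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = np.asarray(params.grid_min, float)[:n_cv]
    hi = np.asarray(params.grid_max, float)[:n_cv]
    if lo.size != n_cv or hi.size != n_cv or np.any(hi <= lo):
        raise ValueError("grid_min/grid_max must give one valid range per CV")
    widths = params.widths(n_cv)
    spacing = params.grid_spacing or float(np.min(widths)) / 5.0
    ns = np.maximum(2, np.ceil((hi - lo) / spacing).astype(int) + 1)
    dx = (hi - lo) / (ns - 1)
    shape = (int(ns[0]), int(ns[1]) if n_cv == 2 else 1)
    return lo, dx, np.zeros(shape)


def _build_trajectory(
    surface, cv, out_pos, out_cv, out_bias, n_frames, dt_frame,
    hills, seed, grid=None, g_lo=None, g_dx=None, meta=None,
) -> BiasedTrajectory:
    times = np.arange(n_frames) * dt_frame
    cols: dict[str, np.ndarray] = {}
    for d in range(surface.dimension):
        cols[f"x{d+1}"] = out_pos[:n_frames, d]
    cv_names = list(cv.names) if cv is not None else []
    for q, name in enumerate(cv_names):
        cols[name] = out_cv[:n_frames, q]
    cols["bias"] = out_bias[:n_frames]
    table = TimeSeriesTable.from_arrays(
        times, cols, units={"time": "ps", "bias": "kJ/mol"}, meta=meta or {}
    )
    return BiasedTrajectory(
        table=table,
        bias_at_frame=out_bias[:n_frames].copy(),
        hill_log=hills,
        seed=seed,
        cv_names=cv_names,
        bias_grid=None if grid is None else grid.copy(),
        grid_lo=g_lo,
        grid_dx=g_dx,
    )


def _check_start(surface: MixtureSurface, x0) -> np.ndarray:
    if x0 is None:
        x0 = surface.means[int(np.argmax(surface.weights))]
    x0 = np.atleast_1d(np.asarray(x0, float))
    if x0.size != surface.dimension:
        raise ValueError("x0 dimension mismatch")
    if not np.all(np.isfinite(surface.gradient(x0))):
        raise ValueError("non-finite force at x0")
    return x0


def run_langevin(
    surface: MixtureSurface,
    step: float,
    n_steps: int,
    friction: float = 1.0,
    seed: int = 0,
    x0: np.ndarray | None = None,
    stride: int = 1,
) -> BiasedTrajectory:
    """Unbiased overdamped Langevin run; bias record identically zero."""
    if step <= 0 or friction <= 0:
        raise ValueError("step and friction must be positive")
    x0 = _check_start(surface, x0)
    n_frames_max = n_steps // stride + 1
    D = surface.dimension
    A = np.zeros((1, D))
    g_lo, g_dx, grid = _dummy_grid()
    out_pos = np.empty((n_frames_max, D))
    out_cv = np.empty((n_frames_max, 1))
    out_bias = np.empty(n_frames_max)
    hill_t = np.empty(0)
    hill_c = np.empty((0, 1))
    hill_h = np.empty(0)
    n_frames, _, _ = _run_kernel(
        x0, step, n_steps, stride, friction, surface.beta,
        surface.means, surface.precisions, surface._lognorms,
        False, A, np.ones(1), 0.0, 1.0, 1,
        g_lo, g_dx, grid,
        False, 0, 0.0, True,
        seed,
        out_pos, out_cv, out_bias, hill_t, hill_c, hill_h,
    )
    return _build_trajectory(
        surface, None, out_pos, out_cv, out_bias, n_frames, step * stride,
        np.empty((0, 3)), seed,
        meta={"stage": "langevin", "seed": seed, "step": step, "friction": friction},
    )


def _metad_setup(surface, cv, params, step):
    n_cv = cv.n_cv
    ratio = params.deposition_interval / step
    dep_stride = int(round(ratio))
    if dep_stride < 1 or abs(ratio - dep_stride) > 1e-9 * max(1.0, ratio):
        raise ValueError("deposition_interval must be a positive multiple of step")
    kbt = params.temperature if params.temperature is not None else 1.0 / surface.beta
    wt_denom = (params.bias_factor - 1.0) * kbt
    g_lo, g_dx, grid = _make_grid(params, n_cv)
    return dep_stride, wt_denom, g_lo, g_dx, grid


def run_metadynamics(
    surface: MixtureSurface,
    cv: LinearCV,
    params: MetadParams,
    step: float,
    n_steps: int,
    seed: int = 0,
    friction: float = 1.0,
    x0: np.ndarray | None = None,
    stride: int = 1,
) -> BiasedTrajectory:
    """Well-tempered metadynamics along ``cv``; hills every deposition_interval."""
    if step <= 0 or friction <= 0:
        raise ValueError("step and friction must be positive")
    x0 = _check_start(surface, x0)
    dep_stride, wt_denom, g_lo, g_dx, grid = _metad_setup(surface, cv, params, step)
    n_cv = cv.n_cv
    n_frames_max = n_steps // stride + 1
    max_hills = n_steps // dep_stride + 1
    out_pos = np.empty((n_frames_max, surface.dimension))
    out_cv = np.empty((n_frames_max, n_cv))
    out_bias = np.empty(n_frames_max)
    hill_t = np.empty(max_hills)
    hill_c = np.empty((max_hills, n_cv))
    hill_h = np.empty(max_hills)
    n_frames, n_hills, _ = _run_kernel(
        x0, step, n_steps, stride, friction, surface.beta,
        surface.means, surface.precisions, surface._lognorms,
        True, cv.matrix, params.widths(n_cv), params.hill_height, wt_denom,
        dep_stride, g_lo, g_dx, grid,
        False, 0, 0.0, True,
        seed,
        out_pos, out_cv, out_bias, hill_t, hill_c, hill_h,
    )
    hills = np.column_stack([hill_t[:n_hills], hill_c[:n_hills], hill_h[:n_hills]])
    return _build_trajectory(
        surface, cv, out_pos, out_cv, out_bias, n_frames, step * stride,
        hills, seed, grid, g_lo, g_dx,
        meta={"stage": "metadynamics", "seed": seed, "step": step,
              "friction": friction, "hill_height": params.hill_height,
              "bias_factor": params.bias_factor,
              "deposition_interval": params.deposition_interval},
    )


def run_unbinding(
    surface: MixtureSurface,
    cv: LinearCV,
    params: MetadParams,
    stop: UnbindingCriterion,
    max_steps: int,
    seed: int = 0,
    step: float = 0.01,
    friction: float = 1.0,
    x0: np.ndarray | None = None,
    stride: int = 1,
) -> UnbindingResult:
    """Infrequent-metadynamics run truncated at the absorbing region.

    The returned ``stop_time`` is the wall (biased) time of the first frame
    inside the absorbing region, or ``None`` with ``censored=True`` when
    ``max_steps`` is exhausted first.
    """
    if step <= 0 or friction <= 0:
        raise ValueError("step and friction must be positive")
    x0 = _check_start(surface, x0)
    dep_stride, wt_denom, g_lo, g_dx, grid = _metad_setup(surface, cv, params, step)
    n_cv = cv.n_cv
    if not 0 <= stop.cv_index < n_cv:
        raise ValueError("stop.cv_index out of range")
    n_frames_max = max_steps // stride + 1
    max_hills = max_steps // dep_stride + 1
    out_pos = np.empty((n_frames_max, surface.dimension))
    out_cv = np.empty((n_frames_max, n_cv))
    out_bias = np.empty(n_frames_max)
    hill_t = np.empty(max_hills)
    hill_c = np.empty((max_hills, n_cv))
    hill_h = np.empty(max_hills)
    n_frames, n_hills, stop_frame = _run_kernel(
        x0, step, max_steps, stride, friction, surface.beta,
        surface.means, surface.precisions, surface._lognorms,
        True, cv.matrix, params.widths(n_cv), params.hill_height, wt_denom,
        dep_stride, g_lo, g_dx, grid,
        True, stop.cv_index, stop.threshold, stop.side == "above",
        seed,
        out_pos, out_cv, out_bias, hill_t, hill_c, hill_h,
    )
    hills = np.column_stack([hill_t[:n_hills], hill_c[:n_hills], hill_h[:n_hills]])
    traj = _build_trajectory(
        surface, cv, out_pos, out_cv, out_bias, n_frames, step * stride,
        hills, seed, grid, g_lo, g_dx,
        meta={"stage": "unbinding", "seed": seed, "step": step,
              "friction": friction,
              "deposition_interval": params.deposition_interval},
    )
    if stop_frame >= 0:
        return UnbindingResult(traj, float(traj.table.times[stop_frame]), False)
    return UnbindingResult(traj, None, True)


def first_passage_times(
    surface: MixtureSurface,
    cv: LinearCV,
    stop: UnbindingCriterion,
    n_runs: int,
    step: float,
    max_steps: int,
    friction: float = 1.0,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force unbiased first-passage sampling.

    Returns ``(times, censored)`` where censored runs carry ``max_steps*step``
    in ``times`` and ``True`` in the mask.
    """
    x0 = _check_start(surface, x0)
    raw = _fpt_kernel(
        x0, step, max_steps, friction, surface.beta,
        surface.means, surface.precisions, surface._lognorms,
        cv.matrix, stop.cv_index, stop.threshold, stop.side == "above",
        n_runs, seed,
    )
    censored = ~np.isfinite(raw)
    times = np.where(censored, max_steps * step, raw)
    return times, censored


def estimate_committor(
    surface: MixtureSurface,
    x_start: np.ndarray,
    basinA: Box,
    basinB: Box,
    n_shots: int,
    step: float,
    friction: float = 1.0,
    seed: int = 0,
    max_steps: int = 1_000_000,
) -> CommittorResult:
    """Shooting estimate of the committor p(B before A) from ``x_start``.

    Shots exceeding ``max_steps`` are counted as unresolved and excluded from
    the probability (but reported), never silently dropped.
    """
    if basinA.overlaps(basinB):
        raise ValueError("basins must be disjoint")
    x_start = _check_start(surface, x_start)
    nA, nB, nU = _committor_kernel(
        x_start, step, max_steps, friction, surface.beta,
        surface.means, surface.precisions, surface._lognorms,
        basinA.lo, basinA.hi, basinB.lo, basinB.hi, n_shots, seed,
    )
    n_resolved = nA + nB
    p = nB / n_resolved if n_resolved else float("nan")
    se = math.sqrt(p * (1 - p) / n_resolved) if n_resolved else float("nan")
    return CommittorResult(p, se, nA, nB, nU)
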