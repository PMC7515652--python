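"""State and pathway characterisation on a GMM free-energy surface.

Pipeline: per-frame reweighting of biased data -> weighted PCA of the
feature set -> cluster-count selection on the first two components
(k-means + Calinski-Harabasz) -> state assignment by a Gaussian mixture on
the first three components -> an N-dimensional Gaussian-mixture free-energy
surface from weighted per-state moments -> nudged-elastic-band (NEB)
minimum-energy paths between minima with climbing-image saddle refinement ->
a transition network of Kramers rates and relative mean first-passage times
(MFPTs), whose largest inter-minimum MFPT marks the rate-limiting step.

Only relative rates/MFPTs are meaningful: the friction-dependent Kramers
prefactor is left out, so uniform rescaling of all rates changes nothing
reported here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score
from sklearn.mixture import GaussianMixture

from .feature_select import FeatureMatrix
from .toy_dynamics import BiasedTrajectory, MixtureSurface

__all__ = [
    "ProjectedData",
    "PathResult",
    "RateNetwork",
    "frame_weights_from_bias",
    "weighted_pca",
    "select_n_clusters",
    "fit_gmm_fes",
    "neb_mep",
    "kramers_rate_from_hessians",
    "kramers_rate_network",
    "mfpt_matrix",
    "assign_states",
]


# ======================================================================
# Reweighting and weighted PCA
# ======================================================================

def frame_weights_from_bias(
    bias_series: np.ndarray, beta: float, bias_factor: float | None = None
) -> np.ndarray:
    """Normalised per-frame weights w_t proportional to exp(beta V_final(s_t)).

    ``bias_series`` is the final accumulated bias evaluated at each frame's
    CV value.  The maximum is subtracted before exponentiation so the
    weights cannot overflow.  Weights always sum to one.
    """
    v = np.asarray(bias_series, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite bias values")
    a = beta * v
    w = np.exp(a - a.max())
    return w / w.sum()


def trajectory_frame_weights(traj: BiasedTrajectory, beta: float) -> np.ndarray:
    """Final-bias frame weights for a metadynamics trajectory."""
    s = traj.cv_values()
    if s is None or traj.bias_grid is None:
        return np.full(traj.n_frames, 1.0 / traj.n_frames)
    return frame_weights_from_bias(traj.final_bias_at(s), beta)


@dataclass
class ProjectedData:
    """Weighted-PCA scores with loadings and explained-variance fractions."""

    scores: np.ndarray             # (frames, N)
    loadings: np.ndarray           # (features, N), orthonormal columns
    explained_variance: np.ndarray  # fractions, non-increasing
    weights: np.ndarray            # per-frame, sum 1
    mean: np.ndarray               # weighted feature mean


def weighted_pca(fm: FeatureMatrix) -> ProjectedData:
    """PCA of the weighted covariance about the weighted mean.

    With uniform weights this reduces to standard PCA.  Zero-variance
    directions are dropped with a warning.
    """
    if fm.n_features < 2:
        raise ValueError("at least 2 features required")
    x = fm.values
    w = (
        fm.frame_weights / fm.frame_weights.sum()
        if fm.frame_weights is not None
        else np.full(fm.n_frames, 1.0 / fm.n_frames)
    )
    mean = w @ x
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    keep = evals > max(1e-12 * evals.max(), 0.0) if evals.max() > 0 else evals > -1
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance principal component(s)"
        )
    evals, evecs = evals[keep], evecs[:, keep]
    total = evals.sum()
    return ProjectedData(
        scores=xc @ evecs,
        loadings=evecs,
        explained_variance=evals / total if total > 0 else evals,
        weights=w,
        mean=mean,
    )


# ======================================================================
# Cluster-count selection and the GMM FES
# ======================================================================

def select_n_clusters(
    scores2d: np.ndarray, k_range: range | list[int] = range(2, 9), seed: int = 0
) -> int:
    """Number of metastable states: k maximising the Calinski-Harabasz index
    of k-means fits on the first two principal components."""
    s = np.asarray(scores2d, float)[:, :2]
    best_k, best_score = None, -np.inf
    for k in k_range:
        if not 2 <= k <= s.shape[0] - 1:
            raise ValueError(f"k={k} outside [2, frames-1]")
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(s)
        score = calinski_harabasz_score(s, labels)
        if score > best_score:
            best_k, best_score = k, score
    return int(best_k)


def fit_gmm_fes(
    scoresND: np.ndarray,
    weights: np.ndarray | None,
    k: int,
    beta: float = 1.0,
    seed: int = 0,
    assign_dims: int = 3,
    cov_reg: float = 1e-6,
) -> MixtureSurface:
    """N-dimensional Gaussian-mixture free-energy surface.

    Two-stage fit: a Gaussian mixture with ``k`` centres on the first
    ``assign_dims`` components assigns frames to states; weighted mean, full
    covariance and mixture weight are then computed per state in all N
    dimensions.  F(x) = -(1/beta) log sum_i pi_i N(x; mu_i, Sigma_i).
    States left empty by the assignment are dropped with a warning.
    """
    x = np.atleast_2d(np.asarray(scoresND, float))
    n, N = x.shape
    w = (
        np.asarray(weights, float) / np.sum(weights)
        if weights is not None
        else np.full(n, 1.0 / n)
    )
    gm = GaussianMixture(
        n_components=k, covariance_type="full", random_state=seed, n_init=3
    ).fit(x[:, : min(assign_dims, N)])
    labels = gm.predict(x[:, : min(assign_dims, N)])
    comps = []
    for c in range(k):
        mask = labels == c
        wc = w[mask]
        if wc.sum() <= 0 or mask.sum() < N + 1:
            warnings.warn(f"state {c} empty after assignment; k reduced")
            continue
        wn = wc / wc.sum()
        mu = wn @ x[mask]
        xc = x[mask] - mu
        cov = (xc * wn[:, None]).T @ xc
        cov += cov_reg * np.trace(cov) / N * np.eye(N)
        comps.append((wc.sum(), mu, cov))
    total = sum(c[0] for c in comps)
    comps = [(wt / total, mu, cov) for wt, mu, cov in comps]
    return MixtureSurface(comps, beta=beta)


def assign_states(scoresND: np.ndarray, surface: MixtureSurface) -> np.ndarray:
    """Maximum-responsibility state label per frame (ties -> lowest index)."""
    x = np.atleast_2d(np.asarray(scoresND, float))
    lt = surface._log_terms(x)
    return np.argmax(lt, axis=1)


# ======================================================================
# NEB minimum-energy paths
# ======================================================================

@dataclass
class PathResult:
    """Converged NEB chain with its saddle and barrier heights."""

    images: np.ndarray             # (n_images, N)
    energies: np.ndarray           # (n_images,)
    saddle_index: int
    saddle: np.ndarray
    barrier_forward: float         # saddle energy - start energy
    barrier_backward: float        # saddle energy - end energy
    converged: bool
    n_iter: int = 0


def _neb_tangents(images: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Improved (energy-weighted upwind) tangent estimate per interior image."""
    n = len(images)
    tangents = np.zeros_like(images)
    for i in range(1, n - 1):
        dplus = images[i + 1] - images[i]
        dminus = images[i] - images[i - 1]
        e0, e1, e2 = energies[i - 1], energies[i], energies[i + 1]
        if e2 > e1 > e0:
            tau = dplus
        elif e2 < e1 < e0:
            tau = dminus
        else:
            dmax = max(abs(e2 - e1), abs(e0 - e1))
            dmin = min(abs(e2 - e1), abs(e0 - e1))
            tau = dplus * dmax + dminus * dmin if e2 > e0 else dplus * dmin + dminus * dmax
        norm = np.linalg.norm(tau)
        tangents[i] = tau / norm if norm > 0 else tau
    return tangents


def neb_mep(
    surface: MixtureSurface,
    start: np.ndarray,
    end: np.ndarray,
    n_images: int = 32,
    spring_k: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 5000,
    climbing: bool = True,
    min_grad_tol: float = 1e-3,
) -> PathResult:
    """Nudged-elastic-band minimum-energy path between two minima.

    The chain is relaxed with FIRE dynamics using the improved-tangent NEB
    force; once roughly converged, the highest image climbs (spring force
    replaced by inverted parallel force) so it lands on the saddle.
    Non-convergence within ``max_iter`` returns the partial path flagged
    ``converged=False``.
    """
    start = np.atleast_1d(np.asarray(start, float))
    end = np.atleast_1d(np.asarray(end, float))
    for name, pt in (("start", start), ("end", end)):
        g = np.linalg.norm(surface.gradient(pt))
        if g > min_grad_tol:
            raise ValueError(f"{name} is not a local minimum (|grad| = {g:.3g})")
    if np.allclose(start, end):
        e = float(surface.energy(start))
        return PathResult(
            images=np.array([start]), energies=np.array([e]), saddle_index=0,
            saddle=start.copy(), barrier_forward=0.0, barrier_backward=0.0,
            converged=True,
        )
    frac = np.linspace(0, 1, n_images)[:, None]
    images = start[None, :] * (1 - frac) + end[None, :] * frac
    length = float(np.linalg.norm(end - start))
    if spring_k is None:
        e_init = surface.energy(images)
        erange = float(e_init.max() - e_init.min()) + 1.0 / surface.beta
        spring_k = erange * (n_images / max(length, 1e-12)) ** 2

    # FIRE relaxation
    v = np.zeros_like(images)
    dt = 0.1 * length / n_images
    dt_max = 10 * dt
    alpha0, alpha = 0.1, 0.1
    n_pos = 0
    climb_idx = -1
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        energies = surface.energy(images)
        grads = surface.gradient(images)
        tangents = _neb_tangents(images, energies)
        forces = np.zeros_like(images)
        if climbing and it > 5:
            climb_idx = int(np.argmax(energies[1:-1])) + 1
        for i in range(1, n_images - 1):
            tau = tangents[i]
            g = grads[i]
            gpar = np.dot(g, tau)
            if i == climb_idx:
                forces[i] = -g + 2.0 * gpar * tau
            else:
                fperp = -(g - gpar * tau)
                fspring = spring_k * (
                    np.linalg.norm(images[i + 1] - images[i])
                    - np.linalg.norm(images[i] - images[i - 1])
                )
                forces[i] = fperp + fspring * tau
        fmax = np.sqrt((forces[1:-1] ** 2).sum(axis=1)).max()
        if fmax < tol and (climb_idx >= 0 or not climbing):
            converged = True
            break
        p = float((forces * v).sum())
        if p > 0:
            n_pos += 1
            fn = np.linalg.norm(forces)
            vn = np.linalg.norm(v)
            if fn > 0:
                v = (1 - alpha) * v + alpha * vn * forces / fn
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = alpha0
            n_pos = 0
        v += dt * forces
        step = dt * v
        smax = np.sqrt((step**2).sum(axis=1)).max()
        cap = 0.5 * length / n_images
        if smax > cap:
            step *= cap / smax
        images[1:-1] += step[1:-1]

    energies = surface.energy(images)
    saddle_idx = int(np.argmax(energies))
    return PathResult(
        images=images,
        energies=energies,
        saddle_index=saddle_idx,
        saddle=images[saddle_idx].copy(),
        barrier_forward=float(energies[saddle_idx] - energies[0]),
        barrier_backward=float(energies[saddle_idx] - energies[-1]),
        converged=converged,
        n_iter=it,
    )


# ======================================================================
# Kramers rates and MFPTs
# ======================================================================

def kramers_rate_from_hessians(
    min_eigenvalues: np.ndarray,
    saddle_eigenvalues: np.ndarray,
    barrier: float,
    beta: float,
) -> float:
    """Relative harmonic Kramers rate (friction prefactor omitted):

    k ∝ (prod omega_min / prod' omega_saddle) exp(-beta dF), with omega the
    sqrt-curvature frequencies and the saddle's single negative mode removed.
    """
    lmin = np.asarray(min_eigenvalues, float)
    lsad = np.asarray(saddle_eigenvalues, float)
    if np.any(lmin <= 0):
        raise ValueError("minimum Hessian must be positive definite")
    neg = lsad < 0
    if neg.sum() != 1:
        raise ValueError(
            f"saddle Hessian must have exactly one negative eigenvalue, got {int(neg.sum())}"
        )
    pos = lsad[~neg]
    pref = np.sqrt(np.prod(lmin) / np.prod(pos))
    return float(pref * np.exp(-beta * barrier))


@dataclass
class RateNetwork:
    """Transition network over FES minima with relative Kramers rates."""

    minima: np.ndarray                    # (n_min, N)
    rates: np.ndarray                     # (n_min, n_min), zero off-network
    adjacency: np.ndarray                 # bool matrix
    mfpt: np.ndarray                      # relative MFPT matrix, nan if unreachable
    rate_limiting_edge: tuple[int, int] | None
    invalid_edges: list[tuple[int, int]] = field(default_factory=list)
    paths: dict = field(default_factory=dict)


def mfpt_matrix(rates: np.ndarray) -> np.ndarray:
    """Mean first-passage times of the Markov jump process with given rates.

    ``M[i, j]`` is the expected time to first reach j from i, from the
    linear system Q m = -1 on the non-target states.
    """
    k = np.asarray(rates, float)
    n = k.shape[0]
    q = k.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    m = np.full((n, n), np.nan)
    for target in range(n):
        idx = [i for i in range(n) if i != target]
        sub = q[np.ix_(idx, idx)]
        try:
            sol = np.linalg.solve(sub, -np.ones(n - 1))
        except np.linalg.LinAlgError:
            continue
        for row, i in enumerate(idx):
            m[i, target] = sol[row]
        m[target, target] = 0.0
    return m


def _path_is_direct(
    path: PathResult, minima: np.ndarray, i: int, j: int, proximity_tol: float
) -> bool:
    """True if no intermediate image sits on a third minimum."""
    others = [m for idx, m in enumerate(minima) if idx not in (i, j)]
    if not others or len(path.images) < 3:
        return True
    interior = path.images[1:-1]
    for m in others:
        if np.min(np.linalg.norm(interior - m[None, :], axis=1)) < proximity_tol:
            return False
    return True


def kramers_rate_network(
    surface: MixtureSurface,
    minima: np.ndarray,
    paths: dict[tuple[int, int], PathResult],
    beta: float | None = None,
    proximity_tol: float | None = None,
) -> RateNetwork:
    """Build the transition network from NEB paths between minima pairs.

    Each supplied path defines a candidate edge; a path passing through a
    third minimum is excluded (those minima are not adjacent).  Per-edge
    Kramers rates use analytic surface Hessians at the minimum and saddle; a
    saddle without exactly one negative mode flags the edge invalid.  The
    rate-limiting edge is the adjacent ordered pair with the largest MFPT.
    """
    beta = beta if beta is not None else surface.beta
    minima = np.atleast_2d(np.asarray(minima, float))
    n = minima.shape[0]
    if proximity_tol is None:
        span = np.linalg.norm(minima.max(axis=0) - minima.min(axis=0))
        proximity_tol = 0.1 * span if span > 0 else 1e-3
    rates = np.zeros((n, n))
    adjacency = np.zeros((n, n), dtype=bool)
    invalid: list[tuple[int, int]] = []
    e_min = np.array([float(surface.energy(m)) for m in minima])
    for (i, j), path in paths.items():
        if not _path_is_direct(path, minima, i, j, proximity_tol):
            continue
        h_sad = np.linalg.eigvalsh(surface.hessian(path.saddle))
        e_sad = float(surface.energy(path.saddle))
        try:
            for a, b in ((i, j), (j, i)):
                h_min = np.linalg.eigvalsh(surface.hessian(minima[a]))
                rates[a, b] = kramers_rate_from_hessians(
                    h_min, h_sad, e_sad - e_min[a], beta
                )
        except ValueError:
            invalid.append((i, j))
            rates[i, j] = rates[j, i] = 0.0
            continue
        adjacency[i, j] = adjacency[j, i] = True
    m = mfpt_matrix(rates)
    edge = None
    best = -np.inf
    for i in range(n):
        for j in range(n):
            if adjacency[i, j] and np.isfinite(m[i, j]) and m[i, j] > best:
                best = m[i, j]
                edge = (i, j)
    return RateNetwork(
        minima=minima,
        rates=rates,
        adjacency=adjacency,
        mfpt=m,
        rate_limiting_edge=edge,
        invalid_edges=invalid,
        paths=dict(paths),
    )
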