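"""Hydration-style switching CVs, unbinding detection and contact fractions.

The switching function is the rational form

    s(r) = (1 - (r/R0)^6) / (1 - (r/R0)^10)

used to count coordinating water molecules continuously: s(0) = 1, s decays
smoothly past R0 and the removable singularity at r = R0 evaluates to the
limit 6/10.  The hydration CV is the sum of s over all water distances.

Contact fractions are reweighted indicator means: the probability that a
minimum-distance channel is below a cutoff (default 5 Å), computed with
per-frame weights, with channels below a display threshold (default 15%)
filtered only from the human-readable report, never from the stored profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TimeSeriesTable

__all__ = [
    "SwitchingParams",
    "ContactProfile",
    "switching",
    "hydration_cv",
    "detect_unbinding",
    "contact_fractions",
]


@dataclass
class SwitchingParams:
    """Rational switching function parameters: (1-(r/R0)^n)/(1-(r/R0)^m)."""

    R0: float = 0.3  # nm
    n: int = 6
    m: int = 10

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if not (self.m > self.n > 0):
            raise ValueError("exponents must satisfy m > n > 0")


def switching(r: np.ndarray | float, p: SwitchingParams = SwitchingParams()) -> np.ndarray | float:
    """Evaluate the rational switching function; strictly decreasing in r.

    At r = R0 the 0/0 form is evaluated as its limit n/m.
    """
    r_arr = np.asarray(r, float)
    if np.any(r_arr < 0):
        raise ValueError("distances must be >= 0")
    u = r_arr / p.R0
    un = u ** p.n
    um = u ** p.m
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - un) / (1.0 - um)
    # removable singularity at u == 1 (and a numerical neighbourhood of it)
    near = np.abs(u - 1.0) < 1e-9
    if np.any(near):
        # l'Hopital limit n/m with the first series-correction term
        n_, m_ = p.n, p.m
        du = u - 1.0
        s = np.where(near, n_ / m_ - (n_ * (m_ - n_)) / (2.0 * m_) * du, s)
    return float(s) if np.ndim(r) == 0 else s


def hydration_cv(distances: np.ndarray | list, p: SwitchingParams = SwitchingParams()) -> float:
    """Hydration CV: S = sum_i s(r_i) over all water distances (0 if empty)."""
    d = np.asarray(distances, float)
    if d.size == 0:
        return 0.0
    return float(np.sum(switching(d, p)))


def detect_unbinding(
    series: np.ndarray,
    times: np.ndarray,
    threshold: float,
) -> tuple[float | None, bool]:
    """First time the distance series strictly exceeds the threshold.

    Returns ``(time, censored)``: the time stamp of the first frame with
    value > threshold, or ``(None, True)`` if no frame crosses.  Appending
    frames after the first crossing cannot change the result.
    """
    series = np.asarray(series, float)
    times = np.asarray(times, float)
    if series.size == 0:
        raise ValueError("empty distance series")
    if series.shape != times.shape:
        raise ValueError("series and times must have equal length")
    if not np.all(np.isfinite(series)):
        raise ValueError("non-finite values in distance series")
    above = series > threshold
    if not np.any(above):
        return None, True
    return float(times[int(np.argmax(above))]), False


def detect_unbinding_table(
    table: TimeSeriesTable, column: str, threshold: float
) -> tuple[float | None, bool]:
    return detect_unbinding(table.column(column), table.times, threshold)


@dataclass
class ContactProfile:
    """Per-channel reweighted contact fractions with display filtering."""

    fractions: dict[str, float]
    cutoff: float = 5.0            # Angstrom
    display_threshold: float = 0.15
    frame_weight_sum: float = 0.0
    meta: dict = field(default_factory=dict)

    def displayed(self) -> dict[str, float]:
        """Channels at or above the display threshold (report view only)."""
        return {
            k: v for k, v in self.fractions.items() if v >= self.display_threshold
        }


def contact_fractions(
    min_dist_matrix: np.ndarray,
    channel_names: list[str],
    frame_weights: np.ndarray | None = None,
    cutoff: float = 5.0,
    display_threshold: float = 0.15,
) -> ContactProfile:
    """Weighted contact fractions: P(d < cutoff) per channel.

    The contact indicator uses a strict inequality (d < cutoff counts,
    d == cutoff does not).  Uniform (or absent) weights reduce to the plain
    empirical frequency.  All channels are retained in the returned profile;
    the display threshold only governs the report view.
    """
    d = np.asarray(min_dist_matrix, float)
    if d.ndim != 2:
        raise ValueError("min_dist_matrix must be frames x channels")
    if len(channel_names) != d.shape[1]:
        raise ValueError("one name per channel required")
    if frame_weights is None:
        w = np.ones(d.shape[0])
    else:
        w = np.asarray(frame_weights, float)
        if w.shape != (d.shape[0],):
            raise ValueError("one weight per frame required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("frame weights must have positive sum")
    frac = (w[:, None] * (d < cutoff)).sum(axis=0) / wsum
    return ContactProfile(
        fractions={n: float(f) for n, f in zip(channel_names, frac)},
        cutoff=cutoff,
        display_threshold=display_threshold,
        frame_weight_sum=float(wsum),
    )
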