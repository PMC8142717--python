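"""Circular descriptive statistics and within-subject confidence intervals.

Bias and dispersion of color reports are summarized as the circular mean
and circular standard deviation of the mean resultant vector:

    R-bar = | mean_j exp(i * theta_j) |
    mean  = arg( mean_j exp(i * theta_j) )
    SD    = sqrt(-2 ln R-bar)            (radians, reported in degrees)

The alternative angular deviation sqrt(2 (1 - R-bar)) is provided but is
not the default dispersion measure.

Error bars for repeated-measures condition means use Cousineau
normalization (remove each participant's mean, add back the grand mean)
with the Morey sqrt(C/(C-1)) bias correction on the normalized variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .angles import wrap_deg

__all__ = [
    "CircularSummary",
    "circ_mean",
    "circ_sd",
    "angular_deviation",
    "circular_summary",
    "within_subject_ci",
]

#: resultant lengths below this are treated as "mean direction undefined"
RESULTANT_FLOOR = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean, SD and resultant length for one condition cell."""

    mean_deg: float
    sd_deg: float
    resultant_length: float
    n: int
    mean_defined: bool = True


def _resultant(angles_deg):
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular statistics require at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    z = np.exp(1j * a).mean()
    return min(float(np.abs(z)), 1.0), np.angle(z)


def circ_mean(angles_deg):
    """Circular mean of angles in degrees.

    Returns
    -------
    mean_deg : float
        Direction of the mean resultant vector, in (-180, 180].
    resultant_length : float
        R-bar in [0, 1].
    """
    rbar, ang = _resultant(angles_deg)
    return wrap_deg(np.degrees(ang)), float(rbar)


def circ_sd(angles_deg):
    """Circular standard deviation sqrt(-2 ln R-bar), in degrees."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise ValueError("circular SD requires at least two angles")
    rbar, _ = _resultant(a)
    if rbar <= RESULTANT_FLOOR:
        warnings.warn("resultant length is numerically zero; circular SD is infinite")
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def angular_deviation(angles_deg):
    """Angular deviation sqrt(2 (1 - R-bar)), in degrees (alternative measure)."""
    rbar, _ = _resultant(angles_deg)
    return float(np.degrees(np.sqrt(2.0 * (1.0 - rbar))))


def circular_summary(angles_deg) -> CircularSummary:
    """Summarize one cell of angles as a :class:`CircularSummary`."""
    a = np.asarray(angles_deg, dtype=float)
    rbar, ang = _resultant(a)
    defined = rbar > RESULTANT_FLOOR
    if defined:
        sd = float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))
        mean = wrap_deg(np.degrees(ang))
    else:
        sd = float("inf")
        mean = 0.0
    return CircularSummary(
        mean_deg=mean,
        sd_deg=sd,
        resultant_length=float(rbar),
        n=int(a.size),
        mean_defined=bool(defined),
    )


def within_subject_ci(cell_means, level: float = 0.95):
    """Within-subject CI half-widths per condition (Cousineau-Morey).

    Parameters
    ----------
    cell_means : array-like, shape (n_participants, n_conditions)
        Complete matrix of per-participant condition means (degrees). The
        cell means are small relative to the circle, so they are treated
        linearly.
    level : float
        Confidence level, default 0.95.

    Returns
    -------
    ndarray, shape (n_conditions,)
        CI half-width per condition.
    """
    y = np.asarray(cell_means, dtype=float)
    if y.ndim != 2:
        raise ValueError("cell_means must be a participants x conditions matrix")
    n, c = y.shape
    if n < 2 or c < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if not np.all(np.isfinite(y)):
        raise ValueError("cell_means must be complete (no missing cells)")
    # Cousineau: remove participant means, restore the grand mean.
    normalized = y - y.mean(axis=1, keepdims=True) + y.mean()
    morey = c / (c - 1.0)
    var = normalized.var(axis=0, ddof=1) * morey
    sem = np.sqrt(var / n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return tcrit * sem
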