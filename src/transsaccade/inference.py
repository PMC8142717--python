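"""Bayesian t-tests, correlation tests and the awareness permutation test.

The Bayes factor implemented here is the JZS (Jeffreys-Zellner-Siow)
default for one-sample / paired designs: a Cauchy(0, r) prior on the
standardized effect size delta (default scale r = sqrt(2)/2) against the
point null delta = 0. Writing the Cauchy as a scale mixture of normals,
delta | g ~ N(0, g r^2) with g ~ InverseGamma(1/2, 1/2), the Bayes
factor reduces to a one-dimensional integral over g (Rouder et al. 2009):

    BF10 = [ integral_0^inf (1 + N g r^2)^(-1/2)
             (1 + t^2 / ((1 + N g r^2) nu))^(-(nu+1)/2) pi(g) dg ]
           / (1 + t^2/nu)^(-(nu+1)/2)

with pi(g) = (2 pi)^(-1/2) g^(-3/2) exp(-1/(2g)), nu = N - 1. The
integral is evaluated by adaptive quadrature.

The permutation test shuffles the aware/unaware labels between
participants, preserving group sizes; when the number of distinct label
assignments C(n, k) is at most 20,000 the null distribution is
enumerated exactly instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "BayesFactorResult",
    "PermutationResult",
    "DEFAULT_PRIOR_SCALE",
    "bf_from_t",
    "bf_ttest",
    "correlation_bf",
    "within_subject_correlation",
    "permutation_test",
]

DEFAULT_PRIOR_SCALE = float(np.sqrt(2.0) / 2.0)
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    t_stat: float
    df: int
    prior_scale: float
    n: int

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    null_distribution: np.ndarray = field(repr=False)
    n_reps: int
    percentile_95: float
    exceeds: bool
    seed: int | None
    method: str  # "exact" or "sampling"
    two_sided: bool = False


def bf_from_t(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS Bayes factor BF10 from a one-sample/paired t statistic.

    Adaptive quadrature of the scale-mixture integral; `n` is the number
    of (difference) observations, df = n - 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    t = float(t)
    nu = n - 1
    r2 = prior_scale**2

    def integrand(g):
        c = 1.0 + n * g * r2
        like = c**-0.5 * (1.0 + t * t / (c * nu)) ** (-(nu + 1) / 2.0)
        prior = g**-1.5 * np.exp(-1.0 / (2.0 * g)) / np.sqrt(2.0 * np.pi)
        return like * prior

    num, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / den


def bf_ttest(x, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesFactorResult:
    """One-sample (or paired-difference) JZS Bayes-factor t-test.

    `x` holds the per-participant values (or paired differences) tested
    against zero.
    """
    a = np.asarray(x, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(a)):
        raise ValueError("values must be finite")
    sd = a.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance input: t statistic undefined")
    n = int(a.size)
    t = a.mean() / (sd / np.sqrt(n))
    return BayesFactorResult(
        bf10=bf_from_t(t, n, prior_scale),
        t_stat=float(t),
        df=n - 1,
        prior_scale=float(prior_scale),
        n=n,
    )


def correlation_bf(per_participant_r, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesFactorResult:
    """Bayesian t-test of Fisher-transformed correlations against zero."""
    r = np.asarray(per_participant_r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("correlations must satisfy |r| < 1")
    return bf_ttest(np.arctanh(r), prior_scale=prior_scale)


def within_subject_correlation(trials: pd.DataFrame, x_col: str, y_col: str):
    """Per-participant Pearson correlation between two trial-level columns.

    Returns ``(per_participant, mean_r, sd_r)`` where `per_participant`
    is a Series indexed by participant. Participants with a constant
    column are skipped (at least 3 paired trials are required).
    """
    rs = {}
    for pid, sub in trials.groupby("participant_id"):
        x = sub[x_col].to_numpy(dtype=float)
        y = sub[y_col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"participant {pid}: need >= 3 paired trials")
        if x[ok].std() == 0 or y[ok].std() == 0:
            continue
        rs[pid] = stats.pearsonr(x[ok], y[ok]).statistic
    per = pd.Series(rs, name=f"r({x_col},{y_col})")
    return per, float(per.mean()), float(per.std(ddof=1)) if len(per) > 1 else float("nan")


def permutation_test(
    values,
    labels,
    n_reps: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
    two_sided: bool = False,
) -> PermutationResult:
    """Group-difference permutation test over aware/unaware labels.

    The statistic is mean(values | label True) - mean(values | label
    False); label shuffles preserve group sizes. With ``method="auto"``
    the null is enumerated exactly when C(n, k) <= 20,000, otherwise
    `n_reps` random shuffles are drawn. One-sided by default: ``exceeds``
    is True when the observed difference is greater than the 95th
    percentile of the null.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.shape != lab.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D and the same length")
    n = v.size
    k = int(lab.sum())
    if k == 0 or k == n:
        raise ValueError("both label classes must be non-empty")

    def diff(mask):
        return v[mask].mean() - v[~mask].mean()

    observed = diff(lab)
    if method == "auto":
        method = "exact" if comb(n, k) <= EXACT_ENUMERATION_LIMIT else "sampling"
    if method == "exact":
        null = np.empty(comb(n, k))
        mask = np.zeros(n, dtype=bool)
        for i, idx in enumerate(combinations(range(n), k)):
            mask[:] = False
            mask[list(idx)] = True
            null[i] = diff(mask)
    elif method == "sampling":
        rng = np.random.default_rng(seed)
        null = np.empty(n_reps)
        for i in range(n_reps):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:k]] = True
            null[i] = diff(mask)
    else:
        raise ValueError(f"unknown method {method!r}")

    if two_sided:
        p95 = float(np.percentile(np.abs(null), 95))
        exceeds = abs(observed) > p95
    else:
        p95 = float(np.percentile(null, 95))
        exceeds = observed > p95
    return PermutationResult(
        observed_diff=float(observed),
        null_distribution=null,
        n_reps=int(null.size),
        percentile_95=p95,
        exceeds=bool(exceeds),
        seed=seed,
        method=method,
        two_sided=two_sided,
    )
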