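"""Optimal (reliability-weighted) integration of pre- and post-saccadic views.

Two noisy circular estimates with von Mises likelihoods VM(mu1, k1) and
VM(mu2, k2) combine, under the product rule, into a von Mises posterior
whose mean direction and concentration are given by the vector sum of the
concentration-weighted unit vectors:

    k_c e^{i mu_c} = k1 e^{i mu1} + k2 e^{i mu2}

For small discrepancies this reduces to the familiar precision-weighted
average with weight w_post = k_post / (k_pre + k_post) on the second cue.

Reliabilities are estimated from single-view conditions by converting the
observed circular SD to a concentration via the inverse of

    sd(kappa) = sqrt(-2 ln( I1(kappa) / I0(kappa) ))

and the predicted BOTH-condition bias and dispersion follow either from
the closed-form combination (bias) or from forward simulation of the full
generative chain (dispersion), because the posterior concentration of a
single trial is not the same thing as the across-trial spread of the
combined estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .angles import wrap_deg
from .design import SHIFT_MAGNITUDE_DEG

__all__ = [
    "IntegrationPrediction",
    "KAPPA_CAP",
    "kappa_to_sd",
    "sd_to_kappa",
    "combine_vonmises",
    "chain_response_moment",
    "predict_both",
    "simulate_integration_chain",
]

#: concentration returned for circular SDs indistinguishable from zero
KAPPA_CAP = 1e6


@dataclass(frozen=True)
class IntegrationPrediction:
    """Predicted BOTH-condition performance from single-view reliabilities."""

    kappa_pre: float
    kappa_post: float
    w_post: float
    pred_bias_deg: float
    pred_sd_deg: float
    pred_bias_product_deg: float
    pred_bias_linear_deg: float
    pred_sd_naive_deg: float
    delta_deg: float = SHIFT_MAGNITUDE_DEG


def _A(kappa):
    """Mean resultant length of VM(., kappa): I1(kappa)/I0(kappa)."""
    k = np.asarray(kappa, dtype=float)
    return special.i1e(k) / special.i0e(k)


def kappa_to_sd(kappa) -> float:
    """Circular SD (degrees) of a von Mises with concentration `kappa`."""
    k = float(kappa)
    if k < 0:
        raise ValueError("kappa must be non-negative")
    if k == 0.0:
        return float("inf")
    rbar = float(_A(k))
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def sd_to_kappa(sd_deg) -> float:
    """Von Mises concentration whose circular SD (degrees) equals `sd_deg`.

    Monotone Brent inversion to |delta sd| < 1e-9 rad; capped at
    :data:`KAPPA_CAP` as sd -> 0, and 0 (uniform) for SDs implying a
    vanishing resultant length.
    """
    sd = float(sd_deg)
    if sd <= 0:
        if sd < 0:
            raise ValueError("sd_deg must be positive")
        return KAPPA_CAP
    sd_rad = np.radians(sd)
    rbar_target = np.exp(-0.5 * sd_rad**2)
    if rbar_target >= float(_A(KAPPA_CAP)):
        return KAPPA_CAP
    if rbar_target <= 1e-12:
        return 0.0

    def f(k):
        return float(_A(k)) - rbar_target

    lo, hi = 1e-12, 10.0
    while f(hi) < 0 and hi < KAPPA_CAP:
        hi *= 10.0
    return float(optimize.brentq(f, lo, min(hi, KAPPA_CAP), xtol=1e-12, rtol=1e-14))


def combine_vonmises(mu1_deg, kappa1, mu2_deg, kappa2):
    """Product-rule combination of two von Mises estimates (degrees).

    Returns ``(mu_c_deg, kappa_c)`` from the vector sum of the
    concentration-weighted unit vectors. With both concentrations zero the
    mean is undefined and NaN is returned for it.
    """
    k1 = np.asarray(kappa1, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    if np.any(k1 < 0) or np.any(k2 < 0):
        raise ValueError("concentrations must be non-negative")
    m1 = np.radians(mu1_deg)
    m2 = np.radians(mu2_deg)
    z = k1 * np.exp(1j * m1) + k2 * np.exp(1j * m2)
    kappa_c = np.abs(z)
    mu_c = np.degrees(np.angle(z))
    mu_c = np.where(kappa_c > 0, mu_c, np.nan)
    if np.ndim(mu_c) == 0:
        return wrap_deg(float(mu_c)), float(kappa_c)
    return wrap_deg(mu_c), kappa_c


def simulate_integration_chain(
    kappa_pre,
    kappa_post,
    n: int,
    rng,
    delta_deg: float = SHIFT_MAGNITUDE_DEG,
    lapse: float = 0.0,
):
    """Simulate aligned BOTH-condition responses from the generative chain.

    Per trial: draw the latent pre-saccadic estimate from VM(0, kappa_pre)
    and the post-saccadic estimate from VM(delta, kappa_post), combine
    them by the product rule, then draw the response from the combined
    posterior VM(mu_c, kappa_c). With probability `lapse` the response is
    uniform. Returns aligned responses in degrees, wrapped to (-180, 180].
    """
    x_pre = np.degrees(rng.vonmises(0.0, kappa_pre, size=n))
    x_post = np.degrees(rng.vonmises(np.radians(delta_deg), kappa_post, size=n))
    mu_c, kappa_c = combine_vonmises(x_pre, kappa_pre, x_post, kappa_post)
    resp = np.degrees(rng.vonmises(np.radians(mu_c), kappa_c, size=n))
    if lapse > 0:
        is_lapse = rng.uniform(size=n) < lapse
        resp = np.where(is_lapse, rng.uniform(-180.0, 180.0, size=n), resp)
    return wrap_deg(resp)


#: concentrations above this are treated as noiseless in the chain quadrature
_KAPPA_DELTA = 200.0


def chain_response_moment(
    kappa_pre,
    kappa_post,
    delta_deg: float = SHIFT_MAGNITUDE_DEG,
    n_latent: int = 256,
):
    """First circular moment of the generative BOTH-trial response.

    The response distribution is the chain: latent estimates around 0
    and `delta`, product-rule combination, then a von Mises draw around
    the combined posterior. Conditional on the latents the response has
    circular moment A(kappa_c) exp(i mu_c), so the across-trial moment
    is the expectation of that over the latent grid (periodic trapezoid
    rule; concentrations above ~200 are treated as noiseless).

    Returns the complex moment; its argument is the predicted bias and
    sqrt(-2 ln |.|) the predicted circular SD.
    """
    delta = np.radians(delta_deg)
    e = np.linspace(-np.pi, np.pi, n_latent, endpoint=False)

    def latent_weights(kappa):
        if kappa >= _KAPPA_DELTA:
            return np.zeros(1), np.ones(1)
        w = np.exp(kappa * (np.cos(e) - 1.0))
        return e, w / w.sum()

    e1, w1 = latent_weights(kappa_pre)
    e2, w2 = latent_weights(kappa_post)
    z = (
        kappa_pre * np.exp(1j * e1)[:, None]
        + kappa_post * np.exp(1j * (delta + e2))[None, :]
    )
    kc = np.abs(z)
    moments = _A(kc) * z / np.where(kc > 0, kc, 1.0)
    return complex((w1[:, None] * w2[None, :] * moments).sum())


def predict_both(
    sd_pre_deg,
    sd_post_deg,
    delta_deg: float = SHIFT_MAGNITUDE_DEG,
    n_latent: int = 256,
) -> IntegrationPrediction:
    """Predict BOTH-condition bias and SD from single-view circular SDs.

    ``pred_bias_deg`` and ``pred_sd_deg`` are the circular mean and SD
    of the full generative response chain (deterministic quadrature via
    :func:`chain_response_moment`), i.e. the across-trial quantities a
    simulated or empirical BOTH condition is summarized by. Also
    reported for comparison: the single-trial product-rule direction
    ``pred_bias_product_deg``, the small-angle precision-weighted bias
    ``w_post * delta``, and the naive SD obtained by converting the
    combined concentration (a single-trial posterior width, not an
    across-trial dispersion).
    """
    kp = sd_to_kappa(sd_pre_deg)
    kq = sd_to_kappa(sd_post_deg)
    w_post = kq / (kp + kq)
    mu_c, kappa_c = combine_vonmises(0.0, kp, delta_deg, kq)
    m1 = chain_response_moment(kp, kq, delta_deg=delta_deg, n_latent=n_latent)
    rbar = abs(m1)
    return IntegrationPrediction(
        kappa_pre=kp,
        kappa_post=kq,
        w_post=float(w_post),
        pred_bias_deg=float(wrap_deg(np.degrees(np.angle(m1)))),
        pred_sd_deg=float(np.degrees(np.sqrt(-2.0 * np.log(min(rbar, 1.0))))),
        pred_bias_product_deg=float(mu_c),
        pred_bias_linear_deg=float(w_post * delta_deg),
        pred_sd_naive_deg=kappa_to_sd(kappa_c),
        delta_deg=float(delta_deg),
    )
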