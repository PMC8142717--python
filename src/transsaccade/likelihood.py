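"""Trial likelihood of the resource-limited observer.

Single-view trials have closed-form densities: the aligned error is von
Mises around 0 (PRE-only, concentration set by the probed item's
resource share) or around the 25-deg shift (POST-only, concentration
kappa_post), mixed with a uniform lapse component.

BOTH trials marginalize over the two latent estimates: the response is
von Mises around the product-rule combination of the latents, so its
marginal density is a double integral over the latent pre/post errors.
The integral is evaluated by the periodic trapezoid rule on an
`n_latent`-point grid per latent (spectrally accurate for von Mises
factors with concentration well below ~n_latent), and the resulting
density is tabulated on a uniform response grid and interpolated at the
observed errors. Everything is deterministic, so the log-likelihood is a
smooth function of the parameters and safe to optimize with
quasi-Newton methods.

Concentrations much above ~60 are not resolved by the default grids;
fitting bounds cap kappa there.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["vm_logpdf", "vm_pdf", "both_density_grid", "interp_circular"]

TWO_PI = 2.0 * np.pi


def _log_i0(kappa):
    return np.log(special.i0e(kappa)) + kappa


def vm_logpdf(x_rad, mu_rad, kappa):
    """Log density of VM(mu, kappa) at x (radians), overflow-safe."""
    k = np.asarray(kappa, dtype=float)
    return k * (np.cos(np.asarray(x_rad) - mu_rad) - 1.0) - np.log(TWO_PI * special.i0e(k))


def vm_pdf(x_rad, mu_rad, kappa):
    return np.exp(vm_logpdf(x_rad, mu_rad, kappa))


def both_density_grid(kappa_pre, kappa_post, delta_rad, r_grid_rad, n_latent: int = 72):
    """Marginal density of the aligned BOTH-trial response on a grid.

    Latent pre error e1 ~ VM(0, kappa_pre), latent post estimate sits at
    delta + e2 with e2 ~ VM(0, kappa_post); response ~ VM(mu_c, kappa_c)
    of the product-rule combination. Returns the density (per radian)
    evaluated at `r_grid_rad`.
    """
    e = np.linspace(-np.pi, np.pi, n_latent, endpoint=False)
    w1 = vm_pdf(e, 0.0, kappa_pre) * (TWO_PI / n_latent)
    w2 = vm_pdf(e, 0.0, kappa_post) * (TWO_PI / n_latent)
    z = kappa_pre * np.exp(1j * e)[:, None] + kappa_post * np.exp(1j * (delta_rad + e))[None, :]
    kc = np.abs(z)
    mu = np.angle(z)
    # weight of each latent pair, with the response-VM normalizer folded in
    w = (w1[:, None] * w2[None, :]) / (TWO_PI * special.i0e(kc))
    kc = kc.ravel()
    mu = mu.ravel()
    dens = np.exp(kc[:, None] * (np.cos(r_grid_rad[None, :] - mu[:, None]) - 1.0))
    return w.ravel() @ dens


def interp_circular(x_rad, grid_rad, values):
    """Linear interpolation of a periodic tabulated function.

    `grid_rad` must be uniform over [-pi, pi) (endpoint excluded)."""
    n = grid_rad.size
    step = TWO_PI / n
    pos = (np.asarray(x_rad) - grid_rad[0]) / step
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    return values[i0] * (1.0 - frac) + values[(i0 + 1) % n] * frac
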