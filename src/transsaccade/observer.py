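"""Resource-limited, optimally integrating observer.

The pre-saccadic display is encoded under a continuous-resource rule: an
item receiving a share ``s`` of the memory resource is encoded with von
Mises concentration

    kappa_pre(s) = kappa1 * s ** alpha

so a lone item (share 1) is encoded at ``kappa1`` and, with ``alpha = 1``,
per-item precision is proportional to its share. Without a cue each of N
items receives share 1/N; an arrow cue diverts a fraction ``p_cue`` to
the cued item, the remaining items sharing the rest equally. Setting
``p_cue = 1/4`` at set size 4 reproduces the no-cue allocation exactly.

The post-saccadic view is encoded at fixed concentration ``kappa_post``
(a single foveally-relevant item; no load dependence). On BOTH trials the
two noisy estimates are combined by the von Mises product rule and the
response is drawn from the combined posterior; single-view trials report
the corresponding single estimate. A ``lapse`` fraction of responses is
uniform on the wheel.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .angles import to_circle_deg
from .integration import combine_vonmises

__all__ = ["ObserverParams", "kappa_pre_for_share", "resource_share", "simulate_responses"]


@dataclass
class ObserverParams:
    """Generative parameters of the resource-limited observer.

    Defaults give a realistic Experiment-1-like observer: single-item
    pre-saccadic encoding substantially more reliable than the peripheral
    post-saccadic view, declining slightly faster than proportionally
    with load, and a small lapse rate.
    """

    kappa1: float = 12.0
    alpha: float = 1.2
    p_cue: float = 0.5
    kappa_post: float = 3.0
    lapse: float = 0.02
    seed: int = 0
    #: simulate POST-only responses from the post view alone (the
    #: pre-saccadic exposure of the probed item leaves no residual trace)
    post_only_pure: bool = True
    #: additive bias (deg) applied to aware participants' aligned errors;
    #: 0 by default so awareness carries no information (a true null)
    aware_bias_deg: float = 0.0

    def validate(self):
        for name in ("kappa1", "alpha", "p_cue", "kappa_post", "lapse"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.kappa1 <= 0 or self.kappa_post <= 0:
            raise ValueError("concentrations must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.25 <= self.p_cue <= 1.0:
            raise ValueError("p_cue must lie in [1/4, 1]")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse must lie in [0, 1)")
        return self

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known).validate()


def kappa_pre_for_share(share, kappa1: float, alpha: float):
    """Per-item pre-saccadic concentration for a given resource share."""
    return kappa1 * np.asarray(share, dtype=float) ** alpha


def resource_share(set_size, cue_condition, probed_is_cued, p_cue: float):
    """Resource share of the probed item.

    No cue: 1/N. With a cue (set size 4): `p_cue` if the probed item was
    cued, (1 - p_cue)/3 otherwise.
    """
    set_size = np.asarray(set_size, dtype=float)
    cue = np.asarray(cue_condition, dtype=object)
    cued = np.asarray(probed_is_cued, dtype=bool)
    share = 1.0 / set_size
    has_cue = (cue == "valid") | (cue == "invalid")
    share = np.where(has_cue & cued, p_cue, share)
    share = np.where(has_cue & ~cued, (1.0 - p_cue) / 3.0, share)
    return share


def simulate_responses(design: pd.DataFrame, params: ObserverParams) -> pd.DataFrame:
    """Simulate color reports for every trial of a design table.

    Returns a copy of `design` with ``response_deg`` filled in (degrees
    on [0, 360)). Reproducible: every participant draws from a substream
    derived from ``params.seed`` and their position in the table, so a
    single participant's trials regenerate identically in isolation.
    """
    params.validate()
    out = design.copy()
    for idx, (pid, sub) in enumerate(out.groupby("participant_id", sort=True), start=1):
        rng = np.random.default_rng([params.seed, 2, idx])
        out.loc[sub.index, "response_deg"] = _simulate_participant(sub, params, rng)
    return out


def _simulate_participant(trials: pd.DataFrame, params: ObserverParams, rng) -> np.ndarray:
    n = len(trials)
    share = resource_share(
        trials["set_size"].to_numpy(),
        trials["cue_condition"].to_numpy(),
        trials["probed_location"].to_numpy() == trials["cued_location"].to_numpy(),
        params.p_cue,
    )
    kappa_pre = kappa_pre_for_share(share, params.kappa1, params.alpha)
    pre = trials["pre_color_deg"].to_numpy(dtype=float)
    post = trials["post_color_deg"].to_numpy(dtype=float)

    x_pre = np.degrees(rng.vonmises(np.radians(pre), kappa_pre, size=n))
    x_post = np.degrees(rng.vonmises(np.radians(post), params.kappa_post, size=n))

    pres = trials["presentation"].to_numpy(dtype=object)
    mu_c, kappa_c = combine_vonmises(x_pre, kappa_pre, x_post, params.kappa_post)
    x_both = np.degrees(rng.vonmises(np.radians(mu_c), kappa_c, size=n))

    # POST-only: by default the report relies on the post view alone, even
    # though the probed item was also displayed pre-saccadically; setting
    # post_only_pure=False integrates the residual pre-saccadic trace just
    # like a BOTH trial
    x_post_only = x_post if params.post_only_pure else x_both
    resp = np.where(
        pres == "pre_only", x_pre, np.where(pres == "post_only", x_post_only, x_both)
    )
    if params.lapse > 0:
        is_lapse = rng.uniform(size=n) < params.lapse
        resp = np.where(is_lapse, rng.uniform(0.0, 360.0, size=n), resp)
    if params.aware_bias_deg != 0.0 and bool(trials["aware"].iloc[0]):
        # push aware participants' reports toward the post-saccadic color
        resp = resp + params.aware_bias_deg * trials["shift_dir"].to_numpy(dtype=float)
    return to_circle_deg(resp)
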