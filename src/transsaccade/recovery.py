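"""Parameter-recovery study: simulate a known observer, refit, compare.

Recovery uses a joint design mixing set-size trials (Experiment 1
layout) with cue x presentation trials (Experiment 2 layout), simulated
from a single set of observer parameters. Set-size variation identifies
the precision--share power law (kappa1, alpha), the cue conditions
identify p_cue, and the single-view conditions pin kappa_pre and
kappa_post separately; an Experiment-2-only design leaves (kappa1,
alpha) identified only through extrapolation over three nearby shares
and is much less stable at a few thousand trials.
"""

from __future__ import annotations

import pandas as pd

from .design import generate_design
from .model import ObserverModel, _PARAM_NAMES
from .observer import ObserverParams, simulate_responses

__all__ = ["make_recovery_design", "recovery_study"]


def make_recovery_design(seed: int, n_exp1_participants: int = 4, n_exp2_participants: int = 4):
    """Joint Exp1 + Exp2 design (~5,000 trials at the defaults)."""
    d1 = generate_design(1, n_exp1_participants, seed)
    d2 = generate_design(2, n_exp2_participants, seed)
    d2 = d2.assign(participant_id="X" + d2["participant_id"].astype(str))
    return pd.concat([d1, d2], ignore_index=True)


def recovery_study(
    true_params: ObserverParams | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    **design_kw,
) -> pd.DataFrame:
    """Fit `n_replicates` fresh simulations from `true_params`.

    Returns one row per replicate with the recovered parameters, plus
    `true_<name>` columns, ready for bias/relative-error summaries.
    """
    if true_params is None:
        true_params = ObserverParams(kappa1=15.0, alpha=1.0, p_cue=0.4, kappa_post=10.0, lapse=0.03)
    rows = []
    for rep in range(n_replicates):
        design = make_recovery_design(seed=int(1e6) + seed * 1000 + rep, **design_kw)
        params = ObserverParams(**{**true_params.to_dict(), "seed": seed * 1000 + rep})
        trials = simulate_responses(design, params)
        res = ObserverModel(trials).fit(seed=seed)
        row = {"replicate": rep, "converged": res.converged, "llf": res.llf}
        for name in _PARAM_NAMES:
            row[name] = getattr(res.params, name)
            row[f"true_{name}"] = getattr(true_params, name)
            row[f"se_{name}"] = res.bse[name]
        rows.append(row)
    return pd.DataFrame(rows)
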