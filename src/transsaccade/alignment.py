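"""Rotation, reflection and per-participant debiasing of color reports.

Reports are expressed relative to the probed item's colors: the raw
response is rotated so 0 deg is the pre-saccadic color, then trials whose
intrasaccadic shift was clockwise are reflected so that the post-saccadic
color always sits at +25 deg. In the resulting aligned frame, positive
errors point toward the post-saccadic color and the circular mean of the
aligned errors is the integration bias.

Because half the trials are reflected, a constant clockwise (or
counter-clockwise) response bias cancels out of the circular mean but
inflates the circular SD. For dispersion estimates only, each
participant's overall bias — the circular mean of their rotated,
*unreflected* errors — is subtracted before reflecting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .circstats import circ_mean, RESULTANT_FLOOR

__all__ = ["align", "debias_per_participant", "ALIGNED_COLUMNS"]

logger = logging.getLogger(__name__)

ALIGNED_COLUMNS = ["error_rot_deg", "error_aligned_deg", "error_debiased_deg"]


def align(trials: pd.DataFrame) -> pd.DataFrame:
    """Append aligned-error columns to a trial table.

    Adds ``error_rot_deg`` (response minus pre-saccadic color, wrapped to
    (-180, 180], rotation only) and ``error_aligned_deg`` (additionally
    reflected so the post-saccadic color is at +25 deg). Trials without a
    response are dropped with a logged count.
    """
    out = trials.copy()
    missing = out["response_deg"].isna()
    if missing.any():
        logger.info("align: dropping %d trial(s) without a response", int(missing.sum()))
        out = out.loc[~missing].copy()
    rot = wrap_deg(out["response_deg"].to_numpy(float) - out["pre_color_deg"].to_numpy(float))
    sign = np.sign(out["shift_dir"].to_numpy(float))
    out["error_rot_deg"] = rot
    out["error_aligned_deg"] = wrap_deg(sign * rot)
    return out


def debias_per_participant(
    aligned: pd.DataFrame, by_condition: list[str] | None = None
) -> pd.DataFrame:
    """Subtract each participant's overall response bias before reflecting.

    For each participant, the bias ``b`` is the circular mean of
    ``error_rot_deg`` over all of their included trials; the debiased
    aligned error is ``sign * wrap(error_rot - b)``, stored as
    ``error_debiased_deg``. The debiased values feed circular-SD
    estimates only — reflecting makes the subtraction cancel out of the
    circular mean, which is always computed from ``error_aligned_deg``.

    Parameters
    ----------
    aligned : DataFrame
        Output of :func:`align`.
    by_condition : list of str, optional
        Extra grouping columns for a sensitivity analysis in which the
        bias is estimated within condition cells rather than pooled
        (default: pooled per participant, as in the primary analysis).
    """
    out = aligned.copy()
    group_cols = ["participant_id"] + (by_condition or [])
    debiased = np.empty(len(out), dtype=float)
    for _, sub in out.groupby(group_cols, sort=False):
        if len(sub) < 2:
            raise ValueError("debiasing requires at least 2 trials per participant")
        b, rbar = circ_mean(sub["error_rot_deg"].to_numpy())
        if rbar <= RESULTANT_FLOOR:
            logger.warning(
                "debias: resultant length ~0 for group %s; using bias 0",
                sub[group_cols].iloc[0].to_dict(),
            )
            b = 0.0
        sign = np.sign(sub["shift_dir"].to_numpy(float))
        debiased[out.index.get_indexer(sub.index)] = wrap_deg(
            sign * wrap_deg(sub["error_rot_deg"].to_numpy() - b)
        )
    out["error_debiased_deg"] = debiased
    return out
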