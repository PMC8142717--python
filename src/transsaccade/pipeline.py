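"""End-to-end orchestration: simulate -> align -> summarize -> predict -> infer.

Every stage is a pure function of its inputs and the master seed, so a
run is fully reproducible from its config file; rerunning with the same
config yields byte-identical CSV outputs. A JSON manifest records the
config, seeds and produced files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import align, debias_per_participant
from .circstats import circ_mean, circ_sd, within_subject_ci
from .design import generate_design, CUE_CONDITIONS, PRESENTATIONS
from .inference import (
    DEFAULT_PRIOR_SCALE,
    bf_ttest,
    correlation_bf,
    permutation_test,
    within_subject_correlation,
)
from .integration import predict_both
from .observer import ObserverParams, simulate_responses

__all__ = [
    "RunConfig",
    "run_experiment",
    "summarize_conditions",
    "predictions_from_summary",
    "standard_inference",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible description of one simulated experiment run."""

    experiment: int = 1
    n_participants: int = 14
    observer: ObserverParams = field(default_factory=ObserverParams)
    debias_by_condition: bool = False
    prediction_level: str = "participant"  # or "group"
    prior_scale: float = DEFAULT_PRIOR_SCALE
    permutation_reps: int = 10_000
    seed: int = 0
    out_dir: str = "run_output"
    make_figures: bool = True

    def to_yaml(self, path):
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = ObserverParams.from_dict(d["observer"])
        return cls(**d)


def condition_columns(experiment: int) -> list[str]:
    return ["set_size"] if experiment == 1 else ["cue_condition", "presentation"]


def summarize_conditions(aligned: pd.DataFrame, experiment: int):
    """Per-participant and group-level bias/SD summaries by condition cell.

    Bias is the circular mean of the aligned error; SD is the circular SD
    of the debiased error (falling back to the aligned error when the
    debias stage was skipped). The group table averages participant cell
    means and attaches 95% within-subject CI half-widths.
    """
    cols = condition_columns(experiment)
    sd_col = "error_debiased_deg" if "error_debiased_deg" in aligned.columns else "error_aligned_deg"
    recs = []
    for key, sub in aligned.groupby(["participant_id"] + cols):
        key = key if isinstance(key, tuple) else (key,)
        bias, rbar = circ_mean(sub["error_aligned_deg"].to_numpy())
        recs.append(
            dict(zip(["participant_id"] + cols, key))
            | {
                "bias_deg": bias,
                "sd_deg": circ_sd(sub[sd_col].to_numpy()),
                "resultant_length": rbar,
                "n": len(sub),
            }
        )
    per = pd.DataFrame(recs)

    group_recs = []
    bias_ci = _cell_ci(per, cols, "bias_deg")
    sd_ci = _cell_ci(per, cols, "sd_deg")
    for key, sub in per.groupby(cols):
        key = key if isinstance(key, tuple) else (key,)
        group_recs.append(
            dict(zip(cols, key))
            | {
                "bias_deg": sub["bias_deg"].mean(),
                "bias_ci95": bias_ci.get(key, float("nan")),
                "sd_deg": sub["sd_deg"].mean(),
                "sd_ci95": sd_ci.get(key, float("nan")),
                "n_participants": len(sub),
                "n_trials": int(sub["n"].sum()),
            }
        )
    return per, pd.DataFrame(group_recs)


def _cell_ci(per: pd.DataFrame, cols, value_col):
    wide = per.pivot_table(index="participant_id", columns=cols, values=value_col)
    if wide.isna().any().any() or wide.shape[0] < 2 or wide.shape[1] < 2:
        return {}
    hw = within_subject_ci(wide.to_numpy())
    keys = [k if isinstance(k, tuple) else (k,) for k in wide.columns]
    return dict(zip(keys, hw))


def predictions_from_summary(per: pd.DataFrame, level: str = "participant", seed: int = 0):
    """Optimal-integration predictions for the BOTH condition (Experiment 2).

    Derives kappa_pre / kappa_post per cue condition from the PRE-only
    and POST-only circular SDs, either per participant (then averaged,
    the default) or from group-mean SDs.
    """
    out = []
    for cue in CUE_CONDITIONS:
        rows = per[per["cue_condition"] == cue]
        if level == "participant":
            preds = []
            for pid, sub in rows.groupby("participant_id"):
                sd_pre = _cell_value(sub, "pre_only", "sd_deg")
                sd_post = _cell_value(sub, "post_only", "sd_deg")
                if np.isnan(sd_pre) or np.isnan(sd_post):
                    continue
                preds.append(predict_both(sd_pre, sd_post))
            if not preds:
                continue
            rec = {
                "cue_condition": cue,
                "level": level,
                "w_post": float(np.mean([p.w_post for p in preds])),
                "pred_bias_deg": float(np.mean([p.pred_bias_deg for p in preds])),
                "pred_sd_deg": float(np.mean([p.pred_sd_deg for p in preds])),
                "pred_bias_linear_deg": float(np.mean([p.pred_bias_linear_deg for p in preds])),
                "n_participants": len(preds),
            }
        else:
            sd_pre = rows.loc[rows["presentation"] == "pre_only", "sd_deg"].mean()
            sd_post = rows.loc[rows["presentation"] == "post_only", "sd_deg"].mean()
            p = predict_both(sd_pre, sd_post)
            rec = {
                "cue_condition": cue,
                "level": level,
                "w_post": p.w_post,
                "pred_bias_deg": p.pred_bias_deg,
                "pred_sd_deg": p.pred_sd_deg,
                "pred_bias_linear_deg": p.pred_bias_linear_deg,
                "n_participants": int(rows["participant_id"].nunique()),
            }
        out.append(rec)
    return pd.DataFrame(out)


def _cell_value(sub, presentation, col):
    v = sub.loc[sub["presentation"] == presentation, col]
    return float(v.iloc[0]) if len(v) else float("nan")


def standard_inference(
    trials: pd.DataFrame,
    per: pd.DataFrame,
    experiment: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    permutation_reps: int = 10_000,
    seed: int = 0,
) -> dict:
    """The experiment's standard comparisons as a JSON-serializable dict.

    Experiment 1: paired BF t-tests between adjacent set sizes (bias and
    SD), the latency-bias correlation test, and awareness permutation
    tests per set size. Experiment 2: BOTH-condition valid/invalid vs
    no-cue BF tests, the PRE-only cue-effect tests, and awareness
    permutation tests per cue condition.
    """
    results = {"bf_tests": [], "correlations": [], "permutation_tests": []}
    aware_map = trials.groupby("participant_id")["aware"].first()

    def paired_bf(name, cells, measure, wide):
        a, b = cells
        if a not in wide.columns or b not in wide.columns:
            return
        diff = (wide[b] - wide[a]).dropna()
        res = bf_ttest(diff.to_numpy(), prior_scale=prior_scale)
        results["bf_tests"].append(
            {
                "comparison": name,
                "measure": measure,
                "bf10": res.bf10,
                "bf01": res.bf01,
                "t": res.t_stat,
                "df": res.df,
                "n": res.n,
            }
        )

    if experiment == 1:
        for measure in ("bias_deg", "sd_deg"):
            wide = per.pivot_table(index="participant_id", columns="set_size", values=measure)
            for a, b in [(1, 2), (2, 3), (3, 4)]:
                paired_bf(f"set_size {b} vs {a}", (a, b), measure, wide)
        perm_cells = [("set_size", s) for s in (1, 2, 3, 4)]
        cell_cols = ["set_size"]
    else:
        both = per[per["presentation"] == "both"]
        for measure in ("bias_deg", "sd_deg"):
            wide = both.pivot_table(
                index="participant_id", columns="cue_condition", values=measure
            )
            paired_bf(f"BOTH valid vs no_cue", ("no_cue", "valid"), measure, wide)
            paired_bf(f"BOTH invalid vs no_cue", ("no_cue", "invalid"), measure, wide)
        pre = per[per["presentation"] == "pre_only"]
        wide = pre.pivot_table(index="participant_id", columns="cue_condition", values="sd_deg")
        paired_bf("PRE-only valid vs no_cue", ("no_cue", "valid"), "sd_deg", wide)
        paired_bf("PRE-only invalid vs no_cue", ("no_cue", "invalid"), "sd_deg", wide)
        perm_cells = [("cue_condition", c) for c in CUE_CONDITIONS]
        cell_cols = ["cue_condition", "presentation"]

    # saccade-latency correlation with the aligned error (BOTH trials)
    both_trials = trials[trials["presentation"] == "both"].dropna(
        subset=["response_deg", "saccade_latency_ms"]
    )
    if len(both_trials) and "error_aligned_deg" in both_trials.columns:
        per_r, mean_r, sd_r = within_subject_correlation(
            both_trials, "saccade_latency_ms", "error_aligned_deg"
        )
        res = correlation_bf(per_r.to_numpy(), prior_scale=prior_scale)
        results["correlations"].append(
            {
                "comparison": "saccade latency vs aligned error",
                "mean_r": mean_r,
                "sd_r": sd_r,
                "bf10": res.bf10,
                "bf01": res.bf01,
                "n": res.n,
            }
        )

    # awareness permutation tests, per condition cell
    labels = aware_map.astype(bool)
    if labels.any() and not labels.all():
        rng = np.random.default_rng([seed, 4])
        for col, value in perm_cells:
            sub = per[(per[col] == value)]
            if experiment == 2:
                sub = sub[sub["presentation"] == "both"]
            for measure in ("bias_deg", "sd_deg"):
                wide = sub.set_index("participant_id")[measure]
                common = wide.index.intersection(labels.index)
                res = permutation_test(
                    wide.loc[common].to_numpy(),
                    labels.loc[common].to_numpy(),
                    n_reps=permutation_reps,
                    seed=int(rng.integers(2**31)),
                )
                results["permutation_tests"].append(
                    {
                        "cell": f"{col}={value}",
                        "measure": measure,
                        "observed_diff": res.observed_diff,
                        "percentile_95": res.percentile_95,
                        "exceeds": res.exceeds,
                        "method": res.method,
                        "n_reps": res.n_reps,
                    }
                )
    return results


def run_experiment(config: RunConfig) -> dict:
    """Run the full pipeline for one config; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    observer = config.observer.validate()

    logger.info("stage: design+simulate (experiment %d)", config.experiment)
    design = generate_design(config.experiment, config.n_participants, config.seed)
    trials = simulate_responses(design, observer)
    trials.to_csv(out / "trials.csv", index=False)

    logger.info("stage: align")
    aligned = align(trials)
    dropped = len(trials) - len(aligned)
    aligned = debias_per_participant(
        aligned,
        by_condition=condition_columns(config.experiment) if config.debias_by_condition else None,
    )
    aligned.to_csv(out / "aligned.csv", index=False)

    logger.info("stage: summarize")
    per, group = summarize_conditions(aligned, config.experiment)
    per.to_csv(out / "summary_participants.csv", index=False)
    group.to_csv(out / "summary_conditions.csv", index=False)

    predictions = None
    if config.experiment == 2:
        logger.info("stage: predict")
        predictions = predictions_from_summary(
            per, level=config.prediction_level, seed=config.seed
        )
        predictions.to_csv(out / "predictions.csv", index=False)

    logger.info("stage: infer")
    inference = standard_inference(
        aligned,
        per,
        config.experiment,
        prior_scale=config.prior_scale,
        permutation_reps=config.permutation_reps,
        seed=config.seed,
    )
    (out / "inference.json").write_text(json.dumps(inference, indent=2, default=float))

    figures = []
    if config.make_figures:
        logger.info("stage: figures")
        from .plots import figure_pack

        figures = figure_pack(aligned, group, predictions, config.experiment, out)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_trials": int(len(trials)),
        "n_trials_dropped": int(dropped),
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.iterdir() if p.name != "manifest.json"
        ),
        "figures": figures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
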