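"""Static figure pack mirroring the structure of the study's result figures:
aligned-response histograms per condition, and bias / SD versus condition
with within-subject error bars and, for the cueing experiment, the
optimal-integration prediction overlaid."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .design import CUE_CONDITIONS

__all__ = ["figure_pack"]


def figure_pack(aligned, group, predictions, experiment: int, out_dir) -> list[str]:
    out_dir = Path(out_dir)
    made = []
    made.append(_histograms(aligned, experiment, out_dir))
    made.append(_condition_means(group, predictions, experiment, out_dir))
    return made


def _histograms(aligned, experiment, out_dir):
    if experiment == 1:
        cells = [("set_size", s) for s in sorted(aligned["set_size"].unique())]
        sub_all = aligned
    else:
        cells = [("cue_condition", c) for c in CUE_CONDITIONS]
        sub_all = aligned[aligned["presentation"] == "both"]
    fig, axes = plt.subplots(1, len(cells), figsize=(3.2 * len(cells), 3), sharey=True)
    bins = np.arange(-180, 181, 10)
    for ax, (col, val) in zip(np.atleast_1d(axes), cells):
        sub = sub_all[sub_all[col] == val]
        ax.hist(sub["error_aligned_deg"], bins=bins, density=True, color="#7a5195")
        for x, c in [(0, "k"), (25, "0.5")]:
            ax.axvline(x, ls=":", color=c, lw=1)
        ax.set_title(f"{col}={val}", fontsize=9)
        ax.set_xlabel("aligned error (deg)")
        ax.set_xlim(-120, 120)
    np.atleast_1d(axes)[0].set_ylabel("density")
    fig.tight_layout()
    path = out_dir / "response_distributions.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path.name


def _condition_means(group, predictions, experiment, out_dir):
    fig, (ax_b, ax_s) = plt.subplots(1, 2, figsize=(8, 3.2))
    if experiment == 1:
        g = group.sort_values("set_size")
        x = g["set_size"]
        ax_b.errorbar(x, g["bias_deg"], yerr=g["bias_ci95"], fmt="o-", color="#003f5c")
        ax_s.errorbar(x, g["sd_deg"], yerr=g["sd_ci95"], fmt="o-", color="#003f5c")
        for ax in (ax_b, ax_s):
            ax.set_xlabel("set size")
            ax.set_xticks(x)
    else:
        xpos = np.arange(len(CUE_CONDITIONS))
        colors = {"pre_only": "c", "post_only": "b", "both": "#7a5195"}
        for pres, g in group.groupby("presentation"):
            g = g.set_index("cue_condition").loc[list(CUE_CONDITIONS)]
            ax_s.errorbar(
                xpos, g["sd_deg"], yerr=g["sd_ci95"], fmt="o-", label=pres,
                color=colors.get(pres, "k"),
            )
            if pres == "both":
                ax_b.errorbar(
                    xpos, g["bias_deg"], yerr=g["bias_ci95"], fmt="o-", color=colors[pres]
                )
        if predictions is not None and len(predictions):
            p = predictions.set_index("cue_condition").reindex(list(CUE_CONDITIONS))
            ax_b.plot(xpos, p["pred_bias_deg"], "--", color="#7a5195", label="prediction")
            ax_s.plot(xpos, p["pred_sd_deg"], "--", color="#7a5195", label="prediction")
        ax_s.legend(fontsize=7)
        for ax in (ax_b, ax_s):
            ax.set_xticks(xpos, CUE_CONDITIONS)
            ax.set_xlabel("cue condition")
    ax_b.axhline(25, ls=":", color="0.5", lw=1)
    ax_b.set_ylabel("bias toward post-saccadic color (deg)")
    ax_s.set_ylabel("circular SD (deg)")
    fig.tight_layout()
    path = out_dir / "condition_means.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path.name
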