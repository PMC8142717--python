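# transsaccade

Simulation and analysis of **transsaccadic color integration** under a
resource-limited visual working memory observer.

When the eyes move, the visual system does not start over: it combines
what it remembers from before the saccade with what it sees after,
weighting each source by its reliability. In the paradigm this package
models, observers view 1–4 colored disks, saccade across the display,
and report the color of one item whose hue was shifted by Δ = 25° on the
color wheel during the eye movement. Where the report falls between the
pre-saccadic color (0° in the aligned frame) and the post-saccadic color
(+25°) measures the weight given to each view. If the pre-saccadic input
lives in a limited memory resource, its precision — and hence its weight
— should fall with set size and rise with attentional cueing.

The package is aimed at visual-psychophysics and computational-cognition
researchers who want a tested, reproducible implementation of this
analysis chain: trial-design generation for both experiments, a
generative observer, circular statistics, optimal-integration
predictions, observer fitting, and the accompanying Bayesian and
permutation inference. No experimental data ship with it — everything is
exercised on simulated data.

## The model

Encoding noise is von Mises. An item receiving a share *s* of the
pre-saccadic resource is encoded with concentration

> κ_pre(s) = κ₁ · s^α

(share 1/N without a cue; a cued item gets p_cue, each uncued item
(1 − p_cue)/3). The post-saccadic view has fixed concentration κ_post.
On trials with both views the noisy estimates x_pre ~ VM(0, κ_pre) and
x_post ~ VM(Δ, κ_post) combine by the von Mises product rule,

> κ_c e^{iμ_c} = κ_pre e^{i x_pre} + κ_post e^{i x_post},

and the response is drawn from VM(μ_c, κ_c), with a lapse fraction
uniform on the wheel. For small discrepancies this is the classic
precision-weighted average with w_post = κ_post/(κ_pre + κ_post).

Reports are summarized by the circular mean (bias toward the
post-saccadic color) and circular SD √(−2 ln R̄) of the aligned errors,
after per-participant debiasing for the SD. Reliabilities estimated from
PRE-only and POST-only conditions yield parameter-free predictions for
the integrated condition; the observer's five parameters (κ₁, α, p_cue,
κ_post, lapse) can also be fit directly by maximum likelihood
(`ObserverModel(trials).fit()`, statsmodels-style).

## Worked example

```python
import transsaccade as ts

design = ts.generate_design(1, n_participants=14, seed=7)     # 480 trials each
trials = ts.simulate_responses(design, ts.ObserverParams(seed=7))
aligned = ts.debias_per_participant(ts.align(trials))
per, group = ts.summarize_conditions(aligned, experiment=1)
print(group.round(2).to_string(index=False))
```

```
 set_size  bias_deg  bias_ci95  sd_deg  sd_ci95  n_participants  n_trials
        1      3.95       1.08   24.53     1.50              14      1680
        2      8.16       2.00   31.93     1.21              14      1680
        3     10.28       1.47   38.54     1.62              14      1680
        4     15.33       2.28   42.48     1.57              14      1680
```

Bias toward the post-saccadic color grows from ~4° at set size one to
~15° at set size four, and the circular SD rises in parallel — the
signature of a shrinking per-item memory resource with a fixed
post-saccadic reliability. Error bars are 95% within-subject CIs
(Cousineau–Morey). A default-prior Bayes-factor t-test quantifies the
load effect:

```python
wide = per.pivot_table(index="participant_id", columns="set_size", values="bias_deg")
res = ts.bf_ttest((wide[4] - wide[1]).to_numpy())
print(f"BF10 (bias, set size 4 vs 1) = {res.bf10:.1f}  (t = {res.t_stat:.2f}, n = {res.n})")
```

```
BF10 (bias, set size 4 vs 1) = 73538.1  (t = 9.91, n = 14)
```

The same pipeline runs from the shell:

```bash
transsaccade simulate --experiment 2 --participants 15 --seed 1 --out trials.csv
transsaccade align --trials trials.csv --out aligned.csv
transsaccade summarize --trials aligned.csv --experiment 2 --out summary
transsaccade predict --summary summary_participants.csv --out predictions.csv
transsaccade run --config my_run.yaml      # all stages + figures + manifest
```

## Layout

- `transsaccade.design` — trial designs for both experiments, display geometry
- `transsaccade.observer` — generative observer, response simulation
- `transsaccade.alignment` — rotation/reflection alignment, debiasing
- `transsaccade.circstats` — circular mean/SD, within-subject CIs
- `transsaccade.integration` — von Mises combination, κ↔SD, predictions
- `transsaccade.model` — `ObserverModel` / `ObserverFitResults` (ML fitting)
- `transsaccade.inference` — JZS Bayes factors, correlations, permutation test
- `transsaccade.pipeline`, `transsaccade.cli` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
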