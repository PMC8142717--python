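# Methods

This note documents the generative model, the analysis conventions, the
numerical choices, and what the synthetic data can and cannot show.

## Task structure

Two simulated designs, mirroring the two experiments of the paradigm:

- **Set-size design (experiment 1).** 480 trials per participant in 4
  blocks of 120; set sizes 1–4 exactly balanced within block (30 each);
  probed location (A–D) exactly balanced within set size across the
  session (30 per cell) and shift direction within that (15/15). Because
  120 trials per block cannot be split evenly over 16 set-size ×
  location cells, location balance is enforced at session level and
  blocks receive as even an allocation as the arithmetic allows; trials
  are randomly interleaved within block. Every trial shows the probed
  item before and after the saccade (presentation `both`, no cue).
- **Cueing design (experiment 2).** Set size fixed at 4; 3 cue
  conditions (valid / invalid / no cue) × 3 presentation conditions
  (PRE-only / POST-only / BOTH); 792 trials in 8 blocks of 99, 11 per
  condition per block, shift direction balanced 44/44 within condition.
  The cued location is uniform over the four positions; valid trials
  probe the cued item, invalid trials probe one of the three uncued
  items with equal probability, making the cued item three times as
  likely to be probed as any specific uncued item.

On every trial the probed item's color shifts by exactly Δ = 25° on the
wheel during the saccade (direction counterbalanced). Colors are pure
wheel angles; rendering (CIELAB coordinates, display code, gaze
contingency) is out of scope. Both colors are recorded on every
experiment-2 trial regardless of presentation condition.

Display geometry is summarized by `stimulus_geometry()`: items sit on a
4°-radius circle around pre-saccadic fixation at polar angles ±20°
(inner) and ±60° (outer); with the 12° saccade, outer items end up 10.0°
horizontally from post-saccadic fixation and inner items 8.24°. The
horizontal offsets are what distinguishes the location classes; full
Euclidean distances are also reported.

## Generative observer

Five parameters (`ObserverParams`):

| parameter | meaning | default |
|---|---|---|
| κ₁ | von Mises concentration of a lone pre-saccadic item (share 1) | 12 |
| α | power-law exponent of the share → precision mapping | 1.2 |
| p_cue | resource share of a cued item (∈ [¼, 1]; ¼ = no cue effect) | 0.5 |
| κ_post | concentration of the post-saccadic view | 3 |
| lapse | probability of a uniform random report | 0.02 |

κ_pre(s) = κ₁ s^α with s the probed item's share (1/N uncued; p_cue
cued; (1 − p_cue)/3 per uncued item under a cue). The power law is the
standard continuous-resource parameterization; α = 1 is pure
proportional allocation and α is exposed as a fittable quantity. The
post-saccadic view is load-independent (one relevant item after the
saccade).

Responses: PRE-only → x_pre ~ VM(pre, κ_pre); POST-only → x_post ~
VM(post, κ_post); BOTH → a fresh von Mises draw around the product-rule
combination of x_pre and x_post (vector sum of concentration-weighted
unit vectors). The final draw represents read-out noise at the
posterior's own width; no separate motor-noise parameter is added. A
`lapse` fraction of responses is uniform.

The defaults were chosen so an experiment-1 simulation lands in the
empirically typical range (bias a few degrees at set size 1 rising to
~15° at set size 4; SD in the 20–45° range). A single parameter set
cannot simultaneously reproduce the much noisier PRE-only condition of
the cueing experiment (where the probed item vanishes during the
saccade); simulations of that design are qualitative unless parameters
are set per use.

POST-only trials are simulated from the post view alone by default even
though the probed item also appeared pre-saccadically; whether a
residual pre-saccadic trace should contribute is unresolved in the
source analysis, so it is configurable (`post_only_pure=False`
integrates the trace exactly like a BOTH trial) and off by default.

Awareness of the color change is assigned per participant
(Bernoulli, defaults 4/14 and 9/15 for the two designs) and has **no**
effect on responses by default, so the awareness permutation test runs
under a true null; `aware_bias_deg` adds a controlled effect for power
studies. Saccade latencies are drawn from a shifted gamma (shift 120 ms,
shape 9) with means 223→251 ms over set sizes; they exist only to
exercise the correlation analyses, not to model oculomotor dynamics.

Randomness: one master seed; each participant draws from a
deterministically derived substream, so any participant's data
regenerate identically in isolation and pipeline reruns are
byte-identical.

## Alignment and circular summaries

Errors are rotated (response − pre-saccadic color, wrapped to
(−180°, 180°], ties at −180 mapped to +180) and reflected by the shift
sign so the post-saccadic color sits at +25°. Bias is the circular mean
of the aligned errors. For dispersion only, each participant's overall
response bias — the circular mean of their rotated, unreflected errors,
pooled over all trials (per-condition debiasing is available as a
sensitivity option, for both experiments) — is subtracted before
reflection; because half the trials are reflected, this leaves the bias
measure untouched while removing the SD inflation a constant
clockwise/counter-clockwise bias would cause.

Circular SD is √(−2 ln R̄) (degrees); the angular deviation
√(2(1 − R̄)) is provided but not default. Condition error bars are 95%
within-subject CIs: Cousineau normalization of participant × condition
cell means with the Morey √(C/(C−1)) variance correction and a
t-quantile; cell means are treated linearly since they are small
relative to the circle.

## Integration predictions

Single-view circular SDs are converted to concentrations by inverting
sd(κ) = √(−2 ln(I₁(κ)/I₀(κ))) (Brent, |Δsd| < 1e−9 rad, κ capped at 1e6
as sd → 0, κ = 0 for SDs implying vanishing resultant). The BOTH
prediction reports:

- `pred_bias_deg`, `pred_sd_deg` — circular mean and SD of the full
  generative chain, computed as the exact first circular moment of the
  response distribution by quadrature over the latent estimates
  (concentrations above 200 treated as noiseless). These are the
  across-trial quantities an empirical BOTH condition is summarized by,
  and they match forward simulation to well within Monte-Carlo error.
  The single-trial posterior direction μ_c differs from the across-trial
  mean by up to ~1° at strongly asymmetric reliabilities, which is why
  the chain moment, not μ_c, is the headline prediction; μ_c is kept as
  `pred_bias_product_deg`.
- `pred_bias_linear_deg` = 25°·w_post, the small-angle precision-weight
  form (within 0.5° of the product rule in the κ range of interest), and
  `pred_sd_naive_deg`, the SD implied by the combined concentration κ_c
  (a single-trial posterior width — it understates across-trial
  dispersion and is reported only for comparison).

Predictions default to per-participant derivation (then averaged), with
a group-level option; raw single-view SDs are used without lapse
correction, matching standard practice for this prediction.

## Observer fitting

`ObserverModel.fit` maximizes the exact trial likelihood. Single-view
cells are analytic von Mises + uniform mixtures. BOTH cells marginalize
the response density over the two latent estimates with a periodic
trapezoid rule (72 points per latent by default — spectrally accurate
for the von Mises factors involved; concentrations are bounded at 64 in
fitting because coarser structure is not resolved), tabulated on a
144-point response grid and interpolated at the observed errors. The
likelihood is deterministic and smooth, optimized by L-BFGS-B on
transformed parameters (log κ, log α, logit shares) with
method-of-moments starts from the single-view conditions (a coarse grid
start when no single-view cells exist). Standard errors come from the
finite-difference Hessian at the optimum, delta-method-transformed to
the natural scale. Parameters the data carry no information about are
frozen automatically (e.g. p_cue for a design without cues).

Identifiability: set-size variation identifies (κ₁, α); cue conditions
identify p_cue; single-view conditions separate κ_pre from κ_post. The
parameter-recovery study therefore simulates a joint design (4
participants of each experiment, ~5,100 trials) from one observer;
recovery of an experiment-2-only design is possible but much less
stable, since (κ₁, α) are then identified only by extrapolating the
power law over three nearby shares. At these problem sizes the
seed-averaged recovery error is a few percent per parameter.

## Inference

- **JZS Bayes factor** (one-sample / paired): Cauchy(0, r) prior on the
  standardized effect, r = √2/2 by default (exposed as a flag), computed
  by adaptive quadrature of the scale-mixture (inverse-gamma over g)
  integral. Cross-checked in tests against an independent noncentral-t ×
  Cauchy quadrature and against pingouin; agreement is better than 4
  significant figures. Bayesian repeated-measures/mixed ANOVAs are
  deliberately **not** implemented — the pairwise BF t-tests and the
  permutation test carry the pairwise claims; model-averaged ANOVA Bayes
  factors are out of scope.
- **Correlation test**: per-participant Pearson r, Fisher-transformed,
  one-sample BF t-test against zero.
- **Permutation test** over awareness labels: difference of group means,
  label shuffles preserving group sizes, one-sided exceedance against
  the null's 95th percentile (a two-sided variant behind a flag). When
  C(n, k) ≤ 20,000 the null is enumerated exactly instead of sampled;
  with the 4/14 split this is 1,001 assignments. The test statistic is
  computed per condition cell (per set size, or per cue condition in the
  BOTH presentation), all cells reported. Note that a single extreme
  participant cannot produce an exceedance at these group sizes: the
  assignments placing the outlier in the smaller group make up k/n ≈ 29%
  of the null, so detection requires a shift shared by the group.

## Problem sizes and determinism

Default analysis problem sizes were chosen to keep every check sharp but
cheap: qualitative pattern checks use ≥20,000 trials per cell,
generator–predictor consistency 100,000 trials (Monte-Carlo error ≪ the
0.3° band), recovery 10 replicates × ~5,100 trials, permutation
calibration 2,000 exact-null replications. All simulations are seeded;
property-based tests run derandomized.

## What passing tests do and do not show

The synthetic generator reproduces the *designs* and an idealized
observer: stationary parameters, independent trials, no sequential
effects, no motor noise beyond the posterior draw, no swap/misbinding
errors, no fixation or latency influence on encoding (latencies are
decorative), and awareness with no behavioral consequence. Passing tests
validate the analysis chain and the internal consistency of the
generative account — they do not certify that real observers satisfy
these assumptions, and empirical effect sizes from human data are not
reproducible from simulation.
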