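# Methods

This note documents the models, defaults, and numerical choices behind
`numopop`, and what passing its tests does and does not establish.

## Task and data model

A trial runs fixation (default 500 ms, times negative relative to
instruction onset), instruction (500 ms), motor planning (1000 ms), and
execution (1000 ms simulated). The condition grid crosses five
numerosities (1–5), two stimulus formats (dot arrays vs numeral signs),
and two stimulus conditions (standard vs visually controlled), giving 20
conditions; each session additionally pairs the standard temporal
arrangement of the execution period with one of two controls (constant
200 ms intervals, or a fixed-total-duration interval table), alternating
by session. Datasets are two CSV tables (trials, spikes), a neuron
table, and a JSON metadata file — diffable, language-neutral, and
round-trip exact (`float_precision="round_trip"` on read). All bins are
half-open `[a, b)` with left-edge alignment; a 200 ms window stepped by
20 ms over 100–1600 ms gives 66 bins.

## Behavioral model

No generative behavioral model is prescribed by the experimental
literature this package serves; the log-Gaussian internal-estimate model
is this package's own choice and is documented as such. The produced
count is `round(exp(x))`, `x ~ Normal(log n, w)`, clipped to ≥ 1, with
Weber fraction `w` (default 0.2, a typical primate value). On a
logarithmic axis a constant `w` yields both signatures of the
approximate number system: errors concentrate at numerically adjacent
values (distance effect) and response spread grows proportionally with
`n` (size effect). With `w = 0` behavior is error-free. Aborted trials
(fixation breaks; default 5% extra trials) carry no produced count and
are excluded from every behavioral ratio. The chance construction — 100
divided by the modal unrestricted maximum count — is heuristic but
implemented exactly as specified; the per-stratum chance is exposed as a
parameter (global default 12.5%).

## Spiking model

Each neuron is an inhomogeneous Poisson process with piecewise-constant
rate

    lambda(t) = max(0, baseline + gain * G(n) * 1[t in window]),
    G(n) = exp(-(log n - log pref)^2 / (2 width^2)),

with tuning on a log-numerosity axis (a linear axis is a flag).
Defaults: baseline 5–15 Hz, gain 15–25 Hz (negative for the inhibited
fraction, 25% of tuned neurons; baselines are floored at 0.8·|gain| so
inhibited tuning is not silenced by rate clipping), width 0.3. Static
neurons hold one window from their response latency (100–300 ms) to the
end of planning; dynamic neurons (30% of tuned) hold a 300 ms window at
a random latency. Format-coupled nuisance neurons draw independent
preferred values per format; untuned neurons fire at baseline. On error
trials the tuned drive follows the *produced* count (clipped to 1–5) by
default — the hypothesis that planning activity predicts the action —
with `error_drive="instructed"` available as the null. Execution-phase
activity is baseline only, since no in-scope analysis reads it.
Randomness derives from one root seed with per-trial and
per-(neuron, trial) seed-sequence streams, so enlarging the population
never perturbs existing trials or other neurons' spikes.

What the generator does *not* emulate: spike-sorting noise, rate
non-stationarities within a phase, correlated variability between
neurons, latency jitter across trials, and eye- or movement-related
signals. Passing tests therefore demonstrate correctness and calibration
of the analyses under a well-specified Poisson world, not performance
guarantees on recorded data.

## Selectivity analysis

The sliding 5 × 2 ANOVA is a fixed-effects decomposition with Type II
sums of squares for unbalanced cells (Type III available; the types
coincide for balanced data). Because trial labels are shared across
bins, the per-bin sums of squares are computed through four projection
matrices built once, which makes the per-neuron surface essentially one
matrix product; the implementation is validated against statsmodels'
`anova_lm` to 12 decimals and against textbook group-mean sums of
squares. Cells with fewer than two observations are rejected rather than
silently yielding significance.

A neuron counts as numerosity-selective when bins with `p_number < 0.01`
and neither a format nor an interaction effect form a run of ≥ 11
consecutive bins. At 20 ms steps, 11 bins span 400 ms of data from
first-bin start to last-bin end; the run count is the operative rule and
the associated "≥ 300 ms" description is treated as informal. Among
several qualifying runs the one with the largest spread (max − min) of
numerosity-mean rates wins; ties break toward the earlier run, and
preferred-value ties toward the smaller numerosity (deterministic).
Neuron inclusion needs a mean rate ≥ 0.5 Hz over the 2000 ms from
baseline onset to planning offset and ≥ 5 correct trials per condition.
Split-half reliability stratifies halves by numerosity × format and
ranks the half-to-half Pearson correlation within a label-permutation
null (10,000 permutations by default; tests use fewer).

## Decoding

All protocols share: per neuron, `trials_per_class` correct trials drawn
without replacement per label; neurons conjoined into pseudotrials by
(label, draw index) — the across-session conjunction rule is this
package's choice, as none is standard; features are window mean rates;
a linear SVC (one-vs-one, C = 1.0) under stratified tenfold
cross-validation; the whole procedure resampled with fresh draws; chance
from the identical protocol on shuffled labels. z-scoring uses
training-fold statistics applied to held-out trials (leak-free default);
a `pooled` mode standardizes the sampled matrix before CV for
comparability with protocols stated in that order. Zero-variance
features are left unscaled (unit divisor) and counted. Confusion
matrices are empirical prediction frequencies, row-normalized; accuracy
is the mean of per-resample fractions correct, with SEM across
resamples. Cross-phase decoding uses non-overlapping windows
(instruction 250–550 ms, planning 700–1600 ms) and shares the sampled
trials between windows so the train/test folds stay aligned. Error-trial
decoding labels error trials by the instructed numerosity and tests one
held-out correct and one error trial per class per fold, reported
separately.

## Time-resolved statistics

ω² may be slightly negative for null factors in small samples; values
are reported unclipped by default (a flag clips at zero). The population
PEV trace averages per-neuron ω² over neurons; each of the 50 resamples
draws 10 trials per numerosity × format cell, and 20 label shuffles per
resample give 1000 null values per bin whose 95th percentile is the
baseline threshold.

Cross-temporal decoding trains per time bin within each fold and tests
the *held-out* trials at every bin, so train and test sets stay disjoint
off the diagonal; test features at other bins are standardized with the
training bin's training-fold statistics. The cluster permutation test
thresholds each cell at the 95th percentile of the *pooled*
null-plus-observed values — pooling keeps the observed matrix
exchangeable with the null matrices, which a null-only threshold is not
(measured family-wise error ≈ 8% at 40 permutations versus 1–3% pooled)
— then labels 4-connected components (8-connectivity by flag), scores
them by cell count, and reports clusters whose permutation rank
`p = (1 + #{null ≥ size}) / (1 + n_perm)` is ≤ 0.05. Fewer than 20
permutations are rejected. The static/dynamic contrast is quantified by
the generalization index (mean off-diagonal minus mean diagonal
accuracy), near zero for a sustained code and strongly negative for a
transient one.

## Problem sizes

The test suite and examples run the full protocols at reduced scale
chosen to keep the statistics interpretable: populations of 8–40
neurons, 18–30 trials per condition, 1000 resamples for null
calibration, a ~30-bin grid and 20 paired datasets for the
static/dynamic contrast, and 500 simulations for family-wise-error
checks. Defaults in the API (50 redraws, 1000 resamples, 10,000
permutations) reflect full-scale analysis practice.

## Known limitations

- Preferred-value recovery is defined through the argmax rule; for
  inhibited neurons that rule deliberately returns the response *peak*,
  which is anti-aligned with the generative trough, so parameter
  recovery is only meaningful for excited tuning.
- The behavioral chance construction and the per-stratum chance
  adjustment are heuristics inherited from the experimental design; the
  package exposes chance as a parameter rather than deriving it.
- Dynamic-code windows shorter than ~200 ms approach the ANOVA window
  width and are detected with temporal blur of roughly one window.
- No LFP, state-space, or latency-median analyses are included.
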