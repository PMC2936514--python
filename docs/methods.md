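# Methods

This note documents the models, conventions and numerical choices behind
`dipscreen`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Normalization model

A compendium is a probe × instance matrix of log2 intensities (post
summarization) plus an instance sheet (drug, cell line, batch, platform,
concentration, control flag) and a probe × instance detection-call matrix
(P/A/M).  Filtering keeps treatment instances from batches with **strictly
more than** `min_batch_size` (default 25) treatments on an allowed platform,
drops vehicle controls, and keeps only each (drug, cell line)'s highest
tested concentration (ties at the maximum are replicates and all remain;
mixed concentration units raise).

Population mean-centering subtracts, per probe and batch, the mean over all
treatment columns in the batch; each treatment column enters that mean
exactly once, replicates included.  A batch with a single treatment is
rejected (its centered values would be identically zero).  The
treatment-vs-control baseline (`control_center_batch`) subtracts the mean of
the batch's control columns instead and exists for comparison.

Two properties matter downstream:

* centering is idempotent, and per-probe per-batch means vanish to numerical
  tolerance afterwards;
* centering a group of T columns forces their residuals to sum to zero, so
  any two same-batch profiles acquire an *exact* correlation of −1/(T−1).
  This is arithmetic, not a bug; see "Category analysis" below.

Replicates are then averaged into one amplitude profile per (drug, cell
line); profiles from different array platforms are never merged.  Input
matrices must be NaN-free; the loaders reject missing values by design.

## Ranking, signatures, DIPS

Ranking is two-step: probes not in the cell line's presence set (called 'P'
in ≥ half of treatments; the threshold is inclusive, marginal calls never
count) have their average difference set to 0; all probes are sorted
descending by this effective value; the zeroed block is sub-sorted descending
by the retained initial value.  Ties anywhere are broken by probe-id
lexicographic order so every ranking is reproducible.  A present probe at
exactly 0 was never "set to 0", so its sub-sort key within the zero block is
0 itself.  The signature is the top n plus bottom n of the ordering (default
n = 250; configurable because small simulated panels need smaller n).

The enrichment score walks the ranked list: +w_i/Σw on a query-set hit,
−1/(N−|S|) on a miss; the ES is the extreme deviation, signed, preferring
the positive extreme on exact magnitude ties.  `classic` weighting (w_i = 1,
the plain KS statistic) is the default; `weighted` uses w_i = |effective
value| (weight exponent 1).  If a weighted query set has zero total weight
(entirely inside the zero block) the increments fall back to uniform rather
than erroring.  The implementation evaluates the walk in closed form at the
2m hit-adjacent points, which reproduces the full O(N) walk exactly; the
test suite checks it against an independently written brute-force walk.

For a pair (X, Y), the directional score of X in Y is
(ES(up_X in Y) − ES(down_X in Y))/2 and the DIPS score is the mean of the two
directional scores.  A plain four-way mean of raw ES values would cancel the
signal (ES_down of a concordant pair is negative); the sign-corrected form
yields +1 for self-comparison, −1 for a rank-reversed profile, and is
symmetric by construction.  The combination rule is isolated in
`combine_directional` so alternatives can be swapped.  Signature probes
missing from a partner profile are tolerated up to 10% (the query restricts
to the shared probes); beyond that the comparison errors.  Cross-cell-line
combination is the unweighted mean over the cell lines scoring the pair.  No
null-based rescaling or p-value is attached to DIPS; significance enters via
the category t-tests and the ROC benchmark.

## Benchmark

Pair labels: Tanimoto strictly greater than the threshold (default 0.8); ATC
level-k sharing by prefix length 1/3/4/5/7 for levels 1–5 (level 4 ⇒ 5
characters), any code of one drug vs any code of the other; drugs without
valid codes are excluded, malformed codes rejected with a warning.  Pairs
lacking either a score or a label are excluded listwise.  The ROC is standard
(descending thresholds; tied scores form diagonal segments), AUC is the
trapezoid area and equals the Mann–Whitney concordance with ties at ½; the
partial AUC integrates TPR for FPR < cutoff without normalization, so a
perfect classifier attains the cutoff itself.

## Regulation screen

Hypotheses are (target gene, action) pairs after filtering: confidence
strictly > 0.7, experimental/database channels, 'binding' folded into
'inhibition' with a per-relation override hook.  Activators and inhibitors of
the same target are separate hypotheses — their expected directions are
opposite and would cancel pooled.  A target enters a cell line only if some
mapped probe is present in ≥ one tenth of that cell line's treatments
(inclusive); multi-probe targets are reduced by the unweighted mean over
their present probes.

Per cell line the targeting drugs' amplitudes are compared against all other
drugs by a Welch t-test (the background is large and heterogeneous; a
targeting group of one is reported without a t-test).  Across cell lines the
pooled per-drug amplitudes enter a fixed-effects OLS ANOVA with factors
targeting-group and cell line (no interaction); the targeting-group p is
reported.  With one cell line this reduces to the one-way ANOVA, whose F
equals the square of the pooled-variance t statistic — the per-cell-line
column stays Welch, so the two p-values differ slightly by design.  A pooled
one-way variant ignoring the cell-line factor is selectable
(`anova_design="pooled"`), as the exact design is a genuinely open choice.
Benjamini–Hochberg q-values are computed over the whole family; the default
call is q < 0.05.  The background deliberately includes drugs hitting the
same target through below-threshold annotations — no exclusion rule is
applied, which is conservative and listed as a limitation.

## Synthetic compendium

The generator is additive on the log2 scale: per-probe baseline
μ_p ~ N(7, 1) (typical microarray range), batch term b ~ N(0, σ_b²) per
batch × probe, sparse drug signature (exactly k probes, amplitude ±a, shared
verbatim within "similar" groups), injected feedback effect on target probes,
and iid N(0, σ_e²) noise.  Presence is sampled per probe × instance with a
logistic probability in μ_p whose midpoint is placed so the average presence
matches `present_rate` — presence correlates with abundance as on real
arrays.  Non-present calls split 80/20 between A and M.

Design choices worth knowing:

* **Layout.** The batch grid fixes B×T instance slots per cell line; every
  drug fills one slot and surplus slots are replicates drawn by cycling
  through a pool of round(replicate_rate × n_drugs) replicate-eligible drugs.
  Replicates land in random batches, populating both same-batch and
  cross-batch same-drug categories.
* **Concentrations.** The configured amplitude applies at a drug's highest
  concentration; a fraction of multiply-profiled drugs get one lower-dose
  instance at amplitude/1.5, exercising the highest-concentration filter
  without changing the post-filter signal.  The feedback effect δ is not
  concentration-scaled, so it stays an exact known constant per instance.
* **Feedback sign.** Injected effect = +δ under inhibitors and −δ under
  activators (for positive δ: compensatory up-regulation under inhibition,
  agonist-induced down-regulation under activation).  Target probes are drawn
  from abundant (μ_p ≥ 7), signature-free probes so the injected effect is
  identifiable and usually present.
* **Labels.** Drugs in a similar group share a 5-character ATC-like prefix
  and pairwise Tanimoto 0.9; between-group Tanimoto is Uniform(0, 0.6), so
  the 0.8 threshold separates classes by construction.  Distractor relations
  (low confidence, text-mining channel) are emitted to exercise the filters.
* **Controls.** Vehicle-control instances (baseline + batch + noise, no
  signature) are optional and off by default.

What the generator does **not** emulate: probe-level CEL data and RMA,
realistic MAS5 call statistics, correlated noise between probes, platform
differences, dose–response shapes, or pharmacokinetics.  Passing tests
therefore demonstrate the pipeline's statistical behaviour under an additive
model with known truth — not performance on real arrays, where effects are
weaker and structured.

## Canonical studies and their sizes

`dipscreen.studies` freezes three study designs used by the test suite and
`scripts/acceptance.py`; sizes were chosen so each study gives stable
statistics yet finishes in seconds on one core.

* **Category study** — 1 cell line, 3 batches × 26 treatments + 2 controls
  each, 60 drugs (18 replicated), σ_b = 0.5, σ_e = 0.3, amplitude 0.6,
  signature n = 100.  Instance-level DIPS scores are stratified into the four
  drug/batch categories.  Under control-centering the different-drug
  same-batch category sits far above the different-batch one (the shared
  control-noise background); under mean-centering that ordering disappears
  while same-drug cross-batch concordance emerges.  Because centering forces
  the exact −1/(T−1) same-batch coupling noted above, same-batch scores end
  slightly *below* different-batch ones, so the category claims are tested
  one-sidedly in the direction stated: "same-batch is higher" must hold
  before centering (one-sided p < 0.01) and must find no support after it
  (one-sided p > 0.05).  A two-sided "no difference" test would reject at any
  realistic pair count on the centering arithmetic alone.
* **Similarity study** — 3 cell lines, 48 drugs with 12 shared-signature
  triplets, amplitude 0.6 = 2σ_e.  Combined DIPS vs ground-truth similar
  pairs: mean-centered AUC must reach 0.9 and exceed the control-centered AUC
  at the same seed; the permuted-label null is the mean AUC over 20 seeded
  permutations (a single permutation with ~36 positives has sd ≈ 0.05, too
  noisy to pin near ½).
* **Regulation study** — 2 single-batch cell lines (30 treatments each), 6
  targets × 5 annotated drugs, δ = 0.9 = 3σ_e.  With no injected effects the
  q < 0.05 fraction over 50 seeded replicates stays within the FDR budget;
  with all targets regulated, recovery must reach 90% with every detected
  direction matching the injected sign.

## Numerical conventions and degenerate inputs

* Ties: probe-id order in rankings; positive preference at exact ±ES
  magnitude ties; equal-maximum concentrations all kept.
* Zero-variance profiles have undefined Pearson correlations — flagged NaN
  with a warning, never silently 0.
* Degenerate rejections: empty/full query sets; signatures larger than half
  the profile; batches with one treatment (mean-centering) or no controls
  (control-centering); all-one-class ROC labels; empty cross-cell-line probe
  intersection; NaN in input matrices.
* Determinism: one `numpy` Generator seeded from the config drives the whole
  simulation; pipeline reruns on identical inputs are byte-identical.

## Limitations

The score and screen inherit the compendium's confounders beyond batch
(vehicle, time point, dose) that the generator does not model.  The
background of the regulation screen is contaminated by drugs with
sub-threshold annotations to the same target.  DIPS has no attached
significance; ranking interpretations at the zero-block boundary follow the
documented tie rule and are a genuine interpretation choice.  Cross-platform
probe matching is exact-id only.
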