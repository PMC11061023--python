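# Methods

## Model and procedure

The pipeline treats responder prediction as binary classification of
compositional relative-abundance vectors. All modelling choices follow from
the regime it targets: N ≈ 96 samples from ~24 subjects, M ≈ 221 taxa,
class imbalance near 4:1, and 60 %+ zeros per taxon.

**Preprocessing** is a fixed chain: subset the taxa to the current set S,
renormalize each row to unit L1 norm (so the subset is again a proper
composition), take the elementwise square root (compressing the dynamic
range so sub-percent taxa are not drowned by dominant ones), and standardize
each taxon by the mean and population variance (divisor K, not K−1) of the
training samples only. Whenever the training set changes — every
cross-validation fold — the statistics are refit and every sample re-scored.
A taxon constant on the training set standardizes to 0 (with a warning)
rather than being dropped, so the coordinate system stays aligned across
folds and trials; this is what makes elementwise averaging of weight
vectors meaningful. Rows that are all-zero over a small subset S are kept as
all-zero compositions inside cross-validation and profiling ("an entirely
absent profile"), which preserves fold geometry; direct calls to the
preprocessor default to a hard error with an opt-in drop policy.

**Classifier.** A linear soft-margin SVM with cost C = 10 and decision rule
sign(wᵀz − b), an exactly-zero decision mapping to the responder class for
determinism. Training is delegated to LIBSVM (via scikit-learn's `SVC`),
followed by an exact Newton step on the active set the solver identified:
samples with margin < 1 − ε keep α = C, samples on the margin become free
support vectors, and (w, b, α_free) are recomputed from the KKT equality
system (iterated at ε = 10·tol, 1e−7, 1e−9). SMO alone stops ~1e−6 short of
the optimum; the refinement drives the objective and KKT residuals to
numerical precision, which the test suite verifies against an independent
QP oracle (scipy `trust-constr` plus the same style of active-set polish,
written separately in `tests/_qp_oracle.py`). The refinement also allows a
loose SMO tolerance (default 1e−4) without sacrificing optimality, which
matters because near-null low-dimensional problems otherwise make SMO crawl.

**Balanced multi-trial cross-validation.** Each trial draws 20 samples per
class without replacement (a class with exactly 20 contributes all of them
every trial), partitions each pool into five fours, and pairs partitions
into five balanced folds of eight; the other K = 32 samples train. T trials
(default 200) give 5T fold accuracies and 5T classifiers, averaged into
(w*, b*). The reported "±" is the standard deviation of the T per-trial
mean accuracies; the per-fold sd is also stored. Samples are the resampling
unit, matching the source procedure; because a subject's four samples can
straddle train and test, an optional grouped mode draws and folds whole
subjects instead for leakage-sensitive analyses. One master seed feeds a
`SeedSequence` tree, so every result is reproducible bit-for-bit.

**Dimensional reduction.** Stage 1 removes "Other" (ambiguous) taxa.
Stage 2 computes per-class absence rates once on the full dataset (a fixed
pre-learning step) and removes a taxon only when both class rates *strictly*
exceed the threshold; all-zero taxa always go. Differential absence is kept
deliberately — a taxon absent often in one class only is informative.
Stage 3 ranks taxa by gain |w*ₘ| (descending, ties broken by ascending
taxon index for reproducibility) and keeps the top r. The (threshold, r)
pair is selected by a joint grid search in which every candidate pair gets
its own second-stage multi-trial cross-validation with fresh draws; the
winner is the smallest final dimensionality whose mean accuracy meets a
floor, ties going to higher accuracy. The floor may be an absolute value
(0.96 was the source analysis' choice for its data) or the `"one-sd"` rule —
one trial-sd below the surface's peak — which adapts the floor to how
accurate the cohort allows classifiers to be and is the analogue of the
usual one-standard-error rule in penalized model selection. The default
threshold grid is every achievable per-class absence rate and every rank,
which is exhaustive but expensive; practical runs pass coarser grids.

**Validation suite.** Cutoff sweeps (accuracy vs top-r), ranked-block
sweeps (blocks of 19 adjacent ranks sliding down the ordering; signal
should fade), controls built solely from discarded taxa (should hover near
chance, and a planted taxon smuggled into the discarded set should be
detected), a permutation null (training labels permuted uniformly per
training phase, test labels kept true), and per-taxon histograms of the
rank received in each of the 5T training phases, summarized by the mean
absolute deviation from the final rank and its Spearman correlation with
the final rank (positive = influential taxa rank more stably).

**Profiles.** For each retained taxon, class-conditional empirical
distributions of √-abundance on the composition the classifier sees
(renormalized over the final S; a flag switches to the original scale),
with medians, a Gaussian KDE (Scott bandwidth) when the sample is
non-degenerate, and a separation score = 1 − histogram overlap on shared
bins. Profiles carry an explicit caveat that marginal views can obscure
inter-taxon relationships; no automatic inference is drawn from them.

**Responder labeling.** A subject is a responder iff any available
non-control dose exceeds the 0 g/day control by ≥ 0.03 — interpreted as an
absolute difference in fractional absorption, the convention matching the
magnitudes of the published class means; a relative mode (ratio − 1) is
provided because the original wording does not disambiguate. With only one
non-control dose available, that dose decides alone. Missing control or
missing all non-control doses make a subject unlabelable (an error, not a
guess).

## Synthetic cohorts

No raw data are deposited, so the generator supplies study-shaped cohorts
with known ground truth. What it emulates, and how:

- **Geometry**: 24 subjects × 4 samples, 221 taxa with 23 "Other" names at
  random positions, exactly round(19/24 · n_subjects) responder subjects
  (the study's 19/5 split under the defaults).
- **Base composition**: per-taxon weights are lognormal (σ = 1.5),
  normalized — a few dominant taxa and a long rare tail.
- **Signal**: each informative taxon's mean √-abundance is shifted by
  ± effect_size/2 per class, in units of that taxon's √-scale sd
  (so `effect_size` reads as a standardized effect). The first informative
  taxon is elevated in non-responders — a *Roseburia*-like profile — and
  signs alternate thereafter. Informative taxa are drawn from the prevalent
  half of the unambiguous community, since taxa censored to zero nearly
  everywhere cannot carry class information.
- **Within-subject structure**: a per-subject latent factor (sd
  `subject_sd`, default 0.3) loads on all informative taxa along the class
  axis — the informative panel behaves as one co-varying guild whose load
  differs between hosts, correlating a subject's samples. Additionally each
  non-responder subject deviates strongly (`deficit_scale` × effect, default
  2.5) on its own `n_subject_deficits` (default 2) informative taxa:
  different hosts lack or overgrow different key taxa, so covering the whole
  panel genuinely helps classification. All class-linked structure scales
  with `effect_size`; zero gives a null cohort.
- **Sparsity**: entries below each taxon's `sparsity` quantile (default
  0.6) are censored to zero — detection-limit zeros that fall on the
  smallest values, making absence itself mildly class-informative, as the
  absence-rate filter assumes. Each row keeps its largest pre-censoring
  entry so no sample is annihilated; rows are then renormalized.
- **Calcium**: per subject per dose, Gaussian around the published class
  means (responder 0.3503/0.4051/0.4062, non-responder 0.3840/0.3484/0.3471
  at 0/10/20 g/day) with sd 0.02 — large enough that label recovery from
  the calcium table is imperfect (the mismatch rate is itself tested), small
  enough that planted classes are recovered with high probability. An
  optional flag deletes one non-control record for a configurable number of
  subjects, emulating partially missing outcome data.

What it does **not** emulate: sequencing noise, phylogenetic correlation,
longitudinal drift within subject, or any fitted model of real 16S data.
Passing tests therefore demonstrate that the pipeline recovers structure of
this synthetic form at these sizes — not that the original biological
findings replicate.

## Problem sizes and numerical choices

The test suite scales simulations to keep runs short while leaving the
procedures intact: qualitative signal tests use a 60-taxon, 8-informative
cohort; chance-level checks use T = 30–100 trials; the panel-recovery
experiment uses a balanced 48-subject cohort (responder fraction 0.5,
effect 1.2, sparsity 0.2) with T = 50, an absence grid of {0.6}, a rank
grid of {8, 16, 24, 32, 40}, and the one-sd floor — balanced cohorts give
the ranking enough non-responder subjects to be stable, and the regular
step-8 grid spans the plausible panel range. Chance-level assertions use
three standard errors of the mean trial accuracy. Exact contracts
(preprocessing moments, QP optimality at 1e−6 relative, combinatorial
geometry) are asserted at fixed tolerances. Tie-breaks are deterministic
everywhere (ascending taxon index in rankings; exact-zero decisions map to
class 1). Degenerate inputs — constant taxa, all-zero rows over a subset,
single-class training sets, unlabelable subjects — raise or are handled as
described above rather than silently propagating NaNs.

## Known limitations

- The generator is a stand-in, not a fit; absolute accuracies on synthetic
  cohorts are not comparable to values on real data.
- With samples as the resampling unit, a subject's samples can appear in
  both train and test folds (the source scheme shares this property); the
  grouped mode exists but changes the fold geometry.
- The exhaustive default grids in `parameter_search` are quadratic in the
  number of distinct absence rates and ranks; realistic use requires coarse
  grids.
- Linear decision functions cannot represent interactions among taxa;
  the influence ranking inherits that restriction.
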