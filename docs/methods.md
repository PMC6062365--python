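# Methods

## Problem and model

The pipeline classifies compounds as acutely toxic (pLD50 > 3) or nontoxic
(pLD50 < 2, in −log₁₀ mol kg⁻¹); compounds in between are marginal and
excluded. Boundary values (exactly 2 or 3) are marginal — the thresholds
are strict inequalities. Three descriptor domains feed the classifiers:

1. **Chemical** — any numeric descriptor table supplied by the user (the
   pipeline does not compute 2-D descriptors itself; in synthetic mode the
   generator supplies them).
2. **Protein target** — scores from a multi-target Laplacian-modified
   naive Bayesian model. For target *t* and fingerprint *x*,
   score(t, x) = Σ_{f∈x} ln[(A_tf + 1)/(N_f·P_t + 1)]. Features absent from
   training are neutral (contribute ln 1 = 0). Scores are relative
   log-likelihoods of interaction, not affinities, and no per-compound
   normalization is applied. Targets are retained only with ≥ 50 records
   and a nondegenerate prior (at least one active and one inactive
   record). Training compounds are identified by `compound_id` when
   present, otherwise by fingerprint identity, so that a compound measured
   against many targets is counted once in N_f.
3. **Cytotoxicity** — each cell line's concentration–response curve is
   divided by its maximum response; a curve whose maximum is ≤ 0 shows no
   measurable cytotoxicity and maps to all zeros (dividing by a negative
   maximum would flip the curve's sign).

Compounds missing from any domain are excluded (intersection semantics),
mirroring how such datasets are assembled from overlapping sources.

## Cross-validation protocol

`make_split_plan` draws class-stratified 5-fold partitions
(scikit-learn's StratifiedKFold), independently per repeat, from seeds
derived from a master seed through `numpy.random.SeedSequence` spawn keys.
The identical plan is reused for every domain combination so that paired,
per-split comparisons isolate the effect of the descriptors.

Within each (repeat, fold) cell the held-out fifth is removed before any
preprocessing. The modelling set then passes through four steps in a fixed,
validated order:

1. **Near-zero variance**: drop zero-variance columns, and columns whose
   top-to-second value-frequency ratio exceeds 19 while the distinct-value
   fraction is below 10% (conventional defaults).
2. **Correlation filter**: greedy elimination on the absolute Pearson
   matrix — repeatedly take the worst pair above the cutoff and remove the
   member with the larger mean absolute correlation to the remaining
   columns; all ties break on column-name order. Domain-specific cutoffs
   are calibrated once on the full table by bisection so that each domain
   finishes within ±10% of the smallest post-step-1 domain width; a strict
   fold-internal recalibration mode is available behind
   `recalibrate_cutoffs_per_fold`.
3. **Range scaling** to [0, 1] with modelling-set minima/maxima; external
   values extrapolate outside [0, 1] and are deliberately not clipped; a
   constant column maps to 0.
4. **Downsampling**: every nontoxic compound's Euclidean distance to its
   nearest toxic compound is computed on the scaled chemical block and the
   ⌈ratio·n_toxic⌉ nearest nontoxics are kept (all toxics kept), giving an
   approximately balanced modelling set deterministically. For
   combinations without the chemical domain the combination's own scaled
   block is used — the table is restricted to the combination's columns
   before preprocessing, so chemical coordinates are unavailable there by
   construction.

Random forests (scikit-learn) use 500 trees by default and
mtry = ⌊√p⌋ with p the post-preprocessing width, recomputed per fold.
Predictions are majority votes recomputed from the individual trees;
p(toxic) is the fraction of trees voting toxic and ties go to the toxic
class, the safety-conservative choice since false negatives are the
costlier error in toxicology.

## Robustness, coverage, independence, interpretation

**y-scrambling.** Modelling-set labels are permuted uniformly (external
labels untouched) and the full pipeline — preprocessing included — is
refitted 10 times. The real external CCR is compared against the scrambled
CCRs with a *predictive* one-tailed t-test,
t = (CCR_real − mean_scr)/(sd_scr·√(1 + 1/n)), p = sf_{t,n−1}(t); a model
passes at p < 0.05. The √(1+1/n) prediction-interval form is used rather
than a standard-error denominator because the real CCR is a single draw,
not a mean: under a true null this form gives a pass rate of ≈ α, whereas
the standard-error form passes ≈ 29% of null models. With zero scrambled
variance the degenerate rule applies (p = 0 if the real CCR exceeds the
common value, else 1). A scramble whose downsampled modelling set loses a
class scores chance level (CCR 0.5).

**Applicability domain.** For every external prediction, the Euclidean
nearest-neighbor distance to that fold's final modelling compounds is
computed in a shared chemical coordinate system (full-data cutoffs, as for
all descriptor-space analyses). Distances pooled over combinations define
five quantile bins; per-bin CCR is reported per combination, with
empty or single-class bins reported as missing rather than zero.

**Mantel tests** between domain distance matrices use the Pearson
correlation of upper off-diagonal triangles with joint row/column
permutations; p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), or exhaustive
enumeration for small matrices. The implementation is cross-checked
against scikit-bio's `mantel` in the test suite.

**Variable importance.** Per tripartite model, raw Gini importances are
range-scaled to [0, 100]; per descriptor the scaled values are averaged
over the models in which the descriptor survived preprocessing (absent
models are skipped, not imputed as zero, and the contributing-model count
is reported).

**Neighbor contrast.** For a toxic query, its k = 5 nearest nontoxic
neighbors in chemical space are found (optionally within a distance cap);
for each neighbor the m = 5 target scores with the largest increase from
neighbor to query are listed (ties by target id) and targets recurring in
≥ 3 of the 5 lists are flagged as mode-of-action candidates.

**Paired improvement** between two combinations uses per-cell CCR
differences over the shared splits and a two-tailed paired t-test (cells
are paired by construction; SE = sd/√n_cells). `roc_auc` is the rank-based
Mann–Whitney statistic with ties counted half.

## Synthetic cohort generator

The generator emulates the benchmark cohort shape — 367 compounds with a
275:92 nontoxic:toxic imbalance, 192 chemical descriptors, 477 targets,
13 cell lines × 14 concentrations log-spaced over 0.6–92 μM — while
routing toxicity signal through 12 latent mechanisms split evenly into
chemical-, target- and cytotoxicity-facing facets:

- pLD50 = baseline + scale·Σ_d √w_d·u_d + ε, where u_d is the standardized
  facet activation, w_d the configured `domain_signal_weights`
  (default ⅓ each) and ε Gaussian with sd `noise_sd` (default 0.6 log
  units). The total spread and baseline are solved from the configured
  class counts with 10% of probability mass left in the marginal band; the
  baseline is anchored on the realized draw's quantile so the expected
  class counts match at any cohort size. Noise is resampled up to 100
  times until both class counts land within ±15% of the configured
  (n_toxic, n − n_toxic); otherwise generation fails naming the
  constraint. The pLD50 location/spread are free generator parameters, not
  claims about any real cohort.
- Chemical descriptors are sparse mixtures of chemical-facing mechanisms
  passed through a saturating (tanh) response — real descriptors have
  bounded ranges, so extreme activations do not push compounds arbitrarily
  far out in descriptor space — plus noise; 25% of columns are pure-noise
  decoys (ground truth records which, for recovery tests). Each compound
  additionally carries a lognormal *distortion* factor multiplying its
  descriptor noise: molecules the descriptor set captures poorly sit far
  out in chemical space and are predicted badly there, which is the
  phenomenon applicability-domain profiling measures.
- Fingerprint bits: each *target-facing* mechanism owns 40 dedicated bits,
  half responding sigmoidally to positive activation and half to negative,
  over a 3% background rate. The symmetric split keeps total fingerprint
  density flat in activation, so signal lives in *which* bits are on
  rather than how many; otherwise all 477 target scores would share one
  density factor and per-target interpretation would be meaningless. Only
  target-facing mechanisms are linked: fingerprints feed solely the target
  scorer, and linking other facets would leak chemical/cytotoxicity signal
  into the target block.
- qHTS responses follow Hill curves Emax·c^h/(EC50^h + c^h) with
  parameters drawn from configurable ranges; cytotoxicity-facing
  activation lowers EC50 multiplicatively (more potent cell killing) and
  cell lines carry lognormal sensitivity factors. Response noise has its
  own scale (`qhts_noise_sd`, default 0.05 response units) because the
  pLD50 noise scale would be meaningless on a unit-response axis.
- The bioactivity training table (1200 training compounds by default —
  enough that Laplacian count estimates for unlinked targets are close to
  neutral) links 35% of targets to 1–2 target-facing mechanisms; active
  flags are Bernoulli with probability increasing in the fingerprint's
  observed signed mechanism-bit counts, and every target receives ≥ 60
  records.

The latent matrix and linkage maps are stored as ground truth for recovery
tests only; the modelling modules never read them.

**What the generator does not emulate:** real chemistry (no valid SMILES),
correlated mechanism activations, heavy-tailed noise, assay artifacts or
plate effects, and the between-domain redundancy present in real data
(the synthetic domains are nearly independent by construction, Mantel
r ≈ 0, whereas real domains showed correlations up to ≈ 0.29). Passing
tests therefore demonstrate that the machinery detects and integrates
signal with the assumed structure, not that a given real dataset will
reach any particular accuracy.

## Problem sizes used in tests and the acceptance script

Directional experiments run the benchmark-shaped default cohort with
5 cross-validation repeats (25 cells per combination), 300-tree forests
and 5 generator seeds; the fast unit-test cohort uses 160 compounds with
proportionally narrowed domains. The y-scrambling null calibration uses
100 cells on the small cohort with 60-tree forests. These are the
package's standard test profiles; the full 20-repeat, 500-tree protocol is
the library default and is exercised end-to-end by the CLI.

## Numerical choices and edge cases

- Correlation matrices are symmetrized (0.5·(C+Cᵀ)) before greedy
  filtering; BLAS products are not bit-symmetric.
- NaN correlations (constant columns inside a fold) are treated as 0.
- Empty fingerprints score 0 for every target, with a warning.
- Degenerate preprocessing inside a fold (e.g. an all-constant block)
  aborts that fold with a diagnostic and the run continues; failed folds
  are excluded from summaries and reported.
- CSV round trips use shortest-repr writing and `float_precision=
  "round_trip"` parsing, so numeric fields survive exactly.
- Known reporting discrepancies in the published reference values this
  design follows: the text and summary table disagree on one dual-domain
  selectivity (0.86 vs 0.84) and one sensitivity SD (0.15 vs 0.10); the
  table is treated as authoritative throughout.

## Open design choices taken

- The bioactivity potency phrase "at least 1 μM" is read as "at least as
  potent as 1 μM" (Ki/Kd/IC50/EC50 ≤ 1 μM ⇒ active) when building records
  from potency values; this is a reading, not an established fact, and is
  isolated in one place.
- Correlation cutoffs are calibrated once on the full dataset and held
  fixed across folds (the same convention used for descriptor-space
  figures); strict fold-internal recalibration is available behind a flag.
- y-scrambling retrains the *entire* pipeline per scramble — the
  strictest reading.
- The score formula above is fixed as the package contract so tests can be
  exact; implementations in commercial software may differ in details that
  were never published.
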