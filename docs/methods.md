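# Methods

This note documents the statistical procedures implemented in
`methylsieve`, the defaults and why they were chosen, what the synthetic
validation does and does not demonstrate, and the numerical decisions a
user auditing results should know about.

## Data model

A `MethylationDataset` is a probe × sample matrix tagged with one of
three scales: `percent` (percent methylation load, [0, 100]), `beta`
(fraction methylated, [0, 1]), or `mvalue` (log2-odds,
M = log2(β / (1 − β)), unbounded).  Statistics and classifiers operate
on M-values, which are far less heteroscedastic than beta values;
the biomarker prefilter operates on the percent scale, where its
thresholds are defined.  Fully (un)methylated cells transform to ±∞ and
the affected probe rows are removed (`drop_nonfinite`) before any
modeling, mirroring array practice where complete methylation states
are rare artifacts.

## Selection algorithm

One bootstrap iteration, given a stratified train/test split:

1. per-probe two-group F-test (one-way ANOVA, df (1, n−2)) on the
   **training** samples only;
2. Benjamini–Hochberg correction across all probes currently under
   consideration; candidates are probes with q < `fdr_gate` (0.001);
3. iterations with fewer than 2 candidates are discarded — a model
   with a single feature is not considered a multivariate signature;
4. the classifier is fitted on the training samples restricted to the
   candidates and scored on the test samples with support-weighted
   one-vs-rest F1;
5. each candidate receives `F1_weighted × (−log10 p_uncorrected)`; the
   uncorrected p is used because it reflects per-probe evidence without
   the rank-dependent FDR adjustment.

Scores are averaged over usable (non-discarded) iterations, counting 0
whenever a probe missed the gate.  The resulting distribution has a
large zero/near-zero mode (noise) plus upper modes (signal).  Otsu's
threshold — computed exactly over all midpoints of consecutive sorted
unique scores, no histogram binning — extracts the upper part; a
Hartigan dip test on the extracted scores decides whether structure
remains.  While the dip rejects unimodality (α = 0.05), the entire
bootstrap reruns on the extracted subset; note the FDR correction then
applies to the smaller set, so the gate adapts.  On termination,
pairwise collinearity is pruned: probes are ranked by score and a probe
is dropped if its VIF = 1/(1 − r²) against any retained higher-scoring
probe exceeds 5 (r = Pearson correlation of M-values across all
samples; zero-variance probes are dropped with a warning).

### Comparisons and splits

Two comparison modes exist.  `binary` contrasts presence vs absence of
the primary condition (for the four-group cohort design, the two
condition-positive groups vs the two without; for a two-group dataset,
simply the groups).  `four_class` fits the classifier on all four
diagnostic groups but computes the F statistic only from the primary
condition group vs controls, because a two-group F-test cannot use the
co-morbidity groups; those samples still contribute to model fitting
and F1.  Splits always stratify on the original group labels.  Built-in
plans cover the 30-sample cohort design (22/8 four-class; 23/7 binary,
where the smallest group contributes 3 train / 1 test); otherwise a
plan is derived per group as an 80/20 split.

### Determinism and ordering

All randomness flows from explicit seeds through `numpy` seed
sequences: per-iteration split seeds and per-round dip-test seeds are
spawned deterministically.  Candidate features are passed to the
classifier in probe-ID-sorted order, so results are invariant to the
row order of the input matrix.  Otsu ties break toward the smallest
threshold (keeps more probes); score ties in VIF pruning break on probe
ID.  F-test degeneracies: zero within-group variance with non-zero
between-group difference reports p = 0 (floored at 1e-300 inside the
score); all-constant probes report F = 0, p = 1.

## The dip statistic

No dip-test implementation is available in the dependency set, so the
statistic is implemented here: the minimal sup-norm distance between
the sample ECDF and any unimodal CDF (convex, then concave, with an
atom permitted at the mode).  Every data value is scanned as a
candidate mode; for a fixed mode the two sides reduce to closed-form
conditions on the greatest convex minorant / least concave majorant of
the ECDF step corners, and a junction-feasibility condition couples the
sides (chords through earlier floor/ceiling constraints bound the
lowest value the convex piece can reach at the mode).  The side
conditions give a lower bound attained whenever the junction has slack;
otherwise the exact value is found by bisection.  The test suite
verifies exactness against a linear-programming oracle that encodes the
definition directly (825+ randomized cases including ties, plus
closed-form cases: dip = 1/(2n) for n ≤ 3 distinct points and for
equally spaced samples, dip → 1/4 for a balanced two-point mixture).

P-values are Monte-Carlo: the observed dip is compared against
`n_null` = 2000 dips of uniform samples of the same size, with an
add-one correction.  Cost is O(n²) per dip in vectorized operations —
negligible for the subset sizes the selection loop produces (tens),
appreciable above ~10³ points.

## Biomarker prefilter

Three criteria per group (six tests per probe), kept when ≥ 4 pass
**and** the absolute between-group mean difference is ≥ 10 percent
points: (1) the 95% confidence interval of the group spans < 40 percent
points; (2) the group mean is < 10% or > 90%; (3) the group SD is < 40
percent points.  Criterion 1 is ambiguous between the CI of the mean
(2·1.96·SD/√n) and the 95% population spread (2·1.96·SD).  Both are
implemented; the default is the mean-CI reading.  The choice matters
more than it looks:

* under the mean-CI reading the criterion is nearly always satisfied at
  cohort sizes, so the 10% mean-difference rule does the screening
  (~78% of uniform-noise probes fail it at n = 25 per group).  The
  surviving noise probes are essential downstream — they populate the
  zero mode of the bootstrap score distribution, and Otsu's threshold
  then separates signal from background;
* under the population-spread reading, uniform background is removed
  entirely (a uniform's SD of ~28.9 gives a span of ~113).  The score
  distribution then contains only signal probes, Otsu's cut falls
  *between signal tiers*, and mid-strength probes are lost.  This
  reading suits probe-economical screening of real data, not the
  planted-signal validation.

## Synthetic validation

`generate_validation_dataset` plants 5 high- (Δ 25–40, SD 6–8), 10
medium- (Δ 15–30, SD 8–10) and 15 low-tier (Δ 10–20, SD 10–12) probes —
per probe, Δ and SD drawn uniformly from the tier ranges — in 10⁶
i.i.d. U(0, 100) background probes over 25 + 25 samples.  Group means
are placed uniformly at random subject to both lying in
[3·SD, 100 − 3·SD], the sign of the difference is randomized, and
values are drawn normal, truncated to (0, 100) by resampling.
Truncation (not clipping) is deliberate: an atom at exactly 0/100 would
become an infinite M-value and silently delete the probe downstream;
with the 3·SD placement rule the truncation correction to the target
moments is < 0.3%.

What the validation shows: the pipeline recovers essentially all
strongly differential probes, most mid-strength ones, few weak ones,
and — across every run performed — zero background probes, i.e. the
score/Otsu/dip construction is a conservative detector.  Typical
detection at the default conditions (500 iterations): high 5/5,
medium ~5–9/10 (long-run rate ≈ 0.6 — single runs vary widely because
only mediums with drawn Δ ≳ 20 reliably clear the q < 0.001 gate
against ~10⁴–10⁵ prefiltered probes), low 0–1/15, false positives 0.

What it does not show: the background is i.i.d. uniform, so the
validation exercises neither probe-probe correlation structure (CpG
islands, co-methylated regions), nor beta-value heteroscedasticity,
nor batch effects, nor annotation-based exclusions.  Passing it
demonstrates the selection mechanics, not robustness to real-array
artifacts.

Detection is scored on the selected set **before** VIF pruning:
planted differential probes all separate the same two groups and are
therefore mutually correlated by construction (pairwise |r| ≈ 0.8–0.9
for the high tier), so the collinearity prune occasionally removes a
probe that was identified — a parsimony decision, not a detection
failure.  `score_detection(stage="final")` scores the pruned set.

## Classifiers and metric

`svm_rbf`: soft-margin SVM, C = 1, variance-scaled kernel width
(gamma = 1/(n_features · Var)); `svm_linear`: linear kernel, C = 1;
`lda`: maximum-likelihood LDA with pooled covariance (no shrinkage by
default; a shrinkage flag covers p > n corners).  Hyperparameters are
deliberately not tuned — the selection loop measures probe usefulness
under default models, and tuning inside the loop would leak.
Multi-class SVM uses one-vs-one voting internally; the reported metric
is always support-weighted one-vs-rest F1 (0.5 ≈ random for balanced
binary labels; classes with zero precision + recall contribute 0).

## Performance evaluation

`performance_bootstrap` repeats stratified splits with the probe set
held fixed and reports the F1 distribution; the median is the headline
number because the distributions are markedly non-normal (often a mass
at exactly 1.0, summarized separately as `fraction_perfect`).  No
p-values are computed in this phase — the probe set was already chosen,
and re-testing it on the same data would be circular.

`sensitivity_curve` stress-tests a trained model against growing
within-group variance: per probe and group, synthetic samples are drawn
uniform on [μ − A·σ, μ + A·σ] (μ, σ estimated per probe per group from
the training data — the only self-contained choice) for A = 1..10,
30 samples per group, 20 replicate draws per A with the median F1
reported.  Expected shape on well-separated binary data (group
separation ≈ 3 within-group SDs): both models beat the 0.5 null
anchor through A ≈ 3–4; as A grows the linear LDA boundary splits the
widened clouds evenly (F1 → ~0.5) while the radial SVM predicts the
far-out samples into one class and drops below the null.

`pca_project_heldout` fits principal axes on all samples except an
under-represented group (centering only, no scaling), then projects
the held-out group with the fitted means and axes — a visualization
device that avoids letting a tiny group distort the axes.  Default 3
components.

## ComBat

Parametric empirical-Bayes location/scale batch adjustment with no
covariates: standardize per probe against the grand mean and pooled
variance, estimate per-batch location/scale, shrink toward batch-level
priors (normal / inverse-gamma, moment-matched hyperparameters, fixed-
point iteration to 1e-4), divide out, restore scale.  A single batch is
a warned no-op; a batch with < 2 samples is an error.  Shrinkage means
batch means are *almost* (not exactly) equalized — the residual is of
order delta/(n·τ²).  The implementation is verified against
Bioconductor `sva::ComBat` on a frozen fixture (agreement ~5e-11).
The non-parametric prior variant is out of scope.

## Problem sizes

The default test/validation scale is 10⁵ background probes and 500
bootstrap iterations (the acceptance script uses 5 independent seeds);
the full 10⁶ × 500 configuration runs in ~4 minutes on one CPU and
gives the same tier expectations — background size only sets the FDR
burden of the gate.  Bootstrap cost is dominated by the vectorized
F-test + BH sort over the prefiltered matrix, ~60 ms per iteration at
2×10⁵ probes.

## Known limitations

* The medium-tier detection rate is a property of the q < 0.001 gate
  against the prefiltered probe count; studies wanting higher
  mid-strength recall should relax the gate or tighten the prefilter,
  both exposed in the configs.
* Monte-Carlo dip calibration at subset sizes ≫ 10³ is slow; an
  asymptotic null table is a possible future addition.
* IDAT parsing, array normalization (noob/SWAN/funnorm), cell-type
  deconvolution and genome-annotation lookup are out of scope; probe
  annotation is consumed as a prepared table.
* The cohort split plans assume the four-group study design; other
  designs use the generic 80/20 per-group plan or a custom `SplitPlan`.
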