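# Methods

This note documents the statistical model behind `maldivote`, the design
choices made where the procedure admitted more than one reading, the
synthetic-data model and what it does and does not emulate, and the
numerical conventions.

## Preprocessing

**Binning.** Peak lists from all replicate spectra are pooled, sorted by
m/z, and cut into bins wherever the gap between adjacent peaks exceeds the
tolerance window (relative by default, 5×10⁻⁴ of the left peak's m/z,
≈ 4.3 Da at 8.5 kDa). This is single-linkage clustering in one dimension:
deterministic, independent of spectrum order, and exactly invertible for
peaks whose jitter stays within half a window. Bin centres are
intensity-weighted mean m/z reported to one decimal (the field's signature
notation, e.g. 8562.3). A bin's per-spectrum intensity is the sum of that
spectrum's peaks in the bin; a peak absent from a spectrum contributes
zero, never a missing value, because the voting classifier needs a complete
matrix and presence/absence itself can carry signal.

**Normalization and averaging.** The order is fixed as bin →
per-spectrum total-intensity normalization → arithmetic mean over each
sample's replicates. Normalizing before averaging removes spot-to-spot
total-signal variation (laser coupling, matrix crystallization) before it
can leak into the sample means.

**Modelling scale.** All model fitting (SAM, voting weights, clustering)
operates on log2 of the normalized averaged intensities (pseudocount: half
the smallest positive entry). MALDI intensities are approximately
log-normal with baselines spanning orders of magnitude; on the raw scale a
vote w_g (x_g − b_g) inherits the signal's abundance scale, so one
high-abundance signal can dominate the voting sum regardless of its
discriminative value. On the log scale within-class spreads are comparable
across signals and the signal-to-noise weights behave as intended. The
rank-based and dichotomized tests are unaffected by this monotone
transform.

## The three-test screen

* **Fisher exact test** on a 2×2 table of class × high/low. The
  dichotomization is not dictated by the procedure itself; the default is
  a median split over all training samples (value > per-signal overall
  median), with presence/absence (value > 0) as an alternative for sparse
  peaks. This is the largest interpretive gap in the screen and both rules
  are exposed in `SelectionCriteria`. Two-sided p-values use the
  minimum-likelihood convention (sum of hypergeometric probabilities of
  tables no more likely than the observed one), the dominant software
  convention.
* **Kruskal–Wallis test**, ties-corrected, p from χ² with k−1 df; for two
  groups this is equivalent to a two-sided rank-sum test. Implemented
  vectorized across signals; scipy's implementation serves as the test
  oracle.
* **SAM**: d_g = (x̄₁ᵍ − x̄₂ᵍ)/(s_g + s₀) with s_g the pooled standard
  error. The fudge factor s₀ is chosen from the 0,5,…,100 percentiles of
  {s_g} to minimize the coefficient of variation of the within-decile
  median absolute deviations of d — the standard stabilization of d for
  low-variance signals. The per-signal q is a permutation FDR: labels are
  permuted (default 1000 times; the same s₀ is reused), and for each
  cutoff δ the FDR is the median permuted count of |d*| ≥ δ divided by the
  observed count; q_g is the minimum FDR over cutoffs δ ≤ |d_g|, clipped
  to [0, 1].

Selection requires at least `min_criteria_met` of: Bonferroni-corrected
Fisher p < 0.05, Bonferroni-corrected KW p < 0.05, SAM q < 0.001. The
default is 2 of 3; 1 of 3 is supported because the two readings of the
screening rule differ, and the choice is surfaced in the configuration
rather than silently resolved.

## Weighted voting and model-size selection

Weights w_g = (μ₁ᵍ − μ₂ᵍ)/(σ₁ᵍ + σ₂ᵍ) use sample SDs (n−1 denominator; the
classical description is ambiguous between population and sample SD, and
the choice is recorded here). The decision boundary is the class-mean
midpoint; V = Σ w_g (x_g − b_g) > 0 calls cancer, and the exact tie V = 0
is assigned to noncancer — a deliberate, configurable bias toward
specificity appropriate for a screening test.

LOOCV model-size selection: for each held-out sample the remaining
samples re-rank the pre-selected candidates by |SAM d| (with the fold's
own s₀), and voting models of every size k predict the held-out sample.
Candidates are pre-selected on the *full* training set; only the ranking
is refreshed per fold. This partial cross-validation is a property of the
emulated procedure (the phrase "most shared" presupposes per-fold
variation in the ranking, not in the candidate set) and its optimistic
bias is the reason frozen-model validation on an independent cohort is
part of the pipeline. Ties everywhere are broken deterministically:
smallest k at equal misclassification counts; ranking ties by smaller
m/z; signature ties by appearance frequency, then larger mean |d| across
folds, then smaller m/z.

The published 7-signal plasma signature (8562.3 … 17250.8 m/z, with three
identified proteins) is kept as a metadata constant for report formatting;
it is a property of the original clinical cohorts and is not recomputable
from synthetic data.

## Evaluation

Cancer is the positive class; every benign class (healthy, acute/chronic
pancreatitis, AIP) is pooled as negative. Percentages are rounded half-up
to one decimal. Confidence intervals are exact two-sided Clopper–Pearson
(beta-quantile form); the x = n rows of the published accuracy tables
match the closed form 100·(α/2)^{1/n} to one decimal, which identifies
the exact method beyond doubt. One published bound (30/38 → 90.5) and one
PPV (89.8 vs 61/68 = 89.7) disagree with recomputation in the last
decimal; the package reports the recomputed values. The published
subgroup contrasts labelled as exact tests (0.142, 0.524) are reproduced
exactly by Pearson χ² *without* continuity correction and by no exact-test
convention; `fisher_2x2` therefore remains a true exact test and
`chi2_2x2` is provided alongside it.

Marker combination is an OR rule: combined-positive ⇔ model-positive or
marker > cutoff (strict inequality at the 37 U/mL cutoff — the boundary
convention is not dictated and is recorded here). OR monotonicity
(sensitivity can only rise, specificity only fall) is asserted as a
property test.

## Clustering

Distance 1 − uncentered correlation with average linkage — the defaults of
the classical expression-clustering software the procedure names — with
centered Pearson and Euclidean as alternatives. Dendrograms are
canonicalized (each merge's children ordered by smallest leaf id) so leaf
order is reproducible under sample permutation. The two-branch cut
reports per-branch class composition with exact binomial intervals.

## Synthetic cohort model

The generator emulates the structure of a two-class plasma profiling
study; none of its distributions are claims about the original data,
which report no noise or abundance parameters.

* **Panel**: 1063 signals on a jittered log-spaced grid over 2–50 kDa,
  spacing ≥ 3× the binning tolerance so binning recovers the panel
  exactly; per-signal baselines log2-normal (mean 10, SD 2).
* **Samples**: per-sample biological deviation SD 0.5 (log2). 5% of
  subjects carry 2.5× inflated biological noise (contaminated normal) —
  outlier plasma profiles are a routine feature of real cohorts and give
  the cross-validation error curve a realistic nonzero floor.
* **Planted signal**: 134 differential signals, of which 7 independent
  strong "drivers" at Cohen's d = 2.0 on the log2 scale, and 127
  "satellites" with marginal |d| ~ U(1.0, 1.4) realized through 2 shared
  latent disease factors of separation 2.0 (loading = |d|/2). Satellites
  are therefore individually detectable by the marginal screen but
  jointly redundant — emulating co-regulated protein species (fragments,
  modifications, family members). This redundancy is what makes the LOOCV
  misclassification curve fall to a minimum near the driver count and
  then degrade as marginally-weighted redundant votes accumulate; with
  134 *independent* signals of that strength the curve would decrease
  essentially monotonically and the minimum would sit far from a small
  signature, contradicting the study structure being emulated. Signs are
  random (markers go both up and down in disease).
* **Replicates**: 6 spots per sample, multiplicative log-normal noise
  with CV 0.25, 5% peak dropout per replicate, m/z jitter uniform within
  half the binning tolerance.
* **Marker**: class-wise log-normal, independent stream (medians 100
  U/mL for PDAC, 10 for healthy, 15 for benign pancreatitis; ≈ 75% of
  cases and < 10% of healthy exceed the 37 U/mL cutoff).
* **Streams**: the panel is keyed by the seed alone; samples additionally
  by a cohort stream, so independent training/validation cohorts share
  one panel. Spectra and marker use separate streams.

`bayes_rates` computes, for any signal subset, the per-class accuracy of
the linear rule optimal for the non-outlier population under the full
generative covariance (factors, replicate attenuation, outlier mixture);
frozen-model validation is checked against this quantity within 3
binomial SDs.

**What passing tests do and do not show.** The generator's signals are
(conditionally) Gaussian on the log scale, independent across samples,
with no batch effects, no chemical/electronic baseline noise, no mass
drift beyond bounded jitter and no isotope structure. Recovery results on
it validate the *statistical machinery* — calibration of the screen,
behaviour of the model-size curve, correctness of the evaluation
arithmetic — not performance on real plasma spectra.

## Problem sizes and determinism

Study-scale simulation checks use 20 cohorts (seeds 1–20) of 80+80
samples × 6 replicates × 1063 signals with 1000-permutation SAM FDR —
about 2–3 s per cohort — and the null-calibration suites use 30+30 × 200
settings. All randomness flows from explicit integer seeds; reruns are
bit-identical, and every tie-break in the pipeline is deterministic.

## Known limitations

* The Fisher dichotomization rule and the screen's 1-of-3 vs 2-of-3
  reading are genuinely underdetermined; defaults are documented choices.
* Candidate pre-selection outside the LOOCV folds biases the learning
  curve optimistically (by design, matching the emulated procedure);
  independent-cohort validation is the corrective.
* The marginal-weight voting classifier is suboptimal under correlated
  signals; no attempt is made to de-correlate (that would be a different
  classifier).
* Signature transfer across independently binned cohorts matches by
  nearest m/z within the binning tolerance; real inter-batch mass drift
  larger than the tolerance would require recalibration, which is out of
  scope.
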