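# maldivote

Plasma MALDI-TOF proteomic profiling yields, per sample, a list of peak
intensities over m/z. Turning such profiles into a small diagnostic
signature — e.g. for detecting pancreatic ductal adenocarcinoma (PDAC) and
discriminating it from benign mimics such as autoimmune pancreatitis (AIP) —
requires a chain of well-defined statistical steps. `maldivote` implements
that chain end to end, with a synthetic cohort generator carrying planted
ground truth so every stage is testable without access to clinical data:

1. **Preprocessing** — peaks from all replicate spectra are pooled and
   binned by single-linkage gap clustering on m/z (split when the gap
   between adjacent peaks exceeds a relative tolerance, default 0.05%);
   spectra are total-intensity normalized and replicate spots averaged into
   one row per sample; modelling proceeds on the log2 intensity scale.
2. **Differential screen** — each binned signal *g* is tested by
   (i) a two-sided Fisher exact test on median-dichotomized intensities,
   (ii) a Kruskal–Wallis rank test (both Bonferroni-corrected at α = 0.05),
   and (iii) the SAM moderated statistic
   d_g = (x̄₁ᵍ − x̄₂ᵍ)/(s_g + s₀) with a permutation FDR
   (default threshold 0.1%). A signal is selected when it meets at least 2
   of the 3 criteria.
3. **Weighted-voting classifier** — each signature signal votes
   v_g = w_g (x_g − b_g) with the signal-to-noise weight
   w_g = (μ₁ᵍ − μ₂ᵍ)/(σ₁ᵍ + σ₂ᵍ) and boundary b_g = (μ₁ᵍ + μ₂ᵍ)/2; the
   sign of V = Σ v_g calls the class (V = 0 → noncancer) and the prediction
   strength PS = (V_win − V_lose)/(V_win + V_lose) measures the margin.
4. **Model-size selection** — leave-one-out cross-validation: each fold
   re-ranks the selected candidates by |SAM d| and predicts the held-out
   sample with voting models of size k = 1…k_max; the k minimizing the
   misclassification count (ties → smallest k) is chosen, and the final
   signature is the k signals *most shared* across the per-fold top-k lists.
5. **Evaluation** — confusion counts (cancer positive, all benign classes
   pooled as negative), sensitivity/specificity/PPV/NPV/accuracy with exact
   two-sided Clopper–Pearson 95% intervals, per-subgroup tables, Fisher
   exact subgroup contrasts, and OR-combination with a scalar serum marker
   (CA19-9-like, positive when > 37 U/mL).
6. **Clustering** — agglomerative hierarchical clustering of samples on the
   selected signals (1 − uncentered correlation, average linkage) with a
   two-branch purity summary.

## Worked example

Simulate a training cohort at study scale (80 PDAC + 80 healthy samples,
6 replicate spectra each, 1063 signals of which 134 are differential with
7 strong drivers), run discovery, and validate the frozen model on an
independent cohort drawn from the same signal panel:

```bash
maldivote simulate --out data --seed 1
maldivote discover --peaks data/peaks.tsv --samples data/samples.tsv \
                   --out run --seed 1
```

prints (abridged):

```
Differential screen (Fisher exact / Kruskal-Wallis / SAM)
============================================================
signals tested:        1063
signals selected:      133

LOOCV model-size curve
========================================
samples: 160   k range: 1..133
optimal k: 8 (2 of 160 misclassified)

Diagnostic accuracy
========================================================
TP=80  FN=0  TN=79  FP=1  (n=160)
sensitivity  100.0% (80/80, 95% CI 95.5-100.0)
specificity  98.8% (79/80, 95% CI 93.2-100.0)
```

The screen found 133 of the 1063 signals differential (the cohort contains
134 planted ones), the cross-validation curve bottoms out at a signature of
8 signals, and the fitted voting model classifies the training cohort with
one false positive. Validating the frozen model on a fresh cohort:

```bash
maldivote validate --model run/model.tsv --peaks test_data/peaks.tsv \
                   --samples test_data/samples.tsv --out val
```

```
TP=78  FN=2  TN=79  FP=1  (n=160)
sensitivity  97.5% (78/80, 95% CI 91.3-99.7)
specificity  98.8% (79/80, 95% CI 93.2-100.0)

OR-combination with serum marker (> 37.0 U/mL):
sensitivity  98.8% (79/80, 95% CI 93.2-100.0)
specificity  90.0% (72/80, 95% CI 81.2-95.6)
```

Generalization error matches the training estimate, and the marker
OR-combination trades specificity for sensitivity, as an OR rule must.

The same pipeline is available as a library in the statsmodels style:

```python
import maldivote as mv
from maldivote.pipeline import build_feature_table

cfg = mv.CohortConfig(seed=1)
spectra, sheet, truth = mv.generate_cohort(cfg)
table = build_feature_table(spectra, sheet, mv.BinningConfig())

screen = mv.DifferentialScreen(table).fit(seed=1)       # ScreenResults
builder = mv.WeightedVoting(table)
curve = builder.loocv_curve(screen.selected_ids)        # CrossValCurve
signature = mv.extract_shared_signature(curve)
model = builder.fit(signature)                          # VotingResults
print(model.summary())
```

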