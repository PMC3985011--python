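# Methods

## Model

For each of the four outcome indexes (IT mean, IT median, LA mean, LA
median) the analysis fits the linear model family

    y_i = β_0 + Σ_{j ∈ M} β_j x_{ij} + ε_i,      ε_i ~ N(0, σ²)

over all predictor subsets M, where `y` is the case's control-normalized
log burden index and `x_j` are control-normalized log candidate
variables. Normalization divides every variable of a treated case by the
mean of the standard-diet control cases (plasma variables per timepoint:
baseline values by the control baseline mean, end-of-diet values by the
control end-of-diet mean) and applies the natural logarithm. The natural
log is a deliberate, documented choice: any log base yields the same
selections and inclusion probabilities, but coefficients scale by 1/ln(base),
and the downstream 0.001 magnitude floor is applied on this natural-log
scale.

### Posterior model weights

With uniform model priors, each subset fit's marginal likelihood is
approximated through its BIC:

    BIC_k = n ln(max(RSS_k, ε) / n) + (q_k + 1) ln n,
    P(M_k | D) = exp(−(BIC_k − BIC_min)/2) / Σ_j exp(−(BIC_j − BIC_min)/2)

with `q_k` the number of included predictors and ε = 1e−12·Var(y)·n an RSS
floor that keeps the criterion finite on perfect fits. Subsets with more
than n − 2 predictors are outside the model space (no residual degrees of
freedom); exactly collinear subsets are rejected rather than
pseudo-inverted — a silent pseudo-inverse would reorder posterior
probabilities irreproducibly — and during exhaustive enumeration such
subsets are skipped with a logged warning, since their full-rank
sub-models carry the same information.

Occam's window retains models with pmp_best/pmp ≤ ratio (default 20,
i.e. ΔBIC ≤ 2 ln 20 ≈ 6), implemented on BIC differences so underflow
cannot drop models spuriously; probabilities are renormalized afterwards.
Inclusion probabilities sum the weights of models containing a variable;
model-averaged coefficients count a slope of 0 where the variable is
excluded, so a variable absent from every retained model has an averaged
coefficient of exactly 0 (shrinkage).

### Iterated selection

Above the enumeration cap (20 variables, 2^20 models) the iterated scheme
is used. Variables are ranked by univariate R² (ties lexicographic) and
stream through an active window of `window_size` variables (default
min(8, n − 3)). After each exhaustive enumeration on the window, variables
with inclusion probability > `retention_threshold` (default 0.5) survive;
the rest are replaced by the next-ranked candidates. Two details are this
package's own resolutions of gaps in the scheme's usual description:

- **Saturated window.** If every window variable survives, no slot opens
  and the scan would stall; the weakest survivor (lowest inclusion
  probability, ties lexicographic) is evicted, logged, and the scan
  continues. Eviction is rare outside pathological regimes.
- **Returned result.** The result of the final enumeration — the first
  one covering the last candidates — is returned, and `retained` is its
  set of above-threshold variables. With `window_size ≥ p` the procedure
  is therefore *identical* (bit for bit) to plain enumeration; to make
  that exact, window variables are always enumerated in their original
  column order, while the R² ranking governs only entry order.

Variables pruned before the final window report inclusion probability and
averaged coefficient 0.

At n = 4 (the 8-week diet group alone) the default window collapses to
min(8, n − 3) = 1 and the run degenerates to univariate screening; this
is logged and mirrors the empirical finding that so small a group
supports no robust multivariable selection.

## Congruence filtering

Stage 1 keeps a variable only if it was selected (above-threshold) for at
least one IT index **and** at least one LA index — association with both
radial and circumferential lesion growth. Stage 2 then requires the
supporting averaged coefficients to share one sign, with at least one
|coefficient| ≥ 0.001; all-below-floor variables are discarded for
negligible magnitude. "Opposite sign at comparable size" is
operationalized as a max/min absolute-coefficient ratio ≤ `size_ratio_cap`
(default 10). The default `strict_sign=True` reading treats *any* sign
mixture as incongruent; the relaxed reading (`strict_sign=False`)
discards only comparable-size sign conflicts and otherwise takes the
direction of the dominant coefficient. Both readings are exposed because
the verbal rule is not a formula; the strict one is the default as the
more conservative filter.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 3 control,
4 HF (8-week) and 6 HHF (16-week) cases by default, 40 secretome
proteins, and an 8-analyte plasma panel at two timepoints. Defaults were
fixed once, on plausibility grounds:

| parameter | default | rationale |
|---|---|---|
| plasma between-case log-SD | 0.25 | moderate biological variation |
| end-of-diet extra log-SD | 0.15 | assay + temporal noise |
| diet fold changes (END, treated) | CHOL ×4, OXLDL ×3, IL6 ×1.8, TNFA ×1.6, ICAM1 ×1.4, HDL ×1.2, TG ×1.5 | strong cholesterol response to a 4% cholesterol diet, milder inflammatory shifts |
| HDL baseline | 0.5 × CHOL × LogN(0, 0.1) | keeps Friedewald LDL positive |
| protein abundance | LogNormal(3.0, 0.8) | right-skewed arbitrary counts |
| noise_sd (log burden) | 0.3 | unexplained case-level variation |
| group burden intercept | ln 0.2 mm (HF), ln 0.45 mm (HHF) | fatty streak vs atheroma scale |
| baseline control intima | 0.05 mm | small nonzero control lesions, so control means are strictly positive |
| segments per case | 9, split over two arteries | typical profiling density |
| localized profile | ⌈n/3⌉ hot segments U(0.8, 1.2) over cold U(0.1, 0.3) | median/mean ≈ 0.45, the focal-lesion divergence |
| diffuse profile | U(0.6, 1.4) | median ≈ mean |
| LA width | IT × 2 mm × LogN(0, 0.25) | lesion area tracks thickness |

Ground truth is planted on the log-log scale: a treated case's log burden
is its group intercept plus Σ_j effect_j·ln(x_j) plus N(0, noise_sd), and
the segment profile is rescaled so the case's mean IT equals exp(burden)
*exactly*. The default effect map is empty (a null cohort): no planted
structure is asserted beyond the diet fold changes and group intercepts.
Concentrations are drawn lognormal because the downstream log transform
requires strict positivity; generated Friedewald LDL is clipped at
1 mg/dL in the rare draw where the formula goes nonpositive.

What the generator does **not** emulate: measurement-error structure of
ELISA/MS assays, protein-protein correlation blocks, longitudinal
within-animal correlation beyond the two plasma timepoints, segment-order
spatial correlation along an artery, and any real biology linking plasma
to secretome. Passing recovery tests therefore demonstrates correctness
of the inference machinery under its own assumptions, not performance on
real vascular data.

Triglycerides are measured and used for the LDL derivation but excluded
from the candidate set by default (`exclude_analytes=("TG",)`), matching
the convention that the lipoprotein candidates are total cholesterol,
LDL, HDL and oxLDL; both total cholesterol and derived LDL are offered.

## Validation studies and problem sizes

`atherobma.evaluation` implements the replicate studies run by the
acceptance script and test suite; sizes were chosen to characterize the
estimator while keeping a single-CPU run in minutes:

- **Oracle agreement** (25 datasets, n = 30, p = 3…8): exhaustive
  enumeration and the iterated selector with an uncompressed window are
  compared against an independent normal-equations brute force over all
  2^p models; agreement is at numerical precision (~1e−15).
- **Recovery** (200 replicates, 40 treated cases, 50 candidates, three
  planted |effect| = 1 at noise 0.3): planted variables reach mean
  inclusion ≈ 1.0, null variables ≈ 0.04, and retained planted signs
  agree with the planted direction essentially always.
- **Null calibration** (100 replicates, default 3/4/6 cohorts, no planted
  effects): the end-to-end ledger retains ≈ 2 variables per cohort on
  average. This is a known small-n limitation, discussed below.
- **Group degeneracy** (50 replicates): the 4-case-group run retains
  strictly fewer variables than the pooled run (near zero).

## Known limitations

- **BIC at n ≈ 10 overfits.** With 10 treated cases and ~54 candidates,
  chance correlates reach |r| ≈ 0.8 and near-saturated window models fit
  almost perfectly, so each index run retains ≈ 5 variables under the
  null. The congruence filter roughly halves, but does not eliminate,
  these false positives, because the four outcome indexes are derived
  from the same per-case burden (the mean-IT index is an exact function
  of it) and are therefore strongly correlated: a per-index false
  positive tends to recur on IT and LA indexes with the same sign.
  Cross-index congruence is consequently a much weaker null filter than
  index-independence intuition suggests. Conclusions at the study's
  native size should rest on the pooled run and be treated as
  hypothesis-generating.
- The magnitude floor (0.001) is scale-dependent; it is meaningful only
  on the control-normalized natural-log scale used here.
- The iterated scan is order-dependent by construction; a variable
  ranked low by univariate R² can be masked by earlier survivors.
- No multiple-testing correction is applied at the congruence stage, by
  design.
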