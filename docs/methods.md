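# Methods

This note documents the models, numerical choices and limitations behind
`afnmr`, in the order the pipeline runs.

## Synthetic cohort model

**What it emulates.** A two-group second-trimester amniotic-fluid ¹H-NMR
cohort: 43 term and 17 preterm samples by default, drawn from a
27-metabolite library covering the aliphatic and aromatic amino acids,
sugars and organic acids typical of AF (glucose, lactate and urea dominate
the total signal, as in real AF).

**Concentrations.** Per-sample metabolite concentrations are log-normal
with the library's mean and coefficient of variation; the preterm group's
means are multiplied by 2^log₂FC for metabolites carrying an effect. The
default effects lower dimethylglycine, glucose and myo-inositol and raise
succinate in preterm samples, all with |log₂FC| = 0.6. With the default
cv = 0.25 this gives a theoretical per-metabolite AUROC of
Φ(d/√2) ≈ 0.88, where d = 0.6·ln2 / √ln(1+cv²) ≈ 1.7 is the standardized
difference on the log scale — deliberately placed in the
"good-but-not-trivial" 0.75–0.9 band where the promotion thresholds bite.
Observed bucket-level AUROCs land around 0.80–0.95 at n = 43/17. The
succinate direction deserves a note: the source literature is internally
inconsistent about whether succinate rises or falls in preterm AF; this
package defaults to *higher in preterm* (the interpretation its own
discussion develops at length) and the direction is a plain `EffectSpec`
parameter either way.

**Spectra.** Each metabolite contributes its multiplets as groups of
evenly spaced Lorentzian lines (spacing = J/500 ppm at the 500 MHz
equivalence, binomial intensity ratios, half-width from the linewidth in
Hz). Every multiplet is rescaled so that its trapezoidal integral over
the full axis equals concentration × relative area *exactly*, which makes
area-conservation testable to 1e-6 despite Lorentzian tails and finite
grids. A Gaussian lineshape is available behind a flag. On top of the
signal: a TSP-like reference singlet at 0.00 ppm, a random cubic baseline
scaled to `baseline_amplitude`, i.i.d. Gaussian noise (`noise_sd`, default
0.2 ≈ 1–2 % of a mid-sized peak apex), and a per-sample *global*
chemical-shift jitter ~ N(0, 0.002 ppm). Defaults: axis 0–10 ppm, 16384
points.

**What it does not emulate.** FID-domain effects (apodization, phasing,
water-suppression artifacts), per-multiplet pH-dependent shift changes
(jitter is global, so alignment has an easier job than on real urine-like
data), peak-shape distortions, macromolecule baselines, and
between-metabolite concentration correlations. Passing tests therefore
demonstrate correctness of the algorithms under a faithful but idealized
generative model, not field performance on real AF spectra.

## Preprocessing

Order is fixed: calibrate → baseline → exclude → align → PQN → bucket.

* **Calibration** shifts each spectrum by an integer number of grid steps
  so the tallest point within ±0.2 ppm of 0.00 ppm lands on the reference
  position; it raises if no candidate exceeds 5× the window's median
  intensity. Integer shifts keep intensities untouched and make
  calibration idempotent.
* **Baseline** is asymmetric least squares (second-difference penalty
  `smoothness` = 1e7, asymmetry p = 1e-3, ≤ 10 reweighting iterations),
  solved with a symmetric banded Cholesky solver (O(n) per iteration).
  The defaults remove polynomial drift at 16384 points while preserving
  apex heights to a few percent; a much smaller `smoothness` would start
  eating broad peaks (urea), a much larger one stops tracking curvature.
* **Water exclusion** defaults to 4.5–5.0 ppm. Exclusion is a mask:
  intensities are kept, but normalization, bucketing and S/N ignore the
  region. (The β-anomeric glucose doublet at 4.64 ppm intentionally falls
  inside the mask; glucose keeps four other multiplets.)
* **Alignment** is hierarchical: reference = sample most correlated with
  the median spectrum; each other sample is shifted segment-wise
  (integer shifts, |s| ≤ 25 points) to maximize Pearson correlation with
  the reference, recursing on segment halves down to 0.1 ppm. Segments
  are only shifted when both reference and sample show an *interior* apex
  above 5× a robust noise level — tail-only segments must not move (a
  monotone slope correlates best when piled onto its own edge fill, a
  classic failure mode). Per-sample changes that do not improve
  correlation with the reference are reverted, so the mean pairwise
  correlation cannot decrease.
* **PQN** integral-normalizes each sample to the cohort-mean total
  integral, takes the median spectrum as reference, and divides each
  sample by the median of pointwise sample/reference quotients over
  unexcluded points where the reference exceeds a noise floor (default:
  the median of the reference — in sparse NMR spectra most points are
  baseline, so this is a robust noise estimate). The reported dilution
  factor is (integral factor × median quotient), so a sample that is c ×
  reference reports factor c.
* **Bucketing** places edges at local minima of the 9-point-smoothed mean
  spectrum within 0.8–8.5 ppm; buckets narrower than 0.01 ppm are merged
  (dropping the higher-intensity bounding edge first), wider than 0.5 ppm
  split at their lowest interior point. Values are per-sample trapezoidal
  integrals over inclusive grid slices, so retained + dropped buckets
  conserve the region integral to 1e-9. A bucket is retained when the
  mean spectrum's maximum inside it reaches `snr_min` = 3 × the SD of the
  mean spectrum over 9.5–10.0 ppm (signal-free by construction) and it
  does not intersect an excluded region. The exact heuristic used by
  commercial "intelligent bucketing" modules is not public; local-minima
  bucketing is this package's documented stand-in.

## Bucket annotation and the promotion funnel

A metabolite is assigned to a bucket iff one of its multiplet centers
lies within the bucket window inflated by ±0.02 ppm. Buckets matching
no metabolite are discarded; buckets matching several (e.g. the
betaine 3.26 / myo-inositol 3.27 ppm clash) are excluded by the
uniqueness filter, which is the point: overlap-free quantification beats
coverage for biomarker work. Each unique bucket gets a two-sided
Mann–Whitney U test (exact when n₁+n₂ ≤ 12 without ties, tie-corrected
normal approximation otherwise; p = 1 for degenerate input) and an AUROC
computed from ranks (identically U/(n₁n₂)). AUROC is folded to
max(A, 1−A) because promotion uses one threshold for both directions;
the raw orientation is kept as the `direction` field from group medians.
Promotion keeps folded AUROC > 0.75 AND p < 0.05 — both strict, so a
bucket at exactly 0.75 fails — then keeps one bucket per metabolite
(highest AUROC; ties by smaller p, then lower ppm). p-values at this
stage are deliberately unadjusted (an informational BH column is
emitted); multiplicity control is applied only at the pathway stage.

## Multivariate models

Pareto scaling divides centered columns by √sd (sd with ddof = 1);
zero-variance columns are centered only and flagged. PCA is an SVD of
the scaled matrix. PLS-DA is NIPALS PLS1 on the {0,1}-coded, centered
label: w ∝ X'y, t = Xw, p = X't/t't, q = y't/t't, deflating X and y;
R²X/R²Y are cumulative residual-variance ratios. The default of 3
components matches common practice for small metabolomics panels; a
CV-based choice is possible via `cross_validate`. VIP follows the
standard SSY-weighted formula, so ΣVIP² = number of features holds by
identity and is asserted on every fit.

Validation: stratified 10-fold CV (seeded, folds capped by the smaller
class), Q² = 1 − PRESS/TSS with TSS against the training-fold mean,
accuracy by thresholding the predicted response at 0.5. The permutation
test refits the model under uniformly permuted labels and compares a
between/within sum-of-squares separation of the score matrix
(a CV-accuracy statistic is selectable); p = (1+b)/(1+B) never returns
zero, and its floor at B = 1000 is 1/1001 ≈ 0.001 — reaching it means no
permutation matched the observed separation. Whether a published
accuracy of this kind is cross-validated or resubstitution is often
unstated; here CV is the headline number and R²Y the resubstitution fit.

## Pathway stage

ORA is the one-tailed hypergeometric sf; expected hits = nK/N. Holm and
BH support a family size m larger than the number of tested pathways
(untested members enter as p = 1, affecting only the multipliers). The
default m is the size of the loaded pathway library — for the KEGG human
metabolome library that is 84, and recomputing a published AF pathway
table's Holm column from its printed −log₁₀(p) values with m = 84
reproduces the printed 4-decimal values at the ranks not corrupted by
the printed log's own rounding (ranks 1, 4, 5; rank 3 differs by one in
the fourth decimal for exactly that reason). Impact is the hit nodes'
share of total betweenness centrality in the pathway's compound graph.
The bundled 14-pathway database over the 27-metabolite library is
synthetic (KEGG-shaped names, hand-built graphs) — shipping a real
pathway database is out of scope, so its enrichment p-values are
structurally, not biologically, meaningful. An enriched flag requires
raw p < 0.05 AND ≥ 2 hits; high impact means impact > 0.1.

## Problem sizes and determinism

Defaults everywhere favour the study-scale problem: 60 spectra × 16384
points simulate and analyze in ~3 s. The test suite's heaviest check runs
50 seeded default cohorts end-to-end (~3 min) to verify that the four
programmed biomarkers are promoted with correct directions and top VIPs
in ≥ 80 % of cohorts; null calibration uses 2000 feature-level
replicates (type-I error in [0.03, 0.07]) and 150 small permutation
replicates (uniformity by KS). All randomness flows through explicit
integer seeds; a full simulate → analyze run is bit-reproducible given
the seed.

## Known limitations

* Alignment shifts are per-segment constant with edge fill; no
  sub-gridpoint interpolation.
* Annotation is 1D shift-matching only; real assignment work uses 2D
  experiments and is out of scope.
* The bundled pathway database is a structural stand-in; swap in a real
  library via `read_pathway_db` for biological conclusions.
* The generator's noise model (white Gaussian, global jitter) flatters
  alignment and S/N estimation relative to real spectra.
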