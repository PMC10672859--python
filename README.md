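# afnmr

A tested pipeline for second-trimester **amniotic-fluid (AF) ¹H-NMR
metabolomics** aimed at preterm-delivery (PTD) biomarker discovery. It is
written for metabolomics researchers who want a transparent, scriptable
version of the workflow usually spread across NMRProcFlow- and
MetaboAnalyst-style tools:

1. **Spectral preprocessing** — TSP calibration (0.00 ppm), asymmetric
   least-squares baseline correction, residual-water exclusion, CluPA-style
   hierarchical segment alignment, probabilistic quotient normalization
   (PQN), and adaptive ("intelligent") bucketing of the 0.8–8.5 ppm region
   with S/N filtering.
2. **Unique-bucket biomarker promotion** — buckets are annotated against a
   27-metabolite chemical-shift library; buckets matching more than one
   metabolite are discarded; each remaining bucket is scored with a
   two-sided Mann–Whitney U test and the AUROC
   (AUROC = U/(n₁n₂), folded to max(A, 1−A)); buckets with
   AUROC > 0.75 and p < 0.05 are promoted, then collapsed to one winning
   bucket per metabolite (highest AUROC).
3. **Multivariate validation** — Pareto scaling (x−x̄)/√s, PCA, a NIPALS
   PLS1 discriminant model (PLS-DA) with VIP scores
   (VIPⱼ = √(p·Σₐ SSYₐ(wₐⱼ/‖wₐ‖)² / Σₐ SSYₐ)), stratified k-fold Q² and
   accuracy, and a label-permutation test of class separation with
   p = (1+#{perm ≥ obs})/(1+B).
4. **Pathway over-representation** — one-tailed hypergeometric tests
   P(X ≥ k) against a pathway library, Holm and Benjamini–Hochberg
   adjustment with an explicit family size, and topological impact as the
   hit compounds' share of betweenness centrality in the pathway graph.

Because raw clinical AF spectra are generally not shareable, the package
includes a first-class **synthetic cohort generator**: two-group cohorts
(default 43 term / 17 preterm) rendered as sums of Lorentzian multiplets
from the 27-metabolite library, with log-normal concentrations, programmed
group effects (dimethylglycine, glucose, myo-inositol lowered and
succinate raised in preterm; |log₂FC| = 0.6), polynomial baselines,
chemical-shift jitter and Gaussian noise. Every downstream stage is tested
against this known ground truth.

## Worked example

```sh
afnmr simulate --out-dir demo --seed 42
afnmr analyze demo/spectra.csv demo/labels.tsv --report demo/report.json --seed 42
```

prints

```
wrote 60 spectra to demo/spectra.csv
promoted: succinate (higher_in_preterm), glucose (lower_in_preterm),
          dimethylglycine (lower_in_preterm), myo-inositol (lower_in_preterm)
report written to demo/report.json
```

and the report contains (seed 42):

```
funnel: buckets_total 281 -> annotated 94 -> unique 76 -> passing 12 -> winners 4
model:  ncomp 3, R2X(cum) 0.857, R2Y(cum) 0.704, Q2(cum) 0.663,
        cv_accuracy 0.95, permutation_p 0.001 (1000 permutations)
succinate        higher_in_preterm  AUROC 0.910  bucket [2.385, 2.426)
glucose          lower_in_preterm   AUROC 0.886  bucket [5.172, 5.230)
dimethylglycine  lower_in_preterm   AUROC 0.876  bucket [2.892, 2.982)
myo-inositol     lower_in_preterm   AUROC 0.850  bucket [3.281, 3.327)
```

The funnel counts are the bucket-reduction story: 281 adaptive buckets,
94 of which match a library metabolite, 76 of which match exactly one
(covering all 27 metabolites), 12 of which pass the AUROC/p thresholds,
collapsing to the 4 programmed biomarkers with their programmed
directions. The permutation p of 0.001 = 1/1001 is the smallest value
attainable with 1000 permutations, i.e. no permuted model separated the
classes as well as the real one. The promoted metabolites feed the
pathway stage, which flags the two-compound inositol-related pathways as
enriched (raw p ≈ 0.017, ≥ 2 hits).

The same run is available programmatically:

```python
from afnmr import CohortConfig, PipelineConfig, SpectraMatrix, analyze, simulate_cohort

spectra, truth = simulate_cohort(CohortConfig(seed=42))
report = analyze(SpectraMatrix.from_spectra(spectra), PipelineConfig(seed=42))
```

## Layout

```
src/afnmr/synth.py       synthetic cohorts: library, concentrations, rendering
src/afnmr/preprocess.py  calibrate / baseline / exclude / align / PQN / bucket
src/afnmr/biomarkers.py  annotation, Mann-Whitney + AUROC, promotion funnel
src/afnmr/mvstats.py     Pareto, PCA, NIPALS PLS-DA, VIP, CV, permutation test
src/afnmr/pathway.py     hypergeometric ORA, Holm/BH, betweenness impact
src/afnmr/io.py          CSV/TSV/YAML/JSON formats
src/afnmr/pipeline.py    orchestration + run report
src/afnmr/cli.py         afnmr simulate / preprocess / analyze / pathway
docs/methods.md          model and design notes
```
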