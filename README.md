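# metacortex

A tested pipeline for cross-species brain metabolome case/control analysis:
from aligned untargeted LC–MS peak tables (prefrontal-cortex gray matter;
human controls, ASD cases, chimpanzees, macaques) to confounder-free
differential metabolites, temporal modules, pathway enrichment, a
stability-selection classifier, and human/chimpanzee lineage-specificity
calls. A synthetic-cohort generator reproduces the study's statistical
structure with known ground truth, so every stage is validated end to end
without any data download.

## Who it is for

Researchers analyzing peaks × samples LC–MS intensity tables with age-
structured case/control (and optionally cross-species) designs who need a
reproducible, scriptable implementation of the full analysis chain rather
than ad-hoc notebook code.

## What it computes

* **Putative annotation** — observed m/z matched to compound monoisotopic
  masses under singly charged adducts ([M+H], [M+NH4], [M+Na] positive;
  [M−H], [M+FA−H], [M−H2O−H], [M+Na−2H] negative) within 10 ppm:
  |(m/z_obs − m/z_theo)/m/z_theo| ≤ 10⁻⁵. All candidates are reported.
* **Injection-order drift correction** — per metabolite, standardized log2
  intensity is regressed on injection order with an RBF-kernel SVR (one
  hyperparameter set for all metabolites); fitted curves are k-means
  clustered and clusters that track the order (|Spearman ρ| ≥ 0.3 or
  amplitude ≥ 0.5 SD, above a 0.65 SD floor) are corrected by subtracting
  the cluster-average curve, then intensities are returned to linear scale.
* **PMD filter** — a natural cubic spline (4 df) of log2 intensity on age,
  fitted to short-PMD (< 20 min) macaque reference samples; metabolites
  whose prolonged-PMD (5–6 h) probe samples leave the 95% prediction band
  are excluded.
* **Upper-quartile normalization** — per sample within each ionization
  mode, intensities are divided by the sample's 75th percentile of nonzero
  values and rescaled by the geometric mean of the per-sample quartiles.
* **Differential calling (ANCOVA)** — per metabolite, the best polynomial
  of age (degree 0–3 by adjusted R², chosen on a reference group) is the
  null model; an F-test (1, n−d−2 df) evaluates an additive case/control
  offset. Run twice (each group as reference), BH-adjusted within each run;
  a metabolite is ASD-related when both adjusted p ≤ 0.05.
* **Temporal modules** — complete-linkage hierarchical clustering of the
  significant metabolites with distance 1 − Pearson r, tree cut at 4.
* **Pathway enrichment** — upper-tail hypergeometric test of metabolite-
  linked genes per pathway against the detected-metabolite gene background,
  BH-corrected; Fisher exact tests for pathway-set overlaps; two-sample KS
  test comparing per-metabolite proportions of expression-shifted
  (|log2FC| > 0.2) linked genes.
* **Classifier** — stability selection over 500 stratified 75/25 splits of
  an L1-logistic model (C = 100): per-metabolite inclusion probabilities,
  mean held-out ROC AUC, top-200 predictor set.
* **Lineage specificity** — stringent: pairwise two-reference species
  ANCOVA on human-equivalent age (human-specific = human/chimp and
  human/macaque significant, chimp/macaque not, after BH); relaxed:
  per-peak z-transform, human-specific when |z̄_H − z̄_M| > |z̄_C − z̄_M|
  with concordant signs. Module excess of human- over chimpanzee-specific
  calls via 1000 subsamplings of 30 samples per species.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic cohort (outputs under `results/`):

```
$ python analysis/01_simulate_cohort.py
cohort seed=7: 300 positive + 200 negative peaks x 152 samples
planted: 60 ASD-affected, 50 drifted, 20 PMD-sensitive, 400 lineage-shifted

$ python analysis/02_preprocess.py
drift: 49 peaks in order-affected clusters (corrected)
PMD filter: excluded 74 of 500 peaks
clean table: 426 peaks x 152 samples

$ python analysis/03_differential_modules.py
54 of 426 metabolites ASD-related (both BH q <= 0.05; implied nominal p < 0.0060)
recovery: sensitivity 0.91, observed FDR 0.09
module sizes: {1: 11, 2: 11, 3: 14, 4: 18} | ARI vs planted archetypes 1.00

$ python analysis/05_classifier.py
stability selection: mean test AUC 0.745 over 500 subsamples (0 convergence failures)
top-200 predictors overlap ANCOVA calls: 41 shared, Fisher p = 3.70e-06

$ python analysis/06_evolution.py
stringent: 231 human-specific, 80 chimpanzee-specific of 426 peaks
relaxed: 220 human-specific, 83 chimpanzee-specific of 426 peaks
human:chimp ratio over 1000 subsamples (n = 30/species): median 2.51 [Q1 2.36, Q3 2.66]
```

Reading the numbers: of the 60 planted ASD-affected metabolites that
survive preprocessing, 91% are recovered at ≤ 10% false discoveries; the
four planted age-trajectory archetypes are reconstructed perfectly
(adjusted Rand index 1.0); and the 3:1 planted excess of human-specific
over chimpanzee-specific shifts appears as a subsampled ratio median of
2.5 — diluted below 3 because the relaxed rule's sign-concordance
condition also assigns calls to unshifted metabolites (see
`docs/methods.md`). `analysis/04_annotation_enrichment.py` demonstrates
the annotation → gene-linking → enrichment chain on a table with known
compound identities and recovers the planted pathway at q ≈ 6×10⁻¹⁷.

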