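# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Study design assumed by the pipeline

The pipeline expects aligned peaks × samples intensity tables (linear
scale, one table per ionization mode, per-peak m/z and optional retention
time) and per-sample covariates: species (human / chimpanzee / macaque),
diagnostic group (control / ASD for humans, NA otherwise), age in years
(negative = prenatal), sex, postmortem delay (PMD, hours), RNA integrity,
injection order (unique per run) and batch. The reference design is
40 human controls (0–61 y), 32 ASD cases (2–60 y), 40 chimpanzees
(0–42 y) and 40 macaques (−0.27–21 y), measured in one randomized
injection sequence.

## Annotation

Theoretical m/z = monoisotopic mass + adduct delta, singly charged ions
only. The seven adduct deltas (proton 1.007276 Da; NH4 18.033823; Na−e⁻
22.989218; formic-acid−H 44.998201; −H2O−H −19.018390; +Na−2H 20.974666)
live in one constant table. Tolerance is relative (default 10 ppm) and
inclusive (≤), because a boundary rule must be defined and "within a
tolerance" reads as inclusive. Every (compound, adduct) candidate within
tolerance is reported — putative m/z matching has no defensible basis for
picking a single winner, and downstream gene linking takes the union over
candidates. The indexed interval query is contract-equivalent to an
exhaustive scan (property-tested).

## Injection-order drift correction

Per metabolite, intensities are log2-transformed, centered and scaled to
unit SD, and the dependence on injection order is estimated with an
RBF-kernel support vector regression — one hyperparameter set for all
metabolites (C = 1, ε = 0.3, γ = 1 on the order axis rescaled to [0, 1]).
The ε-tube and the ~0.7-run-length kernel scale keep fits of pure noise
nearly flat while a monotone drift spanning the run is captured
faithfully; this matters because flagging below is amplitude-based.

Fitted curves, evaluated on the common order grid, are clustered with
k-means (k = 10, fixed seed). A cluster is order-affected when its mean
curve has |Spearman ρ| vs order ≥ 0.3 **or** peak-to-trough amplitude
≥ 0.5 SD — an automated surrogate for visual inspection — *provided* its
amplitude exceeds a 0.65 SD floor. The floor exists because k-means groups
null curves by their incidental trend direction, so even a negligible-
amplitude cluster mean is monotone (|ρ| ≈ 1); a drift that cannot be seen
in amplitude is not a drift. The floor was calibrated against the null
envelope of SVR fits at the reference run size (~150 injections; null
cluster means stay below ~0.55 SD, genuine 2-SD drifts above ~1.0). For
much shorter runs (tens of injections) the null envelope rises and the
no-flag guarantee weakens; rescale the thresholds before applying the
stage to small runs.

Affected clusters are corrected by subtracting the cluster-average curve
(default) or discarded (`action="discard"`); corrected values are returned
to the original magnitude scale by inverting the standardization and
exponentiating. The procedure is a no-op on drift-free tables and stable
under a second application.

## PMD filter

Reference samples: macaques with PMD < 20 min; probes: macaques with
longer PMD. Per metabolite, a natural cubic regression spline with 4
degrees of freedom is fitted to log2 intensity vs age on the reference
samples, and each probe is compared with the prediction interval
fit(age) ± z(0.95) · s · √(1 + h), where s² is the residual variance and
h the probe's leverage. A prediction-type interval (residual variance plus
leverage) is used, not a mean-confidence band, because individual probe
samples are being judged. Exclusion requires any probe strictly outside
its interval; probes outside the reference age span are skipped rather
than extrapolated. With two probes the null exclusion rate is
1 − 0.95² ≈ 9.7%, which the tests verify; this is the price of the
filter's sensitivity and mirrors how aggressively confounded peaks should
be dropped before group comparisons.

## Upper-quartile normalization

Within each ionization mode: each sample is divided by the 75th percentile
of its nonzero intensities and multiplied by the geometric mean of the
per-sample quartiles. The restoration constant keeps output near input
magnitude; it makes the output covariant (by a single global factor) under
rescaling of one sample, which is immaterial downstream because every
analysis works on log2, per-peak standardized data.

## Differential calling

For metabolite y over human samples: the best polynomial of age among
degrees 0–3 is chosen by adjusted R² on the *reference group only*
(ties within 1e−8 to the smaller degree; age standardized before powers
for conditioning). The null model refits that polynomial on all samples;
the full model adds a single additive group indicator (no group × age
interaction — the minimal model for an offset question). The F statistic
((RSS₀ − RSS₁)/1)/(RSS₁/(n − d − 2)) is referred to F(1, n − d − 2). The
test runs twice, with control and ASD as reference; BH adjustment is
applied within each run across metabolites, and significance requires both
adjusted p ≤ 0.05.

Two calibration facts the tests pin down: (i) the type-I error of the
procedure is nominal (0.051 over 2000 null simulations at n = 72) even
though the degree is data-chosen — degree selection on the reference group
is independent of the group labels under the null; (ii) adjusted-R² degree
selection admits a spurious degree whenever its partial F exceeds 1
(probability ≈ 0.32 under the null), so the constant model is the modal,
not near-certain, choice on noise. The downstream F-test is insensitive to
this overfitting because the same polynomial enters null and full models.

Modules: significant metabolites are clustered on their standardized
intensity profiles across all human samples with distance 1 − Pearson r
and complete linkage, cut at 4 clusters; peaks are sorted by id first so
tie-breaking is deterministic. Display trajectories per module and group
are cubic-spline smoothed means on a common age grid (a cosmetic choice).

## Pathway enrichment and expression shifts

Gene linking takes the union of directly linked enzymes over all compounds
annotating the chosen peaks; the background is the same union over all
detected peaks. Enrichment per pathway is the upper-tail hypergeometric
probability of the observed overlap with pathway ∩ background, BH-adjusted
across pathways. Pathway-set overlaps use one-sided Fisher exact tests
with the universe = all pathways tested in either run (the minimal
well-defined universe). The expression-shift comparison computes, per
peak, the proportion of its linked genes with |log2FC| > 0.2 and contrasts
ASD-related vs other peaks with a two-sample KS test. Mapping tables are
static CSV-schema inputs; absolute pathway counts depend on the mapping
snapshot and are therefore property-tested, never value-matched.

## Classifier

Stability selection: 500 stratified 75/25 train/test splits (seeded);
per split, per-peak z-standardization with training-fold statistics, an
L1-penalized logistic regression at fixed C = 100 (liblinear), the set of
nonzero coefficients, and the held-out ROC AUC. Outputs are per-peak
inclusion probabilities (fraction of splits with a nonzero coefficient)
and the mean AUC; predictors are ranked by inclusion probability, ties by
mean |coefficient| then peak id. Convergence failures are counted and
reported. The fixed 75/25 split is a documented choice (the split fraction
is not dictated by the method); per-fold standardization makes inclusion
probabilities invariant to feature scaling.

## Lineage specificity

Ages are mapped to human-equivalent years by per-species factors (defaults
1.0 / 1.5 / 3.0 for human / chimpanzee / macaque — coarse developmental-
pace ratios; they are configuration, not estimates, and the synthetic
generator uses the same convention so analyses are internally consistent).
Human samples default to controls only, so disease effects do not
contaminate species contrasts.

Stringent: for each species pair, the two-reference ANCOVA with species as
the group factor; BH within each reference run across peaks; a pair is
significant when both runs pass (pair q = max of the two). Human-specific
= human/chimp and human/macaque significant, chimp/macaque not;
chimpanzee-specific is the mirror image.

Relaxed: per peak, intensities are z-transformed across all samples of the
three species pooled; with species mean z-scores m_H, m_C, m_M, a peak is
human-specific when |m_H − m_M| > |m_C − m_M| and sign(m_H − m_M) =
sign(m_C − m_M), chimpanzee-specific in the mirror case. Two algebraic
properties are tested exactly: swapping the human and chimpanzee labels
swaps the calls, and any per-peak affine transform of the log2 intensities
leaves calls unchanged.

A structural feature of the relaxed rule worth knowing: for a completely
unshifted peak the two distances are exchangeable and the sign condition
holds with probability 2/3 (the two species-mean deviations share the
macaque mean, correlation ½), so roughly a third of null peaks receive
each call. Observed human:chimp ratios are therefore shrunk toward 1
relative to the planted ratio of shifted peaks — the synthetic 3:1
planting yields a subsampled median near 2.4. Conversely, a pure
terminal-branch shift gives the sister species a coin-flip sign, halving
recovery; the generator therefore places a small concordant component
(default 0.1× the shift) in the sister species, the signature of change
accumulated on the shared branch. Stringent and relaxed calls agree on
strongly shifted peaks only when that concordant component is resolvable
in sign but below the pairwise BH detection threshold — a regime that
needs many tested peaks (the agreement test uses 2000).

Module excess: 1000 seeded draws of 30 samples per species without
replacement; relaxed calls are recomputed per draw and the
human-specific : chimpanzee-specific count ratio recorded per module and
genome-wide. Zero denominators are kept as +∞ and summaries use median
and quartiles, which remain finite while fewer than a quarter of draws are
degenerate.

Fold-change concordance between datasets: Pearson r over matched peaks'
human/macaque log2 fold changes, plus a one-sided Fisher exact test on the
2×2 sign-quadrant table.

## Synthetic cohort

Per peak and sample, on log2 scale: baseline (N(20, 2²)) + age trajectory
+ ASD effect + lineage shift + drift + PMD shift + N(0, 0.5²) noise, then
exponentiated; all effect sizes are in units of the residual noise SD.
Ages are uniform within each cohort's range (the study reports only
ranges). Defaults: 500 peaks (60% positive mode), 12% ASD-affected at 1.0
SD, 10% drifted at 2.0 SD across the run, 4% PMD-sensitive at 5.0 SD in
the two prolonged-PMD probes, 60%/20% human/chimp lineage-shifted at
2.0 SD (the 3:1 planting; the large fraction mirrors how pervasive
species differences are in cross-species metabolome data).

ASD-affected peaks carry one of four archetypes; their age trajectories
are mutually near-orthogonal members of the cubic family (Legendre terms;
module 4 anticorrelated with module 1), i.e. within the model family the
ANCOVA assumes, so measured power reflects offset detectability rather
than polynomial misspecification. Modules 1–2 are elevated in ASD, 3–4
decreased; module 3's effect decays with age (strongest in the first two
decades). Effect weights are normalized to mean 1 over the ASD samples'
ages.

What the generator does **not** emulate: missing values and detection-limit
censoring, heteroscedastic (intensity-dependent) noise, retention-time
drift, batch effects, correlated peaks from shared compounds (adducts/
isotopes), and non-uniform age sampling. Passing tests therefore
demonstrate correctness of the statistical machinery under the idealized
noise model, not robustness to those real-data pathologies.

## Numerical conventions

Seeds are mandatory wherever randomness enters (generator, k-means,
classifier splits, subsampling); a fixed seed reproduces results bitwise.
Zero-variance peaks are passed through (drift), dropped with a warning
(module clustering), or called none (relaxed lineage). BH propagates NaN
p-values as NaN with a warning. Degenerate classifier scores (constant
decision function) count as AUC 0.5. Peak order never affects results:
deterministic sorts precede every tie-sensitive step.
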