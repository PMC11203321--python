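# Methods

`dhselect` analyses flowering-time-type traits in a multi-parent doubled-
haploid (DH) maize panel: variance components and entry-mean heritability
from multi-environment trials, BLUP phenotypes, multi-locus GWAS with
pseudo-QTN conditioning, candidate-gene windowing, and RR-BLUP genomic
selection under several cross-validation designs.  Because no raw dataset
ships with the package, a first-class simulator generates panels with the
statistical structure the analysis assumes; every downstream claim is tested
against that simulator's planted truth or against closed-form oracles.

## Population and phenotype model

**Genotypes.**  A DH line is produced by recombining the two haplotypes of
one biparental cross and doubling the gamete, so every call is homozygous
(dosage ∈ {0, 2} on the diploid 0–2 scale; the 0–2 coding keeps GS code
reusable for non-DH material).  Recombination follows the Haldane
(no-interference) model: crossover counts per chromosome are Poisson with
mean equal to the map length in Morgans, crossover positions uniform on the
genetic map.  Two markers d Morgans apart therefore recombine with
probability r = (1 − e^(−2d))/2, which the tests verify against simulation.
The default genome is 10 chromosomes × 150 cM at 1 Mb/cM with markers evenly
spaced, and founder allele frequencies per marker drawn U(0.1, 0.9).  The
default panel layout is 21 crosses of 42 founders yielding 379 lines
(19 + 20 × 18), matching the reference trial's design.

**Phenotypes.**  The two-way multi-environment model

y_ijk = μ + g_i + e_j + (ge)_ij + ε_ijk

with environment main effects e_j fixed (drawn once; defaults emulate two
summer sites, a winter nursery and a late site: −0.6, −5.9, −4.1, +10.5
days), g_i = Σ_q a_q x_iq additive over QTLs, (ge)_ij ~ N(0, σ²ge),
ε_ijk ~ N(0, σ²e).  The QTL contribution is centred and rescaled so its
sample variance (n−1 denominator) equals the target σ²g *exactly* (tested to
1e−9); rescaling by a scalar preserves cross-trait genetic correlations.

**Trait architecture.**  One fully pleiotropic major QTL plus 49 minor QTLs
with geometric-decay effect magnitudes (ratio 0.95 — mildly polygenic, in
line with the many-small-effects view of maize flowering time).  The major
QTL's share of entry-mean phenotypic variance defaults to 0.15, converted to
a share of genetic variance through the implied H² and calibrated
empirically on the population's own QTL genotypes.  Default variance targets
per trait are (13.61, 9.22, 4.26), (19.84, 10.68, 4.29) and
(23.98, 14.12, 4.92) days² for DTT/DTP/DTS with E = 4 and R = 2.

**Correlated traits.**  Minor-QTL effect vectors are drawn with a cross-trait
correlation matrix (defaults 0.93/0.95/0.88 for DTT–DTP, DTP–DTS, DTT–DTS),
and — deliberately — the G×E and error draws use the *same* correlation
matrix.  With genetic correlation alone, entry-mean BLUP correlations
attenuate to roughly r_g·H² ≈ 0.81; since all three traits are scored on the
same plants, correlated residuals are the realistic reading and put
simulated BLUP correlations in the observed 0.88–0.96 range.

**What the simulator does not emulate.**  Real marker ascertainment and LD
decay (markers are evenly spaced and founder alleles independent across
loci), genotyping error, shared field-trial spatial trends, selection during
DH production, and epistasis/dominance (a DH panel cannot express
dominance).  Passing tests therefore demonstrate the *statistical contracts*
of the methods under the assumed model, not their numerical behaviour on any
particular real panel.  One visible consequence: the simulated panel has a
larger effective number of independent chromosome segments than a real
134,785-SNP DH panel, so prediction accuracy keeps improving past a 70%
training fraction instead of plateauing there (see Limitations).

## Variance components, heritability, BLUPs

For balanced data the estimator is the closed-form expected-mean-squares
solution σ̂²e = MSE, σ̂²ge = (MS_GE − MSE)/R, σ̂²g = (MS_G − MS_GE)/(R·E),
which coincides with REML when interior; unbalanced data are handled by
direct REML, a Nelder–Mead search over log variance ratios with the error
variance profiled out (function tolerance 1e−8).  Negative solutions are
truncated at zero with a logged flag.  Environment is treated as fixed;
line and line×environment as random — the structure under which the
entry-mean heritability

H² = σ²g / (σ²g + σ²ge/E + σ²e/(E·R))

is the repeatability of a line mean over E environments and R replicates.
R = 2 is the package default replicate count: it is the unique small integer
for which the bundled variance components reproduce all three published
heritability percentages (82.75/86.09/85.26) exactly, and it is configurable.

BLUPs solve the full Henderson mixed-model equations at the estimated
components; the reported value per line is μ̂ (intercept plus mean
environment effect) plus the line effect — a shrunken entry mean.  On
balanced data this reduces to ridge shrinkage of line means with
λ = (σ²ge/E + σ²e/(E·R))/σ²g, which the tests verify against an
independently assembled dense solve.

Descriptive statistics use sample moments: SD with n−1, skewness m3/m2^1.5,
excess kurtosis m4/m2² − 3 (normal = 0); CV% = 100·SD/mean.  "Combined"
rows are computed on per-line entry means across environments (the package's
labelled choice; raw pooling would mix environment offsets into the spread).

## Marker QC and structure covariates

The marker screen applies the missing-rate filter first (keep MR < 0.20,
strict), then the MAF filter on observed calls (keep MAF > 0.05, strict);
the order and both counts are recorded in the QC report so the reduction is
auditable.  Missing calls are mean-imputed per marker — for fully homozygous
panels at desk scale, model-based imputation buys little; the imputer is a
documented swap point.  Structure covariates are principal-component scores
of the column-centred dosage matrix (default 3), computed by SVD with each
component's sign fixed so its largest-magnitude loading is positive.

## Multi-locus GWAS

Both multi-locus scans iterate a shared inner engine: per-marker OLS of the
entry-mean BLUP on intercept + PCs + current pseudo-QTN dosages + the
marker, with two-sided t-tests (Frisch–Waugh–Lovell residualization,
verified against a normal-equations oracle to 1e−10).  A pseudo-QTN is a
marker promoted to fixed covariate to absorb major-locus signal.

* **Positional-bin variant** ("FarmCPU-like"): candidates are the most
  significant marker per 10 Mb bin among markers with p below a relaxed
  threshold (100 × α/m); the pseudo-QTN set is rebuilt each round by greedy
  forward selection minimizing an information criterion; iteration stops
  when the set stabilizes (max 10 rounds, convergence flagged).
* **LD-pruned variant** ("BLINK-like"): candidates are all sub-threshold
  markers ordered by p, pruned so no kept pair has dosage r² > 0.7; the
  pseudo-QTN set is the criterion-minimizing prefix of the pruned list.

Markers currently in the pseudo-QTN set are exactly collinear with the
covariates, so they are excluded from the conditioned scan; the candidate
pool each round is the scan candidates ∪ the current set, which lets the
criterion drop a pseudo-QTN without losing it by construction.  Final
p-values come from the last conditioned scan; pseudo-QTNs receive their
coefficient p-values from the final joint model.  Significance is always
p < α/m (Bonferroni).

**Selection criterion.**  Subset selection uses the extended BIC
(per-marker penalty log n + 2 log m) rather than plain BIC.  Candidates are
minima over m ≫ n marker p-values; under the plain log n penalty, null
markers passing the relaxed screen are routinely admitted, and their
joint-model p-values then violate family-wise error control.  With the
extended penalty the empirical FWER at Bonferroni is at the nominal level
(tested over 20 null datasets) with no loss of power on a planted 15%-PVE
QTL (20/20 detections for both variants).

These are defined simplified algorithms with their own model tags; numerical
identity with any external FarmCPU/BLINK implementation is not claimed —
the tested contract is behavioural: null-p uniformity of the inner scan,
FWER control, planted-QTL power, and distinct pseudo-QTNs for QTLs in
distinct bins.

**Per-SNP PVE** is the partial R² of the marker — 1 − RSS_full/RSS_reduced
with the reduced model dropping the focal marker but keeping PCs and the
other significant markers of the same model/trait (configurable to marginal
R²).  Overlap summaries identify SNPs by (chromosome, position) and total
PVE within model × trait.

## Candidate-gene windows

A gene is a candidate when its body [start, end] (1-based inclusive)
intersects the closed window [pos − 10 kb, pos + 10 kb]; an edge at exactly
10,000 bp is in, 10,001 bp is out.  Inclusion ignores strand;
upstream/downstream labels are genomic-coordinate relative to the SNP.  The
bundled reference annotation is synthetic: real gene identifiers and
annotations attached to invented coordinates placed inside their SNP's
window, plus decoys outside (the nearest at exactly 10,001 bp), so the
boundary behaviour is testable offline.

## RR-BLUP genomic selection

y = 1μ + Zu + ε with u ~ N(0, Iσ²u), Z column-centred dosages.  The
shrinkage ratio λ = σ²e/σ²u is estimated by REML profiled over λ via the
eigendecomposition of K = ZZᵀ (each λ evaluation is O(n²)), maximized by
bounded 1-D search in ln λ on [−10, 10] (tolerance 1e−6; boundary hits
flagged).  Marker effects û = Zᵀ(K + λI)⁻¹(y − 1μ̂) make training GEBVs
identical to the GBLUP kernel solution, verified to 1e−8.

Prediction accuracy is the Pearson correlation between predicted GEBVs and
the observed BLUPs of held-out lines (true breeding values are unobservable
on real data; on synthetic data the truth-file correlation is additionally
available), averaged over all folds × repetitions.  λ is re-estimated inside
every training partition — test phenotypes never inform shrinkage.

Experiments: plain 5-fold CV; a training-fraction sweep (0.1–0.9, one random
split per repetition); a marker-density sweep (10–5,000 markers drawn
uniformly per repetition, 5-fold CV on the subset); and a top-k sweep
restricted to the k lowest-p GWAS markers (k ∈ {1, …, 500}, ties broken by
genomic order).  The top-k ranking is deliberately computed once on the full
population — the literal published procedure, which leaks information and
is optimistically biased; re-ranking inside each training fold is available
by passing a fold-local scan result.

## Problem sizes used in the shipped tests

The test suite runs entirely on simulated data: a 379-line × 5,000-marker
reference panel, a 300-line × 2,000-marker panel for recovery and
error-control runs, and small toys for closed-form oracles.  Stochastic
claims use 20 seeds or 20 CV repetitions; the full suite completes in about
a minute on one core.

## Known limitations

* The training-fraction accuracy curve on the reference synthetic panel is
  still rising at 90% training (0.47 at 70% vs 0.58 at 90%), rather than
  plateauing at 70% as observed on the real panel; the simulated genome's
  effective segment number is larger relative to N·h² than in real
  multi-parent DH data with dense markers.  The corresponding plateau test
  is kept and fails honestly.
* The iterative REML path is dense (O(n³) per likelihood evaluation) and
  intended for desk-scale unbalanced data, not for trials with tens of
  thousands of plots.
* Only the two stated marker filters (MR, MAF) are implemented; real
  pipelines typically also drop heterozygous-excess and multi-allelic sites
  (the VCF reader drops non-SNP and multi-allelic records and counts
  heterozygous calls, but applies no heterozygosity filter).
* No kinship random effect in the GWAS scans, no Bayesian-alphabet GS
  models, no LD-interval gene search.
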