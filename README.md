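# dhselect

GWAS and genomic selection for multi-parent doubled-haploid (DH) panels —
a tested pipeline for the analysis workflow used in maize flowering-time
genetics: multi-environment variance components and heritability, BLUP
phenotypes, dual multi-locus association scans, candidate-gene windows, and
RR-BLUP genomic prediction under training-size / marker-density / top-SNP
cross-validation designs.  A first-class simulator generates DH panels with
the statistical structure the analysis assumes, so the whole pipeline is
testable and reproducible without any external download.

Intended users: quantitative geneticists and breeding-program analysts who
work with fully homozygous line panels (DH or inbred) scored in
multi-location trials.

## The models at the core

**Entry-mean heritability.**  For the two-way trial model
y_ijk = μ + g_i + e_j + (ge)_ij + ε_ijk with line and line×environment
random and environment fixed, variance components (σ²g, σ²ge, σ²e) are
estimated by REML (closed-form expected-mean-squares solution on balanced
data) and the broad-sense heritability on an entry-mean basis is

    H² = σ²g / (σ²g + σ²ge/E + σ²e/(E·R))

for E environments and R replicates.  Line BLUPs (shrunken entry means from
the Henderson equations) are the response for GWAS and GS.

**Multi-locus GWAS.**  Two scan variants iterate pseudo-QTN conditioning —
markers promoted to fixed covariates so large loci cannot mask the rest of
the genome — around a shared per-marker OLS engine with PC structure
covariates: a positional-bin variant (best sub-threshold marker per 10 Mb
bin, greedy extended-BIC selection) and an LD-pruned variant (p-ordered
candidates pruned at r² > 0.7, extended-BIC-minimizing prefix).
Significance is Bonferroni (p < α/m); per-SNP variance explained is partial
R² given the PCs and co-significant markers.

**RR-BLUP.**  y = 1μ + Zu + ε with u ~ N(0, Iσ²u); the shrinkage ratio
λ = σ²e/σ²u is REML-estimated by profiling over the eigendecomposition of
ZZᵀ, and marker effects û = Zᵀ(ZZᵀ + λI)⁻¹(y − 1μ̂) make training GEBVs
identical to the GBLUP kernel solution.  Prediction accuracy is the Pearson
correlation between GEBVs and observed BLUPs of held-out lines.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a 379-line panel (21 crosses, 5,000 SNPs on 10 chromosomes), fit
variance components, scan one trait, and cross-validate genomic prediction:

```python
import dhselect as d
from dhselect import phenostats as ps, gspredict as gs

founders = d.simulate_founders(n_founders=42, n_markers=5000,
                               n_chromosomes=10, seed=11)
pop = d.simulate_dh_population(founders, n_crosses=21,
                               lines_per_cross=[19] + [18] * 20, seed=12)
arch = d.flowering_architecture(pop, n_qtl=50, seed=13)
book = d.simulate_phenotypes(pop, arch, seed=14)

for trait in book.traits:
    vc = ps.fit_variance_components(book, trait)
    print(f"{trait}: s2g={vc.sigma2_g:.2f} s2ge={vc.sigma2_ge:.2f} "
          f"s2e={vc.sigma2_e:.2f} H2={100 * vc.H2:.2f}%")

vcs = {t: ps.fit_variance_components(book, t) for t in book.traits}
blups = ps.compute_blups(book, vcs)
pcs = d.pca_covariates(pop.genotypes, 3)
res = d.farmcpu_like_scan(pop.genotypes, blups["DTT"], pcs=pcs, trait="DTT")
res = d.snp_pve(pop.genotypes, blups["DTT"], res, pcs)
print(res.significant_table()[["marker", "p_value", "pve"]].head())

cv = gs.cross_validate(pop.genotypes, blups, gs.CvDesign(k=5, repetitions=20, seed=44))
print(cv.table[["trait", "mean_accuracy", "sd_accuracy"]].round(3))
```

Output:

```
DTT: s2g=13.86 s2ge=9.62 s2e=4.13 H2=82.60%
DTP: s2g=20.07 s2ge=10.57 s2e=4.10 H2=86.42%
DTS: s2g=24.57 s2ge=13.59 s2e=4.74 H2=86.03%
     marker  p_value    pve
1_115800000 8.81e-06 0.0325
 2_25500000 1.52e-06 0.0494
 3_89100000 1.90e-15 0.1908
3_119100000 3.65e-06 0.0133
4_120600000 7.48e-08 0.1197
trait  mean_accuracy  sd_accuracy
  DTT          0.525        0.072
  DTP          0.537        0.069
  DTS          0.511        0.075
```

The simulator hits its variance-component targets (genotypic 13.61/19.84/
23.98 days², heritabilities 82.75/86.09/85.26%) to within sampling error;
the scan recovers planted QTLs at the Bonferroni threshold (α/5,000 = 1e−5
here, i.e. −log10 p > 5.0), with the major pleiotropic locus at the top;
and 5-fold all-marker prediction accuracy lands near 0.52 for a trait with
H² ≈ 0.83 — genomic prediction recovers about 60% of the attainable
correlation for this architecture.

## Command line

```bash
dhselect make-fixture --scale small --seed 1 --out demo/
dhselect run-all --config demo/config.yaml
```

`run-all` executes simulate/ingest → phenostats → genoqc → mlgwas → genewin
→ gspredict through documented TSV contracts and writes `manifest.json`
with per-stage outputs, SHA-256 checksums and timings; a rerun with the
same config and seed is bit-identical.  Subcommands `pheno`, `qc` and `gs`
run single stages.

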