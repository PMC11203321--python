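"""Bundled reference tables for a maize multi-parent DH flowering-time panel.

These are published summary statistics for a 379-line doubled-haploid
association panel scored for days to tasseling (DTT), days to pollen-shedding
(DTP) and days to silking (DTS) in four environments, genotyped at 134,785
filtered SNPs.  They serve as fixed inputs for consistency checks and demos:
variance components with entry-mean heritability, the significant-SNP table
from two multi-locus GWAS models, and the candidate genes annotated around
those SNPs.

The GFF3 produced by :func:`synthetic_reference_annotation` is SYNTHETIC: it
places each reported candidate gene at a plausible offset inside the 10 kb
window of its SNP (gene-body coordinates are invented), plus decoy genes
outside the windows, so the windowing logic can be exercised offline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genewin import GeneModel

#: Environments (E) and replicates per environment (R) of the reference trial.
REFERENCE_E = 4
REFERENCE_R = 2

#: Total filtered SNP count of the reference panel (Bonferroni denominator).
REFERENCE_N_MARKERS = 134_785

#: Lines in the reference panel.
REFERENCE_N_LINES = 379


def reference_variance_components() -> pd.DataFrame:
    """Genotypic, G×E and error variances (days²) per flowering trait."""
    return pd.DataFrame(
        [
            ("DTT", 13.61, 9.22, 4.26),
            ("DTP", 19.84, 10.68, 4.29),
            ("DTS", 23.98, 14.12, 4.92),
        ],
        columns=["trait", "sigma2_g", "sigma2_ge", "sigma2_e"],
    )


def reference_significant_snps() -> pd.DataFrame:
    """Significant SNPs from the two multi-locus GWAS models.

    Columns: model, trait, snp, chrom, pos, p_value, pve (fraction).
    """
    rows = [
        # model, trait, snp, chrom, pos, p, pve%
        ("blink_like", "DTT", "1_190275500", "1", 190275500, 5.52e-11, 1.41),
        ("blink_like", "DTT", "9_152140631", "9", 152140631, 2.48e-9, 16.92),
        ("blink_like", "DTT", "10_146767704", "10", 146767704, 2.34e-8, 1.97),
        ("blink_like", "DTP", "3_198946071", "3", 198946071, 3.23e-8, 2.64),
        ("blink_like", "DTP", "3_229665314", "3", 229665314, 2.68e-7, 3.90),
        ("blink_like", "DTP", "8_114509981", "8", 114509981, 2.26e-7, 3.70),
        ("blink_like", "DTP", "9_152140631", "9", 152140631, 3.98e-11, 12.68),
        ("blink_like", "DTS", "8_78666793", "8", 78666793, 2.42e-12, 3.39),
        ("blink_like", "DTS", "9_152140631", "9", 152140631, 3.52e-7, 24.17),
        ("farmcpu_like", "DTT", "3_198946071", "3", 198946071, 2.52e-8, 4.34),
        ("farmcpu_like", "DTT", "9_152140631", "9", 152140631, 7.35e-15, 15.53),
        ("farmcpu_like", "DTT", "10_149653921", "10", 149653921, 1.27e-7, 3.55),
        ("farmcpu_like", "DTP", "3_10537234", "3", 10537234, 2.67e-8, 1.02),
        ("farmcpu_like", "DTP", "8_77014638", "8", 77014638, 2.05e-7, 0.50),
        ("farmcpu_like", "DTP", "9_18946215", "9", 18946215, 1.42e-7, 3.74),
        ("farmcpu_like", "DTP", "9_146646966", "9", 146646966, 3.90e-9, 1.18),
        ("farmcpu_like", "DTP", "9_152140631", "9", 152140631, 8.05e-13, 5.82),
        ("farmcpu_like", "DTP", "10_145158286", "10", 145158286, 7.89e-14, 3.73),
        ("farmcpu_like", "DTS", "3_199485386", "3", 199485386, 1.35e-7, 7.16),
        ("farmcpu_like", "DTS", "8_78666793", "8", 78666793, 8.63e-9, 2.30),
        ("farmcpu_like", "DTS", "9_146646966", "9", 146646966, 3.68e-7, 3.30),
        ("farmcpu_like", "DTS", "9_152140631", "9", 152140631, 3.40e-9, 8.53),
    ]
    df = pd.DataFrame(
        rows, columns=["model", "trait", "snp", "chrom", "pos", "p_value", "pve"]
    )
    df["pve"] = df["pve"] / 100.0
    return df


def reference_candidate_genes() -> pd.DataFrame:
    """Candidate genes reported within 10 kb of the significant SNPs."""
    rows = [
        ("1_190275500", "DTT", "Zm00001d031445", "Ethylene-insensitive3-like protein"),
        ("1_190275500", "DTT", "Zm00001d031444", "IRK-interacting protein"),
        ("1_190275500", "DTT", "Zm00001d031443", "DUF2361 family protein"),
        ("1_190275500", "DTT", "Zm00001d031447", "ABC transporter C family member 10"),
        ("3_10537234", "DTP", "Zm00001d039650", "Cytochrome P450 734A1"),
        ("3_198946071", "DTT,DTP", "Zm00001d043406", "Interactor of constitutive active ROPs 1"),
        ("3_199485386", "DTS", "Zm00001d043427", "Uncharacterized LOC109945323"),
        ("3_199485386", "DTS", "Zm00001d043426", "Pentatricopeptide repeat-containing protein At3g58590"),
        ("3_229665314", "DTP", "Zm00001d044495", "Vacuolar-processing enzyme"),
        ("3_229665314", "DTP", "Zm00001d044496", "Pentatricopeptide repeat-containing protein chloroplastic"),
        ("8_77014638", "DTP", "Zm00001d009708", "Calcium-dependent protein kinase 1"),
        ("8_77014638", "DTP", "Zm00001d009707", "Protein ABIL1"),
        ("8_78666793", "DTS", "Zm00001d009738", "Tubulin gamma-2 chain"),
        ("8_114509981", "DTP", "Zm00001d010425", "Coiled-coil domain-containing protein 25"),
        ("9_146646966", "DTP,DTS", "Zm00001d047969", "CONSTANS interacting protein 6"),
        ("9_146646966", "DTP,DTS", "Zm00001d047968", "Zinc finger protein 7"),
        ("9_152140631", "DTT,DTP,DTS", "Zm00001d048190", "RNase L inhibitor protein-related"),
        ("9_152140631", "DTT,DTP,DTS", "Zm00001d048191", "Membrane protein"),
        ("9_18946215", "DTP", "Zm00001d045323", "Double B-box zinc finger protein 11"),
        ("9_18946215", "DTP", "Zm00001d045324", "Dual specificity protein phosphatase DSP8"),
        ("10_145158286", "DTP", "Zm00001d026397", "RNA-binding protein AKIP1"),
        ("10_145158286", "DTP", "Zm00001d026396", "Formation of crista junctions protein 1"),
        ("10_146767704", "DTT", "Zm00001d026482", "Uncharacterized LOC111590308"),
        ("10_149653921", "DTT", "Zm00001d026668", "Receptor-like kinase TMK2"),
    ]
    return pd.DataFrame(rows, columns=["snp", "traits", "gene_id", "annotation"])


def reference_snp_positions() -> pd.DataFrame:
    """The 14 distinct significant SNPs as (snp, chrom, pos)."""
    sig = reference_significant_snps()
    return (
        sig[["snp", "chrom", "pos"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s)
        .reset_index(drop=True)
    )


def _chrom_key(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return 10**6


def synthetic_reference_annotation(n_decoys: int = 6, gene_length: int = 3000,
                                   seed: int = 0) -> list[GeneModel]:
    """SYNTHETIC gene models around the 14 reference SNPs.

    Each reported candidate gene is placed so its nearest edge lies within
    10 kb of its SNP; the first gene of each SNP is placed with its body
    spanning the SNP (distance 0), subsequent ones at increasing upstream/
    downstream offsets, and one gene is pinned at exactly 10,000 bp to probe
    the closed-interval boundary.  ``n_decoys`` extra genes are placed beyond
    the windows (the nearest at exactly 10,001 bp).  Coordinates are invented;
    only SNP↔gene assignments and annotations reflect the reference tables.
    """
    snps = reference_snp_positions().set_index("snp")
    cand = reference_candidate_genes()
    genes: list[GeneModel] = []
    boundary_done = False
    for snp, group in cand.groupby("snp", sort=False):
        chrom = str(snps.loc[snp, "chrom"])
        pos = int(snps.loc[snp, "pos"])
        for rank, (_, row) in enumerate(group.iterrows()):
            if rank == 0:  # gene body spans the SNP
                start = pos - gene_length // 2
            elif not boundary_done:
                # nearest edge exactly at the 10 kb boundary (inclusive)
                start = pos + 10_000
                boundary_done = True
            else:
                side = 1 if rank % 2 else -1
                off = 2_000 + 1_500 * rank
                start = pos + side * off if side > 0 else pos - side * 0 - off - gene_length
            genes.append(GeneModel(
                gene_id=row["gene_id"], chrom=chrom, start=max(1, start),
                end=max(1, start) + gene_length - 1,
                strand="+" if rank % 2 == 0 else "-",
                description=row["annotation"],
            ))
    rng = np.random.default_rng(seed)
    snp_list = snps.reset_index()
    for i in range(n_decoys):
        s = snp_list.iloc[i % len(snp_list)]
        off = 10_001 + gene_length if i else 10_001
        start = int(s["pos"]) + off if i % 2 == 0 else int(s["pos"]) - off - gene_length + 1
        genes.append(GeneModel(
            gene_id=f"DECOY_{i + 1:02d}", chrom=str(s["chrom"]),
            start=max(1, start), end=max(1, start) + gene_length - 1,
            strand="+", description="synthetic decoy outside the 10 kb window",
        ))
    return genes
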