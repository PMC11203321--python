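"""Genotype containers, I/O, marker QC and population-structure covariates.

The central container is :class:`GenotypeMatrix`: a lines × markers matrix of
minor/major-allele dosages on the diploid 0–2 scale with an explicit missing
mask (NaN).  Doubled-haploid (DH) panels are fully homozygous, so dosages are
{0, 2, missing}; heterozygous calls read from a file are retained but counted
and reported, since their presence in a declared-DH dataset indicates
genotyping error.

Marker filtering follows the usual two-step screen: per-marker missing rate
(MR) strictly below a ceiling, then minor allele frequency (MAF) strictly
above a floor, with MAF computed on observed calls only.  Both filters use
strict inequalities (keep MR < missing_max, keep MAF > maf_min).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgument

logger = logging.getLogger(__name__)

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclass
class GenotypeMatrix:
    """Lines × markers dosage matrix with a marker map.

    Parameters
    ----------
    line_ids
        Names of the lines (rows).
    marker_ids
        Names of the markers (columns).
    chrom
        Chromosome identifier per marker.
    pos
        1-based physical position (bp) per marker.
    dosage
        ``(n_lines, n_markers)`` float array; counts of the ALT allele on a
        0–2 scale, NaN for missing calls.
    ref, alt
        Allele labels per marker (defaults A/G, used for VCF/HapMap export).
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    ref: np.ndarray = field(default=None)
    alt: np.ndarray = field(default=None)

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise InvalidArgument(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines × {len(self.marker_ids)} markers"
            )
        if len(self.chrom) != len(self.marker_ids) or len(self.pos) != len(self.marker_ids):
            raise InvalidArgument("marker map length does not match marker count")
        if self.ref is None:
            self.ref = np.full(self.n_markers, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_markers, "G", dtype=object)

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-marker ALT-allele frequency on observed calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency on observed calls."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def het_count(self) -> int:
        """Number of heterozygous calls (dosage exactly 1)."""
        return int(np.sum(self.dosage == 1.0))

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given line/marker index arrays."""
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            line_ids=self.line_ids[li],
            marker_ids=self.marker_ids[mi],
            chrom=self.chrom[mi],
            pos=self.pos[mi],
            dosage=self.dosage[np.ix_(li, mi)].copy(),
            ref=self.ref[mi],
            alt=self.alt[mi],
        )

    def marker_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass
class QcReport:
    """Audit trail of the sequential MR → MAF marker filter."""

    markers_in: int
    markers_out: int
    removed_by_missing: int
    removed_by_maf: int
    maf_min: float
    missing_max: float

    def __post_init__(self):
        assert self.markers_out == (
            self.markers_in - self.removed_by_missing - self.removed_by_maf
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write biallelic SNP genotypes as uncompressed VCF v4.2.

    Dosages must be integral (0, 1, 2) or missing; fractional (imputed)
    dosages cannot be represented as GT calls.
    """
    d = geno.dosage
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise InvalidArgument("VCF export requires integer dosages in {0,1,2} or missing")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dhselect\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(geno.chrom):
            length = int(geno.pos[geno.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.line_ids))
            + "\n"
        )
        for j in range(geno.n_markers):
            calls = [
                "./." if np.isnan(x) else gt_map[x] for x in d[:, j]
            ]
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.marker_ids[j]}\t"
                f"{geno.ref[j]}\t{geno.alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multi-allelic and non-SNP records are
    dropped with a logged tally.  Heterozygous calls are counted and logged
    (a DH panel should have none)."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    ids, chroms, poss, refs, alts = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP/multi-allelic records", n_skipped)
    dosage = (
        np.asarray(rows, dtype=float).T
        if rows
        else np.empty((len(samples), 0))
    )
    geno = GenotypeMatrix(
        line_ids=np.asarray(samples, dtype=object),
        marker_ids=np.asarray(ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        dosage=dosage,
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )
    nhet = geno.het_count()
    if nhet:
        logger.warning("read_vcf: %d heterozygous calls in declared-DH data", nhet)
    return geno


def write_hapmap(geno: GenotypeMatrix, path) -> None:
    """Write genotypes in HapMap text format (two-letter genotype codes)."""
    d = geno.dosage
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise InvalidArgument("HapMap export requires integer dosages in {0,1,2} or missing")
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + [str(s) for s in geno.line_ids]) + "\n")
        for j in range(geno.n_markers):
            r, a = geno.ref[j], geno.alt[j]
            codes = {0.0: r + r, 1.0: r + a, 2.0: a + a}
            calls = ["NN" if np.isnan(x) else codes[x] for x in d[:, j]]
            meta = [
                str(geno.marker_ids[j]), f"{r}/{a}", str(geno.chrom[j]),
                str(geno.pos[j]), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(meta + calls) + "\n")


def read_hapmap(path) -> GenotypeMatrix:
    """Read a HapMap-format genotype table."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse HapMap table {path}: {exc}") from exc
    if list(df.columns[:4]) != _HAPMAP_META[:4]:
        raise FormatError(
            f"{path}: header line 1 does not start with {_HAPMAP_META[:4]}"
        )
    samples = list(df.columns[len(_HAPMAP_META):])
    n_m = len(df)
    dosage = np.full((len(samples), n_m), np.nan)
    refs, alts = [], []
    for j, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2:
            raise FormatError(f"{path}: line {j + 2}: bad alleles field {row['alleles']!r}")
        r, a = alleles
        refs.append(r)
        alts.append(a)
        for i, s in enumerate(samples):
            call = row[s]
            if call in ("NN", "N", "--", ""):
                continue
            dosage[i, j] = sum(1 for ch in call if ch == a)
    return GenotypeMatrix(
        line_ids=np.asarray(samples, dtype=object),
        marker_ids=df["rs#"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].astype(np.int64).to_numpy(),
        dosage=dosage,
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or HapMap, auto-detecting by extension."""
    p = str(path)
    if fmt is None:
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "hapmap"
    if fmt == "vcf":
        return read_vcf(p)
    if fmt == "hapmap":
        return read_hapmap(p)
    raise InvalidArgument(f"unknown genotype format {fmt!r}")


# ----------------------------------------------------------------------
# QC operations
# ----------------------------------------------------------------------

def filter_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sequential marker screen: missing rate, then minor allele frequency.

    Keeps markers with MR < ``missing_max`` (strict) and, among those, markers
    with MAF > ``maf_min`` (strict, MAF on observed calls).  Returns the
    filtered matrix together with an auditable :class:`QcReport`.
    """
    if not (0 <= maf_min <= 1 and 0 <= missing_max <= 1):
        raise InvalidArgument("thresholds must lie in [0, 1]")
    mr = geno.missing_rate()
    pass_mr = mr < missing_max
    maf = geno.maf()
    pass_maf = maf > maf_min
    keep = pass_mr & pass_maf
    removed_mr = int(np.sum(~pass_mr))
    removed_maf = int(np.sum(pass_mr & ~pass_maf))
    out = geno.subset(markers=np.flatnonzero(keep))
    report = QcReport(
        markers_in=geno.n_markers,
        markers_out=out.n_markers,
        removed_by_missing=removed_mr,
        removed_by_maf=removed_maf,
        maf_min=maf_min,
        missing_max=missing_max,
    )
    return out, report


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker's mean observed dosage."""
    d = geno.dosage.copy()
    miss = np.isnan(d)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = geno.marker_ids[all_missing]
        raise InvalidArgument(f"markers with no observed calls: {list(bad[:5])}")
    if miss.any():
        col_means = np.nanmean(geno.dosage, axis=0)
        d[miss] = np.take(col_means, np.nonzero(miss)[1])
    return GenotypeMatrix(
        line_ids=geno.line_ids,
        marker_ids=geno.marker_ids,
        chrom=geno.chrom,
        pos=geno.pos,
        dosage=d,
        ref=geno.ref,
        alt=geno.alt,
    )


def pca_covariates(geno: GenotypeMatrix, n_components: int = 3) -> np.ndarray:
    """Principal-component scores of the column-centred dosage matrix.

    Used as fixed population-structure covariates in association scans.
    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-magnitude marker loading is positive.
    """
    if np.isnan(geno.dosage).any():
        raise InvalidArgument("pca_covariates requires a complete (imputed) matrix")
    if n_components >= min(geno.n_lines, geno.n_markers):
        raise InvalidArgument("n_components must be < min(lines, markers)")
    X = geno.dosage - geno.dosage.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"rank-deficient genotype matrix: returning {k} components", stacklevel=2
        )
    scores = u[:, :k] * s[:k]
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            scores[:, c] *= -1
    return scores
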