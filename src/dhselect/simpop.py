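"""Simulation of multi-parent doubled-haploid (DH) panels and their phenotypes.

The generator emulates the structure of a maize association panel built from
biparental hybrids: each hybrid contributes two founder haplotypes, and every
DH line is a recombinant mosaic of exactly one hybrid's two haplotypes,
chromosome-doubled (so every call is homozygous, dosage ∈ {0, 2}).

Recombination follows the Haldane (no-interference) model: the number of
crossovers per chromosome is Poisson with mean equal to the map length in
Morgans, and crossover positions are uniform on the genetic map.  Two markers
d Morgans apart therefore recombine with probability r = (1 − e^(−2d))/2.

Phenotypes follow the two-way model of a multi-environment trial,

    y_ijk = μ + g_i + e_j + (ge)_ij + ε_ijk,

with additive genetic values g_i = Σ_q a_q x_iq rescaled so their realized
sample variance equals the target genotypic variance σ²g exactly, environment
main effects as fixed offsets, (ge)_ij ~ N(0, σ²ge) and ε_ijk ~ N(0, σ²e).
Across traits, QTL effects and both residual terms can be drawn with a common
correlation matrix, emulating correlated flowering traits scored on the same
plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgument
from .genoqc import GenotypeMatrix


# ----------------------------------------------------------------------
# Types
# ----------------------------------------------------------------------

@dataclass
class FounderSet:
    """Founder haplotypes with a physical + genetic marker map."""

    haplotypes: np.ndarray  # (n_founders, n_markers), binary
    chrom: np.ndarray       # chromosome id per marker
    pos_bp: np.ndarray      # physical position, 1-based bp
    pos_cm: np.ndarray      # genetic position, cM

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise InvalidArgument("founder haplotypes must be binary")
        for c in pd.unique(self.chrom):
            m = self.chrom == c
            if np.any(np.diff(self.pos_bp[m]) <= 0):
                raise InvalidArgument(f"bp positions not strictly increasing on {c}")
            if np.any(np.diff(self.pos_cm[m]) < 0):
                raise InvalidArgument(f"cM positions decreasing on {c}")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def marker_ids(self) -> np.ndarray:
        return np.asarray(
            [f"{c}_{p}" for c, p in zip(self.chrom, self.pos_bp)], dtype=object
        )


@dataclass
class DhPopulation:
    """A simulated DH panel: homozygous genotypes plus pedigree."""

    genotypes: GenotypeMatrix
    pedigree: pd.Series  # line id -> cross id

    def __post_init__(self):
        d = self.genotypes.dosage
        if not np.isin(d[~np.isnan(d)], (0.0, 2.0)).all():
            raise InvalidArgument("DH genotypes must be homozygous (dosage 0 or 2)")


@dataclass
class TraitArchitecture:
    """Additive QTL architecture shared by a set of correlated traits.

    ``qtl_effects[t, q]`` is the additive effect of QTL q on trait t (days per
    dosage unit, before the exact variance rescaling applied at phenotype
    time).  ``target_variances[t]`` is ``(σ²g, σ²ge, σ²e)`` for trait t.
    ``residual_corr`` is the cross-trait correlation of the G×E and error
    draws (identity = uncorrelated residuals).
    """

    qtl_indices: np.ndarray          # (Q,) marker indices
    qtl_effects: np.ndarray          # (T, Q)
    trait_names: list[str]
    target_variances: np.ndarray     # (T, 3): σ²g, σ²ge, σ²e
    E: int = 4
    R: int = 2
    trait_means: np.ndarray | None = None    # (T,)
    env_offsets: np.ndarray | None = None    # (E,), fixed environment effects
    residual_corr: np.ndarray | None = None  # (T, T)

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.qtl_effects = np.atleast_2d(np.asarray(self.qtl_effects, dtype=float))
        self.target_variances = np.atleast_2d(
            np.asarray(self.target_variances, dtype=float)
        )
        if self.E < 1 or self.R < 1:
            raise InvalidArgument("E and R must be >= 1")
        if (self.target_variances < 0).any():
            raise InvalidArgument("target variances must be non-negative")
        if self.qtl_effects.shape != (len(self.trait_names), len(self.qtl_indices)):
            raise InvalidArgument("qtl_effects must be (n_traits, n_qtl)")
        if self.trait_means is None:
            self.trait_means = np.zeros(len(self.trait_names))
        if self.residual_corr is None:
            self.residual_corr = np.eye(len(self.trait_names))

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def pleiotropy_map(self) -> np.ndarray:
        """Boolean (Q,): QTLs with a nonzero effect on more than one trait."""
        return (self.qtl_effects != 0).sum(axis=0) > 1


@dataclass
class PhenotypeBook:
    """Long-format phenotype records plus simulation truth when available."""

    records: pd.DataFrame  # columns: line, environment, replicate, trait, value
    traits: list[str]
    true_values: pd.DataFrame | None = None  # line × trait genetic values (μ + g)

    def __post_init__(self):
        need = {"line", "environment", "replicate", "trait", "value"}
        if not need.issubset(self.records.columns):
            raise InvalidArgument(f"records must have columns {sorted(need)}")
        if not np.isfinite(self.records["value"].to_numpy(dtype=float)).all():
            raise InvalidArgument("phenotype values must be finite")

    @property
    def environments(self) -> list:
        return sorted(self.records["environment"].unique().tolist())


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def simulate_founders(
    n_founders: int,
    n_markers: int,
    n_chromosomes: int = 10,
    chrom_length_cm: float = 150.0,
    bp_per_cm: int = 1_000_000,
    freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> FounderSet:
    """Draw founder haplotypes with per-marker allele frequencies ~ U(freq_range).

    Markers are spread evenly across ``n_chromosomes`` chromosomes of
    ``chrom_length_cm`` centimorgans each, with physical positions on a
    uniform 1 cM ≈ ``bp_per_cm`` scale.
    """
    if n_founders < 2:
        raise InvalidArgument("need at least 2 founders")
    if n_markers < n_chromosomes or n_chromosomes < 1 or chrom_length_cm <= 0:
        raise InvalidArgument("non-positive or inconsistent dimensions")
    rng = np.random.default_rng(seed)
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    chrom, pos_bp, pos_cm = [], [], []
    for c in range(n_chromosomes):
        k = per[c]
        cm = chrom_length_cm * (np.arange(k) + 1) / k
        chrom.extend([str(c + 1)] * k)
        pos_cm.extend(cm)
        pos_bp.extend(np.round(cm * bp_per_cm).astype(np.int64))
    freqs = rng.uniform(*freq_range, size=n_markers)
    haplos = (rng.random((n_founders, n_markers)) < freqs).astype(np.int8)
    return FounderSet(
        haplotypes=haplos,
        chrom=np.asarray(chrom, dtype=object),
        pos_bp=np.asarray(pos_bp),
        pos_cm=np.asarray(pos_cm),
    )


def _make_gamete(hapA, hapB, chrom_slices, pos_cm, rng) -> np.ndarray:
    """One recombinant gamete under the Haldane model."""
    out = np.empty_like(hapA)
    for sl in chrom_slices:
        cm = pos_cm[sl]
        lo, hi = cm[0], cm[-1]
        length_m = (hi - lo) / 100.0
        n_xo = rng.poisson(length_m)
        start = rng.integers(2)
        if n_xo == 0:
            phase = np.full(cm.size, start)
        else:
            xo = np.sort(rng.uniform(lo, hi, size=n_xo))
            phase = (start + np.searchsorted(xo, cm, side="right")) % 2
        out[sl] = np.where(phase == 0, hapA[sl], hapB[sl])
    return out


def simulate_dh_population(
    founders: FounderSet,
    n_crosses: int,
    lines_per_cross,
    seed: int = 0,
) -> DhPopulation:
    """Simulate DH lines from biparental crosses of consecutive founder pairs.

    Cross *c* pairs founders ``2c`` and ``2c+1``.  ``lines_per_cross`` may be
    an int (same count for every cross) or a sequence of per-cross counts.
    Each line is one Haldane-recombined gamete of its cross, doubled.
    """
    if n_crosses < 1:
        raise InvalidArgument("n_crosses must be >= 1")
    if 2 * n_crosses > founders.n_founders:
        raise InvalidArgument(
            f"{n_crosses} crosses need {2 * n_crosses} founders, "
            f"have {founders.n_founders}"
        )
    counts = (
        np.full(n_crosses, lines_per_cross, dtype=int)
        if np.isscalar(lines_per_cross)
        else np.asarray(lines_per_cross, dtype=int)
    )
    if len(counts) != n_crosses or (counts < 1).any():
        raise InvalidArgument("lines_per_cross must give >= 1 line per cross")
    rng = np.random.default_rng(seed)
    chrom_slices = []
    start = 0
    for c in pd.unique(founders.chrom):
        k = int(np.sum(founders.chrom == c))
        chrom_slices.append(slice(start, start + k))
        start += k
    line_ids, cross_ids, rows = [], [], []
    for c in range(n_crosses):
        hapA = founders.haplotypes[2 * c]
        hapB = founders.haplotypes[2 * c + 1]
        for i in range(counts[c]):
            gam = _make_gamete(hapA, hapB, chrom_slices, founders.pos_cm, rng)
            rows.append(2.0 * gam)
            line_ids.append(f"DH{c + 1:02d}_{i + 1:03d}")
            cross_ids.append(f"cross{c + 1:02d}")
    geno = GenotypeMatrix(
        line_ids=np.asarray(line_ids, dtype=object),
        marker_ids=founders.marker_ids(),
        chrom=founders.chrom,
        pos=founders.pos_bp,
        dosage=np.asarray(rows, dtype=float),
    )
    return DhPopulation(
        genotypes=geno, pedigree=pd.Series(cross_ids, index=line_ids, name="cross")
    )


def _correlated_normals(rng, shape, corr):
    """(…, T) standard normals with cross-trait correlation ``corr``."""
    z = rng.standard_normal(shape)
    chol = np.linalg.cholesky(corr)
    return z @ chol.T


def simulate_phenotypes(
    pop: DhPopulation,
    arch: TraitArchitecture,
    seed: int = 0,
) -> PhenotypeBook:
    """Simulate line × environment × replicate phenotypes for every trait.

    The QTL contribution of each trait is centred and rescaled so its sample
    variance (n−1 denominator) equals the target σ²g exactly; rescaling by a
    positive scalar preserves cross-trait genetic correlations.
    """
    geno = pop.genotypes
    if arch.qtl_indices.max(initial=-1) >= geno.n_markers or (arch.qtl_indices < 0).any():
        raise InvalidArgument("QTL indices outside the population's marker set")
    n, T, E, R = geno.n_lines, arch.n_traits, arch.E, arch.R
    rng = np.random.default_rng(seed)
    X = geno.dosage[:, arch.qtl_indices]
    env_offsets = (
        rng.normal(0.0, 5.0, size=E) if arch.env_offsets is None
        else np.asarray(arch.env_offsets, dtype=float)
    )
    # genetic values, exactly calibrated per trait
    G = np.empty((n, T))
    for t in range(T):
        s2g = arch.target_variances[t, 0]
        g_raw = X @ arch.qtl_effects[t]
        v = np.var(g_raw, ddof=1)
        if v == 0.0:
            if s2g > 0:
                raise InvalidArgument(
                    f"trait {arch.trait_names[t]}: zero realized genetic variance "
                    "with nonzero target σ²g"
                )
            G[:, t] = 0.0
        else:
            G[:, t] = (g_raw - g_raw.mean()) * np.sqrt(s2g / v)
    sd_ge = np.sqrt(arch.target_variances[:, 1])
    sd_e = np.sqrt(arch.target_variances[:, 2])
    ge = _correlated_normals(rng, (n, E, T), arch.residual_corr) * sd_ge
    eps = _correlated_normals(rng, (n, E, R, T), arch.residual_corr) * sd_e
    # assemble long-format records
    y = (
        arch.trait_means[None, None, None, :]
        + G[:, None, None, :]
        + env_offsets[None, :, None, None]
        + ge[:, :, None, :]
        + eps
    )
    line_ids = np.asarray(geno.line_ids)
    idx = pd.MultiIndex.from_product(
        [line_ids, [f"E{j + 1}" for j in range(E)], np.arange(1, R + 1),
         arch.trait_names],
        names=["line", "environment", "replicate", "trait"],
    )
    records = idx.to_frame(index=False)
    records["value"] = y.reshape(-1)
    truth = pd.DataFrame(
        G + arch.trait_means[None, :], index=line_ids, columns=arch.trait_names
    )
    truth.index.name = "line"
    return PhenotypeBook(records=records, traits=list(arch.trait_names),
                         true_values=truth)


def inject_missingness(geno: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Mask a Bernoulli(rate) random subset of calls as missing."""
    if not 0 <= rate < 1:
        raise InvalidArgument("missingness rate must lie in [0, 1)")
    if rate == 0:
        return geno.subset()
    rng = np.random.default_rng(seed)
    d = geno.dosage.copy()
    d[rng.random(d.shape) < rate] = np.nan
    return GenotypeMatrix(
        line_ids=geno.line_ids, marker_ids=geno.marker_ids, chrom=geno.chrom,
        pos=geno.pos, dosage=d, ref=geno.ref, alt=geno.alt,
    )


# ----------------------------------------------------------------------
# Default flowering-trait architecture
# ----------------------------------------------------------------------

#: Reference-trial variance components (σ²g, σ²ge, σ²e) for the three traits.
FLOWERING_VARIANCES = {
    "DTT": (13.61, 9.22, 4.26),
    "DTP": (19.84, 10.68, 4.29),
    "DTS": (23.98, 14.12, 4.92),
}

#: Grand means (days) and cross-trait correlation of the flowering traits.
FLOWERING_MEANS = {"DTT": 60.55, "DTP": 65.00, "DTS": 66.30}
FLOWERING_CORR = np.array([
    [1.00, 0.93, 0.88],
    [0.93, 1.00, 0.95],
    [0.88, 0.95, 1.00],
])
#: Fixed environment offsets (days) emulating two summer sites, one winter
#: nursery and one late site.
FLOWERING_ENV_OFFSETS = np.array([-0.6, -5.9, -4.1, 10.5])


def flowering_architecture(
    pop: DhPopulation,
    n_qtl: int = 50,
    major_pve: float = 0.15,
    decay: float = 0.95,
    trait_corr: np.ndarray = FLOWERING_CORR,
    variances: dict | None = None,
    E: int = 4,
    R: int = 2,
    seed: int = 0,
) -> TraitArchitecture:
    """Build the default flowering-time architecture on a simulated panel.

    One fully pleiotropic major QTL plus ``n_qtl − 1`` geometric-decay minor
    QTLs; minor-effect vectors are drawn with cross-trait correlation
    ``trait_corr``.  ``major_pve`` is the major QTL's share of the entry-mean
    phenotypic variance; it is converted to a share of genetic variance via
    the entry-mean heritability implied by the target components, and the
    major/minor contributions are calibrated empirically on the population's
    own QTL genotypes.
    """
    if variances is None:
        variances = FLOWERING_VARIANCES
    traits = list(variances.keys())
    T = len(traits)
    tv = np.asarray([variances[t] for t in traits], dtype=float)
    geno = pop.genotypes
    rng = np.random.default_rng(seed)
    poly = np.flatnonzero(geno.dosage.std(axis=0, ddof=1) > 0)
    if n_qtl > poly.size:
        raise InvalidArgument("more QTLs requested than polymorphic markers available")
    qtl_idx = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    X = geno.dosage[:, qtl_idx]
    sd = X.std(axis=0, ddof=1)
    # major QTL = the sampled QTL with the highest variance (most informative)
    major = int(np.argmax(sd))
    minors = np.asarray([q for q in range(n_qtl) if q != major])
    # correlated minor effects with geometric decay of magnitude
    weights = decay ** np.arange(len(minors))
    z = _correlated_normals(rng, (len(minors), T), trait_corr)  # (Q-1, T)
    effects = np.zeros((T, n_qtl))
    # entry-mean heritability implied by the targets: share of genetic variance
    h2 = tv[:, 0] / (tv[:, 0] + tv[:, 1] / E + tv[:, 2] / (E * R))
    f_major = np.clip(major_pve / h2, 0.0, 0.95)
    for t in range(T):
        a_min = np.zeros(n_qtl)
        a_min[minors] = weights * z[:, t] / np.where(sd[minors] > 0, sd[minors], 1.0)
        g_min = X @ a_min
        v_min = np.var(g_min, ddof=1)
        s2g = tv[t, 0]
        a_min *= np.sqrt(s2g * (1 - f_major[t]) / v_min)
        a_maj = np.zeros(n_qtl)
        a_maj[major] = 1.0 / sd[major]
        g_maj = X @ a_maj
        a_maj *= np.sqrt(s2g * f_major[t] / np.var(g_maj, ddof=1))
        effects[t] = a_min + a_maj
    return TraitArchitecture(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        trait_names=traits,
        target_variances=tv,
        E=E,
        R=R,
        trait_means=np.asarray([FLOWERING_MEANS.get(t, 0.0) for t in traits]),
        env_offsets=FLOWERING_ENV_OFFSETS[:E] if E <= 4 else None,
        residual_corr=trait_corr,
    )


# ----------------------------------------------------------------------
# Export helpers
# ----------------------------------------------------------------------

def write_phenotypes(book: PhenotypeBook, path) -> None:
    """Write the long phenotype table as TSV, values rounded to 0.1 day."""
    out = book.records.copy()
    out["value"] = out["value"].round(1)
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeBook:
    """Read a long-format phenotype TSV (line, environment, replicate, trait, value)."""
    df = pd.read_csv(path, sep="\t")
    return PhenotypeBook(records=df, traits=sorted(df["trait"].unique().tolist()))


def write_truth(pop: DhPopulation, arch: TraitArchitecture, book: PhenotypeBook,
                prefix) -> None:
    """Write QTL-effect and true-genetic-value TSVs for recovery tests."""
    geno = pop.genotypes
    qtl = pd.DataFrame({
        "marker": geno.marker_ids[arch.qtl_indices],
        "chrom": geno.chrom[arch.qtl_indices],
        "pos": geno.pos[arch.qtl_indices],
    })
    for t, name in enumerate(arch.trait_names):
        qtl[f"effect_{name}"] = arch.qtl_effects[t]
    qtl.to_csv(f"{prefix}_qtl.tsv", sep="\t", index=False)
    if book.true_values is not None:
        book.true_values.to_csv(f"{prefix}_tbv.tsv", sep="\t")
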