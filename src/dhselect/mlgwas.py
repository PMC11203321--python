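"""Multi-locus association scans with pseudo-QTN conditioning.

Three scan modes share one inner engine — per-marker ordinary least squares
of the entry-mean BLUP on intercept + structure covariates (PCs) + current
pseudo-QTN dosages + the candidate marker — and differ in how pseudo-QTNs
(markers promoted to fixed covariates to absorb major-locus signal) are
chosen:

``single_marker``
    No conditioning; one OLS test per marker.
``farmcpu_like``
    Iterative positional-bin conditioning: each round, the most significant
    marker per genomic bin among markers passing a relaxed threshold enters a
    candidate pool; the pseudo-QTN set is rebuilt by greedy forward selection
    minimizing BIC; rounds repeat until the set stabilizes.
``blink_like``
    Same skeleton, but candidates are pruned by linkage disequilibrium
    (drop any candidate with r² above a ceiling with an already-kept, more
    significant candidate) and the pseudo-QTN set is the BIC-minimizing
    prefix of the pruned, p-ordered list.

Both multi-locus scans are deterministic given (data, config).  Significance
is always declared at the Bonferroni threshold α/m on the final conditioned
p-values; pseudo-QTNs receive their coefficient p-values from the final
joint model.  Per-SNP phenotypic variance explained (PVE) is the partial R²
of the marker given the PCs and the other significant markers of the same
model/trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgument

_DEGENERATE_TOL = 1e-12


@dataclass
class GwasConfig:
    """Settings for an association scan."""

    model: str = "farmcpu_like"
    alpha: float = 0.05
    n_pcs: int = 3
    bin_size: int = 10_000_000
    ld_r2_max: float = 0.7
    relax_factor: float = 100.0
    max_pseudo_qtns: int = 20
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidArgument("alpha must lie in (0, 1)")
        if self.bin_size <= 0:
            raise InvalidArgument("bin_size must be positive")
        if not 0 < self.ld_r2_max <= 1:
            raise InvalidArgument("ld_r2_max must lie in (0, 1]")


@dataclass
class AssociationResult:
    """Per-marker association statistics for one model × trait."""

    table: pd.DataFrame  # marker, chrom, pos, p_value, effect, pve, significant, pseudo_qtn, degenerate
    model: str
    trait: str
    n_markers: int
    alpha: float
    converged: bool = True
    pseudo_qtns: list = field(default_factory=list)

    @property
    def p_threshold(self) -> float:
        return self.alpha / self.n_markers

    def significant_table(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].copy()


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> tuple[float, float]:
    """Family-wise threshold α/m and its −log10 transform."""
    if n_markers < 1 or alpha <= 0:
        raise InvalidArgument("need n_markers >= 1 and alpha > 0")
    p = alpha / n_markers
    return p, -np.log10(p)


# ----------------------------------------------------------------------
# Inner scan
# ----------------------------------------------------------------------

def _ols_scan(M: np.ndarray, y: np.ndarray, covars: np.ndarray | None):
    """Per-column OLS test of ``y ~ 1 + covars + M[:, j]``.

    Implemented by Frisch–Waugh–Lovell: residualize y and every marker on
    [1, covars], then test the simple slope on the residualized marker with
    df = n − p − 1.  Returns (p_values, effects, degenerate mask).
    """
    n = len(y)
    Q = np.ones((n, 1)) if covars is None or covars.size == 0 else np.hstack(
        [np.ones((n, 1)), covars]
    )
    qr_q, _ = np.linalg.qr(Q)
    p_cov = np.linalg.matrix_rank(Q)
    ry = y - qr_q @ (qr_q.T @ y)
    RM = M - qr_q @ (qr_q.T @ M)
    sxx = np.einsum("ij,ij->j", RM, RM)
    degenerate = sxx <= _DEGENERATE_TOL * n
    sxx_safe = np.where(degenerate, 1.0, sxx)
    beta = (RM.T @ ry) / sxx_safe
    df = n - p_cov - 1
    if df <= 0:
        raise InvalidArgument("not enough lines for the covariate set")
    rss = ry @ ry - beta ** 2 * sxx_safe
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(np.maximum(rss / df, 1e-300) / sxx_safe)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(degenerate, 1.0, np.clip(pvals, np.finfo(float).tiny, 1.0))
    beta = np.where(degenerate, 0.0, beta)
    return pvals, beta, degenerate


def _joint_fit(y, covars, Mq):
    """OLS of y ~ 1 + covars + Mq; per-column p-values of the Mq block."""
    n = len(y)
    parts = [np.ones((n, 1))]
    if covars is not None and covars.size:
        parts.append(covars)
    k0 = sum(p.shape[1] for p in parts)
    X = np.hstack(parts + [Mq])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    df = n - rank
    s2 = (r @ r) / max(df, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 1e-300))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), max(df, 1))
    return p[k0:], beta[k0:]


def _bic(y, covars, Mq, m_total: int = 1):
    """Extended BIC (Chen & Chen) for pseudo-QTN subset selection.

    The per-marker penalty log n + 2 log m guards against over-selection when
    candidates are the minima of m ≫ n marker p-values; with the plain log n
    penalty, null markers passing a relaxed screen are routinely admitted and
    the family-wise error contract of the conditioned scan breaks.
    """
    n = len(y)
    parts = [np.ones((n, 1))]
    if covars is not None and covars.size:
        parts.append(covars)
    k_markers = 0
    if Mq is not None and Mq.size:
        parts.append(Mq)
        k_markers = Mq.shape[1]
    X = np.hstack(parts)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = max(r @ r, 1e-300)
    return (n * np.log(rss / n) + rank * np.log(n)
            + 2.0 * k_markers * np.log(max(m_total, 1)))


def _align(geno, blups: pd.Series):
    b = blups.dropna()
    idx = {l: i for i, l in enumerate(geno.line_ids)}
    keep = [l for l in b.index if l in idx]
    rows = np.asarray([idx[l] for l in keep])
    return geno.dosage[rows], b.loc[keep].to_numpy(float), rows


def _result_frame(geno, pvals, effects, degenerate, thresh, pseudo_set):
    df = pd.DataFrame({
        "marker": geno.marker_ids,
        "chrom": geno.chrom,
        "pos": geno.pos,
        "p_value": pvals,
        "effect": effects,
        "pve": np.nan,
        "significant": pvals < thresh,
        "pseudo_qtn": np.isin(np.arange(geno.n_markers), pseudo_set),
        "degenerate": degenerate,
    })
    return df


def single_marker_scan(geno, blups: pd.Series, covariates: np.ndarray | None = None,
                       config: GwasConfig | None = None,
                       trait: str = "trait") -> AssociationResult:
    """Baseline one-marker-at-a-time OLS scan with fixed covariates."""
    config = config or GwasConfig(model="single_marker")
    M, y, rows = _align(geno, blups)
    if np.isnan(M).any():
        raise InvalidArgument("scan requires a complete (imputed) genotype matrix")
    C = covariates[rows] if covariates is not None else None
    pvals, effects, degen = _ols_scan(M, y, C)
    thresh = config.alpha / geno.n_markers
    table = _result_frame(geno, pvals, effects, degen, thresh, [])
    return AssociationResult(table, "single_marker", trait, geno.n_markers,
                             config.alpha)


# ----------------------------------------------------------------------
# Multi-locus scans
# ----------------------------------------------------------------------

def _farmcpu_candidates(pvals, chrom, pos, bin_size, relax_thresh):
    """Most significant marker per genomic bin among sub-threshold markers."""
    hits = np.flatnonzero(pvals < relax_thresh)
    if hits.size == 0:
        return []
    bins = {}
    for j in hits:
        key = (chrom[j], pos[j] // bin_size)
        if key not in bins or pvals[j] < pvals[bins[key]]:
            bins[key] = j
    return sorted(bins.values(), key=lambda j: pvals[j])


def _ld_prune(candidates, M, pvals, r2_max):
    """Keep p-ordered candidates whose r² with every kept one is <= r2_max."""
    kept = []
    for j in sorted(candidates, key=lambda j: pvals[j]):
        ok = True
        for k in kept:
            x, z = M[:, j], M[:, k]
            sx, sz = x.std(), z.std()
            r2 = 1.0 if sx == 0 or sz == 0 else np.corrcoef(x, z)[0, 1] ** 2
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


def _greedy_bic(y, C, M, pool, m_total):
    """Greedy forward extended-BIC selection over a p-ordered pool."""
    best = _bic(y, C, None, m_total)
    chosen = []
    for j in pool:
        trial = chosen + [j]
        b = _bic(y, C, M[:, trial], m_total)
        if b < best - 1e-9:
            best = b
            chosen = trial
    return chosen


def _prefix_bic(y, C, M, pool, m_total):
    """Extended-BIC-minimizing prefix of a p-ordered candidate pool."""
    best = _bic(y, C, None, m_total)
    chosen = []
    for k in range(1, len(pool) + 1):
        b = _bic(y, C, M[:, pool[:k]], m_total)
        if b < best - 1e-9:
            best = b
            chosen = pool[:k]
    return list(chosen)


def _multilocus_scan(geno, blups, config, pcs, trait, mode):
    M, y, rows = _align(geno, blups)
    if np.isnan(M).any():
        raise InvalidArgument("scan requires a complete (imputed) genotype matrix")
    C = pcs[rows] if pcs is not None else None
    m = geno.n_markers
    thresh = config.alpha / m
    relax_thresh = min(thresh * config.relax_factor, 0.01)
    S: list[int] = []
    converged = False
    pvals = effects = degen = None
    for _ in range(config.max_iterations):
        cov = C if not S else (
            np.hstack([C, M[:, S]]) if C is not None else M[:, S]
        )
        pvals, effects, degen = _ols_scan(M, y, cov)
        if S:  # pseudo-QTNs are collinear with covariates; neutralize
            pvals[S] = 1.0
        if mode == "farmcpu":
            cand = _farmcpu_candidates(pvals, geno.chrom, geno.pos,
                                       config.bin_size, relax_thresh)
        else:
            cand = np.flatnonzero(pvals < relax_thresh).tolist()
        pool = sorted(set(cand) | set(S), key=lambda j: pvals[j])
        if mode == "blink":
            pool = _ld_prune(pool, M, pvals, config.ld_r2_max)
        pool = pool[: max(config.max_pseudo_qtns, 1)]
        if mode == "farmcpu":
            new_S = _greedy_bic(y, C, M, pool, m)
        else:
            new_S = _prefix_bic(y, C, M, pool, m)
        if set(new_S) == set(S):
            converged = True
            S = new_S
            break
        S = new_S
    # final conditioned scan + joint-model p-values for the pseudo-QTNs
    cov = C if not S else (np.hstack([C, M[:, S]]) if C is not None else M[:, S])
    pvals, effects, degen = _ols_scan(M, y, cov)
    if S:
        pq, bq = _joint_fit(y, C, M[:, S])
        pvals[S] = np.clip(pq, np.finfo(float).tiny, 1.0)
        effects[S] = bq
        degen[S] = False
    table = _result_frame(geno, pvals, effects, degen, thresh, S)
    tag = "farmcpu_like" if mode == "farmcpu" else "blink_like"
    return AssociationResult(table, tag, trait, m, config.alpha, converged,
                             [geno.marker_ids[j] for j in S])


def farmcpu_like_scan(geno, blups, config: GwasConfig | None = None,
                      pcs: np.ndarray | None = None,
                      trait: str = "trait") -> AssociationResult:
    """Iterative positional-bin pseudo-QTN scan (FarmCPU-style conditioning)."""
    config = config or GwasConfig(model="farmcpu_like")
    return _multilocus_scan(geno, blups, config, pcs, trait, "farmcpu")


def blink_like_scan(geno, blups, config: GwasConfig | None = None,
                    pcs: np.ndarray | None = None,
                    trait: str = "trait") -> AssociationResult:
    """Iterative LD-pruned pseudo-QTN scan (BLINK-style conditioning)."""
    config = config or GwasConfig(model="blink_like")
    return _multilocus_scan(geno, blups, config, pcs, trait, "blink")


# ----------------------------------------------------------------------
# PVE and overlap summaries
# ----------------------------------------------------------------------

def snp_pve(geno, blups: pd.Series, result: AssociationResult,
            pcs: np.ndarray | None = None,
            definition: str = "partial") -> AssociationResult:
    """Fill per-SNP phenotypic variance explained for significant markers.

    ``definition='partial'``: squared partial correlation — 1 − RSS_full /
    RSS_reduced where the reduced model drops the focal marker but keeps PCs
    and the other significant markers of the same model/trait.
    ``definition='marginal'``: marginal R² given PCs only.
    """
    M, y, rows = _align(geno, blups)
    C = pcs[rows] if pcs is not None else None
    table = result.table.copy()
    sig = np.flatnonzero(table["significant"].to_numpy())
    pve = table["pve"].to_numpy(float)

    def rss(cols):
        n = len(y)
        parts = [np.ones((n, 1))]
        if C is not None and C.size:
            parts.append(C)
        if len(cols):
            parts.append(M[:, cols])
        X = np.hstack(parts)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r

    for j in sig:
        if definition == "partial":
            others = [k for k in sig if k != j]
            full = rss(list(sig))
            red = rss(others)
        else:
            full = rss([j])
            red = rss([])
        pve[j] = 0.0 if red <= 0 else max(0.0, min(1.0, 1.0 - full / red))
    table["pve"] = pve
    return replace(result, table=table)


@dataclass
class OverlapSummary:
    """Cross-model / cross-trait accounting of significant SNPs."""

    snp_table: pd.DataFrame          # snp, chrom, pos, model, trait, pve
    unique_per_model: dict           # model -> count of distinct (chrom, pos)
    venn: dict                       # frozenset of models -> count of SNPs
    pleiotropic: pd.DataFrame        # snp, traits (detected for > 1 trait)
    total_pve: pd.DataFrame          # model, trait, total_pve


def overlap_summary(results: list) -> OverlapSummary:
    """Summarize significant SNPs across models and traits.

    Accepts :class:`AssociationResult` objects or pre-built significant-SNP
    DataFrames with columns (snp, chrom, pos, model, trait, pve).  SNP
    identity is (chrom, pos).
    """
    frames = []
    for r in results:
        if isinstance(r, AssociationResult):
            t = r.significant_table()
            if t.empty:
                continue
            frames.append(pd.DataFrame({
                "snp": t["marker"], "chrom": t["chrom"], "pos": t["pos"],
                "model": r.model, "trait": r.trait, "pve": t["pve"],
            }))
        else:
            if len(r):
                frames.append(pd.DataFrame(r))
    if frames:
        snps = pd.concat(frames, ignore_index=True)
    else:
        snps = pd.DataFrame(columns=["snp", "chrom", "pos", "model", "trait", "pve"])
    snps["key"] = list(zip(snps["chrom"].astype(str), snps["pos"].astype(int) if len(snps) else []))
    unique_per_model = {
        m: g["key"].nunique() for m, g in snps.groupby("model")
    }
    key_models = snps.groupby("key")["model"].agg(lambda s: frozenset(s))
    venn: dict = {}
    for ms in key_models:
        venn[ms] = venn.get(ms, 0) + 1
    key_traits = snps.groupby("key")["trait"].agg(lambda s: sorted(set(s)))
    plei_keys = [k for k, ts in key_traits.items() if len(ts) > 1]
    plei = (
        snps[snps["key"].isin(plei_keys)]
        .groupby("key")
        .agg(snp=("snp", "first"), traits=("trait", lambda s: sorted(set(s))))
        .reset_index(drop=True)
    )
    total = (
        snps.groupby(["model", "trait"])["pve"].sum().reset_index()
        .rename(columns={"pve": "total_pve"})
    )
    return OverlapSummary(snps.drop(columns="key"), unique_per_model, venn,
                          plei, total)


# ----------------------------------------------------------------------
# Report tables
# ----------------------------------------------------------------------

def bin_label(chrom, pos, chrom_lengths: dict) -> str:
    """Decile-style reporting label ``chrom.decile`` (e.g. ``9.07``)."""
    L = chrom_lengths[chrom]
    decile = min(9, int(10 * pos / L))
    return f"{chrom}.{decile:02d}"


def manhattan_table(result: AssociationResult) -> pd.DataFrame:
    """Marker, chromosome, position, −log10 p — ready for a Manhattan plot."""
    t = result.table
    return pd.DataFrame({
        "marker": t["marker"], "chrom": t["chrom"], "pos": t["pos"],
        "neg_log10_p": -np.log10(t["p_value"]),
    })


def qq_table(result: AssociationResult) -> pd.DataFrame:
    """Expected vs observed −log10 p under the global null."""
    p = np.sort(result.table["p_value"].to_numpy())
    m = len(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame({
        "expected_neg_log10_p": -np.log10(expected),
        "observed_neg_log10_p": -np.log10(p),
    })
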