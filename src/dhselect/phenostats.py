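"""Descriptive statistics, variance components, heritability and BLUPs.

Model for a line evaluated in a multi-environment trial with replication:

    y_ijk = μ + g_i + e_j + (ge)_ij + ε_ijk

with environment main effects e_j fixed, line effects g_i ~ N(0, σ²g),
interaction (ge)_ij ~ N(0, σ²ge) and plot error ε_ijk ~ N(0, σ²e).

For balanced data the REML estimates coincide (when interior) with the
closed-form expected-mean-squares solution

    σ̂²e = MSE,  σ̂²ge = (MS_GE − MSE)/R,  σ̂²g = (MS_G − MS_GE)/(R·E),

which is used as the fast path; unbalanced data are handled by direct REML
maximization over log variance ratios.  Negative iterates/solutions are
truncated at zero (REML boundary) with a logged flag.

Entry-mean broad-sense heritability:

    H² = σ²g / (σ²g + σ²ge/E + σ²e/(E·R)).

BLUPs are mixed-model solutions of the full Henderson equations at the
estimated components; the reported value for line i is μ̂ + ĝ_i (the
shrunken across-environment entry mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError, InvalidArgument, MissingCellError

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """REML/ANOVA variance components for one trait."""

    trait: str
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    E: int
    R: float
    n_lines: int = 0
    method: str = "anova"
    converged: bool = True
    truncated: bool = False

    @property
    def H2(self) -> float:
        return heritability_entry_mean(self)

    def to_frame(self) -> pd.DataFrame:
        d = dict(self.__dict__)
        d["H2_percent"] = round(100 * self.H2, 2)
        return pd.DataFrame([d])


def heritability_entry_mean(vc=None, *, sigma2_g=None, sigma2_ge=None,
                            sigma2_e=None, E=None, R=None) -> float:
    """Entry-mean broad-sense heritability H² = σ²g/(σ²g + σ²ge/E + σ²e/(E·R)).

    Accepts either a :class:`VarianceComponents` or keyword components with
    the design constants E (environments) and R (replicates per environment).
    Multiply by 100 for percent reporting.
    """
    if vc is not None:
        sigma2_g, sigma2_ge, sigma2_e = vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e
        E, R = vc.E, vc.R
    if E is None or R is None or E < 1 or R < 1:
        raise InvalidArgument("E and R must be >= 1")
    if min(sigma2_g, sigma2_ge, sigma2_e) < 0:
        raise InvalidArgument("variance components must be non-negative")
    denom = sigma2_g + sigma2_ge / E + sigma2_e / (E * R)
    if denom <= 0:
        raise InvalidArgument("zero denominator: all components are zero")
    return sigma2_g / denom


# ----------------------------------------------------------------------
# Descriptive statistics
# ----------------------------------------------------------------------

def descriptive_stats(book, include_combined: bool = True) -> pd.DataFrame:
    """Per trait × environment range, mean, SD, skewness, kurtosis and CV%.

    SD uses the n−1 denominator; skewness/kurtosis are the sample-moment
    definitions (g1 = m3/m2^1.5, excess g2 = m4/m2² − 3).  The "Combined"
    row is computed on per-line entry means across environments.
    """
    rows = []
    for trait in book.traits:
        sub = book.records[book.records["trait"] == trait]
        envs = sorted(sub["environment"].unique().tolist())
        cells = [(e, sub.loc[sub["environment"] == e, "value"].to_numpy(float))
                 for e in envs]
        if include_combined:
            entry = sub.groupby("line")["value"].mean().to_numpy()
            cells.append(("Combined", entry))
        for env, v in cells:
            if v.size == 0:
                raise MissingCellError(f"no observations for trait {trait!r}, "
                                       f"environment {env!r}")
            if v.size < 3:
                raise MissingCellError(
                    f"trait {trait!r} × environment {env!r}: need >= 3 observations"
                )
            mean = v.mean()
            sd = v.std(ddof=1)
            skw = stats.skew(v, bias=True) if sd > 0 else 0.0
            krt = stats.kurtosis(v, fisher=True, bias=True) if sd > 0 else 0.0
            rows.append({
                "trait": trait,
                "environment": env,
                "n": v.size,
                "min": v.min(),
                "max": v.max(),
                "mean": mean,
                "sd": sd,
                "skewness": skw,
                "kurtosis": krt,
                "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Variance components
# ----------------------------------------------------------------------

def _trait_table(book, trait: str) -> pd.DataFrame:
    sub = book.records[book.records["trait"] == trait]
    if sub.empty:
        raise InvalidArgument(f"no records for trait {trait!r}")
    return sub


def _is_balanced(sub: pd.DataFrame) -> tuple[bool, int]:
    counts = sub.groupby(["line", "environment"], observed=True).size()
    lines = sub["line"].nunique()
    envs = sub["environment"].nunique()
    R = counts.iloc[0]
    balanced = (len(counts) == lines * envs) and (counts == R).all()
    return bool(balanced), int(R)


def _anova_components(sub: pd.DataFrame) -> tuple[float, float, float, bool]:
    """Closed-form expected-mean-squares solution for balanced data."""
    lines = sub["line"].unique()
    envs = sub["environment"].unique()
    L, E = len(lines), len(envs)
    _, R = _is_balanced(sub)
    y = sub["value"].to_numpy(float)
    grand = y.mean()
    cell = sub.groupby(["line", "environment"], observed=True)["value"].mean()
    line_m = sub.groupby("line", observed=True)["value"].mean()
    env_m = sub.groupby("environment", observed=True)["value"].mean()
    ss_g = R * E * ((line_m - grand) ** 2).sum()
    cell_df = cell.reset_index()
    cell_df["dev"] = (
        cell_df["value"]
        - cell_df["line"].map(line_m)
        - cell_df["environment"].map(env_m)
        + grand
    )
    ss_ge = R * (cell_df["dev"] ** 2).sum()
    key = list(zip(sub["line"], sub["environment"]))
    cell_map = cell.to_dict()
    resid = y - np.asarray([cell_map[k] for k in key])
    ss_err = (resid ** 2).sum()
    ms_g = ss_g / (L - 1)
    ms_ge = ss_ge / ((L - 1) * (E - 1))
    s2e = ss_err / (L * E * (R - 1)) if R > 1 else 0.0
    s2ge = (ms_ge - s2e) / R
    s2g = (ms_g - ms_ge) / (R * E)
    truncated = s2ge < 0 or s2g < 0
    return max(s2g, 0.0), max(s2ge, 0.0), max(s2e, 0.0), truncated


def _design(sub: pd.DataFrame):
    """Fixed (intercept + environment) and random (line, line×env) designs."""
    lines = pd.Categorical(sub["line"])
    envs = pd.Categorical(sub["environment"])
    n = len(sub)
    L, E = len(lines.categories), len(envs.categories)
    X = np.zeros((n, E))
    X[:, 0] = 1.0
    for j in range(1, E):
        X[envs.codes == j, j] = 1.0
    Zg = np.zeros((n, L))
    Zg[np.arange(n), lines.codes] = 1.0
    ge_codes = lines.codes.astype(np.int64) * E + envs.codes
    used = np.unique(ge_codes)
    remap = {c: k for k, c in enumerate(used)}
    Zge = np.zeros((n, len(used)))
    Zge[np.arange(n), [remap[c] for c in ge_codes]] = 1.0
    y = sub["value"].to_numpy(float)
    return X, Zg, Zge, y, list(lines.categories)


def _reml_loglik(gam_g, gam_ge, X, Zg, Zge, y):
    """Profile restricted log-likelihood at variance ratios γ = σ²/σ²e."""
    n, p = X.shape
    H = np.eye(n) + gam_g * (Zg @ Zg.T) + gam_ge * (Zge @ Zge.T)
    c, low = np.linalg.cholesky(H), True
    logdet_H = 2.0 * np.log(np.diag(c)).sum()
    Hi_y = np.linalg.solve(H, y)
    Hi_X = np.linalg.solve(H, X)
    XtHiX = X.T @ Hi_X
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    r = y - X @ beta
    quad = r @ np.linalg.solve(H, r)
    s2e = quad / (n - p)
    ll = -0.5 * (logdet_H + logdet_XtHiX + (n - p) * (np.log(s2e) + 1.0))
    return ll, s2e, beta


def fit_variance_components(book, trait: str, method: str = "auto",
                            tol: float = 1e-8) -> VarianceComponents:
    """Estimate (σ²g, σ²ge, σ²e) for one trait.

    ``method='auto'`` uses the closed-form expected-mean-squares solution for
    balanced data (equal to REML when interior) and iterative REML otherwise;
    ``method='reml'`` forces the iterative path; ``method='anova'`` forces the
    closed form (balanced data only).
    """
    sub = _trait_table(book, trait)
    E = sub["environment"].nunique()
    L = sub["line"].nunique()
    if E < 2:
        raise EstimationError("G×E variance inestimable with a single environment")
    if L < 2:
        raise InvalidArgument("need at least 2 lines")
    balanced, R = _is_balanced(sub)
    if method == "anova" or (method == "auto" and balanced):
        if not balanced:
            raise InvalidArgument("ANOVA closed form requires balanced data")
        s2g, s2ge, s2e, trunc = _anova_components(sub)
        if trunc:
            logger.warning("variance component truncated at 0 for trait %s", trait)
        return VarianceComponents(trait, s2g, s2ge, s2e, E, R, L, "anova", True, trunc)
    # iterative REML on log variance ratios
    X, Zg, Zge, y, _ = _design(sub)
    vy = np.var(y, ddof=1)
    if vy == 0:
        raise EstimationError("zero phenotypic variance")

    def neg_ll(theta):
        ll, _, _ = _reml_loglik(np.exp(theta[0]), np.exp(theta[1]), X, Zg, Zge, y)
        return -ll

    x0 = np.log([0.5, 0.25])
    res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                            options={"fatol": tol, "xatol": 1e-8, "maxiter": 2000})
    gam_g, gam_ge = np.exp(res.x)
    _, s2e, _ = _reml_loglik(gam_g, gam_ge, X, Zg, Zge, y)
    truncated = False
    if gam_g < 1e-8 or gam_ge < 1e-8:
        truncated = True
        logger.warning("REML boundary solution truncated at 0 for trait %s", trait)
    s2g = 0.0 if gam_g < 1e-8 else gam_g * s2e
    s2ge = 0.0 if gam_ge < 1e-8 else gam_ge * s2e
    R_mean = len(sub) / (L * E)
    return VarianceComponents(trait, s2g, s2ge, s2e, E, R_mean, L, "reml",
                              bool(res.success), truncated)


# ----------------------------------------------------------------------
# BLUPs
# ----------------------------------------------------------------------

def compute_blups(book, vcs) -> pd.DataFrame:
    """Across-environment BLUPs (μ̂ + ĝ_i) per line × trait.

    ``vcs`` is a dict trait → :class:`VarianceComponents` (or a single VC for
    a one-trait book).  Lines without observations for a trait get NaN with a
    logged warning.  Solves the full mixed-model (Henderson) equations with
    environment fixed and line, line×environment random.
    """
    if isinstance(vcs, VarianceComponents):
        vcs = {vcs.trait: vcs}
    out = {}
    all_lines = pd.Index(sorted(book.records["line"].unique()), name="line")
    for trait in book.traits:
        vc = vcs[trait]
        sub = _trait_table(book, trait)
        X, Zg, Zge, y, line_levels = _design(sub)
        n, p = X.shape
        s2e = max(vc.sigma2_e, 1e-8 * np.var(y, ddof=1), 1e-12)
        lam_g = s2e / max(vc.sigma2_g, 1e-12)
        use_ge = vc.sigma2_ge > 1e-12
        if use_ge:
            lam_ge = s2e / vc.sigma2_ge
            Z = np.hstack([Zg, Zge])
            D = np.concatenate([
                np.full(Zg.shape[1], lam_g), np.full(Zge.shape[1], lam_ge)
            ])
        else:
            Z = Zg
            D = np.full(Zg.shape[1], lam_g)
        C = np.block([
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + np.diag(D)],
        ])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(C, rhs)
        beta = sol[:p]
        g_hat = sol[p: p + Zg.shape[1]]
        # reported entry-mean scale: intercept + mean environment effect + g
        mu = beta[0] + np.mean(np.concatenate([[0.0], beta[1:]]))
        s = pd.Series(mu + g_hat, index=pd.Index(line_levels, name="line"))
        missing = all_lines.difference(s.index)
        if len(missing):
            logger.warning("trait %s: %d lines with no observations excluded",
                           trait, len(missing))
        out[trait] = s.reindex(all_lines)
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# Trait correlations
# ----------------------------------------------------------------------

def _sig_code(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def trait_correlations(blups: pd.DataFrame):
    """Pearson correlations between trait BLUPs with two-sided p-values.

    Returns ``(r, p, codes)`` DataFrames; p-values come from the t-transform
    t = r·sqrt((n−2)/(1−r²)).
    """
    traits = list(blups.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = blups[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                raise InvalidArgument(
                    f"need >= 3 lines with BLUPs for {traits[i]}/{traits[j]}"
                )
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                raise EstimationError(
                    f"zero-variance trait: correlation undefined for "
                    f"{traits[i]}/{traits[j]}"
                )
            rij, pij = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    codes = pdf.map(_sig_code)
    np.fill_diagonal(codes.values, "")
    return rdf, pdf, codes
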