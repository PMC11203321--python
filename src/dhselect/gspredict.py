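"""Ridge-regression BLUP (RR-BLUP) genomic selection and CV experiments.

Model: y = 1μ + Zu + ε with marker effects u ~ N(0, I σ²u) and Z the
column-centred dosage matrix.  The shrinkage ratio λ = σ²e/σ²u is estimated
by restricted maximum likelihood profiled over λ: with the eigendecomposition
K = ZZᵀ = U S Uᵀ, the restricted log-likelihood at each λ is evaluated in
O(n²) and maximized by 1-D search in ln λ on [−10, 10].  Marker effects are
û = Zᵀ(K + λI)⁻¹(y − 1μ̂), so training GEBVs coincide with the GBLUP kernel
solution ĝ = K(K + λI)⁻¹(y − 1μ̂) by construction.

Prediction accuracy is the Pearson correlation between predicted GEBVs and
the observed entry-mean BLUPs of held-out lines, averaged over all folds ×
repetitions.  λ is re-estimated inside every training partition, so test
phenotypes never leak into shrinkage estimation.  The top-k experiment
ranks markers by a GWAS computed once on the full population (the literal
published procedure, optimistically biased); pass ``refit_ranking`` a
callable to re-rank inside each training fold instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError, InvalidArgument


@dataclass
class RrBlupModel:
    """A fitted RR-BLUP model."""

    intercept: float
    marker_effects: np.ndarray
    marker_means: np.ndarray
    trained_marker_ids: np.ndarray
    lambda_: float
    lambda_at_boundary: bool = False
    fitted_gebv: np.ndarray | None = None


@dataclass
class CvDesign:
    """Cross-validation layout for a GS experiment."""

    scheme: str = "kfold"          # kfold | fraction
    k: int = 5
    repetitions: int = 100
    training_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise InvalidArgument("k must be >= 2")
        if self.repetitions < 1:
            raise InvalidArgument("repetitions must be >= 1")
        if not 0 < self.training_fraction < 1:
            raise InvalidArgument("training_fraction must lie in (0, 1)")


_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


def _profile_reml_lambda(s: np.ndarray, Uty: np.ndarray, UtX: np.ndarray,
                         n: int) -> tuple[float, bool]:
    """Maximize the restricted log-likelihood over ln λ.

    ``s`` are the eigenvalues of K = ZZᵀ, ``Uty``/``UtX`` the rotated response
    and fixed-effect design (intercept only here, but kept general).
    """
    p = UtX.shape[1]

    def neg_restricted_ll(log_lam):
        lam = np.exp(log_lam)
        d = s + lam
        XtHiX = (UtX / d[:, None]).T @ UtX
        XtHiy = (UtX / d[:, None]).T @ Uty
        beta = np.linalg.solve(XtHiX, XtHiy)
        r = Uty - UtX @ beta
        quad = np.sum(r * r / d)
        sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
        s2u = quad / (n - p)
        ll = -0.5 * ((n - p) * np.log(s2u) + np.sum(np.log(d))
                     + logdet_XtHiX + (n - p))
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-6},
    )
    log_lam = float(res.x)
    at_boundary = (
        log_lam - _LOG_LAMBDA_BOUNDS[0] < 1e-3
        or _LOG_LAMBDA_BOUNDS[1] - log_lam < 1e-3
    )
    return np.exp(log_lam), at_boundary


def fit_rrblup(train_geno, train_blups, lambda_: float | None = None) -> RrBlupModel:
    """Fit RR-BLUP on a training set.

    ``train_geno`` may be a :class:`~dhselect.genoqc.GenotypeMatrix` or a
    plain (lines × markers) array; ``train_blups`` a pandas Series aligned to
    lines or a plain vector.  Pass ``lambda_`` to skip REML and use a fixed
    shrinkage ratio.
    """
    Z_raw, marker_ids = _as_matrix(train_geno)
    y = np.asarray(
        train_blups.to_numpy(float) if hasattr(train_blups, "to_numpy") else train_blups,
        dtype=float,
    )
    n, m = Z_raw.shape
    if n < 10:
        raise InvalidArgument("need at least 10 training lines")
    if m < 1:
        raise InvalidArgument("need at least 1 marker")
    if np.isnan(Z_raw).any():
        raise InvalidArgument("training genotypes must be complete (imputed)")
    if np.var(y, ddof=1) == 0:
        raise EstimationError("zero phenotypic variance in training set")
    means = Z_raw.mean(axis=0)
    Z = Z_raw - means
    K = Z @ Z.T
    at_boundary = False
    if lambda_ is None:
        s, U = np.linalg.eigh(K)
        s = np.maximum(s, 0.0)
        lambda_, at_boundary = _profile_reml_lambda(
            s, U.T @ y, (U.T @ np.ones((n, 1))), n
        )
    A = K + lambda_ * np.eye(n)
    Ai = np.linalg.inv(A)
    ones = np.ones(n)
    mu = (ones @ Ai @ y) / (ones @ Ai @ ones)
    r = y - mu
    effects = Z.T @ (Ai @ r)
    fitted = mu + Z @ effects
    return RrBlupModel(
        intercept=float(mu),
        marker_effects=effects,
        marker_means=means,
        trained_marker_ids=marker_ids,
        lambda_=float(lambda_),
        lambda_at_boundary=at_boundary,
        fitted_gebv=fitted,
    )


def _as_matrix(geno):
    if hasattr(geno, "dosage"):
        return geno.dosage, np.asarray(geno.marker_ids)
    arr = np.asarray(geno, dtype=float)
    return arr, np.arange(arr.shape[1])


def predict_gebv(model: RrBlupModel, geno) -> np.ndarray:
    """GEBV = μ̂ + (dosage − training marker means) · û for each line."""
    X, marker_ids = _as_matrix(geno)
    if hasattr(geno, "marker_ids"):
        trained = {m: j for j, m in enumerate(marker_ids)}
        missing = [m for m in model.trained_marker_ids if m not in trained]
        if missing:
            raise InvalidArgument(
                f"prediction genotypes lack trained markers: {missing[:5]}"
            )
        cols = [trained[m] for m in model.trained_marker_ids]
        X = X[:, cols]
    elif X.shape[1] != len(model.trained_marker_ids):
        raise InvalidArgument("prediction matrix has wrong marker count")
    return model.intercept + (X - model.marker_means) @ model.marker_effects


# ----------------------------------------------------------------------
# Cross-validation experiments
# ----------------------------------------------------------------------

@dataclass
class GsExperimentResult:
    """Mean ± sd prediction accuracy per (trait × factor level)."""

    table: pd.DataFrame  # trait, experiment, level, mean_accuracy, sd_accuracy, n
    experiment: str


def _accuracy(pred, obs) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(stats.pearsonr(pred, obs)[0])


def _kfold_indices(n, k, rng):
    perm = rng.permutation(n)
    return np.array_split(perm, k)


def _cv_accuracies(Z, y, k, reps, rng):
    """Fold-level accuracies of k-fold CV repeated ``reps`` times."""
    n = Z.shape[0]
    if n < 3 * k:
        raise InvalidArgument("too few lines for k-fold CV")
    accs = []
    for _ in range(reps):
        for fold in _kfold_indices(n, k, rng):
            if fold.size < 3:
                raise InvalidArgument("fold with fewer than 3 lines")
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            model = fit_rrblup(Z[mask], y[mask])
            pred = model.intercept + (Z[fold] - model.marker_means) @ model.marker_effects
            accs.append(_accuracy(pred, y[fold]))
    return np.asarray(accs)


def _traits_and_matrix(geno, blups):
    Z, _ = _as_matrix(geno)
    if isinstance(blups, pd.Series):
        blups = blups.to_frame()
    if hasattr(geno, "line_ids"):
        blups = blups.reindex(np.asarray(geno.line_ids))
    if blups.isna().any().any():
        raise InvalidArgument("BLUP table does not cover every genotyped line")
    return Z, blups


def cross_validate(geno, blups, design: CvDesign | None = None) -> GsExperimentResult:
    """Plain k-fold CV accuracy per trait (all markers)."""
    design = design or CvDesign()
    Z, blups = _traits_and_matrix(geno, blups)
    rows = []
    for t, (trait, y) in enumerate(blups.items()):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, t]))
        accs = _cv_accuracies(Z, y.to_numpy(float), design.k,
                              design.repetitions, rng)
        rows.append({
            "trait": trait, "experiment": "kfold", "level": f"k={design.k}",
            "mean_accuracy": accs.mean(), "sd_accuracy": accs.std(ddof=1),
            "n": len(accs),
        })
    return GsExperimentResult(pd.DataFrame(rows), "kfold")


def sweep_training_size(
    geno, blups,
    fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    repetitions: int = 100,
    seed: int = 0,
) -> GsExperimentResult:
    """Accuracy as a function of training-population fraction.

    Per repetition and fraction, one random training/prediction split; the
    held-out accuracy is recorded.
    """
    Z, blups = _traits_and_matrix(geno, blups)
    n = Z.shape[0]
    rows = []
    for t, (trait, ys) in enumerate(blups.items()):
        y = ys.to_numpy(float)
        for f_i, frac in enumerate(fractions):
            n_train = int(round(frac * n))
            if n_train < 10 or n - n_train < 3:
                raise InvalidArgument(f"fraction {frac} leaves too few lines")
            rng = np.random.default_rng(np.random.SeedSequence([seed, t, f_i]))
            accs = []
            for _ in range(repetitions):
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
                model = fit_rrblup(Z[tr], y[tr])
                pred = model.intercept + (Z[te] - model.marker_means) @ model.marker_effects
                accs.append(_accuracy(pred, y[te]))
            accs = np.asarray(accs)
            rows.append({
                "trait": trait, "experiment": "training_size", "level": frac,
                "mean_accuracy": accs.mean(), "sd_accuracy": accs.std(ddof=1),
                "n": len(accs),
            })
    return GsExperimentResult(pd.DataFrame(rows), "training_size")


def sweep_marker_density(
    geno, blups,
    densities=(10, 30, 50, 100, 300, 500, 1000, 3000, 5000),
    repetitions: int = 100,
    k: int = 5,
    seed: int = 0,
) -> GsExperimentResult:
    """Accuracy as a function of the number of randomly sampled markers.

    Per repetition, a fresh uniform marker subset of the stated size is drawn
    and 5-fold CV accuracy computed on that subset.
    """
    Z, blups = _traits_and_matrix(geno, blups)
    m = Z.shape[1]
    if max(densities) > m:
        raise InvalidArgument(f"density {max(densities)} exceeds {m} markers")
    rows = []
    for t, (trait, ys) in enumerate(blups.items()):
        y = ys.to_numpy(float)
        for d_i, dens in enumerate(densities):
            rng = np.random.default_rng(np.random.SeedSequence([seed, t, d_i]))
            accs = []
            for _ in range(repetitions):
                cols = rng.choice(m, size=dens, replace=False)
                accs.extend(_cv_accuracies(Z[:, cols], y, k, 1, rng))
            accs = np.asarray(accs)
            rows.append({
                "trait": trait, "experiment": "marker_density", "level": dens,
                "mean_accuracy": accs.mean(), "sd_accuracy": accs.std(ddof=1),
                "n": len(accs),
            })
    return GsExperimentResult(pd.DataFrame(rows), "marker_density")


def _rank_markers(table, order_map) -> np.ndarray:
    """Column indices ordered by ascending p, ties broken by genomic order."""
    tb = table[table["marker"].isin(order_map)].copy()
    tb["col"] = tb["marker"].map(order_map)
    tb = tb.sort_values(["p_value", "col"], kind="mergesort")
    return tb["col"].to_numpy()


def sweep_top_snps(
    geno, blups, gwas_result=None,
    ks=(1, 3, 5, 10, 30, 50, 100, 300, 500),
    repetitions: int = 100,
    k: int = 5,
    seed: int = 0,
    refit_ranking=None,
) -> GsExperimentResult:
    """Accuracy using only the k GWAS-top-ranked markers.

    ``gwas_result`` is an :class:`~dhselect.mlgwas.AssociationResult` (or a
    DataFrame with columns marker/p_value) computed once on the full
    population; markers are ranked by ascending p-value with ties broken by
    genomic order, and GS is restricted to the top k for each grid value.
    Ranking on the full population leaks test phenotypes into marker choice
    and is optimistically biased (it mirrors the published procedure); pass
    ``refit_ranking`` — a callable ``(row_indices, trait) -> ranking table``
    returning per-marker p-values computed from those training rows only —
    for the leakage-free variant.
    """
    Z, blups = _traits_and_matrix(geno, blups)
    marker_ids = (
        np.asarray(geno.marker_ids) if hasattr(geno, "marker_ids")
        else np.arange(Z.shape[1])
    )
    order_map = {mk: j for j, mk in enumerate(marker_ids)}
    if gwas_result is None and refit_ranking is None:
        raise InvalidArgument("need a gwas_result or a refit_ranking callable")
    ranked = None
    if refit_ranking is None:
        table = gwas_result.table if hasattr(gwas_result, "table") else gwas_result
        ranked = _rank_markers(table, order_map)
        if max(ks) > len(ranked):
            raise InvalidArgument(f"k={max(ks)} exceeds {len(ranked)} ranked markers")
    n = Z.shape[0]
    rows = []
    for t, (trait, ys) in enumerate(blups.items()):
        y = ys.to_numpy(float)
        for k_i, topk in enumerate(ks):
            rng = np.random.default_rng(np.random.SeedSequence([seed, t, k_i]))
            accs = []
            for _ in range(repetitions):
                for fold in _kfold_indices(n, k, rng):
                    mask = np.ones(n, dtype=bool)
                    mask[fold] = False
                    if refit_ranking is None:
                        cols = ranked[:topk]
                    else:
                        tab = refit_ranking(np.flatnonzero(mask), trait)
                        tab = tab.table if hasattr(tab, "table") else tab
                        cols = _rank_markers(tab, order_map)[:topk]
                    model = fit_rrblup(Z[mask][:, cols], y[mask])
                    pred = (model.intercept
                            + (Z[fold][:, cols] - model.marker_means)
                            @ model.marker_effects)
                    accs.append(_accuracy(pred, y[fold]))
            accs = np.asarray(accs)
            rows.append({
                "trait": trait, "experiment": "top_snps", "level": topk,
                "mean_accuracy": accs.mean(), "sd_accuracy": accs.std(ddof=1),
                "n": len(accs),
            })
    return GsExperimentResult(pd.DataFrame(rows), "top_snps")
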