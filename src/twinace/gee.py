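"""Gaussian GEE with a robust sandwich variance for twin-clustered data.

Co-twins are correlated, so ordinary least-squares standard errors on
pooled individual-level data are wrong.  Generalized estimating equations
with an identity link solve

    sum_i  X_i' V_i^{-1} (y_i - X_i beta) = 0

over clusters i (twin pairs), with V_i built from a working correlation
(independence or exchangeable), and the Liang-Zeger sandwich

    cov(beta) = B^{-1} M B^{-1},
    B = sum_i X_i' V_i^{-1} X_i,
    M = sum_i X_i' V_i^{-1} r_i r_i' V_i^{-1} X_i

gives standard errors that are valid even when the working correlation is
misspecified.  Used for covariate screening, residualization of trait
scores before twin modelling, and polygenic-score association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeeFit",
    "ScreeningResult",
    "to_long",
    "fit_gee",
    "screen_covariates",
    "residualize",
    "pgs_association",
]

logger = logging.getLogger(__name__)

Z95 = 1.96


@dataclass(frozen=True)
class GeeFit:
    response: str
    predictors: tuple[str, ...]          # includes "intercept"
    coefficients: dict[str, float]
    robust_se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    n_individuals: int
    n_clusters: int
    working_correlation: str
    converged: bool
    standardized: bool
    alpha_exchangeable: float | None = None
    scale: float = 1.0
    robust_cov: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def summary_row(self, predictor: str) -> dict[str, float]:
        return {
            "beta": self.coefficients[predictor],
            "se": self.robust_se[predictor],
            "ci_low": self.ci_low[predictor],
            "ci_high": self.ci_high[predictor],
            "p": self.p_values[predictor],
        }


def to_long(dataset: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Stack the per-twin ``_t1``/``_t2`` columns into one row per twin."""
    frames = []
    for j in (1, 2):
        cols = {f"{c}_t{j}": c for c in columns}
        missing = [c for c in cols if c not in dataset.columns]
        if missing:
            raise KeyError(f"columns not found in pair table: {missing}")
        frame = dataset[["pair_id", "zygosity", *cols]].rename(columns=cols)
        frame.insert(2, "twin", j)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    # pinpoint collinear columns via the QR diagonal
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [names[i] for i in range(len(names)) if diag[i] < 1e-10 * scale]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _solve_beta(
    xs: list[np.ndarray], ys: list[np.ndarray], alpha: float
) -> np.ndarray:
    p = xs[0].shape[1]
    lhs = np.zeros((p, p))
    rhs = np.zeros(p)
    for xi, yi in zip(xs, ys):
        ni = len(yi)
        xv = _apply_rinv(xi, alpha, ni)
        lhs += xv.T @ xi
        rhs += xv.T @ yi
    return np.linalg.solve(lhs, rhs)


def _apply_rinv(a: np.ndarray, alpha: float, ni: int) -> np.ndarray:
    """R^{-1} a for exchangeable correlation R = (1-alpha) I + alpha J."""
    if alpha == 0.0 or ni == 1:
        return a.copy()
    # Sherman-Morrison: R^{-1} = [I - alpha/(1+(ni-1)alpha) J] / (1-alpha)
    colsum = a.sum(axis=0, keepdims=True)
    return (a - alpha / (1.0 + (ni - 1) * alpha) * colsum) / (1.0 - alpha)


def fit_gee(
    dataset: pd.DataFrame,
    response: str,
    predictors: list[str],
    working_correlation: str = "exchangeable",
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GeeFit:
    """Fit an identity-link Gaussian GEE on the pooled individual data.

    With ``standardize`` (default) the response and every predictor are
    z-scored first, so slopes are in SD units and comparable across
    covariates.  Rows with any missing value among response or predictors
    are dropped.  The exchangeable within-pair correlation ``alpha`` is
    re-estimated from Pearson residuals each iteration (Liang-Zeger moment
    estimator) until the coefficients stabilize.
    """
    if working_correlation not in ("independence", "exchangeable"):
        raise ValueError("working_correlation must be independence or exchangeable")
    long = to_long(dataset, [response, *predictors]).dropna(
        subset=[response, *predictors]
    )
    n_ind = len(long)
    clusters = long["pair_id"].to_numpy()
    n_clusters = long["pair_id"].nunique()
    if n_clusters < 2:
        raise ValueError(f"need >= 2 clusters, got {n_clusters}")

    y = long[response].to_numpy(float)
    xmat = long[predictors].to_numpy(float)
    if standardize:
        sds = xmat.std(axis=0, ddof=1)
        zero = [predictors[i] for i in range(len(predictors)) if sds[i] == 0]
        if zero:
            raise ValueError(
                f"design matrix is rank deficient; collinear columns: {zero}"
            )
        xmat = (xmat - xmat.mean(axis=0)) / sds
        y = (y - y.mean()) / y.std(ddof=1)
    names = ["intercept", *predictors]
    x = np.column_stack([np.ones(n_ind), xmat])
    _check_rank(x, names)

    # per-cluster blocks (row order within the long frame)
    order = np.argsort(clusters, kind="stable")
    xo, yo, co = x[order], y[order], clusters[order]
    bounds = np.flatnonzero(np.r_[True, co[1:] != co[:-1], True])
    xs = [xo[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    ys = [yo[a:b] for a, b in zip(bounds[:-1], bounds[1:])]

    p = x.shape[1]
    alpha = 0.0
    beta = _solve_beta(xs, ys, 0.0)
    converged = True
    if working_correlation == "exchangeable":
        converged = False
        for _ in range(max_iter):
            resid = [yi - xi @ beta for xi, yi in zip(xs, ys)]
            nres = sum(len(r) for r in resid)
            phi = sum(float(r @ r) for r in resid) / (nres - p)
            num, npairs = 0.0, 0
            for r in resid:
                ni = len(r)
                if ni > 1:
                    num += (r.sum() ** 2 - r @ r) / 2.0
                    npairs += ni * (ni - 1) // 2
            alpha_new = num / ((npairs - p) * phi) if npairs > p else 0.0
            alpha_new = float(np.clip(alpha_new, -0.99, 0.99))
            beta_new = _solve_beta(xs, ys, alpha_new)
            if np.max(np.abs(beta_new - beta)) < tol and abs(alpha_new - alpha) < tol:
                beta, alpha = beta_new, alpha_new
                converged = True
                break
            beta, alpha = beta_new, alpha_new
        if not converged:
            logger.warning("exchangeable alpha update did not converge")

    # sandwich
    bread = np.zeros((p, p))
    meat = np.zeros((p, p))
    for xi, yi in zip(xs, ys):
        ni = len(yi)
        xv = _apply_rinv(xi, alpha, ni)
        bread += xv.T @ xi
        score = xv.T @ (yi - xi @ beta)
        meat += np.outer(score, score)
    binv = np.linalg.inv(bread)
    cov = binv @ meat @ binv
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.diag(cov))

    resid = [yi - xi @ beta for xi, yi in zip(xs, ys)]
    nres = sum(len(r) for r in resid)
    phi = sum(float(r @ r) for r in resid) / (nres - p)

    coef = dict(zip(names, beta.tolist()))
    ses = dict(zip(names, se.tolist()))
    pvals = {
        k: float(2 * stats.norm.sf(abs(coef[k]) / ses[k])) if ses[k] > 0 else np.nan
        for k in names
    }
    return GeeFit(
        response=response,
        predictors=tuple(names),
        coefficients=coef,
        robust_se=ses,
        ci_low={k: coef[k] - Z95 * ses[k] for k in names},
        ci_high={k: coef[k] + Z95 * ses[k] for k in names},
        p_values=pvals,
        n_individuals=n_ind,
        n_clusters=n_clusters,
        working_correlation=working_correlation,
        converged=converged,
        standardized=standardize,
        alpha_exchangeable=alpha if working_correlation == "exchangeable" else None,
        scale=phi,
        robust_cov=cov,
    )


@dataclass(frozen=True)
class ScreeningResult:
    fits: dict[str, GeeFit]                 # per trait
    p_values: dict[str, dict[str, float]]   # trait -> covariate -> p
    retained: tuple[str, ...]
    alpha: float
    mode: str


def screen_covariates(
    dataset: pd.DataFrame,
    traits: list[str],
    candidate_covariates: list[str],
    alpha: float = 0.05,
    working_correlation: str = "exchangeable",
    mode: str = "joint",
) -> ScreeningResult:
    """Flag covariates associated with any trait at level ``alpha``.

    ``mode='joint'`` (default) tests each covariate in one model containing
    all candidates; ``mode='marginal'`` fits one single-covariate model per
    candidate.  A covariate is retained when its robust Wald p-value is
    <= alpha for at least one trait.
    """
    if mode not in ("joint", "marginal"):
        raise ValueError("mode must be 'joint' or 'marginal'")
    fits: dict[str, GeeFit] = {}
    pvals: dict[str, dict[str, float]] = {}
    for trait in traits:
        if mode == "joint":
            fit = fit_gee(dataset, trait, candidate_covariates, working_correlation)
            fits[trait] = fit
            pvals[trait] = {c: fit.p_values[c] for c in candidate_covariates}
        else:
            pvals[trait] = {}
            for c in candidate_covariates:
                fit = fit_gee(dataset, trait, [c], working_correlation)
                pvals[trait][c] = fit.p_values[c]
            fits[trait] = fit
    retained = tuple(
        c for c in candidate_covariates
        if any(pvals[t][c] <= alpha for t in traits)
    )
    return ScreeningResult(fits=fits, p_values=pvals, retained=retained,
                           alpha=alpha, mode=mode)


def residualize(
    dataset: pd.DataFrame,
    trait: str,
    covariates: list[str],
) -> pd.DataFrame:
    """Replace a trait with residuals from a pooled linear adjustment.

    One fit over all individuals (independence working correlation, i.e.
    pooled least squares, which makes the residuals exactly orthogonal to
    every regressor and mean zero).  A twin with an observed trait but a
    missing covariate gets a missing residual; the count is logged.
    """
    fit = fit_gee(dataset, trait, covariates,
                  working_correlation="independence", standardize=False)
    beta = np.array([fit.coefficients[k] for k in fit.predictors])
    out = dataset.copy()
    n_lost = 0
    for j in (1, 2):
        ycol = f"{trait}_t{j}"
        y = out[ycol].to_numpy(float)
        xcols = np.column_stack(
            [np.ones(len(out))] + [out[f"{c}_t{j}"].to_numpy(float) for c in covariates]
        )
        fitted = xcols @ beta
        resid = y - fitted
        lost = ~np.isnan(y) & np.isnan(fitted)
        n_lost += int(lost.sum())
        out[ycol] = resid
    if n_lost:
        logger.info(
            "residualize(%s): %d observed values dropped for missing covariates",
            trait, n_lost,
        )
    return out


def pgs_association(
    dataset: pd.DataFrame,
    trait: str,
    score_column: str,
    pc_columns: list[str],
    working_correlation: str = "exchangeable",
) -> GeeFit:
    """Association between a polygenic score and a trait, adjusting for
    ancestry principal components; robust to twin clustering.  P-values are
    reported without multiple-testing correction by design."""
    return fit_gee(
        dataset, trait, [score_column, *pc_columns],
        working_correlation=working_correlation,
    )
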