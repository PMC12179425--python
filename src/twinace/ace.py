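"""Full-information maximum likelihood (FIML) twin models.

Each twin pair contributes the multivariate-normal log-density of exactly
its observed trait values (rows/columns for missing entries deleted), so
incomplete pairs enter the likelihood without imputation.  On top of that
likelihood this module fits:

* the fully saturated model (free means and covariances per zygosity),
* constrained saturated submodels used to test the classical twin-design
  assumptions (equal means/variances across twin order and zygosity),
* the univariate ACE model, and
* the bivariate correlated-factors ACE model (per-trait A/C/E plus the
  aetiological correlations rA, rC, rE; 11 parameters),

with likelihood-ratio comparisons, AIC/BIC, and likelihood-based (profile)
confidence intervals found by bisection on the profile -2 log-likelihood.

Parameterization: component standard deviations are unconstrained (the
variance is the square, so a2 = 0 is reachable without a hard bound) and
correlations go through tanh, keeping them inside (-1, 1).  Optimization is
quasi-Newton (L-BFGS-B, numerical gradients) from moment-based starting
values (Falconer estimates), with seeded random restarts when a fit fails.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .simulate import AceParams, build_pair_covariance

__all__ = [
    "PreparedPairs",
    "FitResult",
    "ModelComparison",
    "ProfileCI",
    "prepare_pairs",
    "fiml_minus2ll",
    "fit_saturated",
    "assumption_tests",
    "fit_univariate_ace",
    "fit_bivariate_correlated_factors",
    "compare_models",
    "profile_ci",
]

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))
ZYG_INDEX = {"MZ": 0, "DZ": 1}

#: default convergence tolerance on -2LL
M2LL_TOL = 1e-8


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreparedPairs:
    """Pair-level trait matrices grouped by zygosity and missingness pattern.

    ``groups`` holds (zygosity index, observed-column index array, value
    matrix) triples; grouping by pattern lets the likelihood factor each
    sub-covariance once per group instead of once per pair.
    """

    traits: tuple[str, ...]
    groups: tuple[tuple[int, np.ndarray, np.ndarray], ...]
    raw: dict[str, np.ndarray] = field(repr=False)
    n_obs: int = 0
    n_pairs: int = 0
    n_pairs_by_zyg: tuple[int, int] = (0, 0)

    @property
    def dim(self) -> int:
        return 2 * len(self.traits)


def prepare_pairs(dataset: pd.DataFrame, traits: Sequence[str]) -> PreparedPairs:
    traits = tuple(traits)
    cols = [f"{t}_t1" for t in traits] + [f"{t}_t2" for t in traits]
    missing = [c for c in cols if c not in dataset.columns]
    if missing:
        raise KeyError(f"trait columns not found: {missing}")
    groups: list[tuple[int, np.ndarray, np.ndarray]] = []
    raw: dict[str, np.ndarray] = {}
    n_obs = 0
    n_pairs = 0
    by_zyg = [0, 0]
    for zyg, zi in ZYG_INDEX.items():
        block = dataset.loc[dataset["zygosity"] == zyg, cols].to_numpy(float)
        observed = ~np.isnan(block)
        keep = observed.any(axis=1)
        block, observed = block[keep], observed[keep]
        raw[zyg] = block
        n_pairs += len(block)
        by_zyg[zi] = len(block)
        n_obs += int(observed.sum())
        if len(block) == 0:
            continue
        patterns, inverse = np.unique(observed, axis=0, return_inverse=True)
        for p_idx in range(len(patterns)):
            rows = block[inverse == p_idx]
            obs_cols = np.flatnonzero(patterns[p_idx])
            groups.append((zi, obs_cols, rows[:, obs_cols]))
    if n_pairs == 0:
        raise ValueError("no informative pairs in dataset")
    return PreparedPairs(
        traits=traits, groups=tuple(groups), raw=raw,
        n_obs=n_obs, n_pairs=n_pairs, n_pairs_by_zyg=(by_zyg[0], by_zyg[1]),
    )


def _minus2ll_moments(
    means: np.ndarray, covs: np.ndarray, prep: PreparedPairs
) -> float:
    """-2 log-likelihood given per-zygosity mean vectors and covariances.

    ``means``: (2, 2T); ``covs``: (2, 2T, 2T), indexed MZ=0, DZ=1.  Returns
    +inf when an implied covariance is not positive definite on an observed
    subspace, which keeps optimizers safe.
    """
    total = 0.0
    for zi, obs, values in prep.groups:
        mu = means[zi][obs]
        sigma = covs[zi][np.ix_(obs, obs)]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return np.inf
        diff = values - mu
        sol = solve_triangular(chol, diff.T, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        d = len(obs)
        total += len(values) * (d * LOG_2PI + logdet) + float(np.sum(sol * sol))
    return total


def fiml_minus2ll(
    params: AceParams,
    dataset: pd.DataFrame | PreparedPairs,
    traits: Sequence[str] | None = None,
) -> float:
    """FIML -2 log-likelihood of an ACE parameterization on a pair table."""
    if isinstance(dataset, PreparedPairs):
        prep = dataset
    else:
        prep = prepare_pairs(dataset, traits if traits is not None else params.traits)
    mu = np.concatenate([params.means, params.means]).astype(float)
    means = np.stack([mu, mu])
    covs = np.stack([
        build_pair_covariance(params, "MZ"),
        build_pair_covariance(params, "DZ"),
    ])
    return _minus2ll_moments(means, covs, prep)


# ---------------------------------------------------------------------------
# model structures
# ---------------------------------------------------------------------------

class _Structure:
    """A parameterized map theta -> (per-zygosity means, covariances)."""

    name: str
    param_names: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def start(self, prep: PreparedPairs) -> np.ndarray:
        raise NotImplementedError

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def params_dict(self, theta: np.ndarray) -> dict[str, float]:
        raise NotImplementedError


def _complete_moments(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean (per column, available-case) and ML covariance
    (complete rows, regularized toward PD)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(raw, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    complete = raw[~np.isnan(raw).any(axis=1)]
    d = raw.shape[1]
    if len(complete) > d:
        cov = np.cov(complete, rowvar=False, ddof=0)
        cov = np.atleast_2d(cov)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(raw, axis=0)
        cov = np.diag(np.where(np.isnan(var) | (var <= 0), 1.0, var))
    w, v = np.linalg.eigh(cov)
    floor = max(1e-6, 1e-8 * max(w.max(), 1.0))
    w = np.clip(w, floor, None)
    return mu, (v * w) @ v.T


def _falconer_start(prep: PreparedPairs, trait_idx: int) -> tuple[float, float, float, float, float]:
    """(mean, a2, c2, e2, total_var) moment-based starting values."""
    t = trait_idx
    t2 = trait_idx + len(prep.traits)
    corrs = {}
    variances = []
    means = []
    for zyg in ("MZ", "DZ"):
        raw = prep.raw[zyg][:, [t, t2]]
        complete = raw[~np.isnan(raw).any(axis=1)]
        pooled = raw[~np.isnan(raw)]
        means.append(np.mean(pooled) if len(pooled) else 0.0)
        variances.append(np.var(pooled, ddof=1) if len(pooled) > 1 else 1.0)
        if len(complete) >= 3:
            x = np.concatenate([complete[:, 0], complete[:, 1]])
            y = np.concatenate([complete[:, 1], complete[:, 0]])
            sd = np.std(x)
            corrs[zyg] = float(np.corrcoef(x, y)[0, 1]) if sd > 0 else 0.0
        else:
            corrs[zyg] = 0.5
    rmz, rdz = corrs["MZ"], corrs["DZ"]
    a = 2.0 * (rmz - rdz)
    c = 2.0 * rdz - rmz
    e = 1.0 - rmz
    props = np.clip([a, c, e], 0.02, None)
    props = props / props.sum()
    total = float(np.mean(variances))
    return float(np.mean(means)), props[0] * total, props[1] * total, props[2] * total, total


class UnivariateACE(_Structure):
    """Mean + A/C/E variance components for one trait; k = 4 when free."""

    NATURAL = ("mean", "a2", "c2", "e2")

    def __init__(self, trait: str, fixed: dict[str, float] | None = None):
        self.trait = trait
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(self.NATURAL)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        self.free = tuple(n for n in self.NATURAL if n not in self.fixed)
        self.param_names = self.free
        self.name = f"ace_univariate[{trait}]"
        if self.fixed:
            self.name += "{" + ",".join(f"{k}={v}" for k, v in sorted(self.fixed.items())) + "}"

    def _natural(self, theta: np.ndarray) -> dict[str, float]:
        vals = dict(self.fixed)
        for name, val in zip(self.free, theta):
            # variances are parameterized through their square root
            vals[name] = float(val * val) if name != "mean" else float(val)
        return vals

    def start(self, prep: PreparedPairs) -> np.ndarray:
        idx = prep.traits.index(self.trait)
        mean, a2, c2, e2, _ = _falconer_start(prep, idx)
        full = {"mean": mean, "a2": np.sqrt(a2), "c2": np.sqrt(c2), "e2": np.sqrt(e2)}
        return np.array([full[n] for n in self.free])

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nat = self._natural(theta)
        a2, c2, e2, m = nat["a2"], nat["c2"], nat["e2"], nat["mean"]
        v = a2 + c2 + e2
        means = np.full((2, 2), m)
        covs = np.empty((2, 2, 2))
        for zi, share in ((0, 1.0), (1, 0.5)):
            cross = share * a2 + c2
            covs[zi] = [[v, cross], [cross, v]]
        return means, covs

    def params_dict(self, theta: np.ndarray) -> dict[str, float]:
        nat = self._natural(theta)
        return {f"{n}_{self.trait}" if n != "mean" else f"mean_{self.trait}": nat[n]
                for n in self.NATURAL}


class BivariateACE(_Structure):
    """Correlated-factors bivariate ACE model; k = 11 when free.

    Per-trait means and A/C/E component variances plus the aetiological
    correlations rA, rC, rE between like-type factors across traits.
    """

    def __init__(self, traits: Sequence[str], fixed: dict[str, float] | None = None):
        if len(traits) != 2:
            raise ValueError("BivariateACE needs exactly two traits")
        self.traits = tuple(traits)
        natural = []
        for t in self.traits:
            natural.append(f"mean_{t}")
        for t in self.traits:
            natural += [f"a2_{t}", f"c2_{t}", f"e2_{t}"]
        natural += ["r_a", "r_c", "r_e"]
        self.NATURAL = tuple(natural)
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(self.NATURAL)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        self.free = tuple(n for n in self.NATURAL if n not in self.fixed)
        self.param_names = self.free
        self.name = f"ace_correlated_factors[{self.traits[0]},{self.traits[1]}]"
        if self.fixed:
            self.name += "{" + ",".join(f"{k}={v}" for k, v in sorted(self.fixed.items())) + "}"

    def _natural(self, theta: np.ndarray) -> dict[str, float]:
        vals = dict(self.fixed)
        for name, val in zip(self.free, theta):
            if name.startswith("r_"):
                vals[name] = float(np.tanh(val))
            elif name.startswith("mean_"):
                vals[name] = float(val)
            else:
                vals[name] = float(val * val)
        return vals

    def _ace_params(self, theta: np.ndarray) -> AceParams:
        nat = self._natural(theta)
        t1, t2 = self.traits
        return AceParams(
            traits=self.traits,
            means=(nat[f"mean_{t1}"], nat[f"mean_{t2}"]),
            a2=(nat[f"a2_{t1}"], nat[f"a2_{t2}"]),
            c2=(nat[f"c2_{t1}"], nat[f"c2_{t2}"]),
            e2=(max(nat[f"e2_{t1}"], 1e-12), max(nat[f"e2_{t2}"], 1e-12)),
            r_a=nat["r_a"], r_c=nat["r_c"], r_e=nat["r_e"],
        )

    def start(self, prep: PreparedPairs) -> np.ndarray:
        comps = [_falconer_start(prep, i) for i in range(2)]
        # moment starts for the factor correlations from cross-twin
        # cross-trait and phenotypic correlations
        ctct = {}
        for zyg in ("MZ", "DZ"):
            raw = prep.raw[zyg]
            a1, b1, a2_, b2_ = raw[:, 0], raw[:, 1], raw[:, 2], raw[:, 3]
            x = np.concatenate([a1, a2_])
            y = np.concatenate([b2_, b1])
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                ctct[zyg] = float(np.corrcoef(x[ok], y[ok])[0, 1])
            else:
                ctct[zyg] = 0.0
        allraw = np.vstack([prep.raw["MZ"], prep.raw["DZ"]])
        px = np.concatenate([allraw[:, 0], allraw[:, 2]])
        py = np.concatenate([allraw[:, 1], allraw[:, 3]])
        ok = ~np.isnan(px) & ~np.isnan(py)
        r_ph = float(np.corrcoef(px[ok], py[ok])[0, 1]) if ok.sum() >= 3 else 0.0

        tot = [c[4] for c in comps]
        prop = [(c[1] / c[4], c[2] / c[4], c[3] / c[4]) for c in comps]
        sq = lambda i, j: np.sqrt(max(prop[0][j] * prop[1][j], 1e-4))
        ra0 = 2.0 * (ctct["MZ"] - ctct["DZ"]) / sq(0, 0)
        rc0 = (2.0 * ctct["DZ"] - ctct["MZ"]) / sq(0, 1)
        re0 = (r_ph - ctct["MZ"]) / sq(0, 2)
        clip = lambda r: float(np.clip(r, -0.9, 0.9))
        full = {}
        for i, t in enumerate(self.traits):
            full[f"mean_{t}"] = comps[i][0]
            full[f"a2_{t}"] = np.sqrt(comps[i][1])
            full[f"c2_{t}"] = np.sqrt(comps[i][2])
            full[f"e2_{t}"] = np.sqrt(comps[i][3])
        full["r_a"] = np.arctanh(clip(ra0))
        full["r_c"] = np.arctanh(clip(rc0))
        full["r_e"] = np.arctanh(clip(re0))
        return np.array([full[n] for n in self.free])

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        params = self._ace_params(theta)
        mu = np.concatenate([params.means, params.means]).astype(float)
        means = np.stack([mu, mu])
        covs = np.stack([
            build_pair_covariance(params, "MZ", validate=False),
            build_pair_covariance(params, "DZ", validate=False),
        ])
        return means, covs

    def params_dict(self, theta: np.ndarray) -> dict[str, float]:
        return self._natural(theta)


def _cell_index(equal_twins: bool, equal_zyg: bool) -> tuple[dict[tuple[int, int], int], list[str]]:
    """Map (zygosity, twin) cells to shared parameter slots."""
    mapping: dict[tuple[int, int], int] = {}
    names: list[str] = []
    keys: dict[tuple[int, int], int] = {}
    for zi, zyg in enumerate(("MZ", "DZ")):
        for tw in (0, 1):
            key = (0 if equal_zyg else zi, 0 if equal_twins else tw)
            if key not in keys:
                keys[key] = len(names)
                ztag = "both" if equal_zyg else ("MZ", "DZ")[key[0]]
                ttag = "both" if equal_twins else f"t{key[1] + 1}"
                names.append(f"{ztag}_{ttag}")
            mapping[(zi, tw)] = keys[key]
    return mapping, names


class UnivariateSaturated(_Structure):
    """Free means/SDs per zygosity and twin order plus per-zygosity twin
    correlation (k = 10), with optional equality constraints used by the
    twin-design assumption tests."""

    def __init__(
        self,
        trait: str,
        equal_means_twins: bool = False,
        equal_means_zyg: bool = False,
        equal_vars_twins: bool = False,
        equal_vars_zyg: bool = False,
    ):
        self.trait = trait
        self.mean_map, mean_names = _cell_index(equal_means_twins, equal_means_zyg)
        self.sd_map, sd_names = _cell_index(equal_vars_twins, equal_vars_zyg)
        self.n_means = len(mean_names)
        self.n_sds = len(sd_names)
        self.param_names = tuple(
            [f"mean_{n}" for n in mean_names]
            + [f"log_sd_{n}" for n in sd_names]
            + ["z_r_MZ", "z_r_DZ"]
        )
        tags = [
            name for flag, name in [
                (equal_means_twins, "=m_twins"), (equal_means_zyg, "=m_zyg"),
                (equal_vars_twins, "=v_twins"), (equal_vars_zyg, "=v_zyg"),
            ] if flag
        ]
        self.name = f"saturated[{trait}]" + ("".join(tags) if tags else "")

    def start(self, prep: PreparedPairs) -> np.ndarray:
        idx = prep.traits.index(self.trait)
        t2 = idx + len(prep.traits)
        means = np.zeros(self.n_means)
        counts_m = np.zeros(self.n_means)
        logsd = np.zeros(self.n_sds)
        counts_s = np.zeros(self.n_sds)
        zr = []
        for zi, zyg in enumerate(("MZ", "DZ")):
            raw = prep.raw[zyg][:, [idx, t2]]
            for tw in (0, 1):
                col = raw[:, tw]
                col = col[~np.isnan(col)]
                m = np.mean(col) if len(col) else 0.0
                s = np.std(col, ddof=1) if len(col) > 1 else 1.0
                slot = self.mean_map[(zi, tw)]
                means[slot] += m
                counts_m[slot] += 1
                vslot = self.sd_map[(zi, tw)]
                logsd[vslot] += np.log(max(s, 1e-6))
                counts_s[vslot] += 1
            complete = raw[~np.isnan(raw).any(axis=1)]
            if len(complete) >= 3 and complete.std(axis=0).min() > 0:
                r = float(np.corrcoef(complete[:, 0], complete[:, 1])[0, 1])
            else:
                r = 0.5
            zr.append(np.arctanh(np.clip(r, -0.95, 0.95)))
        return np.concatenate([means / counts_m, logsd / counts_s, zr])

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m_vals = theta[: self.n_means]
        sd_vals = np.exp(theta[self.n_means: self.n_means + self.n_sds])
        r_vals = np.tanh(theta[self.n_means + self.n_sds:])
        means = np.empty((2, 2))
        covs = np.empty((2, 2, 2))
        for zi in (0, 1):
            s1 = sd_vals[self.sd_map[(zi, 0)]]
            s2 = sd_vals[self.sd_map[(zi, 1)]]
            r = r_vals[zi]
            means[zi] = [m_vals[self.mean_map[(zi, 0)]], m_vals[self.mean_map[(zi, 1)]]]
            covs[zi] = [[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]]
        return means, covs

    def params_dict(self, theta: np.ndarray) -> dict[str, float]:
        out = {}
        for name, val in zip(self.param_names, theta):
            if name.startswith("log_sd_"):
                out["var_" + name[len("log_sd_"):]] = float(np.exp(2 * val))
            elif name.startswith("z_r_"):
                out["r_" + name[len("z_r_"):]] = float(np.tanh(val))
            else:
                out[name] = float(val)
        return out


class BivariateSaturated(_Structure):
    """Free 4-dimensional mean vector and covariance per zygosity
    (8 + 20 = 28 parameters); the covariance is parameterized by its
    Cholesky factor so any PD matrix is reachable."""

    def __init__(self, traits: Sequence[str]):
        if len(traits) != 2:
            raise ValueError("BivariateSaturated needs exactly two traits")
        self.traits = tuple(traits)
        names = []
        labels = [f"{t}_t{j}" for j in (1, 2) for t in self.traits]
        self.labels = [f"{t}_t1" for t in self.traits] + [f"{t}_t2" for t in self.traits]
        for zyg in ("MZ", "DZ"):
            names += [f"mean_{zyg}_{lab}" for lab in self.labels]
        self.tril = np.tril_indices(4)
        for zyg in ("MZ", "DZ"):
            names += [
                f"chol_{zyg}_{i}{j}" for i, j in zip(*self.tril)
            ]
        self.param_names = tuple(names)
        self.name = f"saturated[{self.traits[0]},{self.traits[1]}]"
        del labels

    def start(self, prep: PreparedPairs) -> np.ndarray:
        parts_mu, parts_chol = [], []
        for zyg in ("MZ", "DZ"):
            mu, cov = _complete_moments(prep.raw[zyg])
            parts_mu.append(mu)
            parts_chol.append(np.linalg.cholesky(cov)[self.tril])
        return np.concatenate(parts_mu + parts_chol)

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        means = theta[:8].reshape(2, 4).copy()
        covs = np.empty((2, 4, 4))
        offset = 8
        n_chol = len(self.tril[0])
        for zi in (0, 1):
            chol = np.zeros((4, 4))
            chol[self.tril] = theta[offset + zi * n_chol: offset + (zi + 1) * n_chol]
            covs[zi] = chol @ chol.T
        return means, covs

    def params_dict(self, theta: np.ndarray) -> dict[str, float]:
        out = dict(zip(self.param_names[:8], theta[:8].astype(float)))
        _, covs = self.implied(theta)
        for zi, zyg in enumerate(("MZ", "DZ")):
            for i in range(4):
                for j in range(i + 1):
                    out[f"cov_{zyg}_{self.labels[i]}_{self.labels[j]}"] = float(covs[zi][i, j])
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    model: str
    params: dict[str, float]
    minus2ll: float
    k: int
    n_obs: int
    n_pairs: int
    df: int
    aic: float
    bic: float
    converged: bool
    n_restarts_used: int
    notes: tuple[str, ...] = ()
    ci: dict[str, "ProfileCI"] | None = None
    theta: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    structure: _Structure = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    prepared: PreparedPairs = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "minus2ll": float(self.minus2ll),
            "k": self.k,
            "n_obs": self.n_obs,
            "n_pairs": self.n_pairs,
            "df": self.df,
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "notes": list(self.notes),
        }
        if self.ci:
            out["ci"] = {
                k: {"low": v.low, "high": v.high,
                    "low_at_bound": v.low_at_bound, "high_at_bound": v.high_at_bound}
                for k, v in self.ci.items()
            }
        return out


def _fit_structure(
    structure: _Structure,
    prep: PreparedPairs,
    n_restarts: int = 10,
    seed: int = 0,
    maxiter: int = 2000,
    fast: bool = False,
) -> FitResult:
    def objective(theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)):
            return np.inf
        try:
            means, covs = structure.implied(theta)
        except ValueError:
            return np.inf
        return _minus2ll_moments(means, covs, prep)

    theta0 = structure.start(prep)

    # "fast" trades the last digits of -2LL for wall time: right for
    # Monte-Carlo replicates where sampling error dwarfs optimizer error
    jac = "2-point" if fast else "3-point"
    opts = (
        {"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6}
        if fast
        else {"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-8}
    )

    def solve(x0: np.ndarray):
        with warnings.catch_warnings():
            # +inf objective values outside the PD region are expected
            warnings.simplefilter("ignore", RuntimeWarning)
            return optimize.minimize(
                objective, x0, method="L-BFGS-B", jac=jac, options=opts,
            )

    best = solve(theta0)
    restarts = 0
    rng = np.random.default_rng(seed)
    while (not best.success or not np.isfinite(best.fun)) and restarts < n_restarts:
        restarts += 1
        jitter = theta0 * (1.0 + 0.2 * rng.standard_normal(theta0.shape))
        jitter += 0.1 * rng.standard_normal(theta0.shape)
        trial = solve(jitter)
        if np.isfinite(trial.fun) and (not np.isfinite(best.fun) or trial.fun < best.fun - M2LL_TOL or (trial.success and not best.success and trial.fun < best.fun + M2LL_TOL)):
            best = trial

    theta_hat = best.x
    m2ll = float(best.fun)
    params = structure.params_dict(theta_hat)
    notes = []
    for name, val in params.items():
        if (name.startswith("a2_") or name.startswith("c2_")) and 0 <= val < 1e-8:
            notes.append(f"boundary solution: {name} ~ 0")
    k = structure.k
    return FitResult(
        model=structure.name,
        params=params,
        minus2ll=m2ll,
        k=k,
        n_obs=prep.n_obs,
        n_pairs=prep.n_pairs,
        df=prep.n_obs - k,
        aic=m2ll + 2 * k,
        bic=m2ll + k * np.log(prep.n_pairs),
        converged=bool(best.success and np.isfinite(m2ll)),
        n_restarts_used=restarts,
        notes=tuple(notes),
        theta=theta_hat,
        structure=structure,
        prepared=prep,
    )


def _as_prepared(dataset, traits: Sequence[str]) -> PreparedPairs:
    if isinstance(dataset, PreparedPairs):
        return dataset
    return prepare_pairs(dataset, traits)


def _require_both_zygosities(prep: PreparedPairs, what: str) -> None:
    if min(prep.n_pairs_by_zyg) < 2:
        raise ValueError(
            f"{what} requires pairs of both zygosities "
            f"(got MZ={prep.n_pairs_by_zyg[0]}, DZ={prep.n_pairs_by_zyg[1]}): "
            "A and C are not jointly identified otherwise"
        )


def fit_saturated(
    dataset, traits: Sequence[str], n_restarts: int = 10, seed: int = 0
) -> FitResult:
    """ML fit of the unconstrained means-and-covariances model.

    With complete data the moment-based starting values are already the
    MLE, so the optimizer verifies rather than searches."""
    traits = tuple(traits)
    prep = _as_prepared(dataset, traits)
    if len(traits) == 1:
        structure: _Structure = UnivariateSaturated(traits[0])
    else:
        structure = BivariateSaturated(traits)
    return _fit_structure(structure, prep, n_restarts=n_restarts, seed=seed)


@dataclass(frozen=True)
class ModelComparison:
    parent_model: str
    nested_model: str
    delta_ll: float
    delta_df: int
    p_value: float
    delta_aic: float
    delta_bic: float
    preferred: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_models(fit_parent: FitResult, fit_nested: FitResult) -> ModelComparison:
    """Likelihood-ratio comparison of a nested model against its parent.

    ``delta_ll`` is the -2LL increase of the constrained model, referred to
    a chi-square with ``delta_df`` = k_parent - k_nested degrees of freedom.
    ``preferred`` follows the BIC alone (lower wins), the conservative rule
    used for model selection; the LRT p-value is reported for transparency.
    """
    if fit_nested.k >= fit_parent.k:
        raise ValueError(
            "models are not nested: the nested model must have fewer parameters"
        )
    if fit_nested.n_obs != fit_parent.n_obs:
        raise ValueError("models were fitted to different data")
    delta = fit_nested.minus2ll - fit_parent.minus2ll
    if delta < -1e-6:
        raise ValueError(
            f"nested model fits better than its parent (delta -2LL = {delta:.3g}); "
            "models are not nested or the parent fit did not converge"
        )
    delta = max(delta, 0.0)
    ddf = fit_parent.k - fit_nested.k
    return ModelComparison(
        parent_model=fit_parent.model,
        nested_model=fit_nested.model,
        delta_ll=float(delta),
        delta_df=ddf,
        p_value=float(stats.chi2.sf(delta, ddf)),
        delta_aic=float(fit_nested.aic - fit_parent.aic),
        delta_bic=float(fit_nested.bic - fit_parent.bic),
        preferred=fit_nested.model if fit_nested.bic <= fit_parent.bic else fit_parent.model,
    )


#: cumulative equality constraints of the four assumption submodels
ASSUMPTION_LADDER = (
    ("1_equal_means_across_twins", {"equal_means_twins": True}),
    ("2_equal_means_across_zygosity", {"equal_means_twins": True,
                                       "equal_means_zyg": True}),
    ("3_equal_variances_across_twins", {"equal_means_twins": True,
                                        "equal_means_zyg": True,
                                        "equal_vars_twins": True}),
    ("4_equal_variances_across_zygosity", {"equal_means_twins": True,
                                           "equal_means_zyg": True,
                                           "equal_vars_twins": True,
                                           "equal_vars_zyg": True}),
)


def assumption_tests(
    dataset, trait: str, n_restarts: int = 10, seed: int = 0
) -> list[ModelComparison]:
    """Test the twin-design equality assumptions for one trait.

    Four progressively constrained saturated submodels (means equal across
    twin order, then across zygosity; variances likewise) are each compared
    to the fully saturated model by LRT.  A significant test is a warning,
    not an error: the pipeline reports it and continues.
    """
    prep = _as_prepared(dataset, (trait,))
    saturated = _fit_structure(UnivariateSaturated(trait), prep,
                               n_restarts=n_restarts, seed=seed)
    results = []
    for label, constraints in ASSUMPTION_LADDER:
        sub = _fit_structure(UnivariateSaturated(trait, **constraints), prep,
                             n_restarts=n_restarts, seed=seed)
        comp = compare_models(saturated, sub)
        comp = replace(comp, nested_model=f"{label}[{trait}]")
        if comp.p_value < 0.05:
            warnings.warn(
                f"twin-model assumption check {label} rejected for {trait} "
                f"(p = {comp.p_value:.3g})",
                stacklevel=2,
            )
        results.append(comp)
    return results


def fit_univariate_ace(
    dataset, trait: str, n_restarts: int = 10, seed: int = 0,
    fixed: dict[str, float] | None = None,
) -> FitResult:
    """FIML univariate ACE fit (mean equated across twins and zygosity)."""
    prep = _as_prepared(dataset, (trait,))
    _require_both_zygosities(prep, "the ACE model")
    return _fit_structure(UnivariateACE(trait, fixed=fixed), prep,
                          n_restarts=n_restarts, seed=seed)


def fit_bivariate_correlated_factors(
    dataset, traits: Sequence[str] = ("motor", "social_communication"),
    n_restarts: int = 10, seed: int = 0,
    fixed: dict[str, float] | None = None,
    fast: bool = False,
) -> FitResult:
    """FIML bivariate correlated-factors ACE fit (11 parameters)."""
    traits = tuple(traits)
    prep = _as_prepared(dataset, traits)
    _require_both_zygosities(prep, "the bivariate ACE model")
    return _fit_structure(BivariateACE(traits, fixed=fixed), prep,
                          n_restarts=n_restarts, seed=seed, fast=fast)


# ---------------------------------------------------------------------------
# profile (likelihood-based) confidence intervals
# ---------------------------------------------------------------------------

class ProfileCI(NamedTuple):
    low: float
    high: float
    low_at_bound: bool = False
    high_at_bound: bool = False


def _make_target(structure: _Structure, parameter: str) -> tuple[Callable[[np.ndarray], float], tuple[float, float]]:
    """Scalar function of theta for a natural or standardized parameter,
    with its domain."""

    def from_params(name):
        def g(theta):
            return structure.params_dict(theta)[name]
        return g

    if parameter in ("r_a", "r_c", "r_e") or parameter.startswith("r_"):
        return from_params(parameter), (-1.0, 1.0)

    for prefix in ("A_", "C_", "E_"):
        if parameter.startswith(prefix):
            trait = parameter[len(prefix):]
            comp = prefix[0].lower() + "2"

            def g(theta, trait=trait, comp=comp):
                p = structure.params_dict(theta)
                total = p[f"a2_{trait}"] + p[f"c2_{trait}"] + p[f"e2_{trait}"]
                return p[f"{comp}_{trait}"] / total

            return g, (0.0, 1.0)

    if parameter.startswith(("a2_", "c2_", "e2_", "var_")):
        return from_params(parameter), (0.0, np.inf)
    # means and covariances: unbounded
    return from_params(parameter), (-np.inf, np.inf)


def profile_ci(
    fit: FitResult,
    parameter: str,
    level: float = 0.95,
    tol: float = 1e-4,
) -> ProfileCI:
    """Likelihood-based CI: the set of values at which the profile -2LL
    (nuisance parameters re-optimized) exceeds its minimum by the
    chi-square(1) quantile of ``level``.  Bounds that run into the parameter
    domain (a correlation hitting -1, a proportion hitting 0) are returned
    as the domain edge and flagged.
    """
    if fit.theta is None or fit.structure is None or fit.prepared is None:
        raise ValueError("fit does not carry its optimization state")
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    structure, prep = fit.structure, fit.prepared
    crit = float(stats.chi2.ppf(level, 1))
    threshold = fit.minus2ll + crit
    g, (dom_lo, dom_hi) = _make_target(structure, parameter)
    ghat = g(fit.theta)

    def objective(theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)):
            return np.inf
        try:
            means, covs = structure.implied(theta)
        except ValueError:
            return np.inf
        return _minus2ll_moments(means, covs, prep)

    warm = {"x": fit.theta.copy()}

    def prof(c: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                objective, warm["x"], method="SLSQP",
                constraints=[{"type": "eq", "fun": lambda th: g(th) - c}],
                options={"maxiter": 300, "ftol": 1e-10},
            )
            val = res.fun if np.isfinite(res.fun) else np.inf
            retry = optimize.minimize(
                objective, fit.theta, method="SLSQP",
                constraints=[{"type": "eq", "fun": lambda th: g(th) - c}],
                options={"maxiter": 300, "ftol": 1e-10},
            ) if not res.success else None
        if retry is not None and np.isfinite(retry.fun) and retry.fun < val:
            res, val = retry, retry.fun
        if np.isfinite(val):
            warm["x"] = res.x
        return float(val)

    scale = 0.05 + 0.1 * abs(ghat)

    def find_bound(direction: int) -> tuple[float, bool]:
        edge = dom_hi if direction > 0 else dom_lo
        inside = ghat
        step = scale
        outside = None
        for _ in range(60):
            c = inside + direction * step
            if (direction > 0 and c >= edge) or (direction < 0 and c <= edge):
                if np.isfinite(edge) and prof(edge) <= threshold:
                    return float(edge), True
                c = edge if np.isfinite(edge) else inside + direction * step
                outside = c
                break
            if prof(c) > threshold:
                outside = c
                break
            inside = c
            step *= 1.8
        if outside is None:
            # never crossed: report the furthest point probed, flagged
            return float(inside), True
        lo, hi = (inside, outside) if direction > 0 else (outside, inside)
        for _ in range(80):
            if hi - lo < tol * (1.0 + abs(ghat)):
                break
            mid = 0.5 * (lo + hi)
            if prof(mid) > threshold:
                if direction > 0:
                    hi = mid
                else:
                    lo = mid
            else:
                if direction > 0:
                    lo = mid
                else:
                    hi = mid
        bound = lo if direction > 0 else hi
        return float(bound), False

    warm["x"] = fit.theta.copy()
    low, low_at_bound = find_bound(-1)
    warm["x"] = fit.theta.copy()
    high, high_at_bound = find_bound(+1)
    return ProfileCI(low=low, high=high,
                     low_at_bound=low_at_bound, high_at_bound=high_at_bound)
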