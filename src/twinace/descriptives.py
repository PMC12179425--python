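"""Twin-pair descriptive statistics.

Per-zygosity twin-twin correlations, cross-twin cross-trait correlations,
the individual-level phenotypic correlation between traits, and sample
moments.  Twin order within a pair is arbitrary in the data file, so by
default twin correlations are computed on the double-entered (symmetrized)
data, which makes them invariant to swapping twin labels; confidence
intervals use the Fisher z transform on the number of pairs (not the
doubled count).  The phenotypic correlation CI resamples whole pairs
(cluster bootstrap) because co-twins are not independent observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "twin_twin_correlation",
    "cross_twin_cross_trait_correlation",
    "phenotypic_correlation",
    "moment_descriptives",
    "describe_dataset",
]

Z95 = 1.96


@dataclass(frozen=True)
class CorrelationReport:
    estimate: float
    ci_low: float
    ci_high: float
    n_pairs: int
    kind: str
    zygosity: str
    traits: tuple[str, ...]
    method: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must contain the estimate")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a column has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3:
        return -1.0, 1.0
    r = min(max(r, -0.999999999), 0.999999999)
    z = np.arctanh(r)
    half = Z95 / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def twin_twin_correlation(
    dataset: pd.DataFrame,
    trait: str,
    zygosity: str,
    double_entry: bool = True,
) -> CorrelationReport:
    """Correlation between co-twins' values of one trait, per zygosity.

    Complete pairs only.  With ``double_entry`` (default) each pair enters
    as both (twin1, twin2) and (twin2, twin1) so the estimate does not
    depend on which twin is listed first.
    """
    sub = dataset.loc[dataset["zygosity"] == zygosity, [f"{trait}_t1", f"{trait}_t2"]]
    sub = sub.dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete {zygosity} pairs, got {n}")
    x = sub.iloc[:, 0].to_numpy(float)
    y = sub.iloc[:, 1].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a column has zero variance")
    if double_entry:
        r = _pearson(np.concatenate([x, y]), np.concatenate([y, x]))
    else:
        r = _pearson(x, y)
    lo, hi = _fisher_ci(r, n)
    lo, hi = min(lo, r), max(hi, r)
    return CorrelationReport(
        estimate=r, ci_low=lo, ci_high=hi, n_pairs=n,
        kind="twin_twin", zygosity=zygosity, traits=(trait,),
        method="double_entry_pearson" if double_entry else "pearson",
    )


def cross_twin_cross_trait_correlation(
    dataset: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    zygosity: str,
    double_entry: bool = True,
) -> CorrelationReport:
    """Correlation of one twin's trait A with the co-twin's trait B.

    An MZ > DZ pattern here implicates genetic overlap between the traits;
    equal values implicate the shared environment.  Both orderings
    (twin1-A with twin2-B and twin2-A with twin1-B) are pooled by default.
    """
    sub = dataset.loc[dataset["zygosity"] == zygosity]
    a1 = sub[f"{trait_a}_t1"].to_numpy(float)
    a2 = sub[f"{trait_a}_t2"].to_numpy(float)
    b1 = sub[f"{trait_b}_t1"].to_numpy(float)
    b2 = sub[f"{trait_b}_t2"].to_numpy(float)
    fwd = ~np.isnan(a1) & ~np.isnan(b2)
    rev = ~np.isnan(a2) & ~np.isnan(b1)
    n = int(np.sum(fwd | rev))
    if n < 3:
        raise ValueError(f"need >= 3 informative {zygosity} pairs, got {n}")
    if double_entry:
        x = np.concatenate([a1[fwd], a2[rev]])
        y = np.concatenate([b2[fwd], b1[rev]])
    else:
        x, y = a1[fwd], b2[fwd]
        n = int(np.sum(fwd))
    r = _pearson(x, y)
    lo, hi = _fisher_ci(r, n)
    lo, hi = min(lo, r), max(hi, r)
    return CorrelationReport(
        estimate=r, ci_low=lo, ci_high=hi, n_pairs=n,
        kind="cross_twin_cross_trait", zygosity=zygosity,
        traits=(trait_a, trait_b),
        method="double_entry_pearson" if double_entry else "pearson",
    )


def phenotypic_correlation(
    dataset: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationReport:
    """Individual-level correlation between two traits.

    The 95% CI resamples whole pairs with replacement (cluster bootstrap,
    percentile interval), which respects the within-pair dependence that an
    ordinary n-individuals Fisher interval would ignore.
    """
    cols = [f"{trait_a}_t1", f"{trait_a}_t2", f"{trait_b}_t1", f"{trait_b}_t2"]
    wide = dataset[cols].to_numpy(float)
    x = np.concatenate([wide[:, 0], wide[:, 1]])
    y = np.concatenate([wide[:, 2], wide[:, 3]])
    ok = ~np.isnan(x) & ~np.isnan(y)
    if int(ok.sum()) < 3:
        raise ValueError("need >= 3 individuals with both traits")
    r = _pearson(x[ok], y[ok])

    rng = np.random.default_rng(seed)
    n_pairs = wide.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_pairs, size=n_pairs)
        w = wide[idx]
        bx = np.concatenate([w[:, 0], w[:, 1]])
        by = np.concatenate([w[:, 2], w[:, 3]])
        bok = ~np.isnan(bx) & ~np.isnan(by)
        bxo, byo = bx[bok], by[bok]
        if bok.sum() < 3 or np.std(bxo) == 0 or np.std(byo) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(bxo, byo)[0, 1]
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(float(lo), r), max(float(hi), r)
    return CorrelationReport(
        estimate=r, ci_low=lo, ci_high=hi, n_pairs=n_pairs,
        kind="phenotypic", zygosity="pooled", traits=(trait_a, trait_b),
        method=f"cluster_bootstrap_{len(boots)}",
    )


def moment_descriptives(dataset: pd.DataFrame, trait: str) -> dict[str, float]:
    """Mean, SD, adjusted skewness and excess kurtosis over all individuals."""
    vals = np.concatenate([
        dataset[f"{trait}_t1"].to_numpy(float),
        dataset[f"{trait}_t2"].to_numpy(float),
    ])
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n < 4:
        raise ValueError(f"need >= 4 non-missing values, got {n}")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("moments beyond the mean are undefined for a constant")
    return {
        "n": n,
        "mean": float(np.mean(vals)),
        "sd": sd,
        # adjusted Fisher-Pearson estimators, as spreadsheet software reports
        "skewness": float(stats.skew(vals, bias=False)),
        "excess_kurtosis": float(stats.kurtosis(vals, bias=False)),
    }


def describe_dataset(
    dataset: pd.DataFrame,
    traits: list[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Full descriptive report: moments, twin correlations per zygosity,
    and (for two traits) cross-twin cross-trait and phenotypic correlations."""

    def rep(r: CorrelationReport) -> dict:
        return {
            "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "n_pairs": r.n_pairs, "method": r.method,
        }

    out: dict = {"moments": {}, "twin_twin": {}, "cross_twin_cross_trait": {},
                 "phenotypic": {}}
    for t in traits:
        out["moments"][t] = moment_descriptives(dataset, t)
        out["twin_twin"][t] = {
            z: rep(twin_twin_correlation(dataset, t, z)) for z in ("MZ", "DZ")
        }
    if len(traits) == 2:
        a, b = traits
        out["cross_twin_cross_trait"] = {
            z: rep(cross_twin_cross_trait_correlation(dataset, a, b, z))
            for z in ("MZ", "DZ")
        }
        out["phenotypic"] = rep(
            phenotypic_correlation(dataset, a, b, n_boot=n_boot, seed=seed)
        )
    return out
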