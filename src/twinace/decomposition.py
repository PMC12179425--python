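"""Derived quantities of a fitted (bivariate) ACE model.

Standardized variance proportions, the twin correlations the model implies,

    rMZ = A + C                      rDZ = A/2 + C
    ctct_MZ = rA sqrt(A1 A2) + rC sqrt(C1 C2)
    ctct_DZ = rA sqrt(A1 A2) / 2 + rC sqrt(C1 C2)
    r_ph  = rA sqrt(A1 A2) + rC sqrt(C1 C2) + rE sqrt(E1 E2)

and the decomposition of the phenotypic correlation into its genetic and
environmental contributions (biv_A, biv_C, biv_E, which sum to r_ph; their
proportions sum to one but individual terms may be negative or exceed one
when contributions have opposite signs).  All quantities are computed from
unrounded fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ace import FitResult, fit_bivariate_correlated_factors
from .simulate import AceParams, SimSpec, simulate_dataset

__all__ = [
    "StandardizedParams",
    "DecompositionReport",
    "standardize",
    "implied_twin_correlations",
    "bivariate_decomposition",
    "decompose",
]

DZ_SHARE = 0.5


@dataclass(frozen=True)
class StandardizedParams:
    """Standardized ACE proportions per trait plus aetiological correlations."""

    traits: tuple[str, ...]
    A: tuple[float, ...]
    C: tuple[float, ...]
    E: tuple[float, ...]
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def standardize(fit: FitResult | AceParams) -> StandardizedParams:
    """Proportions of variance X_i / (a2_i + c2_i + e2_i) per trait."""
    if isinstance(fit, AceParams):
        std = fit.standardized()
        return StandardizedParams(
            traits=fit.traits, A=std["A"], C=std["C"], E=std["E"],
            r_a=fit.r_a, r_c=fit.r_c, r_e=fit.r_e,
        )
    p = fit.params
    traits = tuple(
        k[len("mean_"):] for k in p if k.startswith("mean_")
    )
    if not traits or not all(f"a2_{t}" in p for t in traits):
        raise ValueError("fit does not look like an ACE model fit")
    a, c, e = [], [], []
    for t in traits:
        total = p[f"a2_{t}"] + p[f"c2_{t}"] + p[f"e2_{t}"]
        if total <= 0:
            raise ValueError(f"total variance for {t} is not positive")
        a.append(p[f"a2_{t}"] / total)
        c.append(p[f"c2_{t}"] / total)
        e.append(p[f"e2_{t}"] / total)
    return StandardizedParams(
        traits=traits, A=tuple(a), C=tuple(c), E=tuple(e),
        r_a=p.get("r_a", 0.0), r_c=p.get("r_c", 0.0), r_e=p.get("r_e", 0.0),
    )


def implied_twin_correlations(std: StandardizedParams) -> dict:
    """Twin correlations implied by standardized ACE parameters.

    Per-trait MZ/DZ twin-twin correlations, and for two traits the
    cross-twin cross-trait correlations and the phenotypic correlation.
    """
    out: dict = {"twin_twin": {}}
    for i, t in enumerate(std.traits):
        out["twin_twin"][t] = {
            "MZ": std.A[i] + std.C[i],
            "DZ": DZ_SHARE * std.A[i] + std.C[i],
        }
    if std.n_traits == 2:
        ga = std.r_a * float(np.sqrt(std.A[0] * std.A[1]))
        gc = std.r_c * float(np.sqrt(std.C[0] * std.C[1]))
        ge = std.r_e * float(np.sqrt(std.E[0] * std.E[1]))
        out["cross_twin_cross_trait"] = {
            "MZ": ga + gc,
            "DZ": DZ_SHARE * ga + gc,
        }
        out["phenotypic"] = ga + gc + ge
    for t, vals in out["twin_twin"].items():
        for z, v in vals.items():
            if not -1.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"implied correlation out of range for {t}/{z}: {v}")
    return out


def bivariate_decomposition(std: StandardizedParams) -> dict:
    """Split the implied phenotypic correlation into aetiological parts.

    ``biv_A = rA sqrt(A1 A2)`` and likewise for C and E; the three terms sum
    to the phenotypic correlation.  Proportions are each term divided by
    that sum (undefined when it is zero; the absolute terms are still
    returned).
    """
    if std.n_traits != 2:
        raise ValueError("bivariate decomposition needs a two-trait model")
    biv_a = std.r_a * float(np.sqrt(std.A[0] * std.A[1]))
    biv_c = std.r_c * float(np.sqrt(std.C[0] * std.C[1]))
    biv_e = std.r_e * float(np.sqrt(std.E[0] * std.E[1]))
    r_ph = biv_a + biv_c + biv_e
    out = {
        "biv_a": biv_a, "biv_c": biv_c, "biv_e": biv_e,
        "phenotypic": r_ph,
    }
    if r_ph != 0.0:
        out["biv_a_prop"] = biv_a / r_ph
        out["biv_c_prop"] = biv_c / r_ph
        out["biv_e_prop"] = biv_e / r_ph
    else:
        out["biv_a_prop"] = out["biv_c_prop"] = out["biv_e_prop"] = float("nan")
    return out


@dataclass(frozen=True)
class DecompositionReport:
    standardized: StandardizedParams
    implied: dict
    bivariate: dict | None
    ci: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "traits": list(self.standardized.traits),
            "A": list(self.standardized.A),
            "C": list(self.standardized.C),
            "E": list(self.standardized.E),
            "r_a": self.standardized.r_a,
            "r_c": self.standardized.r_c,
            "r_e": self.standardized.r_e,
            "implied": self.implied,
        }
        if self.bivariate is not None:
            out["bivariate"] = self.bivariate
        if self.ci is not None:
            out["ci"] = self.ci
        return out


def decompose(
    fit: FitResult,
    ci: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> DecompositionReport:
    """Full report of derived quantities from a fitted ACE model.

    With ``ci=True`` the derived quantities get percentile confidence
    intervals by parametric bootstrap: datasets of the fitted design size
    are simulated from the fitted parameters, refitted, and re-decomposed.
    Non-converged bootstrap refits are dropped.
    """
    std = standardize(fit)
    implied = implied_twin_correlations(std)
    biv = bivariate_decomposition(std) if std.n_traits == 2 else None
    ci_out = None
    if ci:
        if std.n_traits != 2:
            raise ValueError("bootstrap CIs are implemented for bivariate fits")
        ci_out = _bootstrap_ci(fit, std, n_boot=n_boot, seed=seed)
    return DecompositionReport(standardized=std, implied=implied,
                               bivariate=biv, ci=ci_out)


def _bootstrap_ci(
    fit: FitResult, std: StandardizedParams, n_boot: int, seed: int
) -> dict:
    n_mz, n_dz = fit.prepared.n_pairs_by_zyg
    p = fit.params
    traits = std.traits
    total = tuple(p[f"a2_{t}"] + p[f"c2_{t}"] + p[f"e2_{t}"] for t in traits)
    seeds = np.random.SeedSequence(seed).generate_state(n_boot) % (2**31)
    draws: dict[str, list[float]] = {}
    for b in range(n_boot):
        spec = SimSpec(
            n_mz=n_mz, n_dz=n_dz, traits=traits,
            means=tuple(p[f"mean_{t}"] for t in traits),
            total_var=total,
            ace=tuple((std.A[i], std.C[i], std.E[i]) for i in range(2)),
            r_a=std.r_a, r_c=std.r_c, r_e=std.r_e,
            seed=int(seeds[b]),
        )
        data = simulate_dataset(spec)
        refit = fit_bivariate_correlated_factors(
            data, traits, n_restarts=2, seed=int(seeds[b]), fast=True
        )
        if not refit.converged:
            continue
        s = standardize(refit)
        biv = bivariate_decomposition(s)
        for i, t in enumerate(traits):
            draws.setdefault(f"A_{t}", []).append(s.A[i])
            draws.setdefault(f"C_{t}", []).append(s.C[i])
            draws.setdefault(f"E_{t}", []).append(s.E[i])
        for key in ("r_a", "r_c", "r_e"):
            draws.setdefault(key, []).append(getattr(s, key))
        for key in ("biv_a", "biv_c", "biv_e", "phenotypic"):
            draws.setdefault(key, []).append(biv[key])
    out = {"method": "parametric_bootstrap", "n_effective": 0}
    for key, vals in draws.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[key] = {"low": float(lo), "high": float(hi)}
        out["n_effective"] = len(vals)
    return out
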