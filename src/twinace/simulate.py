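"""Synthetic twin-pair data with an exact ACE covariance structure.

The classical twin design contrasts monozygotic (MZ) pairs, who share all
segregating genetic variation, with dizygotic (DZ) pairs, who share half of
it on average.  Under the ACE model each trait decomposes into additive
genetic (A), shared environmental (C) and unique environmental (E) variance.
This module builds the model-implied per-pair covariance matrix for one or
two traits (the bivariate "correlated factors" structure, in which like-type
factors across traits correlate with coefficients rA, rC, rE) and draws
multivariate-normal twin pairs from it, optionally with covariate effects,
polygenic-score columns and per-twin missingness.

All downstream fitting machinery shares :func:`build_pair_covariance`, so
data simulated here have exactly the covariance structure the likelihood
assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AceParams",
    "CovariateSpec",
    "SimSpec",
    "build_pair_covariance",
    "simulate_dataset",
    "simulate_pgs_columns",
    "save_pairs",
    "load_pairs",
    "infant_cohort_spec",
]

ZYGOSITIES = ("MZ", "DZ")

#: DZ twins share on average half of the additive genetic variance.
DZ_GENETIC_SHARING = 0.5


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AceParams:
    """ACE variance components for one or two traits, in score units squared.

    For two traits the like-type factors across traits correlate with
    ``r_a`` (genetic correlation), ``r_c`` (shared-environment correlation)
    and ``r_e`` (unique-environment correlation).
    """

    traits: tuple[str, ...]
    means: tuple[float, ...]
    a2: tuple[float, ...]
    c2: tuple[float, ...]
    e2: tuple[float, ...]
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0

    def __post_init__(self) -> None:
        t = len(self.traits)
        if t not in (1, 2):
            raise ValueError("AceParams supports 1 or 2 traits")
        for name in ("means", "a2", "c2", "e2"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} must have one entry per trait")
        for i in range(t):
            if self.a2[i] < 0:
                raise ValueError(f"a2 must be >= 0 for trait {self.traits[i]}")
            if self.c2[i] < 0:
                raise ValueError(f"c2 must be >= 0 for trait {self.traits[i]}")
            if self.e2[i] <= 0:
                raise ValueError(f"e2 must be > 0 for trait {self.traits[i]}")
        for rname in ("r_a", "r_c", "r_e"):
            r = getattr(self, rname)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{rname} must lie in [-1, 1], got {r}")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def k(self) -> int:
        """Free-parameter count of the corresponding ML model."""
        return 4 if self.n_traits == 1 else 11

    def total_var(self) -> tuple[float, ...]:
        return tuple(a + c + e for a, c, e in zip(self.a2, self.c2, self.e2))

    def standardized(self) -> dict[str, tuple[float, ...]]:
        """Proportions of variance: A + C + E = 1 per trait."""
        tot = self.total_var()
        return {
            "A": tuple(a / v for a, v in zip(self.a2, tot)),
            "C": tuple(c / v for c, v in zip(self.c2, tot)),
            "E": tuple(e / v for e, v in zip(self.e2, tot)),
        }


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate and its additive effect on the trait means.

    ``kind`` is one of ``normal`` (requires ``mean`` and ``sd``), ``binary``
    (requires ``p``) or ``ordinal`` (requires ``levels`` and optionally
    ``probs``).  ``level`` decides whether the value is drawn once per pair
    (age, household income, ...) or per twin.  ``effects`` maps trait name to
    a standardized slope: one SD of the covariate moves the trait mean by
    ``effect`` trait SDs.
    """

    name: str
    kind: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5
    levels: tuple[float, ...] = ()
    probs: tuple[float, ...] = ()
    level: str = "pair"
    effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "binary", "ordinal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.level not in ("pair", "twin"):
            raise ValueError("level must be 'pair' or 'twin'")
        if self.kind == "ordinal" and not self.levels:
            raise ValueError("ordinal covariate needs levels")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        if self.kind == "binary":
            return rng.binomial(1, self.p, size=n).astype(float)
        levels = np.asarray(self.levels, dtype=float)
        probs = np.asarray(self.probs, dtype=float) if self.probs else None
        return rng.choice(levels, size=n, p=probs)

    def moments(self) -> tuple[float, float]:
        """Theoretical mean and SD used to standardize effects."""
        if self.kind == "normal":
            return self.mean, self.sd
        if self.kind == "binary":
            return self.p, float(np.sqrt(self.p * (1 - self.p)))
        levels = np.asarray(self.levels, dtype=float)
        probs = (
            np.asarray(self.probs, dtype=float)
            if self.probs
            else np.full(len(levels), 1.0 / len(levels))
        )
        m = float(levels @ probs)
        v = float(((levels - m) ** 2) @ probs)
        return m, float(np.sqrt(v))


@dataclass(frozen=True)
class SimSpec:
    """Design of one simulated twin study.

    ``ace`` holds the standardized per-trait proportions (A, C, E), which
    must sum to one; raw component variances are ``proportion * total_var``.
    """

    n_mz: int
    n_dz: int
    traits: tuple[str, ...] = ("trait",)
    means: tuple[float, ...] = (0.0,)
    total_var: tuple[float, ...] = (1.0,)
    ace: tuple[tuple[float, float, float], ...] = ((0.4, 0.3, 0.3),)
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0
    missing_rate: float = 0.0
    covariates: tuple[CovariateSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        t = len(self.traits)
        for name in ("means", "total_var", "ace"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} must have one entry per trait")
        for trait, (a, c, e) in zip(self.traits, self.ace):
            if a < 0 or c < 0 or e <= 0:
                raise ValueError(
                    f"trait {trait}: need A >= 0, C >= 0, E > 0, got {(a, c, e)}"
                )
            if abs(a + c + e - 1.0) > 1e-12:
                raise ValueError(
                    f"trait {trait}: A + C + E must equal 1, got {a + c + e!r}"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def ace_params(self) -> AceParams:
        return AceParams(
            traits=self.traits,
            means=self.means,
            a2=tuple(p[0] * v for p, v in zip(self.ace, self.total_var)),
            c2=tuple(p[1] * v for p, v in zip(self.ace, self.total_var)),
            e2=tuple(p[2] * v for p, v in zip(self.ace, self.total_var)),
            r_a=self.r_a,
            r_c=self.r_c,
            r_e=self.r_e,
        )

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, CovariateSpec):
                return {k: getattr(o, k) for k in o.__dataclass_fields__}
            raise TypeError(o)

        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(payload, default=default, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# biometric covariance
# ---------------------------------------------------------------------------

def _component_matrix(var: Sequence[float], r: float, label: str) -> np.ndarray:
    """T x T covariance contributed by one factor type (A, C or E)."""
    v = np.asarray(var, dtype=float)
    if np.any(v < 0):
        raise ValueError(f"component {label}: negative variance {v}")
    sigma = np.diag(v).astype(float)
    if len(v) == 2:
        off = r * np.sqrt(v[0] * v[1])
        sigma[0, 1] = sigma[1, 0] = off
    return sigma


def build_pair_covariance(
    params: AceParams, zygosity: str, validate: bool = True
) -> np.ndarray:
    """Model-implied covariance of the stacked pair vector.

    Row/column order is (twin1 trait1, twin1 trait2, twin2 trait1,
    twin2 trait2); for one trait the matrix is 2 x 2.  The within-person
    block is Sigma_A + Sigma_C + Sigma_E for both twins; the cross-twin
    block is Sigma_A + Sigma_C for MZ pairs and 0.5 * Sigma_A + Sigma_C for
    DZ pairs, where Sigma_X[i, j] = r_X * sqrt(x2_i * x2_j).

    ``validate=False`` skips the eigenvalue check (likelihood code detects
    non-PD matrices itself via the Cholesky factorization).
    """
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    sig_a = _component_matrix(params.a2, params.r_a, "A")
    sig_c = _component_matrix(params.c2, params.r_c, "C")
    sig_e = _component_matrix(params.e2, params.r_e, "E")
    within = sig_a + sig_c + sig_e
    share = 1.0 if zygosity == "MZ" else DZ_GENETIC_SHARING
    cross = share * sig_a + sig_c
    full = np.block([[within, cross], [cross, within]])
    if validate:
        # valid inputs always give a PSD matrix; a violation means the
        # component matrices themselves were inconsistent
        tol = 1e-10 * max(1.0, float(np.abs(full).max()))
        eigvals = np.linalg.eigvalsh(full)
        if eigvals.min() < -tol:
            for label, comp in (("A", sig_a), ("C", sig_c), ("E", sig_e)):
                if np.linalg.eigvalsh(comp).min() < -tol:
                    raise ValueError(
                        f"implied pair covariance is not PSD: component {label} "
                        f"matrix is indefinite"
                    )
            raise ValueError("implied pair covariance is not PSD")
    return full


def pair_mean_vector(params: AceParams) -> np.ndarray:
    """Stacked mean vector matching :func:`build_pair_covariance` order."""
    mu = np.asarray(params.means, dtype=float)
    return np.concatenate([mu, mu])


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _trait_cols(traits: Sequence[str]) -> list[str]:
    return [f"{t}_t1" for t in traits] + [f"{t}_t2" for t in traits]


def simulate_dataset(spec: SimSpec) -> pd.DataFrame:
    """Draw a wide-format twin-pair table from the generating model.

    One row per pair with columns ``pair_id``, ``zygosity``,
    ``<trait>_t1/_t2`` and ``<covariate>_t1/_t2``.  Trait vectors are
    multivariate normal with the ACE-implied pair covariance; covariates add
    linear effects to the trait means; each twin-trait cell is then set
    missing independently with probability ``missing_rate``.  Pairs with all
    trait cells missing are dropped.  Output is deterministic for a fixed
    seed.
    """
    if spec.n_mz + spec.n_dz == 0:
        raise ValueError("at least one pair must be requested")
    rng = np.random.default_rng(spec.seed)
    params = spec.ace_params()
    traits = spec.traits
    n_traits = len(traits)
    mean_vec = pair_mean_vector(params)

    frames = []
    for zyg, n in (("MZ", spec.n_mz), ("DZ", spec.n_dz)):
        if n == 0:
            continue
        cov = build_pair_covariance(params, zyg)
        values = rng.multivariate_normal(mean_vec, cov, size=n, method="cholesky")
        frame = pd.DataFrame(values, columns=_trait_cols(traits))
        frame.insert(0, "zygosity", zyg)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)

    # covariate draws and their additive effects on the trait means
    trait_sd = np.sqrt(np.asarray(spec.total_var, dtype=float))
    for cov_spec in spec.covariates:
        n_rows = len(df)
        if cov_spec.level == "pair":
            shared = cov_spec.draw(n_rows, rng)
            per_twin = (shared, shared)
        else:
            per_twin = (cov_spec.draw(n_rows, rng), cov_spec.draw(n_rows, rng))
        m, s = cov_spec.moments()
        for j, col_vals in enumerate(per_twin, start=1):
            df[f"{cov_spec.name}_t{j}"] = col_vals
            z = (col_vals - m) / s if s > 0 else np.zeros(n_rows)
            for i, trait in enumerate(traits):
                beta = cov_spec.effects.get(trait, 0.0)
                if beta:
                    df[f"{trait}_t{j}"] += beta * trait_sd[i] * z

    if spec.missing_rate > 0:
        for j in (1, 2):
            # one missingness draw per twin: an absent twin lacks all traits
            twin_missing = rng.random(len(df)) < spec.missing_rate
            for trait in traits:
                df.loc[twin_missing, f"{trait}_t{j}"] = np.nan
        observed = df[_trait_cols(traits)].notna().any(axis=1)
        df = df.loc[observed].reset_index(drop=True)

    counts: dict[str, int] = {"MZ": 0, "DZ": 0}

    def make_id(zyg: str) -> str:
        counts[zyg] += 1
        return f"{zyg}{counts[zyg]:04d}"

    df.insert(0, "pair_id", [make_id(z) for z in df["zygosity"]])
    return df


def simulate_pgs_columns(
    dataset: pd.DataFrame,
    n_scores: int,
    effect_sizes: Sequence[float] | None = None,
    seed: int = 0,
    score_names: Sequence[str] | None = None,
    traits: Sequence[str] = (),
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Append polygenic-score and ancestry-PC columns to a pair table.

    Scores are standard normal per individual with the genetic sharing of the
    design: MZ co-twins receive identical values, DZ co-twins values
    correlated 0.5.  ``n_pcs`` independent standard-normal principal
    components are added per twin.  A nonzero ``effect_sizes[i]``
    (standardized slope) shifts every column in ``traits`` by
    ``effect * trait_sd * score``.
    """
    if dataset.empty:
        raise ValueError("dataset must be non-empty")
    if n_scores < 1:
        raise ValueError("n_scores must be >= 1")
    effects = list(effect_sizes) if effect_sizes is not None else [0.0] * n_scores
    if len(effects) != n_scores:
        raise ValueError("effect_sizes must have one entry per score")
    names = list(score_names) if score_names else [f"pgs{i + 1}" for i in range(n_scores)]
    if len(names) != n_scores:
        raise ValueError("score_names must have one entry per score")

    rng = np.random.default_rng(seed)
    df = dataset.copy()
    n = len(df)
    is_mz = (df["zygosity"] == "MZ").to_numpy()

    trait_sds = {
        t: float(np.nanstd(np.concatenate([df[f"{t}_t1"], df[f"{t}_t2"]]), ddof=1))
        for t in traits
    }

    for name, eff in zip(names, effects):
        g1 = rng.standard_normal(n)
        # DZ co-twin: correlation 0.5 with twin1's score, unit variance
        g2_dz = 0.5 * g1 + np.sqrt(0.75) * rng.standard_normal(n)
        g2 = np.where(is_mz, g1, g2_dz)
        df[f"{name}_t1"] = g1
        df[f"{name}_t2"] = g2
        if eff:
            for t in traits:
                df[f"{t}_t1"] += eff * trait_sds[t] * g1
                df[f"{t}_t2"] += eff * trait_sds[t] * g2
    for p in range(1, n_pcs + 1):
        df[f"pc{p}_t1"] = rng.standard_normal(n)
        df[f"pc{p}_t2"] = rng.standard_normal(n)
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_pairs(df: pd.DataFrame, path: str | Path, spec: SimSpec | None = None) -> None:
    """Write a pair table as CSV (missing cells empty); optionally record the
    generating :class:`SimSpec` in a sidecar ``<path>.spec.json``."""
    path = Path(path)
    df.to_csv(path, index=False, na_rep="")
    if spec is not None:
        sidecar = path.with_name(path.name + ".spec.json")
        sidecar.write_text(spec.to_json() + "\n")


def load_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "zygosity" not in df.columns or "pair_id" not in df.columns:
        raise ValueError("pair table must have 'pair_id' and 'zygosity' columns")
    bad = set(df["zygosity"].unique()) - set(ZYGOSITIES)
    if bad:
        raise ValueError(f"unknown zygosity values: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# study-shaped default specification
# ---------------------------------------------------------------------------

def infant_cohort_spec(
    n_mz: int = 164,
    n_dz: int = 131,
    missing_rate: float = 0.01,
    seed: int = 0,
    with_covariates: bool = True,
) -> SimSpec:
    """A generating specification shaped like a 5-month twin cohort.

    Two adaptive-behaviour domains (motor and social-communication raw
    scores) with the fitted bivariate correlated-factors values
    (motor A=0.21, C=0.67, E=0.12; social-communication A=0.12, C=0.78,
    E=0.10; rA=-0.39, rC=0.45, rE=0.32), observed score means/SDs, and
    pair-level demographic covariates with standardized effects of the
    magnitudes seen in covariate screening.  Incomplete pairs arise from
    per-twin missingness at ``missing_rate``.
    """
    covariates: tuple[CovariateSpec, ...] = ()
    if with_covariates:
        covariates = (
            CovariateSpec(
                name="age_days", mean=167.29, sd=8.88, level="pair",
                effects={"motor": 0.28, "social_communication": 0.15},
            ),
            CovariateSpec(
                name="term_age", mean=259.21, sd=7.84, level="pair",
                effects={"motor": 0.17, "social_communication": 0.11},
            ),
            CovariateSpec(
                name="sex", kind="binary", p=0.4765, level="pair",
                effects={"motor": 0.10, "social_communication": 0.21},
            ),
            CovariateSpec(
                name="parental_age", mean=35.30, sd=4.81, level="pair",
                effects={"motor": -0.07, "social_communication": -0.04},
            ),
            CovariateSpec(
                name="parental_education", kind="ordinal",
                levels=(1, 2, 3, 4, 5), probs=(0.01, 0.02, 0.12, 0.50, 0.35),
                level="pair",
                effects={"motor": -0.08, "social_communication": -0.06},
            ),
            CovariateSpec(
                name="income", kind="ordinal",
                levels=tuple(range(1, 12)),
                probs=(0.01, 0.02, 0.03, 0.06, 0.12, 0.18, 0.20, 0.15, 0.10, 0.07, 0.06),
                level="pair",
                effects={"motor": -0.19, "social_communication": -0.11},
            ),
        )
    return SimSpec(
        n_mz=n_mz,
        n_dz=n_dz,
        traits=("motor", "social_communication"),
        means=(10.27, 34.22),
        total_var=(1.05**2, 1.65**2),
        ace=((0.21, 0.67, 0.12), (0.12, 0.78, 0.10)),
        r_a=-0.39,
        r_c=0.45,
        r_e=0.32,
        missing_rate=missing_rate,
        covariates=covariates,
        seed=seed,
    )
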