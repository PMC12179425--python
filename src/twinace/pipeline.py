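"""Config-driven end-to-end twin analysis.

Runs the full analysis order on any conforming wide-format pair table:
domain combination, descriptives, GEE covariate screening,
residualization, twin correlations, saturated model and assumption tests,
univariate ACE per trait, the bivariate correlated-factors model, model
comparison, decomposition, and optional power and polygenic-score stages.
Every output is JSON/CSV under one output directory together with a
manifest recording the configuration, seed and package version, so a run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace import (
    assumption_tests,
    compare_models,
    fit_bivariate_correlated_factors,
    fit_saturated,
    fit_univariate_ace,
    profile_ci,
)
from .decomposition import decompose
from .descriptives import describe_dataset, moment_descriptives
from .gee import pgs_association, residualize, screen_covariates
from .power import posthoc_power
from .simulate import AceParams, load_pairs

__all__ = ["PipelineConfig", "PipelineError", "combine_domains", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input: str
    output_dir: str
    traits: list[str] = field(default_factory=lambda: ["motor", "social_communication"])
    combine: dict | None = None          # {"new": ..., "sources": [a, b]}
    covariate_candidates: list[str] = field(
        default_factory=lambda: [
            "age_days", "sex", "term_age", "parental_age",
            "parental_education", "income",
        ]
    )
    alpha: float = 0.05
    seed: int = 0
    working_correlation: str = "exchangeable"
    screening_mode: str = "joint"
    double_entry: bool = True
    n_boot_phenotypic: int = 2000
    profile_cis: bool = True
    run_power: bool = False
    power_replicates: int = 500
    pgs_scores: list[str] = field(default_factory=list)
    pc_columns: list[str] = field(default_factory=lambda: [f"pc{i}" for i in range(1, 11)])
    standardized_scores: bool = False    # accept norm-referenced scores instead of raw

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def combine_domains(
    dataset: pd.DataFrame, domain_a: str, domain_b: str, new_name: str
) -> pd.DataFrame:
    """Sum two raw-score domains into one per twin.

    The result is missing whenever either input is missing.  Distribution
    diagnostics for the combined column should be checked afterwards with
    :func:`twinace.descriptives.moment_descriptives`.
    """
    for j in (1, 2):
        if f"{new_name}_t{j}" in dataset.columns:
            raise ValueError(f"column {new_name}_t{j} already exists")
    out = dataset.copy()
    for j in (1, 2):
        a = out[f"{domain_a}_t{j}"]
        b = out[f"{domain_b}_t{j}"]
        out[f"{new_name}_t{j}"] = a + b
    return out


def _write_json(path: Path, payload) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict.

    Each stage writes its outputs before the next stage starts, so a
    failure leaves partial results on disk and raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "load"

    def run_stage(name, fn):
        nonlocal stage
        stage = name
        logger.info("pipeline stage: %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    def load():
        df = load_pairs(config.input)
        return df

    df = run_stage("load", load)

    if config.combine:
        def combine():
            a, b = config.combine["sources"]
            new = config.combine["new"]
            combined = combine_domains(df, a, b, new)
            diag = moment_descriptives(combined, new)
            bundle["combine_diagnostics"] = diag
            _write_json(outdir / "combine_diagnostics.json", diag)
            return combined

        df = run_stage("combine", combine)

    missing_traits = [
        t for t in config.traits
        if f"{t}_t1" not in df.columns or f"{t}_t2" not in df.columns
    ]
    if missing_traits:
        raise PipelineError("schema", KeyError(f"trait columns missing: {missing_traits}"))

    def describe():
        rep = describe_dataset(df, config.traits,
                               n_boot=config.n_boot_phenotypic, seed=config.seed)
        bundle["descriptives_raw"] = rep
        _write_json(outdir / "descriptives_raw.json", rep)
        return rep

    run_stage("describe", describe)

    def screen():
        result = screen_covariates(
            df, config.traits, config.covariate_candidates,
            alpha=config.alpha, working_correlation=config.working_correlation,
            mode=config.screening_mode,
        )
        payload = {
            "alpha": result.alpha,
            "mode": result.mode,
            "retained": list(result.retained),
            "p_values": result.p_values,
            "estimates": {
                t: {c: result.fits[t].summary_row(c) for c in config.covariate_candidates}
                for t in config.traits
            },
        }
        bundle["screening"] = payload
        _write_json(outdir / "gee_screening.json", payload)
        return result

    screening = run_stage("gee_screen", screen)

    def do_residualize():
        out = df
        for t in config.traits:
            if screening.retained:
                out = residualize(out, t, list(screening.retained))
        out.to_csv(outdir / "pairs_residualized.csv", index=False)
        return out

    df_res = run_stage("residualize", do_residualize)

    def describe_residualized():
        rep = describe_dataset(df_res, config.traits,
                               n_boot=config.n_boot_phenotypic, seed=config.seed)
        bundle["descriptives_residualized"] = rep
        _write_json(outdir / "descriptives_residualized.json", rep)

    run_stage("twin_correlations", describe_residualized)

    def assumptions():
        out = {}
        for t in config.traits:
            comps = assumption_tests(df_res, t, seed=config.seed)
            out[t] = [c.to_dict() for c in comps]
        bundle["assumption_tests"] = out
        _write_json(outdir / "assumption_tests.json", out)

    run_stage("assumption_tests", assumptions)

    def univariate():
        out = {}
        for t in config.traits:
            fit = fit_univariate_ace(df_res, t, seed=config.seed)
            if config.profile_cis:
                cis = {
                    p: profile_ci(fit, p)
                    for p in (f"A_{t}", f"C_{t}", f"E_{t}")
                }
                fit = _with_ci(fit, cis)
            out[t] = fit
            _write_json(outdir / f"fit_univariate_{t}.json", fit.to_dict())
        bundle["univariate_fits"] = {t: f.to_dict() for t, f in out.items()}
        return out

    run_stage("univariate_ace", univariate)

    def bivariate():
        saturated = fit_saturated(df_res, config.traits, seed=config.seed)
        fit = fit_bivariate_correlated_factors(df_res, config.traits, seed=config.seed)
        if config.profile_cis:
            targets = ["r_a", "r_c", "r_e"]
            for t in config.traits:
                targets += [f"A_{t}", f"C_{t}", f"E_{t}"]
            fit = _with_ci(fit, {p: profile_ci(fit, p) for p in targets})
        comparison = compare_models(saturated, fit)
        _write_json(outdir / "fit_saturated.json", saturated.to_dict())
        _write_json(outdir / "fit_bivariate.json", fit.to_dict())
        table = pd.DataFrame([
            {"model": saturated.model, "n_parameters": saturated.k,
             "minus2ll": saturated.minus2ll, "df": saturated.df,
             "aic": saturated.aic, "bic": saturated.bic,
             "delta_ll": np.nan, "delta_df": np.nan, "p": np.nan},
            {"model": fit.model, "n_parameters": fit.k,
             "minus2ll": fit.minus2ll, "df": fit.df,
             "aic": fit.aic, "bic": fit.bic,
             "delta_ll": comparison.delta_ll, "delta_df": comparison.delta_df,
             "p": comparison.p_value},
        ])
        table.to_csv(outdir / "model_comparison.csv", index=False)
        bundle["saturated_fit"] = saturated.to_dict()
        bundle["bivariate_fit"] = fit.to_dict()
        bundle["model_comparison"] = comparison.to_dict()
        return fit

    biv_fit = run_stage("bivariate_ace", bivariate)

    def decomposition_stage():
        report = decompose(biv_fit)
        payload = report.to_dict()
        bundle["decomposition"] = payload
        _write_json(outdir / "decomposition.json", payload)
        rows = []
        biv = report.bivariate
        for i, t in enumerate(report.standardized.traits):
            rows.append({
                "trait": t,
                "A": report.standardized.A[i],
                "C": report.standardized.C[i],
                "E": report.standardized.E[i],
                "r_a": report.standardized.r_a,
                "r_c": report.standardized.r_c,
                "r_e": report.standardized.r_e,
                "biv_A": biv["biv_a"], "biv_C": biv["biv_c"], "biv_E": biv["biv_e"],
                "biv_A_prop": biv["biv_a_prop"], "biv_C_prop": biv["biv_c_prop"],
                "biv_E_prop": biv["biv_e_prop"],
            })
        pd.DataFrame(rows).to_csv(outdir / "decomposition.csv", index=False)

    run_stage("decomposition", decomposition_stage)

    if config.run_power:
        def power():
            p = biv_fit.params
            traits = tuple(config.traits)
            generating = AceParams(
                traits=traits,
                means=tuple(p[f"mean_{t}"] for t in traits),
                a2=tuple(p[f"a2_{t}"] for t in traits),
                c2=tuple(p[f"c2_{t}"] for t in traits),
                e2=tuple(p[f"e2_{t}"] for t in traits),
                r_a=p["r_a"], r_c=p["r_c"], r_e=p["r_e"],
            )
            n_mz, n_dz = biv_fit.prepared.n_pairs_by_zyg
            report = posthoc_power(
                generating, n_mz=n_mz, n_dz=n_dz,
                n_replicates=config.power_replicates, alpha=config.alpha,
                seed=config.seed,
            )
            bundle["power"] = report.to_dict()
            _write_json(outdir / "power.json", report.to_dict())

        run_stage("power", power)

    if config.pgs_scores:
        def pgs():
            rows = []
            for score in config.pgs_scores:
                for t in config.traits:
                    fit = pgs_association(
                        df, t, score, config.pc_columns,
                        working_correlation=config.working_correlation,
                    )
                    row = {"score": score, "trait": t, **fit.summary_row(score)}
                    rows.append(row)
            table = pd.DataFrame(rows)
            table.to_csv(outdir / "pgs_associations.csv", index=False)
            bundle["pgs"] = rows

        run_stage("pgs", pgs)

    manifest = {
        "package": "twinace",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": sorted(bundle.keys()),
    }
    _write_json(outdir / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle


def _with_ci(fit, cis):
    from dataclasses import replace
    return replace(fit, ci=cis)
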