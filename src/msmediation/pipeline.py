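"""End-to-end orchestration: generate/ingest -> code -> weight -> fit -> report.

:func:`analyze_cohort` is the single-pass estimator (eligibility, coding,
weights, both MSMs, decomposition, E-values) reused by the bootstrap, the
multiple-imputation loop and every sensitivity variant;
:func:`run_pipeline` executes a :class:`RunConfig` and writes a structured
JSON report plus CSV artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coding import CodingRules, apply_eligibility, code_cohort
from .cohort import CohortTable, write_data_dictionary
from .errors import MsmediationError, ParameterError
from .missing import mice_impute, mnar_complete, rubin_pool
from .msm import (
    build_analysis_rows,
    decompose_effects,
    fit_msm_binary,
    fit_msm_continuous,
    md_to_rr,
)
from .synthetic import GeneratorParams, generate_cohort
from .uncertainty import bca_bootstrap, evalue
from .weights import (
    combine_weights,
    compute_component_weights,
    default_weight_specs,
    fit_weight_models,
    truncate_weights,
    weight_diagnostics,
)

logger = logging.getLogger(__name__)

VARIANTS = (
    "primary",
    "lenient_exposure",
    "strict_mediator",
    "baseline_exclusion",
    "continuous",
    "mnar_best",
    "mnar_worst",
)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    cohort_csv: str | None = None
    generator: GeneratorParams | None = None
    rules: CodingRules = field(default_factory=CodingRules)
    truncation_percentile: float = 95.0
    positivity_low: float = 0.05
    positivity_high: float = 0.95
    mode: str = "binary"  # binary | continuous
    mi_enabled: bool = False
    mi_m: int = 10
    mi_seed: int = 2025
    mi_max_iter: int = 10
    bootstrap_enabled: bool = False
    bootstrap_B: int = 5000
    bootstrap_seed: int = 2025
    variants: tuple = ("primary",)
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        if (self.cohort_csv is None) == (self.generator is None):
            raise ParameterError("exactly one of cohort_csv / generator must be set")
        unknown = [v for v in self.variants if v not in VARIANTS]
        if unknown:
            raise ParameterError(f"unknown variants: {unknown}; choose from {VARIANTS}")
        if self.mode not in ("binary", "continuous"):
            raise ParameterError("mode must be 'binary' or 'continuous'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        gen_keys = {k: v for k, v in raw.items() if k.startswith("generator.")}
        if gen_keys:
            cfg.generator = GeneratorParams.from_flat(
                {k.split(".", 1)[1]: v for k, v in gen_keys.items()}
            )
        rule_map = {
            "exposure.rule": "exposure_rule",
            "mediator.threshold": "mediator_threshold",
            "outcome.threshold": "outcome_threshold",
        }
        for k, attr in rule_map.items():
            if k in raw:
                setattr(cfg.rules, attr, raw[k])
        if raw.get("mode") == "continuous":
            cfg.mode = "continuous"
            cfg.rules.continuous_mode = True
        simple = {
            "cohort_csv": "cohort_csv",
            "truncation.percentile": "truncation_percentile",
            "positivity.low": "positivity_low",
            "positivity.high": "positivity_high",
            "mi.enabled": "mi_enabled",
            "mi.m": "mi_m",
            "mi.seed": "mi_seed",
            "mi.max_iter": "mi_max_iter",
            "bootstrap.enabled": "bootstrap_enabled",
            "bootstrap.B": "bootstrap_B",
            "bootstrap.seed": "bootstrap_seed",
            "out_dir": "out_dir",
            "seed": "seed",
        }
        for k, attr in simple.items():
            if k in raw:
                setattr(cfg, attr, raw[k])
        if "variants" in raw:
            cfg.variants = tuple(raw["variants"])
        return cfg.validate()

    def resolved_dict(self) -> dict:
        out = {
            "cohort_csv": self.cohort_csv,
            "generator": self.generator.to_flat() if self.generator else None,
            "rules": {
                "exposure_rule": self.rules.exposure_rule,
                "mediator_threshold": self.rules.mediator_threshold,
                "outcome_threshold": self.rules.outcome_threshold,
                "continuous_mode": self.rules.continuous_mode,
            },
            "truncation_percentile": self.truncation_percentile,
            "positivity": [self.positivity_low, self.positivity_high],
            "mode": self.mode,
            "mi": {"enabled": self.mi_enabled, "m": self.mi_m, "seed": self.mi_seed},
            "bootstrap": {
                "enabled": self.bootstrap_enabled,
                "B": self.bootstrap_B,
                "seed": self.bootstrap_seed,
            },
            "variants": list(self.variants),
            "seed": self.seed,
        }
        return out


#: analysis columns that must be complete, by the wave they belong to
_WAVE1_ANALYSIS = [
    "chew_group_1",
    "tils_1",
    "social_support_1",
    "mobility_1",
    "cerebrovascular_1",
    "coronary_heart_1",
    "diabetes_1",
    "cancer_1",
    "age_1",
]
_WAVE2_ANALYSIS = [
    "chew_group_2",
    "tils_2",
    "social_support_2",
    "mobility_2",
    "cerebrovascular_2",
    "coronary_heart_2",
    "diabetes_2",
    "cancer_2",
    "age_2",
]


def complete_case_filter(cohort: CohortTable) -> tuple[CohortTable, int]:
    """Drop subjects with item missingness in any analysis column.

    Subjects censored at wave 2 are kept if their wave-1 record is
    complete (their later values are structurally missing, not item
    missingness).  Returns the filtered cohort and the number dropped.
    """
    df = cohort.df
    keep = df[_WAVE1_ANALYSIS].notna().all(axis=1)
    at2 = df["observed_2"] == 1
    keep &= ~at2 | df[_WAVE2_ANALYSIS].notna().all(axis=1)
    at3 = df["observed_3"] == 1
    keep &= ~at3 | df["cesd_3"].notna()
    dropped = int((~keep).sum())
    return CohortTable(df.loc[keep].reset_index(drop=True), dict(cohort.meta)), dropped


def analyze_cohort(
    cohort: CohortTable,
    rules: CodingRules | None = None,
    mode: str = "binary",
    truncation_percentile: float | None = 95.0,
    include_censoring_weights: bool = True,
    exclude_cognitive: bool = False,
    skip_eligibility: bool = False,
    positivity_bounds: tuple = (0.05, 0.95),
    on_missing: str = "error",
) -> dict:
    """Run the full single-dataset estimation once and return all pieces.

    Total and direct models share the same combined weight
    (exposure x mediator x censoring components); the decomposition
    compares exp(b1) across the two models.  ``on_missing`` controls item
    missingness in analysis columns: ``"error"`` (impute first) or
    ``"complete_case"`` (drop incomplete subjects, counted in the
    exclusion ledger).
    """
    rules = (rules or CodingRules()).validate()
    if mode == "continuous" and not rules.continuous_mode:
        rules = dataclasses.replace(rules, continuous_mode=True)
    if skip_eligibility:
        eligible, exclusions = cohort, {}
        n_input = cohort.n_subjects
    else:
        res = apply_eligibility(cohort, rules, exclude_cognitive=exclude_cognitive)
        eligible, exclusions, n_input = res.cohort, res.exclusions, res.n_input
    if on_missing == "complete_case":
        eligible, dropped = complete_case_filter(eligible)
        exclusions = dict(exclusions)
        exclusions["incomplete_record"] = dropped
    elif on_missing != "error":
        raise ParameterError("on_missing must be 'error' or 'complete_case'")

    coded = code_cohort(eligible, rules)
    wide = coded.df
    if mode == "continuous":
        # weight models always work on the binary states
        binary_rules = dataclasses.replace(rules, continuous_mode=False)
        wide_bin = code_cohort(eligible, binary_rules).df
    else:
        wide_bin = wide

    specs = default_weight_specs()
    if not include_censoring_weights:
        specs = [s for s in specs if s.target != "censoring"]
    fitted = fit_weight_models(wide_bin, specs)
    components = compute_component_weights(fitted, wide_bin)
    combined = combine_weights(
        components, wide_bin, include_mediator=True, include_censoring=include_censoring_weights
    )
    if truncation_percentile is not None:
        combined = truncate_weights(combined, upper_percentile=truncation_percentile)
        sw = combined.sw_truncated
    else:
        sw = combined.sw_total
    diags = weight_diagnostics(
        combined, fitted, prob_low=positivity_bounds[0], prob_high=positivity_bounds[1]
    )

    rows = build_analysis_rows(wide)
    w = sw.loc[rows.index]
    if mode == "binary":
        total = fit_msm_binary(rows, w, include_mediator=False)
        direct = fit_msm_binary(rows, w, include_mediator=True)
        summary = decompose_effects(total, direct)
        extra = {}
    else:
        total = fit_msm_continuous(rows, w, include_mediator=False)
        direct = fit_msm_continuous(rows, w, include_mediator=True)
        unexposed = rows.loc[rows["cum_x"] == 0, "y"]
        ref_sd = float(unexposed.std(ddof=1)) if len(unexposed) > 1 else float(rows["y"].std(ddof=1))
        rr_total = md_to_rr(total.effect["cum_x"], ref_sd)
        rr_direct = md_to_rr(direct.effect["cum_x"], ref_sd)
        rr_med = md_to_rr(direct.effect["cum_m"], ref_sd)
        extra = {
            "reference_sd": ref_sd,
            "approx_rr": {
                "total": rr_total,
                "direct": rr_direct,
                "mediator": rr_med,
            },
            "evalue_total_approx_rr": evalue(rr_total).to_dict(),
        }
        summary = None
    return {
        "n_input": n_input,
        "exclusions": exclusions,
        "n_analyzed": len(rows),
        "weights": combined,
        "diagnostics": diags,
        "rows": rows,
        "total": total,
        "direct": direct,
        "summary": summary,
        "extra": extra,
        "rules": rules,
    }


def estimate_total_rr(cohort_df: pd.DataFrame, rules: CodingRules | None = None, **kw) -> float:
    """Total-effect RR from one wide table — the bootstrap statistic."""
    result = analyze_cohort(CohortTable(cohort_df.copy()), rules=rules, **kw)
    return result["total"].effect["cum_x"]


def _variant_result(cohort: CohortTable, variant: str, config: RunConfig) -> dict:
    rules = dataclasses.replace(config.rules)
    kwargs: dict = {"truncation_percentile": config.truncation_percentile,
                    "positivity_bounds": (config.positivity_low, config.positivity_high)}
    mode = config.mode
    work = cohort
    if variant == "lenient_exposure":
        rules.exposure_rule = "lenient"
    elif variant == "strict_mediator":
        rules.mediator_threshold = 4
    elif variant == "baseline_exclusion":
        kwargs["exclude_cognitive"] = True
    elif variant == "continuous":
        mode = "continuous"
        rules.continuous_mode = True
    elif variant in ("mnar_best", "mnar_worst"):
        res = apply_eligibility(cohort, rules)
        work = mnar_complete(res.cohort, variant.split("_")[1], mode="binary")
        kwargs["skip_eligibility"] = True
        kwargs["include_censoring_weights"] = False
    elif variant != "primary":
        raise ParameterError(f"unknown variant {variant}")
    result = analyze_cohort(
        work, rules=rules, mode=mode, on_missing="complete_case", **kwargs
    )
    return result


def _result_block(result: dict) -> dict:
    block = {
        "n_input": result["n_input"],
        "exclusions": result["exclusions"],
        "n_analyzed": result["n_analyzed"],
        "total": result["total"].to_dict(),
        "direct": result["direct"].to_dict(),
        "weight_diagnostics": result["diagnostics"].to_dict(),
    }
    if result["summary"] is not None:
        block["decomposition"] = result["summary"].to_dict()
    if result["extra"]:
        block["continuous"] = result["extra"]
    return block


def run_pipeline(config: RunConfig) -> dict:
    """Execute every requested analysis variant and assemble the report."""
    config.validate()
    if config.generator is not None:
        params = dataclasses.replace(config.generator)
        cohort = generate_cohort(params)
        source = {"type": "generator", "seed": params.seed, "n_subjects": params.n_subjects}
    else:
        cohort = CohortTable.from_csv(config.cohort_csv)
        source = {"type": "csv", "path": str(config.cohort_csv), "n_subjects": cohort.n_subjects}
    logger.info("cohort loaded: %d subjects", cohort.n_subjects)

    report: dict = {
        "config": config.resolved_dict(),
        "source": source,
        "analyses": {},
    }

    for variant in config.variants:
        logger.info("running variant: %s", variant)
        result = _variant_result(cohort, variant, config)
        block = _result_block(result)

        if variant == "primary" and config.mi_enabled and config.mode == "binary":
            block["mi"] = _mi_block(cohort, config)
        if variant == "primary" and config.bootstrap_enabled:
            rules = config.rules

            def stat(df):
                return estimate_total_rr(
                    df,
                    rules=rules,
                    mode=config.mode,
                    truncation_percentile=config.truncation_percentile,
                )

            eligible = apply_eligibility(cohort, rules).cohort
            boot = bca_bootstrap(
                eligible.df, stat, B=config.bootstrap_B, seed=config.bootstrap_seed
            )
            block["bootstrap_total_rr"] = boot.to_dict()
        report["analyses"][variant] = block

    report["subject_ledger"] = _ledger(report)
    if config.out_dir:
        _write_artifacts(report, config)
    return report


def _mi_block(cohort: CohortTable, config: RunConfig) -> dict:
    rules = config.rules
    res = apply_eligibility(cohort, rules)
    imp = mice_impute(
        res.cohort.df, m=config.mi_m, seed=config.mi_seed, max_iter=config.mi_max_iter
    )
    log_rrs, variances = [], []
    for completed in imp.datasets:
        result = analyze_cohort(
            CohortTable(completed),
            rules=rules,
            mode="binary",
            truncation_percentile=config.truncation_percentile,
            skip_eligibility=True,
        )
        log_rrs.append(result["total"].beta["cum_x"])
        variances.append(result["total"].robust_se["cum_x"] ** 2)
    pooled = rubin_pool(log_rrs, variances)
    return {
        "m": imp.m,
        "seed": imp.seed,
        "method_map": imp.method_map,
        "n_missing": imp.n_missing,
        "pooled_log_rr": pooled.to_dict(),
        "pooled_total_rr": float(np.exp(pooled.estimate)),
        "pooled_total_rr_ci95": [float(np.exp(v)) for v in pooled.ci95],
    }


def _ledger(report: dict) -> dict:
    ledger = {}
    for name, block in report["analyses"].items():
        n_excl = sum(block["exclusions"].values())
        ledger[name] = {
            "input": block["n_input"],
            "excluded": block["exclusions"],
            "censored_or_unanalyzed": block["n_input"] - n_excl - block["n_analyzed"],
            "analyzed": block["n_analyzed"],
        }
    return ledger


def _write_artifacts(report: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    write_data_dictionary(out / "data_dictionary.csv")
    logger.info("report written to %s", out / "report.json")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate_cohort_csv(path) -> CohortTable:
    """Read and structurally validate a long-format cohort CSV."""
    table = CohortTable.from_csv(path)
    long = table.to_long()
    logger.info(
        "validated cohort: %d subjects, %d long rows, %d missing cells",
        table.n_subjects,
        len(long),
        int(long.isna().sum().sum()),
    )
    return table
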