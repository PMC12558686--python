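"""Chained-equations multiple imputation, Rubin pooling, MNAR bounds.

Imputation runs per column in a fixed causal sweep order (covariates ->
exposure -> mediator -> outcome): binary columns are imputed by posterior
draws from a logistic fit, score columns by predictive mean matching
(nearest-prediction donors).  Every sub-model uses all other analysis
columns, including the outcome, as predictors — standard practice for
chained equations.  Pooling across completed datasets follows Rubin's
combination rules; ratio effects should be pooled on the log scale.

The MNAR bounds replace multiple imputation for the censored: every
subject lost before wave 3 re-enters with the outcome set to 0 (best case:
no dropout developed the outcome) or 1 (worst case: all did).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from .cohort import CohortTable, wide_name
from .errors import DataError, ImputationError, UnsupportedScenarioError

logger = logging.getLogger(__name__)

#: canonical sweep order over the raw analysis columns (causal ordering)
DEFAULT_SWEEP = [
    "social_support_1",
    "social_support_2",
    "mobility_1",
    "mobility_2",
    "chew_group_1",
    "chew_group_2",
    "tils_1",
    "tils_2",
    "cesd_1",
    "cesd_3",
]

#: columns always usable as (complete) predictors
BASE_PREDICTORS = ["female", "education_low", "age_1"]


def _column_wave(col: str) -> int:
    tail = col.rsplit("_", 1)[-1]
    return int(tail) if tail in ("1", "2", "3") else 1


@dataclass
class ImputationSet:
    datasets: list  # completed wide DataFrames
    m: int
    seed: int
    max_iter: int
    method_map: dict
    n_missing: dict
    warnings_log: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        """Write the m completed datasets as CSVs plus a JSON manifest."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        for i, ds in enumerate(self.datasets):
            name = f"imputed_{i + 1:02d}.csv"
            ds.to_csv(out / name, index=False)
            files.append(name)
        manifest = {
            "m": self.m,
            "seed": self.seed,
            "max_iter": self.max_iter,
            "method_map": self.method_map,
            "n_missing": self.n_missing,
            "files": files,
            "warnings": self.warnings_log,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _pmm_draw(
    y_obs: np.ndarray, pred_obs: np.ndarray, pred_mis: np.ndarray, rng, k: int = 5
) -> np.ndarray:
    """Predictive mean matching: draw one of the k nearest observed donors."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    for j, p in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, p)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - p)
        donors = window[np.argsort(dist, kind="stable")[:k]]
        out[j] = y_obs[rng.choice(donors)]
    return out


def mice_impute(
    wide: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    max_iter: int = 10,
    columns: list | None = None,
) -> ImputationSet:
    """Produce ``m`` completed datasets by chained equations.

    Only columns with missingness among ``columns`` (default: the standard
    sweep restricted to subjects present in the table) are imputed;
    observed cells are never altered.  A wave-t column is imputed among
    subjects still observed at wave t, using predictors measured no later
    than wave t (monotone dropout makes later waves unusable for the
    censored).  A non-convergent sub-model falls back to a draw from the
    observed margin, with a logged warning.  Deterministic under ``seed``.
    """
    if m < 2:
        raise DataError("m must be >= 2 for Rubin pooling")
    sweep = [c for c in (columns or DEFAULT_SWEEP) if c in wide.columns]

    def _at_risk(col):
        wave = _column_wave(col)
        if wave == 1 or f"observed_{wave}" not in wide.columns:
            return np.ones(len(wide), dtype=bool)
        return wide[f"observed_{wave}"].to_numpy() == 1

    # a column needs imputing only if it is missing among subjects still
    # observed at its wave (post-censoring holes are structural, not data)
    to_impute = [c for c in sweep if (wide[c].isna().to_numpy() & _at_risk(c)).any()]
    for c in to_impute:
        if wide[c].isna().all():
            raise ImputationError(f"column {c} is entirely missing; cannot impute")
    method_map = {c: ("logistic" if _is_binary(wide[c]) else "pmm") for c in to_impute}
    n_missing = {c: int(wide[c].isna().sum()) for c in to_impute}
    warnings_log: list[str] = []

    at_risk_mask = _at_risk
    predictor_sets = {}
    for c in to_impute:
        wave = _column_wave(c)
        predictor_sets[c] = [
            p
            for p in BASE_PREDICTORS + sweep
            if p != c and p in wide.columns and _column_wave(p) <= wave
        ]

    datasets = []
    for i in range(m):
        rng = np.random.default_rng([seed, i])
        work = wide.copy()
        masks = {c: (wide[c].isna().to_numpy() & at_risk_mask(c)) for c in to_impute}
        # initial fill: bootstrap draws from each column's observed values
        for c in to_impute:
            obs_vals = wide[c].dropna().to_numpy()
            work.loc[masks[c], c] = rng.choice(obs_vals, size=masks[c].sum(), replace=True)
        for _ in range(max_iter if to_impute else 0):
            for c in to_impute:
                mask = masks[c]
                preds = predictor_sets[c]
                X_all = work[preds].to_numpy(dtype=float)
                # predictors may themselves be masked after censoring; keep
                # complete predictor rows only
                row_ok = np.isfinite(X_all).all(axis=1)
                observed_col = work[c].notna().to_numpy()
                fit_rows = row_ok & observed_col & ~mask
                mis_rows = row_ok & mask
                if fit_rows.sum() < len(preds) + 2 or mis_rows.sum() == 0:
                    continue
                Xf = sm.add_constant(X_all[fit_rows], has_constant="add")
                Xm = sm.add_constant(X_all[mis_rows], has_constant="add")
                yf = work.loc[fit_rows, c].to_numpy(dtype=float)
                try:
                    if method_map[c] == "logistic":
                        if yf.min() == yf.max():
                            raise np.linalg.LinAlgError("constant response")
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res = sm.GLM(yf, Xf, family=sm.families.Binomial()).fit(
                                maxiter=100
                            )
                        if not np.all(np.isfinite(res.params)):
                            raise np.linalg.LinAlgError("diverged")
                        p = res.predict(Xm)
                        draws = (rng.random(len(p)) < p).astype(float)
                    else:
                        beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
                        draws = _pmm_draw(yf, Xf @ beta, Xm @ beta, rng)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    msg = f"dataset {i}, column {c}: fallback to marginal draw ({exc})"
                    logger.warning(msg)
                    warnings_log.append(msg)
                    obs_vals = wide[c].dropna().to_numpy()
                    draws = rng.choice(obs_vals, size=int(mis_rows.sum()), replace=True)
                col_idx = work.columns.get_loc(c)
                work.iloc[np.where(mis_rows)[0], col_idx] = draws
        datasets.append(work)
    return ImputationSet(
        datasets=datasets,
        m=m,
        seed=seed,
        max_iter=max_iter,
        method_map=method_map,
        n_missing=n_missing,
        warnings_log=warnings_log,
    )


@dataclass
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci95: tuple
    m: int

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "within_var": self.within_var,
            "between_var": self.between_var,
            "total_var": self.total_var,
            "df": self.df,
            "ci95": list(self.ci95),
            "m": self.m,
        }


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Rubin's rules: Q̄, W̄, B, T = W̄ + (1 + 1/m) B, df and 95% CI.

    For ratio effects pass log-scale estimates and variances and
    back-transform the interval afterwards.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise DataError("estimates and variances must be equal-length 1-d sequences")
    m = len(est)
    if m < 2:
        raise DataError("Rubin pooling needs m >= 2")
    if np.any(var < 0):
        raise DataError("variances must be non-negative")
    qbar = float(est.mean())
    wbar = float(var.mean())
    between = float(est.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * between
    if between > 0 and total > 0:
        r = (1.0 + 1.0 / m) * between / wbar if wbar > 0 else np.inf
        df = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) and r > 0 else float(m - 1)
        tq = float(t_dist.ppf(0.975, df))
    else:
        df = float("inf")
        tq = 1.959963984540054
    half = tq * np.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        within_var=wbar,
        between_var=between,
        total_var=total,
        df=df,
        ci95=(qbar - half, qbar + half),
        m=m,
    )


def mnar_complete(cohort: CohortTable, scenario: str, mode: str = "binary") -> CohortTable:
    """Deterministic best/worst-case outcome completion for the censored.

    ``best`` assigns CES-D below the clinical threshold (outcome-negative)
    to every wave-3-censored subject; ``worst`` assigns the maximum score
    (outcome-positive).  Censored-before-wave-2 subjects have their wave-2
    exposure/mediator and time-varying covariates carried forward from
    wave 1 so they can re-enter the analysis set.  Only defined for the
    binary-outcome analysis.
    """
    if mode != "binary":
        raise UnsupportedScenarioError("MNAR bounds are defined only for the binary outcome")
    if scenario not in ("best", "worst"):
        raise DataError("scenario must be 'best' or 'worst'")
    out = cohort.copy()
    df = out.df
    lost2 = df["observed_2"] == 0
    carry = [
        "age",
        "mobility",
        "cerebrovascular",
        "coronary_heart",
        "diabetes",
        "cancer",
        "social_support",
        "chew_group",
        "tils",
    ]
    for base in carry:
        df.loc[lost2, wide_name(base, 2)] = df.loc[lost2, wide_name(base, 1)].to_numpy()
    lost3 = df["observed_3"] == 0
    df.loc[lost3, "cesd_3"] = 0.0 if scenario == "best" else 22.0
    df["mnar_completed"] = lost3.astype(float)
    df.loc[lost2, "observed_2"] = 1
    df.loc[lost3, "observed_3"] = 1
    # wave-3 covariates are not needed by the outcome models; carry forward
    # wave-2 values where absent so the table stays internally consistent
    for base in ["age", "mobility", "cerebrovascular", "coronary_heart", "diabetes", "cancer", "social_support"]:
        col3, col2 = wide_name(base, 3), wide_name(base, 2)
        hole = df[col3].isna()
        df.loc[hole, col3] = df.loc[hole, col2].to_numpy()
    out.meta["mnar_scenario"] = scenario
    return out
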