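"""Weighted marginal structural outcome models and effect decomposition.

Two pooled models are fitted on one analysis row per subject observed
through wave 3:

* total effect:   log P(Y=1 | cum_x) = b0 + b1 * cum_x
* direct effect:  log P(Y=1 | cum_x, cum_m) = b0 + b1 * cum_x + b2 * cum_m

estimated as weighted Poisson regressions with a log link and a sandwich
(heteroskedasticity-robust) variance, the standard device for relative
risks with binary outcomes.  ``cum_x`` is by default the *mean* of the two
wave indicators, so exp(b1) is the always-vs-never-exposed risk ratio.
The continuous-outcome sensitivity analysis swaps in weighted least
squares with an identity link; mean differences can be converted to
approximate risk ratios for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConsistencyError, DataError, DegenerateFitError, FittingError
from .uncertainty import EValueResult, evalue

Z95 = 1.959963984540054


@dataclass
class MSMResult:
    model: str  # "total" | "direct"
    link: str  # "log" | "identity"
    beta: dict  # coefficient estimates on the link scale
    robust_se: dict
    effect: dict  # exp(beta) for log link, raw difference for identity
    ci95: dict  # on the effect scale
    n_effective: int
    sum_weights: float

    @property
    def beta1_cum(self) -> float:
        return self.beta["cum_x"]

    @property
    def beta2_cum(self) -> float | None:
        return self.beta.get("cum_m")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "link": self.link,
            "beta": self.beta,
            "robust_se": self.robust_se,
            "effect": self.effect,
            "ci95": self.ci95,
            "n_effective": self.n_effective,
            "sum_weights": self.sum_weights,
        }


@dataclass
class MediationSummary:
    total_rr: float
    direct_rr: float
    mediator_rr: float | None
    proportion_mediated: float | None  # percent of the total effect
    proportion_direct: float | None
    evalues: dict = field(default_factory=dict)
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "total_rr": self.total_rr,
            "direct_rr": self.direct_rr,
            "mediator_rr": self.mediator_rr,
            "proportion_mediated": self.proportion_mediated,
            "proportion_direct": self.proportion_direct,
            "evalues": {k: v.to_dict() for k, v in self.evalues.items()},
            "note": self.note,
        }


def build_analysis_rows(wide: pd.DataFrame, cum_coding: str = "mean") -> pd.DataFrame:
    """One row per analysis-set subject with cumulative exposure/mediator.

    ``cum_coding="mean"`` averages the two wave indicators (cum in {0, .5,
    1}); ``"sum"`` adds them (cum in {0, 1, 2}).  Requires coded columns
    and complete exposure/mediator at both waves for every subject
    observed through wave 3 (impute first if needed).
    """
    if cum_coding not in ("mean", "sum"):
        raise ValueError("cum_coding must be 'mean' or 'sum'")
    analysis = wide.loc[wide["observed_3"] == 1]
    if len(analysis) == 0:
        raise DataError("analysis set is empty (no subjects observed through wave 3)")
    needed = ["x_1", "x_2", "m_1", "m_2", "y"]
    incomplete = analysis[needed].isna().any(axis=1)
    if incomplete.any():
        bad = analysis.loc[incomplete, "subject_id"].tolist()
        raise ConsistencyError(
            "missing exposure/mediator/outcome for uncensored subjects "
            f"{bad[:5]}; impute before building analysis rows"
        )
    scale = 0.5 if cum_coding == "mean" else 1.0
    rows = pd.DataFrame(
        {
            "subject_id": analysis["subject_id"].to_numpy(),
            "cum_x": scale * (analysis["x_1"] + analysis["x_2"]).to_numpy(),
            "cum_m": scale * (analysis["m_1"] + analysis["m_2"]).to_numpy(),
            "y": analysis["y"].to_numpy(),
        },
        index=analysis.index,
    )
    return rows


def _design(rows: pd.DataFrame, include_mediator: bool) -> pd.DataFrame:
    cols = ["cum_x", "cum_m"] if include_mediator else ["cum_x"]
    X = rows[cols].copy()
    X.insert(0, "const", 1.0)
    return X


def _extract(res, names, link: str, model: str, n: int, sum_w: float) -> MSMResult:
    beta = {k: float(v) for k, v in zip(names, res.params)}
    se = {k: float(v) for k, v in zip(names, res.bse)}
    effect, ci = {}, {}
    for k in names:
        if k == "const":
            continue
        lo, hi = beta[k] - Z95 * se[k], beta[k] + Z95 * se[k]
        if link == "log":
            effect[k] = float(np.exp(beta[k]))
            ci[k] = (float(np.exp(lo)), float(np.exp(hi)))
        else:
            effect[k] = beta[k]
            ci[k] = (float(lo), float(hi))
    return MSMResult(
        model=model,
        link=link,
        beta=beta,
        robust_se=se,
        effect=effect,
        ci95=ci,
        n_effective=n,
        sum_weights=sum_w,
    )


def fit_msm_binary(
    rows: pd.DataFrame, weights: pd.Series | np.ndarray, include_mediator: bool = False
) -> MSMResult:
    """Weighted log-link Poisson fit with HC0 sandwich standard errors."""
    w = np.asarray(pd.Series(weights).loc[rows.index] if isinstance(weights, pd.Series) else weights, dtype=float)
    if len(w) != len(rows):
        raise DataError("weight vector length does not match analysis rows")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DataError("weights must be positive and finite")
    y = rows["y"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateFitError("outcome is constant; risk ratio undefined")
    X = _design(rows, include_mediator)
    try:
        model = sm.GLM(y, X, family=sm.families.Poisson(), freq_weights=w)
        res = model.fit(cov_type="HC0", maxiter=200)
    except Exception as exc:
        raise FittingError(f"MSM Poisson fit failed ({exc})") from exc
    if not np.all(np.isfinite(res.params)):
        raise FittingError("MSM Poisson fit produced non-finite coefficients")
    return _extract(
        res,
        list(X.columns),
        "log",
        "direct" if include_mediator else "total",
        len(rows),
        float(w.sum()),
    )


def fit_msm_continuous(
    rows: pd.DataFrame, weights: pd.Series | np.ndarray, include_mediator: bool = False
) -> MSMResult:
    """Weighted least squares (identity link) with HC0 sandwich errors."""
    w = np.asarray(pd.Series(weights).loc[rows.index] if isinstance(weights, pd.Series) else weights, dtype=float)
    if len(w) != len(rows):
        raise DataError("weight vector length does not match analysis rows")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DataError("weights must be positive and finite")
    y = rows["y"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateFitError("outcome is constant; mean difference undefined")
    X = _design(rows, include_mediator)
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    return _extract(
        res,
        list(X.columns),
        "identity",
        "direct" if include_mediator else "total",
        len(rows),
        float(w.sum()),
    )


def decompose_effects(total: MSMResult, direct: MSMResult) -> MediationSummary:
    """Excess-relative-risk decomposition of the total effect.

    proportion_direct = (RR_direct - 1) / (RR_total - 1) x 100 and
    proportion_mediated is its complement to 100 (exact by construction).
    When the total RR does not exceed 1 the proportions are undefined and
    reported as such rather than as NaN.
    """
    if total.link != direct.link:
        raise ConsistencyError("total and direct models use different links")
    if total.link == "log":
        rr_t = total.effect["cum_x"]
        rr_d = direct.effect["cum_x"]
        rr_m = direct.effect.get("cum_m")
    else:
        raise ConsistencyError(
            "decompose_effects operates on risk-ratio models; convert mean "
            "differences with md_to_rr first"
        )
    evalues = {
        "total": evalue(rr_t, _ci_limit_near_null(total.ci95.get("cum_x"), rr_t)),
        "direct": evalue(rr_d, _ci_limit_near_null(direct.ci95.get("cum_x"), rr_d)),
    }
    if rr_m is not None:
        evalues["mediator"] = evalue(rr_m, _ci_limit_near_null(direct.ci95.get("cum_m"), rr_m))
    if rr_t <= 1.0:
        return MediationSummary(
            total_rr=rr_t,
            direct_rr=rr_d,
            mediator_rr=rr_m,
            proportion_mediated=None,
            proportion_direct=None,
            evalues=evalues,
            note="total RR <= 1: proportion mediated is undefined",
        )
    proportion_direct = (rr_d - 1.0) / (rr_t - 1.0) * 100.0
    proportion_mediated = 100.0 - proportion_direct
    return MediationSummary(
        total_rr=rr_t,
        direct_rr=rr_d,
        mediator_rr=rr_m,
        proportion_mediated=proportion_mediated,
        proportion_direct=proportion_direct,
        evalues=evalues,
    )


def _ci_limit_near_null(ci: tuple | None, rr: float) -> float | None:
    if ci is None:
        return None
    lo, hi = ci
    return lo if rr >= 1.0 else hi


def md_to_rr(mean_diff: float, reference_sd: float, scaling: float = 0.91) -> float:
    """Approximate risk ratio from a mean difference in score units.

    Standardizes the difference by ``reference_sd`` and exponentiates after
    the usual standardized-mean-difference-to-log-RR scaling (default
    0.91); monotone in ``mean_diff``.
    """
    if reference_sd <= 0:
        raise DataError("reference_sd must be > 0")
    return float(np.exp(scaling * mean_diff / reference_sd))


__all__ = [
    "MSMResult",
    "MediationSummary",
    "build_analysis_rows",
    "fit_msm_binary",
    "fit_msm_continuous",
    "decompose_effects",
    "md_to_rr",
    "EValueResult",
]
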