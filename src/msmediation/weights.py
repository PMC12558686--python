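"""Stabilized inverse-probability weights for exposure, mediator, censoring.

Each weight component is the ratio of two fitted logistic probabilities of
the subject's *observed* state:

* exposure, wave t:  P(X_t | X_{t-1}) / P(X_t | X_{t-1}, L_t)
* mediator, wave t:  P(M_t | X_t, M_{t-1}) / P(M_t | X_t, M_{t-1}, L_t)
* censoring, wave t: P(observed_t) / P(observed_t | history, L)

with the wave-1 numerators conditioning on nothing beyond the available
history (no wave-0 state exists).  The combined weight is the product over
all components, optionally truncated at an upper percentile.  Models are
fitted only on subjects at risk (uncensored entering the wave).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import (
    ConsistencyError,
    DataError,
    FittingError,
    PositivityError,
)

L0_COLUMNS = ["female", "C(ethnicity)", "education_low", "C(housing)"]


def _lt_columns(wave: int) -> list[str]:
    return [
        f"age_{wave}",
        f"mobility_{wave}",
        f"cerebrovascular_{wave}",
        f"coronary_heart_{wave}",
        f"diabetes_{wave}",
        f"cancer_{wave}",
        f"social_support_{wave}",
    ]


@dataclass
class WeightModelSpec:
    """One numerator/denominator logistic model pair."""

    target: str  # "exposure" | "mediator" | "censoring"
    wave: int
    response: str  # binary response column in the wide table
    numerator: list[str]
    denominator: list[str]
    at_risk: str | None = None  # column that must equal 1, or None for all

    def __post_init__(self):
        if self.target not in ("exposure", "mediator", "censoring"):
            raise ValueError(f"unknown weight target: {self.target!r}")
        missing = [c for c in self.numerator if c not in self.denominator]
        if missing:
            raise ValueError(
                f"numerator covariates must be a subset of denominator covariates; "
                f"extra: {missing}"
            )

    @property
    def key(self) -> str:
        prefix = {"exposure": "x", "mediator": "m", "censoring": "c"}[self.target]
        return f"{prefix}{self.wave}"

    def formula(self, which: str) -> str:
        covs = self.numerator if which == "numerator" else self.denominator
        rhs = " + ".join(covs) if covs else "1"
        return f"{self.response} ~ {rhs}"


def default_weight_specs() -> list[WeightModelSpec]:
    """The six standard model pairs for a three-wave analysis.

    Censoring numerators are marginal retention probabilities; censoring
    denominators additionally condition on exposure/mediator history so
    exposure-dependent dropout is corrected.
    """
    specs = [
        WeightModelSpec(
            target="exposure",
            wave=1,
            response="x_1",
            numerator=[],
            denominator=L0_COLUMNS + _lt_columns(1),
        ),
        WeightModelSpec(
            target="mediator",
            wave=1,
            response="m_1",
            numerator=["x_1"],
            denominator=["x_1"] + L0_COLUMNS + _lt_columns(1),
        ),
        WeightModelSpec(
            target="censoring",
            wave=2,
            response="observed_2",
            numerator=[],
            denominator=["x_1", "m_1"] + L0_COLUMNS + _lt_columns(1),
        ),
        WeightModelSpec(
            target="exposure",
            wave=2,
            response="x_2",
            numerator=["x_1"],
            denominator=["x_1"] + L0_COLUMNS + _lt_columns(2),
            at_risk="observed_2",
        ),
        WeightModelSpec(
            target="mediator",
            wave=2,
            response="m_2",
            numerator=["x_2", "m_1"],
            denominator=["x_2", "m_1"] + L0_COLUMNS + _lt_columns(2),
            at_risk="observed_2",
        ),
        WeightModelSpec(
            target="censoring",
            wave=3,
            response="observed_3",
            numerator=[],
            denominator=["x_1", "x_2", "m_1", "m_2"] + L0_COLUMNS + _lt_columns(2),
            at_risk="observed_2",
        ),
    ]
    return specs


@dataclass
class FittedWeightModel:
    spec: WeightModelSpec
    p_numerator: pd.Series  # P(response = 1), indexed like the wide table
    p_denominator: pd.Series
    at_risk_index: pd.Index
    n_at_risk: int


def _fit_logistic(formula: str, data: pd.DataFrame, label: str):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(formula, data=data, family=sm.families.Binomial())
            res = model.fit(maxiter=200)
    except Exception as exc:  # numerical failure inside IRLS
        raise FittingError(f"{label}: logistic fit failed ({exc})") from exc
    if not np.all(np.isfinite(res.params.to_numpy())):
        raise FittingError(f"{label}: non-finite coefficients (separation?)")
    fitted = np.asarray(res.fittedvalues)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        raise FittingError(f"{label}: fitted probabilities at the boundary (perfect separation)")
    return res


def fit_weight_models(wide: pd.DataFrame, specs: list[WeightModelSpec]) -> dict:
    """Fit every numerator/denominator pair on its at-risk set.

    Returns a dict keyed by spec key (``x1``, ``m1``, ``c2``, ...) of
    :class:`FittedWeightModel` with predicted P(response = 1) for at-risk
    subjects (NaN elsewhere).
    """
    fitted: dict[str, FittedWeightModel] = {}
    for spec in specs:
        mask = np.ones(len(wide), dtype=bool) if spec.at_risk is None else (
            wide[spec.at_risk].to_numpy() == 1
        )
        data = wide.loc[mask]
        n_params = len(spec.denominator) + 1
        if len(data) == 0:
            raise DataError(f"{spec.key}: at-risk set is empty")
        if len(data) <= n_params:
            raise FittingError(
                f"{spec.key}: at-risk set of {len(data)} cannot support "
                f"{n_params} parameters"
            )
        if data[spec.response].isna().any():
            raise ConsistencyError(f"{spec.key}: missing response values in at-risk set")
        resp = data[spec.response].to_numpy()
        if len(np.unique(resp)) < 2:
            raise FittingError(f"{spec.key}: response is constant in the at-risk set")
        num_res = _fit_logistic(spec.formula("numerator"), data, f"{spec.key} numerator")
        den_res = _fit_logistic(spec.formula("denominator"), data, f"{spec.key} denominator")
        p_num = pd.Series(np.nan, index=wide.index)
        p_den = pd.Series(np.nan, index=wide.index)
        p_num.loc[data.index] = np.asarray(num_res.predict(data))
        p_den.loc[data.index] = np.asarray(den_res.predict(data))
        fitted[spec.key] = FittedWeightModel(
            spec=spec,
            p_numerator=p_num,
            p_denominator=p_den,
            at_risk_index=data.index,
            n_at_risk=len(data),
        )
    return fitted


@dataclass
class StabilizedWeights:
    """Per-subject weight components and their combined product."""

    components: pd.DataFrame  # one column per spec key, NaN off the at-risk set
    sw_total: pd.Series | None = None
    sw_truncated: pd.Series | None = None
    truncation_threshold: float | None = None
    truncation_lower: float | None = None
    included_keys: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.components.copy()
        if self.sw_total is not None:
            out["sw_total"] = self.sw_total
        if self.sw_truncated is not None:
            out["sw_truncated"] = self.sw_truncated
        return out


def compute_component_weights(fitted: dict, wide: pd.DataFrame) -> StabilizedWeights:
    """Stabilized component = P_num(observed state) / P_den(observed state).

    For censoring models the observed state among at-risk *and retained*
    subjects is "still observed", so the component is the ratio of
    retention probabilities; subjects censored at that wave carry no
    component (they leave the analysis set).
    """
    comp = {}
    for key, fm in fitted.items():
        spec = fm.spec
        p_num = fm.p_numerator
        p_den = fm.p_denominator
        at_risk = fm.at_risk_index
        if np.any(p_den.loc[at_risk].to_numpy() <= 0):
            raise PositivityError(f"{key}: denominator probability of 0 for an observed state")
        if spec.target == "censoring":
            retained = wide.loc[at_risk, spec.response] == 1
            idx = at_risk[retained.to_numpy()]
            w = p_num.loc[idx] / p_den.loc[idx]
        else:
            resp = wide.loc[at_risk, spec.response].to_numpy()
            pn = p_num.loc[at_risk].to_numpy()
            pd_ = p_den.loc[at_risk].to_numpy()
            pn_obs = np.where(resp == 1, pn, 1 - pn)
            pd_obs = np.where(resp == 1, pd_, 1 - pd_)
            if np.any(pd_obs <= 0):
                raise PositivityError(
                    f"{key}: denominator probability of 0 for an observed state"
                )
            w = pd.Series(pn_obs / pd_obs, index=at_risk)
        series = pd.Series(np.nan, index=wide.index)
        series.loc[w.index] = w
        comp[key] = series
    return StabilizedWeights(components=pd.DataFrame(comp, index=wide.index))


def combine_weights(
    weights: StabilizedWeights,
    wide: pd.DataFrame,
    include_mediator: bool = True,
    include_censoring: bool = True,
) -> StabilizedWeights:
    """Multiply components into the combined weight on the analysis set.

    The analysis set is subjects observed through wave 3.  Dropping the
    mediator components yields the weighting for a total-effect-only model;
    dropping censoring components supports sensitivity re-analyses where
    censored subjects re-enter with completed outcomes.
    """
    keys = [k for k in weights.components.columns if k.startswith("x")]
    if include_mediator:
        keys += [k for k in weights.components.columns if k.startswith("m")]
    if include_censoring:
        keys += [k for k in weights.components.columns if k.startswith("c")]
    analysis = wide["observed_3"].to_numpy() == 1
    block = weights.components.loc[analysis, keys]
    if block.isna().any().any():
        bad = block.index[block.isna().any(axis=1)].tolist()
        raise ConsistencyError(
            f"missing weight components for uncensored subjects (rows {bad[:5]})"
        )
    total = pd.Series(np.nan, index=wide.index)
    total.loc[block.index] = block.prod(axis=1)
    return StabilizedWeights(
        components=weights.components,
        sw_total=total,
        included_keys=sorted(keys),
    )


def truncate_weights(
    weights: StabilizedWeights,
    upper_percentile: float = 95.0,
    absolute_cap: float | None = None,
    lower_percentile: float | None = None,
) -> StabilizedWeights:
    """Cap combined weights at an empirical percentile (or an absolute cap).

    Linear-interpolation percentiles; values at or below the threshold are
    untouched.  ``lower_percentile`` switches on symmetric truncation.
    """
    if weights.sw_total is None:
        raise ConsistencyError("combine_weights must run before truncation")
    sw = weights.sw_total.dropna()
    if np.any(sw.to_numpy() <= 0):
        raise DataError("weights must be positive")
    if absolute_cap is not None:
        upper = float(absolute_cap)
    else:
        if not (50.0 < upper_percentile <= 100.0):
            raise DataError("upper_percentile must lie in (50, 100]")
        upper = float(np.percentile(sw.to_numpy(), upper_percentile, method="linear"))
    truncated = sw.clip(upper=upper)
    lower = None
    if lower_percentile is not None:
        lower = float(np.percentile(sw.to_numpy(), lower_percentile, method="linear"))
        truncated = truncated.clip(lower=lower)
    out = pd.Series(np.nan, index=weights.sw_total.index)
    out.loc[truncated.index] = truncated
    return StabilizedWeights(
        components=weights.components,
        sw_total=weights.sw_total,
        sw_truncated=out,
        truncation_threshold=upper,
        truncation_lower=lower,
        included_keys=weights.included_keys,
    )


@dataclass
class WeightDiagnostics:
    before: dict
    after: dict | None
    positivity: dict
    alarm_level: float
    alarms: list

    def to_dict(self) -> dict:
        return {
            "before": self.before,
            "after": self.after,
            "positivity": self.positivity,
            "alarm_level": self.alarm_level,
            "alarms": self.alarms,
        }


def _summary(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "p01": float(np.percentile(values, 1, method="linear")),
        "p95": float(np.percentile(values, 95, method="linear")),
        "p99": float(np.percentile(values, 99, method="linear")),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "n": int(len(values)),
    }


def weight_diagnostics(
    weights: StabilizedWeights,
    fitted: dict | None = None,
    prob_low: float = 0.05,
    prob_high: float = 0.95,
    alarm_level: float = 0.05,
) -> WeightDiagnostics:
    """Distribution summaries plus a positivity screen.

    Positivity is screened on each denominator model's predicted
    probability of the modeled state: the fraction outside
    (``prob_low``, ``prob_high``) is reported per model-wave, with an alarm
    recorded when a fraction exceeds ``alarm_level``.
    """
    if weights.sw_total is None:
        raise ConsistencyError("combine_weights must run before diagnostics")
    before = _summary(weights.sw_total.dropna().to_numpy())
    after = (
        _summary(weights.sw_truncated.dropna().to_numpy())
        if weights.sw_truncated is not None
        else None
    )
    positivity = {}
    alarms = []
    if fitted:
        for key, fm in fitted.items():
            probs = fm.p_denominator.loc[fm.at_risk_index].to_numpy()
            frac_low = float(np.mean(probs < prob_low))
            frac_high = float(np.mean(probs > prob_high))
            positivity[key] = {
                "frac_below": frac_low,
                "frac_above": frac_high,
                "n": int(len(probs)),
            }
            if frac_low + frac_high > alarm_level:
                alarms.append(
                    f"{key}: {100 * (frac_low + frac_high):.1f}% of predicted "
                    f"probabilities outside ({prob_low}, {prob_high})"
                )
    return WeightDiagnostics(
        before=before,
        after=after,
        positivity=positivity,
        alarm_level=alarm_level,
        alarms=alarms,
    )
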