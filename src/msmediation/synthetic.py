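"""Synthetic three-wave cohort generator with a counterfactual oracle.

The generator emulates a community cohort of older adults followed over
three survey waves, with a time-varying binary exposure (chewing
disability), a time-varying binary mediator (loneliness), informative
monotone dropout, and a terminal depressive-symptom outcome at wave 3.
The causal structure is the usual exposure-confounder feedback DAG:

    L1 -> X1 -> M1 -> C2 ;  X1 -> L2 -> X2 -> M2 -> C3 ;  {X, M, L} -> Y

Binary nodes follow logistic structural equations with main effects;
continuous scores follow linear-Gaussian autoregressions, rounded and
clipped to their instrument ranges.  Wave-1 margins are calibrated to the
published baseline distribution of the source survey by solving each
structural intercept so the realized marginal prevalence matches its
target; downstream intercepts are likewise calibrated to wave-level
retention and outcome-prevalence targets so the cohort's gross shape does
not drift when structural coefficients are changed.

Ground truth is available because the same structural equations can be
propagated under interventions: :func:`true_effects` sets the exposure to
1 or 0 at both waves (removing censoring), and obtains a "direct" contrast
by holding the mediator path at its natural value under never-exposure — a
randomized-interventional analogue of the natural direct effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .cohort import ETHNICITIES, HOUSING, CohortTable, wide_columns
from .errors import DegenerateEstimandError, ParameterError

__all__ = [
    "BaselineMargins",
    "StructuralCoefficients",
    "GeneratorParams",
    "TrueEffects",
    "generate_cohort",
    "true_effects",
    "default_params",
    "null_params",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class BaselineMargins:
    """Wave-1 marginal targets plus wave-level retention/outcome targets.

    Defaults reproduce the baseline column of the source survey's
    descriptive table (prevalences in fractions, scores on their native
    scales); retention targets reflect the survey's attrition between
    waves, and ``outcome_prevalence`` the cumulative wave-3 incidence of
    clinically significant depressive symptoms.
    """

    female: float = 0.535
    ethnicity: dict = field(
        default_factory=lambda: {
            "Chinese": 0.760,
            "Malay": 0.153,
            "Indian": 0.077,
            "Others": 0.010,
        }
    )
    education_low: float = 0.676
    housing: dict = field(
        default_factory=lambda: {
            "1-2_room_public": 0.067,
            "3_room_public": 0.271,
            "4-5_room_or_private": 0.662,
        }
    )
    age_mean: float = 70.4
    age_sd: float = 7.1
    mobility: float = 0.295
    cerebrovascular: float = 0.021
    coronary_heart: float = 0.055
    diabetes: float = 0.217
    cancer: float = 0.019
    support_mean: float = 30.2
    support_sd: float = 12.6
    exposure_w1: float = 0.168
    mediator_w1: float = 0.417
    exposure_w2: float = 0.253
    mediator_w2: float = 0.360
    retention_w2: float = 0.645
    retention_w3: float = 0.520
    outcome_prevalence: float = 0.103
    cognitive_flag: float = 0.12


@dataclass
class StructuralCoefficients:
    """Log-odds (binary nodes) / score-point (linear nodes) DAG coefficients.

    ``age_c`` is (age - 70)/10 and ``support_c`` is (support - 30)/10, so
    the covariate coefficients are per-decade and per-10-points.
    """

    # L -> X (chewing disability)
    l_x: dict = field(
        default_factory=lambda: {
            "mobility": 0.50,
            "age_c": 0.35,
            "education_low": 0.40,
            "support_c": -0.15,
            "female": -0.10,
        }
    )
    x_persist: float = 1.8  # X_{t-1} -> X_t
    # X_t -> M_t and L -> M (loneliness)
    x_m: float = 0.50
    l_m: dict = field(
        default_factory=lambda: {
            "mobility": 0.40,
            "age_c": 0.10,
            "support_c": -0.35,
            "female": 0.20,
        }
    )
    m_persist: float = 1.6  # M_{t-1} -> M_t
    # retention (observed-at-next-wave) structural terms
    x_c: float = -0.35  # exposure lowers retention (informative dropout)
    l_c: dict = field(
        default_factory=lambda: {
            "age_c": -0.45,
            "mobility": -0.30,
            "support_c": 0.10,
        }
    )
    # outcome (defaults put the oracle total risk ratio near 1.5 with a
    # mediated share around one fifth, the regime the package targets)
    x_y: float = 0.11  # per exposed wave
    m_y: float = 0.30  # per lonely wave
    l_y: dict = field(
        default_factory=lambda: {
            "mobility": 0.50,
            "age_c": 0.30,
            "support_c": -0.20,
            "female": 0.30,
        }
    )
    # exposure -> later time-varying confounders (the feedback that makes
    # naive regression adjustment fail and motivates weighting)
    x_feedback_mobility: float = 0.40
    x_feedback_support: float = -1.5  # score points

    def as_flat_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dict):
                for k, coef in v.items():
                    out[f"{f.name}.{k}"] = coef
            else:
                out[f.name] = v
        return out


@dataclass
class GeneratorParams:
    """Full parameterization of the synthetic cohort."""

    n_subjects: int = 2000
    baseline_margins: BaselineMargins = field(default_factory=BaselineMargins)
    structural: StructuralCoefficients = field(default_factory=StructuralCoefficients)
    outcome_scale: str = "binary"  # "binary" | "continuous"
    noise_sd: float = 4.0  # residual SD of the continuous latent CES-D score
    missingness: float = 0.0  # MCAR item-missingness rate on score columns
    seed: int = 0

    def validate(self) -> "GeneratorParams":
        m = self.baseline_margins
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        for name in (
            "female",
            "education_low",
            "mobility",
            "cerebrovascular",
            "coronary_heart",
            "diabetes",
            "cancer",
            "exposure_w1",
            "mediator_w1",
            "exposure_w2",
            "mediator_w2",
            "retention_w2",
            "retention_w3",
            "outcome_prevalence",
            "cognitive_flag",
        ):
            v = getattr(m, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"baseline_margins.{name} must lie in (0, 1); got {v}")
        for name in ("age_sd", "support_sd"):
            if getattr(m, name) <= 0:
                raise ParameterError(f"baseline_margins.{name} must be > 0")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if not (0.0 <= self.missingness < 1.0):
            raise ParameterError("missingness must lie in [0, 1)")
        if self.outcome_scale not in ("binary", "continuous"):
            raise ParameterError("outcome_scale must be 'binary' or 'continuous'")
        for key, coef in self.structural.as_flat_dict().items():
            if not np.isfinite(coef):
                raise ParameterError(f"structural.{key} is not finite")
        for label, probs in (("ethnicity", m.ethnicity), ("housing", m.housing)):
            if any(p <= 0 for p in probs.values()):
                raise ParameterError(f"baseline_margins.{label} probabilities must be > 0")
        return self

    # flat-config round trip (path-style keys -> numbers / strings)
    def to_flat(self) -> dict:
        flat = {
            "n_subjects": self.n_subjects,
            "outcome_scale": self.outcome_scale,
            "noise_sd": self.noise_sd,
            "missingness": self.missingness,
            "seed": self.seed,
        }
        for f in dataclasses.fields(self.baseline_margins):
            v = getattr(self.baseline_margins, f.name)
            if isinstance(v, dict):
                for k, p in v.items():
                    flat[f"baseline_margins.{f.name}.{k}"] = p
            else:
                flat[f"baseline_margins.{f.name}"] = v
        for k, coef in self.structural.as_flat_dict().items():
            flat[f"structural.{k}"] = coef
        return flat

    @classmethod
    def from_flat(cls, flat: dict) -> "GeneratorParams":
        params = cls()
        margins = params.baseline_margins
        struct = params.structural
        for key, value in flat.items():
            parts = key.split(".")
            if parts[0] == "baseline_margins":
                if len(parts) == 3:
                    getattr(margins, parts[1])[parts[2]] = float(value)
                else:
                    setattr(margins, parts[1], float(value))
            elif parts[0] == "structural":
                if len(parts) == 3:
                    getattr(struct, parts[1])[parts[2]] = float(value)
                else:
                    setattr(struct, parts[1], float(value))
            elif key in ("n_subjects", "seed"):
                setattr(params, key, int(value))
            elif key == "outcome_scale":
                params.outcome_scale = str(value)
            elif key in ("noise_sd", "missingness"):
                setattr(params, key, float(value))
            else:
                raise ParameterError(f"unknown config key: {key}")
        return params


@dataclass
class TrueEffects:
    """Oracle marginal contrasts computed from potential outcomes."""

    true_total_rr: float
    true_direct_rr: float
    risk_always: float
    risk_never: float
    risk_direct: float
    mc_se_total: float
    mc_se_direct: float
    n_mc: int


def default_params(**overrides) -> GeneratorParams:
    """Generator defaults calibrated to the source survey's margins."""
    return dataclasses.replace(GeneratorParams(), **overrides)


def null_params(**overrides) -> GeneratorParams:
    """Defaults with every exposure/mediator effect pathway switched off.

    Confounding arrows (L -> X, L -> M, L -> C, L -> Y) are retained, so the
    cohort is still confounded but the causal null holds: the oracle total
    and direct risk ratios are exactly 1.
    """
    p = GeneratorParams(**overrides) if overrides else GeneratorParams()
    s = p.structural
    s.x_m = 0.0
    s.x_y = 0.0
    s.m_y = 0.0
    s.x_feedback_mobility = 0.0
    s.x_feedback_support = 0.0
    return p


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _calibrate_intercept(offsets: np.ndarray, target: float) -> float:
    """Solve mean(expit(b + offsets)) = target for the intercept b."""

    def gap(b):
        return expit(b + offsets).mean() - target

    lo, hi = -30.0, 30.0
    return brentq(gap, lo, hi, xtol=1e-12)


def _score_c(values: np.ndarray, center: float) -> np.ndarray:
    return (values - center) / 10.0


def _ldot(coefs: dict, cov: dict) -> np.ndarray:
    """Linear combination of named covariate arrays."""
    total = 0.0
    for name, beta in coefs.items():
        total = total + beta * cov[name]
    return total


def _draw_exogenous(params: GeneratorParams, rng: np.random.Generator) -> dict:
    """Draw everything exogenous up front, in a fixed order.

    Structural uniforms are pre-drawn so that counterfactual propagation can
    reuse them (common random numbers) and so that changing a downstream
    coefficient never perturbs an upstream draw.
    """
    n = params.n_subjects
    m = params.baseline_margins
    d = {}
    d["female"] = (rng.random(n) < m.female).astype(float)
    eth_p = np.array([m.ethnicity[e] for e in ETHNICITIES], dtype=float)
    d["ethnicity"] = rng.choice(np.array(ETHNICITIES), size=n, p=eth_p / eth_p.sum())
    d["education_low"] = (rng.random(n) < m.education_low).astype(float)
    house_p = np.array([m.housing[h] for h in HOUSING], dtype=float)
    d["housing"] = rng.choice(np.array(HOUSING), size=n, p=house_p / house_p.sum())
    d["cognitive_flag"] = (rng.random(n) < m.cognitive_flag).astype(float)
    d["age_1"] = np.clip(rng.normal(m.age_mean, m.age_sd, n), 60.0, 100.0)
    d["mobility_1"] = (rng.random(n) < m.mobility).astype(float)
    d["cerebrovascular_1"] = (rng.random(n) < m.cerebrovascular).astype(float)
    d["coronary_heart_1"] = (rng.random(n) < m.coronary_heart).astype(float)
    d["diabetes_1"] = (rng.random(n) < m.diabetes).astype(float)
    d["cancer_1"] = (rng.random(n) < m.cancer).astype(float)
    d["social_support_1"] = np.round(
        np.clip(rng.normal(m.support_mean, m.support_sd, n), 0.0, 60.0)
    )
    # structural uniforms, fixed order
    for key in ("u_x1", "u_m1", "u_c2", "u_mob2", "u_x2", "u_m2", "u_c3", "u_mob3", "u_y"):
        d[key] = rng.random(n)
    # disease incidence uniforms and support innovations
    for t, scale in ((2, 1.0), (3, 1.6)):
        for base, inc in (
            ("cerebrovascular", 0.012),
            ("coronary_heart", 0.020),
            ("diabetes", 0.045),
            ("cancer", 0.012),
        ):
            d[f"u_{base}_{t}"] = rng.random(n)
            d[f"inc_{base}_{t}"] = inc * scale
    d["eps_support_2"] = rng.normal(0.0, 6.0, n)
    d["eps_support_3"] = rng.normal(0.0, 6.0, n)
    d["eps_cesd"] = rng.normal(0.0, params.noise_sd, n)  # continuous-scale latent noise
    d["eps_cesd_1"] = rng.normal(2.4, 2.7, n)  # baseline depressive-score noise
    return d


def _wave_cov(d: dict, t: int, mobility: np.ndarray, support: np.ndarray, age: np.ndarray) -> dict:
    return {
        "mobility": mobility,
        "age_c": _score_c(age, 70.0),
        "support_c": _score_c(support, 30.0),
        "education_low": d["education_low"],
        "female": d["female"],
    }


def _propagate(
    params: GeneratorParams,
    d: dict,
    intercepts: dict | None = None,
    x_policy: int | None = None,
    m_path: tuple[np.ndarray, np.ndarray] | None = None,
    with_censoring: bool = True,
) -> dict:
    """Run the structural equations forward given pre-drawn exogenous terms.

    With ``intercepts=None`` the propagation is *natural* and calibrates the
    intercepts so realized margins hit their targets; interventional arms
    must re-use the intercepts returned by a natural pass so that do()
    operations change only the targeted node.
    """
    s = params.structural
    m = params.baseline_margins
    calibrating = intercepts is None
    ic = {} if calibrating else intercepts
    out = {}

    age1, age2, age3 = d["age_1"], d["age_1"] + 2.0, d["age_1"] + 5.5
    mob1 = d["mobility_1"]
    sup1 = d["social_support_1"]
    cov1 = _wave_cov(d, 1, mob1, sup1, age1)

    # wave 1 exposure
    off_x1 = _ldot(s.l_x, cov1)
    if calibrating:
        ic["x1"] = _calibrate_intercept(off_x1, m.exposure_w1)
    p_x1 = expit(ic["x1"] + off_x1)
    x1 = (d["u_x1"] < p_x1).astype(float) if x_policy is None else np.full_like(p_x1, x_policy)

    # wave 1 mediator
    off_m1 = s.x_m * x1 + _ldot(s.l_m, cov1)
    if calibrating:
        ic["m1"] = _calibrate_intercept(off_m1, m.mediator_w1)
    p_m1 = expit(ic["m1"] + off_m1)
    m1 = (d["u_m1"] < p_m1).astype(float) if m_path is None else m_path[0]

    # baseline depressive score (eligibility screening only)
    cesd1 = np.round(np.clip(d["eps_cesd_1"] + 1.8 * m1 + 0.6 * mob1, 0.0, 22.0))

    # retention into wave 2
    off_c2 = s.x_c * x1 + _ldot(s.l_c, cov1)
    if calibrating:
        ic["c2"] = _calibrate_intercept(off_c2, m.retention_w2)
    obs2 = (
        (d["u_c2"] < expit(ic["c2"] + off_c2)).astype(float)
        if with_censoring
        else np.ones_like(x1)
    )

    # wave 2 time-varying covariates (exposure feedback acts here)
    lp_mob2 = -1.4 + 1.9 * mob1 + 0.25 * _score_c(age2, 70.0) + s.x_feedback_mobility * x1
    mob2 = (d["u_mob2"] < expit(lp_mob2)).astype(float)
    sup2 = np.round(
        np.clip(
            30.0 + 0.75 * (sup1 - 30.0) + s.x_feedback_support * x1 + d["eps_support_2"],
            0.0,
            60.0,
        )
    )
    dis2 = {}
    for base in ("cerebrovascular", "coronary_heart", "diabetes", "cancer"):
        dis2[base] = np.maximum(
            d[f"{base}_1"], (d[f"u_{base}_2"] < d[f"inc_{base}_2"]).astype(float)
        )
    cov2 = _wave_cov(d, 2, mob2, sup2, age2)

    # wave 2 exposure
    off_x2 = s.x_persist * x1 + _ldot(s.l_x, cov2)
    if calibrating:
        ic["x2"] = _calibrate_intercept(off_x2, m.exposure_w2)
    p_x2 = expit(ic["x2"] + off_x2)
    x2 = (d["u_x2"] < p_x2).astype(float) if x_policy is None else np.full_like(p_x2, x_policy)

    # wave 2 mediator
    off_m2 = s.m_persist * m1 + s.x_m * x2 + _ldot(s.l_m, cov2)
    if calibrating:
        ic["m2"] = _calibrate_intercept(off_m2, m.mediator_w2)
    p_m2 = expit(ic["m2"] + off_m2)
    m2 = (d["u_m2"] < p_m2).astype(float) if m_path is None else m_path[1]

    # retention into wave 3
    off_c3 = s.x_c * x2 + _ldot(s.l_c, cov2)
    if calibrating:
        ic["c3"] = _calibrate_intercept(off_c3, m.retention_w3)
    obs3 = obs2 * (
        (d["u_c3"] < expit(ic["c3"] + off_c3)).astype(float)
        if with_censoring
        else np.ones_like(x1)
    )

    # wave 3 covariates
    lp_mob3 = -1.4 + 1.9 * mob2 + 0.25 * _score_c(age3, 70.0) + s.x_feedback_mobility * x2
    mob3 = (d["u_mob3"] < expit(lp_mob3)).astype(float)
    sup3 = np.round(
        np.clip(
            30.0 + 0.75 * (sup2 - 30.0) + s.x_feedback_support * x2 + d["eps_support_3"],
            0.0,
            60.0,
        )
    )
    dis3 = {}
    for base in ("cerebrovascular", "coronary_heart", "diabetes", "cancer"):
        dis3[base] = np.maximum(dis2[base], (d[f"u_{base}_3"] < d[f"inc_{base}_3"]).astype(float))
    cov3 = _wave_cov(d, 3, mob3, sup3, age3)

    # outcome; the prevalence target is matched among wave-3 completers,
    # mirroring how a cohort's follow-up table reports incidence.  The
    # binary outcome uses a log-risk link (risk multiplicative in every
    # parent, capped at 0.98) so marginal risk ratios are collapsible and
    # the log-linear pooled outcome model is correctly specified for the
    # cohort it analyzes; X, M and C stay logistic.
    off_y = s.x_y * (x1 + x2) + s.m_y * (m1 + m2) + _ldot(s.l_y, cov3)
    completer = obs3 == 1

    def _log_risk(b, off):
        return np.minimum(np.exp(b + off), 0.98)

    if params.outcome_scale == "binary":
        if calibrating:

            def gap(b):
                return _log_risk(b, off_y[completer]).mean() - m.outcome_prevalence

            ic["y"] = brentq(gap, -40.0, 5.0, xtol=1e-12)
        p_y = _log_risk(ic["y"], off_y)
        y = (d["u_y"] < p_y).astype(float)
        cesd_latent = None
    else:
        # linear latent CES-D score; coefficients scaled from log-odds to
        # score points; prevalence target enforced through the threshold
        score_off = 4.0 * off_y
        if calibrating:

            def gap(b):
                return norm.sf(
                    6.5, loc=b + score_off[completer], scale=params.noise_sd
                ).mean() - m.outcome_prevalence

            ic["y"] = brentq(gap, -40.0, 40.0, xtol=1e-10)
        cesd_latent = ic["y"] + score_off + d["eps_cesd"]
        p_y = norm.sf(6.5, loc=ic["y"] + score_off, scale=params.noise_sd)
        y = (np.round(np.clip(cesd_latent, 0.0, 22.0)) >= 7).astype(float)

    out.update(
        x1=x1,
        m1=m1,
        cesd1=cesd1,
        x2=x2,
        m2=m2,
        obs2=obs2,
        obs3=obs3,
        y=y,
        p_y=p_y,
        mob2=mob2,
        mob3=mob3,
        sup2=sup2,
        sup3=sup3,
        dis2=dis2,
        dis3=dis3,
        age2=age2,
        age3=age3,
        cesd_latent=cesd_latent,
        intercepts=ic,
    )
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_CHEW_GROUPS = np.array([2, 3, 4, 5, 6])
_CHEW_P = np.array([0.30, 0.25, 0.20, 0.15, 0.10])


def generate_cohort(params: GeneratorParams) -> CohortTable:
    """Generate one synthetic three-wave cohort.

    The same seed always yields the identical table; values after a
    subject's censoring wave are missing, as they would be in the field.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    d = _draw_exogenous(params, rng)
    nat = _propagate(params, d, intercepts=None, with_censoring=True)
    n = params.n_subjects

    # ordinal chewing group consistent with the binary exposure
    chew_extra_1 = rng.choice(_CHEW_GROUPS, size=n, p=_CHEW_P)
    chew_extra_2 = rng.choice(_CHEW_GROUPS, size=n, p=_CHEW_P)
    chew1 = np.where(nat["x1"] == 1, chew_extra_1, 1).astype(float)
    chew2 = np.where(nat["x2"] == 1, chew_extra_2, 1).astype(float)

    # TILS score consistent with the binary loneliness indicator
    t_extra_1 = np.clip(1 + np.round(np.abs(rng.normal(1.5, 2.2, n))), 1, 12)
    t_extra_2 = np.clip(1 + np.round(np.abs(rng.normal(1.5, 2.2, n))), 1, 12)
    tils1 = np.where(nat["m1"] == 1, t_extra_1, 0.0)
    tils2 = np.where(nat["m2"] == 1, t_extra_2, 0.0)

    cesd1 = nat["cesd1"]

    # wave-3 CES-D score consistent with the binary outcome
    if params.outcome_scale == "binary":
        hi = 7 + np.clip(np.round(np.abs(rng.normal(2.5, 3.0, n))), 0, 15)
        lo = np.clip(np.round(rng.normal(3.0, 1.8, n)), 0, 6)
        cesd3 = np.where(nat["y"] == 1, hi, lo).astype(float)
    else:
        cesd3 = np.round(np.clip(nat["cesd_latent"], 0.0, 22.0))

    obs2 = nat["obs2"]
    obs3 = nat["obs3"]

    def mask(values, observed):
        return np.where(observed == 1, values, np.nan)

    df_cols = {
        "subject_id": np.arange(1, n + 1),
        "female": d["female"],
        "ethnicity": d["ethnicity"],
        "education_low": d["education_low"],
        "housing": d["housing"],
        "cognitive_flag": d["cognitive_flag"],
        "age_1": np.round(d["age_1"], 1),
        "age_2": mask(np.round(nat["age2"], 1), obs2),
        "age_3": mask(np.round(nat["age3"], 1), obs3),
        "mobility_1": d["mobility_1"],
        "mobility_2": mask(nat["mob2"], obs2),
        "mobility_3": mask(nat["mob3"], obs3),
        "cerebrovascular_1": d["cerebrovascular_1"],
        "cerebrovascular_2": mask(nat["dis2"]["cerebrovascular"], obs2),
        "cerebrovascular_3": mask(nat["dis3"]["cerebrovascular"], obs3),
        "coronary_heart_1": d["coronary_heart_1"],
        "coronary_heart_2": mask(nat["dis2"]["coronary_heart"], obs2),
        "coronary_heart_3": mask(nat["dis3"]["coronary_heart"], obs3),
        "diabetes_1": d["diabetes_1"],
        "diabetes_2": mask(nat["dis2"]["diabetes"], obs2),
        "diabetes_3": mask(nat["dis3"]["diabetes"], obs3),
        "cancer_1": d["cancer_1"],
        "cancer_2": mask(nat["dis2"]["cancer"], obs2),
        "cancer_3": mask(nat["dis3"]["cancer"], obs3),
        "social_support_1": d["social_support_1"],
        "social_support_2": mask(nat["sup2"], obs2),
        "social_support_3": mask(nat["sup3"], obs3),
        "chew_group_1": chew1,
        "chew_group_2": mask(chew2, obs2),
        "tils_1": tils1,
        "tils_2": mask(tils2, obs2),
        "cesd_1": cesd1,
        "cesd_3": mask(cesd3, obs3),
        "observed_1": np.ones(n),
        "observed_2": obs2,
        "observed_3": obs3,
    }
    import pandas as pd

    df = pd.DataFrame(df_cols)[wide_columns()]

    if params.missingness > 0:
        # MCAR item missingness on score columns, never on censoring flags
        targets = [
            ("chew_group_2", obs2),
            ("tils_1", np.ones(n)),
            ("tils_2", obs2),
            ("social_support_1", np.ones(n)),
            ("social_support_2", obs2),
        ]
        for col, at_risk in targets:
            gone = (rng.random(n) < params.missingness) & (at_risk == 1)
            df.loc[gone, col] = np.nan

    table = CohortTable(
        df,
        meta={
            "seed": params.seed,
            "intercepts": {k: float(v) for k, v in nat["intercepts"].items()},
            "outcome_scale": params.outcome_scale,
        },
    )
    return table.validate()


def true_effects(
    params: GeneratorParams,
    n_mc: int = 200_000,
    seed: int = 12345,
    eligible_only: bool = True,
    baseline_threshold: int = 7,
) -> TrueEffects:
    """Monte-Carlo oracle for the marginal causal contrasts the MSM targets.

    Risks are population means of the structural outcome probability under
    interventions on the exposure at both waves with censoring removed.
    ``true_direct_rr`` holds the mediator path at its natural value under
    never-exposure while setting the exposure to 1 (a randomized-
    interventional direct-effect analogue).  Common random numbers pair the
    arms subject-by-subject.  With ``eligible_only`` the contrast is taken
    in the analysis-eligible subpopulation (natural baseline depressive
    score below the clinical threshold), matching the estimand of an
    analysis that screens out baseline cases.
    """
    params.validate()
    if n_mc < 1000:
        raise ParameterError("n_mc must be >= 1000 for a stable oracle")
    p = dataclasses.replace(params, n_subjects=int(n_mc))
    rng = np.random.default_rng(seed)
    d = _draw_exogenous(p, rng)
    # intercepts come from a natural pass (censoring included) so the
    # interventional arms share the cohort's structural model exactly
    nat = _propagate(p, d, intercepts=None, with_censoring=True)
    ic = nat["intercepts"]
    arm1 = _propagate(p, d, intercepts=ic, x_policy=1, with_censoring=False)
    arm0 = _propagate(p, d, intercepts=ic, x_policy=0, with_censoring=False)
    armd = _propagate(
        p, d, intercepts=ic, x_policy=1, m_path=(arm0["m1"], arm0["m2"]), with_censoring=False
    )

    keep = nat["cesd1"] < baseline_threshold if eligible_only else np.ones(int(n_mc), dtype=bool)
    n_kept = int(keep.sum())
    r1, r0, rd = (
        arm1["p_y"][keep].mean(),
        arm0["p_y"][keep].mean(),
        armd["p_y"][keep].mean(),
    )
    if r0 <= 0:
        raise DegenerateEstimandError("zero risk in the never-exposed arm")
    se = {
        k: arm["p_y"][keep].std(ddof=1) / np.sqrt(n_kept)
        for k, arm in (("1", arm1), ("0", arm0), ("d", armd))
    }
    rr_t = r1 / r0
    rr_d = rd / r0
    mc_se_total = rr_t * np.sqrt((se["1"] / r1) ** 2 + (se["0"] / r0) ** 2)
    mc_se_direct = rr_d * np.sqrt((se["d"] / rd) ** 2 + (se["0"] / r0) ** 2)
    return TrueEffects(
        true_total_rr=float(rr_t),
        true_direct_rr=float(rr_d),
        risk_always=float(r1),
        risk_never=float(r0),
        risk_direct=float(rd),
        mc_se_total=float(mc_se_total),
        mc_se_direct=float(mc_se_direct),
        n_mc=int(n_mc),
    )
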