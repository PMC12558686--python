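"""Generator calibration, determinism, censoring structure, and the oracle."""

import dataclasses

import numpy as np
import pytest

import msmediation as mm
from msmediation.errors import ParameterError


def _binomial_3se(p, n):
    return 3.0 * np.sqrt(p * (1 - p) / n)


def test_null_coefficient_margins_match_targets():
    """With all structural coefficients zero, margins equal their targets."""
    p = mm.null_params(n_subjects=10000, seed=3)
    s = p.structural
    for dct in (s.l_x, s.l_m, s.l_c, s.l_y):
        for k in dct:
            dct[k] = 0.0
    s.x_persist = s.m_persist = s.x_c = 0.0
    p.baseline_margins.exposure_w1 = 0.5
    df = mm.generate_cohort(p).df
    x1 = (df["chew_group_1"] > 1).mean()
    assert abs(x1 - 0.5) < _binomial_3se(0.5, 10000)


def test_calibrated_margins_match_survey_table():
    """Default margins reproduce the published baseline distribution."""
    p = mm.default_params(n_subjects=20000, seed=11)
    df = mm.generate_cohort(p).df
    n = len(df)
    checks = {
        "female": (df["female"].mean(), 0.535),
        "chewing disability": ((df["chew_group_1"] > 1).mean(), 0.168),
        "loneliness": ((df["tils_1"] >= 1).mean(), 0.417),
        "education": (df["education_low"].mean(), 0.676),
    }
    for name, (observed, target) in checks.items():
        assert abs(observed - target) < _binomial_3se(target, n), name
    assert df["age_1"].mean() == pytest.approx(70.4, abs=0.3)
    assert df["social_support_1"].mean() == pytest.approx(30.2, abs=0.4)


def test_same_seed_identical_tables(tmp_path):
    p = mm.default_params(n_subjects=500, seed=42)
    a = mm.generate_cohort(p)
    b = mm.generate_cohort(dataclasses.replace(p))
    fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(fa)
    b.to_csv(fb)
    assert fa.read_bytes() == fb.read_bytes()
    c = mm.generate_cohort(dataclasses.replace(p, seed=43))
    assert not a.df.equals(c.df)


def test_monotone_censoring_everywhere():
    df = mm.generate_cohort(mm.default_params(n_subjects=8000, seed=9)).df
    assert (df["observed_1"] == 1).all()
    assert not ((df["observed_2"] == 0) & (df["observed_3"] == 1)).any()
    # post-censoring values are missing
    lost2 = df["observed_2"] == 0
    assert df.loc[lost2, "chew_group_2"].isna().all()
    assert df.loc[df["observed_3"] == 0, "cesd_3"].isna().all()


def test_no_anticipation_of_outcome_parameters():
    """Changing wave-3 (outcome) coefficients never touches waves 1-2."""
    p1 = mm.default_params(n_subjects=2000, seed=13)
    p2 = mm.default_params(n_subjects=2000, seed=13)
    p2.structural.x_y = 0.9
    p2.structural.m_y = 0.0
    p2.structural.l_y = {k: -v for k, v in p2.structural.l_y.items()}
    a, b = mm.generate_cohort(p1).df, mm.generate_cohort(p2).df
    w12 = [c for c in a.columns if not c.endswith("_3")]
    assert a[w12].equals(b[w12])


def test_score_ranges_respected():
    df = mm.generate_cohort(mm.default_params(n_subjects=5000, seed=21)).df
    assert df["tils_1"].between(0, 12).all()
    assert df["cesd_1"].between(0, 22).all()
    assert df["cesd_3"].dropna().between(0, 22).all()
    assert df["social_support_1"].between(0, 60).all()
    assert df["chew_group_1"].isin([1, 2, 3, 4, 5, 6]).all()


def test_parameter_validation_names_offender():
    p = mm.default_params()
    p.baseline_margins.mediator_w1 = 1.5
    with pytest.raises(ParameterError, match="mediator_w1"):
        mm.generate_cohort(p)
    q = mm.default_params()
    q.structural.x_y = float("nan")
    with pytest.raises(ParameterError, match="x_y"):
        mm.generate_cohort(q)


def test_flat_config_round_trip():
    p = mm.default_params(n_subjects=123, seed=9)
    p.structural.x_y = 0.21
    q = mm.GeneratorParams.from_flat(p.to_flat())
    assert q.to_flat() == p.to_flat()


def test_oracle_null_effect_is_one():
    te = mm.true_effects(mm.null_params(), n_mc=50000, seed=2)
    assert te.true_total_rr == pytest.approx(1.0, abs=3 * te.mc_se_total)
    assert te.true_direct_rr == pytest.approx(1.0, abs=3 * te.mc_se_direct)


def test_oracle_pure_mediation():
    """No direct path: total RR > 1 while the direct contrast is null."""
    p = mm.default_params()
    p.structural.x_y = 0.0
    p.structural.x_feedback_mobility = 0.0
    p.structural.x_feedback_support = 0.0
    p.structural.x_m = 0.8
    p.structural.m_y = 0.5
    te = mm.true_effects(p, n_mc=80000, seed=4)
    assert te.true_total_rr > 1.0 + 3 * te.mc_se_total
    assert te.true_direct_rr == pytest.approx(1.0, abs=3 * te.mc_se_direct)


def test_oracle_monotone_in_direct_effect():
    rrs = []
    for x_y in (0.0, 0.1, 0.2, 0.35):
        p = mm.default_params()
        p.structural.x_y = x_y
        rrs.append(mm.true_effects(p, n_mc=60000, seed=8).true_total_rr)
    assert all(a <= b + 1e-9 for a, b in zip(rrs, rrs[1:]))


def test_oracle_mc_se_scaling():
    """Quadrupling the counterfactual draw halves the Monte-Carlo SE."""
    p = mm.default_params()
    se_small = mm.true_effects(p, n_mc=20000, seed=6).mc_se_total
    se_large = mm.true_effects(p, n_mc=80000, seed=6).mc_se_total
    assert se_small / se_large == pytest.approx(2.0, rel=0.2)


def test_oracle_rejects_tiny_mc():
    with pytest.raises(ParameterError):
        mm.true_effects(mm.default_params(), n_mc=10)


def test_default_conditions_sit_in_target_regime():
    """The shipped defaults put the oracle total RR near 1.5 with a
    positive mediated component (direct < total)."""
    te = mm.true_effects(mm.default_params(), n_mc=150000, seed=5)
    assert 1.3 < te.true_total_rr < 1.7
    assert te.true_direct_rr < te.true_total_rr
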