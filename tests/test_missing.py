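"""Chained-equations imputation, Rubin pooling, and MNAR bound completion."""

import numpy as np
import pytest

import msmediation as mm
from msmediation.errors import DataError, ImputationError, UnsupportedScenarioError


@pytest.fixture(scope="module")
def mcar_cohort():
    """Eligible cohort with ~15% MCAR holes punched into score columns."""
    cohort = mm.generate_cohort(mm.default_params(n_subjects=3000, seed=314))
    eligible = mm.apply_eligibility(cohort).cohort
    df = eligible.df
    gen = np.random.default_rng(99)
    for col, at_risk in (
        ("tils_1", np.ones(len(df), dtype=bool)),
        ("tils_2", (df["observed_2"] == 1).to_numpy()),
        ("social_support_2", (df["observed_2"] == 1).to_numpy()),
    ):
        holes = (gen.random(len(df)) < 0.15) & at_risk
        df.loc[holes, col] = np.nan
    return eligible


def test_no_missingness_returns_input_unchanged(small_cohort):
    eligible = mm.apply_eligibility(small_cohort).cohort
    complete = eligible.df.dropna(subset=["chew_group_1", "tils_1"]).head(300).copy()
    complete = complete[complete["observed_3"] == 1].reset_index(drop=True)
    imp = mm.mice_impute(complete, m=2, seed=0, max_iter=2)
    for ds in imp.datasets:
        assert ds.equals(complete)
    assert imp.method_map == {}


def test_observed_cells_never_altered(mcar_cohort):
    imp = mm.mice_impute(mcar_cohort.df, m=3, seed=5, max_iter=3)
    original = mcar_cohort.df
    for ds in imp.datasets:
        for col in ("tils_1", "tils_2", "social_support_2"):
            obs = original[col].notna()
            assert np.array_equal(ds.loc[obs, col].to_numpy(), original.loc[obs, col].to_numpy())
            assert ds[col][original[col].isna() & (original["observed_2"] == 1)].notna().all()


def test_imputation_determinism_and_seed_sensitivity(mcar_cohort):
    a = mm.mice_impute(mcar_cohort.df, m=2, seed=7, max_iter=2)
    b = mm.mice_impute(mcar_cohort.df, m=2, seed=7, max_iter=2)
    c = mm.mice_impute(mcar_cohort.df, m=2, seed=8, max_iter=2)
    assert all(x.equals(y) for x, y in zip(a.datasets, b.datasets))
    assert not all(x.equals(y) for x, y in zip(a.datasets, c.datasets))


def test_imputed_values_stay_on_scale(mcar_cohort):
    imp = mm.mice_impute(mcar_cohort.df, m=2, seed=3, max_iter=3)
    for ds in imp.datasets:
        assert ds["tils_1"].between(0, 12).all()
        holes = mcar_cohort.df["social_support_2"].isna() & (
            mcar_cohort.df["observed_2"] == 1
        )
        assert ds.loc[holes, "social_support_2"].between(0, 60).all()


def test_fully_missing_column_raises(mcar_cohort):
    broken = mcar_cohort.df.copy()
    broken["tils_1"] = np.nan
    with pytest.raises(ImputationError):
        mm.mice_impute(broken, m=2, seed=0)


def test_mcar_recovery_of_complete_data_estimate(mcar_cohort):
    """Pooled MI total effect agrees with the complete-data fit under MCAR."""
    complete = mm.generate_cohort(mm.default_params(n_subjects=3000, seed=314))
    complete_res = mm.analyze_cohort(complete)
    ref = complete_res["total"].beta["cum_x"]

    imp = mm.mice_impute(mcar_cohort.df, m=5, seed=17, max_iter=5)
    ests, variances = [], []
    for ds in imp.datasets:
        r = mm.analyze_cohort(mm.CohortTable(ds), skip_eligibility=True)
        ests.append(r["total"].beta["cum_x"])
        variances.append(r["total"].robust_se["cum_x"] ** 2)
    pooled = mm.rubin_pool(ests, variances)
    assert pooled.estimate == pytest.approx(ref, abs=3 * np.sqrt(pooled.total_var))


def test_rubin_degenerate_between_variance():
    pooled = mm.rubin_pool([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
    assert pooled.estimate == 1.0
    assert pooled.between_var == 0.0
    assert pooled.total_var == 0.5
    assert pooled.df == float("inf")


def test_rubin_hand_example():
    pooled = mm.rubin_pool([1.0, 2.0], [0.5, 0.5])
    assert pooled.estimate == 1.5
    assert pooled.between_var == pytest.approx(0.5)
    assert pooled.total_var == pytest.approx(1.25)


def test_rubin_order_invariance_and_input_checks(rng):
    est = rng.normal(size=6)
    var = rng.random(6)
    a = mm.rubin_pool(est, var)
    perm = rng.permutation(6)
    b = mm.rubin_pool(est[perm], var[perm])
    assert a.estimate == pytest.approx(b.estimate)
    assert a.total_var == pytest.approx(b.total_var)
    with pytest.raises(DataError):
        mm.rubin_pool([1.0], [0.5])
    with pytest.raises(DataError):
        mm.rubin_pool([1.0, 2.0], [0.5])


def test_mnar_completion_semantics(small_cohort):
    eligible = mm.apply_eligibility(small_cohort).cohort
    best = mm.mnar_complete(eligible, "best")
    worst = mm.mnar_complete(eligible, "worst")
    lost = eligible.df["observed_3"] == 0
    assert (best.df.loc[lost.to_numpy(), "cesd_3"] == 0).all()
    assert (worst.df.loc[lost.to_numpy(), "cesd_3"] == 22).all()
    # observed outcomes untouched: best-case event count equals observed count
    kept = eligible.df["observed_3"] == 1
    assert (
        best.df["cesd_3"].ge(7).sum() == eligible.df.loc[kept.to_numpy(), "cesd_3"].ge(7).sum()
    )
    # everyone re-enters the analysis set
    assert (best.df["observed_3"] == 1).all()


def test_mnar_no_censoring_is_identity(small_cohort):
    eligible = mm.apply_eligibility(small_cohort).cohort
    full = mm.CohortTable(
        eligible.df[eligible.df["observed_3"] == 1].reset_index(drop=True).copy()
    )
    for scenario in ("best", "worst"):
        completed = mm.mnar_complete(full, scenario)
        assert completed.df["cesd_3"].equals(full.df["cesd_3"])


def test_mnar_rejects_continuous_mode(small_cohort):
    with pytest.raises(UnsupportedScenarioError):
        mm.mnar_complete(small_cohort, "best", mode="continuous")


def outcome_dependent_dropout_params(seed, n_subjects=4000):
    """Dropout driven by the outcome's risk factors, with retention mildly
    favoring the exposed — the attrition pattern under which the source
    study's own bounds bracketed its primary estimate."""
    p = mm.default_params(n_subjects=n_subjects, seed=seed)
    s = p.structural
    s.x_c = 0.35
    s.l_c = {k: 2.0 * v for k, v in s.l_c.items()}
    p.baseline_margins.retention_w2 = 0.85
    p.baseline_margins.retention_w3 = 0.85
    return p


def test_mnar_bounds_bracket_mar_estimate():
    """Best/worst completions bracket the censoring-weighted estimate."""
    hits = 0
    reps = 12
    for s in range(reps):
        cohort = mm.generate_cohort(outcome_dependent_dropout_params(7000 + s))
        eligible = mm.apply_eligibility(cohort).cohort
        mar = mm.analyze_cohort(cohort)["total"].effect["cum_x"]
        bounds = []
        for scenario in ("best", "worst"):
            completed = mm.mnar_complete(eligible, scenario)
            r = mm.analyze_cohort(
                completed, skip_eligibility=True, include_censoring_weights=False
            )
            bounds.append(r["total"].effect["cum_x"])
        lo, hi = min(bounds), max(bounds)
        if lo <= mar <= hi:
            hits += 1
    assert hits >= 0.9 * reps
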