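"""Stabilized-weight construction, truncation, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import msmediation as mm
from msmediation.errors import ConsistencyError, DataError, FittingError
from msmediation.weights import (
    FittedWeightModel,
    WeightModelSpec,
    _summary,
)


@pytest.fixture(scope="module")
def fitted_and_components(coded_wide):
    fitted = mm.fit_weight_models(coded_wide, mm.default_weight_specs())
    comp = mm.compute_component_weights(fitted, coded_wide)
    return fitted, comp


def test_spec_numerator_must_be_subset():
    with pytest.raises(ValueError):
        WeightModelSpec(
            target="exposure", wave=1, response="x_1", numerator=["m_1"], denominator=["x_1"]
        )


def test_stabilization_identity(coded_wide):
    """Numerator model == denominator model forces every component to 1."""
    spec = WeightModelSpec(
        target="exposure",
        wave=1,
        response="x_1",
        numerator=["mobility_1", "age_1"],
        denominator=["mobility_1", "age_1"],
    )
    fitted = mm.fit_weight_models(coded_wide, [spec])
    comp = mm.compute_component_weights(fitted, coded_wide)
    np.testing.assert_allclose(comp.components["x1"].to_numpy(), 1.0, atol=1e-12)


def test_component_is_probability_ratio(coded_wide):
    """Components reproduce p_num/p_den of the observed state by hand."""
    fitted = mm.fit_weight_models(coded_wide, mm.default_weight_specs())
    comp = mm.compute_component_weights(fitted, coded_wide)
    fm = fitted["x1"]
    obs = coded_wide["x_1"].to_numpy()
    pn = np.where(obs == 1, fm.p_numerator, 1 - fm.p_numerator)
    pdn = np.where(obs == 1, fm.p_denominator, 1 - fm.p_denominator)
    np.testing.assert_allclose(comp.components["x1"].to_numpy(), pn / pdn, rtol=1e-12)


def test_components_cover_expected_at_risk_sets(fitted_and_components, coded_wide):
    _, comp = fitted_and_components
    c = comp.components
    assert c["x1"].notna().all()
    assert (c["x2"].notna() == (coded_wide["observed_2"] == 1)).all()
    # censoring components exist only for subjects retained at that wave
    assert (c["c3"].notna() == (coded_wide["observed_3"] == 1)).all()


def test_mean_component_near_one(fitted_and_components):
    """Correctly specified stabilized components average close to 1."""
    _, comp = fitted_and_components
    for key in comp.components:
        assert comp.components[key].dropna().mean() == pytest.approx(1.0, abs=0.05)


def test_combine_is_exact_product(fitted_and_components, coded_wide):
    _, comp = fitted_and_components
    sw = mm.combine_weights(comp, coded_wide)
    analysis = coded_wide["observed_3"] == 1
    manual = comp.components.loc[analysis, ["x1", "x2", "m1", "m2", "c2", "c3"]].prod(axis=1)
    np.testing.assert_allclose(
        sw.sw_total.loc[analysis].to_numpy(), manual.to_numpy(), rtol=1e-12
    )
    assert sw.sw_total[~analysis].isna().all()


def test_total_vs_direct_weighting_ratio(fitted_and_components, coded_wide):
    """Dropping mediator components divides out exactly the mediator product."""
    _, comp = fitted_and_components
    with_m = mm.combine_weights(comp, coded_wide, include_mediator=True)
    without_m = mm.combine_weights(comp, coded_wide, include_mediator=False)
    analysis = coded_wide["observed_3"] == 1
    ratio = with_m.sw_total.loc[analysis] / without_m.sw_total.loc[analysis]
    med = comp.components.loc[analysis, ["m1", "m2"]].prod(axis=1)
    np.testing.assert_allclose(ratio.to_numpy(), med.to_numpy(), rtol=1e-10)


def test_combine_flags_missing_components(fitted_and_components, coded_wide):
    _, comp = fitted_and_components
    broken_components = comp.components.copy()
    idx = coded_wide.index[coded_wide["observed_3"] == 1][0]
    broken_components.loc[idx, "m2"] = np.nan
    broken = mm.StabilizedWeights(components=broken_components)
    with pytest.raises(ConsistencyError):
        mm.combine_weights(broken, coded_wide)


def _weights_from_values(values):
    n = len(values)
    comp = pd.DataFrame({"x1": values})
    return mm.StabilizedWeights(
        components=comp, sw_total=pd.Series(values, dtype=float), included_keys=["x1"]
    )


def test_truncation_semantics():
    sw = _weights_from_values([1.0, 1.0, 1.0, 1.0, 100.0])
    capped = mm.truncate_weights(sw, absolute_cap=2.0)
    assert capped.sw_truncated.tolist() == [1.0, 1.0, 1.0, 1.0, 2.0]
    assert capped.truncation_threshold == 2.0

    const = mm.truncate_weights(_weights_from_values([1.0] * 6), upper_percentile=95)
    assert const.truncation_threshold == 1.0
    assert (const.sw_truncated == 1.0).all()


def test_truncation_is_contraction_from_above(rng):
    values = rng.lognormal(0, 0.8, 500)
    sw = mm.truncate_weights(_weights_from_values(values), upper_percentile=95)
    assert (sw.sw_truncated.to_numpy() <= values + 1e-15).all()
    assert sw.sw_truncated.mean() <= values.mean()
    # threshold equals the linear-interpolation percentile
    assert sw.truncation_threshold == pytest.approx(
        np.percentile(values, 95, method="linear")
    )


def test_truncation_rejects_nonpositive_weights():
    with pytest.raises(DataError):
        mm.truncate_weights(_weights_from_values([1.0, -0.5, 2.0]))


def test_positivity_fraction_counting():
    spec = WeightModelSpec(
        target="exposure", wave=1, response="x_1", numerator=[], denominator=["age_1"]
    )
    probs = pd.Series([0.01, 0.5, 0.97])
    fm = FittedWeightModel(
        spec=spec,
        p_numerator=probs,
        p_denominator=probs,
        at_risk_index=probs.index,
        n_at_risk=3,
    )
    sw = _weights_from_values([1.0, 1.0, 1.0])
    diags = mm.weight_diagnostics(sw, {"x1": fm})
    assert diags.positivity["x1"]["frac_below"] == pytest.approx(1 / 3)
    assert diags.positivity["x1"]["frac_above"] == pytest.approx(1 / 3)
    assert diags.alarms  # 2/3 outside bounds exceeds the 5% alarm level


def test_diagnostics_constant_weights():
    diags = mm.weight_diagnostics(_weights_from_values([1.0] * 50))
    assert diags.before["mean"] == 1.0
    assert diags.before["sd"] == 0.0
    assert diags.before["p01"] == diags.before["p99"] == 1.0


def test_well_specified_cohort_has_few_extreme_probabilities(fitted_and_components):
    fitted, comp = fitted_and_components
    diags = mm.weight_diagnostics(
        mm.StabilizedWeights(
            components=comp.components, sw_total=comp.components["x1"]
        ),
        fitted,
    )
    for key in ("x1", "x2", "m1", "m2"):
        rep = diags.positivity[key]
        assert rep["frac_below"] + rep["frac_above"] < 0.05


def test_degenerate_at_risk_set_raises(coded_wide):
    tiny = coded_wide.head(1)
    with pytest.raises(FittingError):
        mm.fit_weight_models(tiny, mm.default_weight_specs()[:1])
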