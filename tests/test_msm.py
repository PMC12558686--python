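"""Weighted outcome models, decomposition arithmetic, and MD-to-RR conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msmediation as mm
from msmediation.errors import ConsistencyError, DataError, DegenerateFitError
from msmediation.msm import MSMResult


def _two_group_rows(n1, e1, n0, e0):
    """Exposed group of n1 with e1 events; unexposed n0 with e0 events."""
    rows = pd.DataFrame(
        {
            "cum_x": [1.0] * n1 + [0.0] * n0,
            "cum_m": 0.0,
            "y": [1.0] * e1 + [0.0] * (n1 - e1) + [1.0] * e0 + [0.0] * (n0 - e0),
        }
    )
    rows["subject_id"] = np.arange(len(rows))
    return rows


def test_saturated_two_group_rr_is_exact():
    rows = _two_group_rows(10, 4, 10, 2)
    res = mm.fit_msm_binary(rows, np.ones(20))
    assert res.effect["cum_x"] == pytest.approx(2.0, rel=1e-10)


def test_uniform_within_group_weights_cancel():
    rows = _two_group_rows(10, 4, 10, 2)
    w = np.where(rows["cum_x"] == 1, 2.0, 1.0)
    res = mm.fit_msm_binary(rows, w)
    assert res.effect["cum_x"] == pytest.approx(2.0, rel=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    e1=st.integers(1, 19),
    e0=st.integers(1, 19),
    w1=st.floats(0.2, 5.0),
    w0=st.floats(0.2, 5.0),
)
def test_weighted_two_group_rr_matches_hand_formula(e1, e0, w1, w0):
    """exp(b1) equals the hand-computed weighted risk ratio on any 2x2 table."""
    rows = _two_group_rows(20, e1, 20, e0)
    w = np.where(rows["cum_x"] == 1, w1, w0)
    res = mm.fit_msm_binary(rows, w)
    hand = (w1 * e1 / (w1 * 20)) / (w0 * e0 / (w0 * 20))
    assert res.effect["cum_x"] == pytest.approx(hand, rel=1e-8)


def test_binary_fit_rejects_constant_outcome():
    rows = _two_group_rows(5, 0, 5, 0)
    with pytest.raises(DegenerateFitError):
        mm.fit_msm_binary(rows, np.ones(10))


def test_binary_fit_rejects_bad_weights():
    rows = _two_group_rows(5, 2, 5, 1)
    with pytest.raises(DataError):
        mm.fit_msm_binary(rows, np.zeros(10))


def test_continuous_noiseless_recovery_and_scale_invariance(rng):
    cum_x = rng.choice([0.0, 0.5, 1.0], 300)
    rows = pd.DataFrame(
        {"cum_x": cum_x, "cum_m": 0.0, "y": 3.0 + 2.0 * cum_x, "subject_id": range(300)}
    )
    res = mm.fit_msm_continuous(rows, np.ones(300))
    assert res.effect["cum_x"] == pytest.approx(2.0, abs=1e-10)
    scaled = mm.fit_msm_continuous(rows, 7.3 * np.ones(300))
    assert scaled.beta["cum_x"] == pytest.approx(res.beta["cum_x"], rel=1e-12)


def _fake_result(rr_x, rr_m=None, link="log"):
    beta = {"const": -2.0, "cum_x": np.log(rr_x)}
    effect = {"cum_x": rr_x}
    ci = {"cum_x": (rr_x * 0.8, rr_x * 1.25)}
    if rr_m is not None:
        beta["cum_m"] = np.log(rr_m)
        effect["cum_m"] = rr_m
        ci["cum_m"] = (rr_m * 0.8, rr_m * 1.25)
    return MSMResult(
        model="direct" if rr_m is not None else "total",
        link=link,
        beta=beta,
        robust_se={k: 0.1 for k in beta},
        effect=effect,
        ci95=ci,
        n_effective=100,
        sum_weights=100.0,
    )


@pytest.mark.parametrize(
    "rr_t, rr_d, expected_pm",
    [
        (1.5, 1.5, 0.0),
        (1.5, 1.0, 100.0),
        (1.48, 1.40, pytest.approx(100 * (1.48 - 1.40) / 0.48, abs=1e-9)),
    ],
)
def test_decomposition_examples(rr_t, rr_d, expected_pm):
    summary = mm.decompose_effects(_fake_result(rr_t), _fake_result(rr_d, rr_m=1.26))
    assert summary.proportion_mediated == expected_pm


@settings(max_examples=80, deadline=None, derandomize=True)
@given(rr_t=st.floats(1.0001, 8.0), frac=st.floats(0.0, 1.0))
def test_decomposition_closure_is_exact(rr_t, frac):
    """With the direct RR between the null and the total RR, the two
    shares are proportions and add to exactly 100 percent."""
    rr_d = 1.0 + frac * (rr_t - 1.0)
    summary = mm.decompose_effects(_fake_result(rr_t), _fake_result(rr_d, rr_m=1.1))
    assert summary.proportion_direct + summary.proportion_mediated == 100.0


def test_decomposition_undefined_below_null():
    summary = mm.decompose_effects(_fake_result(0.9), _fake_result(0.95, rr_m=1.0))
    assert summary.proportion_mediated is None
    assert summary.note is not None


def test_decomposition_carries_evalues():
    summary = mm.decompose_effects(_fake_result(1.48), _fake_result(1.40, rr_m=1.26))
    assert round(summary.evalues["direct"].evalue_point, 2) == 2.15


def test_md_to_rr_values_and_monotonicity():
    assert mm.md_to_rr(0.0, 1.0) == 1.0
    assert mm.md_to_rr(1.0, 1.0) == pytest.approx(np.exp(0.91))
    grid = [mm.md_to_rr(d, 2.5) for d in np.linspace(-2, 2, 9)]
    assert all(a < b for a, b in zip(grid, grid[1:]))
    with pytest.raises(DataError):
        mm.md_to_rr(1.0, 0.0)


def test_build_analysis_rows_codings(coded_wide):
    rows = mm.build_analysis_rows(coded_wide)
    assert set(np.unique(rows["cum_x"])) <= {0.0, 0.5, 1.0}
    sums = mm.build_analysis_rows(coded_wide, cum_coding="sum")
    assert np.allclose(sums["cum_x"], 2 * rows["cum_x"])
    # analysis rows only cover subjects observed through wave 3
    assert len(rows) == int((coded_wide["observed_3"] == 1).sum())


def test_build_analysis_rows_requires_complete_histories(coded_wide):
    broken = coded_wide.copy()
    idx = broken.index[broken["observed_3"] == 1][0]
    broken.loc[idx, "m_2"] = np.nan
    with pytest.raises(ConsistencyError):
        mm.build_analysis_rows(broken)
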