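"""Model-fitting tests: oracles, equivalences, the RTM correction."""

import numpy as np
import pandas as pd
import pytest

from telosim import (
    ErrorModel,
    fit_ancova_change,
    fit_ancova_followup,
    fit_change_score,
    fit_model,
    fit_repeated_measures,
    make_scenario,
    rtm_correct,
    simulate_cohort,
    standardize_beta,
)
from telosim.models import as_cohort_table

from conftest import random_small_cohort


def normal_equations(y, columns):
    """Independent least-squares oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.ones(len(y))] + list(columns))
    return np.linalg.solve(X.T @ X, X.T @ y)


def hand_table(m_b, m_fu, exposed, years=10.0):
    return pd.DataFrame({
        "exposed": exposed,
        "m_ltl_b": m_b,
        "m_ltl_fu": m_fu,
        "interval_years": years,
    })


class TestChangeScore:
    def test_equals_group_mean_difference(self, small_cohort):
        rec = small_cohort.records
        oracle = (rec.loc[rec.exposed == 1, "m_delta_yr"].mean()
                  - rec.loc[rec.exposed == 0, "m_delta_yr"].mean())
        fit = fit_change_score(small_cohort)
        np.testing.assert_allclose(fit.beta_bp_yr, oracle, rtol=1e-12)

    def test_null_identity(self):
        # change scores vary within groups but identically across them:
        # zero contrast, p exactly 1
        tab = hand_table([7000, 7400, 7000, 7400], [6620, 6980, 6620, 6980],
                         [0, 0, 1, 1])
        fit = fit_change_score(tab)
        assert fit.beta_bp_yr == pytest.approx(0, abs=1e-12)
        assert fit.p_value == pytest.approx(1, abs=1e-9)
        assert not fit.significant

    def test_single_group_rejected(self):
        tab = hand_table([7000, 7100, 7200], [6800, 6900, 7000], [1, 1, 1])
        with pytest.raises(ValueError, match="inestimable"):
            fit_change_score(tab)


class TestLeastSquaresOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_models_1_to_3_match_normal_equations(self, seed):
        ds = random_small_cohort(seed, n_per_group=5, cv=6.0)
        tab = as_cohort_table(ds)
        y = tab["m_delta_yr"].to_numpy()
        x = tab["exposed"].to_numpy(dtype=float)
        b = tab["m_ltl_b"].to_numpy()
        fu = tab["m_ltl_fu"].to_numpy()

        np.testing.assert_allclose(
            fit_change_score(ds).beta_bp_yr, normal_equations(y, [x])[1], rtol=1e-10)
        np.testing.assert_allclose(
            fit_ancova_change(ds).beta_bp_yr, normal_equations(y, [b, x])[2], rtol=1e-10)
        np.testing.assert_allclose(
            fit_ancova_followup(ds).beta_bp_yr,
            normal_equations(fu, [b, x])[2] / 10.0, rtol=1e-10)

    def test_collinear_baseline_rejected(self):
        tab = hand_table([7000] * 4, [6600, 6700, 6500, 6800], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="collinear"):
            fit_ancova_change(tab)


class TestModelEquivalences:
    @pytest.mark.parametrize("seed", range(20))
    def test_change_vs_repeated_and_ancova_pair(self, seed):
        """Models 1 and 4 share an estimate, as do models 2 and 3."""
        ds = random_small_cohort(seed, n_per_group=12,
                                 cv=float(np.random.default_rng(seed).uniform(0, 12)))
        f1, f2, f3, f4 = (fit_model(ds, m) for m in (1, 2, 3, 4))
        assert abs(f1.beta_bp_yr - f4.beta_bp_yr) <= 1e-6
        assert abs(f2.beta_bp_yr - f3.beta_bp_yr) <= 1e-6

    @pytest.mark.parametrize("seed", [0, 7])
    def test_closed_form_matches_mixedlm(self, seed):
        ds = random_small_cohort(seed, n_per_group=25, cv=4.0)
        closed = fit_repeated_measures(ds, engine="closed")
        numeric = fit_repeated_measures(ds, engine="mixedlm")
        assert abs(closed.beta_bp_yr - numeric.beta_bp_yr) <= 1e-6

    def test_interaction_is_difference_in_differences(self):
        # 4-participant worked example: cell means computed by hand
        tab = hand_table([7000, 7200, 7100, 6900],
                         [6500, 6900, 6400, 6300], [0, 0, 1, 1])
        # group 0 mean change: (-500 + -300)/2 = -400; group 1: (-700-600)/2=-650
        fit = fit_repeated_measures(tab)
        assert fit.beta_bp_yr == pytest.approx((-650 - -400) / 10.0)

    def test_zero_change_gives_zero_interaction(self):
        tab = hand_table([7000, 7200, 7100, 6900],
                         [7000, 7200, 7100, 6900], [0, 0, 1, 1])
        assert fit_repeated_measures(tab).beta_bp_yr == 0


class TestRtmCorrection:
    def test_change_score_invariant_under_correction(self):
        ds = simulate_cohort(make_scenario("C", n_exposed=300, n_unexposed=300),
                             ErrorModel.proportional(8), 21)
        raw = fit_change_score(ds).beta_bp_yr
        corrected = fit_model(ds, 1, outcome="rtm_corrected").beta_bp_yr
        assert corrected == pytest.approx(raw, abs=1e-9)

    def test_hand_computation_five_records(self):
        # single exposure group of 5 plus a 3-record reference group
        m_b = [7000.0, 7200.0, 6800.0, 7400.0, 7100.0]
        m_fu = [6600.0, 6900.0, 6500.0, 6800.0, 6700.0]
        tab = hand_table(m_b + [7000.0, 7300.0, 6900.0],
                         m_fu + [6700.0, 6800.0, 6600.0],
                         [1] * 5 + [0] * 3)
        d = rtm_correct(tab).d_bp_yr[:5]
        # spreadsheet-style evaluation for the exposed group
        mean_b = sum(m_b) / 5
        mean_fu = sum(m_fu) / 5
        sxy = sum((a - mean_b) * (b - mean_fu) for a, b in zip(m_b, m_fu))
        sxx = sum((a - mean_b) ** 2 for a in m_b)
        syy = sum((b - mean_fu) ** 2 for b in m_fu)
        r = sxy / (sxx * syy) ** 0.5
        expected = [((fu - b) + (1 - r) * (b - mean_b)) / 10.0
                    for b, fu in zip(m_b, m_fu)]
        np.testing.assert_allclose(d, expected, rtol=1e-12)

    def test_degenerate_variance_rejected(self):
        tab = hand_table([7000, 7000, 7000, 7100], [6600, 6700, 6500, 6900],
                         [1, 1, 1, 0])
        with pytest.raises(ValueError):
            rtm_correct(tab)
        with pytest.raises(ValueError, match="at least 3"):
            rtm_correct(hand_table([7000, 7100], [6900, 6800], [0, 1]))


class TestStandardizedBeta:
    def test_zero_maps_to_zero(self):
        tab = hand_table([7000, 7400, 7000, 7400], [6620, 6980, 6620, 6980],
                         [0, 0, 1, 1])
        assert fit_change_score(tab).beta_std == pytest.approx(0, abs=1e-12)

    def test_refit_oracle(self, small_cohort):
        """Standardization equals refitting on z-scored variables."""
        tab = as_cohort_table(small_cohort)
        y = tab["m_delta_yr"].to_numpy()
        x = tab["exposed"].to_numpy(dtype=float)
        zy = (y - y.mean()) / y.std(ddof=1)
        zx = (x - x.mean()) / x.std(ddof=1)
        oracle = np.linalg.solve(
            *(lambda X: (X.T @ X, X.T @ zy))(np.column_stack([np.ones(len(zy)), zx]))
        )[1]
        fit = fit_change_score(small_cohort)
        assert fit.beta_std == pytest.approx(oracle, rel=1e-10)
        assert standardize_beta(fit, small_cohort) == pytest.approx(oracle, rel=1e-10)

    def test_scale_invariance(self, small_cohort):
        tab = as_cohort_table(small_cohort)
        doubled = tab.copy()
        for col in ("m_ltl_b", "m_ltl_fu", "m_delta_yr"):
            doubled[col] = 2 * doubled[col]
        assert fit_change_score(doubled).beta_std == pytest.approx(
            fit_change_score(tab).beta_std, rel=1e-12)
        assert fit_ancova_change(doubled).beta_std == pytest.approx(
            fit_ancova_change(tab).beta_std, rel=1e-10)
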