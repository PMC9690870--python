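"""Isotemporal substitution: reallocation arithmetic, deltas, intervals."""

import numpy as np
import pandas as pd
import pytest

from codaqol.coda import Composition, close, ilr, pivot_basis
from codaqol.regression import clr_gradient, fit_model
from codaqol.simulate import GeneratorConfig, generate_survey
from codaqol.substitution import (
    InfeasibleReallocation,
    Reallocation,
    delta_ci,
    grid_frame,
    predict_delta,
    reallocate,
    substitution_grid,
    substitution_table,
)

A_2021 = np.array([2.82, -2.61, -0.21]) / np.sqrt(1.5)
A_2021 -= A_2021.mean()


@pytest.fixture(scope="module")
def fitted():
    cfg = GeneratorConfig(n=600, seed=7, missing_qol=0, missing_age=0, missing_sex=0)
    df, _ = generate_survey(cfg)
    return fit_model(df)


@pytest.fixture
def baseline():
    return Composition(np.array([4.0, 5.0, 15.0]))


class TestReallocate:
    def test_moves_time_between_two_parts_only(self, baseline):
        out = reallocate(baseline, Reallocation("SB", "PA", 0.25))
        np.testing.assert_allclose(out.values, [4.25, 4.75, 15.0])
        assert out.values.sum() == pytest.approx(24.0)

    def test_zero_amount_is_identity(self, baseline):
        out = reallocate(baseline, Reallocation("PA", "SB", 0.0))
        np.testing.assert_array_equal(out.values, baseline.values)

    def test_infeasible_amount_rejected(self, baseline):
        with pytest.raises(InfeasibleReallocation):
            reallocate(baseline, Reallocation("PA", "SB", 4.5))

    def test_donor_equals_recipient_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            Reallocation("PA", "PA", 0.25)


class TestPredictDelta:
    def test_hand_evaluation_at_printed_scale(self):
        base = Composition(np.array([3.83, 4.59, 11.17]), kappa=3.83 + 4.59 + 11.17)
        delta = predict_delta(A_2021, base, Reallocation("SB", "PA", 0.25))
        assert delta == pytest.approx(0.2648, abs=5e-4)

    def test_antisymmetric_in_endpoints(self, baseline):
        fwd = predict_delta(A_2021, baseline, Reallocation("SB", "PA", 0.5))
        new = reallocate(baseline, Reallocation("SB", "PA", 0.5))
        back = predict_delta(A_2021, new, Reallocation("PA", "SB", 0.5))
        assert fwd == pytest.approx(-back, abs=1e-12)

    def test_delta_vanishes_with_amount(self, baseline):
        deltas = [
            predict_delta(A_2021, baseline, Reallocation("SB", "PA", a))
            for a in (0.1, 0.01, 0.001)
        ]
        assert abs(deltas[2]) < abs(deltas[1]) < abs(deltas[0])
        assert deltas[2] == pytest.approx(0.0, abs=1e-2)

    def test_full_model_prediction_equals_gradient_shortcut(self, fitted, baseline):
        r = Reallocation("SL", "PA", 0.75)
        shortcut = predict_delta(fitted, baseline, r)
        new = reallocate(baseline, r)
        direct = (
            fitted.predict_composition(new.values)[0]
            - fitted.predict_composition(baseline.values)[0]
        )
        assert shortcut == pytest.approx(direct, abs=1e-10)

    def test_covariate_cancellation(self, fitted, baseline):
        r = Reallocation("SB", "SL", 0.5)
        new = reallocate(baseline, r)
        for cov in ([0.0, 0.0], [5.9, 1.0]):
            c = np.array([cov])
            diff = (
                fitted.predict_composition(new.values, c)[0]
                - fitted.predict_composition(baseline.values, c)[0]
            )
            assert diff == pytest.approx(predict_delta(fitted, baseline, r), abs=1e-10)

    def test_basis_invariance(self, baseline):
        cfg = GeneratorConfig(n=400, seed=11, missing_qol=0, missing_age=0, missing_sex=0)
        df, _ = generate_survey(cfg)
        r = Reallocation("SB", "PA", 0.25)
        deltas = [
            predict_delta(fit_model(df, basis=pivot_basis(first=p)), baseline, r)
            for p in ("PA", "SB", "SL")
        ]
        np.testing.assert_allclose(deltas, deltas[0], atol=1e-10)

    def test_first_order_taylor_limit(self, baseline):
        """delta/amount -> a_rec/x_rec - a_don/x_don as amount -> 0."""
        x = baseline.values
        expected = A_2021[0] / x[0] - A_2021[1] / x[1]  # SB -> PA
        for amount in (1e-4, 1e-6):
            rate = predict_delta(A_2021, baseline, Reallocation("SB", "PA", amount)) / amount
            assert rate == pytest.approx(expected, rel=1e-3)


class TestDeltaCI:
    def test_contains_and_centres_the_estimate(self, fitted, baseline):
        r = Reallocation("SB", "PA", 0.25)
        delta = predict_delta(fitted, baseline, r)
        lo, hi = delta_ci(fitted, baseline, r)
        assert lo <= delta <= hi
        assert (lo + hi) / 2 == pytest.approx(delta, abs=1e-10)

    def test_noiseless_fit_gives_zero_width(self, baseline):
        cfg = GeneratorConfig(n=200, seed=3, sigma=0.0,
                              missing_qol=0, missing_age=0, missing_sex=0)
        df, _ = generate_survey(cfg)
        m = fit_model(df)
        lo, hi = delta_ci(m, baseline, Reallocation("SB", "PA", 0.25))
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_gradient_only_model_has_no_ci(self, baseline):
        with pytest.raises(TypeError, match="covariance"):
            delta_ci(A_2021, baseline, Reallocation("SB", "PA", 0.25))

    def test_normal_quantile_narrower_than_t(self, fitted, baseline):
        r = Reallocation("SB", "PA", 0.25)
        lo_t, hi_t = delta_ci(fitted, baseline, r, quantile="t")
        lo_n, hi_n = delta_ci(fitted, baseline, r, quantile="normal")
        assert hi_n - lo_n < hi_t - lo_t


class TestGrid:
    def test_24_cells_for_three_parts(self, fitted, baseline):
        results = substitution_grid(fitted, baseline)
        assert len(results) == 24

    def test_cell_matches_direct_evaluation(self, fitted, baseline):
        results = substitution_grid(fitted, baseline)
        cell = next(
            r for r in results
            if (r.donor, r.recipient, r.amount) == ("SB", "PA", 0.25)
        )
        assert cell.delta == pytest.approx(
            predict_delta(fitted, baseline, Reallocation("SB", "PA", 0.25))
        )
        assert cell.percent_of_baseline == pytest.approx(
            100 * cell.delta / fitted.predict_composition(baseline.values)[0]
        )

    def test_magnitude_increases_with_amount(self, fitted, baseline):
        long = grid_frame(substitution_grid(fitted, baseline))
        for (d, r), grp in long.groupby(["donor", "recipient"]):
            grp = grp.sort_values("amount_hours")
            mags = grp["delta"].abs().to_numpy()
            if np.isfinite(mags).all() and mags.min() > 1e-6:
                assert (np.diff(mags) > 0).all()

    def test_reciprocal_pairs_opposite_sign_unequal_magnitude(self, baseline):
        ab = predict_delta(A_2021, baseline, Reallocation("SB", "PA", 1.0))
        ba = predict_delta(A_2021, baseline, Reallocation("PA", "SB", 1.0))
        assert np.sign(ab) == -np.sign(ba)
        assert abs(ab) != pytest.approx(abs(ba), rel=1e-3)

    def test_infeasible_cells_reported_not_fatal(self, fitted):
        tight = Composition(np.array([0.5, 8.5, 15.0]))
        results = substitution_grid(fitted, tight)
        bad = [r for r in results if not np.isfinite(r.delta)]
        assert bad and all(r.donor == "PA" for r in bad)
        assert len(results) == 24

    def test_table_shape(self, fitted, baseline):
        wide = substitution_table(substitution_grid(fitted, baseline))
        assert wide.shape == (12, 3)  # 4 amounts x 3 recipients, 3 donor columns
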