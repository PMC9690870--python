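"""Core compositional geometry: transforms, centre, dispersion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codaqol.coda import (
    Composition,
    CompositionSet,
    ZeroPartError,
    clr,
    close,
    compositional_mean,
    ilr,
    ilr_inverse,
    pivot_basis,
    replace_zeros,
    ternary_coordinates,
    variation_matrix,
)

positive_triples = st.lists(
    st.floats(min_value=0.01, max_value=100, allow_nan=False), min_size=3, max_size=3
)


class TestClosure:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((8, 8, 8), (8, 8, 8)),
            ((1, 1, 2), (6, 6, 12)),
            ((3.83, 4.59, 11.17), (4.69219, 5.623277, 13.684533)),
        ],
    )
    def test_closes_to_24(self, values, expected):
        np.testing.assert_allclose(close(values, 24.0), expected, atol=1e-5)

    def test_zero_part_directs_to_replacement(self):
        with pytest.raises(ZeroPartError, match="replace_zeros"):
            close([0.0, 4.0, 20.0])

    @given(positive_triples)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_result_proportional_and_sums_to_kappa(self, values):
        c = close(values, 24.0)
        assert c.sum() == pytest.approx(24.0, rel=1e-9)
        ratios = c / np.asarray(values)
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)


class TestReplaceZeros:
    def test_multiplicative_replacement_preserves_total(self):
        out = replace_zeros(np.array([0.0, 4.0, 20.0]), 0.25)
        np.testing.assert_allclose(out, [0.25, 3.958333, 19.791667], atol=1e-5)
        assert out.sum() == pytest.approx(24.0)

    def test_no_zeros_is_identity(self):
        np.testing.assert_array_equal(
            replace_zeros(np.array([3.0, 9.0, 12.0]), 0.25), [3.0, 9.0, 12.0]
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            replace_zeros(np.zeros(3), 0.25)

    def test_nonzero_ratios_preserved(self):
        out = replace_zeros(np.array([0.0, 4.0, 20.0]), 0.25)
        assert out[2] / out[1] == pytest.approx(5.0)


class TestTransforms:
    def test_clr_equal_parts_is_zero(self):
        np.testing.assert_allclose(clr(np.array([8.0, 8, 8])), 0.0, atol=1e-12)

    def test_clr_hand_example(self):
        np.testing.assert_allclose(
            clr(np.array([12.0, 6, 6])), [0.4621, -0.2310, -0.2310], atol=5e-5
        )

    def test_clr_against_skbio(self, random_compositions):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        np.testing.assert_allclose(
            clr(random_compositions),
            skbio_comp.clr(skbio_comp.closure(random_compositions)),
            atol=1e-10,
        )

    def test_pivot_basis_matches_stated_contrast(self):
        V = pivot_basis().contrast
        expected = np.array(
            [
                [np.sqrt(2 / 3), -1 / np.sqrt(6), -1 / np.sqrt(6)],
                [0.0, 1 / np.sqrt(2), -1 / np.sqrt(2)],
            ]
        )
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_ilr_pivot_formula_oracle(self, random_compositions):
        """Coordinates match the explicit pivot formulas, independently coded."""
        x = random_compositions
        z1 = np.sqrt(2 / 3) * np.log(x[:, 0] / np.sqrt(x[:, 1] * x[:, 2]))
        z2 = np.sqrt(1 / 2) * np.log(x[:, 1] / x[:, 2])
        np.testing.assert_allclose(ilr(x), np.column_stack([z1, z2]), atol=1e-10)

    def test_ilr_hand_example(self):
        z = ilr(np.array([12.0, 6, 6]))
        np.testing.assert_allclose(z, [np.sqrt(2 / 3) * np.log(2), 0.0], atol=1e-12)

    @given(positive_triples, st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ilr_scale_invariance(self, values, c):
        v = np.asarray(values)
        np.testing.assert_allclose(ilr(close(v)), ilr(close(c * v)), atol=1e-9)

    def test_roundtrip_over_random_compositions(self, random_compositions):
        z = ilr(random_compositions)
        back = ilr_inverse(z)
        assert np.max(np.abs(back - random_compositions)) < 1e-8

    def test_ilr_inverse_neutral_element(self):
        np.testing.assert_allclose(ilr_inverse([0.0, 0.0]), [8.0, 8, 8], atol=1e-12)

    def test_ilr_inverse_hand_example(self):
        np.testing.assert_allclose(
            ilr_inverse([0.5659, 0.0]), [12.0, 6, 6], atol=2e-3
        )

    def test_label_mismatch_rejected(self):
        basis = pivot_basis(("PA", "SB", "SL"))
        comp = Composition(np.array([8.0, 8, 8]), labels=("SL", "SB", "PA"))
        with pytest.raises(ValueError, match="label"):
            ilr(comp, basis)


class TestCentreAndDispersion:
    def test_mean_idempotent_on_identical_rows(self):
        cs = CompositionSet(np.tile([4.0, 6.0, 14.0], (5, 1)))
        np.testing.assert_allclose(compositional_mean(cs), [4, 6, 14], atol=1e-10)

    def test_mean_hand_example(self):
        cs = CompositionSet(np.array([[12.0, 6, 6], [6, 12, 6]]))
        np.testing.assert_allclose(
            compositional_mean(cs), [8.8656, 8.8656, 6.2689], atol=5e-4
        )

    def test_mean_equals_ilr_inverse_of_mean_coords(self, random_compositions):
        cs = CompositionSet(random_compositions)
        via_ilr = ilr_inverse(ilr(random_compositions).mean(axis=0))
        np.testing.assert_allclose(compositional_mean(cs), via_ilr, atol=1e-9)

    def test_variation_matrix_hand_example(self):
        cs = CompositionSet(np.array([[12.0, 6, 6], [6, 12, 6]]))
        T = variation_matrix(cs).matrix
        # var over {ln2, -ln2} = 2 ln(2)^2 ; var over {ln2, 0} = ln(2)^2 / 2
        assert T[0, 1] == pytest.approx(2 * np.log(2) ** 2)
        assert T[0, 2] == pytest.approx(np.log(2) ** 2 / 2)
        assert T[1, 2] == pytest.approx(np.log(2) ** 2 / 2)

    def test_identical_rows_give_zero_matrix(self):
        cs = CompositionSet(np.tile([4.0, 6.0, 14.0], (4, 1)))
        np.testing.assert_allclose(variation_matrix(cs).matrix, 0.0, atol=1e-12)

    def test_variation_matrix_brute_force_oracle(self, rng):
        """Pairwise double loop with explicit sample variances."""
        for _ in range(50):
            n = rng.integers(2, 51)
            x = rng.lognormal(0, 1, size=(n, 3))
            T = variation_matrix(CompositionSet(close(x, 24.0))).matrix
            for i in range(3):
                for j in range(3):
                    expected = np.var(np.log(x[:, i] / x[:, j]), ddof=1)
                    assert abs(T[i, j] - expected) < 1e-10

    def test_closure_invariance_of_variation_matrix(self, rng):
        x = rng.lognormal(0, 1, size=(30, 3))
        scales = rng.uniform(0.5, 2.0, size=(30, 1))
        T1 = variation_matrix(CompositionSet(close(x, 24.0))).matrix
        T2 = variation_matrix(CompositionSet(close(x * scales, 24.0))).matrix
        np.testing.assert_allclose(T1, T2, atol=1e-10)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            variation_matrix(CompositionSet(np.array([[8.0, 8, 8]])))


class TestTernary:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (1.0, 0.0)),
            ((0, 0, 1), (0.5, np.sqrt(3) / 2)),
        ],
    )
    def test_vertices(self, p, expected):
        np.testing.assert_allclose(
            ternary_coordinates(np.array(p, float)), expected, atol=1e-12
        )

    def test_centre_maps_to_centroid(self):
        xy = ternary_coordinates(np.array([8.0, 8, 8]))
        np.testing.assert_allclose(xy, [0.5, np.sqrt(3) / 6], atol=1e-12)
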