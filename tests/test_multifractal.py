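"""Spectrum estimation: box measures, q-moments, regressions, Hölder map."""

import numpy as np
import pytest

from bemdmf.multifractal import (
    BoxCountingConfig,
    DegenerateMeasureError,
    alpha_of_q,
    box_probabilities,
    f_of_q,
    generalized_dimensions,
    holder_exponent_map,
    legendre_spectrum,
    normalized_measure,
    select_box_range,
)
from bemdmf.synthetic import (
    CascadeSpec,
    FbmSpec,
    cascade_analytic_spectrum,
    generate_binomial_cascade,
    generate_fbm_surface,
)

W = (0.4, 0.3, 0.2, 0.1)
Q_GRID = tuple(np.round(np.arange(-39, 40) * 0.1, 10))


class TestBoxProbabilities:
    def test_constant_image_uniform_probabilities(self):
        m = box_probabilities(np.ones((64, 64)), 8)
        assert m.n_boxes_total == 64
        np.testing.assert_allclose(m.probabilities, 1 / 64)

    def test_unit_boxes_recover_the_measure(self):
        img = np.array([[0.4, 0.3], [0.2, 0.1]])
        m = box_probabilities(img, 1)
        assert sorted(m.probabilities) == pytest.approx([0.1, 0.2, 0.3, 0.4])

    def test_trailing_partial_boxes_dropped(self):
        m = box_probabilities(np.ones((65, 65)), 8)
        assert m.n_boxes_total == 64
        np.testing.assert_allclose(m.probabilities, 1 / 64)

    def test_oversized_box_rejected(self):
        with pytest.raises(ValueError):
            box_probabilities(np.ones((8, 8)), 16)

    def test_zero_image_degenerate(self):
        with pytest.raises(DegenerateMeasureError):
            box_probabilities(np.zeros((8, 8)), 2)

    def test_signed_image_offset_keeps_probabilities_positive(self):
        img = np.random.default_rng(0).normal(size=(16, 16))
        m = box_probabilities(img, 2)
        assert np.all(m.probabilities > 0)
        assert m.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestNormalizedMeasure:
    def test_q_one_is_identity(self):
        m = box_probabilities(np.arange(1.0, 17.0).reshape(4, 4), 2)
        np.testing.assert_allclose(normalized_measure(m, 1.0), m.probabilities, atol=1e-15)

    def test_q_zero_is_uniform(self):
        m = box_probabilities(np.arange(1.0, 17.0).reshape(4, 4), 2)
        np.testing.assert_allclose(normalized_measure(m, 0.0), 0.25)

    def test_small_case_by_hand(self):
        from bemdmf.multifractal import BoxMeasure

        m = BoxMeasure(1, np.array([0.5, 0.25, 0.25]), 3, 3)
        np.testing.assert_allclose(
            normalized_measure(m, 2.0), [4 / 6, 1 / 6, 1 / 6], atol=1e-12
        )

    def test_extreme_q_stays_normalized(self):
        m = box_probabilities(np.arange(1.0, 65.0).reshape(8, 8), 2)
        for q in (-50.0, 50.0):
            mu = normalized_measure(m, q)
            assert mu.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.isfinite(mu))


class TestBruteForceOracle:
    """Exhaustive enumeration on a 4x4 integer image, s in {1, 2}."""

    IMG = np.array(
        [[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12], [13, 14, 15, 16]], dtype=float
    )

    def _brute(self, s, q):
        boxes = []
        for r in range(0, 4, s):
            for c in range(0, 4, s):
                boxes.append(self.IMG[r : r + s, c : c + s].sum())
        total = sum(boxes)
        P = [b / total for b in boxes if b > 0]
        Z = sum(p**q for p in P)
        mu = [p**q / Z for p in P]
        A = sum(m * np.log(p) for m, p in zip(mu, P))
        F = sum(m * np.log(m) for m in mu)
        return np.array(P), np.array(mu), A, F

    @pytest.mark.parametrize("s", [1, 2])
    @pytest.mark.parametrize("q", [-2.0, 0.0, 1.0, 3.0])
    def test_measures_match_enumeration(self, s, q):
        P_ref, mu_ref, _, _ = self._brute(s, q)
        m = box_probabilities(self.IMG, s)
        np.testing.assert_allclose(np.sort(m.probabilities), np.sort(P_ref), atol=1e-12)
        np.testing.assert_allclose(
            np.sort(normalized_measure(m, q)), np.sort(mu_ref), atol=1e-12
        )

    @pytest.mark.parametrize("q", [-2.0, 0.0, 1.0, 3.0])
    def test_regression_numerators_match_enumeration(self, q):
        from bemdmf.multifractal import _moment_numerators

        _, _, A_ref, F_ref = self._brute(2, q)
        cfg = BoxCountingConfig(box_sizes=(2, 4), q_grid=(q,))
        _, A, F, logZ = _moment_numerators(self.IMG, np.array([q]), cfg)
        assert A[0][0] == pytest.approx(A_ref, abs=1e-12)
        assert F[0][0] == pytest.approx(F_ref, abs=1e-12)
        P_ref, _, _, _ = self._brute(2, q)
        assert logZ[0][0] == pytest.approx(np.log(np.sum(P_ref**q)), abs=1e-12)

    def test_mu_normalized_across_full_q_grid(self):
        for s in (1, 2):
            m = box_probabilities(self.IMG, s)
            for q in Q_GRID:
                assert normalized_measure(m, q).sum() == pytest.approx(1.0, abs=1e-9)


class TestScalingEstimates:
    def test_constant_image_alpha_two(self, pow2_boxes):
        for q in (-2.0, 0.0, 2.0):
            a, r2 = alpha_of_q(np.ones((128, 128)), q, pow2_boxes)
            assert a == pytest.approx(2.0, abs=0.02)
        assert r2 > 0.999

    def test_cascade_alpha_matches_closed_form(self, cascade_128, pow2_boxes):
        """On dyadic cascades with power-of-2 boxes the scaling is an exact line."""
        for q in (-2.0, 0.0, 1.0, 2.0):
            a_est, r2 = alpha_of_q(cascade_128, q, pow2_boxes)
            a_ref = cascade_analytic_spectrum(W, [q])[0][0]
            assert a_est == pytest.approx(a_ref, abs=1e-6)
            assert r2 > 1 - 1e-9

    def test_alpha_orders_with_q(self, cascade_128, pow2_boxes):
        a_pos, _ = alpha_of_q(cascade_128, 2.0, pow2_boxes)
        a_neg, _ = alpha_of_q(cascade_128, -2.0, pow2_boxes)
        assert a_pos < a_neg

    def test_constant_image_f_two(self, pow2_boxes):
        f, _ = f_of_q(np.ones((128, 128)), 1.5, pow2_boxes)
        assert f == pytest.approx(2.0, abs=0.02)

    def test_f_zero_is_support_dimension(self, cascade_128, pow2_boxes):
        f, _ = f_of_q(cascade_128, 0.0, pow2_boxes)
        assert f == pytest.approx(2.0, abs=0.1)

    def test_cascade_f_matches_closed_form(self, cascade_128, pow2_boxes):
        f_est, _ = f_of_q(cascade_128, 2.0, pow2_boxes)
        f_ref = cascade_analytic_spectrum(W, [2.0])[1][0]
        assert f_est == pytest.approx(f_ref, abs=1e-6)

    def test_dimensions_constant_image(self, pow2_boxes):
        for q in (-2.0, 0.0, 2.0):
            assert generalized_dimensions(np.ones((128, 128)), q, pow2_boxes) == pytest.approx(
                2.0, abs=0.05
            )

    def test_information_dimension_limit(self, cascade_128, pow2_boxes):
        d1 = generalized_dimensions(cascade_128, 1.0, pow2_boxes)
        f1, _ = f_of_q(cascade_128, 1.0, pow2_boxes)
        assert d1 == pytest.approx(f1, abs=1e-6)

    def test_legendre_relation_at_q_two(self, cascade_128, pow2_boxes):
        a, _ = alpha_of_q(cascade_128, 2.0, pow2_boxes)
        f, _ = f_of_q(cascade_128, 2.0, pow2_boxes)
        d2 = generalized_dimensions(cascade_128, 2.0, pow2_boxes)
        assert d2 == pytest.approx(2 * a - f, abs=1e-6)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            alpha_of_q(np.ones((64, 64)), 0.0, BoxCountingConfig(box_sizes=(2, 4)))


class TestLegendreSpectrum:
    def test_constant_image_degenerate_spectrum(self, pow2_boxes):
        spec = legendre_spectrum(np.ones((128, 128)), pow2_boxes)
        assert spec.delta_alpha <= 0.1
        assert spec.feature("alpha0") == pytest.approx(2.0, abs=0.05)

    def test_cascade_width_matches_closed_form(self, cascade_128, pow2_boxes):
        spec = legendre_spectrum(cascade_128, pow2_boxes)
        a_ref, _ = cascade_analytic_spectrum(W, spec.q_grid)
        ref_width = a_ref.max() - a_ref.min()
        assert abs(spec.delta_alpha - ref_width) <= 0.25 * ref_width

    def test_alpha_non_increasing_on_cascade(self, cascade_128, pow2_boxes):
        spec = legendre_spectrum(cascade_128, pow2_boxes)
        assert np.all(np.diff(spec.alpha_q) <= 1e-6)

    def test_width_ordering_cascade_vs_controls(self, cascade_128, pow2_boxes):
        fbm = generate_fbm_surface(FbmSpec(hurst=0.5, side=128, seed=0))
        d_cascade = legendre_spectrum(cascade_128, pow2_boxes).delta_alpha
        d_const = legendre_spectrum(np.ones((128, 128)), pow2_boxes).delta_alpha
        d_fbm = legendre_spectrum(fbm, pow2_boxes).delta_alpha
        assert d_cascade > d_const
        assert d_cascade > d_fbm

    def test_delta_f_sign_convention(self, cascade_128, pow2_boxes):
        spec = legendre_spectrum(cascade_128, pow2_boxes)
        assert spec.delta_f == pytest.approx(
            spec.f_at_alpha_max - spec.f_at_alpha_min, abs=1e-12
        )


class TestSelectBoxRange:
    def test_single_candidate_returned(self, cascade_64, pow2_boxes):
        sel, r2 = select_box_range(cascade_64, [(2, 32)], pow2_boxes)
        assert sel == (2, 32)

    def test_tie_breaks_toward_widest(self, pow2_boxes):
        sel, r2 = select_box_range(np.ones((128, 128)), [(2, 32), (2, 64)], pow2_boxes)
        assert sel == (2, 64)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_artifact_shifts_selection_to_enumerated_argmax(self, cascade_64, pow2_boxes):
        corrupted = cascade_64.copy()
        corrupted[:2, :] += cascade_64.max() * 50  # heavy border stripe
        candidates = [(2, 16), (2, 64), (8, 64)]

        def enumerate_best(image):
            scored = []
            for lo, hi in candidates:
                sizes = tuple(s for s in pow2_boxes.box_sizes if lo <= s <= hi)
                sub = BoxCountingConfig(box_sizes=sizes, q_grid=(0.0,))
                scored.append((alpha_of_q(image, 0.0, sub)[1], (lo, hi)))
            return max(scored)[1]

        sel, _ = select_box_range(corrupted, candidates, pow2_boxes)
        assert sel == enumerate_best(corrupted)
        assert sel != (2, 64)  # the degraded sizes are excluded

    def test_narrow_candidate_rejected(self, cascade_64, pow2_boxes):
        with pytest.raises(ValueError):
            select_box_range(cascade_64, [(2, 4)], pow2_boxes)


class TestHolderMap:
    def test_constant_image_alpha_two_everywhere(self):
        hm = holder_exponent_map(np.full((32, 32), 5.0), [1, 2, 3])
        np.testing.assert_allclose(hm.alpha_xy, 2.0, atol=0.05)

    def test_spike_is_more_singular_than_background(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        hm = holder_exponent_map(img + 1e-6, [1, 2, 3, 4])
        assert hm.alpha_xy[16, 16] < hm.alpha_xy[4, 4]

    def test_translation_covariance_in_interior(self, cascade_64):
        radii = [1, 2, 3]
        base = holder_exponent_map(cascade_64, radii).alpha_xy
        shifted = holder_exponent_map(np.roll(cascade_64, 5, axis=1), radii).alpha_xy
        # windows never cross the border in the compared region
        np.testing.assert_allclose(
            shifted[10:50, 15:50], np.roll(base, 5, axis=1)[10:50, 15:50], atol=1e-9
        )

    def test_radii_validation(self):
        with pytest.raises(ValueError):
            holder_exponent_map(np.ones((16, 16)), [3])
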