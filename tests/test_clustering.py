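"""Unified gravitational fuzzy clustering: KDE seeding, memberships,
gravity, objective bookkeeping and ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugfc.clustering import (
    FUZZY_LABEL,
    ClusterState,
    extract_roi,
    fcm_memberships,
    find_critical_bandwidth,
    gravity_force,
    kde_histogram,
    ugfc_cluster,
    ugfc_objective,
)
from ugfc.errors import InitializationError, InputDomainError, ParameterError
from ugfc.phantom import sample_mixture_1d, three_class_spec, make_phantom


def two_level_image(lo=50, hi=200, n=32):
    img = np.full((n, n), float(lo))
    img[:, n // 2:] = hi
    return img


class TestKDE:
    def test_constant_image_single_mode(self):
        prof = kde_histogram(np.full((16, 16), 100.0), h=3.0)
        assert prof.modes.size == 1
        assert prof.modes[0] == pytest.approx(100, abs=1)

    def test_two_levels_narrow_bandwidth_two_modes(self):
        prof = kde_histogram(two_level_image(), h=1.0)
        assert prof.modes.size == 2
        np.testing.assert_allclose(np.sort(prof.modes), [50, 200], atol=1)

    def test_oversmoothing_merges_modes(self):
        prof = kde_histogram(two_level_image(), h=200.0)
        assert prof.modes.size == 1

    def test_density_normalized(self):
        prof = kde_histogram(two_level_image(100, 180), h=5.0)
        assert np.trapezoid(prof.density, prof.grid) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ParameterError):
            kde_histogram(two_level_image(), h=0.0)


class TestCriticalBandwidth:
    def test_two_level_image_seeds_both_levels(self):
        h, v0 = find_critical_bandwidth(two_level_image(), c=2)
        assert 0 < h < 50
        np.testing.assert_allclose(np.sort(v0), [50, 200], atol=2)

    def test_mixture_modes_recover_component_means(self):
        x = sample_mixture_1d([50, 120, 200], [8, 8, 8], [1 / 3] * 3,
                              n=10000, seed=7)
        h, v0 = find_critical_bandwidth(x.reshape(100, 100), c=3)
        np.testing.assert_allclose(np.sort(v0), [50, 120, 200], atol=5)

    def test_constant_image_cannot_seed(self):
        with pytest.raises(InitializationError):
            find_critical_bandwidth(np.full((8, 8), 42.0), c=2)


class TestMemberships:
    def test_equidistant_gives_uniform(self):
        d = np.ones((4, 10))
        np.testing.assert_allclose(fcm_memberships(d, w=1.7), 0.25)

    def test_zero_distance_gives_crisp_membership(self):
        d = np.array([[0.0, 1.0], [2.0, 1.0]])
        mu = fcm_memberships(d, w=2.0)
        assert mu[0, 0] == 1.0 and mu[1, 0] == 0.0

    def test_known_two_cluster_value(self):
        # d1=1, d2=2, w=2: exponent 2, mu1 = 1/(1 + (1/2)^-2)^-1 ... = 0.8
        mu = fcm_memberships(np.array([[1.0], [2.0]]), w=2.0)
        np.testing.assert_allclose(mu[:, 0], [0.8, 0.2])

    def test_negative_distance_rejected(self):
        with pytest.raises(InputDomainError):
            fcm_memberships(np.array([[-1.0]]), w=2.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        c=st.integers(2, 5),
        n=st.integers(1, 30),
        w=st.floats(1.45, 2.55),
        seed=st.integers(0, 2**16),
    )
    def test_columns_always_sum_to_one(self, c, n, w, seed):
        d = np.random.default_rng(seed).uniform(0, 100, size=(c, n))
        mu = fcm_memberships(d, w)
        np.testing.assert_allclose(mu.sum(axis=0), 1.0, atol=1e-12)
        assert mu.min() >= 0 and mu.max() <= 1


class TestGravity:
    @pytest.mark.parametrize("mass, d2, expected",
                             [(1, 1.0, 2.0), (8, 4.0, 4.0), (0, 7.0, 0.0)])
    def test_force_examples(self, mass, d2, expected):
        assert gravity_force(mass, d2) == expected

    def test_distance_floor_prevents_singularity(self):
        assert gravity_force(5, 1e-12) == gravity_force(5, 1.0)

    def test_force_linear_in_mass(self, rng):
        d2 = rng.uniform(1, 50, size=20)
        m = rng.integers(1, 100, size=20)
        np.testing.assert_allclose(gravity_force(2 * m, d2),
                                   2 * gravity_force(m, d2))

    def test_negative_mass_rejected(self):
        with pytest.raises(InputDomainError):
            gravity_force(-1, 4.0)


class TestObjective:
    def test_zero_distance_hard_assignment(self):
        x = np.array([0.0, 0.0, 10.0, 10.0])
        labels = np.array([0, 0, 1, 1])
        mu = np.zeros((2, 4))
        j_gc, j_cm, j_gfc = ugfc_objective(x, np.array([0.0, 10.0]), mu,
                                           labels, w=1.7)
        assert j_gc == 0.0 and j_gfc == 0.0

    def test_empty_hard_set_convention(self):
        # with no hard pixels J_GC := 1, so the product reduces to J_CM
        x = np.array([0.0, 4.0])
        labels = np.full(2, FUZZY_LABEL)
        mu = np.array([[0.75, 0.25], [0.25, 0.75]])
        v = np.array([1.0, 3.0])
        j_gc, j_cm, j_gfc = ugfc_objective(x, v, mu, labels, w=2.0)
        assert j_gc == 1.0
        expected = (0.75**2 * 1 + 0.25**2 * 9) + (0.25**2 * 9 + 0.75**2 * 1)
        assert j_cm == pytest.approx(expected)
        assert j_gfc == pytest.approx(j_cm)

    def test_mixed_assignment_sums(self):
        x = np.array([1.0, 9.0, 5.0])
        labels = np.array([0, 1, FUZZY_LABEL])
        mu = np.array([[0.1, 0.2, 0.5], [0.9, 0.8, 0.5]])
        v = np.array([0.0, 10.0])
        j_gc, j_cm, _ = ugfc_objective(x, v, mu, labels, w=2.0)
        assert j_gc == pytest.approx(1.0 + 1.0)
        assert j_cm == pytest.approx(0.25 * 25 + 0.25 * 25)


class TestClusterLoop:
    def test_two_level_image_converges_exactly(self):
        st_ = ugfc_cluster(two_level_image(), c=2, w=1.7)
        np.testing.assert_allclose(np.sort(st_.centroids), [50, 200], atol=1e-9)
        assert np.all(st_.hard_labels != FUZZY_LABEL)
        assert st_.converged

    def test_three_class_centroid_recovery(self):
        for seed in (0, 1, 2):
            img, _, _ = make_phantom(three_class_spec(seed=seed))
            st_ = ugfc_cluster(img, c=3, w=1.7)
            np.testing.assert_allclose(np.sort(st_.centroids),
                                       [50, 120, 200], atol=5)

    def test_fcm_limit_matches_textbook_implementation(self):
        """With hard-clustering and gravity disabled the loop is plain FCM."""
        def fcm_reference(x, v0, w, iters):
            v = np.array(v0, dtype=float)
            for _ in range(iters):
                d = np.maximum(np.abs(x[None, :] - v[:, None]), 1e-300)
                inv = d ** (-2.0 / (w - 1.0))
                mu = inv / inv.sum(axis=0)
                v = (mu**w @ x) / (mu**w).sum(axis=1)
            return v, mu

        x = sample_mixture_1d([60, 180], [12, 12], [0.5, 0.5], n=160, seed=3)
        v0 = np.array([80.0, 150.0])
        st_ = ugfc_cluster(x, c=2, w=1.8, theta_hard=1.5, gamma=np.inf,
                           v0=v0, rho=1e-10, max_iter=60)
        v_ref, mu_ref = fcm_reference(x, v0, 1.8, st_.t)
        np.testing.assert_allclose(st_.centroids, v_ref, atol=1e-6)
        np.testing.assert_allclose(st_.memberships, mu_ref, atol=1e-6)

    def test_mass_conservation_and_membership_normalization(self):
        img, _, _ = make_phantom(three_class_spec(seed=4))
        st_ = ugfc_cluster(img, c=3, w=1.7)
        n_fuzzy = int(np.sum(st_.hard_labels == FUZZY_LABEL))
        assert st_.masses.sum() + n_fuzzy == img.size
        assert max(st_.membership_sum_err_trace) < 1e-9

    def test_nonconvergence_is_flagged_not_raised(self):
        x = sample_mixture_1d([90, 150], [25, 25], [0.5, 0.5], n=300, seed=2)
        st_ = ugfc_cluster(x, c=2, v0=np.array([10.0, 250.0]),
                           rho=1e-12, max_iter=1)
        assert not st_.converged
        assert st_.t == 1

    def test_parameter_validation(self):
        img = two_level_image()
        with pytest.raises(ParameterError):
            ugfc_cluster(img, c=1)
        with pytest.raises(ParameterError):
            ugfc_cluster(img, c=2, w=1.0)
        with pytest.raises(ParameterError):
            ugfc_cluster(img, c=2, rho=0.0)


class TestROI:
    def test_two_level_roi_is_bright_region(self):
        img = two_level_image()
        st_ = ugfc_cluster(img, c=2)
        roi = extract_roi(st_, img.shape)
        np.testing.assert_array_equal(roi.mask, img == 200)
        assert not roi.empty

    def test_index_rule_selects_requested_cluster(self):
        img = two_level_image()
        st_ = ugfc_cluster(img, c=2)
        k_dark = int(np.argmin(st_.centroids))
        roi = extract_roi(st_, img.shape, rule=f"index:{k_dark}")
        np.testing.assert_array_equal(roi.mask, img == 50)

    def test_degenerate_state_yields_empty_flag(self):
        state = ClusterState(
            c=2, centroids=np.array([10.0, 200.0]),
            memberships=np.vstack([np.ones(16), np.zeros(16)]),
            hard_labels=np.zeros(16, dtype=np.int64),
            masses=np.array([16, 0]), core_centroids_xy=np.zeros((2, 2)),
            t=1, shape=(4, 4))
        roi = extract_roi(state, (4, 4))  # brightest cluster holds no pixel
        assert roi.empty and not roi.mask.any()

    def test_exclude_border_removes_touching_components(self):
        img = np.full((24, 24), 40.0)
        img[0:24, 0:3] = 220.0        # bright band on the border
        img[10:14, 10:14] = 220.0     # interior bright blob
        st_ = ugfc_cluster(img, c=2)
        roi = extract_roi(st_, img.shape, exclude_border=True)
        assert roi.mask[12, 12]
        assert not roi.mask[:, 0:3].any()
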