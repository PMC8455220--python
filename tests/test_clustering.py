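import numpy as np
import pytest

from fuzzyseg import (
    ClusteringConfig,
    GuidedFilterParams,
    NoiseSpec,
    PhantomSpec,
    add_noise,
    fcm,
    fcm_gf,
    fcm_s,
    ifcm_gf,
    make_phantom,
    mrifcm_gf,
    segment,
    segmentation_accuracy,
    update_centers,
    update_memberships,
)


def eq5_scalar(x, v, m):
    """Membership of scalar x in each cluster, evaluated term by term."""
    d = np.abs(x - np.asarray(v, dtype=float))
    u = np.empty(len(v))
    for c in range(len(v)):
        u[c] = 1.0 / np.sum((d[c] / d) ** (2.0 / (m - 1.0)))
    return u


class TestMembershipUpdate:
    def test_matches_direct_evaluation(self):
        X = [0.0, 0.2, 1.0]
        V = [0.1, 0.9]
        u = update_memberships(X, V, m=2.0)
        expected = np.column_stack([eq5_scalar(x, V, 2.0) for x in X])
        assert np.allclose(u, expected)
        assert np.allclose(u.sum(axis=0), 1.0)

    def test_pixel_on_center_is_crisp(self):
        u = update_memberships([0.3], [0.3, 0.9], m=2.0)
        assert np.allclose(u[:, 0], [1.0, 0.0])

    def test_equidistant_pixel_splits_evenly(self):
        u = update_memberships([0.5], [0.2, 0.8], m=2.0)
        assert np.allclose(u[:, 0], [0.5, 0.5])

    def test_coincident_center_tie_splits_equally(self):
        u = update_memberships([0.3], [0.3, 0.3, 0.9], m=2.0)
        assert np.allclose(u[:, 0], [0.5, 0.5, 0.0])

    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_columns_stochastic(self, rng, m):
        x = rng.random(50)
        u = update_memberships(x, [0.1, 0.5, 0.9], m=m)
        assert np.allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert u.min() >= 0.0 and u.max() <= 1.0


class TestCenterUpdate:
    def test_crisp_memberships_give_class_means(self):
        x = np.array([0.0, 0.1, 0.8, 1.0])
        u = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        assert np.allclose(update_centers(x, u, 2.0), [0.05, 0.9])

    def test_uniform_memberships_give_global_mean(self):
        x = np.array([0.0, 0.5, 1.0])
        u = np.full((3, 3), 1 / 3)
        assert np.allclose(update_centers(x, u, 2.0), x.mean())

    def test_matches_weighted_mean_oracle(self, rng):
        x = rng.random(5)
        u = rng.random((3, 5))
        u /= u.sum(axis=0)
        m = 2.0
        expected = [(u[c] ** m * x).sum() / (u[c] ** m).sum() for c in range(3)]
        assert np.allclose(update_centers(x, u, m), expected)

    def test_empty_cluster_reseeded(self):
        x = np.array([0.2, 0.4, 0.6])
        u = np.array([[1, 1, 1], [0, 0, 0]], dtype=float)
        v = update_centers(x, u, 2.0, rng=0)
        assert np.isfinite(v).all()
        assert v[1] in x


class TestFcm:
    def test_separable_toy_recovers_crisp_clusters(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        res = fcm(x, ClusteringConfig(2, seed=0, init_centers=[0.2, 0.8]))
        assert np.allclose(np.sort(res.centers), [0.0, 1.0], atol=1e-6)
        assert res.memberships.max(axis=0).min() > 0.999

    def test_clean_phantom_perfect_sa_and_centers(self):
        img, truth = make_phantom(PhantomSpec("ST", 64))
        res = fcm(img, ClusteringConfig(3, seed=0))
        assert segmentation_accuracy(res.labels, truth).sa == 1.0
        assert np.allclose(np.sort(res.centers),
                           np.array([0, 85, 170]) / 255.0, atol=1e-6)

    def test_objective_monotone_nonincreasing(self):
        img, _ = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.05, seed=1))
        res = fcm(noisy, ClusteringConfig(3, seed=1))
        assert np.all(np.diff(res.objective_trace) <= 1e-10)

    def test_seed_determinism(self):
        img, _ = make_phantom(PhantomSpec("SF", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.05, seed=1))
        a = fcm(noisy, ClusteringConfig(4, seed=7))
        b = fcm(noisy, ClusteringConfig(4, seed=7))
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)

    def test_permuting_initial_centers_permutes_clusters_only(self):
        img, truth = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.03, seed=2))
        init = [0.1, 0.4, 0.7]
        a = fcm(noisy, ClusteringConfig(3, init_centers=init))
        b = fcm(noisy, ClusteringConfig(3, init_centers=init[::-1]))
        assert segmentation_accuracy(a.labels, b.labels).sa == 1.0
        sa_t = segmentation_accuracy(a.labels, truth).sa
        sb_t = segmentation_accuracy(b.labels, truth).sa
        assert sa_t == pytest.approx(sb_t)

    def test_max_iter_flags_not_converged(self):
        img, _ = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.1, seed=3))
        res = fcm(noisy, ClusteringConfig(3, seed=0, max_iter=2))
        assert res.n_iter == 2 and not res.converged

    def test_labels_consistent_with_membership_argmax(self):
        img, _ = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.05, seed=4))
        res = fcm(noisy, ClusteringConfig(3, seed=0))
        assert np.array_equal(res.labels.ravel(),
                              np.argmax(res.memberships, axis=0))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ClusteringConfig(1)
        with pytest.raises(ValueError):
            ClusteringConfig(2, m=1.0)
        with pytest.raises(ValueError):
            ClusteringConfig(2, xi=0.0)
        with pytest.raises(ValueError):
            segment(np.ones((4, 4)), ClusteringConfig(2), "nope")


class TestSpatialVariants:
    def test_alpha_zero_matches_plain_fcm(self):
        img, _ = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.05, seed=5))
        a = fcm(noisy, ClusteringConfig(3, seed=9))
        for variant in ("S1", "S2"):
            b = fcm_s(noisy, ClusteringConfig(3, seed=9, alpha=0.0), variant)
            assert np.array_equal(a.labels, b.labels)
            assert np.allclose(a.centers, b.centers)

    def test_one_step_matches_hand_formulas(self):
        # 5-pixel toy, one iteration from fixed centers
        x = np.array([[0.0, 0.1, 0.5, 0.9, 1.0]])
        alpha, m = 3.8, 2.0
        v0 = np.array([0.2, 0.8])
        from fuzzyseg.filters import box_mean

        xbar = box_mean(x, 1).ravel()
        xf = x.ravel()
        d2 = (xf[None, :] - v0[:, None]) ** 2 + alpha * (xbar[None, :] - v0[:, None]) ** 2
        u = (1.0 / d2) / (1.0 / d2).sum(axis=0)
        v1 = (u**m @ (xf + alpha * xbar)) / ((1 + alpha) * (u**m).sum(axis=1))
        res = fcm_s(x, ClusteringConfig(2, alpha=alpha, max_iter=1,
                                        init_centers=v0), "S1")
        assert np.allclose(res.centers, v1)
        assert np.allclose(res.memberships, u)

    def test_s2_robust_to_salt_pepper(self):
        img, truth = make_phantom(PhantomSpec("ST", 64))
        noisy = add_noise(img, NoiseSpec("salt_pepper", 0.2, seed=6))
        res = fcm_s(noisy, ClusteringConfig(3, seed=0), "S2")
        assert segmentation_accuracy(res.labels, truth).sa > 0.9

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            fcm_s(np.ones((4, 4)), ClusteringConfig(2), "S3")


class TestGuidedFilterVariants:
    def test_rho_one_ifcm_equals_fcm_gf(self):
        img, _ = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.05, seed=8))
        gf = GuidedFilterParams(1, 1e-4, 1.0)
        a = fcm_gf(noisy, ClusteringConfig(3, seed=3, gf=gf))
        b = ifcm_gf(noisy, ClusteringConfig(3, seed=3, gf=gf))
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)

    def test_rho_equivalent_to_rescaled_epsilon(self):
        # running with (eps, rho) must match (eps/rho^2, 1) up to round-off
        img, _ = make_phantom(PhantomSpec("ST", 32))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.05, seed=9))
        for rho in (0.05, 0.5, 2.0):
            a = ifcm_gf(noisy, ClusteringConfig(
                3, seed=4, gf=GuidedFilterParams(1, 1e-4, rho)))
            b = ifcm_gf(noisy, ClusteringConfig(
                3, seed=4, gf=GuidedFilterParams(1, 1e-4 / rho**2, 1.0)))
            assert np.array_equal(a.labels, b.labels)
            assert np.allclose(a.memberships, b.memberships, atol=1e-7)

    def test_memberships_stay_stochastic_after_filtering(self):
        img, _ = make_phantom(PhantomSpec("ST", 48))
        noisy = add_noise(img, NoiseSpec("salt_pepper", 0.2, seed=10))
        res = ifcm_gf(noisy, ClusteringConfig(
            3, seed=5, gf=GuidedFilterParams(1, 1e-4, 0.01)))
        u = res.memberships
        assert np.allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert u.min() >= 0.0 and u.max() <= 1.0 + 1e-12

    def test_mrifcm_clean_phantom_near_perfect(self):
        # the membership smoothing can flip a handful of isolated
        # highest-curvature boundary pixels even on a noise-free image;
        # everything else must be exact
        img, truth = make_phantom(PhantomSpec("SF", 64))
        res = mrifcm_gf(img, ClusteringConfig(
            4, seed=0, gf=GuidedFilterParams(1, 1e-4, 0.01)))
        assert segmentation_accuracy(res.labels, truth).sa >= 0.999

    def test_mrifcm_beats_fcm_on_heavy_noise(self):
        img, truth = make_phantom(PhantomSpec("ST", 96))
        noisy = add_noise(img, NoiseSpec("gaussian", 0.15, seed=11))
        plain = fcm(noisy, ClusteringConfig(3, seed=1))
        mr = mrifcm_gf(noisy, ClusteringConfig(
            3, seed=1, gf=GuidedFilterParams(1, 1e-4, 0.005)))
        sa_plain = segmentation_accuracy(plain.labels, truth).sa
        sa_mr = segmentation_accuracy(mr.labels, truth).sa
        assert sa_mr > sa_plain + 0.1
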