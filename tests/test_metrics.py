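"""Colour-difference, centroid-model and contrast statistics."""

import numpy as np
import pandas as pd
import pytest

import chromadapt as ca
from chromadapt.exceptions import DegenerateDataError, InsufficientPoolError, SamplingError
from chromadapt.metrics import (
    ColorCentroids,
    ciede2000,
    color_contrast,
    gower_distance,
    load_ciede2000_reference,
    permanova_source_check,
)


class TestCiede2000:
    def test_reference_pairs(self):
        """Match every pair of the published verification dataset to 1e-4."""
        ref = load_ciede2000_reference()
        got = ciede2000(ref[["l1", "a1", "b1"]].to_numpy(), ref[["l2", "a2", "b2"]].to_numpy())
        np.testing.assert_allclose(got, ref["delta_e00"], atol=1e-4, rtol=0)

    def test_matches_independent_implementation(self, rng):
        """Agree with scikit-image's CIEDE2000 on random colour pairs."""
        from skimage.color import deltaE_ciede2000

        lab1 = rng.uniform([0, -60, -60], [100, 60, 60], size=(200, 3))
        lab2 = rng.uniform([0, -60, -60], [100, 60, 60], size=(200, 3))
        np.testing.assert_allclose(ciede2000(lab1, lab2), deltaE_ciede2000(lab1, lab2), atol=1e-9)

    def test_identity_symmetry_nonnegativity(self, rng):
        lab = rng.uniform([0, -60, -60], [100, 60, 60], size=(100, 3))
        other = rng.uniform([0, -60, -60], [100, 60, 60], size=(100, 3))
        assert np.allclose(ciede2000(lab, lab), 0.0)
        np.testing.assert_allclose(ciede2000(lab, other), ciede2000(other, lab), atol=1e-12)
        assert np.all(ciede2000(lab, other) >= 0)


class TestCiede2000Properties:
    """Invariant sweep with hypothesis-generated colour pairs."""

    from hypothesis import given, settings, strategies as st

    lab_triplet = st.tuples(
        st.floats(0, 100), st.floats(-80, 80), st.floats(-80, 80)
    )

    @given(lab1=lab_triplet, lab2=lab_triplet)
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_symmetry_nonnegativity_identity(self, lab1, lab2):
        d12 = ciede2000(lab1, lab2)
        assert d12 >= 0.0
        assert d12 == pytest.approx(ciede2000(lab2, lab1), abs=1e-10)
        assert ciede2000(lab1, lab1) == 0.0

    @given(lab1=lab_triplet, lab2=lab_triplet)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_gower_bounded_by_unit_interval(self, lab1, lab2):
        ranges = (100.0, 160.0, 160.0)  # full axis spans
        d = gower_distance(lab1, lab2, ranges)
        assert 0.0 <= d <= 1.0


class TestGower:
    def test_hand_computed(self):
        d = gower_distance((50, 0, 0), (60, 5, -10), ranges=(100, 50, 100))
        assert d == pytest.approx(0.1, abs=1e-12)

    def test_identity_and_extremes(self):
        assert gower_distance((1, 2, 3), (1, 2, 3), ranges=(10, 10, 10)) == 0.0
        assert gower_distance((0, 0, 0), (10, 20, 30), ranges=(10, 20, 30)) == pytest.approx(1.0)

    def test_zero_range_rejected(self):
        with pytest.raises(DegenerateDataError):
            gower_distance((1, 2, 3), (4, 5, 6), ranges=(10, 0, 10))


class TestColorCentroids:
    def test_recovers_planted_centroids(self, two_cluster_pool):
        """Trimmed K-means lands within 0.5 CIELAB units of the planted means."""
        pool, mu1, mu2, _ = two_cluster_pool
        model = ColorCentroids(trim=0.05, random_state=0).fit(pool)
        planted = np.vstack([mu1, mu2])
        err = max(
            min(np.linalg.norm(c - p) for p in planted) for c in model.centroids_
        )
        assert err < 0.5
        assert model.neighborhoods_.shape == (2, 200, 3)
        assert np.all(model.ranges_ > 0)

    def test_trimming_beats_plain_kmeans_under_outliers(self):
        """With 5% gross outliers the trimmed fit is closer to the planted
        means than an untrimmed fit in at least 95 of 100 replicates."""
        mu = np.vstack([[55.0, -38.0, 32.0], [48.0, 18.0, 30.0]])
        wins = 0
        master = np.random.default_rng(7)
        for rep in range(100):
            r = np.random.default_rng(master.integers(2**31 - 1))
            clean = np.vstack([m + 2.0 * r.standard_normal((250, 3)) for m in mu])
            outliers = r.uniform([-20, -120, -120], [130, 120, 120], size=(26, 3))
            pool = np.vstack([clean, outliers])

            def err(model):
                return sum(
                    min(np.linalg.norm(c - m) for c in model.centroids_) for m in mu
                )

            seed = int(r.integers(2**31 - 1))
            trimmed = ColorCentroids(trim=0.05, n_restarts=8, random_state=seed).fit(pool)
            plain = ColorCentroids(trim=0.0, n_restarts=8, random_state=seed).fit(pool)
            if err(trimmed) < err(plain):
                wins += 1
        assert wins >= 95

    def test_centroid_set_stable_across_seeds(self, two_cluster_pool):
        """On well-separated data the centroid set is seed-independent."""
        pool = two_cluster_pool[0]
        a = ColorCentroids(random_state=1, n_restarts=10).fit(pool).centroids_
        b = ColorCentroids(random_state=99, n_restarts=10).fit(pool).centroids_
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_degenerate_and_small_pools_rejected(self):
        with pytest.raises(InsufficientPoolError):
            ColorCentroids().fit(np.zeros((300, 3)))
        with pytest.raises(DegenerateDataError):
            ColorCentroids().fit(np.tile([50.0, 0.0, 0.0], (500, 1)))


class TestCentroidDistance:
    def test_equals_brute_force(self, two_cluster_pool):
        """Vectorised statistic equals an explicit loop over all
        neighbourhood colours, to 1e-12."""
        pool = two_cluster_pool[0]
        model = ColorCentroids(random_state=0).fit(pool)
        r = np.random.default_rng(3)
        for mean in r.uniform([20, -50, -50], [90, 50, 50], size=(20, 3)):
            per = []
            for j in range(2):
                acc = 0.0
                for colour in model.neighborhoods_[j]:
                    acc += np.mean(np.abs(mean - colour) / model.ranges_)
                per.append(acc / model.neighborhoods_[j].shape[0])
            assert model.centroid_distance(mean) == pytest.approx(min(per), abs=1e-12)

    def test_monotone_in_displacement(self, two_cluster_pool):
        pool, mu1, _, _ = two_cluster_pool
        model = ColorCentroids(random_state=0).fit(pool)
        near = model.centroid_distance(mu1)
        far = model.centroid_distance(mu1 + 5.0 * model.ranges_)
        assert near < far

    def test_identical_means_identical_distances(self, two_cluster_pool):
        model = ColorCentroids(random_state=0).fit(two_cluster_pool[0])
        m = np.array([50.0, 0.0, 10.0])
        assert model.centroid_distance(m) == model.centroid_distance(m.copy())


class TestColorContrast:
    def test_zero_on_identical_samples(self):
        assert color_contrast(np.tile([50.0, 10.0, 10.0], (10, 1))) == 0.0

    def test_permutation_invariant(self, rng):
        samples = rng.uniform([0, -60, -60], [100, 60, 60], size=(10, 3))
        perm = samples[rng.permutation(10)]
        assert color_contrast(samples) == pytest.approx(color_contrast(perm), abs=1e-12)

    def test_increases_with_pair_difference(self):
        """At fixed 50% coverage, contrast grows with the ΔE00 of the two
        mixed colours."""
        base = np.array([55.0, -38.0, 32.0])
        prev = -1.0
        for shift in (5.0, 20.0, 50.0):
            other = base + np.array([0.0, shift, 0.0])
            samples = np.vstack([np.tile(base, (5, 1)), np.tile(other, (5, 1))])
            c = color_contrast(samples)
            assert c > prev
            prev = c

    def test_requires_ten_samples(self):
        with pytest.raises(ValueError):
            color_contrast(np.zeros((9, 3)))


class TestPermanovaSourceCheck:
    @staticmethod
    def _profiles(shift_l=0.0, n_each=80, seed=0):
        r = np.random.default_rng(seed)
        a = r.normal([55, -10, 20], [4, 3, 3], size=(n_each, 3))
        b = r.normal([55 + shift_l, -10, 20], [4, 3, 3], size=(n_each, 3))
        df = pd.DataFrame(np.vstack([a, b]), columns=["l", "a", "b"])
        df["source"] = ["author"] * n_each + ["community"] * n_each
        return df

    def test_null_calibration_and_uniform_pvalues(self):
        """Same-distribution sources: over independent datasets the rejection
        rate sits near alpha and the p-values are uniform (KS at 0.01).

        Each dataset is freshly drawn — subsampling one fixed pool would
        yield dependent p-values concentrated on that pool's idiosyncrasy.
        """
        from scipy import stats

        pvals = np.empty(500)
        for i in range(500):
            _, p = permanova_source_check(
                self._profiles(seed=1000 + i), n_permutations=199, n_resamples=1, seed=i
            )
            pvals[i] = p[0]
        reject = float(np.mean(pvals < 0.05))
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(reject - 0.05) <= 3 * se
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_lightness_shift(self):
        """A 3-SD lightness shift between sources is detected almost always."""
        frac_ns, _ = permanova_source_check(
            self._profiles(shift_l=12.0), n_permutations=199, n_resamples=200, seed=5
        )
        assert frac_ns < 0.10

    def test_insufficient_source_counts(self):
        with pytest.raises(SamplingError):
            permanova_source_check(self._profiles(n_each=30), n_resamples=5, seed=0)
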