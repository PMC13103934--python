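"""Reproducibility statistics, peak identification, correlation, clustering
and dimensionality reduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spectrakit as sk
from conftest import random_set


def sigma_avg_double_loop(intensities):
    """Independent brute-force oracle: explicit loops over k and i."""
    n, m = intensities.shape
    total = 0.0
    for k in range(m):
        mean_k = sum(intensities[i, k] for i in range(n)) / n
        ss = sum((intensities[i, k] - mean_k) ** 2 for i in range(n))
        total += (ss / (n - 1)) ** 0.5
    return total / m


class TestSigmaAvg:
    def test_identical_spectra_give_zero(self):
        sset = sk.SpectrumSet(np.arange(3.0), np.ones((4, 3)) * 7, tuple("abcd"))
        assert sk.sigma_avg(sset) == 0.0

    def test_hand_value_constant_pair(self):
        sset = sk.SpectrumSet(
            np.arange(4.0), np.vstack([np.zeros(4), np.full(4, 2.0)]), ("a", "b")
        )
        assert sk.sigma_avg(sset) == pytest.approx(np.sqrt(2), abs=1e-15)

    def test_hand_value_two_by_two(self):
        sset = sk.SpectrumSet(
            np.array([0.0, 1.0]), np.array([[0.0, 0.0], [2.0, 4.0]]), ("a", "b")
        )
        assert sk.sigma_avg(sset) == pytest.approx(1.5 * np.sqrt(2), abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_double_loop_oracle(self, seed):
        sset = random_set(np.random.default_rng(seed))
        assert sk.sigma_avg(sset) == pytest.approx(
            sigma_avg_double_loop(sset.intensities), abs=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), c=st.floats(-5, 5), offset=st.floats(-100, 100))
    def test_scale_equivariance_and_shift_invariance(self, seed, c, offset):
        sset = random_set(np.random.default_rng(seed))
        scaled = sset.with_intensities(c * sset.intensities)
        shifted = sset.with_intensities(sset.intensities + offset)
        assert sk.sigma_avg(scaled) == pytest.approx(
            abs(c) * sk.sigma_avg(sset), rel=1e-10, abs=1e-12
        )
        assert sk.sigma_avg(shifted) == pytest.approx(sk.sigma_avg(sset), rel=1e-10)

    def test_needs_two_spectra(self):
        one = sk.SpectrumSet(np.arange(3.0), np.ones((1, 3)), ("a",))
        with pytest.raises(ValueError):
            sk.sigma_avg(one)


class TestRelativeVariation:
    def test_hand_value(self):
        sset = sk.SpectrumSet(
            np.array([0.0, 1.0]), np.array([[0.0, 0.0], [2.0, 4.0]]), ("a", "b")
        )
        # mean spectrum (1, 2), trapezoidal area 1.5
        assert sk.relative_variation(sset) == pytest.approx(
            1.5 * np.sqrt(2) / 1.5, abs=1e-14
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_equals_sigma_avg_after_area_normalization(self, seed):
        rng = np.random.default_rng(seed)
        sset = random_set(rng)
        sset = sset.with_intensities(np.abs(sset.intensities) + 1.0)
        normed = sk.normalize(sset, mode="area")
        assert sk.relative_variation(normed) == pytest.approx(
            sk.sigma_avg(normed), rel=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        sset = random_set(rng)
        sset = sset.with_intensities(np.abs(sset.intensities) + 1.0)
        tripled = sset.with_intensities(3.0 * sset.intensities)
        assert sk.relative_variation(tripled) == pytest.approx(
            sk.relative_variation(sset), rel=1e-12
        )


class TestSummarize:
    def test_identical_spectra_collapse_band(self):
        sset = sk.SpectrumSet(np.arange(3.0), np.ones((3, 3)) * 4, tuple("abc"))
        st_ = sk.summarize(sset)
        assert np.array_equal(st_.sd, np.zeros(3))
        assert np.array_equal(st_.lower, st_.mean)
        assert np.array_equal(st_.upper, st_.mean)

    def test_hand_pair(self):
        sset = sk.SpectrumSet(
            np.arange(2.0), np.array([[0.0, 0.0], [2.0, 2.0]]), ("a", "b")
        )
        st_ = sk.summarize(sset, k=1)
        np.testing.assert_allclose(st_.mean, 1.0)
        np.testing.assert_allclose(st_.sd, np.sqrt(2))
        np.testing.assert_allclose(st_.lower, 1 - np.sqrt(2))
        np.testing.assert_allclose(st_.upper, 1 + np.sqrt(2))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_mean_matches_double_loop(self, seed):
        sset = random_set(np.random.default_rng(seed))
        st_ = sk.summarize(sset)
        naive = [
            sum(sset.intensities[i, k] for i in range(sset.n_spectra)) / sset.n_spectra
            for k in range(sset.n_points)
        ]
        np.testing.assert_allclose(st_.mean, naive, atol=1e-12)
        assert np.all(st_.lower <= st_.mean) and np.all(st_.mean <= st_.upper)


class TestCorrelation:
    def test_identical_spectra_all_ones(self):
        y = np.sin(np.arange(10.0))
        sset = sk.SpectrumSet(np.arange(10.0), np.vstack([y, y]), ("a", "b"))
        mat = sk.correlation_matrix(sset)
        assert mat.shape == (3, 3)  # mean appended as final reference
        np.testing.assert_allclose(mat.to_numpy(), 1.0, atol=1e-12)

    def test_negation_gives_minus_one(self):
        y = np.sin(np.arange(10.0))
        neg = 2 * y.mean() - y
        sset = sk.SpectrumSet(np.arange(10.0), np.vstack([y, neg]), ("a", "b"))
        mat = sk.correlation_matrix(sset, include_mean=False)
        assert mat.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_covariance_oracle(self, seed):
        sset = random_set(np.random.default_rng(seed))
        mat = sk.correlation_matrix(sset, include_mean=False).to_numpy()
        n = sset.n_spectra
        for i in range(n):
            for j in range(n):
                xi, xj = sset.intensities[i], sset.intensities[j]
                cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
                r = cov / (xi.std() * xj.std())
                assert mat[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_spectrum_rejected(self):
        sset = sk.SpectrumSet(
            np.arange(3.0), np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
            ("ok", "flat"),
        )
        with pytest.raises(ValueError, match="flat"):
            sk.correlation_matrix(sset)


class TestFindPeaks:
    def test_triangle_peak(self):
        y = np.array([0.0, 5.0, 10.0, 5.0, 0.0])
        pl = sk.find_peaks(np.arange(5.0), y, top_n=3)
        assert pl.positions.tolist() == [2.0]
        assert pl.prominences.tolist() == [10.0]

    def test_contour_prominence_toy(self):
        """Heights 10 and 6 with a valley at 2 between them and zero
        boundaries: prominences 10 and 6 - max(2, 0) = 4."""
        y = np.array([0.0, 10.0, 2.0, 6.0, 0.0])
        pl = sk.find_peaks(np.arange(5.0), y, top_n=5)
        assert pl.positions.tolist() == [1.0, 3.0]
        assert pl.prominences.tolist() == [10.0, 4.0]
        assert pl.heights.tolist() == [10.0, 6.0]

    def test_top_n_selects_by_prominence(self):
        y = np.array([0.0, 10.0, 2.0, 6.0, 0.0])
        pl = sk.find_peaks(np.arange(5.0), y, top_n=1)
        assert pl.positions.tolist() == [1.0]

    def test_min_prominence_filter(self):
        y = np.array([0.0, 10.0, 2.0, 6.0, 0.0])
        pl = sk.find_peaks(np.arange(5.0), y, top_n=5, min_prominence=5.0)
        assert pl.positions.tolist() == [1.0]

    def test_generator_centers_recovered(self, bsa_set):
        sset, truth = bsa_set
        from conftest import fig4_chain_steps

        out, _ = sk.run_pipeline(sset, sk.PipelineConfig.from_steps(fig4_chain_steps()))
        pl = sk.find_peaks(out.axis, out.intensities.mean(axis=0), top_n=5)
        assert len(pl.positions) == 5
        for center in truth.peak_centers:
            assert np.min(np.abs(pl.positions - center)) <= 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), offset=st.floats(-1000, 1000))
    def test_offset_invariance(self, seed, offset):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=60)
        try:
            pl = sk.find_peaks(np.arange(60.0), y, top_n=5)
        except ValueError:
            return
        pl2 = sk.find_peaks(np.arange(60.0), y + offset, top_n=5)
        assert np.array_equal(pl.positions, pl2.positions)
        np.testing.assert_allclose(pl.prominences, pl2.prominences, atol=1e-9)

    def test_monotone_signal_errors(self):
        with pytest.raises(ValueError, match="local maxima"):
            sk.find_peaks(np.arange(5.0), np.arange(5.0), top_n=1)


class TestWardHCA:
    def test_identical_pair_merges_at_zero(self):
        y = np.sin(np.arange(10.0))
        sset = sk.SpectrumSet(np.arange(10.0), np.vstack([y, y]), ("a", "b"))
        res = sk.hca_ward(sset)
        assert res.merges.shape == (1, 4)
        assert res.merges[0, 2] == 0.0

    def test_hand_lance_williams_values(self):
        """Points 0, 1, 10 (padded to M=2): first merge at height 1, second
        at sqrt(361/3) = 19/sqrt(3)."""
        sset = sk.SpectrumSet(
            np.array([0.0, 1.0]),
            np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]]),
            ("a", "b", "c"),
        )
        res = sk.hca_ward(sset)
        assert res.merges[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert res.merges[1, 2] == pytest.approx(19 / np.sqrt(3), abs=1e-9)
        assert sorted(res.leaf_order.tolist()) == [0, 1, 2]

    def test_two_class_top_split_is_label_pure(self, two_class_set):
        res = sk.hca_ward(two_class_set)
        cut = res.cut(2)
        groups = np.asarray(two_class_set.groups)
        for c in np.unique(cut):
            assert len(set(groups[cut == c])) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_merge_heights_monotone(self, seed):
        sset = random_set(np.random.default_rng(seed))
        if sset.n_spectra < 3:
            return
        heights = sk.hca_ward(sset).merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)


class TestPCA:
    def test_two_spectra_single_component(self):
        sset = sk.SpectrumSet(
            np.arange(4.0),
            np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]]),
            ("a", "b"),
        )
        res = sk.pca(sset, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(1)
        sset = random_set(rng, n=5, m=8)
        res = sk.pca(sset, min(sset.n_spectra - 1, sset.n_points))
        centered = sset.intensities - sset.intensities.mean(axis=0)
        recon = res.scores @ res.loadings
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_ratios_match_covariance_eigendecomposition(self):
        x = np.array(
            [[2.0, 0.0, 1.0], [0.0, 1.0, -1.0], [3.0, 1.0, 0.0], [1.0, 2.0, 2.0]]
        )
        sset = sk.SpectrumSet(np.arange(3.0), x, tuple("abcd"))
        res = sk.pca(sset, 3)
        centered = x - x.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, eigvals[:3] / eigvals.sum(), atol=1e-12
        )

    def test_matches_sklearn_cross_check(self, two_class_set):
        from sklearn.decomposition import PCA as SkPCA

        res = sk.pca(two_class_set, 3)
        ref = SkPCA(n_components=3).fit(two_class_set.intensities)
        np.testing.assert_allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(res.loadings), np.abs(ref.components_), atol=1e-8
        )

    def test_invariants(self, two_class_set):
        res = sk.pca(two_class_set, 4)
        ratios = res.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        assert np.all(ratios >= 0) and ratios.sum() <= 1 + 1e-9
        gram = res.loadings @ res.loadings.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        # sign convention: largest-|.| element of each loading is positive
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_component_range_validation(self, two_class_set):
        with pytest.raises(ValueError, match="n_components"):
            sk.pca(two_class_set, 0)
        with pytest.raises(ValueError, match="n_components"):
            sk.pca(two_class_set, two_class_set.n_spectra)

    def test_two_class_scores_separate(self, two_class_set):
        res = sk.pca(two_class_set, 2)
        groups = np.asarray(two_class_set.groups)
        pc1 = res.scores[:, 0]
        a, b = pc1[groups == "BPE"], pc1[groups == "R6G"]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # margin > 0


class TestTSNE:
    def test_determinism_by_seed(self, two_class_set):
        e1 = sk.tsne_embed(two_class_set, perplexity=3, n_iter=500, seed=4)
        e2 = sk.tsne_embed(two_class_set, perplexity=3, n_iter=500, seed=4)
        assert np.array_equal(e1.coordinates, e2.coordinates)
        assert np.all(np.isfinite(e1.coordinates))

    def test_two_class_separation(self, two_class_set):
        emb = sk.tsne_embed(two_class_set, perplexity=3, n_iter=500, seed=0)
        groups = np.asarray(two_class_set.groups)
        coords = emb.coordinates
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        same = (groups[:, None] == groups[None, :]) & ~np.eye(len(groups), dtype=bool)
        diff = groups[:, None] != groups[None, :]
        assert d[same].mean() < d[diff].mean()

    def test_infeasible_perplexity(self, two_class_set):
        with pytest.raises(ValueError, match="perplexity"):
            sk.tsne_embed(two_class_set, perplexity=10, n_iter=500, seed=0)
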