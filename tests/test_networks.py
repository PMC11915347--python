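"""Ward networks and multi-scale mutual information with permutation nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gmconn as gc

from conftest import mc_from_table


def brute_mi(a, b):
    """Contingency-table MI computed cell by cell, independent of the package."""
    import collections
    import math

    a, b = list(a), list(b)
    n = len(a)
    ca = collections.Counter(a)
    cb = collections.Counter(b)
    cab = collections.Counter(zip(a, b))
    return sum(
        c / n * math.log((c / n) / ((ca[x] / n) * (cb[y] / n))) for (x, y), c in cab.items()
    )


def entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _dendrogram_from_distance(d, tag="x"):
    names = tuple(f"r{i}" for i in range(d.shape[0]))
    return gc.ward_dendrogram(d, names, "MC", tag)


def _block_distance(blocks, within=0.2, between=1.4):
    blocks = np.asarray(blocks)
    d = np.where(blocks[:, None] == blocks[None, :], within, between)
    np.fill_diagonal(d, 0.0)
    return d


class TestDistance:
    @pytest.mark.parametrize(
        "r, use_abs, expected",
        [(1.0, False, 0.0), (0.0, False, np.sqrt(2)), (-1.0, True, 0.0), (-1.0, False, 2.0)],
    )
    def test_cosine_theorem_values(self, r, use_abs, expected):
        m = gc.ConnectivityMatrix("MC", "FT", np.array([[1.0, r], [r, 1.0]]), ("a", "b"))
        d = gc.corr_to_distance(m, use_abs=use_abs)
        assert d[0, 1] == pytest.approx(expected)
        assert d[0, 0] == 0.0

    def test_distance_bounds(self, small_cohort):
        _, ds = small_cohort
        m = mc_from_table(ds.metrics["FT"])
        d = gc.corr_to_distance(m, use_abs=True)
        assert d.min() >= 0 and d.max() <= 2 + 1e-12
        np.testing.assert_allclose(d, d.T)


class TestWardDendrogram:
    def test_two_planted_blocks_recovered_at_k2(self):
        blocks = np.repeat([0, 1], [8, 12])
        dend = _dendrogram_from_distance(_block_distance(blocks))
        cut = dend.cut(2)
        assert gc.mutual_information(cut, blocks) == pytest.approx(entropy(blocks))

    def test_all_equal_distances_no_crash(self):
        d = np.full((10, 10), 1.0)
        np.fill_diagonal(d, 0.0)
        dend = _dendrogram_from_distance(d)
        assert len(np.unique(dend.cut(10))) == 10

    def test_leaf_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 40))
        d = np.sqrt(2 * (1 - np.corrcoef(x)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = rng.permutation(12)
        da = _dendrogram_from_distance(d)
        db = _dendrogram_from_distance(d[np.ix_(perm, perm)])
        for k in range(2, 12):
            ca = da.cut(k)[perm]
            cb = db.cut(k)
            # identical partitions up to label renaming
            assert gc.mutual_information(ca, cb) == pytest.approx(entropy(ca), abs=1e-12)

    def test_merge_table_roundtrip(self, tmp_path):
        dend = _dendrogram_from_distance(_block_distance(np.repeat([0, 1, 2], 5)))
        path = tmp_path / "dend.csv"
        dend.save_csv(path)
        back = gc.Dendrogram.load_csv(path, dend.roi_names, "MC", "x")
        np.testing.assert_allclose(back.linkage_matrix, dend.linkage_matrix)


@pytest.fixture(scope="module")
def dend():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(20, 50))
    d = np.sqrt(2 * (1 - np.corrcoef(x)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return _dendrogram_from_distance(d)


@pytest.fixture(scope="module")
def dendros():
    def make(seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=(20, 60))
        d = np.sqrt(2 * (1 - np.corrcoef(x)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return _dendrogram_from_distance(d)

    return make(10), make(11)


class TestCutDendrogram:
    def test_extreme_cuts(self, dend):
        assert len(np.unique(dend.cut(1))) == 1
        assert len(np.unique(dend.cut(20))) == 20

    def test_every_cut_has_exactly_k_clusters(self, dend):
        for k in range(1, 21):
            assert len(np.unique(dend.cut(k))) == k

    def test_adjacent_cuts_differ_by_one_split(self, dend):
        for k in range(1, 20):
            a, b = dend.cut(k), dend.cut(k + 1)
            # each cluster of the finer cut sits inside one coarser cluster
            for lab in np.unique(b):
                assert len(np.unique(a[b == lab])) == 1

    def test_out_of_range_rejected(self, dend):
        with pytest.raises(ValueError):
            dend.cut(0)
        with pytest.raises(ValueError):
            dend.cut(21)


class TestMutualInformation:
    def test_identical_two_cluster_labeling(self):
        labels = [0, 0, 1, 1]
        assert gc.mutual_information(labels, labels) == pytest.approx(np.log(2))

    def test_independent_margins_zero(self):
        assert gc.mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_single_cluster_zero(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, 30)
        assert gc.mutual_information(labels, np.zeros(30)) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc.mutual_information([], [])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 80))
        a = rng.integers(0, rng.integers(1, 8), n)
        b = rng.integers(0, rng.integers(1, 8), n)
        assert gc.mutual_information(a, b) == pytest.approx(brute_mi(a, b), abs=1e-12)


class TestMultiScale:
    def test_shape_and_transpose_symmetry(self, dendros):
        da, db = dendros
        mi = gc.mi_across_scales(da, db, k_range=range(2, 21))
        assert mi.shape == (19, 19)
        mi_t = gc.mi_across_scales(db, da, k_range=range(2, 21))
        np.testing.assert_allclose(mi, mi_t.T, atol=1e-12)

    def test_self_comparison_diagonal_is_cut_entropy(self, dendros):
        da, _ = dendros
        mi = gc.mi_across_scales(da, da, k_range=range(2, 21))
        for i, k in enumerate(range(2, 21)):
            assert mi[i, i] == pytest.approx(entropy(da.cut(k)), abs=1e-12)

    def test_leaf_mismatch_rejected(self, dendros):
        da, _ = dendros
        other = _dendrogram_from_distance(_block_distance(np.repeat([0, 1], 5)))
        with pytest.raises(ValueError, match="leaf"):
            gc.mi_across_scales(da, other)


class TestPermutationNull:
    def test_identical_labelings_significant(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, 75)
        obs = gc.mutual_information(labels, labels)
        _, p95 = gc.mi_permutation_null(labels, labels, n_perm=100, seed=0)
        assert obs > p95

    def test_single_cluster_never_significant(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, 75)
        b = np.zeros(75, dtype=int)
        obs = gc.mutual_information(a, b)
        _, p95 = gc.mi_permutation_null(a, b, n_perm=100, seed=0)
        assert obs == pytest.approx(0.0)
        assert not obs > p95

    def test_same_seed_identical_null(self):
        rng = np.random.default_rng(6)
        a, b = rng.integers(0, 4, (2, 60))
        n1, _ = gc.mi_permutation_null(a, b, n_perm=50, seed=9)
        n2, _ = gc.mi_permutation_null(a, b, n_perm=50, seed=9)
        np.testing.assert_array_equal(n1, n2)

    def test_null_preserves_cluster_sizes(self):
        """The shuffle must permute assignments, not resample them."""
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        null, _ = gc.mi_permutation_null(a, b, n_perm=30, seed=1)
        # MI of shuffled labels is bounded by the margin entropies
        assert (null <= min(entropy(a), entropy(b)) + 1e-12).all()


class TestSummaries:
    def test_empty_mask_reports_no_overlap(self):
        comp = gc.MIComparison(
            name="x", k_values=(2, 3), mi=np.zeros((2, 2)),
            null_p95=np.ones((2, 2)), n_perm=100, seed=0,
        )
        mean, sd, n = gc.summarize_mi(comp)
        assert n == 0 and np.isnan(mean) and np.isnan(sd)

    def test_identical_dendrograms_diagonal_significant(self):
        dend = _dendrogram_from_distance(_block_distance(np.repeat(np.arange(5), 15)))
        comp = gc.compare_dendrograms(dend, dend, k_range=range(2, 76), n_perm=100, seed=2)
        mean, sd, n = gc.summarize_mi(comp)
        assert n >= 74  # at least every matched-size pair
        diag = np.diag(comp.significant)
        assert diag.sum() >= 70
        assert mean > 0
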