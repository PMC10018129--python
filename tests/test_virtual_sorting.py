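import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasticitome.io_formats import ValidationError
from plasticitome.rank_norm import RankMatrix
from plasticitome.virtual_sorting import (
    VirtualSortParams,
    cosine_similarity,
    delta_scores,
    kmeans2_split,
    virtual_sort,
)


def brute_force_2means(values):
    """Minimal within-cluster sum of squares over ALL 2-partitions."""
    values = np.asarray(values, dtype=float)
    n = values.size
    best = None
    for mask_bits in range(1, 2 ** n - 1):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        a, b = values[mask], values[~mask]
        wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if best is None or wss < best:
            best = wss
    return best


class TestKmeansSplit:
    def test_clear_gap_split(self):
        labels = kmeans2_split([0, 0, 1, 100, 100])
        assert list(labels) == ["g2", "g2", "g2", "g1", "g1"]

    def test_two_samples_forced(self):
        assert list(kmeans2_split([0, 100])) == ["g2", "g1"]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="not plastic"):
            kmeans2_split([5, 5, 5])

    def test_small_sample_warning(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kmeans2_split([0.0, 1.0, 100.0])

    @given(
        st.lists(st.integers(0, 100), min_size=4, max_size=12).filter(
            lambda v: len(set(v)) > 1
        )
    )
    def test_matches_exhaustive_wss_minimum(self, values):
        values = np.asarray(values, dtype=float)
        labels = kmeans2_split(values)
        g1 = values[labels == "g1"]
        g2 = values[labels == "g2"]
        wss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        assert wss == pytest.approx(brute_force_2means(values), abs=1e-9)
        assert g1.mean() > g2.mean()  # g1 is the target-high group

    def test_never_worse_than_sklearn_kmeans(self, rng):
        # the exact scan must match or beat Lloyd's algorithm on WSS
        from sklearn.cluster import KMeans

        def wss(values, assign):
            total = 0.0
            for lab in np.unique(assign):
                grp = values[assign == lab]
                total += ((grp - grp.mean()) ** 2).sum()
            return total

        for _ in range(20):
            values = rng.uniform(0, 100, size=rng.integers(5, 30))
            ours = wss(values, kmeans2_split(values))
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
                values.reshape(-1, 1)
            )
            assert ours <= wss(values, km.labels_) + 1e-9


class TestDeltaScores:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return RankMatrix(
            values=values,
            gene_ids=[f"G{i}" for i in range(values.shape[0])],
            sample_ids=[f"S{j}" for j in range(values.shape[1])],
            platform="rnaseq-tpm",
        )

    def test_extreme_and_constant_genes(self):
        r = self._matrix([[100, 100, 0, 0], [50, 50, 50, 50]])
        labels = np.array(["g1", "g1", "g2", "g2"])
        d = delta_scores(r, labels)
        assert d["G0"] == pytest.approx(100)
        assert d["G1"] == pytest.approx(0)

    def test_swapping_groups_negates_delta(self, rng):
        values = rng.uniform(0, 100, (5, 8))
        r = self._matrix(values)
        labels = np.array(["g1"] * 4 + ["g2"] * 4)
        swapped = np.where(labels == "g1", "g2", "g1")
        d1 = delta_scores(r, labels)
        d2 = delta_scores(r, swapped)
        for g in d1:
            assert d2[g] == pytest.approx(-d1[g])

    def test_empty_group_rejected(self):
        r = self._matrix([[1, 2]])
        with pytest.raises(ValidationError, match="non-empty"):
            delta_scores(r, np.array(["g1", "g1"]))


class TestCosine:
    def test_parallel_is_one(self):
        assert cosine_similarity([1, 1], [1, 1]) == pytest.approx(1.0)
        assert cosine_similarity([1, 1], [2, 2]) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_vector_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero vector"):
            assert cosine_similarity([0, 0], [1, 2]) == 0.0

    def test_two_zero_vectors_undefined(self):
        with pytest.raises(ValidationError):
            cosine_similarity([0, 0], [0, 0])

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=2, max_size=20),
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=2, max_size=20),
    )
    def test_range_for_nonnegative_vectors(self, x, y):
        n = min(len(x), len(y))
        x, y = np.asarray(x[:n]), np.asarray(y[:n])
        if np.linalg.norm(x) == 0 and np.linalg.norm(y) == 0:
            return
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = cosine_similarity(x, y)
        assert 0.0 <= c <= 1.0


class TestVirtualSort:
    def test_planted_blocks_recovered(self, rnaseq_ranks, bulk_data):
        *_, truth = bulk_data
        v = virtual_sort("DRV1", rnaseq_ranks)
        correlated = set(truth.members("DRV1", "correlated"))
        anticorrelated = set(truth.members("DRV1", "anticorrelated"))
        found_c, found_a = set(v.correlated), set(v.anticorrelated)
        assert len(found_c & correlated) / len(correlated) >= 0.9
        assert len(found_c & correlated) / max(len(found_c), 1) >= 0.9
        assert len(found_a & anticorrelated) / len(anticorrelated) >= 0.8
        assert "DRV1" not in found_c | found_a  # target excluded
        assert not (found_c & found_a)

    def test_threshold_signs_by_construction(self, rnaseq_ranks):
        v = virtual_sort("DRV2", rnaseq_ranks)
        assert all(v.delta[g] >= 20 and v.pearson[g] >= 0.5 for g in v.correlated)
        assert all(
            v.delta[g] <= -10 and v.pearson[g] < 0 and v.cosine[g] <= 0.1
            for g in v.anticorrelated
        )

    def test_lists_sorted_by_abs_delta_descending(self, rnaseq_ranks):
        v = virtual_sort("DRV3", rnaseq_ranks)
        for lst in (v.correlated, v.anticorrelated):
            deltas = [abs(v.delta[g]) for g in lst]
            assert deltas == sorted(deltas, reverse=True)

    def test_self_identical_matrix_has_no_anticorrelated(self):
        row = np.array([0.0, 0.0, 100.0, 100.0, 100.0])
        r = RankMatrix(
            values=np.tile(row, (4, 1)),
            gene_ids=["T", "A", "B", "C"],
            sample_ids=[f"S{j}" for j in range(5)],
            platform="rnaseq-tpm",
        )
        v = virtual_sort("T", r)
        assert v.anticorrelated == []
        assert set(v.correlated) == {"A", "B", "C"}

    def test_low_plasticity_target_rejected(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(40, 60, (3, 10))  # nothing spans 50 rank points
        r = RankMatrix(
            values=values,
            gene_ids=["A", "B", "C"],
            sample_ids=[f"S{j}" for j in range(10)],
            platform="rnaseq-tpm",
        )
        with pytest.raises(ValidationError, match="not a highly plastic"):
            virtual_sort("A", r)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            VirtualSortParams(delta_pos_min=-5)
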