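import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dtocf import (
    EntityVocabulary,
    FingerprintSet,
    SimilarityMatrix,
    build_chemical_similarity,
    build_protein_similarity,
    laplacian_quadratic,
    read_similarity_triplets,
    subsample_similarity,
    tanimoto_similarity,
    write_similarity_triplets,
)
from dtocf.errors import DataError, ShapeError


def fingerprint_set(bit_sets, n_bits=32):
    vocab = EntityVocabulary.from_ids([f"c{i}" for i in range(len(bit_sets))])
    return FingerprintSet(
        vocabulary=vocab, n_bits=n_bits, bits=tuple(frozenset(b) for b in bit_sets)
    )


class TestTanimoto:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),
            (set(), set(), 0.0),
            ({1}, set(), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert tanimoto_similarity(a, b) == pytest.approx(expected)

    @given(
        a=st.sets(st.integers(0, 31), max_size=32),
        b=st.sets(st.integers(0, 31), max_size=32),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        s = tanimoto_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto_similarity(b, a)


class TestChemicalSimilarity:
    def test_noise_threshold_is_strictly_below(self):
        # pair 0-1: Tanimoto 0.5 exactly (retained); pair 0-2: 1/3 (zeroed)
        fps = fingerprint_set([{0, 1, 2}, {1, 2, 3}, {2, 3}])
        S = build_chemical_similarity(fps, noise_threshold=0.5)
        dense = S.matrix.toarray()
        assert dense[0, 1] == pytest.approx(0.5)
        assert dense[0, 2] == 0.0

    def test_single_chemical_gives_empty_matrix(self):
        S = build_chemical_similarity(fingerprint_set([{1, 2}]))
        assert S.matrix.nnz == 0
        assert S.degree.tolist() == [0.0]

    def test_symmetry_zero_diagonal_and_degree(self):
        fps = fingerprint_set([{0, 1, 2, 3}, {0, 1, 2}, {0, 1, 2, 3, 4}])
        S = build_chemical_similarity(fps, noise_threshold=0.0)
        dense = S.matrix.toarray()
        assert np.allclose(dense, dense.T)
        assert np.all(np.diag(dense) == 0.0)
        assert np.allclose(S.degree, dense.sum(axis=1))

    def test_invariant_to_entity_ordering(self):
        bit_sets = [{0, 1, 2}, {1, 2, 3}, {0, 1, 2, 3}, {5, 6}]
        S = build_chemical_similarity(fingerprint_set(bit_sets), noise_threshold=0.0)
        perm = [2, 0, 3, 1]
        S_perm = build_chemical_similarity(
            fingerprint_set([bit_sets[p] for p in perm]), noise_threshold=0.0
        )
        dense, dense_perm = S.matrix.toarray(), S_perm.matrix.toarray()
        for a, pa in enumerate(perm):
            for b, pb in enumerate(perm):
                assert dense_perm[a, b] == pytest.approx(dense[pa, pb])


class TestProteinSimilarity:
    def test_one_directional_hit_averages_with_zero(self):
        hits = [("p1", "p1", 100.0), ("p2", "p2", 80.0), ("p1", "p2", 50.0)]
        S = build_protein_similarity(hits, {"p1": 100.0, "p2": 80.0})
        i, j = S.vocabulary.index["p1"], S.vocabulary.index["p2"]
        # directed ratio 50/100 = 0.5, reverse missing: (0.5 + 0)/2
        assert S.matrix[i, j] == pytest.approx(0.25)
        assert S.matrix[j, i] == pytest.approx(0.25)

    def test_bidirectional_hits_average(self):
        hits = [
            ("p1", "p1", 100.0), ("p2", "p2", 50.0),
            ("p1", "p2", 40.0), ("p2", "p1", 40.0),
        ]
        S = build_protein_similarity(hits, {"p1": 100.0, "p2": 50.0})
        i, j = S.vocabulary.index["p1"], S.vocabulary.index["p2"]
        assert S.matrix[i, j] == pytest.approx((0.4 + 0.8) / 2)

    def test_directed_ratio_above_one_is_clipped(self):
        hits = [("p1", "p1", 50.0), ("p2", "p2", 200.0), ("p1", "p2", 60.0)]
        S = build_protein_similarity(hits, {"p1": 50.0, "p2": 200.0})
        i, j = S.vocabulary.index["p1"], S.vocabulary.index["p2"]
        assert S.matrix[i, j] == pytest.approx(0.5)  # clip(1.2) -> 1.0, mean with 0

    def test_diagonal_stored_zero(self):
        hits = [("p1", "p1", 100.0)]
        S = build_protein_similarity(hits, {"p1": 100.0})
        assert S.matrix.toarray()[0, 0] == 0.0

    def test_missing_self_score_names_protein(self):
        with pytest.raises(DataError, match="p1"):
            build_protein_similarity([("p1", "p2", 10.0), ("p2", "p2", 5.0)], {"p2": 5.0})


class TestSubsample:
    def _random_similarity(self, n=60, seed=3):
        rng = np.random.default_rng(seed)
        vocab = EntityVocabulary.from_ids([f"e{i}" for i in range(n)])
        pairs = [
            (i, j, float(rng.uniform(0.5, 1.0)))
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.6
        ]
        return SimilarityMatrix.from_pairs(vocab, pairs)

    def test_keep_all_and_keep_none(self):
        S = self._random_similarity()
        assert (subsample_similarity(S, 1.0, 0).matrix != S.matrix).nnz == 0
        assert subsample_similarity(S, 0.0, 0).matrix.nnz == 0

    def test_half_keep_count_within_binomial_bounds(self):
        S = self._random_similarity()
        n_pairs = len(S.nonzero_pairs())
        kept = len(subsample_similarity(S, 0.5, seed=11).nonzero_pairs())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, 0.5)
        assert lo <= kept <= hi

    def test_seeded_and_symmetric(self):
        S = self._random_similarity()
        a = subsample_similarity(S, 0.5, seed=5)
        b = subsample_similarity(S, 0.5, seed=5)
        assert (a.matrix != b.matrix).nnz == 0
        assert (a.matrix != a.matrix.T).nnz == 0


class TestLaplacianQuadratic:
    def test_identical_rows_give_zero(self):
        vocab = EntityVocabulary.from_ids(["a", "b", "c"])
        S = SimilarityMatrix.from_pairs(vocab, [(0, 1, 0.7), (1, 2, 0.3)])
        M = np.tile([1.0, 2.0], (3, 1))
        assert laplacian_quadratic(S, M) == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_unit_weight(self):
        vocab = EntityVocabulary.from_ids(["a", "b", "c"])
        S = SimilarityMatrix.from_pairs(vocab, [(0, 1, 1.0)])
        M = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        # ½·Σ S_ij ‖M_i − M_j‖² over both ordered pairs = 2
        assert laplacian_quadratic(S, M) == pytest.approx(2.0)

    def test_empty_similarity_gives_zero(self):
        vocab = EntityVocabulary.from_ids(["a", "b"])
        S = SimilarityMatrix.empty(vocab)
        assert laplacian_quadratic(S, np.ones((2, 3))) == 0.0

    def test_shape_mismatch_raises(self):
        vocab = EntityVocabulary.from_ids(["a", "b"])
        S = SimilarityMatrix.empty(vocab)
        with pytest.raises(ShapeError):
            laplacian_quadratic(S, np.ones((3, 2)))

    @pytest.mark.parametrize("seed", range(8))
    def test_psd_and_matches_pairwise_form(self, seed):
        rng = np.random.default_rng(seed)
        n, r = 7, 3
        vocab = EntityVocabulary.from_ids([f"e{i}" for i in range(n)])
        pairs = [
            (i, j, float(rng.random()))
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.5
        ]
        S = SimilarityMatrix.from_pairs(vocab, pairs)
        M = rng.normal(size=(n, r))
        value = laplacian_quadratic(S, M)
        dense = S.matrix.toarray()
        pairwise = 0.5 * sum(
            dense[i, j] * np.sum((M[i] - M[j]) ** 2)
            for i in range(n) for j in range(n)
        )
        assert value == pytest.approx(pairwise, rel=1e-10, abs=1e-12)
        assert value >= -1e-12


class TestTripletFile:
    def test_round_trip(self, tmp_path):
        vocab = EntityVocabulary.from_ids(["a", "b", "c"])
        S = SimilarityMatrix.from_pairs(vocab, [(0, 1, 0.8), (0, 2, 0.55)])
        path = tmp_path / "sim.tsv"
        write_similarity_triplets(S, path)
        loaded = read_similarity_triplets(path, vocab)
        assert (loaded.matrix != S.matrix).nnz == 0
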