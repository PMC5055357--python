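"""Chemical-chemical and protein-protein similarity matrices.

Chemical similarity is 1 minus the Tanimoto dissimilarity on fingerprint bit
sets, with scores below 0.5 treated as noise and set to zero.  Protein
similarity is the BLAST bit-score ratio d_bit(p1,p2)/d_bit(p1,p1),
symmetrized by averaging the two directed ratios.  Both feed the
graph-Laplacian penalty tr(Mᵀ(D−S)M) of the factorization objective, so the
diagonal is stored as zero (it cancels in the quadratic form) and the degree
vector excludes self.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import DataError, ShapeError
from .io import EntityVocabulary, FingerprintSet


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric nonnegative entity-entity similarity with sparse storage.

    ``matrix`` is a CSR matrix with values in [0, 1], zero diagonal and
    exact symmetry; ``degree`` is the per-entity sum of incident
    similarities (the diagonal of D in the Laplacian D − S).
    """

    vocabulary: EntityVocabulary
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.vocabulary)
        if self.matrix.shape != (n, n):
            raise ShapeError(
                f"similarity matrix {self.matrix.shape} does not match vocabulary size {n}"
            )

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def n_entities(self) -> int:
        return len(self.vocabulary)

    def nonzero_pairs(self) -> list[tuple[int, int, float]]:
        """Unordered nonzero pairs (i < j, value)."""
        coo = sp.triu(self.matrix, k=1).tocoo()
        return [(int(i), int(j), float(v)) for i, j, v in zip(coo.row, coo.col, coo.data)]

    @classmethod
    def from_pairs(
        cls, vocabulary: EntityVocabulary, pairs: list[tuple[int, int, float]]
    ) -> "SimilarityMatrix":
        """Build from unordered (i, j, value) pairs; symmetrizes, drops the diagonal."""
        n = len(vocabulary)
        rows, cols, vals = [], [], []
        for i, j, v in pairs:
            if i == j or v == 0.0:
                continue
            if not 0.0 <= v <= 1.0:
                raise DataError(f"similarity {v} for pair ({i}, {j}) outside [0, 1]")
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((v, v))
        mat = sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
        )
        mat.sum_duplicates()
        return cls(vocabulary=vocabulary, matrix=mat)

    @classmethod
    def empty(cls, vocabulary: EntityVocabulary) -> "SimilarityMatrix":
        n = len(vocabulary)
        return cls(vocabulary=vocabulary, matrix=sp.csr_matrix((n, n)))


def tanimoto_similarity(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|a ∩ b| / |a ∪ b| on bit sets; 0 when both are empty."""
    if not a and not b:
        return 0.0
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union


def build_chemical_similarity(
    fps: FingerprintSet, noise_threshold: float = 0.5
) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity with sub-threshold values zeroed as noise.

    A value exactly at the threshold is retained (only scores strictly below
    it are discarded).
    """
    if not 0.0 <= noise_threshold <= 1.0:
        raise ValueError("noise_threshold must lie in [0, 1]")
    n = len(fps.vocabulary)
    pairs = []
    for i in range(n):
        bi = fps.bits[i]
        for j in range(i + 1, n):
            sim = tanimoto_similarity(bi, fps.bits[j])
            if sim >= noise_threshold and sim > 0.0:
                pairs.append((i, j, sim))
    return SimilarityMatrix.from_pairs(fps.vocabulary, pairs)


def build_protein_similarity(
    hits: list[tuple[str, str, float]],
    self_scores: dict[str, float],
    vocabulary: EntityVocabulary | None = None,
) -> SimilarityMatrix:
    """Bit-score-ratio protein similarity, symmetrized over the two directions.

    The directed ratio t(p1, p2) = d_bit(p1, p2) / d_bit(p1, p1) is clipped
    to [0, 1] (a subject longer than the query can push the raw ratio above
    one); the symmetric entry is the mean of the two directed ratios with a
    missing direction contributing 0.
    """
    if vocabulary is None:
        order: dict[str, None] = {}
        for q, s, _ in hits:
            order.setdefault(q)
            order.setdefault(s)
        if not order:
            raise DataError("no hits and no vocabulary supplied")
        vocabulary = EntityVocabulary.from_ids(sorted(order))
    directed: dict[tuple[int, int], float] = {}
    for q, s, score in hits:
        if q not in vocabulary or s not in vocabulary:
            continue
        if q == s:
            continue
        if q not in self_scores:
            raise DataError(f"missing self bit score for protein {q!r}")
        ratio = min(1.0, max(0.0, score / self_scores[q]))
        i, j = vocabulary.index[q], vocabulary.index[s]
        directed[(i, j)] = max(directed.get((i, j), 0.0), ratio)
    pairs = {}
    for (i, j), ratio in directed.items():
        key = (min(i, j), max(i, j))
        pairs[key] = pairs.get(key, 0.0) + ratio / 2.0
    pair_list = [(i, j, min(1.0, v)) for (i, j), v in pairs.items()]
    return SimilarityMatrix.from_pairs(vocabulary, pair_list)


def subsample_similarity(
    S: SimilarityMatrix, keep_fraction: float, seed: int
) -> SimilarityMatrix:
    """Randomly retain each unordered nonzero pair with probability keep_fraction.

    Sampling unordered pairs (not directed entries) preserves symmetry; used
    for similarity-ablation experiments (half-filled / zero-filled matrices).
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = [
        (i, j, v)
        for (i, j, v) in S.nonzero_pairs()
        if rng.random() < keep_fraction
    ]
    return SimilarityMatrix.from_pairs(S.vocabulary, kept)


def laplacian_quadratic(S: SimilarityMatrix, M: np.ndarray) -> float:
    """tr(Mᵀ(D − S)M) = ½ Σ_ij S(i,j)·‖M(i,:) − M(j,:)‖²."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != S.n_entities:
        raise ShapeError(
            f"matrix has {M.shape[0]} rows, vocabulary has {S.n_entities} entities"
        )
    degree_term = float(np.einsum("i,ij,ij->", S.degree, M, M))
    smooth_term = float(np.sum((S.matrix @ M) * M))
    return degree_term - smooth_term


def read_similarity_triplets(
    path, vocabulary: EntityVocabulary | None = None
) -> SimilarityMatrix:
    """Read a precomputed similarity TSV (id_a, id_b, score)."""
    import csv

    from .errors import ParseError

    raw: list[tuple[str, str, float]] = []
    order: dict[str, None] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for line_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].strip() == "id_a":
                continue
            if len(row) < 3:
                raise ParseError(f"line {line_no}: expected 3 columns")
            raw.append((row[0].strip(), row[1].strip(), float(row[2])))
            order.setdefault(row[0].strip())
            order.setdefault(row[1].strip())
    if vocabulary is None:
        if not order:
            raise DataError("empty triplet file and no vocabulary supplied")
        vocabulary = EntityVocabulary.from_ids(sorted(order))
    pairs: dict[tuple[int, int], float] = {}
    for a, b, v in raw:
        if a not in vocabulary or b not in vocabulary:
            continue
        i, j = vocabulary.index[a], vocabulary.index[b]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        pairs[key] = max(pairs.get(key, 0.0), v)
    return SimilarityMatrix.from_pairs(
        vocabulary, [(i, j, v) for (i, j), v in pairs.items()]
    )


def write_similarity_triplets(S: SimilarityMatrix, path) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id_a", "id_b", "score"])
        for i, j, v in S.nonzero_pairs():
            writer.writerow(
                [S.vocabulary.ids[i], S.vocabulary.ids[j], format(v, ".10g")]
            )
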