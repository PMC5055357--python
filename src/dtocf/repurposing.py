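"""Latent-profile drug-drug similarity and Markov clustering.

A drug's row of the fitted factor U is its low-rank target-interaction
profile.  Cosine similarity between profiles captures functional
relatedness even between structurally dissimilar molecules; pairs with
high profile similarity but low structural (Tanimoto) similarity are the
interesting repurposing leads, because the shared behaviour is not
explained by shared scaffolds.  The filtered profile-similarity network is
partitioned with the Markov Cluster algorithm (MCL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import InteractionTable
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class ProfileEdge:
    a: int
    b: int
    cosine: float
    tanimoto: float
    structural_novel: bool


@dataclass
class ProfileNetwork:
    """Drug-drug network filtered on cosine profile similarity."""

    n_nodes: int
    edges: list[ProfileEdge] = field(default_factory=list)

    def adjacency(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for e in self.edges:
            rows.extend((e.a, e.b))
            cols.extend((e.b, e.a))
            vals.extend((e.cosine, e.cosine))
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes))


@dataclass(frozen=True)
class ClusterSet:
    """Disjoint clusters covering all nodes; ``converged`` flags clean MCL exit."""

    clusters: tuple[tuple[int, ...], ...]
    converged: bool = True

    def labels(self) -> np.ndarray:
        n = sum(len(c) for c in self.clusters)
        out = np.empty(n, dtype=np.int64)
        for label, members in enumerate(self.clusters):
            for node in members:
                out[node] = label
        return out


def cosine_profile_similarity(U: np.ndarray, i: int, j: int) -> float | None:
    """Cosine of two latent drug profiles; None when a profile is all-zero.

    Nonnegativity of U keeps the value in [0, 1].
    """
    ui, uj = U[i], U[j]
    norm_i = np.linalg.norm(ui)
    norm_j = np.linalg.norm(uj)
    if norm_i == 0.0 or norm_j == 0.0:
        return None
    return float(min(1.0, np.dot(ui, uj) / (norm_i * norm_j)))


def build_repurposing_network(
    U: np.ndarray,
    C: SimilarityMatrix | None,
    cos_threshold: float = 0.3,
    struct_threshold: float = 0.5,
) -> ProfileNetwork:
    """Keep drug pairs with profile cosine strictly above the threshold.

    Each edge carries the structural Tanimoto similarity and a
    ``structural_novel`` flag marking high-cosine / low-Tanimoto pairs —
    the repurposing-relevant combination.
    """
    if not 0.0 <= cos_threshold <= 1.0 or not 0.0 <= struct_threshold <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    n = U.shape[0]
    norms = np.linalg.norm(U, axis=1)
    network = ProfileNetwork(n_nodes=n)
    # normalized profiles once; all-zero rows never form edges
    safe = norms > 0
    G = np.zeros_like(U)
    G[safe] = U[safe] / norms[safe, None]
    cos = G @ G.T
    C_dense = C.matrix if C is not None else None
    for i in range(n):
        if not safe[i]:
            continue
        for j in range(i + 1, n):
            if not safe[j]:
                continue
            value = float(min(1.0, cos[i, j]))
            if value <= cos_threshold:
                continue
            tc = float(C_dense[i, j]) if C_dense is not None else 0.0
            network.edges.append(
                ProfileEdge(
                    a=i,
                    b=j,
                    cosine=value,
                    tanimoto=tc,
                    structural_novel=tc < struct_threshold,
                )
            )
    return network


def mcl_cluster(
    network: ProfileNetwork,
    expansion: int = 2,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
) -> ClusterSet:
    """Markov clustering on the cosine-weighted network.

    Standard MCL: add unit self-loops, column-normalize, then alternate
    expansion (matrix power) and inflation (entrywise power followed by
    column renormalization), pruning entries below the threshold, until the
    matrix is stable.  Attractors (nodes with nonzero diagonal) define the
    clusters; a node covered by several attractor rows joins the cluster of
    its lowest-index attractor.
    """
    if network.n_nodes == 0:
        raise ValueError("network has no nodes")
    if expansion < 2 or inflation <= 1.0:
        raise ValueError("expansion must be >= 2 and inflation > 1")
    n = network.n_nodes
    M = network.adjacency().tolil()
    M.setdiag(1.0)
    M = M.tocsc()
    M = _normalize_columns(M)
    converged = False
    for _ in range(max_iter):
        previous = M.copy()
        expanded = M
        for _ in range(expansion - 1):
            expanded = expanded @ M
        inflated = expanded.power(inflation)
        inflated.data[inflated.data < prune_threshold] = 0.0
        inflated.eliminate_zeros()
        M = _normalize_columns(inflated)
        diff = abs(M - previous)
        if diff.nnz == 0 or diff.max() < 1e-9:
            converged = True
            break
    M = M.tocsr()
    assignment = np.full(n, -1, dtype=np.int64)
    attractors = [i for i in range(n) if M[i, i] > prune_threshold]
    for attractor in attractors:
        row = M.getrow(attractor)
        for j in row.indices:
            if assignment[j] == -1:
                assignment[j] = attractor
            else:
                assignment[j] = min(assignment[j], attractor)
    # resolve attractor chains: an attractor itself may be claimed by a
    # lower-index attractor of the same attractor system
    for node in range(n):
        label = assignment[node]
        while label != -1 and assignment[label] != label:
            label = assignment[label]
        if label != -1:
            assignment[node] = label
    clusters: dict[int, list[int]] = {}
    for node in range(n):
        label = assignment[node] if assignment[node] != -1 else node
        clusters.setdefault(label, []).append(node)
    ordered = tuple(
        tuple(sorted(members)) for _, members in sorted(clusters.items())
    )
    return ClusterSet(clusters=ordered, converged=converged)


def _normalize_columns(M: sp.spmatrix) -> sp.csc_matrix:
    M = sp.csc_matrix(M)
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    scale = sp.diags(1.0 / sums)
    return sp.csc_matrix(M @ scale)


def shared_target_fraction(
    pairs: list[tuple[int, int]], table: InteractionTable
) -> float | None:
    """Fraction of drug pairs sharing at least one known active target."""
    if not pairs:
        return None
    by_chem = table.positives_by_chemical()
    shared = sum(
        1
        for (a, b) in pairs
        if by_chem.get(a, set()) & by_chem.get(b, set())
    )
    return shared / len(pairs)
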