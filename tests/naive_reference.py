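"""Independent dense reference implementations used as oracles.

Everything here is written the slow, obvious way — explicit dense weight
and target matrices, double loops, full matrix products — precisely so it
shares no code path with the package's sparse/decomposed implementations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def dense_weight_target(table, cfg):
    """Explicit n x m weight and target matrices of the one-class scheme."""
    n, m = table.n_chemicals, table.n_proteins
    W = np.full((n, m), cfg.p_wt, dtype=float)
    R = np.full((n, m), cfg.p_imp, dtype=float)
    for (i, j) in table.observed_positive_set:
        W[i, j] = 1.0
        R[i, j] = 1.0
    if cfg.weight_overrides is not None:
        ov = sp.coo_matrix(cfg.weight_overrides)
        for i, j, w in zip(ov.row, ov.col, ov.data):
            W[i, j] = w
    if cfg.target_overrides is not None:
        ov = sp.coo_matrix(cfg.target_overrides)
        for i, j, t in zip(ov.row, ov.col, ov.data):
            R[i, j] = t
    return W, R


def _dense_similarity(S, n):
    if S is None:
        return np.zeros((n, n))
    return S.matrix.toarray()


def naive_objective(table, model, C, T, cfg):
    """Double-loop evaluation of the regularized weighted loss."""
    U, V = model.U, model.V
    n, m = table.n_chemicals, table.n_proteins
    W, R = dense_weight_target(table, cfg)
    total = 0.0
    for i in range(n):
        for j in range(m):
            pred = float(U[i] @ V[j])
            total += W[i, j] * (R[i, j] - pred) ** 2
    total += cfg.p_reg * (np.sum(U**2) + np.sum(V**2))
    for S, M, coeff in ((C, U, cfg.p_chem), (T, V, cfg.p_prot)):
        if S is None or coeff == 0:
            continue
        Sd = _dense_similarity(S, M.shape[0])
        acc = 0.0
        for i in range(M.shape[0]):
            for j in range(M.shape[0]):
                acc += Sd[i, j] * np.sum((M[i] - M[j]) ** 2)
        total += coeff * acc / 2.0
    return total


def naive_update_step(model, table, C, T, cfg):
    """One multiplicative round with fully dense W, R̃ and similarities.

    Mirrors the contract of the package's update: U first with the old V,
    then V with the updated U.
    """
    U, V = model.U.copy(), model.V.copy()
    n, m = table.n_chemicals, table.n_proteins
    W, R = dense_weight_target(table, cfg)
    Cd = _dense_similarity(C, n)
    Td = _dense_similarity(T, m)
    DC = np.diag(Cd.sum(axis=1))
    DT = np.diag(Td.sum(axis=1))

    num = (W * R) @ V + cfg.p_chem * (Cd @ U)
    den = (W * (U @ V.T)) @ V + cfg.p_reg * U + cfg.p_chem * (DC @ U) + cfg.epsilon
    U_new = U * num / den

    num_v = (W * R).T @ U_new + cfg.p_prot * (Td @ V)
    den_v = (
        (W * (U_new @ V.T)).T @ U_new
        + cfg.p_reg * V
        + cfg.p_prot * (DT @ V)
        + cfg.epsilon
    )
    V_new = V * num_v / den_v
    return U_new, V_new


def naive_mcl(adjacency: np.ndarray, inflation: float = 2.0, max_iter: int = 200):
    """Plain dense Markov clustering, no pruning; returns frozenset partition."""
    M = adjacency.astype(float).copy()
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        previous = M.copy()
        M = M @ M
        M = M**inflation
        sums = M.sum(axis=0, keepdims=True)
        sums[sums == 0] = 1.0
        M /= sums
        if np.abs(M - previous).max() < 1e-12:
            break
    n = M.shape[0]
    assignment = {}
    attractors = [i for i in range(n) if M[i, i] > 1e-8]
    for a in attractors:
        for j in range(n):
            if M[a, j] > 1e-8:
                assignment[j] = min(assignment.get(j, a), a)
    for node in range(n):
        label = assignment.get(node, node)
        while assignment.get(label, label) != label:
            label = assignment[label]
        assignment[node] = label
    clusters: dict[int, set[int]] = {}
    for node in range(n):
        clusters.setdefault(assignment[node], set()).add(node)
    return frozenset(frozenset(c) for c in clusters.values())
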