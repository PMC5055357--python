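"""Dual-regularized one-class weighted matrix factorization.

The model approximates the sparse chemical-protein association matrix R
(n chemicals × m proteins, positives only) by a product of nonnegative
low-rank factors U (n×r) and V (m×r).  Observed positives enter the loss
with weight 1 and target 1; every unobserved pair enters with a small
weight p_wt and an imputed target p_imp — the one-class treatment of
implicit feedback, where absence of a record is weak evidence against an
interaction, never a hard negative.  Two graph-Laplacian penalties pull the
latent rows of structurally similar chemicals (matrix C) and of
sequence-similar proteins (matrix T) together:

    min_{U,V ≥ 0}  Σ_ij W_ij (R̃_ij − U_i·V_j)²
                   + p_reg (‖U‖²_F + ‖V‖²_F)
                   + p_chem tr(Uᵀ(D_C − C)U) + p_prot tr(Vᵀ(D_T − T)V)

The solver is block multiplicative updates in the graph-regularized NMF
style; with the global weight scheme every quantity is computed from the
sparse observed set and r-dimensional Gram matrices, so no dense n×m array
is ever materialized and a genome-scale matrix (tens of thousands of
chemicals, thousands of proteins) fits in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .errors import ShapeError
from .io import InteractionTable
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class OccfConfig:
    """Hyper-parameters of the one-class factorization.

    Defaults are the benchmark setting: p_wt = p_imp = p_reg = 0.1,
    p_chem = 0.75, p_prot = 0.1, rank 300, 400 iterations (a documented
    alternative sets p_chem = p_prot = 0.25).  ``weight_overrides`` and
    ``target_overrides`` are optional sparse matrices whose stored entries
    replace the per-entry weight / imputed target of the global scheme,
    letting prior knowledge enter pair by pair.
    """

    p_wt: float = 0.1
    p_imp: float = 0.1
    p_reg: float = 0.1
    p_chem: float = 0.75
    p_prot: float = 0.1
    r: int = 300
    p_iter: int = 400
    seed: int = 0
    epsilon: float = 1e-12
    tol: float | None = None
    weight_overrides: sp.spmatrix | None = field(default=None, compare=False)
    target_overrides: sp.spmatrix | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_wt <= 1.0 or not 0.0 <= self.p_imp <= 1.0:
            raise ValueError("p_wt and p_imp must lie in [0, 1]")
        if min(self.p_reg, self.p_chem, self.p_prot) < 0:
            raise ValueError("regularization coefficients must be nonnegative")
        if self.r < 1 or self.p_iter < 0:
            raise ValueError("rank must be >= 1 and p_iter >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def with_(self, **kwargs) -> "OccfConfig":
        return replace(self, **kwargs)


@dataclass
class FactorModel:
    """Nonnegative factors U (the per-drug low-rank profiles) and V."""

    U: np.ndarray
    V: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.U.shape[1]


class WeightTargetScheme:
    """Effective per-entry weights and regression targets.

    Global base: weight p_wt and target p_imp for every pair; observed
    positives get weight 1 and target 1; sparse overrides, when given,
    replace the value at their stored entries.  Internally the scheme is
    held as two sparse correction matrices over the union support S of the
    observed positives and the overrides:

        A_ij = w_ij t_ij − p_wt p_imp      (numerator correction)
        entries (i, j, w_ij, t_ij)          (for loss / denominator terms)

    so that e.g. (W∘R̃)V = p_wt p_imp 1(1ᵀV) + A V without any dense n×m
    intermediate.
    """

    def __init__(self, table: InteractionTable, cfg: OccfConfig):
        self.n = table.n_chemicals
        self.m = table.n_proteins
        self.p_wt = cfg.p_wt
        self.p_imp = cfg.p_imp
        entries: dict[tuple[int, int], list[float]] = {
            (i, j): [1.0, 1.0] for (i, j) in table.observed_positive_set
        }
        if cfg.weight_overrides is not None:
            ov = sp.coo_matrix(cfg.weight_overrides)
            if ov.shape != (self.n, self.m):
                raise ShapeError("weight_overrides shape mismatch")
            for i, j, w in zip(ov.row, ov.col, ov.data):
                key = (int(i), int(j))
                entries.setdefault(key, [cfg.p_wt, cfg.p_imp])[0] = float(w)
        if cfg.target_overrides is not None:
            ov = sp.coo_matrix(cfg.target_overrides)
            if ov.shape != (self.n, self.m):
                raise ShapeError("target_overrides shape mismatch")
            for i, j, t in zip(ov.row, ov.col, ov.data):
                key = (int(i), int(j))
                entries.setdefault(key, [cfg.p_wt, cfg.p_imp])[1] = float(t)
        keys = sorted(entries)
        self.rows = np.asarray([k[0] for k in keys], dtype=np.int64)
        self.cols = np.asarray([k[1] for k in keys], dtype=np.int64)
        self.w = np.asarray([entries[k][0] for k in keys], dtype=float)
        self.t = np.asarray([entries[k][1] for k in keys], dtype=float)
        self._A = sp.csr_matrix(
            (self.w * self.t - self.p_wt * self.p_imp, (self.rows, self.cols)),
            shape=(self.n, self.m),
        )

    def weight(self, i: int, j: int) -> float:
        """Dense-equivalent weight of a single entry (reference accessor)."""
        mask = (self.rows == i) & (self.cols == j)
        return float(self.w[mask][0]) if mask.any() else self.p_wt

    def target(self, i: int, j: int) -> float:
        mask = (self.rows == i) & (self.cols == j)
        return float(self.t[mask][0]) if mask.any() else self.p_imp

    def support_predictions(self, U: np.ndarray, V: np.ndarray) -> np.ndarray:
        """U_i·V_j evaluated only on the support entries."""
        return np.einsum("ij,ij->i", U[self.rows], V[self.cols])

    def weighted_target_matmul(self, V: np.ndarray, colsum_V: np.ndarray) -> np.ndarray:
        """(W∘R̃) V, decomposed as rank-1 base plus sparse correction."""
        base = self.p_wt * self.p_imp * colsum_V
        return base[None, :] + self._A @ V

    def weighted_target_rmatmul(self, U: np.ndarray, colsum_U: np.ndarray) -> np.ndarray:
        """(W∘R̃)ᵀ U."""
        base = self.p_wt * self.p_imp * colsum_U
        return base[None, :] + self._A.T @ U

    def correction_matrix(self, p_support: np.ndarray) -> sp.csr_matrix:
        """Sparse B with B_ij = (w_ij − p_wt)·(U_i·V_j) on the support."""
        return sp.csr_matrix(
            ((self.w - self.p_wt) * p_support, (self.rows, self.cols)),
            shape=(self.n, self.m),
        )


def _laplacian_terms(S: SimilarityMatrix | None, n: int):
    if S is None:
        return None, None
    if S.n_entities != n:
        raise ShapeError("similarity matrix does not match interaction table")
    return S.matrix, S.degree


def objective_value(
    table: InteractionTable,
    model: FactorModel,
    C: SimilarityMatrix | None,
    T: SimilarityMatrix | None,
    cfg: OccfConfig,
) -> float:
    """Evaluate the regularized one-class loss without dense intermediates.

    The weighted residual splits into a closed-form global part —
    p_wt (nm p_imp² − 2 p_imp Σ P + Σ P²) with Σ P = (1ᵀU)(1ᵀV)ᵀ and
    Σ P² = tr((UᵀU)(VᵀV)) — plus a correction evaluated only on the sparse
    support where the weight or target differs from the base.
    """
    U, V = model.U, model.V
    n, m = table.n_chemicals, table.n_proteins
    if U.shape[0] != n or V.shape[0] != m or U.shape[1] != V.shape[1]:
        raise ShapeError(
            f"factors {U.shape} x {V.shape} inconsistent with table {n} x {m}"
        )
    scheme = WeightTargetScheme(table, cfg)
    sum_p = float(U.sum(axis=0) @ V.sum(axis=0))
    sum_p2 = float(np.sum((U.T @ U) * (V.T @ V)))
    base = cfg.p_wt * (n * m * cfg.p_imp**2 - 2.0 * cfg.p_imp * sum_p + sum_p2)
    p_support = scheme.support_predictions(U, V)
    correction = float(
        np.sum(
            scheme.w * (scheme.t - p_support) ** 2
            - cfg.p_wt * (cfg.p_imp - p_support) ** 2
        )
    )
    total = base + correction
    total += cfg.p_reg * (float(np.sum(U * U)) + float(np.sum(V * V)))
    if C is not None and cfg.p_chem > 0:
        from .similarity import laplacian_quadratic

        total += cfg.p_chem * laplacian_quadratic(C, U)
    if T is not None and cfg.p_prot > 0:
        from .similarity import laplacian_quadratic

        total += cfg.p_prot * laplacian_quadratic(T, V)
    return total


def initialize_factors(n: int, m: int, cfg: OccfConfig) -> FactorModel:
    """Seeded i.i.d. uniform initialization on (0, 1/sqrt(r)]."""
    if n < 1 or m < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    scale = 1.0 / np.sqrt(cfg.r)
    # 1 - random() lies in (0, 1]; keeps every entry strictly positive
    U = (1.0 - rng.random((n, cfg.r))) * scale
    V = (1.0 - rng.random((m, cfg.r))) * scale
    return FactorModel(U=U, V=V, objective_trace=[])


def update_step(
    model: FactorModel,
    table: InteractionTable,
    C: SimilarityMatrix | None,
    T: SimilarityMatrix | None,
    cfg: OccfConfig,
    scheme: WeightTargetScheme | None = None,
) -> FactorModel:
    """One round of multiplicative updates: U with the old V, then V with the new U.

    U ← U ∘ [(W∘R̃)V + p_chem C U] ⊘ [(W∘(UVᵀ))V + p_reg U + p_chem D_C U + ε]
    and symmetrically for V.  With the global scheme, (W∘(UVᵀ))V is
    decomposed as p_wt U(VᵀV) + B V where B is sparse on the support, and
    (W∘R̃)V as a rank-1 base plus sparse correction, so nonnegativity is
    preserved and no dense n×m product is formed.
    """
    if scheme is None:
        scheme = WeightTargetScheme(table, cfg)
    U, V = model.U, model.V
    C_mat, C_deg = _laplacian_terms(C, table.n_chemicals)
    T_mat, T_deg = _laplacian_terms(T, table.n_proteins)

    # -- U half-step
    num = scheme.weighted_target_matmul(V, V.sum(axis=0))
    if C_mat is not None and cfg.p_chem > 0:
        num = num + cfg.p_chem * (C_mat @ U)
    B = scheme.correction_matrix(scheme.support_predictions(U, V))
    den = cfg.p_wt * (U @ (V.T @ V)) + B @ V + cfg.p_reg * U
    if C_deg is not None and cfg.p_chem > 0:
        den = den + cfg.p_chem * C_deg[:, None] * U
    U_new = U * num / (den + cfg.epsilon)

    # -- V half-step (uses the updated U)
    num_v = scheme.weighted_target_rmatmul(U_new, U_new.sum(axis=0))
    if T_mat is not None and cfg.p_prot > 0:
        num_v = num_v + cfg.p_prot * (T_mat @ V)
    B = scheme.correction_matrix(scheme.support_predictions(U_new, V))
    den_v = cfg.p_wt * (V @ (U_new.T @ U_new)) + B.T @ U_new + cfg.p_reg * V
    if T_deg is not None and cfg.p_prot > 0:
        den_v = den_v + cfg.p_prot * T_deg[:, None] * V
    V_new = V * num_v / (den_v + cfg.epsilon)

    return FactorModel(U=U_new, V=V_new, objective_trace=list(model.objective_trace))


def fit(
    table: InteractionTable,
    C: SimilarityMatrix | None,
    T: SimilarityMatrix | None,
    cfg: OccfConfig,
    record_objective: bool = True,
) -> FactorModel:
    """Run the full optimization: seeded init, then p_iter multiplicative rounds.

    ``objective_trace`` holds the loss at initialization and after every
    round.  The iteration budget is fixed; an explicit ``tol`` stops early
    once the relative objective decrease falls below it.
    """
    n, m = table.n_chemicals, table.n_proteins
    if cfg.r > min(n, m):
        warnings.warn(
            f"rank {cfg.r} exceeds min(n, m) = {min(n, m)}; model is over-parameterized",
            stacklevel=2,
        )
    model = initialize_factors(n, m, cfg)
    scheme = WeightTargetScheme(table, cfg)
    if record_objective:
        model.objective_trace.append(objective_value(table, model, C, T, cfg))
    for _ in range(cfg.p_iter):
        model = update_step(model, table, C, T, cfg, scheme=scheme)
        if record_objective:
            model.objective_trace.append(objective_value(table, model, C, T, cfg))
            if cfg.tol is not None and len(model.objective_trace) >= 2:
                prev, cur = model.objective_trace[-2], model.objective_trace[-1]
                if prev > 0 and (prev - cur) / prev < cfg.tol:
                    break
    return model


def predict_scores(model: FactorModel, chemical_index: int) -> np.ndarray:
    """Raw predicted scores P(i, :) = U(i, :) Vᵀ for one chemical."""
    if not 0 <= chemical_index < model.U.shape[0]:
        raise IndexError(f"chemical index {chemical_index} out of range")
    return model.U[chemical_index] @ model.V.T


def predict_top_k(
    model: FactorModel,
    chemical_index: int,
    k: int,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> list[tuple[int, float, int]]:
    """Top-k proteins by descending raw score as (protein index, score, rank).

    Training positives are excluded from the candidate list; ties break by
    ascending protein index for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = predict_scores(model, chemical_index)
    candidates = [j for j in range(scores.shape[0]) if j not in exclude]
    candidates.sort(key=lambda j: (-scores[j], j))
    return [(j, float(scores[j]), rank) for rank, j in enumerate(candidates[:k], start=1)]


def rank_of_protein(
    model: FactorModel,
    chemical_index: int,
    protein_index: int,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> tuple[int, int]:
    """Rank of one candidate protein (1-based) and the candidate-panel size.

    Uses the same descending-score, index-ascending tie order as
    :func:`predict_top_k` without materializing the full sorted list.
    """
    scores = predict_scores(model, chemical_index)
    if protein_index in exclude:
        raise ValueError("protein to rank is excluded from the candidate panel")
    target = scores[protein_index]
    better = 0
    n_candidates = 0
    for j in range(scores.shape[0]):
        if j in exclude:
            continue
        n_candidates += 1
        if scores[j] > target or (scores[j] == target and j < protein_index):
            better += 1
    return better + 1, n_candidates
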