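"""Cross-validated benchmark: fold plans, stratification, TPR-at-rank.

Model quality is summarized as the true positive rate at a cutoff rank —
the fraction of held-out chemical-protein positives that the model ranks
within the top k candidates for their chemical (top 1% of a 3,500-protein
panel is rank 35).  Because one-class data has no trustworthy negatives,
no ROC/AUC is computed.  Held-out pairs are stratified by

* NT class — the chemical's total known targets (1, 2, or >= 3); NT1 pairs
  are the cold-start regime, since hiding the only association leaves the
  chemical with no training signal;
* L bucket — how many training ligands the test protein has (1-5, 6-10,
  11-15, 16-20, >= 21);
* Tc bucket — the chemical's maximum structural similarity to any trained
  chemical, in 0.1-wide intervals (d − 0.1, d], lowest bucket closed at 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .factorization import OccfConfig, fit, rank_of_protein
from .io import ACTIVE, InteractionTable
from .similarity import SimilarityMatrix

L_BUCKETS = ("L0", "L1to5", "L6to10", "L11to15", "L16to20", "L21more")
TC_BUCKETS = (
    "TcNone",
    "Tc0.5to0.6",
    "Tc0.6to0.7",
    "Tc0.7to0.8",
    "Tc0.8to0.9",
    "Tc0.9to1.0",
)


@dataclass(frozen=True)
class CvFoldPlan:
    """Seeded partition of the observed positives into k near-equal folds."""

    folds: tuple[frozenset[tuple[int, int]], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class BenchmarkCategory:
    nt_class: str
    l_bucket: str | None = None
    tc_bucket: str | None = None

    def labels(self) -> list[str]:
        out = []
        if self.l_bucket is not None:
            out.append(f"{self.nt_class}{self.l_bucket}")
        if self.tc_bucket is not None:
            out.append(f"{self.nt_class}{self.tc_bucket}")
        return out


@dataclass
class BenchmarkReport:
    """Per-category TPR at each cutoff rank, with per-fold raw values."""

    cutoffs: tuple[int, ...]
    #: category label -> cutoff -> list of per-fold TPR values
    per_fold: dict[str, dict[int, list[float]]] = field(default_factory=dict)
    #: category label -> number of held-out pairs seen over all folds
    category_counts: dict[str, int] = field(default_factory=dict)

    def record(self, label: str, cutoff: int, fold_tpr: float) -> None:
        self.per_fold.setdefault(label, {}).setdefault(cutoff, []).append(fold_tpr)

    def mean_tpr(self, label: str, cutoff: int) -> float:
        return float(np.mean(self.per_fold[label][cutoff]))

    def sem_tpr(self, label: str, cutoff: int) -> float:
        vals = self.per_fold[label][cutoff]
        if len(vals) < 2:
            return 0.0
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    def categories(self) -> list[str]:
        return sorted(self.per_fold)


def make_folds(table: InteractionTable, k: int = 10, seed: int = 0) -> CvFoldPlan:
    """Uniform random partition of the positive pairs into k folds (sizes ±1)."""
    positives = sorted(table.observed_positive_set)
    if len(positives) < k:
        raise ConfigurationError(
            f"{len(positives)} positive pairs cannot fill {k} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds: list[set[tuple[int, int]]] = [set() for _ in range(k)]
    for slot, idx in enumerate(order):
        folds[slot % k].add(positives[idx])
    return CvFoldPlan(folds=tuple(frozenset(f) for f in folds), seed=seed)


def training_table(table: InteractionTable, heldout: frozenset[tuple[int, int]]) -> InteractionTable:
    """Copy of the table with the held-out positives removed."""
    records = tuple(
        (c, p, label)
        for (c, p, label) in table.records
        if not (
            label == ACTIVE
            and (table.chemicals.index[c], table.proteins.index[p]) in heldout
        )
    )
    return InteractionTable(
        chemicals=table.chemicals,
        proteins=table.proteins,
        records=records,
        observed_positive_set=table.observed_positive_set - heldout,
    )


def categorize(
    test_pair: tuple[int, int],
    training: InteractionTable,
    C: SimilarityMatrix | None,
) -> BenchmarkCategory:
    """Assign a held-out pair to its NT class, L bucket and Tc bucket.

    The NT class counts the chemical's remaining training positives plus
    the hidden pair itself; the L bucket counts the protein's training
    ligands; the Tc bucket takes the chemical's maximum similarity to any
    trained chemical (one with at least one training positive).  Chemicals
    with no similar trained neighbour fall in the TcNone stratum, proteins
    with no training ligand in L0.
    """
    i, j = test_pair
    by_chem = training.positives_by_chemical()
    n_targets = len(by_chem.get(i, ())) + 1
    nt_class = "NT1" if n_targets == 1 else ("NT2" if n_targets == 2 else "NT3")

    n_ligands = sum(1 for (ci, pj) in training.observed_positive_set if pj == j)
    if n_ligands == 0:
        l_bucket = "L0"
    elif n_ligands <= 5:
        l_bucket = "L1to5"
    elif n_ligands <= 10:
        l_bucket = "L6to10"
    elif n_ligands <= 15:
        l_bucket = "L11to15"
    elif n_ligands <= 20:
        l_bucket = "L16to20"
    else:
        l_bucket = "L21more"

    tc_bucket = "TcNone"
    if C is not None:
        trained = [c for c in by_chem if c != i]
        if trained:
            row = C.matrix.getrow(i).toarray().ravel()
            max_sim = float(row[trained].max()) if trained else 0.0
            if max_sim >= 0.5:
                if max_sim <= 0.6:
                    tc_bucket = "Tc0.5to0.6"
                elif max_sim <= 0.7:
                    tc_bucket = "Tc0.6to0.7"
                elif max_sim <= 0.8:
                    tc_bucket = "Tc0.7to0.8"
                elif max_sim <= 0.9:
                    tc_bucket = "Tc0.8to0.9"
                else:
                    tc_bucket = "Tc0.9to1.0"
    return BenchmarkCategory(nt_class=nt_class, l_bucket=l_bucket, tc_bucket=tc_bucket)


def top_percent_cutoff(candidate_count: int, fraction: float) -> int:
    """floor(fraction · candidates), minimum 1 (3,500 candidates at 1% -> 35)."""
    if candidate_count < 1:
        raise ValueError("candidate_count must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, math.floor(fraction * candidate_count))


def tpr_at_cutoff(ranks: list[int], cutoff: int) -> float | None:
    """Fraction of held-out positives ranked at or above the cutoff."""
    if not ranks:
        return None
    return sum(1 for r in ranks if r <= cutoff) / len(ranks)


def run_benchmark(
    table: InteractionTable,
    C: SimilarityMatrix | None,
    T: SimilarityMatrix | None,
    cfg: OccfConfig,
    folds: CvFoldPlan,
    top_fraction: float = 0.01,
) -> BenchmarkReport:
    """Full cross-validated benchmark.

    For each fold: refit on the remaining positives, rank every held-out
    pair against the chemical's non-training-positive candidate panel,
    stratify, and record TPR per category at every cutoff rank from 1 up to
    the top-fraction rank.  Reports mean and s.e.m. over folds; per-fold
    values are kept so method comparisons can run a paired t-test.
    """
    max_cutoff = top_percent_cutoff(table.n_proteins, top_fraction)
    cutoffs = tuple(range(1, max_cutoff + 1))
    report = BenchmarkReport(cutoffs=cutoffs)
    for fold in folds.folds:
        training = training_table(table, fold)
        model = fit(training, C, T, cfg, record_objective=False)
        train_by_chem = training.positives_by_chemical()
        fold_ranks: dict[str, list[int]] = {}
        for (i, j) in sorted(fold):
            exclude = frozenset(train_by_chem.get(i, set()))
            rank, _ = rank_of_protein(model, i, j, exclude=exclude)
            category = categorize((i, j), training, C)
            for label in category.labels() + ["ALL"]:
                fold_ranks.setdefault(label, []).append(rank)
        for label, ranks in fold_ranks.items():
            report.category_counts[label] = report.category_counts.get(label, 0) + len(ranks)
            for cutoff in cutoffs:
                report.record(label, cutoff, tpr_at_cutoff(ranks, cutoff))
    return report


def compare_reports(
    a: BenchmarkReport, b: BenchmarkReport, label: str, cutoff: int
) -> tuple[float, float]:
    """Paired t-test on per-fold TPRs of two methods; returns (t, p)."""
    xs = a.per_fold[label][cutoff]
    ys = b.per_fold[label][cutoff]
    if len(xs) != len(ys):
        raise ConfigurationError("reports have different fold counts")
    t, p = stats.ttest_rel(xs, ys)
    return float(t), float(p)
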