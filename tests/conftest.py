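import sys
from pathlib import Path

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dtocf import (
    EntityVocabulary,
    InteractionTable,
    OccfConfig,
    SimilarityMatrix,
    SyntheticSpec,
    generate,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the default planted-block specification."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture
def small_cfg():
    return OccfConfig(p_chem=0.3, p_prot=0.3, r=2, p_iter=5, seed=7)


def random_instance(rng, n=6, m=5, r=2, with_overrides=False, with_similarity=True):
    """A random small problem: table, C, T, config, initialized model."""
    from dtocf import FactorModel

    n_pos = int(rng.integers(1, n * m // 2 + 1))
    flat = rng.choice(n * m, size=n_pos, replace=False)
    positives = {(int(f) // m, int(f) % m) for f in flat}
    chems = EntityVocabulary.from_ids([f"c{i}" for i in range(n)])
    prots = EntityVocabulary.from_ids([f"p{j}" for j in range(m)])
    records = tuple((chems.ids[i], prots.ids[j], "active") for (i, j) in sorted(positives))
    table = InteractionTable(
        chemicals=chems, proteins=prots, records=records,
        observed_positive_set=frozenset(positives),
    )
    C = T = None
    if with_similarity:
        C = SimilarityMatrix.from_pairs(
            chems,
            [(i, j, float(rng.random()))
             for i in range(n) for j in range(i + 1, n) if rng.random() < 0.5],
        )
        T = SimilarityMatrix.from_pairs(
            prots,
            [(i, j, float(rng.random()))
             for i in range(m) for j in range(i + 1, m) if rng.random() < 0.5],
        )
    kwargs = dict(
        p_wt=float(rng.uniform(0.05, 0.9)),
        p_imp=float(rng.uniform(0.0, 0.9)),
        p_reg=float(rng.uniform(0.0, 0.5)),
        p_chem=float(rng.uniform(0.0, 1.0)) if with_similarity else 0.0,
        p_prot=float(rng.uniform(0.0, 1.0)) if with_similarity else 0.0,
        r=r, p_iter=1, seed=int(rng.integers(0, 2**16)),
    )
    if with_overrides:
        def sparse_override(low, high):
            rows, cols, vals = [], [], []
            for _ in range(int(rng.integers(1, 6))):
                rows.append(int(rng.integers(0, n)))
                cols.append(int(rng.integers(0, m)))
                vals.append(float(rng.uniform(low, high)))
            mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, m))
            mat.sum_duplicates()
            return mat
        kwargs["weight_overrides"] = sparse_override(0.01, 1.0)
        kwargs["target_overrides"] = sparse_override(0.0, 1.0)
    cfg = OccfConfig(**kwargs)
    U = rng.uniform(0.01, 1.0, size=(n, r))
    V = rng.uniform(0.01, 1.0, size=(m, r))
    model = FactorModel(U=U, V=V)
    return table, C, T, cfg, model
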