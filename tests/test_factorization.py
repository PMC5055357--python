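import numpy as np
import pytest

from conftest import random_instance
from naive_reference import naive_objective, naive_update_step

from dtocf import (
    EntityVocabulary,
    FactorModel,
    InteractionTable,
    OccfConfig,
    fit,
    initialize_factors,
    objective_value,
    predict_scores,
    predict_top_k,
    rank_of_protein,
    update_step,
)
from dtocf.errors import ShapeError


def table_from_positives(n, m, positives):
    chems = EntityVocabulary.from_ids([f"c{i}" for i in range(n)])
    prots = EntityVocabulary.from_ids([f"p{j}" for j in range(m)])
    records = tuple(
        (chems.ids[i], prots.ids[j], "active") for (i, j) in sorted(positives)
    )
    return InteractionTable(
        chemicals=chems, proteins=prots, records=records,
        observed_positive_set=frozenset(positives),
    )


class TestObjective:
    def test_zero_factors_no_positives(self):
        table = table_from_positives(2, 2, set())
        model = FactorModel(U=np.zeros((2, 1)), V=np.zeros((2, 1)))
        cfg = OccfConfig(p_wt=0.1, p_imp=0.1, p_reg=0.0, p_chem=0.0, p_prot=0.0, r=1)
        # 4 entries, each weight 0.1 and residual 0.1: 4·0.1·0.01
        assert objective_value(table, model, None, None, cfg) == pytest.approx(0.004)

    def test_single_positive_hand_computed(self):
        table = table_from_positives(2, 2, {(0, 0)})
        model = FactorModel(
            U=np.array([[1.0], [0.0]]), V=np.array([[1.0], [0.0]])
        )
        cfg = OccfConfig(p_wt=0.1, p_imp=0.1, p_reg=0.1, p_chem=0.0, p_prot=0.0, r=1)
        # observed (0,0): residual 0; three unobserved: 0.1·0.01 each = 0.003;
        # regularization: 0.1·(1 + 1) = 0.2
        assert objective_value(table, model, None, None, cfg) == pytest.approx(0.203)

    def test_identical_rows_kill_chemical_laplacian_term(self):
        from dtocf import SimilarityMatrix

        table = table_from_positives(3, 2, {(0, 0)})
        vocab = table.chemicals
        C = SimilarityMatrix.from_pairs(
            vocab, [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)]
        )
        U = np.tile([0.4, 0.2], (3, 1))
        V = np.random.default_rng(0).uniform(size=(2, 2))
        model = FactorModel(U=U, V=V)
        base_cfg = OccfConfig(p_chem=0.0, p_prot=0.0, r=2)
        reg_cfg = base_cfg.with_(p_chem=5.0)
        assert objective_value(table, model, C, None, reg_cfg) == pytest.approx(
            objective_value(table, model, C, None, base_cfg)
        )

    def test_shape_mismatch_raises(self):
        table = table_from_positives(2, 2, set())
        model = FactorModel(U=np.zeros((3, 1)), V=np.zeros((2, 1)))
        with pytest.raises(ShapeError):
            objective_value(table, model, None, None, OccfConfig(r=1))


class TestOracleEquivalence:
    @pytest.mark.parametrize("with_overrides", [False, True])
    def test_objective_and_update_match_naive_dense(self, with_overrides):
        """The sparse/decomposed path equals explicit dense W, R̃ algebra."""
        rng = np.random.default_rng(42 + with_overrides)
        for _ in range(30):
            table, C, T, cfg, model = random_instance(
                rng,
                n=int(rng.integers(2, 11)),
                m=int(rng.integers(2, 9)),
                r=int(rng.integers(1, 4)),
                with_overrides=with_overrides,
            )
            ours = objective_value(table, model, C, T, cfg)
            naive = naive_objective(table, model, C, T, cfg)
            assert ours == pytest.approx(naive, rel=1e-10)
            stepped = update_step(model, table, C, T, cfg)
            U_ref, V_ref = naive_update_step(model, table, C, T, cfg)
            assert np.abs(stepped.U - U_ref).max() < 1e-10
            assert np.abs(stepped.V - V_ref).max() < 1e-10

    def test_update_preserves_nonnegativity(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            table, C, T, cfg, model = random_instance(rng)
            stepped = update_step(model, table, C, T, cfg)
            assert stepped.U.min() >= 0.0
            assert stepped.V.min() >= 0.0


class TestInitialization:
    def test_seeded_determinism_and_open_interval(self):
        cfg = OccfConfig(r=4, seed=123)
        a = initialize_factors(5, 3, cfg)
        b = initialize_factors(5, 3, cfg)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)
        assert a.U.min() > 0.0 and a.V.min() > 0.0
        assert a.U.max() <= 1.0 / np.sqrt(cfg.r)

    def test_different_seeds_differ(self):
        a = initialize_factors(5, 3, OccfConfig(r=4, seed=1))
        b = initialize_factors(5, 3, OccfConfig(r=4, seed=2))
        assert not np.array_equal(a.U, b.U)


class TestFit:
    def test_zero_iterations_returns_initialization(self):
        table = table_from_positives(4, 3, {(0, 0)})
        cfg = OccfConfig(r=2, p_iter=0, seed=5, p_chem=0.0, p_prot=0.0)
        model = fit(table, None, None, cfg)
        init = initialize_factors(4, 3, cfg)
        assert np.array_equal(model.U, init.U)
        assert len(model.objective_trace) == 1

    def test_rank1_recovery_of_all_ones_matrix(self):
        n = m = 4
        table = table_from_positives(n, m, {(i, j) for i in range(n) for j in range(m)})
        cfg = OccfConfig(
            p_wt=1.0, p_imp=0.0, p_reg=1e-6, p_chem=0.0, p_prot=0.0,
            r=1, p_iter=400, seed=3,
        )
        model = fit(table, None, None, cfg)
        recon = model.U @ model.V.T
        assert np.abs(recon - 1.0).max() < 1e-3

    def test_objective_trace_non_increasing_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            table, C, T, cfg, _ = random_instance(rng)
            cfg = cfg.with_(p_iter=40)
            model = fit(table, C, T, cfg)
            trace = np.asarray(model.objective_trace)
            rel_increase = np.diff(trace) / np.maximum(np.abs(trace[:-1]), 1e-30)
            assert rel_increase.max() <= 1e-9

    def test_objective_trace_strictly_decreases_early_on_synthetic(self, default_dataset):
        cfg = OccfConfig(r=40, p_iter=10, seed=1)
        model = fit(default_dataset.observed, default_dataset.C, default_dataset.T, cfg)
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace[:11]) < 0)

    def test_overparameterized_rank_warns_but_runs(self):
        table = table_from_positives(3, 2, {(0, 0)})
        with pytest.warns(UserWarning, match="over-parameterized"):
            fit(table, None, None, OccfConfig(r=10, p_iter=2, p_chem=0, p_prot=0))

    def test_deterministic_given_seed(self):
        table = table_from_positives(5, 4, {(0, 0), (1, 2), (4, 3)})
        cfg = OccfConfig(r=2, p_iter=15, seed=9, p_chem=0.0, p_prot=0.0)
        a = fit(table, None, None, cfg)
        b = fit(table, None, None, cfg)
        assert np.array_equal(a.U, b.U)
        assert a.objective_trace == b.objective_trace


class TestPrediction:
    def test_scores_are_inner_products(self):
        model = FactorModel(U=np.array([[2.0]]), V=np.array([[1.0], [3.0]]))
        assert predict_scores(model, 0).tolist() == [2.0, 6.0]

    def test_zero_profile_gives_zero_scores(self):
        model = FactorModel(U=np.zeros((1, 3)), V=np.ones((4, 3)))
        assert predict_scores(model, 0).tolist() == [0.0] * 4

    def test_out_of_range_index_raises(self):
        model = FactorModel(U=np.ones((2, 1)), V=np.ones((2, 1)))
        with pytest.raises(IndexError):
            predict_scores(model, 2)

    def test_scores_invariant_under_column_permutation(self):
        rng = np.random.default_rng(4)
        U, V = rng.uniform(size=(3, 4)), rng.uniform(size=(5, 4))
        perm = [2, 0, 3, 1]
        a = predict_scores(FactorModel(U=U, V=V), 1)
        b = predict_scores(FactorModel(U=U[:, perm], V=V[:, perm]), 1)
        assert np.allclose(a, b)

    def test_top_k_ordering_exclusion_and_ties(self):
        U = np.array([[1.0]])
        V = np.array([[0.1], [0.9], [0.5]])
        model = FactorModel(U=U, V=V)
        top = predict_top_k(model, 0, k=2)
        assert [j for j, _, _ in top] == [1, 2]
        assert [r for _, _, r in top] == [1, 2]
        # all scores equal: ranks follow protein index
        tied = FactorModel(U=U, V=np.ones((3, 1)))
        assert [j for j, _, _ in predict_top_k(tied, 0, k=3)] == [0, 1, 2]
        # excluding everything empties the list
        assert predict_top_k(model, 0, k=2, exclude={0, 1, 2}) == []

    def test_rank_of_protein_matches_full_sort(self):
        rng = np.random.default_rng(8)
        model = FactorModel(U=rng.uniform(size=(2, 3)), V=rng.uniform(size=(20, 3)))
        exclude = {3, 7}
        full = predict_top_k(model, 1, k=18, exclude=exclude)
        for j, _, rank in full:
            got_rank, n_candidates = rank_of_protein(model, 1, j, exclude=exclude)
            assert got_rank == rank
            assert n_candidates == 18
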