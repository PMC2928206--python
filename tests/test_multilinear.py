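import numpy as np
import pytest

from chromvalence import multilinear as ml
from chromvalence import synthetic as syn


class TestEnumerateTerms:
    def test_full_panel_counts(self):
        terms = ml.enumerate_terms(21)
        by_valency = {v: sum(1 for t in terms if len(t) == v) for v in (1, 2, 3)}
        assert by_valency == {1: 21, 2: 210, 3: 1330}
        assert len(terms) == 1561

    def test_three_marks(self):
        assert len(ml.enumerate_terms(3)) == 7

    def test_single_mark_monovalent(self):
        assert ml.enumerate_terms(1, max_valency=1) == [(0,)]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ml.enumerate_terms(0)
        with pytest.raises(ValueError):
            ml.enumerate_terms(2, max_valency=3)

    def test_canonical_order_free(self):
        assert ml.canonical_term((2, 0)) == ml.canonical_term((0, 2)) == (0, 2)
        with pytest.raises(ValueError):
            ml.canonical_term((1, 1))


class TestDesign:
    def test_products(self, rng):
        A = rng.uniform(1, 2, (10, 3))
        X = ml.build_design(A, [(0,), (0, 1), (0, 1, 2)])
        assert np.allclose(X[:, 0], A[:, 0])
        assert np.allclose(X[:, 1], A[:, 0] * A[:, 1])
        assert np.allclose(X[:, 2], A.prod(axis=1))


class TestStepwise:
    def test_near_noiseless_recovery(self, rng):
        A = rng.lognormal(0, 0.5, (300, 4))
        y = 3.0 * A[:, 0] + rng.normal(0, 1e-8, 300)
        terms = [(0,), (1,)]
        X = ml.build_design(A, terms)
        fit = ml.stepwise_fit(X, y, terms)
        assert fit.terms == [(0,)]
        assert fit.beta[1] == pytest.approx(3.0, rel=1e-4)

    def test_null_false_inclusion_rate(self):
        # per-term type-I error alpha=0.05, 20 independent candidates
        included = []
        for s in range(40):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((150, 20))
            y = rng.standard_normal(150)
            terms = [(i,) for i in range(20)]
            fit = ml.stepwise_fit(X, y, terms)
            included.append(len(fit.terms))
        assert 0.2 <= np.mean(included) <= 2.5

    def test_planted_terms_recovered(self):
        ds = syn.planted_three_term_scenario(n_genes=2000, seed=5)
        A = ds.ground_truth.true_amplitudes.to_numpy()
        y = ds.ground_truth.expression.to_numpy()
        terms = ml.enumerate_terms(8)
        X = ml.build_design(A, terms)
        fit = ml.stepwise_fit(X, y, terms)
        got = dict(zip(fit.terms, fit.beta[1:]))
        assert got[(0,)] > 0
        assert got[(1, 2)] > 0
        assert got[(3, 4, 5)] < 0

    def test_included_terms_all_significant(self, rng):
        A = rng.lognormal(0, 0.5, (500, 5))
        y = 2 * A[:, 0] - A[:, 1] * A[:, 2] + rng.normal(0, 1, 500)
        terms = ml.enumerate_terms(5)
        X = ml.build_design(A, terms)
        fit = ml.stepwise_fit(X, y, terms)
        assert np.all(fit.p[1:] <= 0.05)

    def test_aliased_column_dropped(self, rng):
        A = rng.lognormal(0, 0.5, (200, 2))
        X = np.column_stack([A[:, 0], A[:, 0]])  # duplicated column
        y = A[:, 0] * 2 + rng.normal(0, 0.01, 200)
        terms = [(0,), (1,)]
        with pytest.warns(UserWarning, match="aliased"):
            fit = ml.stepwise_fit(X, y, terms, initial_terms=[(0,), (1,)])
        assert len(fit.terms) == 1

    def test_forced_in_equals_ols(self, rng):
        # with alpha_remove=1 and all terms initial, stepwise == plain OLS
        A = rng.lognormal(0, 0.4, (100, 3))
        terms = ml.enumerate_terms(3, max_valency=1)
        X = ml.build_design(A, terms)
        y = rng.standard_normal(100)
        fit = ml.stepwise_fit(X, y, terms, initial_terms=terms,
                              alpha_enter=0.0, alpha_remove=1.0)
        X1 = np.column_stack([np.ones(100), X])
        beta_ols, *_ = np.linalg.lstsq(X1, y, rcond=None)
        assert np.allclose(fit.beta, beta_ols)

    def test_canonicalization_permutation_invariant(self, rng):
        A = rng.lognormal(0, 0.5, (400, 4))
        y = 2 * A[:, 1] * A[:, 3] + rng.normal(0, 0.5, 400)
        terms = ml.enumerate_terms(4)
        X = ml.build_design(A, terms)
        fit = ml.stepwise_fit(X, y, terms)
        # permute marks: swap 1<->3 in the amplitude matrix
        perm = [0, 3, 2, 1]
        A2 = A[:, perm]
        X2 = ml.build_design(A2, terms)
        fit2 = ml.stepwise_fit(X2, y, terms)
        remap = {0: 0, 1: 3, 2: 2, 3: 1}
        terms2 = {tuple(sorted(remap[m] for m in t)) for t in fit2.terms}
        assert set(fit.terms) == terms2


class TestSurvival:
    def test_dominant_term_survives_always(self, rng):
        A = rng.lognormal(0, 0.5, (300, 3))
        y = 5 * A[:, 0] + rng.normal(0, 0.2, 300)
        terms = ml.enumerate_terms(3, max_valency=1)
        X = ml.build_design(A, terms)
        rates, surviving = ml.round1_survival(X, y, terms, n_runs=10,
                                              n_initial=1, seed=3)
        assert rates[str((0,))] == pytest.approx(1.0)
        assert (0,) in surviving

    def test_null_design_survivors_rare(self, rng):
        X = rng.standard_normal((200, 15))
        y = rng.standard_normal(200)
        terms = [(i,) for i in range(15)]
        _, surviving = ml.round1_survival(X, y, terms, n_runs=20,
                                          cutoff=0.35, n_initial=5, seed=1)
        assert len(surviving) <= 2

    def test_cutoff_monotone(self, rng):
        ds = syn.planted_three_term_scenario(400, seed=2)
        A = ds.ground_truth.true_amplitudes.to_numpy()
        y = ds.ground_truth.expression.to_numpy()
        terms = ml.enumerate_terms(8, max_valency=2)
        X = ml.build_design(A, terms)
        rates, _ = ml.round1_survival(X, y, terms, n_runs=10, seed=0)
        sets = []
        for cutoff in (0.1, 0.35, 0.7):
            sets.append({t for t in terms if rates[str(t)] >= cutoff})
        assert sets[0] >= sets[1] >= sets[2]

    def test_needs_two_runs(self, rng):
        with pytest.raises(ValueError):
            ml.round1_survival(rng.standard_normal((50, 2)),
                               rng.standard_normal(50), [(0,), (1,)],
                               n_runs=1)


class TestCvProtocol:
    def test_noiseless_planted_model(self, rng):
        A = rng.lognormal(0, 0.5, (400, 4))
        y = 4.0 + 2.0 * A[:, 0] - 3.0 * A[:, 1] * A[:, 2]
        terms = ml.enumerate_terms(4)
        planted = [(0,), (1, 2)]
        model = ml.cv_protocol(A, y, planted, candidate_terms=terms,
                               runs_per_fold=2, extra_random_terms=5, seed=9)
        assert set(planted) <= set(model.terms)
        got = dict(zip(model.terms, model.beta))
        assert got[(0,)] == pytest.approx(2.0, abs=1e-6)
        assert got[(1, 2)] == pytest.approx(-3.0, abs=1e-6)
        assert model.intercept == pytest.approx(4.0, abs=1e-6)
        # per-fold betas essentially identical in the noiseless case
        assert np.allclose(model.fold_betas.std(axis=0), 0.0, atol=1e-6)

    def test_impossible_retention_gives_empty_model(self, rng):
        A = rng.lognormal(0, 0.5, (200, 3))
        y = 2 * A[:, 0] + rng.normal(0, 0.5, 200)
        model = ml.cv_protocol(A, y, [(0,)], retention=11, runs_per_fold=2,
                               extra_random_terms=2, seed=1)
        assert model.terms == []
        pred = model.predict(A)
        assert np.allclose(pred, model.intercept)

    def test_train_test_mse_close_when_well_specified(self):
        ds = syn.planted_three_term_scenario(1500, seed=7)
        A = ds.ground_truth.true_amplitudes.to_numpy()
        y = ds.ground_truth.expression.to_numpy()
        terms = ml.enumerate_terms(8)
        model = ml.cv_protocol(A, y, [(0,), (1, 2), (3, 4, 5)],
                               candidate_terms=terms, runs_per_fold=3,
                               extra_random_terms=10, seed=4)
        rel = abs(model.test_mse.mean() - model.train_mse.mean())
        assert rel / model.train_mse.mean() < 0.1

    def test_fold_assignment_by_gene(self, rng):
        # two probes per gene must never straddle folds; give each gene's
        # probes an identical, gene-specific response and check determinism
        A = np.repeat(rng.lognormal(0, 0.5, (100, 3)), 2, axis=0)
        y = 2 * A[:, 0] + rng.normal(0, 0.3, 200)
        genes = np.repeat(np.arange(100), 2)
        m1 = ml.cv_protocol(A, y, [(0,)], gene_ids=genes, runs_per_fold=2,
                            extra_random_terms=2, seed=5)
        m2 = ml.cv_protocol(A, y, [(0,)], gene_ids=genes, runs_per_fold=2,
                            extra_random_terms=2, seed=5)
        assert m1.terms == m2.terms
        assert np.array_equal(m1.fold_betas, m2.fold_betas)


class TestTermStatistics:
    def _tiny_model(self, A, y, terms):
        return ml.cv_protocol(A, y, terms, runs_per_fold=2,
                              extra_random_terms=2, seed=0)

    def test_impact_arithmetic(self, rng):
        A = rng.lognormal(0, 0.5, (300, 2))
        y = 2.0 * A[:, 0] + rng.normal(0, 0.1, 300)
        model = self._tiny_model(A, y, [(0,)])
        stats = ml.term_statistics(model, A, ["m0", "m1"])
        row = stats[stats["term"] == "m0"].iloc[0]
        iqr = np.subtract(*np.percentile(A[:, 0], [75, 25]))
        assert row["impact"] == pytest.approx(row["beta"] * iqr)
        assert row["label"] == "a"

    def test_sorted_by_impact_descending(self, default_dataset):
        A = default_dataset.ground_truth.true_amplitudes.to_numpy()
        y = default_dataset.ground_truth.expression.to_numpy()
        model = ml.cv_protocol(A, y, [(0,), (7,)], runs_per_fold=2,
                               extra_random_terms=5, seed=2)
        stats = ml.term_statistics(model, A, default_dataset.mark_names)
        assert list(stats["impact"]) == sorted(stats["impact"], reverse=True)

    def test_confounded_repressor_negative_impact(self, default_dataset):
        A = default_dataset.ground_truth.true_amplitudes.to_numpy()
        y = default_dataset.ground_truth.expression.to_numpy()
        terms = ml.enumerate_terms(8)
        model = ml.cv_protocol(A, y, [(7,)], candidate_terms=terms,
                               runs_per_fold=3, extra_random_terms=10, seed=3)
        assert (7,) in model.terms
        stats = ml.term_statistics(model, A, default_dataset.mark_names)
        row = stats[stats["term"] == "conf"].iloc[0]
        assert row["impact"] < 0
        assert row["z"] < -3

    def test_trimmed_mean_drops_extremes(self):
        vals = np.array([[0.0], [1.0], [1.0], [1.0], [100.0]])
        assert ml.trimmed_mean(vals, axis=0)[0] == pytest.approx(1.0)
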