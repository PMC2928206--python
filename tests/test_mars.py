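import numpy as np
import pytest

from chromvalence import mars
from chromvalence import synthetic as syn


class TestHinge:
    def test_positive_direction(self):
        assert mars.hinge(np.array([0.5]), 0.3, 1)[0] == pytest.approx(0.2)

    def test_at_knot_both_zero(self):
        assert mars.hinge(np.array([0.3]), 0.3, 1)[0] == 0.0
        assert mars.hinge(np.array([0.3]), 0.3, -1)[0] == 0.0

    def test_pair_sums_to_absolute_value(self):
        x = np.linspace(-3, 3, 101)
        k = 0.37
        total = mars.hinge(x, k, 1) + mars.hinge(x, k, -1)
        assert np.allclose(total, np.abs(x - k))

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            mars.hinge(np.array([1.0]), 0.0, 2)


class TestBasis:
    def test_no_repeated_marks(self):
        f = mars.HingeFactor(0, 1.0, 1)
        with pytest.raises(ValueError):
            mars.MarsBasis((f, mars.HingeFactor(0, 2.0, -1)))

    def test_degree_and_evaluation(self, rng):
        A = rng.uniform(0, 2, (50, 3))
        b = mars.MarsBasis((mars.HingeFactor(0, 0.5, 1),
                            mars.HingeFactor(2, 1.0, -1)))
        assert b.degree == 2
        expected = np.maximum(0, A[:, 0] - 0.5) * np.maximum(0, 1.0 - A[:, 2])
        assert np.allclose(b.evaluate(A), expected)

    def test_describe(self):
        b = mars.MarsBasis((mars.HingeFactor(1, 0.25, -1),))
        assert b.describe(["mA", "mB"]) == "h(0.25-mB)"


class TestForwardPass:
    def test_constant_response_intercept_only(self, rng):
        A = rng.uniform(0, 1, (100, 3))
        model = mars.forward_pass(A, np.full(100, 2.5))
        assert model.bases == []
        assert model.intercept == pytest.approx(2.5)

    def test_intercept_is_response_mean_initially(self, rng):
        A = rng.uniform(0, 1, (100, 2))
        y = rng.standard_normal(100)
        model = mars.forward_pass(A, y, max_terms=1)
        assert model.intercept == pytest.approx(y.mean())

    def test_exact_hinge_recovery(self):
        ds = syn.hinge_scenario(n_genes=400, seed=1, knot=0.7, coef=2.0)
        A = ds.ground_truth.true_amplitudes.to_numpy()
        y = ds.ground_truth.expression.to_numpy()
        planted = ds.ground_truth.planted_terms[0].knot
        model = mars.forward_pass(A, y, max_knots=401)
        assert model.rss == pytest.approx(0.0, abs=1e-12)
        knots = {f.knot for b in model.bases for f in b.factors}
        assert planted in knots

    def test_saturation_flat_above_knot(self, rng):
        # response min(x0, 0.7): piecewise-linear, representable
        A = rng.uniform(0, 2, (600, 2))
        y = np.minimum(A[:, 0], 0.7)
        model = mars.fit_mars(A, y, max_knots=200)
        surface = mars.response_surface(model, A, (0,), grid_size=50)
        above = surface[surface["x"] > 0.8]["prediction"].to_numpy()
        slopes = np.diff(above) / np.diff(
            surface[surface["x"] > 0.8]["x"].to_numpy())
        assert np.all(np.abs(slopes) < 0.05)

    def test_hierarchy_constraint(self, default_amplitudes,
                                  default_expression):
        model = mars.forward_pass(default_amplitudes, default_expression,
                                  max_knots=10, max_terms=25)
        present = set()
        for b in model.bases:
            if b.degree > 1:
                parents = {frozenset(b.factors) - {f} for f in b.factors}
                assert any(frozenset(p) in present for p in parents), \
                    f"basis {b} has no parent"
            present.add(frozenset(b.factors))

    def test_max_terms_respected(self, rng):
        A = rng.uniform(0, 2, (200, 3))
        y = rng.standard_normal(200)
        model = mars.forward_pass(A, y, max_terms=5, max_knots=10,
                                  min_rss_reduction=0.0)
        assert model.n_terms <= 5

    def test_invalid_max_terms(self, rng):
        with pytest.raises(ValueError):
            mars.forward_pass(np.ones((10, 2)) * [[1], [2]] * 5,
                              np.ones(10), max_terms=0)

    def test_constant_mark_rejected(self, rng):
        A = np.column_stack([np.ones(50), rng.uniform(0, 1, 50)])
        with pytest.raises(ValueError, match="distinct"):
            mars.forward_pass(A, rng.standard_normal(50))


class TestBackwardPass:
    def test_gcv_arithmetic(self):
        assert mars.gcv_score(rss=100.0, n_obs=1000, enp=10) == \
            pytest.approx((100 / 1000) / (1 - 10 / 1000) ** 2)
        assert mars.gcv_score(rss=1.0, n_obs=10, enp=10) == np.inf

    def test_pure_noise_pruned_to_intercept_majority(self):
        intercept_only = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            A = rng.lognormal(0, 0.5, (300, 4))
            y = rng.standard_normal(300)
            model = mars.fit_mars(A, y, max_knots=20, max_terms=21)
            intercept_only += (len(model.bases) == 0)
        assert intercept_only > 5

    def test_noiseless_model_not_pruned_below_exact_fit(self):
        ds = syn.hinge_scenario(n_genes=300, seed=2, knot=0.7, coef=2.0)
        A = ds.ground_truth.true_amplitudes.to_numpy()
        y = ds.ground_truth.expression.to_numpy()
        model = mars.fit_mars(A, y, max_knots=301)
        assert model.rss == pytest.approx(0.0, abs=1e-10)
        assert len(model.bases) >= 1

    def test_pruned_gcv_not_worse(self, default_amplitudes,
                                  default_expression):
        fwd = mars.forward_pass(default_amplitudes, default_expression,
                                max_knots=10, max_terms=21)
        pruned = mars.backward_pass(fwd, default_amplitudes,
                                    default_expression)
        assert pruned.gcv <= fwd.gcv + 1e-12

    def test_oversized_model_rejected(self, rng):
        A = rng.uniform(0, 1, (10, 2))
        y = rng.standard_normal(10)
        # 4 bases on 2 distinct knots: enp = 5 + 3*2 = 11 >= 10 observations
        bases = [mars.MarsBasis((mars.HingeFactor(0, k, d),))
                 for k in (0.3, 0.6) for d in (1, -1)]
        fwd = mars.MarsModel(intercept=0.0, bases=bases,
                             coefficients=np.zeros(4), n_obs=10, penalty=3.0)
        with pytest.raises(ValueError, match="oversized"):
            mars.backward_pass(fwd, A, y)

    def test_beats_linear_fit_on_hinge_data(self):
        # planted hinge terms at R^2 ~ 0.5: MARS should beat plain linear
        rng = np.random.default_rng(12)
        A = rng.lognormal(0, 0.5, (1500, 4))
        signal = 2.0 * np.maximum(0, A[:, 0] - 1.0) - 3.0 * np.minimum(A[:, 1], 0.8)
        y = signal + rng.normal(0, signal.std(), 1500)
        model = mars.fit_mars(A, y, max_knots=30)
        X1 = np.column_stack([np.ones(1500), A])
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss_lin = np.sum((y - X1 @ beta) ** 2)
        assert model.rss < rss_lin


@pytest.fixture(scope="module")
def fitted(default_amplitudes, default_expression):
    return mars.fit_mars(default_amplitudes, default_expression,
                         max_knots=16, max_terms=25)


class TestReports:

    def test_nonzero_counts(self, fitted, default_amplitudes):
        basis_table, _ = mars.mars_report(fitted, default_amplitudes)
        assert basis_table.iloc[0]["basis"] == "1"
        assert basis_table.iloc[0]["n_nonzero"] == default_amplitudes.shape[0]
        for _, row in basis_table.iloc[1:].iterrows():
            assert 0 <= row["n_nonzero"] <= default_amplitudes.shape[0]

    def test_unused_knot_below_range_zero_count(self, default_amplitudes):
        b = mars.MarsBasis((mars.HingeFactor(0, -5.0, -1),))  # h(-5 - x): always 0 for x>0
        model = mars.MarsModel(intercept=0.0, bases=[b],
                               coefficients=np.array([1.0]),
                               n_obs=10, penalty=3.0)
        table, _ = mars.mars_report(model, default_amplitudes)
        assert table.iloc[1]["n_nonzero"] == 0

    def test_absent_mark_zero_impact(self, fitted, default_amplitudes):
        _, impact = mars.mars_report(fitted, default_amplitudes)
        absent = set(range(8)) - fitted.marks_in_model
        for j in absent:
            assert impact[impact["mark_index"] == j]["impact"].iloc[0] == 0.0

    def test_confounded_repressor_negative_impact(self, fitted,
                                                  default_amplitudes):
        _, impact = mars.mars_report(fitted, default_amplitudes)
        conf = impact[impact["mark_index"] == 7]["impact"].iloc[0]
        assert conf < 0

    def test_monotone_single_mark_impact_equals_rise(self, rng):
        A = rng.lognormal(0, 0.5, (800, 2))
        y = 2.0 * A[:, 0]
        model = mars.fit_mars(A, y, max_knots=50)
        _, impact = mars.mars_report(model, A)
        row = impact[impact["mark_index"] == 0].iloc[0]
        lo, hi = np.percentile(A[:, 0], [5, 95])
        med = np.median(A, axis=0)
        p_hi, p_lo = med.copy(), med.copy()
        p_hi[0], p_lo[0] = hi, lo
        rise = model.predict(p_hi[None])[0] - model.predict(p_lo[None])[0]
        assert row["impact"] == pytest.approx(rise)
        assert row["impact"] > 0


class TestSynergy:
    def test_additive_model_no_synergy(self, rng):
        A = rng.lognormal(0, 0.5, (500, 3))
        bases = [mars.MarsBasis((mars.HingeFactor(0, 0.5, 1),)),
                 mars.MarsBasis((mars.HingeFactor(1, 0.5, 1),))]
        model = mars.MarsModel(intercept=1.0, bases=bases,
                               coefficients=np.array([2.0, -1.0]),
                               n_obs=500, penalty=3.0)
        table = mars.synergy_tables(model, A, (0, 1))
        vals = dict(zip(table["levels"], table["prediction"]))
        assert (vals["high-high"] - vals["high-low"]) == pytest.approx(
            vals["low-high"] - vals["low-low"])

    def test_planted_synergy_exceeds_additive(self, rng):
        A = rng.lognormal(0, 0.5, (500, 2))
        interaction = mars.MarsBasis((mars.HingeFactor(0, 0.5, 1),
                                      mars.HingeFactor(1, 0.5, 1),))
        model = mars.MarsModel(intercept=0.0,
                               bases=[mars.MarsBasis((mars.HingeFactor(0, 0.5, 1),)),
                                      interaction],
                               coefficients=np.array([1.0, 3.0]),
                               n_obs=500, penalty=3.0)
        table = mars.synergy_tables(model, A, (0, 1))
        vals = dict(zip(table["levels"], table["prediction"]))
        additive = vals["high-low"] + vals["low-high"] - vals["low-low"]
        assert vals["high-high"] > additive

    def test_mark_must_be_in_model(self, rng):
        A = rng.lognormal(0, 0.5, (100, 3))
        model = mars.MarsModel(intercept=1.0, bases=[], coefficients=np.array([]),
                               n_obs=100, penalty=3.0)
        with pytest.raises(ValueError):
            mars.synergy_tables(model, A, (0, 1))


class TestResponseSurface:
    def test_intercept_only_flat(self, rng):
        A = rng.lognormal(0, 0.5, (100, 2))
        model = mars.MarsModel(intercept=2.0, bases=[],
                               coefficients=np.array([]), n_obs=100,
                               penalty=3.0)
        surf = mars.response_surface(model, A, (0,), grid_size=10)
        assert np.allclose(surf["prediction"], 2.0)

    def test_surface_matches_predict(self, default_amplitudes,
                                     default_expression):
        model = mars.fit_mars(default_amplitudes, default_expression,
                              max_knots=8, max_terms=11)
        surf = mars.response_surface(model, default_amplitudes, (0, 1),
                                     grid_size=5)
        med = np.median(default_amplitudes, axis=0)
        for _, row in surf.sample(5, random_state=0).iterrows():
            pt = med.copy()
            pt[0], pt[1] = row["x"], row["y"]
            assert row["prediction"] == pytest.approx(
                model.predict(pt[None])[0])

    def test_grid_size_validation(self, rng):
        model = mars.MarsModel(intercept=0.0, bases=[],
                               coefficients=np.array([]), n_obs=10,
                               penalty=3.0)
        with pytest.raises(ValueError):
            mars.response_surface(model, rng.uniform(0, 1, (10, 2)), (0,),
                                  grid_size=1)


def test_prediction_linear_in_coefficients(rng):
    A = rng.lognormal(0, 0.5, (100, 2))
    b = mars.MarsBasis((mars.HingeFactor(0, 0.8, 1),))
    m1 = mars.MarsModel(intercept=1.0, bases=[b],
                        coefficients=np.array([2.0]), n_obs=100, penalty=3.0)
    m2 = mars.MarsModel(intercept=2.0, bases=[b],
                        coefficients=np.array([4.0]), n_obs=100, penalty=3.0)
    assert np.allclose(m2.predict(A), 2.0 * m1.predict(A))
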