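import numpy as np
import pytest

from grninfer import (
    GoalAttainmentProblem,
    GRNModel,
    GRNResults,
    ObjectiveTerm,
    SignedNetwork,
    ensemble_combine,
    moo_fit,
    objective_distance,
    sample_kinetics,
    simulate_dense_series,
    soo_fit,
    sqe,
)
from grninfer.datasets import InterpolatedSeries
from grninfer.model import _closed_form


def series_from(values, derivatives, times=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    derivatives = np.atleast_2d(np.asarray(derivatives, dtype=float))
    times = np.arange(values.shape[1], dtype=float) if times is None else times
    return InterpolatedSeries(
        values=values,
        derivatives=derivatives,
        times=times,
        gene_names=[f"G{k}" for k in range(values.shape[0])],
    )


def random_series(rng, n_genes=4, n_t=40):
    t = np.linspace(0, 1, n_t)
    coeff = rng.normal(size=(n_genes, 4))
    values = sum(c[:, None] * t**k for k, c in enumerate(coeff.T))
    derivs = sum(
        k * c[:, None] * t ** (k - 1) for k, c in enumerate(coeff.T) if k > 0
    )
    noise = 0.2 * rng.normal(size=values.shape)
    return series_from(values, derivs + noise, times=t)


class TestSqe:
    def test_constant_data_zero_parameters_zero_error(self):
        s = series_from(np.full((2, 30), 1.5), np.zeros((2, 30)))
        assert sqe(np.zeros((2, 2)), np.zeros(2), s) == 0.0

    def test_exponential_decay_matches_its_own_ode(self):
        t = np.linspace(0, 5, 300)
        x = np.exp(-t)
        s = series_from(x, -x, times=t)
        assert sqe(np.array([[-1.0]]), np.zeros(1), s) <= 1e-12

    def test_zero_weight_error_equals_sum_of_squares(self):
        t = np.linspace(0, 5, 100)
        x = np.exp(-t)
        s = series_from(x, -x, times=t)
        manual = sum(xv**2 for xv in x)
        assert sqe(np.zeros((1, 1)), np.zeros(1), s) == pytest.approx(manual)


class TestObjectiveDistance:
    def test_equal_on_mask_is_zero(self, rng):
        o = rng.normal(size=(3, 3))
        term = ObjectiveTerm(O=o)
        assert objective_distance(o, term) == 0.0

    def test_three_four_five(self):
        o = np.zeros((2, 2))
        w = np.array([[3.0, 0.0], [0.0, 4.0]])
        mask = np.eye(2, dtype=bool)
        term = ObjectiveTerm(O=o, mask=mask)
        assert objective_distance(w, term) == pytest.approx(5.0)

    def test_matches_elementwise_loop(self, rng):
        w = rng.normal(size=(5, 5))
        o = rng.normal(size=(5, 5))
        mask = rng.random((5, 5)) < 0.6
        term = ObjectiveTerm(O=o, mask=mask)
        manual = 0.0
        for i in range(5):
            for j in range(5):
                if mask[i, j]:
                    manual += (w[i, j] - o[i, j]) ** 2
        assert objective_distance(w, term) == pytest.approx(np.sqrt(manual))

    def test_empty_mask_warns_and_returns_zero(self):
        term = ObjectiveTerm(O=np.zeros((2, 2)), mask=np.zeros((2, 2), bool))
        with pytest.warns(UserWarning):
            assert objective_distance(np.ones((2, 2)), term) == 0.0


class TestSooFit:
    def test_recovers_generating_linear_model(self):
        net = SignedNetwork(
            ["A", "B", "C"], {("A", "B", 1), ("B", "C", -1), ("C", "A", 1)}
        )
        model = sample_kinetics(net, seed=3, mode="linear")
        series = simulate_dense_series(model, n_points=300, seed=4)
        res = soo_fit(series, init_seed=0)
        w_true = model.linear_matrix() - np.diag(model.decay_rates)
        np.testing.assert_allclose(res.w, w_true, atol=1e-3)

    def test_constant_data_attains_zero_error(self):
        s = series_from(np.full((2, 50), 2.0), np.zeros((2, 50)))
        res = soo_fit(s)
        assert res.sqe_value <= 1e-12

    def test_matches_closed_form_error(self, rng):
        s = random_series(rng)
        res = soo_fit(s, init_seed=1)
        _w, _b, best = _closed_form(s)
        assert res.sqe_value <= best * (1 + 1e-6) + 1e-12

    def test_independent_inits_agree(self, rng):
        s = random_series(rng)
        r1 = soo_fit(s, init_seed=1)
        r2 = soo_fit(s, init_seed=99)
        assert r1.sqe_value == pytest.approx(r2.sqe_value, rel=1e-6)


class TestMooFit:
    def test_term_at_soo_solution_reproduces_soo(self, rng):
        s = random_series(rng)
        soo = soo_fit(s, solver="exact")
        term = ObjectiveTerm(O=soo.w, label="custom", theta=1.0, J=0.0)
        res = moo_fit(GoalAttainmentProblem(data=s, terms=[term]))
        np.testing.assert_allclose(res.w, soo.w, atol=1e-3)
        assert res.gamma == pytest.approx(0.0, abs=1e-3)

    def test_single_gene_matches_grid_search_oracle(self):
        # one-parameter slice: minimise |w - O| s.t. the quadratic SQE bound
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 60)
        x = 1.0 + 0.8 * t
        d = 0.8 * np.ones_like(t) + 0.1 * rng.normal(size=t.size)
        s = series_from(x, d, times=t)
        o_val = 5.0
        term = ObjectiveTerm(O=np.array([[o_val]]), label="custom")
        prob = GoalAttainmentProblem(data=s, terms=[term], sqe_slack=0.5)
        res = moo_fit(prob)

        _w, _b, sqe_min = _closed_form(s)
        bound = sqe_min * 1.5 + 1e-9 * np.sum(d**2)
        best = np.inf
        for w in np.linspace(-1, o_val, 20001):
            b = np.mean(d - w * x)  # optimal intercept given w
            if np.sum((w * x + b - d) ** 2) <= bound:
                best = min(best, abs(w - o_val))
        assert res.gamma == pytest.approx(best, rel=1e-2)
        assert abs(res.w[0, 0] - o_val) == pytest.approx(best, rel=1e-2)

    def test_agrees_with_slsqp_transcription(self, rng):
        s = random_series(rng, n_genes=3, n_t=30)
        o = rng.normal(size=(3, 3))
        term = ObjectiveTerm(O=o, label="custom")
        prob = GoalAttainmentProblem(data=s, terms=[term], init_seed=5)
        dual = moo_fit(prob, solver="dual")
        slsqp = moo_fit(prob, solver="slsqp")
        assert slsqp.gamma == pytest.approx(dual.gamma, rel=5e-2, abs=1e-3)

    def test_no_terms_falls_back_to_soo(self, rng):
        s = random_series(rng)
        res = moo_fit(GoalAttainmentProblem(data=s, terms=[]))
        _w, _b, best = _closed_form(s)
        assert res.sqe_value == pytest.approx(best, rel=1e-4)

    def test_sqe_bound_respected(self, rng):
        s = random_series(rng)
        o = rng.normal(size=(4, 4))
        res = moo_fit(
            GoalAttainmentProblem(
                data=s, terms=[ObjectiveTerm(O=o, label="custom")], sqe_slack=0.05
            )
        )
        _w, _b, sqe_min = _closed_form(s)
        assert res.sqe_value <= sqe_min * 1.05 * (1 + 1e-6) + 1e-6

    def test_soft_attainments_equalised_across_terms(self, rng):
        # linear trajectories give a rank-deficient design, so the SQE
        # constraint leaves genuine freedom to trade the two objectives off
        t = np.linspace(0, 1, 40)
        a = rng.normal(size=4)[:, None]
        b = rng.normal(size=4)[:, None]
        s = series_from(a + b * t, np.broadcast_to(b, (4, 40)).copy(), times=t)
        o1 = rng.normal(size=(4, 4))
        o2 = rng.normal(size=(4, 4))
        terms = [
            ObjectiveTerm(O=o1, label="custom", theta=1.0),
            ObjectiveTerm(O=o2, label="DSp", theta=2.0),
        ]
        res = moo_fit(GoalAttainmentProblem(data=s, terms=terms))
        g1 = res.attainment["custom"] / 1.0
        g2 = res.attainment["DSp"] / 2.0
        assert g1 == pytest.approx(g2, rel=1e-2)
        assert res.gamma == pytest.approx(max(g1, g2), rel=1e-6)

    def test_gamma_never_increases_with_weight(self, rng):
        # a larger theta_k grants goal k more slack: the feasible set for a
        # given gamma grows, so the attained gamma cannot increase
        s = random_series(rng)
        o1 = rng.normal(size=(4, 4))
        o2 = rng.normal(size=(4, 4))
        gammas = []
        for theta in [0.25, 0.5, 1.0, 2.0, 4.0]:
            terms = [
                ObjectiveTerm(O=o1, label="custom", theta=theta),
                ObjectiveTerm(O=o2, label="DSp", theta=1.0),
            ]
            gammas.append(moo_fit(GoalAttainmentProblem(data=s, terms=terms)).gamma)
        assert all(a >= b - 1e-6 for a, b in zip(gammas, gammas[1:]))

    def test_deterministic_across_seeds(self, small_series):
        from grninfer import delayed_spearman_objective

        _res, term = delayed_spearman_objective(small_series)
        model = GRNModel(small_series, terms=[term])
        fits = [model.fit("moo", seed=s) for s in (0, 1, 2)]
        for f in fits[1:]:
            np.testing.assert_array_equal(f.w, fits[0].w)


class TestEnsembleCombine:
    def make(self, w):
        w = np.asarray(w, dtype=float)
        return GRNResults(
            w=w, b=np.zeros(w.shape[0]),
            gene_names=[f"G{k}" for k in range(w.shape[0])], role="moo",
        )

    def test_magnitude_from_first_sign_from_second(self):
        r = ensemble_combine(self.make([[0.0, 0.5], [0.3, 0.0]]),
                             self.make([[0.0, -0.2], [0.0, 0.0]]))
        assert r.w[0, 1] == -0.5
        # zero magnitude stays zero; zero sign donor defaults to +
        assert r.w[1, 0] == 0.3
        assert r.role == "ensemble"

    def test_zero_magnitude_stays_zero(self):
        r = ensemble_combine(self.make([[0.0, 0.0], [0.0, 0.0]]),
                             self.make([[0.0, -1.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(r.w, 0.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ensemble_combine(self.make(np.zeros((2, 2))), self.make(np.zeros((3, 3))))


class TestModelApi:
    def test_from_timecourse_and_summary(self, small_timecourse):
        model = GRNModel.from_timecourse(small_timecourse)
        res = model.fit("soo", seed=0)
        assert res.w.shape == (10, 10)
        text = res.summary()
        assert "E_SQE" in text and "soo" in text
        edges = res.to_edge_list()
        assert list(edges.columns) == ["regulator", "target", "weight", "sign"]
        assert (edges.weight.abs().diff().dropna() <= 1e-12).all()

    def test_save_round_trip(self, small_series, tmp_path):
        res = soo_fit(small_series)
        prefix = str(tmp_path / "fit")
        res.save(prefix)
        from grninfer import read_expression_tsv

        w, genes, _ = read_expression_tsv(prefix + "_w.tsv")
        np.testing.assert_allclose(w, res.w, rtol=1e-11)
        assert genes == res.gene_names
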