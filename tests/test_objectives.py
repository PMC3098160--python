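import numpy as np
import pytest
from scipy.stats import spearmanr

from grninfer import (
    KnockoutPanel,
    ObjectiveTerm,
    correlation_objective,
    delayed_spearman_objective,
    ratio_objective,
    scale_objective,
    select_tp,
)
from grninfer.datasets import InterpolatedSeries


def series_from(values, times=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.shape[1], dtype=float) if times is None else times
    return InterpolatedSeries(
        values=values,
        derivatives=np.gradient(values, times, axis=1),
        times=times,
        gene_names=[f"G{k}" for k in range(values.shape[0])],
    )


class TestDelayedSpearman:
    def test_shifted_copy_detected_at_its_delay(self):
        t = np.arange(60.0)
        bump = np.exp(-0.5 * ((t - 20.0) / 5.0) ** 2)
        x_j = bump
        x_i = np.roll(bump, 2)  # target follows regulator by 2 steps
        series = series_from(np.vstack([x_i, x_j]))
        res, term = delayed_spearman_objective(series, max_delay=6, t_o=1)
        assert res.dt[0, 1] == 2
        assert term.O[0, 1] == pytest.approx(1.0, abs=1e-6)
        # the reverse orientation is best unshifted -> filtered out
        assert res.dt[1, 0] == 0
        assert term.O[1, 0] == 0.0

    def test_matches_exhaustive_spearman_search(self, small_series):
        x = small_series.values
        res, _term = delayed_spearman_objective(small_series, max_delay=5, t_o=1)
        n_t = x.shape[1]
        rng = np.random.default_rng(0)
        for i, j in rng.integers(0, x.shape[0], size=(10, 2)):
            if i == j:
                continue
            best, best_d = 0.0, 0
            for d in range(6):
                rho = spearmanr(x[i, d:], x[j, : n_t - d]).statistic
                if np.isnan(rho):
                    rho = 0.0
                if abs(rho) > abs(best) + 1e-12:
                    best, best_d = rho, d
            assert res.d_src[i, j] == pytest.approx(best, abs=1e-9)
            assert res.dt[i, j] == best_d

    def test_diagonal_is_zero(self, small_series):
        _res, term = delayed_spearman_objective(small_series, max_delay=5, t_o=1)
        np.testing.assert_array_equal(np.diag(term.O), 0.0)

    def test_unshifted_comonotone_pair_filtered(self):
        t = np.arange(30.0)
        series = series_from(np.vstack([t, 2 * t + 1]))
        res, term = delayed_spearman_objective(series, max_delay=5, t_o=1)
        assert res.dt[0, 1] == 0 and res.dt[1, 0] == 0
        assert term.O[0, 1] == 0.0 and term.O[1, 0] == 0.0

    def test_minimum_delay_filter_invariant(self, small_series):
        res, term = delayed_spearman_objective(small_series, max_delay=8, t_o=3)
        assert np.all(term.O[res.dt < 3] == 0)

    def test_constant_profile_gives_zero(self):
        series = series_from(np.vstack([np.ones(20), np.arange(20.0)]))
        res, _ = delayed_spearman_objective(series, max_delay=4, t_o=1)
        assert res.d_src[0, 1] == 0.0
        assert res.d_src[1, 0] == 0.0

    def test_parameter_validation(self, small_series):
        with pytest.raises(ValueError):
            delayed_spearman_objective(small_series, max_delay=150)
        with pytest.raises(ValueError):
            delayed_spearman_objective(small_series, max_delay=5, t_o=6)


def planted_panel(argmax_index_per_gene, n_t=12, n_mut=4):
    """Time-resolved panel whose per-gene |derivative| peaks at given indices."""
    n = len(argmax_index_per_gene)
    n_mut = min(n_mut, n)
    times = np.arange(n_t, dtype=float)
    vals = np.zeros((n, n_mut, n_t))
    for g, idx in enumerate(argmax_index_per_gene):
        # a sigmoidal step centred on the requested index: steepest slope there
        vals[g] = 1.0 / (1.0 + np.exp(-(times - idx) * 2.0))
    return KnockoutPanel(
        mutant_values=vals,
        mutant_ids=[f"G{k}" for k in range(n_mut)],
        wildtype_reference=np.ones((n, n_t)),
        gene_names=[f"G{k}" for k in range(n)],
        t_p=0,
        times=times,
    )


class TestSelectTp:
    def test_modal_index(self):
        panel = planted_panel([3, 3, 7])
        assert select_tp(panel) == 3

    def test_tie_takes_earliest(self):
        panel = planted_panel([4, 6])
        assert select_tp(panel) == 4

    def test_matches_brute_force_scan(self, timecourse_panel):
        tp = select_tp(timecourse_panel)
        deriv = np.gradient(
            timecourse_panel.mutant_values, timecourse_panel.times, axis=2
        )
        mean_abs = np.abs(deriv).mean(axis=1)
        mean_abs[:, 0] = 0.0
        votes = [int(np.argmax(row)) for row in mean_abs]
        counts = np.bincount(votes, minlength=mean_abs.shape[1])
        assert tp == int(np.argmax(counts))

    def test_constant_panel_falls_back_to_midpoint(self):
        n_t = 10
        panel = KnockoutPanel(
            mutant_values=np.ones((3, 3, n_t)),
            mutant_ids=["G0", "G1", "G2"],
            wildtype_reference=np.ones((3, n_t)),
            gene_names=["G0", "G1", "G2"],
            t_p=0,
            times=np.arange(n_t, dtype=float),
        )
        with pytest.warns(UserWarning):
            assert select_tp(panel) == n_t // 2


def steady_panel_from(mut, wt, gene_names=None, mutant_ids=None):
    mut = np.asarray(mut, dtype=float)
    gene_names = gene_names or [f"G{k}" for k in range(mut.shape[0])]
    mutant_ids = mutant_ids or gene_names[: mut.shape[1]]
    return KnockoutPanel(
        mutant_values=mut,
        mutant_ids=mutant_ids,
        wildtype_reference=np.asarray(wt, dtype=float),
        gene_names=gene_names,
        t_p="steady",
    )


class TestRatioObjective:
    def test_log_and_negated_log_and_raw_conventions(self):
        # gene G1's expression halves in the G0 knockout
        panel = steady_panel_from([[2.0], [1.0]], [2.0, 2.0], mutant_ids=["G0"])
        log = ratio_objective(panel, sign_convention="log")
        assert log.O[1, 0] == pytest.approx(-1.0)
        neg = ratio_objective(panel, sign_convention="negated_log")
        assert neg.O[1, 0] == pytest.approx(1.0)
        raw = ratio_objective(panel, sign_convention="raw")
        assert raw.O[1, 0] == pytest.approx(0.5)

    def test_unchanged_expression_gives_zero(self):
        panel = steady_panel_from([[2.0], [3.0]], [2.0, 3.0], mutant_ids=["G0"])
        term = ratio_objective(panel, sign_convention="log")
        assert term.O[1, 0] == 0.0

    def test_self_entry_and_uncovered_columns_masked(self):
        panel = steady_panel_from(
            [[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]],
            [1.0, 1.0, 2.0],
            gene_names=["G0", "G1", "G2"],
            mutant_ids=["G0", "G1"],
        )
        term = ratio_objective(panel)
        assert not term.mask[0, 0] and not term.mask[1, 1]
        assert not term.mask[:, 2].any()  # G2 has no knockout column
        assert term.mask[1, 0] and term.mask[0, 1] and term.mask[2, 0]

    def test_floors_nonpositive_wildtype(self):
        panel = steady_panel_from([[1.0]], [0.0], gene_names=["G0"], mutant_ids=["G0"])
        with pytest.warns(UserWarning):
            ratio_objective(panel)


def pair_panel(xi, xj):
    """Panel where genes A and B have the given cross-mutant profiles and the
    deleted genes are unrelated (so pairwise exclusion leaves all columns)."""
    xi = np.asarray(xi, dtype=float)
    m = xi.size
    others = [f"C{k}" for k in range(m)]
    mut = np.vstack([xi, xj, np.ones((m, m))])
    return steady_panel_from(
        mut, np.ones(m + 2), gene_names=["A", "B"] + others, mutant_ids=others
    )


class TestCorrelationObjective:
    def test_identical_profiles_correlate_to_one(self):
        term = correlation_objective(pair_panel([1, 2, 3, 1.5], [1, 2, 3, 1.5]))
        assert term.O[0, 1] == pytest.approx(1.0)
        assert term.O[1, 0] == pytest.approx(1.0)

    def test_antimonotone_profiles_correlate_to_minus_one(self):
        term = correlation_objective(pair_panel([1, 2, 3], [3, 2, 1]))
        assert term.O[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        xi = np.array([1.0, 2.0, 4.0])
        xj = np.array([2.0, 3.0, 9.0])
        expected = float(
            ((xi - xi.mean()) @ (xj - xj.mean()))
            / np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
        )
        term = correlation_objective(pair_panel(xi, xj))
        assert term.O[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_bounded_zero_diagonal(self, steady_panel):
        term = correlation_objective(steady_panel)
        np.testing.assert_allclose(term.O, term.O.T)
        assert np.all(np.abs(term.O) <= 1.0)
        np.testing.assert_array_equal(np.diag(term.O), 0.0)

    def test_own_knockout_columns_excluded_per_pair(self):
        # gene A's engineered zero must not drive its correlations
        mut = np.array(
            [[0.0, 5.0, 5.0],
             [1.0, 1.1, 0.9],
             [9.0, 1.0, 1.1]]
        )
        panel = steady_panel_from(
            mut, np.ones(3), gene_names=["A", "B", "C"],
            mutant_ids=["A", "B", "C"],
        )
        term = correlation_objective(panel)
        # with column A removed for pairs involving A, gene A is constant
        assert abs(term.O[0, 2]) < 0.999

    def test_spearman_flavour(self, steady_panel):
        term = correlation_objective(steady_panel, method="spearman")
        assert term.label == "Sc"
        assert np.all(np.abs(term.O) <= 1.0)

    def test_too_few_mutants(self):
        panel = steady_panel_from(
            np.ones((3, 2)), np.ones(3),
            gene_names=["A", "B", "C"], mutant_ids=["A", "B"],
        )
        with pytest.raises(ValueError, match="3 mutant"):
            correlation_objective(panel)


class TestScaleObjective:
    def base_term(self, o):
        return ObjectiveTerm(O=np.asarray(o, dtype=float), label="custom")

    def test_unit_max_divides_by_max_abs(self):
        term = self.base_term([[0.0, -4.0], [2.0, 0.0]])
        out = scale_objective(term, "unit_max")
        np.testing.assert_allclose(out.O, [[0.0, -1.0], [0.5, 0.0]])

    def test_none_is_identity(self):
        term = self.base_term([[0.0, 3.0], [1.0, 0.0]])
        assert scale_objective(term, "none") is term

    def test_zscore_moments(self, rng):
        term = self.base_term(rng.normal(size=(6, 6)))
        out = scale_objective(term, "zscore")
        vals = out.O[out.mask]
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std() - 1.0) < 1e-9

    def test_all_zero_returned_unchanged(self):
        term = self.base_term(np.zeros((3, 3)))
        assert scale_objective(term, "unit_max") is term
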