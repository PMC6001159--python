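"""Factorial designs, ANOVA decomposition and sensitivity indices."""

import itertools

import numpy as np
import pytest

import ppa
from ppa import sensitivity
from ppa.sensitivity import (
    DesignError,
    anova_decompose,
    build_two_level_design,
    inactive_parameter_ratio,
    pca_generalised_indices,
    total_sensitivity_indices,
)


def _alias_free(design):
    """Brute-force check that no product of <= 4 distinct coded columns
    is the identity column (resolution >= V)."""
    m = design.matrix.astype(int)
    k = design.n_factors
    for r in (2, 3, 4):
        for combo in itertools.combinations(range(k), r):
            prod = np.prod(m[:, combo], axis=1)
            if np.all(prod == 1) or np.all(prod == -1):
                return False
    return True


class TestDesignConstruction:
    def test_two_factors_full_factorial(self):
        d = build_two_level_design(["a", "b"])
        assert d.n_runs == 4
        assert sorted(map(tuple, d.matrix.tolist())) == \
            sorted(itertools.product((-1, 1), repeat=2))

    def test_five_factors_sixteen_runs_resolution_v(self):
        d = build_two_level_design(5, max_runs=64)
        assert d.n_runs == 16
        assert _alias_free(d)

    def test_fifty_factors_use_4096_runs(self, clock):
        factors = [p for p in clock.parameters if p not in clock.fixed_parameters]
        assert len(factors) == 50
        d = build_two_level_design(factors, max_runs=4096,
                                   nominal=clock.parameters)
        assert d.n_runs == 4096
        d.validate()  # balance, orthogonality, Sidon columns

    def test_balance_and_orthogonality(self):
        d = build_two_level_design(9, max_runs=256)
        m = d.matrix.astype(float)
        assert np.all(m.sum(axis=0) == 0)
        gram = m.T @ m
        assert np.allclose(gram, d.n_runs * np.eye(d.n_factors))
        assert _alias_free(d)

    def test_infeasible_budget_reports_minimum(self):
        with pytest.raises(DesignError, match="minimal feasible run count"):
            build_two_level_design(20, max_runs=64)

    def test_levels_are_twenty_percent(self):
        d = build_two_level_design(["k"], nominal={"k": 2.0}, rel_change=0.2)
        assert d.levels("k") == (pytest.approx(1.6), pytest.approx(2.4))
        p0 = d.run_parameters(0)["k"]
        assert p0 in (pytest.approx(1.6), pytest.approx(2.4))


class TestAnova:
    @pytest.fixture(scope="class")
    def design3(self):
        return build_two_level_design(["A", "B", "C"])  # full 2^3

    def test_constant_response_has_no_variance(self, design3):
        dec = anova_decompose(np.full(8, 3.7), design3)
        assert dec.ss_total == pytest.approx(0.0)
        assert all(v == pytest.approx(0.0) for v in dec.ss_factor.values())

    def test_pure_main_effect_takes_all_variance(self, design3):
        y = design3.matrix[:, 0].astype(float)
        dec = anova_decompose(y, design3)
        assert dec.ss_factor["A"] == pytest.approx(dec.ss_total)
        assert dec.ss_factor["B"] == pytest.approx(0.0)
        assert dec.ss_residual == pytest.approx(0.0, abs=1e-10)

    def test_matches_least_squares_oracle(self, design3):
        # y = A + 2 A.B (+ noiseless): compare SS with a direct
        # regression on the full effect matrix
        m = design3.matrix.astype(float)
        y = m[:, 0] + 2.0 * m[:, 0] * m[:, 1]
        dec = anova_decompose(y, design3)
        cols = {"A": m[:, 0], "B": m[:, 1], "C": m[:, 2],
                ("A", "B"): m[:, 0] * m[:, 1],
                ("A", "C"): m[:, 0] * m[:, 2],
                ("B", "C"): m[:, 1] * m[:, 2]}
        X = np.column_stack([np.ones(8), *cols.values()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ss = {name: 8 * b ** 2 for name, b in zip(cols, beta[1:])}
        assert dec.ss_factor["A"] == pytest.approx(ss["A"])
        assert dec.ss_interaction[("A", "B")] == pytest.approx(ss[("A", "B")])
        assert dec.ss_model == pytest.approx(sum(ss.values()))
        assert dec.ss_total == pytest.approx(dec.ss_model + dec.ss_residual)

    def test_non_finite_response_rejected(self, design3):
        y = np.ones(8)
        y[3] = np.nan
        with pytest.raises(ValueError):
            anova_decompose(y, design3)


class TestIndices:
    @pytest.fixture(scope="class")
    def design3(self):
        return build_two_level_design(["A", "B", "C"])

    def test_single_factor_response_gives_unit_index(self, design3):
        y = 5.0 * design3.matrix[:, 1].astype(float)
        idx = total_sensitivity_indices(anova_decompose(y, design3))
        assert idx.tSI["B"] == pytest.approx(1.0)
        assert idx.tSI["A"] == pytest.approx(0.0)
        assert idx.tSI_prime["B"] == pytest.approx(idx.variance)

    def test_interaction_shared_between_both_factors(self, design3):
        m = design3.matrix.astype(float)
        y = m[:, 0] + 2.0 * m[:, 0] * m[:, 1]
        idx = total_sensitivity_indices(anova_decompose(y, design3))
        # SS_A = 8, SS_AB = 32, SS_T = 40
        assert idx.tSI["A"] == pytest.approx(40 / 40)
        assert idx.tSI["B"] == pytest.approx(32 / 40)

    def test_zero_response_defines_zero_indices(self, design3):
        idx = total_sensitivity_indices(anova_decompose(np.zeros(8), design3))
        assert all(v == 0.0 for v in idx.tSI.values())


class TestGeneralisedIndices:
    @pytest.fixture(scope="class")
    def design4(self):
        return build_two_level_design(["A", "B", "C", "D"])

    def test_single_column_reduces_to_plain_tsi(self, design4):
        y = design4.matrix[:, 2].astype(float) + 0.3
        gsi = pca_generalised_indices(y[:, None], design4)
        assert gsi.n_retained == 1
        assert gsi.inertia[0] == pytest.approx(1.0)
        assert gsi.tGSI["C"] == pytest.approx(1.0)

    def test_identical_columns_share_one_component(self, design4):
        y = design4.matrix[:, 0].astype(float)
        gsi = pca_generalised_indices(np.column_stack([y, y]), design4)
        assert gsi.n_retained == 1
        assert gsi.tGSI["A"] == pytest.approx(1.0)

    def test_disjoint_drivers_split_by_variance(self, design4):
        m = design4.matrix.astype(float)
        a = 3.0 * m[:, 0]       # variance 9, driven by A
        b = 1.0 * m[:, 1]       # variance 1, driven by B
        gsi = pca_generalised_indices(np.column_stack([a, b]), design4)
        assert gsi.tGSI["A"] == pytest.approx(0.9, abs=1e-9)
        assert gsi.tGSI["B"] == pytest.approx(0.1, abs=1e-9)

    def test_rank_zero_matrix_gives_zero_indices(self, design4):
        gsi = pca_generalised_indices(np.ones((design4.n_runs, 3)), design4)
        assert all(v == 0.0 for v in gsi.tGSI.values())


class TestInactiveRatio:
    def _gsi(self, tgsi):
        return sensitivity.GeneralisedIndices(
            factors=tuple(tgsi), inertia=np.array([1.0]), n_retained=1,
            component_tSI=[dict(tgsi)], tGSI=dict(tgsi))

    def test_no_inactive_factor_gives_zero(self):
        gsi = self._gsi({"a": 0.5, "b": 0.3, "c": 0.2})
        assert inactive_parameter_ratio(gsi, set(), k=3) == 0.0

    def test_all_inactive_gives_hundred(self):
        gsi = self._gsi({"a": 0.5, "b": 0.3, "c": 0.2})
        assert inactive_parameter_ratio(gsi, {"a", "b", "c"}, k=3) == 100.0

    def test_partial_share(self):
        gsi = self._gsi({"a": 0.6, "b": 0.3, "c": 0.1})
        assert inactive_parameter_ratio(gsi, {"b"}, k=2) == \
            pytest.approx(100 * 0.3 / 0.9)

    def test_k_larger_than_factor_count_rejected(self):
        gsi = self._gsi({"a": 1.0})
        with pytest.raises(ValueError):
            inactive_parameter_ratio(gsi, set(), k=5)


class TestExperiment:
    @pytest.fixture(scope="class")
    def toy_setup(self):
        res = ppa.PrincipalProcessAnalysis(ppa.build_toy_feedback(),
                                           delta=0.1).fit(compute_errors=False)
        factors = tuple(p for p in res.model.parameters)
        design = build_two_level_design(factors, max_runs=256,
                                        nominal=res.model.parameters)
        return res, design

    def test_window_errors_positive_and_complete(self, toy_setup):
        res, design = toy_setup
        table = sensitivity.run_error_experiment(
            res.model, res.schedule, design, window=res.schedule.n_windows,
            reference=res.trajectory)
        x = table.to_numpy()
        assert x.shape == (design.n_runs, len(res.model.variables))
        assert np.isfinite(x).all() and (x >= 0).all()
        assert not table.attrs["failures"]

    def test_column_permutation_is_label_invariant(self, toy_setup):
        res, design = toy_setup
        perm = list(reversed(design.factors))
        d2 = sensitivity.FactorialDesign(
            factors=tuple(perm), nominal=design.nominal,
            rel_change=design.rel_change,
            matrix=design.matrix[:, ::-1].copy(),
            columns=tuple(reversed(design.columns)), q=design.q)
        t1 = sensitivity.run_error_experiment(
            res.model, res.schedule, design, window=1, reference=res.trajectory)
        t2 = sensitivity.run_error_experiment(
            res.model, res.schedule, d2, window=1, reference=res.trajectory)
        # same runs, same parameters per run -> identical error rows
        assert np.allclose(t1.to_numpy(), t2.to_numpy())

    def test_window_parameter_classification_worst_case(self, clock_results):
        cls = sensitivity.window_parameter_classification(
            clock_results.model, clock_results.schedule, window=1)
        # basal degradation and CRY degradation parameters are dropped...
        assert {"kdn", "kdnc", "kdmp", "kdmb", "kdmc"} <= cls
        # ...and V2B appears in a dropped process even though it is also
        # kept elsewhere (worst case keeps it classified as neglected)
        assert "V2B" in cls
        assert "k3" not in cls
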