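import math

import numpy as np
import pandas as pd
import pytest

from healthvep import logit, synthetic
from healthvep.config import PopulationConfig
from healthvep.logit import (DesignInfo, RegressionSpec, SeparationError,
                             build_design, fit_logit, marginal_effects,
                             run_table_suite, wald_joint)


def _two_by_two() -> pd.DataFrame:
    # x=0: 40 events / 60 non-events; x=1: 60 / 40
    rows = ([(0, 1)] * 40 + [(0, 0)] * 60 + [(1, 1)] * 60 + [(1, 0)] * 40)
    return pd.DataFrame(rows, columns=["x", "y"])


def _fit_frame(table, outcome, terms, **kw):
    spec = RegressionSpec(outcome=outcome, main_terms=tuple(terms),
                          fixed_effects=None, **kw)
    design = build_design(table, spec)
    return design, fit_logit(design)


class TestFitLogit:
    def test_two_by_two_matches_log_odds_ratio(self):
        _, fit = _fit_frame(_two_by_two(), "y", ["x"])
        est = fit.coefficients["x"][0]
        assert math.isclose(est, math.log(2.25), abs_tol=1e-8)
        assert math.isclose(fit.coefficients["const"][0],
                            math.log(40 / 60), abs_tol=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 800
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n)
        eta = 0.3 - 0.8 * x1 + 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        _, fit = _fit_frame(table, "y", ["x1", "x2"])
        sm_fit = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
        np.testing.assert_allclose(fit.params, sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(
            [fit.coefficients[c][1] for c in ("const", "x1", "x2")],
            sm_fit.bse, atol=1e-5)
        assert math.isclose(fit.log_likelihood, sm_fit.llf, abs_tol=1e-6)

    def test_separation_detected_and_named(self):
        table = pd.DataFrame({"x": [0] * 50 + [1] * 50,
                              "y": [0] * 50 + [1] * 50})
        with pytest.raises(SeparationError, match="x"):
            _fit_frame(table, "y", ["x"])

    def test_parameter_recovery_generator_defaults(self):
        cfg = PopulationConfig(n_individuals=20_000, seed=15)
        t = synthetic.generate_population(cfg)
        spec = RegressionSpec(
            outcome="vep",
            main_terms=("gs", "pm", "gender", "age", "family_size",
                        "marriage", "education", "urban"),
            second_layer=True, eh_column="e_h_true",
            interactions=("gs", "pm"), fixed_effects="province")
        fit = fit_logit(build_design(t, spec))
        truth = {"gs": cfg.logit_coefs["gs"], "pm": cfg.logit_coefs["pm"],
                 "e_h_true": cfg.logit_coefs["e_h"],
                 "gs_x_e_h_true": cfg.logit_coefs["gs_x_eh"],
                 "pm_x_e_h_true": cfg.logit_coefs["pm_x_eh"]}
        for term, want in truth.items():
            est, se, _, _ = fit.coefficients[term]
            assert abs(est - want) < 3 * se, term


class TestBuildDesign:
    def test_interaction_is_elementwise_product(self):
        table = pd.DataFrame({"y": [0, 1, 0, 1], "gs": [0, 1, 1, 0],
                              "e_h": [0.2, 0.5, 0.0, 0.3]})
        spec = RegressionSpec(outcome="y", main_terms=("gs",),
                              second_layer=True, eh_column="e_h",
                              interactions=("gs",), fixed_effects=None)
        design = build_design(table, spec)
        j = design.columns.index("gs_x_e_h")
        np.testing.assert_allclose(design.X[:, j], [0.0, 0.5, 0.0, 0.0])

    def test_province_reference_coding(self, small_population):
        spec = RegressionSpec(outcome="vep", main_terms=("gs",),
                              fixed_effects="province")
        design = build_design(small_population, spec)
        # groups with constant outcome are dropped (their dummy would separate)
        varying = small_population.groupby("province")["vep"].nunique()
        assert design.fe_levels == int((varying >= 2).sum()) - 1

    def test_subgroup_filter_counts(self, small_population):
        spec = RegressionSpec(outcome="vep", main_terms=("gs",),
                              fixed_effects=None, subgroup=("urban", 1))
        design = build_design(small_population, spec)
        assert len(design.y) == int((small_population["urban"] == 1).sum())

    def test_constant_outcome_errors(self):
        table = pd.DataFrame({"y": [1, 1, 1], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            build_design(table, RegressionSpec(outcome="y", main_terms=("x",),
                                               fixed_effects=None))

    def test_empty_subgroup_errors(self, small_population):
        spec = RegressionSpec(outcome="vep", main_terms=("gs",),
                              fixed_effects=None, subgroup=("urban", 7))
        with pytest.raises(ValueError, match="empty"):
            build_design(small_population, spec)

    def test_interactions_require_second_layer(self):
        with pytest.raises(ValueError, match="second layer"):
            RegressionSpec(outcome="y", main_terms=("x",),
                           interactions=("x",),
                           fixed_effects=None).validate(
                pd.DataFrame({"y": [0, 1], "x": [0, 1]}))

    def test_missing_rows_dropped_and_counted(self, rng):
        table = pd.DataFrame({"y": rng.integers(0, 2, 50).astype(float),
                              "x": rng.normal(size=50)})
        table.loc[:4, "x"] = np.nan
        design = build_design(table, RegressionSpec(
            outcome="y", main_terms=("x",), fixed_effects=None))
        assert design.n_dropped_missing == 5
        assert len(design.y) == 45


class TestMarginalEffects:
    def test_zero_coefficient_zero_ame(self):
        # manual fit with an exactly-zero slope for x2
        X = np.column_stack([np.ones(30), np.linspace(-1, 1, 30),
                             np.linspace(0, 1, 30)])
        design = DesignInfo(X=X, y=np.zeros(30), columns=("const", "x1", "x2"),
                            binary_terms=frozenset(), interaction_of={},
                            n_dropped_missing=0, fe_levels=0)
        fit = logit.FitResult(coefficients={}, log_likelihood=0.0, n_obs=30,
                              converged=True, fe_absorbed=0,
                              columns=("const", "x1", "x2"),
                              params=np.array([0.2, 0.7, 0.0]),
                              cov=np.eye(3) * 1e-4)
        ame = marginal_effects(fit, design)
        assert ame.dydx["x2"][0] == 0.0

    def test_continuous_ame_matches_mean_identity(self, rng):
        # no interactions: AME must equal mean(p(1-p)) * beta to 1e-10
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.9 * x)))).astype(int)
        design, fit = _fit_frame(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        ame = marginal_effects(fit, design)
        X = design.X
        pr = 1 / (1 + np.exp(-(X @ fit.params)))
        want = float(np.mean(pr * (1 - pr)) * fit.coefficients["x"][0])
        assert math.isclose(ame.dydx["x"][0], want, abs_tol=1e-10)

    def test_continuous_ame_matches_finite_difference(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.1 + 0.8 * x)))).astype(int)
        design, fit = _fit_frame(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        ame = marginal_effects(fit, design)
        h = 1e-6
        up = np.column_stack([np.ones(n), x + h]) @ fit.params
        dn = np.column_stack([np.ones(n), x - h]) @ fit.params
        fd = np.mean((1 / (1 + np.exp(-up)) - 1 / (1 + np.exp(-dn))) / (2 * h))
        assert math.isclose(ame.dydx["x"][0], fd, abs_tol=1e-6)

    def test_discrete_ame_with_interaction_matches_bruteforce(self, rng):
        n = 2000
        gs = rng.integers(0, 2, n)
        eh = rng.random(n)
        eta = 0.5 - 0.9 * gs - 1.2 * eh + 1.5 * gs * eh
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        table = pd.DataFrame({"y": y, "gs": gs, "e_h": eh})
        spec = RegressionSpec(outcome="y", main_terms=("gs",),
                              second_layer=True, eh_column="e_h",
                              interactions=("gs",), fixed_effects=None)
        design = build_design(table, spec)
        fit = fit_logit(design)
        ame = marginal_effects(fit, design)
        assert "gs" in ame.discrete_terms
        # brute-force predict-and-difference oracle, interaction updated too
        b = dict(zip(fit.columns, fit.params))
        eta1 = b["const"] + b["gs"] + (b["e_h"] + b["gs_x_e_h"]) * eh
        eta0 = b["const"] + b["e_h"] * eh
        oracle = np.mean(1 / (1 + np.exp(-eta1)) - 1 / (1 + np.exp(-eta0)))
        assert math.isclose(ame.dydx["gs"][0], oracle, abs_tol=1e-10)

    def test_absent_term_errors(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        design, fit = _fit_frame(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        with pytest.raises(KeyError, match="zzz"):
            marginal_effects(fit, design, terms=["zzz"])


class TestWald:
    def test_single_term_equals_z_squared(self, rng):
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.5 * x)))).astype(int)
        _, fit = _fit_frame(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        w = wald_joint(fit, ["x"])
        z = fit.coefficients["x"][2]
        assert math.isclose(w.statistic, z * z, abs_tol=1e-10)
        assert w.df == 1

    def test_missing_term_errors(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        _, fit = _fit_frame(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        with pytest.raises(KeyError, match="nope"):
            wald_joint(fit, ["nope"])


@pytest.fixture(scope="module")
def suite():
    t = synthetic.generate_population(
        PopulationConfig(n_individuals=20_000, seed=42))
    from healthvep.elasticity import assign_eh, fit_elasticity
    t["e_h"] = assign_eh(t, fit_elasticity(t))
    return t, run_table_suite(t)


class TestTableSuite:
    def test_five_blocks_present(self, suite):
        _, results = suite
        assert set(results) == {"table4", "table5", "table6", "table7", "table8"}

    def test_blocks_have_structure(self, suite):
        _, results = suite
        for name in ("table4", "table6"):
            block = results[name]
            assert block["n_obs"] > 0
            assert {"term", "dydx", "z"} <= set(block["rows"][0])
        assert results["table5"]["joint"].df == 2

    def test_subgroup_ns_partition_total(self, suite):
        # exhaustive splits partition the table once rows dropped for
        # constant-outcome fixed-effect cells are added back
        t, results = suite
        total = len(t)

        def full_n(block):
            return block["n_obs"] + block["n_dropped_fe"] + block["n_dropped_missing"]

        t7 = results["table7"]
        assert full_n(t7["urban"]) + full_n(t7["rural"]) == total
        t8 = results["table8"]
        assert sum(full_n(t8[r]) for r in ("east", "central", "west")) == total

    def test_second_layer_gs_more_negative(self, suite):
        # generator defaults reproduce the published sign pattern: adding the
        # elasticity terms strengthens the (negative) subsidy effect
        _, results = suite
        gs4 = next(r for r in results["table4"]["rows"] if r["term"] == "gs")
        gs6 = next(r for r in results["table6"]["rows"] if r["term"] == "gs")
        assert gs6["dydx"] < gs4["dydx"] < 0

    def test_report_renders(self, suite):
        _, results = suite
        for name, block in results.items():
            text = logit.format_report(name, block)
            assert name in text

    def test_failed_subgroup_does_not_abort(self, small_population):
        t = small_population.copy()
        t.loc[t["region"] == "west", "vep"] = 1  # constant outcome in west
        results = run_table_suite(t, eh_column="e_h_true", designs=("table8",))
        blocks = results["table8"]
        assert "error" in blocks["west"]
        assert "error" not in blocks["east"]
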