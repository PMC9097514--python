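"""OLS fitting, sequential ANOVA, stepwise selection and validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formurs.design_space import DesignTable, FactorSpec, build_fcc_ccd
from formurs.response_surface import (ModelSpec, SingularDesignError, Term,
                                      anova, fit_ols, full_quadratic_terms,
                                      kfold_cv, stepwise_select)
from formurs.response_surface import test_set_q2 as q2_score
from formurs.synthetic import DEFAULT_FACTORS, SyntheticTruth, simulate_ccd_responses


def normal_equations_oracle(X, y):
    """Brute-force (X'X)^-1 X'y, independent of the fitting path."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def random_design(rng, n_runs, factors=DEFAULT_FACTORS, response="y"):
    raw = np.column_stack([rng.uniform(f.low, f.high, n_runs) for f in factors])
    data = pd.DataFrame(raw, columns=[f.name for f in factors],
                        index=pd.Index([str(i) for i in range(n_runs)], name="run_id"))
    data[response] = rng.normal(size=n_runs)
    return DesignTable(list(factors), data, [response])


class TestTerm:
    @pytest.mark.parametrize("text,kind,factors", [
        ("CC", "main", ("CC",)),
        ("CC:CT", "interaction", ("CC", "CT")),
        ("CT:CC", "interaction", ("CC", "CT")),  # stored sorted
        ("CT^2", "quadratic", ("CT",)),
        ("1", "intercept", ()),
    ])
    def test_parse(self, text, kind, factors):
        t = Term.parse(text)
        assert (t.kind, t.factors) == (kind, factors)

    def test_self_interaction_rejected(self):
        with pytest.raises(ValueError):
            Term("interaction", ("CC", "CC"))

    def test_heredity_completion(self):
        spec = ModelSpec.from_strings("y", ["CC:CT", "CT^2"])
        assert spec.heredity_violations() == [Term.parse("CC"), Term.parse("CT")]
        fixed = spec.with_heredity()
        assert not fixed.heredity_violations()
        assert set(fixed.labels) == {"CC", "CT", "CC:CT", "CT^2"}


class TestFitOls:
    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(7)
        spec = ModelSpec.from_strings("y", ["CC", "CT", "CC:CT", "CT^2"])
        for _ in range(20):
            design = random_design(rng, rng.integers(8, 21))
            fitted = fit_ols(design, spec)
            coded = design.coded()
            X = np.column_stack([np.ones(design.n_runs), coded.CC, coded.CT,
                                 coded.CC * coded.CT, coded.CT**2])
            expected = normal_equations_oracle(X, design.response("y").to_numpy())
            got = [fitted.coefficients[k] for k in ["1", "CC", "CT", "CC:CT", "CT^2"]]
            assert np.allclose(got, expected, atol=1e-10, rtol=0)

    def test_six_run_fit_equals_oracle(self):
        rng = np.random.default_rng(11)
        design = random_design(rng, 6)
        spec = ModelSpec.from_strings("y", ["CC", "CT"])
        fitted = fit_ols(design, spec)
        coded = design.coded()
        X = np.column_stack([np.ones(6), coded.CC, coded.CT])
        expected = normal_equations_oracle(X, design.response("y").to_numpy())
        assert np.allclose([fitted.coefficients[k] for k in ["1", "CC", "CT"]],
                           expected, atol=1e-10)

    def test_residuals_orthogonal_to_model_columns(self):
        rng = np.random.default_rng(3)
        design = random_design(rng, 15)
        spec = ModelSpec.from_strings("y", ["CC", "CT", "CP", "CC:CP"])
        fitted = fit_ols(design, spec)
        coded = design.coded()
        yhat = fitted.predict({c: coded[c].to_numpy() for c in coded}, coding="coded")
        resid = design.response("y").to_numpy() - yhat
        X = np.column_stack([np.ones(15), coded.CC, coded.CT, coded.CP,
                             coded.CC * coded.CP])
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_constant_response_flags_zero_variance(self):
        rng = np.random.default_rng(0)
        design = random_design(rng, 8)
        design.data["y"] = 5.0
        fitted = fit_ols(design, ModelSpec.from_strings("y", []))
        assert fitted.zero_variance
        assert fitted.r2 == 1.0

    def test_singular_design_names_collinear_terms(self):
        factors = [FactorSpec("A", 0, 1), FactorSpec("B", 0, 1)]
        data = pd.DataFrame({"A": [0, 1, 0, 1, 0.5, 0.5],
                             "B": [0, 1, 0, 1, 0.5, 0.5],  # B duplicates A
                             "y": [1, 2, 3, 4, 5, 6.0]},
                            index=pd.Index(list("abcdef"), name="run_id"))
        design = DesignTable(factors, data, ["y"])
        with pytest.raises(SingularDesignError, match="B"):
            fit_ols(design, ModelSpec.from_strings("y", ["A", "B"]))

    def test_coding_invariance_of_predictions(self, train):
        """Raw-space and coded-space fits of a heredity-respecting spec agree."""
        rng = np.random.default_rng(5)
        terms = ["CC", "CT", "CP", "CC:CT", "CT^2"]
        m_coded = fit_ols(train, ModelSpec.from_strings("size", terms, "coded"))
        m_raw = fit_ols(train, ModelSpec.from_strings("size", terms, "raw"))
        pts = {"CC": rng.uniform(0.1, 0.3, 100), "CT": rng.uniform(3, 7, 100),
               "CP": rng.uniform(0.25, 0.5, 100)}
        a, b = m_coded.predict(pts), m_raw.predict(pts)
        assert np.allclose(a, b, rtol=1e-8)

    def test_raw_coefficients_reproduce_predictions(self, reported_models):
        m = reported_models["size"]
        raw = m.raw_coefficients()
        cc, ct = 0.17, 4.4
        by_hand = (raw["1"] + raw["CC"] * cc + raw["CT"] * ct
                   + raw["CC:CT"] * cc * ct + raw["CT^2"] * ct**2)
        assert by_hand == pytest.approx(
            float(m.predict({"CC": cc, "CT": ct, "CP": 0.3})), rel=1e-12)

    def test_monotone_nesting_of_residual_ss(self, train):
        """Adding a term never increases the residual sum of squares."""
        labels = ["CC", "CT", "CP", "CC:CT", "CC:CP", "CT:CP", "CC^2", "CT^2"]
        prev = np.inf
        for j in range(len(labels) + 1):
            m = fit_ols(train, ModelSpec.from_strings("size", labels[:j]))
            rss = anova(m, train).row("residual")["sum_sq"]
            assert rss <= prev + 1e-8
            prev = rss


class TestAnova:
    def test_sum_of_squares_decomposition(self, train, reported_models):
        for resp, fitted in reported_models.items():
            tbl = anova(fitted, train)
            ss_model = tbl.row("model")["sum_sq"]
            ss_resid = tbl.row("residual")["sum_sq"]
            ss_total = tbl.row("total")["sum_sq"]
            y = train.response(resp).to_numpy()
            assert ss_model + ss_resid == pytest.approx(ss_total, rel=1e-8)
            assert ss_total == pytest.approx(((y - y.mean())**2).sum(), rel=1e-10)
            assert (tbl.row("model")["df"] + tbl.row("residual")["df"]
                    == tbl.row("total")["df"])

    def test_lack_of_fit_plus_pure_error_equals_residual(self, train, reported_models):
        for fitted in reported_models.values():
            tbl = anova(fitted, train)
            assert tbl.has_pure_error
            assert (tbl.row("lack_of_fit")["sum_sq"] + tbl.row("pure_error")["sum_sq"]
                    == pytest.approx(tbl.row("residual")["sum_sq"], rel=1e-8))
            assert (tbl.row("lack_of_fit")["df"] + tbl.row("pure_error")["df"]
                    == tbl.row("residual")["df"])

    def test_center_triplicate_pure_error(self, train, reported_models):
        # sizes {132.3, 138.6, 135.2} at the replicated center -> SS 19.8867, df 2
        tbl = anova(reported_models["size"], train)
        assert tbl.row("pure_error")["sum_sq"] == pytest.approx(19.8867, abs=1e-4)
        assert tbl.row("pure_error")["df"] == 2

    def test_sequential_ss_identities_on_random_models(self):
        """model+residual=total and LOF+PE=residual on 200 random fits."""
        rng = np.random.default_rng(42)
        candidates = full_quadratic_terms(["CC", "CT", "CP"])
        for _ in range(200):
            truth = SyntheticTruth(
                coefficients={"1": rng.normal(), "CC": rng.normal(),
                              "CT": rng.normal()},
                sigma=float(rng.uniform(0.1, 2.0)), seed=int(rng.integers(2**31)))
            design = simulate_ccd_responses(truth)
            k = int(rng.integers(1, 7))
            terms = [candidates[i] for i in rng.choice(len(candidates), k,
                                                       replace=False)]
            spec = ModelSpec("y", tuple(terms)).with_heredity()
            fitted = fit_ols(design, spec)
            tbl = anova(fitted, design)
            assert (tbl.row("model")["sum_sq"] + tbl.row("residual")["sum_sq"]
                    == pytest.approx(tbl.row("total")["sum_sq"], rel=1e-8, abs=1e-12))
            seq = tbl.table[~tbl.table.source.isin(
                ["model", "residual", "lack_of_fit", "pure_error", "total"])]
            assert seq["sum_sq"].sum() == pytest.approx(
                tbl.row("model")["sum_sq"], rel=1e-8, abs=1e-12)
            if tbl.has_pure_error:
                assert (tbl.row("lack_of_fit")["sum_sq"]
                        + tbl.row("pure_error")["sum_sq"]
                        == pytest.approx(tbl.row("residual")["sum_sq"],
                                         rel=1e-8, abs=1e-12))

    def test_no_replicates_omits_lack_of_fit(self):
        rng = np.random.default_rng(1)
        factors = list(DEFAULT_FACTORS)
        raw = np.column_stack([rng.uniform(f.low, f.high, 10) for f in factors])
        data = pd.DataFrame(raw, columns=[f.name for f in factors],
                            index=pd.Index([str(i) for i in range(10)], name="run_id"))
        data["y"] = rng.normal(size=10)
        design = DesignTable(factors, data, ["y"])
        tbl = anova(fit_ols(design, ModelSpec.from_strings("y", ["CC"])), design)
        assert not tbl.has_pure_error
        assert "lack_of_fit" not in set(tbl.table.source)

    def test_against_statsmodels_overall_f(self, train):
        """Independent cross-check of the overall model F via statsmodels OLS."""
        import statsmodels.api as sm

        coded = train.coded()
        X = sm.add_constant(np.column_stack([coded.CC, coded.CT,
                                             coded.CC * coded.CT, coded.CT**2]))
        res = sm.OLS(train.response("size").to_numpy(), X).fit()
        fitted = fit_ols(train, ModelSpec.from_strings("size",
                                                       ["CC", "CT", "CC:CT", "CT^2"]))
        tbl = anova(fitted, train)
        assert tbl.row("model")["F"] == pytest.approx(res.fvalue, rel=1e-10)
        assert fitted.r2 == pytest.approx(res.rsquared, rel=1e-10)


class TestStepwise:
    def test_recovers_sparse_truth_at_low_noise(self):
        """Selected terms equal the generating set in >=90% of simulated designs."""
        truth_terms = {"CC", "CT", "CC:CT"}
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            truth = SyntheticTruth(
                coefficients={"1": 100.0, "CC": 50.0, "CT": 10.0, "CC:CT": 8.0},
                sigma=2.0, seed=i)
            design = simulate_ccd_responses(truth)
            spec = stepwise_select(design, "y")
            if set(spec.labels) == truth_terms:
                hits += 1
        assert hits >= 0.90 * n_sim

    def test_pure_noise_prefers_intercept_only(self):
        """A no-signal response keeps no terms in most replicates."""
        empty = 0
        n_sim = 100
        for i in range(n_sim):
            truth = SyntheticTruth(coefficients={"1": 0.0}, sigma=1.0, seed=1000 + i)
            design = simulate_ccd_responses(truth)
            spec = stepwise_select(design, "y")
            if not spec.terms:
                empty += 1
        assert empty > n_sim / 2

    def test_training_size_column_selects_cc_with_high_r2(self, train):
        # classical stepwise mode: admits the moderate interaction and
        # curvature effects alongside the dominant CC main effect
        spec = stepwise_select(train, "size", criterion="pvalue")
        assert "CC" in spec.labels
        fitted = fit_ols(train, spec)
        assert fitted.r2 >= 0.99

    def test_selected_specs_respect_heredity(self, train):
        for resp in ("size", "PDI", "ZP", "EE"):
            for crit in ("bonferroni", "pvalue", "ebic"):
                sel = stepwise_select(train, resp, criterion=crit)
                assert sel.heredity_violations() == []

    def test_empty_candidate_set_rejected(self, train):
        with pytest.raises(ValueError, match="empty candidate"):
            stepwise_select(train, "size", candidate_terms=[])


class TestPrediction:
    def test_center_point_prediction_equals_replicate_mean(self):
        """When params match the distinct points, least squares reproduces
        the group means, so the center prediction equals the replicate mean."""
        rng = np.random.default_rng(99)
        factors = [FactorSpec("A", -1, 1), FactorSpec("B", -1, 1)]
        corners = [(-1, -1), (1, -1), (-1, 1), (1, 1)]
        rows = corners + [(0, 0)] * 3
        data = pd.DataFrame(rows, columns=["A", "B"],
                            index=pd.Index([str(i) for i in range(7)],
                                           name="run_id"))
        data["y"] = rng.normal(100, 5, size=7)
        design = DesignTable(factors, data, ["y"])
        # intercept + A + B + A:B + A^2: 5 params over 5 distinct points
        fitted = fit_ols(design, ModelSpec.from_strings("y", ["A", "B", "A:B",
                                                             "A^2"]))
        center_mean = data["y"].iloc[4:].mean()
        pred = fitted.predict({"A": 0.0, "B": 0.0}, coding="coded")
        assert pred == pytest.approx(center_mean, rel=1e-10)

    def test_missing_factor_value_raises(self, reported_models):
        with pytest.raises(KeyError, match="missing factor"):
            reported_models["size"].predict({"CC": 0.2})

    def test_extrapolation_flaggable_via_in_cube(self, reported_models):
        m = reported_models["size"]
        inside = m.in_cube({"CC": 0.2, "CT": 5.0, "CP": 0.375})
        outside = m.in_cube({"CC": 0.5, "CT": 5.0, "CP": 0.375})
        assert inside.all() and not outside.any()


class TestCrossValidation:
    def test_noiseless_model_in_span_gives_zero_rmse(self):
        truth = SyntheticTruth(coefficients={"1": 10.0, "CC": 5.0, "CT": -2.0},
                               sigma=0.0, seed=4)
        design = simulate_ccd_responses(truth)
        rmse = kfold_cv(design, ModelSpec.from_strings("y", ["CC", "CT"]),
                        k=5, seed=0)
        assert rmse < 1e-8

    def test_same_seed_reproduces_rmse(self, train):
        spec = ModelSpec.from_strings("size", ["CC", "CT", "CC:CT", "CT^2"])
        assert kfold_cv(train, spec, seed=17) == kfold_cv(train, spec, seed=17)

    def test_rmse_tracks_noise_scale(self):
        """With sigma=5, CV RMSE stays within [0.5, 2] sigma across replicates."""
        sigma = 5.0
        rmses = []
        for i in range(100):
            truth = SyntheticTruth(
                coefficients={"1": 100.0, "CC": 40.0, "CT": 10.0},
                sigma=sigma, seed=2000 + i)
            design = simulate_ccd_responses(truth)
            rmses.append(kfold_cv(design, ModelSpec.from_strings("y", ["CC", "CT"]),
                                  k=5, seed=i))
        rmses = np.array(rmses)
        assert ((rmses > 0.5 * sigma) & (rmses < 2.0 * sigma)).mean() >= 0.95

    def test_k_below_two_rejected(self, train):
        with pytest.raises(ValueError):
            kfold_cv(train, ModelSpec.from_strings("size", ["CC"]), k=1)


class TestQ2:
    def test_perfect_model_scores_one(self):
        truth = SyntheticTruth(coefficients={"1": 1.0, "CC": 2.0}, sigma=0.0, seed=8)
        design = simulate_ccd_responses(truth)
        fitted = fit_ols(design, ModelSpec.from_strings("y", ["CC"]))
        assert q2_score(fitted, design, method="press") == pytest.approx(1.0)
        assert q2_score(fitted, design, method="correlation") == pytest.approx(1.0)

    def test_mean_only_predictions_score_zero_under_press(self, train, test_set):
        fitted = fit_ols(train, ModelSpec.from_strings("size", []))
        # an intercept-only model predicts the training mean everywhere;
        # recentre it on the test mean so yhat == mean(y_test) exactly
        fitted.coefficients["1"] = float(test_set.response("size").mean())
        assert q2_score(fitted, test_set, method="press") == pytest.approx(0.0)

    def test_zero_variance_test_responses_rejected(self, train, reported_models):
        degenerate = train.subset(train.data.index[:3])
        degenerate.data["size"] = 100.0
        with pytest.raises(ValueError, match="zero-variance"):
            q2_score(reported_models["size"], degenerate)


class TestParameterRecovery:
    def test_coefficients_within_three_se_of_truth(self):
        """17-run FCC CCD, signal-to-noise like the dominant-size surface:
        estimated coefficients fall within +-3 SE of truth >=99% of the time."""
        coef = {"1": 135.0, "CC": 70.0, "CT": 1.0, "CC:CT": 4.0, "CT^2": -5.0}
        sigma = 4.2
        truth0 = SyntheticTruth(coefficients=coef, sigma=sigma, seed=0)
        design = simulate_ccd_responses(truth0)
        coded = design.coded()
        X = np.column_stack([np.ones(17), coded.CC, coded.CT,
                             coded.CC * coded.CT, coded.CT**2])
        beta_true = np.array(list(coef.values()))
        rng = np.random.default_rng(123)
        n_rep = 1000
        noise = rng.normal(0.0, sigma, size=(17, n_rep))
        Y = (X @ beta_true)[:, None] + noise
        beta_hat, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        # true sampling SE of each coefficient (sigma known by construction);
        # coverage is counted per coefficient estimate
        se_true = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        inside = np.abs(beta_hat - beta_true[:, None]) <= 3 * se_true[:, None]
        assert inside.mean() >= 0.99
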