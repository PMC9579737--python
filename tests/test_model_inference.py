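import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from floradyn.model_inference import (CandidateModel, enumerate_candidates,
                                      fit_candidate, fit_all, full_average,
                                      r_squared, rank_and_select)


class TestEnumeration:
    def test_no_predictors_no_time_gives_intercept_only(self):
        out = enumerate_candidates([], time=None)
        assert out == [frozenset()]

    @pytest.mark.parametrize("p,expected", [(0, 2), (1, 5), (2, 13), (3, 35)])
    def test_counts_follow_two_and_three_power_rule(self, p, expected):
        preds = [f"x{i}" for i in range(p)]
        assert len(enumerate_candidates(preds)) == expected

    def test_marginality_interaction_requires_both_parents(self):
        for terms in enumerate_candidates(["a", "b"]):
            for t in terms:
                if ":" in t:
                    left, right = t.split(":")
                    assert left in terms and right in terms


def _line_data():
    x = np.arange(5, dtype=float)
    return pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x,
                         "transect": 1, "plot": np.arange(5)})


class TestFlatFits:
    def test_gaussian_exact_line_recovers_slope(self):
        m = fit_candidate(frozenset({"x"}), _line_data(), "y",
                          family="gaussian", flat=True)
        assert m.params["x"] == pytest.approx(3.0, abs=1e-10)
        assert m.resid_var == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_aic_matches_closed_form(self, rng):
        n = 40
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(0, 0.7, size=n)
        df["transect"] = 1
        df["plot"] = np.arange(n)
        m = fit_candidate(frozenset({"x"}), df, "y", "gaussian", flat=True)
        # direct ML likelihood of OLS: -n/2 (log(2 pi ssr/n) + 1)
        X = np.column_stack([np.ones(n), df["x"]])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        ssr = float(np.sum((df["y"] - X @ beta) ** 2))
        ll = -n / 2 * (np.log(2 * np.pi * ssr / n) + 1)
        assert m.loglik == pytest.approx(ll, abs=1e-8)
        assert m.aic == pytest.approx(-2 * ll + 2 * 3, abs=1e-8)  # b0, b1, sigma2

    def test_poisson_intercept_is_log_mean(self):
        df = pd.DataFrame({"y": [1, 2, 3], "transect": 1, "plot": [1, 2, 3]})
        m = fit_candidate(frozenset(), df, "y", "poisson", flat=True)
        assert m.params["Intercept"] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_poisson_requires_counts(self):
        df = pd.DataFrame({"y": [1.5, 2.0], "transect": 1, "plot": [1, 2]})
        with pytest.raises(ValueError, match="integer"):
            fit_candidate(frozenset(), df, "y", "poisson", flat=True)


def _mixed_poisson_data(seed=42, n_tr=6, n_pl=8, reps=4):
    rng = np.random.default_rng(seed)
    bt = rng.normal(0, 0.3, n_tr)
    bp = rng.normal(0, 0.3, (n_tr, n_pl))
    rows = []
    for t in range(n_tr):
        for p in range(n_pl):
            for _ in range(reps):
                x = rng.normal()
                eta = 1.0 + 0.4 * x + bt[t] + bp[t, p]
                rows.append({"transect": t + 1, "plot": p + 1, "x": x,
                             "y": rng.poisson(np.exp(eta))})
    return pd.DataFrame(rows)


class TestPoissonGLMM:
    def test_laplace_fit_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: the same model fitted by lme4 in R."""
        df = _mixed_poisson_data()
        m = fit_candidate(frozenset({"x"}), df, "y", family="poisson")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|transect) + (1|transect:plot), data=d,
                       family=poisson, control=glmerControl(optimizer="bobyqa"))
            co <- summary(m)$coefficients
            cat(sprintf("%.8f %.8f %.8f %.8f %.8f\\n", as.numeric(logLik(m)),
                co[1,1], co[2,1], co[1,2], co[2,2]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ll, b0, b1, se0, se1 = map(float, out.stdout.split())
        assert m.loglik == pytest.approx(ll, abs=1e-2)
        assert m.params["Intercept"] == pytest.approx(b0, abs=1e-3)
        assert m.params["x"] == pytest.approx(b1, abs=1e-3)
        assert m.bse["Intercept"] == pytest.approx(se0, rel=0.05)
        assert m.bse["x"] == pytest.approx(se1, rel=0.05)
        assert m.k == 2 + 2    # two coefficients + two variance components


class TestRankAndSelect:
    def _model(self, mid, aic, k=3):
        return CandidateModel(mid, frozenset({f"m{mid}"}), "f", "gaussian",
                              loglik=-(aic - 2 * k) / 2, k=k,
                              params=pd.Series({"b": 1.0}),
                              bse=pd.Series({"b": 0.1}), converged=True)

    def test_best_model_always_selected(self):
        sel = rank_and_select([self._model(0, 100.0), self._model(1, 120.0)])
        assert sel.selected[0].model_id == 0
        assert sel.weights[0] == pytest.approx(1.0)

    def test_delta_exactly_four_is_excluded(self):
        sel = rank_and_select([self._model(0, 100.0), self._model(1, 104.0),
                               self._model(2, 103.999)])
        ids = [m.model_id for m in sel.selected]
        assert ids == [0, 2]

    def test_equal_aic_gives_half_weights(self):
        sel = rank_and_select([self._model(0, 100.0), self._model(1, 100.0)])
        assert np.allclose(sel.weights, [0.5, 0.5])

    def test_aic_tie_broken_by_parameter_count(self):
        a = self._model(5, 100.0, k=4)
        b = self._model(9, 100.0, k=2)
        sel = rank_and_select([a, b])
        assert sel.selected[0].model_id == 9

    def test_non_converged_candidates_dropped(self):
        bad = self._model(1, 90.0)
        bad.converged = False
        sel = rank_and_select([self._model(0, 100.0), bad])
        assert [m.model_id for m in sel.selected] == [0]


class TestFullAverage:
    def _model(self, mid, aic, params, bse):
        return CandidateModel(mid, frozenset(params), "f", "gaussian",
                              loglik=-(aic - 2 * 2) / 2, k=2,
                              params=pd.Series(params), bse=pd.Series(bse),
                              converged=True)

    def test_single_model_passthrough(self):
        m = self._model(0, 10.0, {"Intercept": 1.0, "x": 2.0},
                        {"Intercept": 0.1, "x": 0.2})
        avg = full_average(rank_and_select([m]))
        coef = avg.coefficients.set_index("term")
        assert coef.loc["x", "estimate"] == pytest.approx(2.0)
        assert coef.loc["x", "se"] == pytest.approx(0.2)
        assert coef.loc["x", "ci_upper"] == pytest.approx(2.0 + 1.96 * 0.2, abs=1e-3)

    def test_zero_substitution_halves_lone_coefficient(self):
        m1 = self._model(0, 10.0, {"Intercept": 0.0, "x": 3.0},
                         {"Intercept": 0.1, "x": 0.0})
        m2 = self._model(1, 10.0, {"Intercept": 0.0}, {"Intercept": 0.1})
        avg = full_average(rank_and_select([m1, m2]))
        coef = avg.coefficients.set_index("term")
        assert coef.loc["x", "estimate"] == pytest.approx(1.5)
        # between-model variance only: 0.5*|3-1.5| + 0.5*|0-1.5| = 1.5
        assert coef.loc["x", "se"] == pytest.approx(1.5)

    def test_averaged_magnitude_bounded_by_largest_single_model(self, rng):
        models = [self._model(i, 10.0 + rng.uniform(0, 3),
                              {"x": float(rng.normal())}, {"x": 0.1})
                  for i in range(5)]
        avg = full_average(rank_and_select(models))
        est = avg.coefficients.set_index("term").loc["x", "estimate"]
        assert abs(est) <= max(abs(m.params["x"]) for m in models) + 1e-12

    def test_table_has_effect_z_and_ci_columns(self):
        m = self._model(0, 10.0, {"x": 2.0}, {"x": 0.5})
        avg = full_average(rank_and_select([m]))
        assert list(avg.coefficients.columns) == [
            "term", "estimate", "se", "abs_z", "ci_lower", "ci_upper"]


class TestRSquared:
    def test_zero_random_variance_marginal_equals_conditional(self):
        m = CandidateModel(0, frozenset(), "f", "gaussian", 0.0, 1,
                           pd.Series(dtype=float), pd.Series(dtype=float),
                           True, fixed_var=1.0, re_var=0.0, resid_var=1.0)
        marg, cond = r_squared(m)
        assert marg == cond == pytest.approx(0.5)

    def test_zero_fixed_variance_marginal_zero(self):
        m = CandidateModel(0, frozenset(), "f", "gaussian", 0.0, 1,
                           pd.Series(dtype=float), pd.Series(dtype=float),
                           True, fixed_var=0.0, re_var=1.0, resid_var=1.0)
        assert r_squared(m)[0] == 0.0

    def test_poisson_not_implemented(self):
        m = CandidateModel(0, frozenset(), "f", "poisson", 0.0, 1,
                           pd.Series(dtype=float), pd.Series(dtype=float), True)
        with pytest.raises(NotImplementedError):
            r_squared(m)

    def test_known_variance_components_recovered(self):
        rng = np.random.default_rng(7)
        n_tr, n_pl, reps = 20, 10, 10        # n = 2000
        rows = []
        bt = rng.normal(0, np.sqrt(0.5), n_tr)
        bp = rng.normal(0, np.sqrt(0.5), (n_tr, n_pl))
        for t in range(n_tr):
            for p in range(n_pl):
                for _ in range(reps):
                    x = rng.normal()           # fixed-effect variance 1
                    y = x + bt[t] + bp[t, p] + rng.normal(0, np.sqrt(2.0))
                    rows.append({"transect": t + 1, "plot": p + 1, "x": x, "y": y})
        df = pd.DataFrame(rows)
        m = fit_candidate(frozenset({"x"}), df, "y", family="gaussian")
        marg, cond = r_squared(m)
        assert marg == pytest.approx(0.25, abs=0.05)
        assert cond == pytest.approx(0.50, abs=0.07)


class TestMixedVsFlat:
    def test_flat_grouping_matches_ols_closed_form(self, rng):
        n = 60
        df = pd.DataFrame({"x": rng.normal(size=n), "transect": 1,
                           "plot": np.arange(n)})
        df["y"] = 0.3 - 0.8 * df["x"] + rng.normal(0, 0.5, n)
        flat = fit_candidate(frozenset({"x"}), df, "y", "gaussian", flat=True)
        X = np.column_stack([np.ones(n), df["x"]])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert np.allclose(flat.params.to_numpy(), beta, atol=1e-8)

    def test_noise_predictor_rarely_improves_best_aic(self, rng):
        n = 120
        df = pd.DataFrame({"time": rng.normal(size=n),
                           "noise": rng.normal(size=n),
                           "transect": 1, "plot": np.arange(n)})
        df["y"] = 1.0 + 0.5 * df["time"] + rng.normal(0, 1.0, n)
        base = min(m.aic for m in fit_all(enumerate_candidates([], time="time"),
                                          df, "y", flat=True))
        withn = min(m.aic for m in fit_all(enumerate_candidates(["noise"]),
                                           df, "y", flat=True))
        assert base - withn < 2.5       # a pure-noise term buys < 2 AIC
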