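"""Logistic fitting, change-in-estimate selection, interaction and
diagnostics, each against independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pacudesat.modeling import (
    ModelSpec,
    SeparationError,
    change_in_estimate_selection,
    c_statistic,
    design_vif,
    condition_indices,
    fit_logistic,
    hosmer_lemeshow,
    interaction_analysis,
    linearity_of_logits,
    stratified_models,
    viable_candidates,
)
from pacudesat.synthetic import simulate_logistic_cohort

from oracles import naive_concordance


def sim(n=20_000, seed=0, **kw):
    defaults = dict(
        coefficients={"intercept": -4.0, "exposure": 0.7, "z1": 0.5, "z2": -0.3},
        covariate_prevalences={"z1": 0.3, "z2": 0.2},
        exposure_model={"intercept": -1.8},
    )
    defaults.update(kw)
    return simulate_logistic_cohort(n, seed=seed, **defaults)


class TestFit:
    def test_null_covariate_aor_near_one(self):
        df = sim(n=60_000, seed=1, coefficients={"intercept": -3.5, "exposure": 0.7, "z1": 0.0, "z2": 0.0})
        fit = fit_logistic(ModelSpec("outcome", ["exposure"], ["z1", "z2"]), df)
        assert fit.aor["z1"] == pytest.approx(1.0, abs=0.15)
        assert fit.ci_low["z1"] < 1.0 < fit.ci_high["z1"]

    def test_matches_statsmodels_reference_fit(self):
        df = sim(n=5_000, seed=2, coefficients={"intercept": -2.5, "exposure": 0.7, "z1": 0.5, "z2": -0.3})
        fit = fit_logistic(ModelSpec("outcome", ["exposure"], ["z1", "z2"]), df)
        X = sm.add_constant(df[["exposure", "z1", "z2"]].astype(float))
        ref = sm.Logit(df["outcome"].astype(float), X).fit(disp=0)
        for term in ("exposure", "z1", "z2"):
            assert fit.params[term] == pytest.approx(ref.params[term], abs=1e-6)

    def test_perfect_separation_detected(self):
        n = 400
        rng = np.random.default_rng(3)
        x = (rng.random(n) < 0.3).astype(int)
        df = pd.DataFrame({"outcome": x, "sep": x, "z": (rng.random(n) < 0.5).astype(int)})
        with pytest.raises(SeparationError):
            fit_logistic(ModelSpec("outcome", ["sep"], ["z"]), df)

    def test_indicator_recode_flips_sign_exactly(self):
        df = sim(n=8_000, seed=4)
        f1 = fit_logistic(ModelSpec("outcome", ["exposure"], ["z1"]), df)
        flipped = df.copy()
        flipped["exposure"] = 1 - flipped["exposure"]
        f2 = fit_logistic(ModelSpec("outcome", ["exposure"], ["z1"]), flipped)
        assert f1.params["exposure"] == pytest.approx(-f2.params["exposure"], abs=1e-8)

    def test_row_order_invariance(self):
        df = sim(n=6_000, seed=5)
        f1 = fit_logistic(ModelSpec("outcome", ["exposure"], ["z1", "z2"]), df)
        f2 = fit_logistic(
            ModelSpec("outcome", ["exposure"], ["z1", "z2"]),
            df.sample(frac=1.0, random_state=7),
        )
        assert f1.params["exposure"] == pytest.approx(f2.params["exposure"], abs=1e-10)


class TestLinearity:
    def _level_frame(self, odds_by_level, n_per=5_000):
        rows = []
        for lev, odds in odds_by_level.items():
            events = int(round(n_per * odds / (1 + odds)))
            rows += [{"v": lev, "y": 1}] * events + [{"v": lev, "y": 0}] * (n_per - events)
        return pd.DataFrame(rows)

    def test_log_linear_odds_stay_ordinal(self):
        df = self._level_frame({0: 0.01, 1: 0.02, 2: 0.04})
        res = linearity_of_logits(df, "v", "y")
        assert res["decision"] == "ordinal"
        steps = res["steps"]
        assert steps[0] == pytest.approx(steps[1], abs=0.02)

    def test_u_shape_becomes_indicator(self):
        df = self._level_frame({0: 0.08, 1: 0.01, 2: 0.08})
        assert linearity_of_logits(df, "v", "y")["decision"] == "indicator"

    def test_binary_is_vacuous_passthrough(self):
        df = self._level_frame({0: 0.02, 1: 0.05})
        res = linearity_of_logits(df, "v", "y")
        assert res["vacuous"]


class TestSelection:
    def test_no_candidates_gives_exposure_only_model(self):
        df = sim(n=5_000, seed=6)
        fit = change_in_estimate_selection(
            ModelSpec("outcome", ["exposure"], []), df, with_diagnostics=False
        )
        assert fit.terms == ["exposure"]
        assert fit.dropped_terms == []

    def test_confounder_retained_noise_dropped_with_refit_oracle(self):
        df = simulate_logistic_cohort(
            30_000,
            {"intercept": -4.2, "exposure": 0.7, "confounder": 1.2, "noise": 0.0},
            {"confounder": 0.4, "noise": 0.3},
            seed=7,
            exposure_model={"intercept": -2.2, "confounder": 1.5},
        )
        spec = ModelSpec("outcome", ["exposure"], ["confounder", "noise"])
        fit = change_in_estimate_selection(spec, df, with_diagnostics=False)
        assert "confounder" in fit.terms
        ledger = {r["term"]: r for r in fit.dropped_terms}
        assert ledger["noise"]["action"] == "dropped"
        assert ledger["confounder"]["action"] == "retained"

        # refit-both-models oracle for the recorded deltas
        def beta(terms):
            X = sm.add_constant(df[terms].astype(float))
            return sm.Logit(df["outcome"].astype(float), X).fit(disp=0).params["exposure"]

        # noise was screened first, against the full model
        d_noise = abs(beta(["exposure", "confounder", "noise"]) - beta(["exposure", "confounder"]))
        assert ledger["noise"]["delta"] == pytest.approx(d_noise, abs=1e-6)
        d_conf = abs(beta(["exposure", "confounder"]) - beta(["exposure"]))
        assert ledger["confounder"]["delta"] == pytest.approx(d_conf, abs=1e-6)
        assert d_conf > 0.10 and d_noise < 0.10

    def test_ledger_replay_reproduces_final_estimates(self):
        df = sim(n=20_000, seed=8)
        spec = ModelSpec("outcome", ["exposure"], ["z1", "z2"])
        fit = change_in_estimate_selection(spec, df, with_diagnostics=False)
        replay = fit_logistic(ModelSpec("outcome", ["exposure"], fit.terms[1:]), df)
        for t in fit.terms:
            assert fit.params[t] == pytest.approx(replay.params[t], abs=1e-10)

    def test_viable_candidates_drops_zero_event_levels(self):
        rng = np.random.default_rng(9)
        n = 500
        df = pd.DataFrame(
            {
                "outcome": (rng.random(n) < 0.05).astype(int),
                "ok": (rng.random(n) < 0.5).astype(int),
                "rare": 0,
            }
        )
        df.loc[0, "rare"] = 1  # a single unexposed-outcome-free patient
        assert viable_candidates(df, "outcome", ["ok", "rare"]) == ["ok"]


class TestInteraction:
    def _df(self, n, beta_es, seed):
        rng = np.random.default_rng(seed)
        e = (rng.random(n) < 0.5).astype(int)
        s = (rng.random(n) < 0.5).astype(int)
        lp = -3.0 + 0.4 * e + 0.3 * s + beta_es * e * s
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        return pd.DataFrame({"outcome": y, "e": e, "s": s})

    def test_relabeling_stratum_transposes_matrix(self):
        df = self._df(30_000, 0.5, 10)
        r1 = interaction_analysis(df, "outcome", "e", "s")
        swapped = df.copy()
        swapped["s"] = 1 - swapped["s"]
        r2 = interaction_analysis(swapped, "outcome", "e", "s")
        # cell (1, 0) under the original coding is cell (1, 1) after relabel,
        # relative to the new reference (0, 1)
        ratio1 = r1.cell_aor[(1, 0)] / r1.cell_aor[(0, 0)]
        ratio2 = r2.cell_aor[(1, 1)] / r2.cell_aor[(0, 1)]
        assert ratio1 == pytest.approx(ratio2, rel=1e-6)

    def test_empty_cell_flags_degenerate(self):
        df = self._df(2_000, 0.0, 11)
        df = df[~((df["e"] == 1) & (df["s"] == 1))]
        res = interaction_analysis(df, "outcome", "e", "s")
        assert res.degenerate

    def test_strong_product_term_triggers_stratification(self):
        res = interaction_analysis(self._df(20_000, 0.8, 12), "outcome", "e", "s")
        assert res.stratify

    def test_stratified_models_isolate_failures(self):
        df = sim(n=20_000, seed=13)
        df["stratum"] = (np.arange(len(df)) % 2 == 0).astype(int)
        # poison one stratum: no events
        df.loc[df["stratum"] == 1, "outcome"] = 0
        out = stratified_models(
            ModelSpec("outcome", ["exposure"], ["z1"]), df, "stratum", with_diagnostics=False
        )
        assert isinstance(out[1], Exception)
        assert not isinstance(out[0], Exception)


class TestDiagnostics:
    def test_separated_scores_give_perfect_c(self):
        c, se = c_statistic(np.array([0.9, 0.8, 0.7, 0.4]), np.array([1, 1, 0, 0]))
        assert c == 1.0

    def test_independent_scores_give_half(self, rng):
        scores = rng.random(20_000)
        y = (rng.random(20_000) < 0.3).astype(int)
        c, se = c_statistic(scores, y)
        assert c == pytest.approx(0.5, abs=0.02)

    def test_c_statistic_matches_brute_force_with_ties(self, rng):
        scores = rng.integers(0, 6, 20).astype(float)  # ties guaranteed
        y = np.array([1] * 8 + [0] * 12)
        c, _ = c_statistic(scores, y)
        assert c == pytest.approx(naive_concordance(scores, y))

    def test_vif_equals_inverse_one_minus_r2(self, rng):
        n = 200
        x1 = rng.normal(0, 1, n)
        x2 = 0.8 * x1 + rng.normal(0, 0.5, n)
        x3 = rng.normal(0, 1, n)
        X = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2, "x3": x3})
        vifs = design_vif(X)
        for col in ("x1", "x2", "x3"):
            others = [c for c in X.columns if c != col]
            r2 = sm.OLS(X[col], X[others]).fit().rsquared
            assert vifs[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_hosmer_lemeshow_matches_hand_grouping(self, rng):
        n = 1000
        p = np.sort(rng.uniform(0.05, 0.6, n))  # 10 clean deciles of 100
        y = (rng.random(n) < p).astype(int)
        stat, dof, pval, used = hosmer_lemeshow(p, y)
        assert used == 10 and dof == 8
        hand = 0.0
        for g in range(10):
            sl = slice(g * 100, (g + 1) * 100)
            pbar = p[sl].mean()
            o = y[sl].sum()
            hand += (o - 100 * pbar) ** 2 / (100 * pbar * (1 - pbar))
        assert stat == pytest.approx(hand, rel=1e-9)

    def test_condition_indices_flag_collinear_design(self, rng):
        n = 300
        x1 = rng.normal(0, 1, n)
        clean = pd.DataFrame({"const": 1.0, "x1": x1, "x2": rng.normal(0, 1, n)})
        collinear = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x1 + rng.normal(0, 1e-4, n)})
        assert max(condition_indices(clean)) < 30
        assert max(condition_indices(collinear)) > 30

    def test_omnibus_equals_lr_chi_square(self):
        df = sim(n=10_000, seed=14)
        fit = fit_logistic(
            ModelSpec("outcome", ["exposure"], ["z1", "z2"]), df, with_diagnostics=True
        )
        assert fit.diagnostics.omnibus_chi2 == pytest.approx(2 * (fit.llf - fit.llnull))
        assert fit.diagnostics.omnibus_df == 3
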