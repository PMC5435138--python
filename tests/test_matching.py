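"""Greedy matching against exhaustive traces; balance and outcome tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pacudesat.matching import (
    MatchedCohort,
    balance_table,
    charges_by_o2_quartile,
    exclude_rare_procedures,
    fit_propensity,
    matched_outcomes,
    nearest_neighbor_match,
    standardized_mean_difference,
)
from pacudesat.simstudies import matching_balance_study
from pacudesat.univariate import TwoByTwo, odds_ratio_woolf

from oracles import naive_greedy_match


def series(d):
    return pd.Series(d)


class TestRareProcedures:
    def test_floor_boundary(self):
        df = pd.DataFrame({"procedure_region": ["a"] * 49 + ["b"] * 50})
        kept, log = exclude_rare_procedures(df, floor=50)
        assert set(kept["procedure_region"]) == {"b"}
        assert log.iloc[0]["category"] == "a" and log.iloc[0]["count"] == 49

    def test_floor_zero_is_identity(self):
        df = pd.DataFrame({"procedure_region": ["a", "b", "c"]})
        kept, log = exclude_rare_procedures(df, floor=0)
        assert len(kept) == 3 and log.empty

    def test_conservation(self):
        df = pd.DataFrame({"procedure_region": ["a"] * 10 + ["b"] * 60 + ["c"] * 3})
        kept, log = exclude_rare_procedures(df, floor=50)
        assert len(kept) + log["count"].sum() == len(df)

    def test_everything_excluded_rejected(self):
        df = pd.DataFrame({"procedure_region": ["a", "b"]})
        with pytest.raises(ValueError):
            exclude_rare_procedures(df, floor=50)


class TestNearestNeighbor:
    def test_spec_trace(self):
        scores = series(
            {"e1": 0.9, "e2": 0.5, "e3": 0.1, "c1": 0.85, "c2": 0.45, "c3": 0.20, "c4": 0.15, "c5": 0.05}
        )
        exposed = series({k: k.startswith("e") for k in scores.index})
        got = nearest_neighbor_match(scores, exposed)
        pairs = list(zip(got.pairs["exposed_id"], got.pairs["control_id"]))
        assert pairs == [("e1", "c1"), ("e2", "c2"), ("e3", "c4")]

    def test_identical_multisets_match_at_zero(self):
        vals = [0.2, 0.4, 0.6]
        scores = series({f"e{i}": v for i, v in enumerate(vals)} | {f"c{i}": v for i, v in enumerate(vals)})
        exposed = series({k: k.startswith("e") for k in scores.index})
        got = nearest_neighbor_match(scores, exposed)
        assert (got.pairs["abs_delta"] == 0).all()
        assert got.n_pairs == 3

    def test_caliper_on_disjoint_ranges_matches_nothing(self):
        scores = series({"e1": 0.9, "e2": 0.8, "c1": 0.1, "c2": 0.2})
        exposed = series({"e1": True, "e2": True, "c1": False, "c2": False})
        got = nearest_neighbor_match(scores, exposed, caliper=0.01)
        assert got.n_pairs == 0
        assert len(got.unmatched_exposed) == 2

    def test_without_replacement_no_control_reused(self, rng):
        scores = series({f"p{i}": rng.random() for i in range(60)})
        exposed = series({f"p{i}": i < 25 for i in range(60)})
        got = nearest_neighbor_match(scores, exposed)
        assert got.pairs["control_id"].is_unique
        assert got.pairs["exposed_id"].is_unique

    def test_matches_exhaustive_trace_on_random_fixtures(self, rng):
        """Greedy output equals a literal transcription of the rule on
        random cohorts of up to 50 patients (ties included)."""
        for trial in range(40):
            n = int(rng.integers(6, 51))
            ids = [f"p{i}" for i in range(n)]
            # coarse grid scores force frequent exact ties
            sc = {i: float(rng.integers(0, 12)) / 11.0 for i in ids}
            is_exp = {i: bool(rng.random() < 0.4) for i in ids}
            if not any(is_exp.values()) or all(is_exp.values()):
                continue
            got = nearest_neighbor_match(series(sc), series(is_exp))
            exp_ids = [i for i in ids if is_exp[i]]
            ctl_ids = [i for i in ids if not is_exp[i]]
            want = naive_greedy_match(sc, exp_ids, ctl_ids)
            assert list(zip(got.pairs["exposed_id"], got.pairs["control_id"])) == want, trial

    def test_greedy_prefix_stability(self, rng):
        scores = series({f"p{i}": float(rng.random()) for i in range(40)})
        exposed = series({f"p{i}": i < 15 for i in range(40)})
        got = nearest_neighbor_match(scores, exposed)
        # remove the control matched to the LAST exposed and re-run:
        # earlier pairs must be unchanged
        last_ctl = got.pairs["control_id"].iloc[-1]
        got2 = nearest_neighbor_match(scores.drop(last_ctl), exposed.drop(last_ctl))
        k = got.n_pairs - 1
        assert got.pairs.iloc[:k][["exposed_id", "control_id"]].values.tolist() == \
            got2.pairs.iloc[:k][["exposed_id", "control_id"]].values.tolist()


class TestPropensity:
    def _records(self, n, seed, strong=False):
        rng = np.random.default_rng(seed)
        z = (rng.random(n) < 0.5).astype(int)
        lp = -0.5 + (2.0 if strong else 0.0) * z
        e = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        return pd.DataFrame({"z": z, "e": e}, index=[f"p{i}" for i in range(n)])

    def test_independent_covariates_give_flat_scores(self):
        rec = self._records(4_000, 20, strong=False)
        scores = fit_propensity(rec, "e", ["z"], procedure_col=None)
        assert scores.std() < 0.03
        assert scores.mean() == pytest.approx(rec["e"].mean(), abs=0.02)

    def test_strong_determinant_discriminates(self):
        rec = self._records(4_000, 21, strong=True)
        scores = fit_propensity(rec, "e", ["z"], procedure_col=None)
        from pacudesat.modeling import c_statistic

        auc, _ = c_statistic(scores.to_numpy(), rec["e"].to_numpy())
        assert auc > 0.6

    def test_row_order_invariance(self):
        rec = self._records(2_000, 22, strong=True)
        s1 = fit_propensity(rec, "e", ["z"], procedure_col=None)
        s2 = fit_propensity(rec.sample(frac=1.0, random_state=5), "e", ["z"], procedure_col=None)
        assert s1.sort_index().round(12).equals(s2.sort_index().round(12))


class TestBalanceAndOutcomes:
    def test_smd_sign_flips_with_group_swap(self, rng):
        x1 = rng.normal(1, 1, 100)
        x0 = rng.normal(0, 1, 100)
        assert standardized_mean_difference(x1, x0, binary=False) == pytest.approx(
            -standardized_mean_difference(x0, x1, binary=False)
        )

    def test_constant_variable_has_zero_smd(self):
        assert standardized_mean_difference(np.ones(10), np.ones(12), binary=True) == 0.0

    def test_duplicate_patients_perfectly_balanced(self, rng):
        n = 200
        rec = pd.DataFrame(
            {
                "z": (rng.random(n) < 0.4).astype(int),
                "x": rng.normal(0, 1, n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        pairs = pd.DataFrame(
            {
                "exposed_id": rec.index[:100],
                "control_id": rec.index[:100],
                "abs_delta": 0.0,
            }
        )
        rec["e"] = 1  # pre-match stats unused in the post assertions
        matched = MatchedCohort(pairs=pairs)
        bal = balance_table(matched, rec, ["z", "x"], "e")
        assert (bal["post_smd"] == 0).all()

    def test_matching_improves_planted_confounder_balance(self):
        res = matching_balance_study(n=4_000, seed=1)
        assert res.pre_smd > 0.4
        assert res.post_smd < 0.1

    def test_matched_binary_outcome_consistent_with_woolf(self, rng):
        n = 300
        rec = pd.DataFrame(
            {
                "y": (rng.random(n) < 0.3).astype(int),
                "charge": rng.lognormal(9, 0.5, n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        pairs = pd.DataFrame(
            {
                "exposed_id": rec.index[:100],
                "control_id": rec.index[100:200],
                "abs_delta": 0.0,
            }
        )
        out = matched_outcomes(MatchedCohort(pairs=pairs), rec, ["charge"], ["y"]).set_index("outcome")
        g1 = rec.loc[pairs["exposed_id"], "y"]
        g0 = rec.loc[pairs["control_id"], "y"]
        t = TwoByTwo(
            a=float((g1 == 1).sum()), b=float((g0 == 1).sum()),
            c=float((g1 == 0).sum()), d=float((g0 == 0).sum()),
        )
        assert out.loc["y", "odds_ratio"] == pytest.approx(odds_ratio_woolf(t)[0])

    def test_identical_outcome_distributions_null(self, rng):
        n = 400
        vals = rng.lognormal(9, 0.4, n // 2)
        rec = pd.DataFrame(
            {"charge": np.concatenate([vals, vals]), "y": [0] * n},
            index=[f"p{i}" for i in range(n)],
        )
        pairs = pd.DataFrame(
            {
                "exposed_id": rec.index[: n // 2],
                "control_id": rec.index[n // 2:],
                "abs_delta": 0.0,
            }
        )
        out = matched_outcomes(MatchedCohort(pairs=pairs), rec, ["charge"], []).set_index("outcome")
        assert out.loc["charge", "p_value"] > 0.9

    def test_charges_by_quartile_counts(self, rng):
        rec = pd.DataFrame(
            {
                "o2_minute_bin": [1, 1, 2, 3, 4, 4],
                "total_charges": [1.0, np.nan, 3.0, 4.0, 5.0, 6.0],
            }
        )
        tab = charges_by_o2_quartile(rec).set_index("o2_quartile")
        assert tab.loc[1, "valid_n"] == 1 and tab.loc[1, "total_n"] == 2
        assert tab.loc[4, "median"] == pytest.approx(5.5)
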