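"""Scan, Bonferroni selection, composites and outcome associations."""

import numpy as np
import pandas as pd
import pytest

from penclock import (associate_composite, associate_mci, bonferroni_threshold,
                      composite_score, group_compare, normalize_features,
                      scan_associations, select_significant,
                      split_sample_composite)
from conftest import make_scan_inputs


@pytest.fixture(scope="module")
def planted():
    """Two loaded features + six noise features against one test score."""
    rng = np.random.default_rng(31)
    V, scores, covars, u = make_scan_inputs(
        400, {"loaded_a": 0.8, "loaded_b": 0.7}, rng, n_noise_features=6)
    results = scan_associations(V, scores, covars)
    return V, scores, covars, results


class TestScan:
    def test_planted_signal_dominates(self, planted):
        _, _, _, results = planted
        r = results.set_index("feature")
        assert r.loc["loaded_a", "p"] < 1e-20
        assert r.loc["loaded_a", "beta"] > 0
        assert r.loc["loaded_a", "p"] < r["p"].drop(["loaded_a", "loaded_b"]).min()

    def test_exact_linear_feature_recovers_slope(self):
        """A test score that is (almost) a pure linear function of one
        normalized feature: beta matches the slope, p underflows."""
        rng = np.random.default_rng(32)
        n = 300
        raw = pd.DataFrame({"f": rng.lognormal(size=n)},
                           index=[f"P{i}" for i in range(n)])
        V = normalize_features(raw)
        scores = pd.DataFrame({"t": 3.0 * V["f"] + 1e-3 * rng.normal(size=n)},
                              index=V.index)
        covars = pd.DataFrame({"age": rng.normal(62, 13, n),
                               "sex": np.where(rng.random(n) < 0.5, "female", "male"),
                               "education": ["high_school"] * n}, index=V.index)
        res = scan_associations(V, scores, covars)
        assert res.loc[0, "beta"] == pytest.approx(3.0, rel=1e-3)
        assert res.loc[0, "p"] < 1e-200

    def test_column_order_invariance(self, planted):
        V, scores, covars, results = planted
        res2 = scan_associations(V[list(V.columns)[::-1]], scores, covars)
        merged = results.merge(res2, on=["feature", "test"], suffixes=("", "_r"))
        np.testing.assert_allclose(merged["beta"], merged["beta_r"], atol=1e-12)

    def test_constant_feature_excluded_with_warning(self, planted, caplog):
        V, scores, covars, _ = planted
        V = V.copy()
        V["flat"] = np.nan  # what a constant raw column normalizes to
        with caplog.at_level("WARNING", logger="penclock"):
            res = scan_associations(V, scores, covars)
        assert "flat" not in set(res["feature"])
        assert any("flat" in m for m in caplog.messages)

    def test_complete_case_n_varies_with_missingness(self, planted):
        V, scores, covars, _ = planted
        V = V.copy()
        V.loc[V.index[:40], "loaded_a"] = np.nan
        res = scan_associations(V, scores, covars).set_index("feature")
        assert res.loc["loaded_a", "n"] == 360
        assert res.loc["loaded_b", "n"] == 400


class TestSelection:
    def test_all_null_p_selects_nothing(self):
        res = pd.DataFrame({"feature": ["a", "b"], "test": ["t", "t"],
                            "beta": [0, 0], "se": [1, 1], "p": [1.0, 1.0],
                            "n": [10, 10]})
        assert select_significant(res) == {"t": []}

    def test_planted_features_selected_exactly(self, planted):
        _, _, _, results = planted
        sel = select_significant(results, alpha=0.05)
        assert set(sel["score"]) == {"loaded_a", "loaded_b"}

    def test_threshold_is_alpha_over_n_features(self, planted):
        _, _, _, results = planted
        thr = bonferroni_threshold(0.05, results["feature"].nunique())
        sel = select_significant(results)
        expected = set(results.loc[results["p"] < thr, "feature"])
        assert set(sel["score"]) == expected
        # family size is per neuropsychological test, not features x tests
        assert thr == 0.05 / 8


class TestComposite:
    def test_single_feature_identity(self, planted):
        V, _, _, results = planted
        res = results.copy()
        res.loc[res.feature == "loaded_a", "beta"] = 1.0
        comp = composite_score({"score": ["loaded_a"]}, res, V)["score"]
        assert comp.m == 1
        np.testing.assert_allclose(comp.scores.to_numpy(), V["loaded_a"].to_numpy())

    def test_opposite_weights_cancel(self):
        V = pd.DataFrame({"a": [1.0, -0.5, 2.0], "b": [1.0, -0.5, 2.0]},
                         index=list("xyz"))
        res = pd.DataFrame({"feature": ["a", "b"], "test": ["t", "t"],
                            "beta": [1.0, -1.0], "se": [1, 1],
                            "p": [0.001, 0.001], "n": [3, 3]})
        comp = composite_score({"t": ["a", "b"]}, res, V)["t"]
        np.testing.assert_allclose(comp.scores.to_numpy(), 0.0, atol=1e-15)

    def test_hand_computed_three_participant_example(self):
        # spreadsheet oracle: score_i = (b1*V_i1 + b2*V_i2) / 2
        V = pd.DataFrame({"f1": [0.5, -1.0, 2.0], "f2": [1.5, 0.0, -0.5]},
                         index=list("abc"))
        res = pd.DataFrame({"feature": ["f1", "f2"], "test": ["t", "t"],
                            "beta": [0.4, -0.2], "se": [1, 1],
                            "p": [1e-5, 1e-5], "n": [3, 3]})
        comp = composite_score({"t": ["f1", "f2"]}, res, V)["t"]
        expected = (0.4 * V["f1"] + (-0.2) * V["f2"]) / 2
        np.testing.assert_allclose(comp.scores.to_numpy(),
                                   expected.to_numpy(), atol=1e-12)
        # plain-sum variant is exactly m times the weighted mean
        comp_sum = composite_score({"t": ["f1", "f2"]}, res, V, scaling="sum")["t"]
        np.testing.assert_allclose(comp_sum.scores.to_numpy(),
                                   2 * expected.to_numpy(), atol=1e-12)

    def test_missing_contributor_makes_score_missing(self):
        V = pd.DataFrame({"f1": [0.5, np.nan], "f2": [1.0, 1.0]}, index=list("ab"))
        res = pd.DataFrame({"feature": ["f1", "f2"], "test": ["t", "t"],
                            "beta": [1.0, 1.0], "se": [1, 1],
                            "p": [0.0001, 0.0001], "n": [2, 2]})
        strict = composite_score({"t": ["f1", "f2"]}, res, V)["t"].scores
        assert np.isnan(strict["b"]) and np.isfinite(strict["a"])
        renorm = composite_score({"t": ["f1", "f2"]}, res, V,
                                 missing="renormalize")["t"].scores
        assert renorm["b"] == pytest.approx(1.0)

    def test_empty_selection_produces_no_composite(self, planted):
        V, _, _, results = planted
        assert composite_score({"score": []}, results, V) == {}

    def test_composite_features_equal_selection(self, planted):
        V, _, _, results = planted
        sel = select_significant(results)
        comps = composite_score(sel, results, V)
        for test, comp in comps.items():
            assert set(comp.weights) == set(sel[test])


class TestAssociateComposite:
    def test_composite_beats_median_constituent(self, planted):
        V, scores, covars, results = planted
        sel = select_significant(results)
        comps = composite_score(sel, results, V)
        table = associate_composite(comps, scores, covars)
        row = table.set_index("test").loc["score"]
        constituent_p = results.set_index("feature").loc[sel["score"], "p"]
        assert row["p"] <= np.median(constituent_p)
        assert row["m"] == len(sel["score"]) and row["n"] == 400

    def test_p_invariant_to_mean_vs_sum_scaling(self, planted):
        """Rescaling a predictor rescales beta and SE identically."""
        V, scores, covars, results = planted
        sel = select_significant(results)
        t_mean = associate_composite(composite_score(sel, results, V, scaling="mean"),
                                     scores, covars)
        t_sum = associate_composite(composite_score(sel, results, V, scaling="sum"),
                                    scores, covars)
        assert t_mean.loc[0, "p"] == pytest.approx(t_sum.loc[0, "p"], rel=1e-9)
        m = t_mean.loc[0, "m"]
        assert t_mean.loc[0, "beta"] == pytest.approx(m * t_sum.loc[0, "beta"], rel=1e-9)

    def test_bonferroni_reporting_capped_at_one(self):
        V = pd.DataFrame({"f": np.random.default_rng(0).normal(size=50)},
                         index=[f"P{i}" for i in range(50)])
        res = pd.DataFrame({"feature": ["f"], "test": ["t"], "beta": [0.01],
                            "se": [1], "p": [0.2], "n": [50]})
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"t": rng.normal(size=50)}, index=V.index)
        covars = pd.DataFrame({"age": rng.normal(60, 10, 50),
                               "sex": ["female"] * 25 + ["male"] * 25,
                               "education": ["some_college"] * 50}, index=V.index)
        comps = composite_score({"t": ["f"]}, res, V)
        out = associate_composite(comps, scores, covars, n_report_tests=18)
        assert out.loc[0, "p_bonferroni"] <= 1.0


class TestSameSampleVsSplit:
    def test_same_sample_selection_is_anticonservative_under_null(self):
        """Selecting and testing on one sample inflates the composite's
        null rejection rate; the split-sample mode stays calibrated."""
        rng = np.random.default_rng(41)
        same_p, split_p = [], []
        for _ in range(100):
            V, scores, covars, _ = make_scan_inputs(
                120, {}, rng, n_noise_features=5)
            scores["score"] = rng.normal(size=120)  # pure null
            res = scan_associations(V, scores, covars)
            sel = select_significant(res, n_tests=1)  # permissive family of 1
            comps = composite_score(sel, res, V)
            if comps:
                same_p.append(float(associate_composite(
                    comps, scores, covars).loc[0, "p"]))
            sp = split_sample_composite(V, scores, covars, rng, n_tests=1)
            if len(sp):
                split_p.append(float(sp.loc[0, "p"]))
        assert np.mean(np.array(same_p) < 0.05) > 0.30
        assert np.mean(np.array(split_p) < 0.05) < 0.20

    def test_split_sample_still_detects_planted_signal(self):
        rng = np.random.default_rng(42)
        V, scores, covars, _ = make_scan_inputs(
            400, {"loaded_a": 0.8, "loaded_b": 0.7}, rng, n_noise_features=4)
        out = split_sample_composite(V, scores, covars, rng)
        assert len(out) == 1
        assert out.loc[0, "p"] < 1e-6


class TestAssociateMci:
    @pytest.fixture(scope="class")
    def mci_cohort(self):
        """Latent g drives features, battery and the MCI tail."""
        rng = np.random.default_rng(51)
        n = 1500
        V, scores, covars, u = make_scan_inputs(
            n, {f"load{j}": 0.7 for j in range(4)}, rng, n_noise_features=2)
        mci = pd.Series(np.zeros(n, dtype=int), index=V.index)
        mci.iloc[np.argsort(u)[:40]] = 1
        return V, scores, covars, mci

    def test_low_event_count_refused_with_guidance(self, mci_cohort):
        V, scores, covars, mci = mci_cohort
        few = mci.copy()
        few.iloc[:] = 0
        few.iloc[:5] = 1
        with pytest.raises(ValueError, match="min_events"):
            associate_mci(scores, covars, few)

    def test_composite_protective_direction(self, mci_cohort):
        """Higher-is-better composites carry negative MCI log-odds."""
        V, scores, covars, mci = mci_cohort
        res = scan_associations(V, scores, covars)
        comps = composite_score(select_significant(res), res, V)
        pred = pd.DataFrame({"composite": comps["score"].scores})
        out = associate_mci(pred, covars, mci)
        row = out.set_index("predictor").loc["composite"]
        assert row["converged"]
        assert row["coef"] < 0
        assert row["p"] < bonferroni_threshold(0.05, 18)

    def test_education_dummies_enter_mci_model_only(self, mci_cohort):
        V, scores, covars, mci = mci_cohort
        out = associate_mci(scores[["score"]], covars, mci)
        assert set(out.columns) >= {"predictor", "coef", "se", "p", "n",
                                    "converged", "significant"}
        assert out.loc[0, "n"] <= len(V)

    def test_null_predictor_not_significant_at_battery_threshold(self, mci_cohort):
        V, scores, covars, mci = mci_cohort
        rng = np.random.default_rng(52)
        pred = pd.DataFrame({"noise": rng.normal(size=len(V))}, index=V.index)
        out = associate_mci(pred, covars, mci)
        assert not out.loc[0, "significant"] or out.loc[0, "p"] >= 0


class TestGroupCompare:
    def make_cohort(self, rng, n=400, n_mci=30):
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "age": rng.normal(62, 13, n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "education": rng.choice(["no_high_school", "high_school",
                                     "some_college", "college_plus"], n),
            "mci": [1] * n_mci + [0] * (n - n_mci),
        })
        df["Trail Making Test A"] = rng.normal(32, 17, n)
        return df

    def test_gender_chi_square_matches_count_arithmetic(self):
        """2x2 table with 21/15 women/men among cases and 1044/982 among
        controls gives a chi-square p near one half."""
        rows = ([{"sex": "female", "mci": 1}] * 21 + [{"sex": "male", "mci": 1}] * 15
                + [{"sex": "female", "mci": 0}] * 1044
                + [{"sex": "male", "mci": 0}] * 982)
        df = pd.DataFrame(rows)
        df["age"] = 62.0
        df["age"] += np.random.default_rng(0).normal(size=len(df))
        df["education"] = "high_school"
        df["participant_id"] = [f"P{i}" for i in range(len(df))]
        table = group_compare(df)
        p = table.loc[table.variable == "sex=female", "p"].iloc[0]
        assert p == pytest.approx(0.5, abs=0.1)
        assert "21 (58.3)" in table.loc[table.variable == "sex=female", "mci"].iloc[0]

    def test_identical_groups_rank_sum_p_one(self):
        rng = np.random.default_rng(61)
        df = self.make_cohort(rng)
        df["Trail Making Test A"] = 30.0  # identical in both groups
        table = group_compare(df)
        p = table.loc[table.variable == "Trail Making Test A", "p"].iloc[0]
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(62)
        df = self.make_cohort(rng, n_mci=0)
        with pytest.raises(ValueError):
            group_compare(df)
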