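"""PLS-DA, cross-validated Q2, multilevel transform, selection, tiles."""

import numpy as np
import pandas as pd
import pytest

from mdinet import multivariate as mv
from mdinet import preprocess as pp


def make_xy(n_per_class=20, n_features=50, n_informative=5, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(2 * n_per_class, n_features)),
        columns=[f"F{i:04d}" for i in range(n_features)],
    )
    y = np.array(["risk"] * n_per_class + ["nonrisk"] * n_per_class)
    X.iloc[:n_per_class, :n_informative] += effect
    return X, y


class TestFitPlsda:
    def test_perfect_single_feature(self):
        y = np.array(["risk"] * 10 + ["nonrisk"] * 10)
        X = pd.DataFrame({"F1": np.where(y == "risk", 1.0, -1.0)})
        model = mv.fit_plsda(X, y, n_components=1, positive_label="risk")
        assert model.r2 == pytest.approx(1.0)
        assert model.coefficients["F1"] > 0  # positive = higher in risk

    def test_single_class_rejected(self):
        X = pd.DataFrame({"F1": np.arange(6.0)})
        with pytest.raises(ValueError):
            mv.fit_plsda(X, ["risk"] * 6, positive_label="risk")

    def test_duplicated_sample_keeps_signs(self):
        X, y = make_xy(seed=3)
        m1 = mv.fit_plsda(X, y, 2, positive_label="risk")
        X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
        y2 = np.concatenate([y, y[:1]])
        m2 = mv.fit_plsda(X2, y2, 2, positive_label="risk")
        informative = [f"F{i:04d}" for i in range(5)]
        assert (
            np.sign(m1.coefficients[informative]) == np.sign(m2.coefficients[informative])
        ).all()

    def test_constant_feature_dropped(self):
        X, y = make_xy(seed=4)
        X["constant"] = 1.0
        model = mv.fit_plsda(X, y, 2, positive_label="risk")
        assert "constant" not in model.coefficients.index


class TestQ2:
    def test_separable_data_high_q2(self):
        X, y = make_xy(n_per_class=25, n_informative=10, effect=4.0, seed=1)
        q2, _ = mv.crossvalidated_q2(X, y, 7, 2, seed=0, positive_label="risk")
        assert q2 > 0.9

    def test_permuted_labels_nonpositive_on_average(self):
        X, y = make_xy(n_per_class=25, effect=2.0, seed=2)
        rng = np.random.default_rng(0)
        q2s = [
            mv.crossvalidated_q2(X, rng.permutation(y), 7, 2, seed=i, positive_label="risk")[0]
            for i in range(30)
        ]
        assert np.mean(q2s) <= 0.0

    def test_q2_not_above_r2_on_informative_data(self):
        X, y = make_xy(n_per_class=25, effect=3.0, seed=5)
        q2, _ = mv.crossvalidated_q2(X, y, 7, 2, seed=0, positive_label="risk")
        model = mv.fit_plsda(X, y, 2, positive_label="risk")
        assert q2 <= model.r2 <= 1.0

    def test_order_invariance(self):
        X, y = make_xy(seed=6)
        q2a, _ = mv.crossvalidated_q2(X, y, 7, 2, seed=3, positive_label="risk")
        perm = np.random.default_rng(0).permutation(X.shape[1])
        q2b, _ = mv.crossvalidated_q2(X.iloc[:, perm], y, 7, 2, seed=3, positive_label="risk")
        assert q2a == pytest.approx(q2b, abs=1e-10)

    def test_unstratifiable_folds_rejected(self):
        X, y = make_xy(n_per_class=5)
        with pytest.raises(ValueError):
            mv.crossvalidated_q2(X, y, folds=7, n_components=2, positive_label="risk")


class TestIterativeSelection:
    def test_informative_features_recovered(self):
        X, y = make_xy(n_per_class=25, n_features=1000, n_informative=50, effect=2.0, seed=7)
        trace, final = mv.iterative_feature_selection(X, y, seed=0, positive_label="risk")
        informative = {f"F{i:04d}" for i in range(50)}
        hits = informative & set(final.feature_ids)
        assert len(hits) / 50 >= 0.8  # recall
        # the final subset is strongly enriched for the informative features
        from mdinet.enrichment import hypergeom_pvalue

        p = hypergeom_pvalue(1000, 50, len(final.feature_ids), len(hits), "upper")
        assert p < 0.01

    def test_keep_fraction_one_single_iteration(self):
        X, y = make_xy(seed=8)
        trace, final = mv.iterative_feature_selection(
            X, y, keep_fraction=1.0, seed=0, positive_label="risk"
        )
        assert len(trace.iterations) == 1
        assert list(final.feature_ids) == list(X.columns)

    def test_subsets_strictly_shrink(self):
        X, y = make_xy(n_features=200, seed=9)
        trace, _ = mv.iterative_feature_selection(X, y, seed=0, positive_label="risk")
        sizes = [len(it["features"]) for it in trace.iterations]
        assert all(b < a for a, b in zip(sizes, sizes[1:]))
        assert trace.to_frame()["final"].sum() == 1


class TestMultilevelTransform:
    @staticmethod
    def ogtt_matrix(effect=0.0, noise=0.0, subject_sd=1.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, prefix in (("risk", "R"), ("nonrisk", "N")):
            for i in range(n):
                rows.append((f"{prefix}{i}", g))
        sample_ids, subjects, groups, tps = [], [], [], []
        values = {"F1": []}
        for subj, g in rows:
            intercept = rng.normal(0, subject_sd)
            for tp in ("t0", "t1", "t2"):
                sample_ids.append(f"{subj}_{tp}")
                subjects.append(subj)
                groups.append(g)
                tps.append(tp)
                shift = effect if (g == "risk" and tp == "t1") else 0.0
                values["F1"].append(20.0 + intercept + shift + rng.normal(0, noise))
        features = pd.DataFrame({"mz": [200.0]}, index=pd.Index(["F1"], name="feature_id"))
        X = pd.DataFrame([values["F1"]], index=features.index, columns=sample_ids)
        samples = pd.DataFrame(
            {"subject_id": subjects, "timepoint": tps, "group": groups},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return pp.FeatureMatrix(features, X, samples, state="log2")

    def test_subject_intercept_cancels(self):
        m = self.ogtt_matrix(effect=0.0, noise=0.0, subject_sd=5.0)
        out = mv.multilevel_transform(m)
        imm, groups = out["immediate"]
        assert np.allclose(imm.to_numpy(), 0.0)

    def test_injected_effect_appears_in_response(self):
        m = self.ogtt_matrix(effect=1.0, noise=0.0, subject_sd=2.0)
        imm, groups = mv.multilevel_transform(m)["immediate"]
        risk_mean = imm.loc[(groups == "risk").to_numpy(), "F1"].mean()
        ctrl_mean = imm.loc[(groups == "nonrisk").to_numpy(), "F1"].mean()
        assert risk_mean - ctrl_mean == pytest.approx(1.0)

    def test_single_timepoint_rejected(self):
        m = self.ogtt_matrix()
        only_t0 = (m.samples["timepoint"] == "t0").to_numpy()
        m2 = pp.FeatureMatrix(
            m.features,
            m.intensities.loc[:, only_t0],
            m.samples.loc[only_t0],
            state="log2",
        )
        with pytest.raises(ValueError):
            mv.multilevel_transform(m2)


class TestReplicationSelect:
    @staticmethod
    def responses(pattern="updown", effect=2.0, seed=0, n=15):
        rng = np.random.default_rng(seed)
        subjects = [f"R{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
        groups = pd.Series(
            ["risk"] * n + ["nonrisk"] * n, index=pd.Index(subjects, name="subject_id")
        )
        imm = pd.DataFrame(
            {"F1": rng.normal(0, 0.5, 2 * n)}, index=groups.index
        )
        short = pd.DataFrame({"F1": rng.normal(0, 0.5, 2 * n)}, index=groups.index)
        sign = 1.0 if pattern == "updown" else -1.0
        imm.loc[groups == "risk", "F1"] += sign * effect
        short.loc[groups == "risk", "F1"] -= sign * effect
        return imm, short, groups

    def test_up_then_down_selected(self):
        imm, short, groups = self.responses("updown")
        out = mv.replication_select(imm, short, groups)
        assert bool(out.loc["F1", "selected"])

    def test_reversed_pattern_rejected(self):
        imm, short, groups = self.responses("downup")
        out = mv.replication_select(imm, short, groups)
        assert not bool(out.loc["F1", "selected"])

    def test_correct_medians_but_weak_evidence_rejected(self):
        imm, short, groups = self.responses("updown", effect=0.05, seed=3)
        out = mv.replication_select(imm, short, groups)
        if (
            out.loc["F1", "median_immediate_risk"] > out.loc["F1", "median_immediate_nonrisk"]
            and out.loc["F1", "median_short_risk"] < out.loc["F1", "median_short_nonrisk"]
        ):
            assert bool(out.loc["F1", "selected"]) == bool(
                (out.loc["F1", "p_immediate"] < 0.1) or (out.loc["F1", "p_short"] < 0.1)
            )

    def test_empty_group_rejected(self):
        imm, short, groups = self.responses()
        with pytest.raises(ValueError):
            mv.replication_select(imm, short, groups.str.replace("nonrisk", "risk"))


class TestTileStatistics:
    def test_pooled_variance_t_matches_hand_formula(self):
        X = pd.DataFrame({"F1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, index=list("abcdef"))
        groups = pd.Series(["risk"] * 3 + ["nonrisk"] * 3, index=X.index)
        out = mv.group_ttest(X, groups)
        # pooled variance: sp2 = 1.0; t = (2 - 5) / sqrt(1 * (1/3 + 1/3))
        expected_t = -3.0 / np.sqrt(2.0 / 3.0)
        assert out.loc["F1", "t_statistic"] == pytest.approx(expected_t)
        assert out.loc["F1", "mean_difference"] == pytest.approx(-3.0)

    def test_identical_groups_nonsignificant(self):
        X = pd.DataFrame({"F1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, index=list("abcdef"))
        groups = pd.Series(["risk"] * 3 + ["nonrisk"] * 3, index=X.index)
        out = mv.group_ttest(X, groups)
        assert out.loc["F1", "mean_difference"] == 0.0
        assert out.loc["F1", "p_value"] > 0.9

    def test_single_sample_groups_flagged_undefined(self):
        X = pd.DataFrame({"F1": [1.0, 2.0]}, index=["a", "b"])
        groups = pd.Series(["risk", "nonrisk"], index=X.index)
        out = mv.group_ttest(X, groups)
        assert bool(out.loc["F1", "undefined"])

    def test_five_panels(self):
        m = TestMultilevelTransform.ogtt_matrix(effect=1.0, noise=0.1, seed=5)
        tiles = mv.tile_statistics(m)
        assert sorted(tiles["panel"].unique()) == sorted(["t0", "t1", "t2", "t1-t0", "t2-t1"])
        t1 = tiles.loc[tiles["panel"] == "t1-t0"].iloc[0]
        assert t1["p_value"] < 0.05 and t1["mean_difference"] > 0
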