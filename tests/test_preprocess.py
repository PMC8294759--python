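"""Preprocessing: filtering, feasibility, calibration, alignment, cleaning."""

import numpy as np
import pandas as pd
import pytest

from mdinet import preprocess as pp
from mdinet.masscalc import adduct_mz, PROTONATED
from mdinet.synthetic_data import mouse_design, ogtt_design, simulate_study


def peaks_df(mz, intensity=None, snr=None):
    n = len(mz)
    df = pd.DataFrame({"mz": mz, "intensity": intensity if intensity is not None else [1e7] * n})
    if snr is not None:
        df["snr"] = snr
    return df


class TestFilterPeaks:
    def test_all_above_thresholds_unchanged(self):
        df = peaks_df([200.0, 300.0], [2e6, 3e6], [10, 10])
        assert pp.filter_peaks(df).equals(df)

    def test_intensity_boundary(self):
        df = peaks_df([200.0, 300.0], [1.4e6, 1.5e6], [10, 10])
        out = pp.filter_peaks(df)
        assert list(out["mz"]) == [300.0]  # 1.5e6 kept (>=), 1.4e6 dropped

    def test_snr_filter_and_empty(self):
        df = peaks_df([200.0], [1e7], [3.9])
        assert len(pp.filter_peaks(df)) == 0
        assert len(pp.filter_peaks(df.iloc[:0])) == 0


class TestMassDefectFeasibility:
    def test_real_compounds_feasible(self, small_library):
        mzs = np.array([adduct_mz(r.formula, PROTONATED) for r in small_library[:40]])
        assert pp.feasible_mask(mzs).all()

    def test_arginine_feasible(self):
        assert pp.mass_defect_feasible(adduct_mz("C6H14N4O2"))

    def test_low_mass_gap_infeasible(self):
        # 150.50 sits in a genuine gap: exhaustive enumeration finds no
        # CHNOPS+Na composition within 1 ppm (the low-mass region is sparse)
        assert not pp.mass_defect_feasible(150.50)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.mass_defect_feasible(50.0)


class TestCalibration:
    refs = [175.119, 250.1, 350.2, 450.3, 550.4, 650.5]

    def test_zero_error_near_identity(self):
        df = peaks_df(self.refs)
        out, model = pp.calibrate(df, self.refs)
        assert model.applied
        assert model.residual_sd_ppm == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out["mz"], df["mz"], rtol=1e-12)

    def test_constant_offset_recovered(self):
        true = np.array(self.refs)
        observed = true * (1 + 0.5e-6)  # +0.5 ppm systematic error
        out, model = pp.calibrate(peaks_df(observed), list(true))
        err_ppm = (out["mz"].to_numpy() - true) / true * 1e6
        assert np.max(np.abs(err_ppm)) < 0.05

    def test_smooth_error_recovered_below_threshold(self):
        rng = np.random.default_rng(5)
        true = np.sort(rng.uniform(150, 900, 60))
        drift = 0.3 + 0.001 * (true - 500) * 1e-0 * 1e-3  # smooth ppm drift
        observed = true * (1 + drift * 1e-6)
        out, model = pp.calibrate(peaks_df(observed), list(true))
        assert model.residual_sd_ppm < 0.1
        err_ppm = (out["mz"].to_numpy() - true) / true * 1e6
        assert np.abs(err_ppm[true < 500]).max() < 0.1

    def test_too_few_matches_refused(self):
        df = peaks_df([200.0, 300.0, 400.0])
        out, model = pp.calibrate(df, [200.0, 300.0, 400.0])
        assert not model.applied
        assert out.equals(df)


class TestAlignment:
    def test_identical_lists_full_matrix(self):
        df = peaks_df([200.0, 300.0, 400.0])
        m = pp.align_features({"a": df, "b": df, "c": df})
        assert m.n_features == 3
        assert not m.intensities.isna().any().any()

    def test_window_separation(self):
        close = {"a": peaks_df([500.0]), "b": peaks_df([500.0 + 500 * 0.5e-6])}
        far = {"a": peaks_df([500.0]), "b": peaks_df([500.0 + 500 * 5e-6])}
        assert pp.align_features(close).n_features == 1  # 0.5 ppm apart
        assert pp.align_features(far).n_features == 2  # 5 ppm apart

    def test_sample_order_invariance(self, mouse_dataset):
        pk, meta, _, _ = mouse_dataset
        m1 = pp.align_features(pk)
        m2 = pp.align_features(dict(reversed(list(pk.items()))))
        np.testing.assert_allclose(
            m1.features["mz"].to_numpy(), m2.features["mz"].to_numpy(), atol=1e-9
        )
        assert m1.intensities.equals(m2.intensities)

    def test_agreement_with_complete_linkage_oracle(self):
        """On instances with separated features, greedy alignment matches a
        brute-force complete-linkage clustering at the same ppm window."""
        from scipy.cluster.hierarchy import fcluster, linkage

        rng = np.random.default_rng(17)
        agree = 0
        n_instances = 20
        for _ in range(n_instances):
            centers = np.sort(rng.uniform(150, 990, 40))
            centers = centers[np.diff(np.concatenate([[0], centers])) > 0.05]
            peaks, labels = [], []
            for i, c in enumerate(centers):
                for _ in range(rng.integers(1, 6)):
                    peaks.append(c * (1 + 1e-6 * rng.normal(0, 0.15)))
                    labels.append(i)
            peaks = np.array(peaks)
            order = np.argsort(peaks)
            truth = np.array(labels)[order]
            lists = {f"s{j}": peaks_df(peaks[order][j::3]) for j in range(3)}
            m = pp.align_features(lists, window_ppm=1.0)
            # oracle: complete linkage on ppm distances, cut at the window
            logm = np.log(peaks[order])
            z = linkage(logm.reshape(-1, 1), method="complete")
            cl = fcluster(z, t=np.log1p(1e-6), criterion="distance")
            if m.n_features == len(np.unique(cl)) == len(centers):
                agree += 1
        assert agree >= 0.99 * n_instances


class TestIsotopologueRemoval:
    def test_injected_isotopologues_removed_parents_kept(self, small_library):
        design = mouse_design(n_per_group=6, seed=21)
        pk, meta, truth = simulate_study(
            small_library, design, isotopologue_rate=0.5, sodium_adduct_rate=0.0,
            missing_rate=0.0,
        )
        m = pp.align_features(pk)
        cleaned = pp.remove_isotopologues(m)
        kept_mz = cleaned.features["mz"].to_numpy()
        iso = truth.features.loc[truth.features["kind"] == "isotopologue", "mz_theoretical"]
        parents = truth.features.loc[truth.features["kind"] == "parent", "mz_theoretical"]
        for mz in iso:
            assert not np.any(np.abs(kept_mz - mz) / mz * 1e6 < 0.5)
        for mz in parents:
            assert np.any(np.abs(kept_mz - mz) / mz * 1e6 < 0.5)

    def test_uncorrelated_spacing_kept(self):
        rng = np.random.default_rng(3)
        base = 400.0
        lists = {}
        for i in range(8):
            lists[f"s{i}"] = peaks_df(
                [base, base + 1.0033548378],
                [1e7 * 2 ** rng.normal(), 1e7 * 2 ** rng.normal()],
            )
        m = pp.align_features(lists)
        assert pp.remove_isotopologues(m).n_features == 2  # r << 0.9

    def test_no_pair_at_spacing_unchanged(self):
        df = peaks_df([200.0, 250.0, 300.0])
        m = pp.align_features({"a": df, "b": df, "c": df})
        assert pp.remove_isotopologues(m).n_features == 3


class TestMatrixCleaning:
    @staticmethod
    def matrix_with_missing():
        features = pd.DataFrame({"mz": [200.0, 300.0]}, index=pd.Index(["F1", "F2"], name="feature_id"))
        X = pd.DataFrame(
            [[100.0, np.nan, 110.0, 120.0], [np.nan, np.nan, np.nan, 50.0]],
            index=features.index,
            columns=list("abcd"),
        )
        samples = pd.DataFrame(index=pd.Index(list("abcd"), name="sample_id"))
        return pp.FeatureMatrix(features, X, samples)

    def test_presence_filter_boundary(self):
        features = pd.DataFrame({"mz": [200.0, 300.0]}, index=pd.Index(["F1", "F2"], name="feature_id"))
        X = pd.DataFrame(np.nan, index=features.index, columns=[f"s{i}" for i in range(20)])
        X.iloc[0, :1] = 1.0  # 1/20 = 0.05 < 0.10 -> removed
        X.iloc[1, :2] = 1.0  # 2/20 = 0.10 >= 0.10 -> kept
        m = pp.FeatureMatrix(features, X, pd.DataFrame(index=X.columns))
        out = pp.presence_filter(m, 0.10)
        assert list(out.features.index) == ["F2"]

    def test_impute_min09(self):
        m = self.matrix_with_missing().subset(["F1"])
        out = pp.impute_min09(m)
        assert out.intensities.loc["F1", "b"] == pytest.approx(90.0)

    def test_impute_all_missing_rejected(self):
        features = pd.DataFrame({"mz": [200.0]}, index=pd.Index(["F1"], name="feature_id"))
        X = pd.DataFrame([[np.nan, np.nan]], index=features.index, columns=["a", "b"])
        m = pp.FeatureMatrix(features, X, pd.DataFrame(index=X.columns))
        with pytest.raises(ValueError):
            pp.impute_min09(m)

    def test_log2_and_double_transform_guard(self):
        features = pd.DataFrame({"mz": [200.0]}, index=pd.Index(["F1"], name="feature_id"))
        X = pd.DataFrame([[8.0, 1.0]], index=features.index, columns=["a", "b"])
        m = pp.FeatureMatrix(features, X, pd.DataFrame(index=X.columns))
        out = pp.log2_transform(m)
        assert out.state == "log2"
        assert out.intensities.loc["F1", "a"] == 3.0
        assert out.intensities.loc["F1", "b"] == 0.0
        with pytest.raises(ValueError):
            pp.log2_transform(out)

    def test_pipeline_produces_finite_values(self, mouse_dataset):
        pk, meta, _, _ = mouse_dataset
        filtered = {s: pp.filter_peaks(df) for s, df in pk.items()}
        m = pp.align_features(filtered, samples=meta)
        m = pp.presence_filter(pp.remove_isotopologues(m))
        m = pp.log2_transform(pp.impute_min09(m))
        assert np.isfinite(m.intensities.to_numpy()).all()


class TestResponseMatrices:
    @staticmethod
    def build_matrix(rows):
        sample_ids = [f"{s}_{t}" for s, t in rows]
        features = pd.DataFrame({"mz": [200.0]}, index=pd.Index(["F1"], name="feature_id"))
        X = pd.DataFrame(
            [np.arange(len(sample_ids), dtype=float) + 10.0], index=features.index, columns=sample_ids
        )
        samples = pd.DataFrame(
            {
                "subject_id": [s for s, _ in rows],
                "timepoint": [t for _, t in rows],
                "group": ["risk" if s.startswith("R") else "nonrisk" for s, _ in rows],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return pp.FeatureMatrix(features, X, samples, state="log2")

    def test_differences(self):
        m = self.build_matrix([("R1", "t0"), ("R1", "t1"), ("R1", "t2")])
        m.intensities.loc["F1"] = [10.0, 12.0, 11.0]
        imm, short, groups = pp.response_matrices(m)
        assert imm.loc["R1", "F1"] == pytest.approx(2.0)
        assert short.loc["R1", "F1"] == pytest.approx(-1.0)

    def test_subject_missing_timepoint_dropped_from_both(self):
        m = self.build_matrix(
            [("R1", "t0"), ("R1", "t1"), ("R1", "t2"), ("N1", "t0"), ("N1", "t1")]
        )
        imm, short, groups = pp.response_matrices(m)
        assert list(imm.index) == ["R1"]
        assert list(short.index) == ["R1"]

    def test_raw_matrix_rejected(self):
        m = self.build_matrix([("R1", "t0"), ("R1", "t1"), ("R1", "t2")])
        m.state = "raw"
        with pytest.raises(ValueError):
            pp.response_matrices(m)
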