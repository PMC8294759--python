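"""Peak-list preprocessing: from exported spectra to analysis-ready matrices.

Implements the direct-infusion FT-ICR preprocessing chain: intensity and
signal-to-noise filtering (S/N >= 4, >= 1.5e6 counts), removal of peaks whose
mass defect no CHNOPS+Na formula can realise at z = 1, spectrum-wise
recalibration against a reference mass list to sub-0.1-ppm residuals,
cross-sample peak alignment within a 1-ppm window, 13C isotopologue removal
(spacing 1.0033548 Da, intensity correlation r >= 0.9 with the parent),
a >= 10%-presence filter, 0.9-times-feature-minimum imputation, log2
transformation, and per-subject response (difference) matrices for the
paired three-timepoint OGTT design.

All thresholds are "keep if >=" at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masscalc import PROTON_MASS, MONOISOTOPIC_MASS

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "CalibrationModel",
    "filter_peaks",
    "mass_defect_feasible",
    "feasible_mask",
    "calibrate",
    "align_features",
    "remove_isotopologues",
    "presence_filter",
    "impute_min09",
    "log2_transform",
    "response_matrices",
    "ACQUISITION_RANGE",
]

#: Default acquisition window of the instrument method, Th.
ACQUISITION_RANGE = (147.4, 1000.0)


@dataclass
class FeatureMatrix:
    """Aligned features x samples intensity table.

    features: DataFrame indexed by feature_id with column ``mz`` (consensus),
    strictly increasing.  intensities: DataFrame (features x samples) with
    NaN as the missing marker.  samples: metadata indexed by sample_id.
    state: "raw" or "log2".
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities are misaligned")
        mz = self.features["mz"].to_numpy()
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("consensus m/z must be strictly increasing")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def subset(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            self.features.loc[feature_ids],
            self.intensities.loc[feature_ids],
            self.samples,
            self.state,
        )

    def write_tsv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "consensus_mz", self.features["mz"])
        out.to_csv(path, sep="\t", index_label="feature_id")


def filter_peaks(
    peaks: pd.DataFrame, min_snr: float = 4.0, min_intensity: float = 1.5e6
) -> pd.DataFrame:
    """Keep peaks with snr >= min_snr (when present) and intensity >= min_intensity."""
    if min_snr < 0 or min_intensity < 0:
        raise ValueError("thresholds must be >= 0")
    keep = peaks["intensity"] >= min_intensity
    if "snr" in peaks.columns:
        keep &= peaks["snr"].fillna(np.inf) >= min_snr
    return peaks.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mass-defect feasibility: exact CHNOPS+Na subset-sum membership via
# meet-in-the-middle.  Table A holds all {N,O,P,S,Na} partial masses up to
# the range maximum, table B all {C,H} partial masses; a neutral mass is
# realisable iff some a + b lands within tolerance.

_FEAS_TABLES: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _feasibility_tables(max_mass: float) -> tuple[np.ndarray, np.ndarray]:
    key = round(max_mass, 3)
    if key in _FEAS_TABLES:
        return _FEAS_TABLES[key]
    cap = max_mass + 0.5
    a = np.array([0.0])
    for e in ("N", "O", "P", "S", "Na"):
        m = MONOISOTOPIC_MASS[e]
        kmax = int(cap // m)
        a = (a[:, None] + m * np.arange(kmax + 1)[None, :]).ravel()
        a = a[a <= cap]
    a.sort(kind="stable")
    mc, mh = MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"]
    b_parts = []
    for c in range(int(cap // mc) + 1):
        rem = cap - mc * c
        hmax = int(rem // mh)
        b_parts.append(mc * c + mh * np.arange(hmax + 1))
    b = np.concatenate(b_parts)
    _FEAS_TABLES[key] = (a, b)
    return a, b


def mass_defect_feasible(
    mz: float,
    tolerance_ppm: float = 1.0,
    acquisition_range: tuple[float, float] = ACQUISITION_RANGE,
) -> bool:
    """True iff some CHNOPS+Na formula has a protonated m/z within tolerance.

    Exact subset-sum membership over the full composition space (no validity
    heuristics), which is the sense in which a mass defect is "realisable".
    """
    lo, hi = acquisition_range
    if not (lo <= mz <= hi):
        raise ValueError(f"m/z {mz} outside acquisition range [{lo}, {hi}]")
    return bool(feasible_mask(np.array([mz]), tolerance_ppm, acquisition_range)[0])


_FEAS_CACHE: dict[tuple[float, float, float], bool] = {}


def feasible_mask(
    mz: np.ndarray,
    tolerance_ppm: float = 1.0,
    acquisition_range: tuple[float, float] = ACQUISITION_RANGE,
) -> np.ndarray:
    """Vectorised :func:`mass_defect_feasible` over an m/z array.

    Results are memoised at 1e-4 Th granularity (two orders of magnitude
    below the 1-ppm default window at m/z 500), so repeated spectra of the
    same analytes are cheap.
    """
    mz = np.asarray(mz, dtype=float)
    a, b = _feasibility_tables(acquisition_range[1])
    out = np.zeros(len(mz), dtype=bool)
    for i, m in enumerate(mz):
        key = (round(m, 4), tolerance_ppm, acquisition_range[1])
        hit = _FEAS_CACHE.get(key)
        if hit is not None:
            out[i] = hit
            continue
        target = m - PROTON_MASS
        t = tolerance_ppm * 1e-6 * m
        want = target - b  # required contribution from table A per B entry
        w = want[want >= -t]
        if len(w):
            idx = np.searchsorted(a, w - t, side="left")
            idx = np.clip(idx, 0, len(a) - 1)
            feasible = bool(np.any(np.abs(a[idx] - w) <= t))
        else:
            feasible = False
        _FEAS_CACHE[key] = feasible
        out[i] = feasible
    return out


@dataclass
class CalibrationModel:
    """Polynomial ppm-error correction fitted against reference masses."""

    coeffs: np.ndarray  # np.polyfit coefficients of ppm error vs m/z
    residual_sd_ppm: float
    matches: pd.DataFrame  # observed, theoretical, ppm_error, used
    applied: bool

    def predicted_ppm(self, mz) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(mz, dtype=float))

    def correct(self, mz) -> np.ndarray:
        """Remove the fitted systematic ppm error from observed m/z values."""
        mz = np.asarray(mz, dtype=float)
        if not self.applied:
            return mz
        return mz / (1.0 + 1e-6 * self.predicted_ppm(mz))


def calibrate(
    peaks: pd.DataFrame,
    reference_mz: Sequence[float],
    match_tol_ppm: float = 2.0,
    degree: int = 2,
    min_matches: int = 5,
) -> tuple[pd.DataFrame, CalibrationModel]:
    """Recalibrate one peak list against a reference mass list.

    For each reference, the nearest observed peak within ``match_tol_ppm`` is
    taken as a match; a robust polynomial (degree <= 2, one 3-MAD trimming
    pass) of ppm error versus m/z is fitted and removed from every peak.
    With fewer than ``min_matches`` matches calibration is refused and the
    peaks pass through unchanged (``model.applied`` is False).
    """
    if degree > 2:
        raise ValueError("calibration polynomial degree is capped at 2")
    mz = peaks["mz"].to_numpy()
    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]
    rows = []
    for ref in sorted(reference_mz):
        i = np.searchsorted(mz_sorted, ref)
        best, best_err = None, np.inf
        for j in (i - 1, i):
            if 0 <= j < len(mz_sorted):
                err = abs(mz_sorted[j] - ref) / ref * 1e6
                if err < best_err:
                    best, best_err = mz_sorted[j], err
        if best is not None and best_err <= match_tol_ppm:
            rows.append((best, ref, 1e6 * (best - ref) / ref))
    matches = pd.DataFrame(rows, columns=["observed", "theoretical", "ppm_error"])
    matches["used"] = True
    if len(matches) < min_matches:
        logger.warning(
            "calibration refused: %d reference matches (< %d); peaks passed through",
            len(matches),
            min_matches,
        )
        model = CalibrationModel(np.zeros(1), float("nan"), matches, applied=False)
        return peaks.copy(), model

    deg = min(degree, len(matches) - 1)
    x = matches["theoretical"].to_numpy()
    y = matches["ppm_error"].to_numpy()
    coeffs = np.polyfit(x, y, deg)
    resid = y - np.polyval(coeffs, x)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3.0 * 1.4826 * mad
        if keep.sum() >= min_matches and not keep.all():
            matches.loc[~keep, "used"] = False
            deg = min(degree, int(keep.sum()) - 1)
            coeffs = np.polyfit(x[keep], y[keep], deg)
            resid = y - np.polyval(coeffs, x)
    used = matches["used"].to_numpy()
    residual_sd = float(np.std(resid[used], ddof=1)) if used.sum() > 1 else 0.0
    model = CalibrationModel(coeffs, residual_sd, matches, applied=True)
    out = peaks.copy()
    out["mz"] = model.correct(out["mz"].to_numpy())
    return out, model


def align_features(
    peaklists: Mapping[str, pd.DataFrame],
    window_ppm: float = 1.0,
    samples: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Cluster pooled peaks across samples into aligned features.

    Greedy single pass over all peaks sorted by m/z: a peak joins the current
    cluster while it lies within ``window_ppm`` of the running
    intensity-weighted consensus m/z, otherwise it starts a new cluster.
    Sorting keys are independent of input ordering, so the result is
    invariant to sample order.  A sample contributing several peaks to one
    cluster has their intensities summed.
    """
    if not peaklists:
        raise ValueError("no peak lists supplied")
    frames = []
    for sid in sorted(peaklists):
        df = peaklists[sid]
        frames.append(
            pd.DataFrame({"mz": df["mz"], "intensity": df["intensity"], "sample": sid})
        )
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values(["mz", "intensity", "sample"], kind="stable", ignore_index=True)

    mzs = pool["mz"].to_numpy()
    intens = pool["intensity"].to_numpy()
    cluster = np.empty(len(pool), dtype=np.int64)
    cid = -1
    consensus = 0.0
    weight = 0.0
    for i in range(len(pool)):
        if cid < 0 or abs(mzs[i] - consensus) > window_ppm * 1e-6 * consensus:
            cid += 1
            consensus = mzs[i]
            weight = intens[i]
        else:
            weight_new = weight + intens[i]
            consensus = (consensus * weight + mzs[i] * intens[i]) / weight_new
            weight = weight_new
        cluster[i] = cid
    pool["cluster"] = cluster

    grouped = pool.groupby("cluster")
    consensus_mz = grouped.apply(
        lambda g: np.average(g["mz"], weights=g["intensity"]), include_groups=False
    )
    sample_ids = sorted(peaklists)
    wide = (
        pool.pivot_table(index="cluster", columns="sample", values="intensity", aggfunc="sum")
        .reindex(columns=sample_ids)
    )
    order = np.argsort(consensus_mz.to_numpy(), kind="stable")
    n_digits = max(5, len(str(len(order))))
    fids = [f"F{i + 1:0{n_digits}d}" for i in range(len(order))]
    features = pd.DataFrame(
        {"mz": consensus_mz.to_numpy()[order]}, index=pd.Index(fids, name="feature_id")
    )
    intensities = wide.iloc[order]
    intensities.index = features.index
    if samples is None:
        samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    else:
        samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
        samples = samples.loc[sample_ids]
    return FeatureMatrix(features, intensities, samples, state="raw")


def remove_isotopologues(
    matrix: FeatureMatrix,
    spacing: float = 1.0033548378,
    spacing_tol_ppm: float = 3.0,
    min_corr: float = 0.9,
    min_common: int = 3,
) -> FeatureMatrix:
    """Drop +1 13C isotopologue features.

    A feature sitting one 13C spacing above another feature (within
    ``spacing_tol_ppm`` evaluated at the feature's m/z) whose across-sample
    raw-intensity Pearson correlation with that candidate parent is
    >= ``min_corr`` is removed; candidate parents are retained.
    """
    if matrix.state != "raw":
        raise ValueError("isotopologue removal operates on raw intensities")
    mz = matrix.features["mz"].to_numpy()
    X = matrix.intensities.to_numpy()
    drop = np.zeros(len(mz), dtype=bool)
    for j in range(len(mz)):
        target = mz[j] - spacing
        tol = spacing_tol_ppm * 1e-6 * mz[j]
        lo = np.searchsorted(mz, target - tol, side="left")
        hi = np.searchsorted(mz, target + tol, side="right")
        for i in range(lo, hi):
            if i == j:
                continue
            both = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if both.sum() < min_common:
                continue
            xi, xj = X[i, both], X[j, both]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            if r >= min_corr:
                drop[j] = True
                break
    keep_ids = matrix.features.index[~drop]
    logger.info("isotopologue removal: %d of %d features dropped", int(drop.sum()), len(mz))
    return matrix.subset(keep_ids)


def presence_filter(matrix: FeatureMatrix, min_fraction: float = 0.10) -> FeatureMatrix:
    """Remove features observed in fewer than ``min_fraction`` of samples."""
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = matrix.intensities.notna().mean(axis=1)
    keep = frac >= min_fraction  # boundary kept
    return matrix.subset(matrix.features.index[keep.to_numpy()])


def impute_min09(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing cell by 0.9 x the feature's minimum observed value."""
    X = matrix.intensities
    mins = X.min(axis=1)
    if mins.isna().any():
        bad = list(X.index[mins.isna()])
        raise ValueError(f"all-missing feature(s) {bad[:5]}; run presence_filter first")
    filled = X.T.fillna(0.9 * mins).T
    return FeatureMatrix(matrix.features, filled, matrix.samples, matrix.state)


def log2_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Cellwise log2; flips the state flag and refuses a second application."""
    if matrix.state == "log2":
        raise ValueError("matrix is already log2-transformed")
    X = matrix.intensities
    if (X <= 0).any().any():
        raise ValueError("log2 transform requires strictly positive intensities")
    return FeatureMatrix(matrix.features, np.log2(X), matrix.samples, state="log2")


def response_matrices(
    matrix: FeatureMatrix,
    timepoints: tuple[str, str, str] = ("t0", "t1", "t2"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-subject response matrices for the paired OGTT design.

    Returns ``(immediate, short_term, groups)``: the t1-t0 and t2-t1
    differences of log2 intensities (one row per subject, one column per
    feature) and each subject's genotype group.  Subjects missing any of the
    three timepoints are dropped from BOTH matrices, keeping the two response
    matrices on the same subject set.
    """
    if matrix.state != "log2":
        raise ValueError("response matrices are defined on log2 intensities")
    meta = matrix.samples
    for col in ("subject_id", "timepoint", "group"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks column {col!r}")
    t0, t1, t2 = timepoints
    by_subject: dict[str, dict[str, str]] = {}
    for sid, row in meta.iterrows():
        by_subject.setdefault(row["subject_id"], {})[row["timepoint"]] = sid
    complete = sorted(s for s, tps in by_subject.items() if all(t in tps for t in timepoints))
    dropped = sorted(set(by_subject) - set(complete))
    if dropped:
        logger.warning("subjects dropped for missing timepoints: %s", dropped)
    if not complete:
        raise ValueError("no subject has all required timepoints")
    X = matrix.intensities
    imm_rows, short_rows, groups = [], [], []
    for s in complete:
        tps = by_subject[s]
        imm_rows.append(X[tps[t1]] - X[tps[t0]])
        short_rows.append(X[tps[t2]] - X[tps[t1]])
        groups.append(meta.loc[tps[t0], "group"])
    idx = pd.Index(complete, name="subject_id")
    immediate = pd.DataFrame(imm_rows, index=idx)
    short_term = pd.DataFrame(short_rows, index=idx)
    return immediate, short_term, pd.Series(groups, index=idx, name="group")
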