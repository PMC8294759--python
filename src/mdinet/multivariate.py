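"""Two-class PLS-DA with cross-validated Q2 and iterative feature selection.

The discriminant model regresses a +1/-1 class coding on the (centred,
optionally unit-variance scaled) log2 feature matrix with partial least
squares.  Model quality is summarised by R2 (fraction of class-coding
variance explained in training) and Q2, the sevenfold cross-validated R2
(1 - PRESS/TSS over held-out predictions, stratified and seeded).  A
positive regression coefficient means higher abundance in the +1 (risk /
mutant) class.

Feature selection iterates: fit, rank features by absolute regression
coefficient, keep the top fraction, refit; the model is final when neither
R2 nor Q2 improves over the previous iteration.  For paired multi-timepoint
designs the same machinery runs on per-subject response (difference)
matrices — the two-timepoint reduction of multilevel PLS-DA, in which the
subject-level intercept cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .preprocess import FeatureMatrix, response_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "PLSModel",
    "SelectionTrace",
    "encode_classes",
    "fit_plsda",
    "crossvalidated_q2",
    "choose_n_components",
    "iterative_feature_selection",
    "multilevel_transform",
    "replication_select",
    "group_ttest",
    "tile_statistics",
]

DEFAULT_COMPONENT_GRID: tuple[int, ...] = (1, 2, 3, 4, 5)


def encode_classes(y: Sequence, positive_label=None) -> tuple[np.ndarray, object, object]:
    """Code a two-class label vector as +1/-1.

    Returns (coded, positive_label, negative_label).  With string labels the
    positive class must be named (e.g. "risk"); numeric +1/-1 pass through.
    """
    y = np.asarray(y)
    labels = sorted(pd.unique(y).tolist(), key=str)
    if len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {labels}")
    if positive_label is None:
        if set(labels) == {-1, 1}:
            positive_label = 1
        else:
            raise ValueError("positive_label must be given for non +1/-1 labels")
    if positive_label not in labels:
        raise ValueError(f"positive_label {positive_label!r} not among {labels}")
    negative_label = next(l for l in labels if l != positive_label)
    coded = np.where(y == positive_label, 1.0, -1.0)
    return coded, positive_label, negative_label


@dataclass
class PLSModel:
    """A fitted two-class PLS-DA model."""

    n_components: int
    coefficients: pd.Series  # per feature, on the centred/scaled scale
    r2: float
    q2: float | None
    positive_label: object
    negative_label: object
    scale: bool = True

    @property
    def feature_ids(self) -> pd.Index:
        return self.coefficients.index


def _fit_raw(X: np.ndarray, y: np.ndarray, n_components: int, scale: bool) -> PLSRegression:
    nc = int(min(n_components, X.shape[1], max(X.shape[0] - 1, 1)))
    pls = PLSRegression(n_components=nc, scale=scale)
    pls.fit(X, y)
    return pls


def fit_plsda(
    X: pd.DataFrame,
    y: Sequence,
    n_components: int = 2,
    scale: bool = True,
    positive_label=None,
    q2: float | None = None,
) -> PLSModel:
    """Fit PLS-DA on a samples x features matrix.

    Constant features are dropped with a warning when unit-variance scaling
    is requested.  R2 is computed on the training data against the +1/-1
    coding; a positive coefficient means higher abundance in the positive
    class.
    """
    coded, pos, neg = encode_classes(y, positive_label)
    if scale:
        const = X.std(axis=0, ddof=1) == 0
        if const.any():
            logger.warning("dropping %d constant feature(s) before scaling", int(const.sum()))
            X = X.loc[:, ~const]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features left to fit")
    pls = _fit_raw(X.to_numpy(), coded, n_components, scale)
    pred = pls.predict(X.to_numpy()).ravel()
    ss_res = float(np.sum((coded - pred) ** 2))
    ss_tot = float(np.sum((coded - coded.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    coeffs = pd.Series(pls.coef_.ravel(), index=X.columns, name="coefficient")
    return PLSModel(
        n_components=int(pls.n_components),
        coefficients=coeffs,
        r2=r2,
        q2=q2,
        positive_label=pos,
        negative_label=neg,
        scale=scale,
    )


def crossvalidated_q2(
    X: pd.DataFrame,
    y: Sequence,
    folds: int = 7,
    n_components: int = 2,
    seed: int = 0,
    scale: bool = True,
    positive_label=None,
) -> tuple[float, pd.Series]:
    """Sevenfold (by default) stratified cross-validated Q2.

    Q2 = 1 - PRESS/TSS where PRESS sums squared errors of held-out
    predictions of the +1/-1 coding and TSS is taken against the grand mean.
    Deterministic for a given seed.
    """
    coded, pos, neg = encode_classes(y, positive_label)
    counts = pd.Series(coded).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xa = X.to_numpy()
    pred = np.empty(len(coded))
    for train, test in skf.split(Xa, coded):
        pls = _fit_raw(Xa[train], coded[train], n_components, scale)
        pred[test] = pls.predict(Xa[test]).ravel()
    press = float(np.sum((coded - pred) ** 2))
    tss = float(np.sum((coded - coded.mean()) ** 2))
    q2 = 1.0 - press / tss
    return q2, pd.Series(pred, index=X.index, name="cv_prediction")


def choose_n_components(
    X: pd.DataFrame,
    y: Sequence,
    folds: int = 7,
    grid: Sequence[int] = DEFAULT_COMPONENT_GRID,
    seed: int = 0,
    scale: bool = True,
    positive_label=None,
) -> tuple[int, float]:
    """Pick the component count maximising Q2 (ties favour fewer components)."""
    best_nc, best_q2 = None, -np.inf
    cap = min(X.shape[1], X.shape[0] - 1)
    for nc in grid:
        if nc > cap:
            break
        q2, _ = crossvalidated_q2(X, y, folds, nc, seed, scale, positive_label)
        if q2 > best_q2 + 1e-12:
            best_nc, best_q2 = nc, q2
    if best_nc is None:
        best_nc = 1
        best_q2, _ = crossvalidated_q2(X, y, folds, 1, seed, scale, positive_label)[0], None
    return best_nc, best_q2


@dataclass
class SelectionTrace:
    """Record of the iterative feature-selection loop."""

    iterations: list[dict] = field(default_factory=list)  # features, n_components, r2, q2
    final_iteration: int = 0
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": i,
                "n_features": len(it["features"]),
                "n_components": it["n_components"],
                "r2": it["r2"],
                "q2": it["q2"],
                "final": i == self.final_iteration,
            }
            for i, it in enumerate(self.iterations)
        ]
        return pd.DataFrame(rows)


def iterative_feature_selection(
    X: pd.DataFrame,
    y: Sequence,
    folds: int = 7,
    keep_fraction: float = 0.5,
    max_iter: int = 20,
    seed: int = 0,
    component_grid: Sequence[int] = DEFAULT_COMPONENT_GRID,
    scale: bool = True,
    positive_label=None,
) -> tuple[SelectionTrace, PLSModel]:
    """Shrink the feature set until neither R2 nor Q2 improves.

    Each iteration fits PLS-DA (component count chosen by maximising Q2 over
    ``component_grid``), records (R2, Q2), and retains the ``keep_fraction``
    of features with the largest absolute regression coefficients.  The loop
    stops when an iteration improves neither R2 nor Q2 (the final model is
    the previous, last-improving one), when the subset cannot shrink
    further, or at ``max_iter``.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    trace = SelectionTrace()
    current = X
    prev_model: PLSModel | None = None
    for it in range(max_iter):
        nc, q2 = choose_n_components(
            current, y, folds, component_grid, seed, scale, positive_label
        )
        model = fit_plsda(current, y, nc, scale, positive_label, q2=q2)
        trace.iterations.append(
            {
                "features": list(current.columns),
                "n_components": nc,
                "r2": model.r2,
                "q2": q2,
                "coefficients": model.coefficients,
            }
        )
        if prev_model is not None and model.r2 <= prev_model.r2 and q2 <= prev_model.q2:
            trace.final_iteration = it - 1
            return trace, prev_model
        prev_model = model
        trace.final_iteration = it
        if keep_fraction >= 1.0:
            break
        ranked = model.coefficients.abs().sort_values(ascending=False, kind="stable")
        n_keep = max(1, int(np.floor(keep_fraction * len(ranked))))
        subset = sorted(ranked.index[:n_keep])
        if len(subset) >= len(current.columns):
            break
        if len(subset) < 2:
            trace.truncated = True
            break
        current = current.loc[:, subset]
    return trace, prev_model


def multilevel_transform(
    matrix: FeatureMatrix,
    timepoints: tuple[str, str, str] = ("t0", "t1", "t2"),
) -> dict[str, tuple[pd.DataFrame, pd.Series]]:
    """Within-subject response matrices for between-genotype classification.

    Returns {"immediate": (X, groups), "short_term": (X, groups)} where each
    X holds per-subject log2 differences (t1-t0 and t2-t1).  Differencing
    removes the subject-level intercept, which is what makes the paired
    (multilevel) analysis insensitive to between-subject baseline variance.
    """
    immediate, short_term, groups = response_matrices(matrix, timepoints)
    return {"immediate": (immediate, groups), "short_term": (short_term, groups)}


def replication_select(
    immediate: pd.DataFrame,
    short_term: pd.DataFrame,
    groups: pd.Series,
    risk_label="risk",
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """Rule-based selection of up-then-down features in the risk group.

    A feature is selected iff (i) its median immediate (t1-t0) response is
    higher in risk subjects, (ii) its median short-term (t2-t1) response is
    lower in risk subjects, and (iii) an equal-variance two-sample t test on
    at least one of the two responses gives p < ``p_threshold``.
    """
    if not immediate.columns.equals(short_term.columns):
        raise ValueError("response matrices must share one feature set")
    risk = groups == risk_label
    if risk.sum() == 0 or (~risk).sum() == 0:
        raise ValueError("both genotype groups must be non-empty")
    med_imm_r = immediate.loc[risk.to_numpy()].median()
    med_imm_n = immediate.loc[(~risk).to_numpy()].median()
    med_sht_r = short_term.loc[risk.to_numpy()].median()
    med_sht_n = short_term.loc[(~risk).to_numpy()].median()
    p_imm = pd.Series(
        stats.ttest_ind(
            immediate.loc[risk.to_numpy()], immediate.loc[(~risk).to_numpy()], equal_var=True
        ).pvalue,
        index=immediate.columns,
    )
    p_sht = pd.Series(
        stats.ttest_ind(
            short_term.loc[risk.to_numpy()], short_term.loc[(~risk).to_numpy()], equal_var=True
        ).pvalue,
        index=short_term.columns,
    )
    out = pd.DataFrame(
        {
            "median_immediate_risk": med_imm_r,
            "median_immediate_nonrisk": med_imm_n,
            "median_short_risk": med_sht_r,
            "median_short_nonrisk": med_sht_n,
            "p_immediate": p_imm,
            "p_short": p_sht,
        }
    )
    out["selected"] = (
        (out["median_immediate_risk"] > out["median_immediate_nonrisk"])
        & (out["median_short_risk"] < out["median_short_nonrisk"])
        & ((out["p_immediate"] < p_threshold) | (out["p_short"] < p_threshold))
    )
    return out


def group_ttest(X: pd.DataFrame, groups: pd.Series, risk_label="risk") -> pd.DataFrame:
    """Per-feature risk-vs-nonrisk mean difference and equal-variance t test."""
    risk = (groups == risk_label).to_numpy()
    a, b = X.loc[risk], X.loc[~risk]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    mean_diff = a.mean() - b.mean()
    if len(a) < 2 or len(b) < 2:
        p = pd.Series(np.nan, index=X.columns)
        t = pd.Series(np.nan, index=X.columns)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t = pd.Series(res.statistic, index=X.columns)
        p = pd.Series(res.pvalue, index=X.columns)
    out = pd.DataFrame({"mean_difference": mean_diff, "t_statistic": t, "p_value": p})
    out["significant"] = out["p_value"] < 0.05
    out["undefined"] = out["p_value"].isna()
    return out


def tile_statistics(
    matrix: FeatureMatrix,
    timepoints: tuple[str, str, str] = ("t0", "t1", "t2"),
    risk_label="risk",
) -> pd.DataFrame:
    """Tile-map statistics: five panels (t0, t1, t2, t1-t0, t2-t1).

    For each panel and feature, the risk-minus-nonrisk mean difference and
    the equal-variance two-sample t-test p-value, with a significance flag
    at p < 0.05.  Timepoint panels compare log2 intensities between
    genotypes at that timepoint; response panels compare per-subject
    differences.
    """
    if matrix.state != "log2":
        raise ValueError("tile statistics are defined on log2 intensities")
    meta = matrix.samples
    panels: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    for tp in timepoints:
        sel = meta["timepoint"] == tp
        Xtp = matrix.intensities.loc[:, sel.to_numpy()].T
        panels[tp] = (Xtp, meta.loc[sel.to_numpy(), "group"])
    immediate, short_term, groups = response_matrices(matrix, timepoints)
    panels[f"{timepoints[1]}-{timepoints[0]}"] = (immediate, groups)
    panels[f"{timepoints[2]}-{timepoints[1]}"] = (short_term, groups)
    frames = []
    for name, (X, g) in panels.items():
        df = group_ttest(X, g, risk_label)
        df.insert(0, "panel", name)
        df.index.name = "feature_id"
        frames.append(df.reset_index())
    return pd.concat(frames, ignore_index=True)
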