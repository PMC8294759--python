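"""End-to-end runners for the two study shapes.

``run_mouse_pipeline`` chains preprocessing, network reconstruction,
formula annotation, PLS-DA feature selection, sign-aware class ORA and
direction-resolved MDEA for a two-group single-timepoint design.

``run_ogtt_pipeline`` does the same through preprocessing, then builds the
per-subject immediate (t1-t0) and short-term (t2-t1) response matrices,
runs multilevel PLS-DA feature selection and ORA per response, computes
tile-map statistics for all five panels, and (in replication mode) applies
the steroid-adduct prefilter and the median/t-test replication selection.

Every stage persists its outputs as TSV (plus GraphML for the network) into
the results directory and logs the feature count surviving each step.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import enrichment, masscalc, mdin, multivariate, preprocess
from .config import PipelineConfig
from .masscalc import default_mass_differences, load_mass_difference_list, parse_formula
from .preprocess import FeatureMatrix
from .synthetic_data import (
    EffectSpec,
    GroundTruth,
    library_to_frame,
    load_library,
    make_compound_library,
    mouse_design,
    ogtt_design,
    simulate_study,
    write_dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_peaklists",
    "preprocess_dataset",
    "annotate_network",
    "auto_seeds_from_truth",
    "seeds_from_anchors",
    "run_simulate",
    "run_mouse_pipeline",
    "run_ogtt_pipeline",
]


def read_peaklists(data_dir) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Load a dataset directory: peaklists/<sample>.tsv + metadata.tsv."""
    data_dir = Path(data_dir)
    metadata = pd.read_csv(data_dir / "metadata.tsv", sep="\t")
    peaklists = {}
    for sid in metadata["sample_id"]:
        peaklists[sid] = pd.read_csv(data_dir / "peaklists" / f"{sid}.tsv", sep="\t")
    return peaklists, metadata


def preprocess_dataset(
    peaklists: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    config: PipelineConfig,
    calibration_refs: Sequence[float] | None = None,
    steroid_library: pd.DataFrame | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix, dict]:
    """Filter, (optionally) calibrate, align and clean into matrices.

    Returns ``(matrix_log2, matrix_raw_aligned, stage_counts)`` where the
    log2 matrix has been isotopologue-cleaned, presence-filtered and
    imputed, and the raw aligned matrix is kept for diagnostics.
    """
    counts: dict[str, int] = {}
    processed: dict[str, pd.DataFrame] = {}
    acq = (config.acquisition_min_mz, config.acquisition_max_mz)
    for sid, peaks in peaklists.items():
        if peaks.empty:
            raise ValueError(f"sample {sid} has an empty peak list")
        p = preprocess.filter_peaks(peaks, config.snr, config.min_intensity)
        if calibration_refs is not None:
            p, _model = preprocess.calibrate(
                p, calibration_refs, config.calibration_match_ppm, 2, config.calibration_min_matches
            )
        if config.mass_defect_filter:
            in_range = (p["mz"] >= acq[0]) & (p["mz"] <= acq[1])
            p = p.loc[in_range.to_numpy()].reset_index(drop=True)
            mask = preprocess.feasible_mask(p["mz"].to_numpy(), config.mass_defect_ppm, acq)
            p = p.loc[mask].reset_index(drop=True)
        if steroid_library is not None:
            p = mdin.steroid_adduct_prefilter(p, steroid_library, tol_ppm=1.0)
        processed[sid] = p
    counts["peaks_after_filtering"] = int(sum(len(p) for p in processed.values()))

    matrix = preprocess.align_features(processed, config.align_ppm, metadata)
    counts["features_aligned"] = matrix.n_features
    if config.isotopologue_removal:
        matrix = preprocess.remove_isotopologues(
            matrix, spacing_tol_ppm=config.isotope_ppm, min_corr=config.isotope_r
        )
    counts["features_after_isotopologue_removal"] = matrix.n_features
    raw_aligned = matrix
    matrix = preprocess.presence_filter(matrix, config.presence_fraction)
    counts["features_after_presence_filter"] = matrix.n_features
    matrix = preprocess.impute_min09(matrix)
    matrix = preprocess.log2_transform(matrix)
    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)
    return matrix, raw_aligned, counts


def seeds_from_anchors(
    matrix: FeatureMatrix, anchors: Sequence[tuple[float, float, str]]
) -> list[tuple[str, masscalc.MolecularFormula]]:
    """Resolve (m/z, tol_ppm, formula) anchors to (feature_id, formula) seeds."""
    mz = matrix.features["mz"].to_numpy()
    ids = matrix.features.index
    seeds = []
    for target, tol_ppm, formula in anchors:
        err = np.abs(mz - target) / target * 1e6
        j = int(np.argmin(err))
        if err[j] <= tol_ppm:
            seeds.append((ids[j], parse_formula(formula)))
    return seeds


def auto_seeds_from_truth(
    matrix: FeatureMatrix,
    truth: GroundTruth,
    n_seeds: int = 5,
    seed: int = 0,
    tol_ppm: float = 0.5,
) -> list[tuple[str, masscalc.MolecularFormula]]:
    """Seed annotations from ground truth (synthetic runs only).

    Picks ``n_seeds`` parent peaks spread across the mass range and matches
    them to aligned features within ``tol_ppm``; stands in for the manual
    isotopic-fine-structure seed identification of a real experiment.
    """
    parents = truth.features.loc[truth.features["kind"] == "parent"].sort_values("mz_theoretical")
    rng = np.random.default_rng(seed)
    idx = np.linspace(0, len(parents) - 1, n_seeds * 3).astype(int)
    candidates = parents.iloc[np.unique(idx)]
    anchors = [
        (row.mz_theoretical, tol_ppm, row.formula) for row in candidates.itertuples(index=False)
    ]
    seeds = seeds_from_anchors(matrix, anchors)
    if len(seeds) > n_seeds:
        chosen = rng.choice(len(seeds), size=n_seeds, replace=False)
        seeds = [seeds[i] for i in sorted(chosen)]
    return seeds


def library_match_annotations(
    matrix: FeatureMatrix, library: pd.DataFrame, tol_ppm: float = 1.0
) -> dict[str, mdin.Annotation]:
    """Exact-formula annotation: match feature m/z to library [M+H]+ masses.

    The nearest library compound within ``tol_ppm`` supplies the formula;
    complements network propagation for nodes no edge path reaches.
    """
    theo = np.array([masscalc.adduct_mz(parse_formula(s)) for s in library["formula"]])
    order = np.argsort(theo)
    theo_sorted = theo[order]
    formulas = library["formula"].to_numpy()[order]
    out: dict[str, mdin.Annotation] = {}
    for fid, row in matrix.features.iterrows():
        mz = float(row["mz"])
        i = np.searchsorted(theo_sorted, mz)
        best, best_err = None, np.inf
        for j in (i - 1, i):
            if 0 <= j < len(theo_sorted):
                err = abs(mz - theo_sorted[j]) / theo_sorted[j] * 1e6
                if err < best_err:
                    best, best_err = j, err
        if best is not None and best_err <= tol_ppm:
            f = parse_formula(formulas[best])
            out[fid] = mdin.Annotation(
                fid, f, masscalc.ppm_error(mz, masscalc.adduct_mz(f)), "library-match"
            )
    return out


def annotate_network(
    matrix: FeatureMatrix,
    config: PipelineConfig,
    seeds: Sequence[tuple[str, object]],
    mass_diffs=None,
    library: pd.DataFrame | None = None,
) -> tuple[mdin.MDiN, dict, pd.Series]:
    """Build the MDiN, propagate formulas, and map formulas to classes.

    Formula annotations come from two complementary routes: network
    propagation from the seeds, and exact [M+H]+ matching against the
    compound library (propagated assignments win on conflict).
    """
    diffs = mass_diffs if mass_diffs is not None else default_mass_differences()
    net = mdin.build_network(matrix.features, diffs, config.edge_ppm)
    logger.info("network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    annotations = mdin.propagate_formulas(net, seeds, config.max_failures, config.annotation_ppm)
    logger.info("propagation annotated %d of %d nodes", len(annotations), net.n_nodes)
    if library is not None:
        direct = library_match_annotations(matrix, library, config.align_ppm)
        for fid, ann in direct.items():
            annotations.setdefault(fid, ann)
        logger.info("with library matching: %d annotated", len(annotations))
    if library is not None and len(annotations):
        classes = mdin.annotate_classes(annotations, library)
    else:
        classes = pd.Series(dtype=object)
    return net, annotations, classes


def _annotations_frame(annotations: dict, classes: pd.Series) -> pd.DataFrame:
    rows = [
        {
            "feature_id": a.node,
            "formula": a.formula.hill(),
            "ppm_error": a.ppm_error,
            "provenance": a.provenance,
            "compound_class": classes.get(a.node, "unassigned"),
        }
        for a in annotations.values()
    ]
    return pd.DataFrame(
        rows, columns=["feature_id", "formula", "ppm_error", "provenance", "compound_class"]
    ).sort_values("feature_id", ignore_index=True)


def _selection_frame(trace: multivariate.SelectionTrace, final) -> pd.DataFrame:
    initial = trace.iterations[0]
    dropped_at = {}
    for i, it in enumerate(trace.iterations):
        for f in it["features"]:
            dropped_at[f] = i
    final_set = set(final.feature_ids)
    coeffs = initial["coefficients"]
    out = pd.DataFrame(
        {
            "feature_id": coeffs.index,
            "coefficient_initial": coeffs.to_numpy(),
            "sign": np.sign(coeffs.to_numpy()).astype(int),
            "selected": [f in final_set for f in coeffs.index],
            "last_iteration_present": [dropped_at.get(f, 0) for f in coeffs.index],
        }
    )
    out.loc[out["selected"], "coefficient_final"] = final.coefficients.reindex(
        out.loc[out["selected"], "feature_id"]
    ).to_numpy()
    return out


def _ora_features(matrix_columns, classes: pd.Series, coefficients: pd.Series) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_class": [classes.get(f, "unassigned") for f in matrix_columns],
            "coefficient": coefficients.reindex(matrix_columns).to_numpy(),
        },
        index=pd.Index(matrix_columns, name="feature_id"),
    )


def run_simulate(config: PipelineConfig, out_dir) -> Path:
    """Generate a synthetic dataset directory from config.simulate."""
    sim = dict(config.simulate)
    kind = sim.pop("design", "mouse")
    n_per_group = sim.pop("n_per_group", 10 if kind == "mouse" else 25)
    n_per_class = sim.pop("n_per_class", 30)
    effects_spec = sim.pop("effects", [])
    seed = sim.pop("seed", config.seed)
    library = make_compound_library(n_per_class=n_per_class, seed=seed)
    design = (
        mouse_design(n_per_group=n_per_group, seed=seed)
        if kind == "mouse"
        else ogtt_design(n_per_group=n_per_group, seed=seed)
    )
    effects = [
        EffectSpec(e["target_class"], e["log2_by_timepoint"], e.get("fraction", 1.0))
        for e in effects_spec
    ]
    peaklists, metadata, truth = simulate_study(library, design, effects, **sim)
    return write_dataset(out_dir, peaklists, metadata, truth)


def _load_library_frame(config: PipelineConfig, data_dir=None) -> pd.DataFrame | None:
    """Compound library: explicit config path > dataset's own > packaged default."""
    path = config.paths.get("library")
    if path:
        return pd.read_csv(path, sep="\t")
    if data_dir is not None and (Path(data_dir) / "library.tsv").exists():
        return pd.read_csv(Path(data_dir) / "library.tsv", sep="\t")
    from importlib import resources

    with resources.files("mdinet.data").joinpath("compound_library_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _load_mass_diffs(config: PipelineConfig):
    path = config.paths.get("mass_differences")
    return load_mass_difference_list(path) if path else default_mass_differences()


def _load_seeds(config: PipelineConfig, matrix: FeatureMatrix):
    path = config.paths.get("seed_anchors")
    if not path:
        return []
    anchors_df = pd.read_csv(path, sep="\t")
    anchors = [
        (row.mz, row.tol_ppm, row.formula) for row in anchors_df.itertuples(index=False)
    ]
    return seeds_from_anchors(matrix, anchors)


def run_mouse_pipeline(
    config: PipelineConfig,
    data_dir,
    out_dir,
    seeds=None,
    truth: GroundTruth | None = None,
) -> dict:
    """Two-group tissue analysis: preprocess -> MDiN -> PLS-DA -> ORA/MDEA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaklists, metadata = read_peaklists(data_dir)
    matrix, _raw, counts = preprocess_dataset(peaklists, metadata, config)
    matrix.write_tsv(out / "feature_matrix_log2.tsv")
    matrix.samples.to_csv(out / "samples.tsv", sep="\t")

    library = _load_library_frame(config, data_dir)
    if seeds is None:
        if truth is not None:
            seeds = auto_seeds_from_truth(matrix, truth, config.n_auto_seeds, config.seed)
        else:
            seeds = _load_seeds(config, matrix)
    net, annotations, classes = annotate_network(
        matrix, config, seeds, _load_mass_diffs(config), library
    )
    net.write_graphml(out / "network.graphml")
    net.write_edgelist(out / "network_edges.tsv")
    _annotations_frame(annotations, classes).to_csv(out / "annotations.tsv", sep="\t", index=False)

    X = matrix.intensities.T
    y = matrix.samples["group"]
    trace, final = multivariate.iterative_feature_selection(
        X,
        y,
        folds=config.folds,
        keep_fraction=config.keep_fraction,
        max_iter=config.max_iter,
        seed=config.seed,
        component_grid=config.component_grid,
        scale=config.scale,
        positive_label=config.risk_label,
    )
    trace.to_frame().to_csv(out / "selection_trace.tsv", sep="\t", index=False)
    _selection_frame(trace, final).to_csv(out / "selection_features.tsv", sep="\t", index=False)

    initial_coeffs = trace.iterations[0]["coefficients"]
    features = _ora_features(X.columns, classes, initial_coeffs)
    ora = enrichment.ora_classes(
        features,
        list(final.feature_ids),
        min_class_size=config.min_class_size,
        tail=config.ora_tail,
        add_qvalues=config.add_qvalues,
    )
    ora.to_csv(out / "ora_classes.tsv", sep="\t", index=False)

    signs = initial_coeffs
    mdea_frames = []
    for direction in ("forward", "backward"):
        mdea_frames.append(
            enrichment.mdea(
                net,
                signs,
                classes,
                direction=direction,
                min_edges=config.mdea_min_edges,
                tail=config.ora_tail,
            )
        )
    mdea_all = pd.concat(mdea_frames, ignore_index=True)
    mdea_all.to_csv(out / "mdea.tsv", sep="\t", index=False)
    pd.Series(counts).to_csv(out / "stage_counts.tsv", sep="\t", header=["count"])
    config.to_yaml(out / "config_snapshot.yaml")
    return {
        "matrix": matrix,
        "network": net,
        "annotations": annotations,
        "classes": classes,
        "trace": trace,
        "final_model": final,
        "ora": ora,
        "mdea": mdea_all,
        "counts": counts,
    }


def run_ogtt_pipeline(
    config: PipelineConfig,
    data_dir,
    out_dir,
    seeds=None,
    truth: GroundTruth | None = None,
    replication: bool = False,
) -> dict:
    """Three-timepoint OGTT analysis with multilevel PLS-DA per response."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaklists, metadata = read_peaklists(data_dir)
    library = _load_library_frame(config, data_dir)
    steroid_lib = None
    if replication:
        steroid_lib = library.loc[
            library["compound_class"] == "Steroids and steroid derivatives"
        ]
    matrix, _raw, counts = preprocess_dataset(
        peaklists, metadata, config, steroid_library=steroid_lib
    )
    matrix.write_tsv(out / "feature_matrix_log2.tsv")
    matrix.samples.to_csv(out / "samples.tsv", sep="\t")

    if seeds is None:
        if truth is not None:
            seeds = auto_seeds_from_truth(matrix, truth, config.n_auto_seeds, config.seed)
        else:
            seeds = _load_seeds(config, matrix)
    net, annotations, classes = annotate_network(
        matrix, config, seeds, _load_mass_diffs(config), library
    )
    net.write_graphml(out / "network.graphml")
    net.write_edgelist(out / "network_edges.tsv")
    _annotations_frame(annotations, classes).to_csv(out / "annotations.tsv", sep="\t", index=False)

    responses = multivariate.multilevel_transform(matrix)
    results: dict = {
        "matrix": matrix,
        "network": net,
        "annotations": annotations,
        "classes": classes,
        "counts": counts,
        "responses": {},
    }
    for name, (Xr, groups) in responses.items():
        trace, final = multivariate.iterative_feature_selection(
            Xr,
            groups,
            folds=config.folds,
            keep_fraction=config.keep_fraction,
            max_iter=config.max_iter,
            seed=config.seed,
            component_grid=config.component_grid,
            scale=config.scale,
            positive_label=config.risk_label,
        )
        trace.to_frame().to_csv(out / f"selection_trace_{name}.tsv", sep="\t", index=False)
        _selection_frame(trace, final).to_csv(
            out / f"selection_features_{name}.tsv", sep="\t", index=False
        )
        initial_coeffs = trace.iterations[0]["coefficients"]
        features = _ora_features(Xr.columns, classes, initial_coeffs)
        ora = enrichment.ora_classes(
            features,
            list(final.feature_ids),
            min_class_size=None,  # the human-cohort ORA applies no size filter
            tail=config.ora_tail,
            add_qvalues=config.add_qvalues,
        )
        ora.to_csv(out / f"ora_classes_{name}.tsv", sep="\t", index=False)
        results["responses"][name] = {
            "trace": trace,
            "final_model": final,
            "ora": ora,
            "X": Xr,
            "groups": groups,
        }

    tiles = multivariate.tile_statistics(matrix, risk_label=config.risk_label)
    tiles.to_csv(out / "tile_statistics.tsv", sep="\t", index=False)
    results["tiles"] = tiles

    if replication:
        rep = multivariate.replication_select(
            responses["immediate"][0],
            responses["short_term"][0],
            responses["immediate"][1],
            risk_label=config.risk_label,
            p_threshold=config.replication_p,
        )
        rep.to_csv(out / "replication_selection.tsv", sep="\t", index_label="feature_id")
        results["replication"] = rep

    pd.Series(counts).to_csv(out / "stage_counts.tsv", sep="\t", header=["count"])
    config.to_yaml(out / "config_snapshot.yaml")
    return results
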