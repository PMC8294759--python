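"""Ground-truth synthetic data for the full inference chain.

Emulates direct-infusion FT-ICR peak lists for two study shapes:

* a two-genotype, single-timepoint adipose-tissue design (risk vs control,
  one sex, one depot), and
* a two-genotype, three-timepoint oral-glucose-tolerance-test (OGTT) design
  (t0 fasting, t1 = 60 min, t2 = 120 min) with paired samples per subject.

Every compound in a generated library contributes an [M+H]+ peak whose log2
intensity is compound baseline + subject random intercept + sample scaling
offset + genotype/timepoint effect + noise.  With configurable rates a
compound additionally emits a +1 13C isotopologue (1.0033548 Da above the
parent, intensity proportional to carbon count times the parent, hence
perfectly correlated across samples) and an [M+Na]+ adduct; m/z values carry
Gaussian ppm jitter and intensities can be dropped at random (MCAR) or
left-censored.  A ground-truth table traces every emitted peak identity to
its compound, formula, class and differential status, so each downstream
stage can be scored by recovery.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masscalc import (
    C13_C12_SPACING,
    MassDifference,
    MolecularFormula,
    PROTONATED,
    SODIATED,
    adduct_mz,
    default_mass_differences,
    parse_formula,
)
from .mdin import check_formula_validity

__all__ = [
    "CLASS_VOCABULARY",
    "UNASSIGNED_CLASS",
    "CompoundRecord",
    "StudyDesign",
    "EffectSpec",
    "GroundTruth",
    "make_compound_library",
    "library_to_frame",
    "mouse_design",
    "ogtt_design",
    "simulate_study",
    "make_reaction_network_compounds",
    "write_dataset",
]

#: Controlled vocabulary of compound classes (HMDB-style superclass labels).
CLASS_VOCABULARY: tuple[str, ...] = (
    "Steroids and steroid derivatives",
    "Fatty acyls",
    "Glycerophospholipids",
    "Glycerolipids",
    "Prenol lipids",
    "Organooxygen compounds",
    "Carboxylic acids and derivatives",
)
UNASSIGNED_CLASS = "unassigned"


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: MolecularFormula
    compound_class: str

    @property
    def mass(self) -> float:
        return self.formula.mass


@dataclass(frozen=True)
class StudyDesign:
    """Sample layout: subjects per genotype group, sex, tissue, timepoints."""

    n_per_group: int
    groups: tuple[str, str] = ("risk", "nonrisk")
    sex: str = "male"
    tissue: str = "adipose"
    timepoints: tuple[str, ...] = ("t0",)
    seed: int = 0

    def metadata(self) -> pd.DataFrame:
        rows = []
        for g_idx, group in enumerate(self.groups):
            prefix = "R" if g_idx == 0 else "N"
            for i in range(self.n_per_group):
                subject = f"{prefix}{i + 1:03d}"
                for tp in self.timepoints:
                    rows.append(
                        {
                            "sample_id": f"{subject}_{tp}",
                            "subject_id": subject,
                            "group": group,
                            "sex": self.sex,
                            "tissue": self.tissue,
                            "timepoint": tp,
                        }
                    )
        return pd.DataFrame(rows)


def mouse_design(n_per_group: int = 10, sex: str = "male", tissue: str = "vc-gWAT", seed: int = 0) -> StudyDesign:
    """Two-genotype single-timepoint adipose design."""
    return StudyDesign(n_per_group=n_per_group, sex=sex, tissue=tissue, timepoints=("t0",), seed=seed)


def ogtt_design(n_per_group: int = 25, sex: str = "male", seed: int = 0) -> StudyDesign:
    """Two-genotype three-timepoint OGTT plasma design (t0, t1, t2)."""
    return StudyDesign(
        n_per_group=n_per_group, sex=sex, tissue="plasma", timepoints=("t0", "t1", "t2"), seed=seed
    )


@dataclass(frozen=True)
class EffectSpec:
    """A class-targeted genotype effect.

    ``log2_by_timepoint`` maps a timepoint label to the log2 shift applied in
    the risk group at that timepoint; e.g. {"t1": 0.585} injects a 1.5-fold
    increase at t1 only, so the immediate (t1-t0) response goes up and the
    short-term (t2-t1) response goes down in risk subjects.  Only a random
    ``fraction`` of the class members are affected.
    """

    target_class: str
    log2_by_timepoint: Mapping[str, float]
    fraction: float = 1.0


@dataclass
class GroundTruth:
    """Per emitted peak identity: origin, formula, class, differential flag."""

    features: pd.DataFrame  # peak_id, compound, kind, formula, compound_class,
    #                          mz_theoretical, affected + shift_<tp> columns
    library: list[CompoundRecord]

    def affected_compounds(self) -> set[str]:
        return set(self.features.loc[self.features["affected"], "compound"])


# ---------------------------------------------------------------------------
# compound library generation

# Per-class composition samplers: (C range, N range, O range, P range,
# S range, RDBE range).  Hydrogen is solved from the RDBE draw, which keeps
# every candidate an integer-RDBE neutral molecule by construction.
_CLASS_RECIPES: dict[str, dict] = {
    "Steroids and steroid derivatives": dict(C=(17, 30), N=(0, 0), O=(1, 7), P=(0, 0), S=(0, 1), rdbe=(4, 8)),
    "Fatty acyls": dict(C=(12, 26), N=(0, 0), O=(2, 4), P=(0, 0), S=(0, 0), rdbe=(1, 7)),
    "Glycerophospholipids": dict(C=(30, 44), N=(0, 1), O=(8, 10), P=(1, 1), S=(0, 0), rdbe=(2, 8)),
    "Glycerolipids": dict(C=(20, 40), N=(0, 0), O=(5, 6), P=(0, 0), S=(0, 0), rdbe=(2, 8)),
    "Prenol lipids": dict(C=(10, 40), N=(0, 0), O=(0, 2), P=(0, 0), S=(0, 0), rdbe=(2, 8)),
    "Organooxygen compounds": dict(C=(5, 18), N=(0, 0), O=(4, 12), P=(0, 0), S=(0, 0), rdbe=(0, 3)),
    "Carboxylic acids and derivatives": dict(C=(2, 12), N=(0, 3), O=(2, 5), P=(0, 0), S=(0, 1), rdbe=(0, 4)),
}

_CLASS_SHORT = {
    "Steroids and steroid derivatives": "steroid",
    "Fatty acyls": "fattyacyl",
    "Glycerophospholipids": "gpl",
    "Glycerolipids": "glycerolipid",
    "Prenol lipids": "prenol",
    "Organooxygen compounds": "organooxygen",
    "Carboxylic acids and derivatives": "carboxylic",
}


def make_compound_library(
    n_per_class: int = 40,
    seed: int = 0,
    classes: Sequence[str] = CLASS_VOCABULARY,
    mass_range: tuple[float, float] = (150.0, 1000.0),
) -> list[CompoundRecord]:
    """Draw a deterministic library of valid, mass-distinct formulas.

    Compositions are sampled from class-typical element ranges (steroids
    C17-C30 with few oxygens and 4-8 RDBE, fatty acyls CnH(2n-2d)O2, sugars
    oxygen-rich with low RDBE, ...), screened by the same validity rules the
    annotator applies, and deduplicated at 6-decimal mass precision.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    seen_masses: set[float] = set()
    records: list[CompoundRecord] = []
    for cls in classes:
        recipe = _CLASS_RECIPES[cls]
        made = 0
        attempts = 0
        while made < n_per_class:
            attempts += 1
            if attempts > 200 * n_per_class:
                raise RuntimeError(f"cannot generate enough distinct formulas for {cls}")
            c = int(rng.integers(recipe["C"][0], recipe["C"][1] + 1))
            n = int(rng.integers(recipe["N"][0], recipe["N"][1] + 1))
            o = int(rng.integers(recipe["O"][0], recipe["O"][1] + 1))
            p = int(rng.integers(recipe["P"][0], recipe["P"][1] + 1))
            s = int(rng.integers(recipe["S"][0], recipe["S"][1] + 1))
            d = int(rng.integers(recipe["rdbe"][0], recipe["rdbe"][1] + 1))
            h = 2 * c + 2 + n + p - 2 * d
            if h < 1:
                continue
            f = MolecularFormula.from_dict({"C": c, "H": h, "N": n, "O": o, "P": p, "S": s})
            if not (mass_range[0] <= f.mass <= mass_range[1]):
                continue
            if not check_formula_validity(f)[0]:
                continue
            key = round(f.mass, 6)
            if key in seen_masses:
                continue
            seen_masses.add(key)
            records.append(CompoundRecord(f"{_CLASS_SHORT[cls]}_{made + 1:03d}", f, cls))
            made += 1
    return records


def library_to_frame(library: Sequence[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in library],
            "formula": [r.formula.hill() for r in library],
            "compound_class": [r.compound_class for r in library],
        }
    )


def load_library(path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CompoundRecord(row["name"], parse_formula(row["formula"]), row["compound_class"])
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# study simulation


def simulate_study(
    library: Sequence[CompoundRecord],
    design: StudyDesign,
    effects: Sequence[EffectSpec] = (),
    noise_sd_log2: float = 0.2,
    mass_error_ppm_sd: float = 0.05,
    isotopologue_rate: float = 0.3,
    sodium_adduct_rate: float = 0.15,
    missing_rate: float = 0.05,
    subject_sd_log2: float = 0.5,
    sample_scale_sd_log2: float = 0.1,
    base_log2_range: tuple[float, float] = (18.0, 30.0),
    noise_floor: float = 2.0**16,
    missing_mode: str = "mcar",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Simulate per-sample peak lists, metadata and ground truth.

    Returns ``(peaklists, metadata, truth)`` where ``peaklists`` maps
    sample_id to a DataFrame with columns mz, intensity, snr.  Deterministic
    for a fixed ``design.seed``.
    """
    if not library:
        raise ValueError("compound library is empty")
    for r in (isotopologue_rate, sodium_adduct_rate, missing_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    if missing_mode not in ("mcar", "censored"):
        raise ValueError("missing_mode must be 'mcar' or 'censored'")

    rng = np.random.default_rng(design.seed)
    metadata = design.metadata()
    n_samples = len(metadata)
    n_comp = len(library)
    subjects = metadata["subject_id"].unique()

    base = rng.uniform(*base_log2_range, size=n_comp)
    subj_intercept = dict(zip(subjects, rng.normal(0.0, subject_sd_log2, size=len(subjects))))
    sample_offset = rng.normal(0.0, sample_scale_sd_log2, size=n_samples)

    # class-targeted genotype effects: shift[k, sample] in log2 units
    shift = np.zeros((n_comp, n_samples))
    affected = np.zeros(n_comp, dtype=bool)
    shift_by_tp = {tp: np.zeros(n_comp) for tp in design.timepoints}
    risk_group = design.groups[0]
    for eff in effects:
        members = [i for i, r in enumerate(library) if r.compound_class == eff.target_class]
        if not members:
            continue
        k = max(1, int(round(eff.fraction * len(members))))
        chosen = rng.choice(members, size=k, replace=False)
        affected[chosen] = True
        for tp, delta in eff.log2_by_timepoint.items():
            if tp not in design.timepoints:
                raise ValueError(f"effect timepoint {tp!r} not in design")
            shift_by_tp[tp][chosen] += delta
    for s_idx, meta in metadata.iterrows():
        if meta["group"] == risk_group:
            shift[:, s_idx] = shift_by_tp[meta["timepoint"]]

    eps = rng.normal(0.0, noise_sd_log2, size=(n_comp, n_samples))
    log2_parent = (
        base[:, None]
        + np.array([subj_intercept[s] for s in metadata["subject_id"]])[None, :]
        + sample_offset[None, :]
        + shift
        + eps
    )
    raw_parent = 2.0**log2_parent

    has_iso = rng.random(n_comp) < isotopologue_rate
    has_na = rng.random(n_comp) < sodium_adduct_rate
    na_ratio = rng.uniform(0.1, 0.5, size=n_comp)
    eps_na = rng.normal(0.0, 0.1, size=(n_comp, n_samples))

    # assemble emitted peak identities
    identities = []  # (peak_id, comp_idx, kind, mz_theoretical, intensity matrix row)
    for i, rec in enumerate(library):
        mz_mh = adduct_mz(rec.formula, PROTONATED)
        identities.append((f"{rec.name}@M+H", i, "parent", mz_mh, raw_parent[i]))
        if has_iso[i]:
            frac = 0.0107 * rec.formula["C"]
            identities.append(
                (f"{rec.name}@13C", i, "isotopologue", mz_mh + C13_C12_SPACING, raw_parent[i] * frac)
            )
        if has_na[i]:
            mz_na = adduct_mz(rec.formula, SODIATED)
            identities.append(
                (
                    f"{rec.name}@M+Na",
                    i,
                    "sodium_adduct",
                    mz_na,
                    raw_parent[i] * na_ratio[i] * 2.0 ** eps_na[i],
                )
            )

    n_ident = len(identities)
    inten = np.vstack([ident[4] for ident in identities])
    mz_theo = np.array([ident[3] for ident in identities])
    jitter = rng.normal(0.0, mass_error_ppm_sd, size=(n_ident, n_samples))
    mz_obs = mz_theo[:, None] * (1.0 + 1e-6 * jitter)

    if missing_mode == "mcar":
        observed = rng.random((n_ident, n_samples)) >= missing_rate
    else:  # left-censored: drop the lowest-intensity fraction per identity
        if missing_rate > 0:
            thresh = np.quantile(inten, missing_rate, axis=1, keepdims=True)
            observed = inten > thresh
        else:
            observed = np.ones((n_ident, n_samples), dtype=bool)

    peaklists: dict[str, pd.DataFrame] = {}
    for s_idx, meta in metadata.iterrows():
        mask = observed[:, s_idx]
        df = pd.DataFrame(
            {
                "mz": mz_obs[mask, s_idx],
                "intensity": inten[mask, s_idx],
                "snr": inten[mask, s_idx] / noise_floor,
            }
        ).sort_values("mz", kind="stable", ignore_index=True)
        peaklists[meta["sample_id"]] = df

    truth_rows = []
    for peak_id, i, kind, mzt, _ in identities:
        rec = library[i]
        row = {
            "peak_id": peak_id,
            "compound": rec.name,
            "kind": kind,
            "formula": rec.formula.hill(),
            "compound_class": rec.compound_class,
            "mz_theoretical": mzt,
            "affected": bool(affected[i]),
        }
        for tp in design.timepoints:
            row[f"shift_{tp}"] = float(shift_by_tp[tp][i])
        truth_rows.append(row)
    truth = GroundTruth(features=pd.DataFrame(truth_rows), library=list(library))
    return peaklists, metadata, truth


def make_reaction_network_compounds(
    n_compounds: int = 100,
    seed: int = 0,
    mass_diffs: Sequence[MassDifference] | None = None,
    mass_range: tuple[float, float] = (150.0, 1000.0),
) -> list[MolecularFormula]:
    """Grow a connected set of formulas by random biochemical transformations.

    Starting from a few real metabolite formulas, repeatedly apply a random
    mass difference (forward or backward) to a random existing member; keep
    the product if it is valid, in range, and mass-distinct.  Because every
    member differs from some other member by exactly one listed mass
    difference, the resulting feature set forms a connected MDiN (at exact
    masses), which makes it an ideal ground truth for propagation tests.
    """
    diffs = list(mass_diffs) if mass_diffs is not None else default_mass_differences()
    rng = np.random.default_rng(seed)
    roots = [
        parse_formula("C6H12O6"),      # hexose
        parse_formula("C16H32O2"),     # palmitic acid
        parse_formula("C27H46O"),      # cholesterol
        parse_formula("C6H14N4O2"),    # arginine
    ]
    compounds: list[MolecularFormula] = [f for f in roots if mass_range[0] <= f.mass <= mass_range[1]]
    masses = {round(f.mass, 6) for f in compounds}
    guard = 0
    while len(compounds) < n_compounds:
        guard += 1
        if guard > 500 * n_compounds:
            raise RuntimeError("cannot grow the requested number of compounds")
        src = compounds[int(rng.integers(len(compounds)))]
        md = diffs[int(rng.integers(len(diffs)))]
        forward = bool(rng.random() < 0.7)
        cand = md.apply(src, forward=forward)
        if cand is None:
            continue
        if not (mass_range[0] <= cand.mass <= mass_range[1]):
            continue
        if not check_formula_validity(cand)[0]:
            continue
        key = round(cand.mass, 6)
        if key in masses:
            continue
        masses.add(key)
        compounds.append(cand)
    return compounds


def write_dataset(
    out_dir,
    peaklists: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> Path:
    """Write peak lists, metadata and truth tables as TSV plus a manifest."""
    out = Path(out_dir)
    (out / "peaklists").mkdir(parents=True, exist_ok=True)
    files = []
    for sample_id, df in peaklists.items():
        p = out / "peaklists" / f"{sample_id}.tsv"
        df.to_csv(p, sep="\t", index=False)
        files.append(p)
    p = out / "metadata.tsv"
    metadata.to_csv(p, sep="\t", index=False)
    files.append(p)
    if truth is not None:
        p = out / "truth_features.tsv"
        truth.features.to_csv(p, sep="\t", index=False)
        files.append(p)
        p = out / "library.tsv"
        library_to_frame(truth.library).to_csv(p, sep="\t", index=False)
        files.append(p)
    manifest = pd.DataFrame(
        {
            "file": [str(f.relative_to(out)) for f in files],
            "sha256": [hashlib.sha256(f.read_bytes()).hexdigest() for f in files],
        }
    ).sort_values("file", ignore_index=True)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out
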