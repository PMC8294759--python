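"""Mass-difference network (MDiN) reconstruction and formula annotation.

An MDiN has one node per aligned m/z feature and one edge per (node pair,
mass difference) whose observed neutral mass delta matches the exact delta of
a known biochemical transformation within a tight ppm tolerance (0.1 ppm by
default, the regime ultrahigh-resolution FT-ICR mass accuracy affords).
Edges are oriented from the lower-mass to the higher-mass node and carry the
transformation's formula delta, which lets molecular formulas propagate from
a handful of confidently identified seed nodes across the network.

Network arithmetic is done on neutralised masses under a single [M+H]+
hypothesis (observed m/z minus the proton mass); sodiated species are
expected to be removed or targeted separately upstream.

Candidate formulas produced during propagation are screened by heuristic
composition rules (element-ratio windows, mass-scaled element-count maxima,
and an integer non-negative ring-plus-double-bond equivalent) commonly used
to reject impossible CHNOPS compositions, plus consistency with every
already-annotated neighbour.  A node whose candidates are rejected more than
``max_failures`` times is discarded.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .masscalc import (
    EMPTY_FORMULA,
    PROTON_MASS,
    MassDifference,
    MolecularFormula,
    adduct_mz,
    AdductSpec,
    parse_formula,
    ppm_error,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MDiN",
    "Annotation",
    "build_network",
    "propagate_formulas",
    "check_formula_validity",
    "annotate_classes",
    "steroid_adduct_prefilter",
]

#: Heuristic element-ratio windows for plausible biomolecules (applied when C > 0).
RATIO_BOUNDS = {
    "H/C": (0.2, 3.1),
    "N/C": (0.0, 1.3),
    "O/C": (0.0, 1.2),
    "P/C": (0.0, 0.3),
    "S/C": (0.0, 0.8),
}

# Element-count maxima for compounds up to ~500 Da; scaled linearly with mass.
_COUNT_MAX_500 = {"C": 39, "H": 72, "N": 20, "O": 20, "P": 9, "S": 10, "Na": 3}


def rdbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalent of the neutral molecule.

    Valences: C=4, N/P=3, O/S=2, H/Na=1.
    """
    return 1.0 + f["C"] - (f["H"] + f["Na"]) / 2.0 + (f["N"] + f["P"]) / 2.0


def check_formula_validity(
    f: MolecularFormula, mass_context: float | None = None
) -> tuple[bool, str]:
    """Screen a candidate formula; returns (valid, reason).

    Rules: element-ratio windows (H/C etc., only when carbon is present),
    mass-scaled element-count maxima, and RDBE that is a non-negative integer
    (a half-integer RDBE implies an open-shell/charged species, impossible
    for an even-electron neutral molecule).
    """
    mass = f.mass
    if mass <= 0:
        return False, "empty"
    c = f["C"]
    # The ratio windows are asymptotic heuristics; at a single carbon they
    # misfire on legitimate molecules (methane, formic acid), where the RDBE
    # and count rules below already constrain the composition.
    if c > 1:
        for name, (lo, hi) in RATIO_BOUNDS.items():
            num = f[name.split("/")[0]]
            ratio = num / c
            if not (lo <= ratio <= hi):
                return False, f"ratio {name}={ratio:.2f} outside [{lo}, {hi}]"
    scale = max((mass_context or mass) / 500.0, 1.0)
    for e, cap in _COUNT_MAX_500.items():
        if f[e] > cap * scale:
            return False, f"count {e}={f[e]} exceeds {cap * scale:.0f}"
    d = rdbe(f)
    if d < 0:
        return False, f"RDBE {d:.1f} negative"
    if abs(d - round(d)) > 1e-9:
        return False, f"RDBE {d:.1f} not integer"
    return True, "ok"


@dataclass
class MDiN:
    """Mass-difference network over aligned features.

    nodes: DataFrame indexed by feature id with columns mz, neutral_mass.
    edges: DataFrame with columns source, target, diff_name, delta_mass,
           ppm_deviation; source is always the lower-mass node.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    mass_diffs: dict[str, MassDifference] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbours(self) -> dict[str, list[tuple[str, str, bool]]]:
        """Adjacency: node -> [(other, diff_name, outgoing)], outgoing meaning
        the edge points from node (lower mass) to other (higher mass)."""
        adj: dict[str, list[tuple[str, str, bool]]] = {n: [] for n in self.nodes.index}
        for row in self.edges.itertuples(index=False):
            adj[row.source].append((row.target, row.diff_name, True))
            adj[row.target].append((row.source, row.diff_name, False))
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for fid, row in self.nodes.iterrows():
            g.add_node(fid, mz=float(row["mz"]), neutral_mass=float(row["neutral_mass"]))
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                diff_name=row.diff_name,
                delta_mass=float(row.delta_mass),
                ppm_deviation=float(row.ppm_deviation),
            )
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path) -> None:
        cols = ["source", "target", "diff_name", "delta_mass", "ppm_deviation"]
        self.edges.loc[:, cols].rename(
            columns={"source": "source_id", "target": "target_id"}
        ).to_csv(path, sep="\t", index=False)


def build_network(
    features: pd.DataFrame,
    mass_diffs: Sequence[MassDifference],
    edge_tol_ppm: float = 0.1,
    adduct: AdductSpec | None = None,
) -> MDiN:
    """Reconstruct the MDiN over a feature table.

    ``features`` is a DataFrame indexed by feature id with an ``mz`` column
    (consensus m/z).  For every feature pair (i, j) with m(j) > m(i) and every
    mass difference B, an edge i->j is created iff

        |(m(j) - m(i)) - delta(B)| < edge_tol_ppm * 1e-6 * mean(m(i), m(j))

    on neutralised masses.  Implemented as a sorted two-pointer sweep per mass
    difference, O(n log n + n * |diffs| + E).
    """
    if not len(mass_diffs):
        raise ValueError("mass-difference list is empty")
    if "mz" not in features.columns:
        raise ValueError("features must carry an 'mz' column")
    from .masscalc import PROTONATED

    adduct = adduct or PROTONATED
    order = np.argsort(features["mz"].to_numpy(), kind="stable")
    ids = features.index.to_numpy()[order]
    mz = features["mz"].to_numpy()[order]
    neutral = mz - adduct.carrier_mass
    if np.any(np.diff(neutral) < 1e-9):
        raise ValueError("duplicate feature m/z at 1e-9; upstream alignment bug")

    rows = []
    n = len(neutral)
    for md in mass_diffs:
        delta = md.delta_mass
        j = 0
        for i in range(n):
            target = neutral[i] + delta
            # widest possible window at this mass
            w = edge_tol_ppm * 1e-6 * (neutral[i] + target) / 2.0
            lo, hi = target - w, target + w
            j = max(j, i + 1)
            k = np.searchsorted(neutral, lo, side="left")
            k = max(k, i + 1)
            while k < n and neutral[k] <= hi:
                dev = (neutral[k] - neutral[i]) - delta
                tol = edge_tol_ppm * 1e-6 * (neutral[i] + neutral[k]) / 2.0
                if abs(dev) < tol:
                    rows.append(
                        (
                            ids[i],
                            ids[k],
                            md.name,
                            delta,
                            1e6 * dev / ((neutral[i] + neutral[k]) / 2.0),
                        )
                    )
                k += 1

    nodes = pd.DataFrame({"mz": mz, "neutral_mass": neutral}, index=pd.Index(ids, name="feature_id"))
    edges = pd.DataFrame(
        rows, columns=["source", "target", "diff_name", "delta_mass", "ppm_deviation"]
    )
    return MDiN(nodes=nodes, edges=edges, mass_diffs={m.name: m for m in mass_diffs})


@dataclass(frozen=True)
class Annotation:
    """A molecular-formula assignment for one network node."""

    node: str
    formula: MolecularFormula
    ppm_error: float
    provenance: str  # "seed" or "propagated:<diff_name>"


def _implied_ppm(formula: MolecularFormula, neutral_mass: float) -> float:
    return 1e6 * (neutral_mass - formula.mass) / formula.mass


def propagate_formulas(
    net: MDiN,
    seeds: Iterable[tuple[str, MolecularFormula | str]],
    max_failures: int = 10,
    annotation_tol_ppm: float = 0.2,
) -> dict[str, Annotation]:
    """Propagate formulas from seed nodes across mass-difference edges.

    Best-evidence-first search: candidate assignments are processed from a
    priority queue ordered by |implied ppm error|, then m/z, then formula
    string, which makes the outcome deterministic and independent of input
    ordering.  A candidate for an unassigned neighbour is the assigned
    formula plus/minus the edge's formula delta and is accepted iff

      (a) every element count stays >= 0,
      (b) :func:`check_formula_validity` passes,
      (c) the implied neutral mass is within ``annotation_tol_ppm`` of the
          observed neutral mass, and
      (d) it is consistent with every already-annotated adjacent node
          (their formula difference equals each connecting edge's delta).

    Each rejection increments the node's failure counter; nodes rejected more
    than ``max_failures`` times are discarded and never annotated.  Nodes
    still unassigned at termination are simply absent from the output.
    """
    neutral = net.nodes["neutral_mass"]
    adj = net.neighbours()
    assigned: dict[str, Annotation] = {}
    failures: dict[str, int] = {n: 0 for n in net.nodes.index}
    discarded: set[str] = set()

    heap: list[tuple[float, float, str, str, str]] = []

    def push(node: str, formula: MolecularFormula, provenance: str) -> None:
        err = _implied_ppm(formula, float(neutral.loc[node]))
        heapq.heappush(
            heap, (abs(err), float(net.nodes.at[node, "mz"]), node, formula.hill(), provenance)
        )

    for node, formula in seeds:
        if isinstance(formula, str):
            formula = parse_formula(formula)
        if node not in net.nodes.index:
            raise ValueError(f"seed node {node!r} not in network")
        err = _implied_ppm(formula, float(neutral.loc[node]))
        if abs(err) > annotation_tol_ppm:
            raise ValueError(
                f"seed {node!r} formula {formula.hill()} off by {err:.3f} ppm "
                f"(> {annotation_tol_ppm} ppm)"
            )
        push(node, formula, "seed")

    def consistent(node: str, formula: MolecularFormula) -> bool:
        for other, diff_name, outgoing in adj[node]:
            if other not in assigned:
                continue
            md = net.mass_diffs[diff_name]
            expected = md.apply(formula, forward=outgoing)
            if expected is None or expected != assigned[other].formula:
                return False
        return True

    while heap:
        abs_err, _mz, node, hill, provenance = heapq.heappop(heap)
        if node in discarded:
            continue
        formula = parse_formula(hill)
        if node in assigned:
            continue  # first (best-evidence) assignment wins
        ok, _reason = check_formula_validity(formula)
        err = _implied_ppm(formula, float(neutral.loc[node]))
        if not ok or abs(err) > annotation_tol_ppm or not consistent(node, formula):
            if provenance == "seed":
                continue
            failures[node] += 1
            if failures[node] > max_failures:
                discarded.add(node)
            continue
        assigned[node] = Annotation(node, formula, err, provenance)
        for other, diff_name, outgoing in adj[node]:
            if other in assigned or other in discarded:
                continue
            md = net.mass_diffs[diff_name]
            candidate = md.apply(formula, forward=outgoing)
            if candidate is None:
                failures[other] += 1
                if failures[other] > max_failures:
                    discarded.add(other)
                continue
            push(other, candidate, f"propagated:{diff_name}")

    return assigned


def annotate_classes(
    annotations: Mapping[str, Annotation] | Mapping[str, MolecularFormula],
    library: pd.DataFrame,
    unassigned_label: str = "unassigned",
) -> pd.Series:
    """Map annotated formulas to compound classes by exact formula match.

    ``library`` needs columns ``formula`` (Hill string) and ``compound_class``.
    When several library compounds share a formula the modal class wins, ties
    broken alphabetically; formulas absent from the library get the generic
    ``unassigned`` label.
    """
    if library.empty:
        raise ValueError("compound library is empty")
    by_formula: dict[str, str] = {}
    for hill, grp in library.groupby(library["formula"].map(lambda s: parse_formula(s).hill())):
        counts = grp["compound_class"].value_counts()
        top = counts[counts == counts.max()].index.min()  # modal, alphabetical tie-break
        by_formula[hill] = top
    out = {}
    for node, ann in annotations.items():
        formula = ann.formula if isinstance(ann, Annotation) else ann
        out[node] = by_formula.get(formula.hill(), unassigned_label)
    return pd.Series(out, name="compound_class", dtype=object)


def steroid_adduct_prefilter(
    peaks: pd.DataFrame,
    steroid_library: pd.DataFrame,
    tol_ppm: float = 1.0,
) -> pd.DataFrame:
    """Keep only peaks matching a steroid [M+H]+ or [M+Na]+ within tol_ppm.

    Mirrors the targeted replication-cohort preprocessing: the peak list is
    reduced to candidate adducts of any library compound in the steroid class
    before alignment.
    """
    if steroid_library.empty:
        raise ValueError("steroid library subset is empty")
    from .masscalc import PROTONATED, SODIATED

    targets = []
    for s in steroid_library["formula"]:
        f = parse_formula(s)
        targets.append(adduct_mz(f, PROTONATED))
        targets.append(adduct_mz(f, SODIATED))
    targets = np.sort(np.asarray(targets))
    mz = peaks["mz"].to_numpy()
    idx = np.searchsorted(targets, mz)
    keep = np.zeros(len(mz), dtype=bool)
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, len(targets) - 1)
        keep |= np.abs(mz - targets[j]) <= tol_ppm * 1e-6 * targets[j]
    return peaks.loc[keep].reset_index(drop=True)
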