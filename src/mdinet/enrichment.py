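"""Compound-class over-representation and mass-difference enrichment analysis.

ORA asks whether a selected feature subset (e.g. the final PLS-DA feature
set) contains more members of a compound class than random sampling from the
full reference feature set would give, via the hypergeometric distribution.
Tests are sign-aware: besides the overall subset, the selected features with
positive and with negative regression coefficients are tested separately,
which resolves whether a class is *up* or *down* in the risk class.

MDEA (mass-difference enrichment analysis) extends this to reaction
direction over the MDiN: for each mass-difference type, the edges whose
lower-mass (source/substrate) node is down-regulated while the higher-mass
(target/product) node is up-regulated form the "forward" subset (net
consumption of substrate into product); the reverse pattern forms the
"backward" subset.  Class membership of source or target nodes within a
direction subset is tested against all edges of that mass-difference type.

Raw p-values are reported by default; Benjamini-Hochberg q-values are
available on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mdin import MDiN

__all__ = [
    "hypergeom_pvalue",
    "ora_classes",
    "mdea",
]


def hypergeom_pvalue(universe: int, class_in_universe: int, draws: int, hits: int, tail: str = "upper") -> float:
    """Hypergeometric tail probability.

    upper: P(X >= hits); lower: P(X <= hits) for X ~ Hypergeom(N, K, n).
    """
    N, K, n, k = universe, class_in_universe, draws, hits
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if tail == "upper":
        return float(hypergeom.sf(k - 1, N, K, n))
    if tail == "lower":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError("tail must be 'upper' or 'lower'")


def _bh(p: pd.Series) -> pd.Series:
    if len(p) == 0:
        return p.copy()
    return pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)


def ora_classes(
    features: pd.DataFrame,
    selected: Sequence[str],
    min_class_size: int | None = None,
    tail: str = "upper",
    unassigned_label: str = "unassigned",
    add_qvalues: bool = False,
) -> pd.DataFrame:
    """Sign-aware compound-class ORA of a selected feature subset.

    ``features`` is the reference set: a DataFrame indexed by feature id with
    columns ``compound_class`` and ``coefficient`` (the signed regression
    coefficient from the initial model).  For every class (optionally only
    those with reference count strictly greater than ``min_class_size``),
    three hypergeometric tests are run against the full reference set:
    the selected subset overall ("any"), and its positive-coefficient ("up")
    and negative-coefficient ("down") parts.  Positive means higher in the
    risk/mutant class.  The generic unassigned label is kept in universes
    but also tested like any class.
    """
    for col in ("compound_class", "coefficient"):
        if col not in features.columns:
            raise ValueError(f"features must carry a {col!r} column")
    selected = pd.Index(selected)
    missing = selected.difference(features.index)
    if len(missing):
        raise ValueError(f"selected features not in reference set: {list(missing)[:5]}")
    N = len(features)
    sel = features.loc[selected]
    subsets = {
        "any": sel,
        "up": sel.loc[sel["coefficient"] > 0],
        "down": sel.loc[sel["coefficient"] < 0],
    }
    class_counts = features["compound_class"].value_counts()
    rows = []
    for cls, K in class_counts.items():
        if min_class_size is not None and not (K > min_class_size):
            continue
        for direction, sub in subsets.items():
            n = len(sub)
            k = int((sub["compound_class"] == cls).sum())
            p = hypergeom_pvalue(N, int(K), n, k, tail=tail)
            rows.append(
                {
                    "compound_class": cls,
                    "direction": direction,
                    "N": N,
                    "K": int(K),
                    "n": n,
                    "k": k,
                    "p_value": p,
                }
            )
    cols = ["compound_class", "direction", "N", "K", "n", "k", "p_value"]
    out = pd.DataFrame(rows, columns=cols).sort_values(
        ["direction", "compound_class"], ignore_index=True
    )
    if add_qvalues and len(out):
        out["q_value"] = out.groupby("direction")["p_value"].transform(
            lambda s: _bh(s).to_numpy()
        )
    return out


def mdea(
    net: MDiN,
    node_signs: Mapping[str, float] | pd.Series,
    node_classes: Mapping[str, str] | pd.Series,
    direction: str = "forward",
    min_edges: int = 5,
    tail: str = "upper",
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Direction-resolved mass-difference enrichment analysis.

    ``node_signs`` maps node id to the signed regression coefficient of the
    matching feature; ``node_classes`` to its compound class.  Edges whose
    nodes lack a sign are skipped.  For each mass-difference type with at
    least ``min_edges`` usable edges, the direction-consistent subset is

      forward:  sign(source) < 0 and sign(target) > 0
                (substrate down-regulated, product up-regulated),
      backward: sign(source) > 0 and sign(target) < 0,

    and for each role (source/target) and compound class present among that
    type's role nodes, a hypergeometric test compares class membership in
    the subset against all usable edges of the type.  The generic
    unassigned label participates in universes but is never itself tested.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    signs = pd.Series(node_signs, dtype=float)
    classes = pd.Series(node_classes, dtype=object)
    edges = net.edges
    usable = edges["source"].isin(signs.index) & edges["target"].isin(signs.index)
    n_skipped = int((~usable).sum())
    edges = edges.loc[usable]
    s_sign = signs.loc[edges["source"]].to_numpy()
    t_sign = signs.loc[edges["target"]].to_numpy()
    if direction == "forward":
        in_subset = (s_sign < 0) & (t_sign > 0)
    else:
        in_subset = (s_sign > 0) & (t_sign < 0)
    edges = edges.assign(in_subset=in_subset)

    rows = []
    for diff_name, grp in edges.groupby("diff_name"):
        N = len(grp)
        if N < min_edges:
            continue
        sub = grp.loc[grp["in_subset"]]
        n = len(sub)
        for role in ("source", "target"):
            role_classes_all = classes.reindex(grp[role]).fillna(unassigned_label)
            role_classes_sub = classes.reindex(sub[role]).fillna(unassigned_label)
            for cls in sorted(role_classes_all.unique()):
                if cls == unassigned_label:
                    continue
                K = int((role_classes_all == cls).sum())
                k = int((role_classes_sub == cls).sum())
                p = hypergeom_pvalue(N, K, n, k, tail=tail)
                rows.append(
                    {
                        "diff_name": diff_name,
                        "role": role,
                        "direction": direction,
                        "compound_class": cls,
                        "N_edges": N,
                        "K_class": K,
                        "n_subset": n,
                        "k_hits": k,
                        "p_value": p,
                        "edges_skipped_unsigned": n_skipped,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "diff_name",
            "role",
            "direction",
            "compound_class",
            "N_edges",
            "K_class",
            "n_subset",
            "k_hits",
            "p_value",
            "edges_skipped_unsigned",
        ],
    )
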