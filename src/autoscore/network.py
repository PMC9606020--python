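"""Regulatory-network assembly and over-representation enrichment.

Regulators (TFs or miRNAs) recur across cancers when they are called
significant in at least a type-specific number of cancer types (defaults:
miRNA in >= 4, TF in >= 9; target genes in >= 3). Networks are the subset
of a reference regulator->target pair table induced by the selected
regulators and targets; no edge is ever invented. Enrichment of a gene
set collection in a query list is the one-sided hypergeometric
over-representation test with BH adjustment across sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diff import bh_fdr
from .io import GeneSetCollection

#: default recurrence thresholds (number of cancers significant)
RECURRENCE_DEFAULTS = {"TF": 9, "miRNA": 4, "target": 3}


def feature_recurrence(per_cancer: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Number of cancers in which each feature is called significant."""
    counts: dict[str, int] = {}
    for res in per_cancer.values():
        for feat in res.index[res["significant"]]:
            counts[feat] = counts.get(feat, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def max_abs_effect(per_cancer: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Largest |effect| per feature over the cancers where it was significant."""
    best: dict[str, float] = {}
    for res in per_cancer.values():
        sig = res[res["significant"]]
        for feat, eff in sig["effect"].items():
            best[feat] = max(best.get(feat, 0.0), abs(float(eff)))
    return pd.Series(best, dtype=float).sort_index()


def select_recurrent_regulators(
    per_cancer: Mapping[str, pd.DataFrame],
    kind: str,
    min_cancers: int | None = None,
    members: Iterable[str] | None = None,
) -> list[str]:
    """Regulators of a given kind significant in >= min_cancers cancers.

    ``members`` restricts to a membership list (e.g. the known TF list);
    miRNA layers are usually already regulator-only, so members is
    optional there.
    """
    if kind not in ("TF", "miRNA"):
        raise ValueError(f"unknown regulator kind {kind!r}")
    if min_cancers is None:
        min_cancers = RECURRENCE_DEFAULTS[kind]
    rec = feature_recurrence(per_cancer)
    if members is not None:
        rec = rec[rec.index.isin(set(members))]
    return sorted(rec.index[rec >= min_cancers])


def select_recurrent_targets(
    per_cancer: Mapping[str, pd.DataFrame],
    min_cancers: int | None = None,
) -> list[str]:
    """Target genes significantly altered in >= min_cancers cancers."""
    if min_cancers is None:
        min_cancers = RECURRENCE_DEFAULTS["target"]
    rec = feature_recurrence(per_cancer)
    return sorted(rec.index[rec >= min_cancers])


def build_network(
    regulators: Iterable[str],
    targets: Iterable[str],
    pairs: pd.DataFrame,
    recurrence: pd.Series | None = None,
    effect: pd.Series | None = None,
    kind: str = "TF",
) -> nx.DiGraph:
    """Directed regulator->target network induced by a reference pair table.

    Edges are exactly the reference pairs whose regulator and target were
    both selected; isolated nodes are dropped. Node attributes carry the
    node type plus optional recurrence (cancers significant) and max
    |fold change|.
    """
    regs, targs = set(regulators), set(targets)
    g = nx.DiGraph()
    sel = pairs[pairs["regulator"].isin(regs) & pairs["target"].isin(targs)]
    for r, t in sel.itertuples(index=False):
        g.add_edge(r, t)
    for node in g.nodes:
        g.nodes[node]["kind"] = kind if node in regs else "target"
        if recurrence is not None and node in recurrence.index:
            g.nodes[node]["recurrence"] = int(recurrence[node])
        if effect is not None and node in effect.index:
            g.nodes[node]["max_abs_fc"] = float(effect[node])
    return g


def network_tables(g: nx.DiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge-list and node-attribute tables for a network."""
    edges = pd.DataFrame(sorted(g.edges), columns=["regulator", "target"])
    nodes = pd.DataFrame(
        [
            {
                "node": n,
                "kind": d.get("kind", ""),
                "degree": g.degree(n),
                "recurrence": d.get("recurrence", np.nan),
                "max_abs_fc": d.get("max_abs_fc", np.nan),
            }
            for n, d in sorted(g.nodes(data=True))
        ]
    )
    return edges, nodes


def hypergeom_enrichment(
    query: Iterable[str],
    annotation: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation sets.

    With universe size N, set size K (after intersection with the
    universe) and query size n, p = P(X >= overlap) for X ~
    Hypergeom(N, K, n); BH adjustment across sets.
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    q = set(query) & uni
    rows = []
    for gs in annotation:
        members = set(gs.genes) & uni
        overlap = len(members & q)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(q)))
        rows.append({"set": gs.name, "set_size": len(members), "overlap": overlap, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out
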