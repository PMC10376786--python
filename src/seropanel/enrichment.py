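"""Hypergeometric pathway over-representation with degree-centrality impact.

Given a set of selected analytes (e.g. the screened markers), each pathway's
over-representation p-value is the upper hypergeometric tail
P[X >= hits] for X ~ Hypergeometric(universe, set size, selected), with
Benjamini-Hochberg FDR across pathways.  The universe defaults to the set of
quantified analytes, mirroring the screening context, not a global database.

Impact is the mean normalized degree centrality (degree / (n-1) within the
pathway subgraph) of the hit nodes, a simple topology weight for ranking
enriched pathways.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .univariate import bh_adjust

__all__ = [
    "PathwaySet",
    "hypergeom_enrich",
    "degree_impact",
    "read_gmt",
    "read_edge_list",
]


@dataclasses.dataclass
class PathwaySet:
    name: str
    description: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """GMT-like file: pathway <tab> description <tab> member ids..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(PathwaySet(parts[0], parts[1], set(parts[2:])))
    return sets


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def hypergeom_enrich(
    selected: set[str],
    sets: list[PathwaySet],
    universe: set[str],
    edges: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment, BH-corrected across pathways."""
    offenders = set(selected) - set(universe)
    if offenders:
        raise ValueError(f"selected ids outside the universe: {sorted(offenders)[:5]}")
    M = len(universe)
    N = len(selected)
    rows = []
    for ps in sets:
        members = ps.members & universe
        K = len(members)
        hits = len(members & selected)
        if K == 0:
            p = 1.0
        else:
            # P[X >= hits]; sf(hits-1) is the upper tail including hits
            p = float(stats.hypergeom.sf(hits - 1, M, K, N)) if hits > 0 else 1.0
        impact = (
            degree_impact(ps, edges, members & selected) if edges is not None else None
        )
        rows.append(
            {
                "pathway": ps.name,
                "hits": hits,
                "set_size": K,
                "universe_size": M,
                "n_selected": N,
                "p_value": min(p, 1.0),
                "impact": impact,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["fdr"] = []
    return df


def degree_impact(
    pathway: PathwaySet,
    edges: list[tuple[str, str]],
    hit_ids: set[str],
) -> float:
    """Mean normalized degree centrality of hit nodes in the pathway subgraph.

    Centrality = degree / (n-1) within the subgraph induced by the pathway's
    members; nodes absent from the graph count as centrality 0 (warned).
    Returns 0.0 when there are no hits.
    """
    if not hit_ids:
        return 0.0
    g = nx.Graph()
    g.add_nodes_from(pathway.members)
    g.add_edges_from(
        (a, b) for a, b in edges if a in pathway.members and b in pathway.members
    )
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    centrality = nx.degree_centrality(g)  # degree/(n-1)
    vals = []
    for node in sorted(hit_ids):
        if node not in centrality:
            warnings.warn(f"hit node {node!r} absent from pathway graph")
            vals.append(0.0)
        else:
            vals.append(centrality[node])
    return float(sum(vals) / len(vals))
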