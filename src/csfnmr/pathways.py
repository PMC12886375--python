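"""Over-representation pathway analysis with topology-based impact.

Hit metabolites (typically those with VIP > 1.0 from a PLS-DA model)
are tested per pathway with the upper-tail hypergeometric probability
P(X >= k) for k hits among n drawn from a background of N metabolites
containing K pathway members, BH-FDR corrected across pathways.  Each
pathway also receives a relative-betweenness-centrality impact score:
the summed betweenness centrality of the hit nodes over the summed
centrality of all pathway nodes (falling back to the hit fraction when
every centrality is zero, e.g. on graphs of <= 2 nodes).  Candidate
pathways are those with FDR below alpha and impact above a floor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .stats_univariate import bh_fdr

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_IMPACT_MIN = 0.1
DEFAULT_VIP_MIN = 1.0


@dataclass
class Pathway:
    id: str
    name: str
    nodes: list
    edges: list  # pairs of node names

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValidationError(
                    f"pathway {self.id}: edge ({u}, {v}) references "
                    "a node outside the pathway")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class PathwayLibrary:
    pathways: list
    background: list

    def __post_init__(self) -> None:
        if not self.background:
            raise ValidationError("background must be non-empty")
        bg = set(self.background)
        for pw in self.pathways:
            extra = set(pw.nodes) - bg
            if extra:
                raise ValidationError(
                    f"pathway {pw.id} has nodes outside the background: "
                    f"{sorted(extra)}")

    def to_json(self, path) -> None:
        payload = {
            "background": list(self.background),
            "pathways": [
                {"id": pw.id, "name": pw.name, "nodes": list(pw.nodes),
                 "edges": [list(e) for e in pw.edges]}
                for pw in self.pathways
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PathwayLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        pathways = [Pathway(id=d["id"], name=d["name"], nodes=d["nodes"],
                            edges=[tuple(e) for e in d["edges"]])
                    for d in payload["pathways"]]
        return cls(pathways=pathways, background=payload["background"])


def pathway_impact(pathway: Pathway, hits) -> float:
    """Relative betweenness-centrality impact of the hit set.

    impact = sum of betweenness centralities of hit nodes / sum over all
    nodes; falls back to the plain hit fraction when all centralities
    vanish.  Disconnected pathways are scored on the full node set with
    a warning.
    """
    g = pathway.graph()
    if g.number_of_nodes() and not nx.is_connected(g):
        log.warning("pathway %s is disconnected; impact computed on the "
                    "full node set", pathway.id)
    cb = nx.betweenness_centrality(g, normalized=True)
    total = sum(cb.values())
    hit_nodes = set(hits) & set(pathway.nodes)
    if total <= 0:
        return len(hit_nodes) / len(pathway.nodes) if pathway.nodes else 0.0
    return sum(cb[v] for v in hit_nodes) / total


def ora_test(hits, library: PathwayLibrary,
             compute_impact: bool = True) -> pd.DataFrame:
    """Hypergeometric over-representation test for every pathway.

    Hits outside the background are dropped with a warning.  Returns a
    table with columns pathway_id, name, k (hits in pathway), K
    (pathway size in background), n (total hits), N (background size),
    p, fdr and impact.
    """
    background = set(library.background)
    hits = set(hits)
    stray = hits - background
    if stray:
        log.warning("hits outside background dropped (check name mapping): %s",
                    sorted(stray))
    hits &= background
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for pw in library.pathways:
        members = set(pw.nodes) & background
        k = len(hits & members)
        kk = len(members)
        # upper tail: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, n_bg, kk, n_hits))
        rows.append({"pathway_id": pw.id, "name": pw.name, "k": k, "K": kk,
                     "n": n_hits, "N": n_bg, "p": min(p, 1.0),
                     "impact": pathway_impact(pw, hits) if compute_impact
                     else np.nan})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = []
    return table[["pathway_id", "name", "k", "K", "n", "N", "p", "fdr",
                  "impact"]]


def select_pathways(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                    impact_min: float = DEFAULT_IMPACT_MIN) -> pd.DataFrame:
    """Rows with fdr < alpha and impact > impact_min, best first."""
    if results.empty:
        return results.copy()
    keep = results.loc[(results["fdr"] < alpha)
                       & (results["impact"] > impact_min)].copy()
    return keep.sort_values(["fdr", "impact"], ascending=[True, False],
                            kind="mergesort").reset_index(drop=True)
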