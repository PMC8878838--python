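"""Metabolite-set enrichment: hypergeometric over-representation plus
pathway-topology impact via relative betweenness centrality, with
Benjamini–Hochberg FDR adjustment.

The universe is the set of measured metabolites that map to the pathway
database (not the whole database). The impact of a pathway is the sum of
the relative betweenness centralities (node value over the pathway total)
of the hit metabolites within that pathway's directed reaction graph.

A small synthetic "KEGG-like" database (12 toy pathways, 5-20 nodes each)
ships with the package for tests and examples; see
:func:`load_toy_pathway_db`. It carries no real pathway content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class Pathway:
    id: str
    name: str
    members: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for u, v in self.edges:
            if u not in self.members or v not in self.members:
                raise ValueError(
                    f"pathway {self.id}: edge ({u}, {v}) references a non-member"
                )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.members))
        g.add_edges_from(self.edges)
        return g


@dataclass
class PathwayDb:
    pathways: dict[str, Pathway]

    def __post_init__(self):
        if len(self.pathways) != len(set(self.pathways)):
            raise ValueError("duplicate pathway ids")

    def __len__(self) -> int:
        return len(self.pathways)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for pw in self.pathways.values():
            out |= pw.members
        return out


@dataclass
class EnrichmentRecord:
    pathway_id: str
    name: str
    m: int  # pathway members in the universe
    k: int  # hits in the pathway
    p_hyper: float
    fdr_q: float
    impact: float


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT lines: pathway_id <tab> description <tab> member ids..."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        out[parts[0]] = (parts[1], set(parts[2:]))
    return out


def read_edges(path) -> dict[str, list[tuple[str, str]]]:
    """Edge TSV: pathway_id <tab> source <tab> target (directed)."""
    out: dict[str, list[tuple[str, str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pw, u, v = line.rstrip("\n").split("\t")
        out.setdefault(pw, []).append((u, v))
    return out


def load_pathway_db(gmt_path, edges_path=None) -> PathwayDb:
    sets = read_gmt(gmt_path)
    edges = read_edges(edges_path) if edges_path else {}
    return PathwayDb(
        pathways={
            pid: Pathway(id=pid, name=name, members=members, edges=edges.get(pid, []))
            for pid, (name, members) in sets.items()
        }
    )


def load_toy_pathway_db() -> PathwayDb:
    """The bundled synthetic 12-pathway database."""
    data = resources.files("metabscreen") / "data"
    with resources.as_file(data / "toy_pathways.gmt") as gmt, resources.as_file(
        data / "toy_pathway_edges.tsv"
    ) as edges:
        return load_pathway_db(gmt, edges)


def ora_test(k: int, m: int, n: int, N: int) -> float:
    """Exact hypergeometric over-representation tail P(X >= k).

    ``N`` universe size, ``m`` pathway members in the universe, ``n`` hit
    list size, ``k`` hits in the pathway.
    """
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m={m}, n={n})")
    if m > N or n > N:
        raise ValueError("pathway or hit list larger than the universe")
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def pathway_impact(hits, pathway: Pathway) -> float:
    """Topology impact: sum of relative betweenness centralities of hits.

    Betweenness is computed by shortest-path counting on the directed
    pathway graph; each node's value is divided by the sum over all nodes
    (0 when every centrality is zero), and the hit nodes' shares are summed.
    """
    if not pathway.members:
        raise ValueError(f"pathway {pathway.id} is empty")
    g = pathway.graph()
    bc = nx.betweenness_centrality(g, normalized=False)
    total = sum(bc.values())
    if total == 0:
        return 0.0
    hits = set(hits) & pathway.members
    return float(sum(bc[h] for h in hits) / total)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(hits, db: PathwayDb, universe) -> pd.DataFrame:
    """One enrichment record per pathway with members in the universe.

    ``hits`` and ``universe`` are metabolite id collections; hits outside
    the universe are ignored. Returns a DataFrame sorted by p then impact.
    """
    if len(db) == 0:
        raise ValueError("empty pathway database")
    universe = set(universe)
    hits = set(hits) & universe
    if not hits:
        raise ValueError("empty hit list (after restriction to the universe)")
    N, n = len(universe), len(hits)
    rows = []
    for pw in db.pathways.values():
        members_u = pw.members & universe
        m = len(members_u)
        if m == 0:
            continue
        k = len(hits & members_u)
        rows.append(
            {
                "pathway_id": pw.id,
                "name": pw.name,
                "m": m,
                "k": k,
                "match_ratio": k / m,
                "p_hyper": ora_test(k, m, n, N),
                "impact": pathway_impact(hits, pw),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_q"] = fdr_adjust(out["p_hyper"].to_numpy())
    return out.sort_values(
        ["p_hyper", "impact"], ascending=[True, False], ignore_index=True
    )
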