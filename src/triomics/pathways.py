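"""Pathway enrichment and topology-based impact scoring.

Compound-set over-representation by the one-sided hypergeometric test
with Benjamini-Hochberg correction, and a pathway impact score defined
as the fraction of total betweenness centrality carried by the hit
compounds in the pathway graph (the relative-betweenness convention of
metabolomics pathway-analysis tools).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayDb",
    "load_gmt",
    "write_gmt",
    "load_edge_list",
    "match_kegg",
    "enrich",
    "impact",
    "pathway_report",
]

_KEGG_ID = re.compile(r"^C\d{5}$")


@dataclass
class PathwayDb:
    """Pathway membership sets plus per-pathway undirected graphs."""

    sets: dict[str, set[str]]
    graphs: dict[str, nx.Graph] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for pid, members in self.sets.items():
            g = self.graphs.get(pid)
            if g is not None and not set(members) <= set(g.nodes):
                raise ValueError(f"{pid}: set members missing from graph nodes")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= set(members)
        return out


def load_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: pathway TAB description TAB member IDs..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, names: dict[str, str] | None = None):
    lines = [
        "\t".join([pid, (names or {}).get(pid, pid)] + sorted(members))
        for pid, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_edge_list(path) -> nx.Graph:
    """Read an undirected graph from a two-column TAB-separated edge list."""
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        g.add_edge(a.strip(), b.strip())
    return g


def match_kegg(
    names_or_ids, mapping: pd.DataFrame | dict
) -> tuple[list[str], list[str]]:
    """Map metabolite names to KEGG-style compound IDs.

    ``C#####`` tokens pass through unchanged; other entries are matched
    case-insensitively against the name column of ``mapping`` (a
    DataFrame with columns ``name, kegg_id`` or a plain dict). Returns
    (matched IDs, unmatched inputs) — nothing is dropped silently.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.empty:
            raise ValueError("empty mapping table")
        lut = {
            str(n).strip().lower(): str(k)
            for n, k in zip(mapping["name"], mapping["kegg_id"])
        }
    else:
        if not mapping:
            raise ValueError("empty mapping table")
        lut = {str(n).strip().lower(): str(k) for n, k in mapping.items()}
    matched, unmatched = [], []
    for item in names_or_ids:
        token = str(item).strip()
        if _KEGG_ID.match(token):
            matched.append(token)
        elif token.lower() in lut:
            matched.append(lut[token.lower()])
        else:
            unmatched.append(token)
    return matched, unmatched


def enrich(
    query: set[str] | list[str],
    db: PathwayDb,
    universe_override: set[str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    With universe size N, pathway size m, query size n and k hits,
    p = P(X >= k) for X ~ Hypergeom(N, m, n); BH-FDR across pathways.
    Query members outside the universe are dropped with a warning.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    universe = set(universe_override) if universe_override else db.universe
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query compound(s) outside the universe dropped")
        query = query & universe
    n_universe, n_query = len(universe), len(query)
    rows = []
    for pid, members in db.sets.items():
        members = set(members) & universe
        hits = query & members
        k, m = len(hits), len(members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, m, n_query)) if k else 1.0
        rows.append(
            {
                "pathway": pid,
                "name": db.names.get(pid, pid),
                "pathway_size": m,
                "hits": k,
                "hit_compounds": ";".join(sorted(hits)),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("pathway")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p")


def impact(hits, graph: nx.Graph) -> float:
    """Relative-betweenness pathway impact in [0, 1].

    Node importance is unnormalized betweenness centrality (shortest
    paths exclusive of endpoints); impact is the hit nodes' share of the
    graph's total centrality, 0 when the graph has no between-node
    traffic at all. Hits absent from the graph are ignored with a
    warning.
    """
    hits = set(hits)
    missing = hits - set(graph.nodes)
    if missing:
        warnings.warn(f"{len(missing)} hit(s) not in the pathway graph ignored")
        hits -= missing
    bc = nx.betweenness_centrality(graph, normalized=False)
    total = sum(bc.values())
    if total == 0:
        return 0.0
    return float(sum(bc[h] for h in hits) / total)


def pathway_report(
    query,
    db: PathwayDb,
    universe_override: set[str] | None = None,
) -> pd.DataFrame:
    """Per-pathway table (hits, enrichment p, FDR, impact), sorted by p.

    Only pathways with at least one hit are reported (an empty query
    gives an empty report); impact requires a graph for the pathway and
    is NaN otherwise.
    """
    if not set(query):
        return pd.DataFrame(
            columns=["name", "pathway_size", "hits", "hit_compounds", "p",
                     "fdr", "impact"]
        )
    table = enrich(query, db, universe_override=universe_override)
    table = table[table["hits"] > 0].copy()
    impacts = []
    for pid in table.index:
        g = db.graphs.get(pid)
        if g is None:
            impacts.append(float("nan"))
        else:
            hit_ids = set(table.loc[pid, "hit_compounds"].split(";"))
            impacts.append(impact(hit_ids, g))
    table["impact"] = impacts
    return table.sort_values("p")
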