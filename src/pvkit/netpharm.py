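"""Network-pharmacology mechanics on user-supplied gene lists and edges.

Covers the computable core of a drug-toxicity network analysis:
drug-target / disease-gene set intersection with the Venn percentage,
confidence-filtered protein-protein interaction networks, betweenness-
centrality hub ranking (Brandes, via networkx), and hypergeometric
over-representation with Benjamini-Hochberg adjustment over supplied
annotation sets (GMT). No remote database is ever queried; exported
lists and edge tables are inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase-normalised gene symbols."""

    name: str
    members: frozenset

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(_norm(s) for s in symbols if str(s).strip()))

    def __len__(self) -> int:
        return len(self.members)


def intersect(a: GeneSet, b: GeneSet) -> Tuple[frozenset, float]:
    """Overlap of two gene sets and its percentage of the union
    (the Venn-diagram percentage)."""
    if not a.members or not b.members:
        raise ValueError("gene sets must be nonempty")
    overlap_set = a.members & b.members
    union = a.members | b.members
    return overlap_set, 100.0 * len(overlap_set) / len(union)


def threshold_filter(
    table: pd.DataFrame, min_score: float, inclusive: bool = True, name: str = "filtered"
) -> GeneSet:
    """Generic score-threshold selection on a (symbol, score) table,
    the way scored target/disease exports are trimmed before
    intersection. ``inclusive`` picks >= versus strict >."""
    sym = table.iloc[:, 0]
    score = pd.to_numeric(table.iloc[:, 1])
    keep = score >= min_score if inclusive else score > min_score
    return GeneSet.from_iterable(name, sym[keep])


class GeneNetwork:
    """Undirected scored interaction network over gene symbols.

    No self-loops, no duplicate edges (the larger score wins), every
    edge endpoint a node. Thin wrapper over ``networkx.Graph``.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str, float]]) -> "GeneNetwork":
        g = nx.Graph()
        for u, v, score in edges:
            u, v = _norm(u), _norm(v)
            s = float(score)
            if u == v:
                continue  # self-loops carry no centrality information
            if g.has_edge(u, v):
                g[u][v]["score"] = max(g[u][v]["score"], s)
            else:
                g.add_edge(u, v, score=s)
        return cls(g)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def edges(self) -> list:
        return [(u, v, d["score"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_edges(
    network: GeneNetwork, min_score: float, drop_isolated: bool = True
) -> GeneNetwork:
    """Keep edges with confidence score >= min_score (inclusive cutoff).

    ``drop_isolated`` removes nodes left without edges. Idempotent at a
    fixed cutoff.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score {min_score} outside [0,1]")
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, d in network.graph.edges(data=True):
        if d["score"] >= min_score:
            g.add_edge(u, v, score=d["score"])
    if drop_isolated:
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return GeneNetwork(g)


def betweenness(network: GeneNetwork, normalized: bool = True) -> dict:
    """Unweighted shortest-path betweenness centrality per node.

    Brandes accumulation; for undirected graphs the normalisation
    divides by (n-1)(n-2)/2. Unreachable pairs contribute zero, so
    disconnected components are handled naturally.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return dict(nx.betweenness_centrality(network.graph, normalized=normalized))


def rank_hubs(centrality: Mapping[str, float], k: int) -> list:
    """Top-k genes by descending centrality, ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(centrality, key=lambda g: (-centrality[g], g))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds node count {len(ranked)}; returning all nodes",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


@dataclass(frozen=True)
class EnrichmentResult:
    """One annotation set's over-representation test."""

    name: str
    overlap: int
    set_size: int  # after intersection with the universe
    query_size: int
    universe_size: int
    p: float
    p_adj: float


def ora(
    query: GeneSet,
    universe: GeneSet,
    annotation_sets: Sequence[GeneSet],
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each set.

    p = P(X >= overlap) drawing |query| genes from a universe with
    |set ∩ universe| successes; annotation sets are intersected with the
    universe before testing; sets with zero overlap report p = 1 by
    convention. Benjamini-Hochberg adjustment across all tested sets.
    """
    offenders = query.members - universe.members
    if offenders:
        raise ValueError(
            f"query genes outside the universe: {sorted(offenders)[:10]}"
        )
    m = len(universe.members)
    n_query = len(query.members)
    rows = []
    for s in annotation_sets:
        in_universe = s.members & universe.members
        k = len(in_universe & query.members)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, m, len(in_universe), n_query))
        rows.append(
            {
                "name": s.name,
                "overlap": k,
                "set_size": len(in_universe),
                "query_size": n_query,
                "universe_size": m,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df


# ---------------------------------------------------------------------------
# Plain-text readers


def read_gene_list(path, name: Optional[str] = None) -> GeneSet:
    """One gene symbol per line."""
    p = Path(path)
    symbols = [
        line.strip() for line in p.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet.from_iterable(name or p.stem, symbols)


def read_scored_table(path) -> pd.DataFrame:
    """2-column TSV (symbol, score), header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if not pd.api.types.is_numeric_dtype(df.iloc[:, 1]) or isinstance(
        df.iloc[0, 1], str
    ):
        try:
            pd.to_numeric(df.iloc[0, 1])
        except (ValueError, TypeError):
            df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :2]
    df.columns = ["symbol", "score"]
    df["score"] = pd.to_numeric(df["score"])
    return df


def read_edge_list(path) -> GeneNetwork:
    """3-column TSV (gene1, gene2, score)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    try:
        pd.to_numeric(df.iloc[0, 2])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    return GeneNetwork.from_edges(
        (r[0], r[1], float(r[2])) for r in df.itertuples(index=False)
    )


def read_gmt(path) -> list:
    """GMT format: name <tab> description <tab> member symbols..."""
    sets = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet.from_iterable(parts[0], parts[2:]))
    return sets
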