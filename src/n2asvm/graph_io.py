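"""Loading and validation of PPI networks and gene sets, plus tabular output.

The network is an undirected, weighted, simple graph over opaque gene
identifiers.  Edge lists are whitespace-separated text with two or three
columns (``u v [weight]``); ``#`` lines are comments.  Gene sets are plain
text, one identifier per line.  Ranked predictions are written as a TSV with
columns ``gene  score  rank``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("gene", "score", "rank")


class GeneGraph:
    """Undirected weighted simple graph over gene identifiers.

    Invariants: no self-loops, no duplicate edges, strictly positive finite
    weights, symmetric adjacency.  Backed by :class:`networkx.Graph`; the
    wrapper enforces the invariants at mutation time and provides sorted,
    deterministic iteration orders.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction ----------------------------------------------------
    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> bool:
        """Add edge {u, v}.  Returns False (and keeps the first weight) if the
        edge already exists; raises on self-loops and bad weights."""
        if u == v:
            raise ValidationError(f"self-loop on node {u!r} is not allowed")
        if not (math.isfinite(weight) and weight > 0):
            raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive or non-finite weight {weight!r}")
        if self._g.has_edge(u, v):
            return False
        self._g.add_edge(u, v, weight=float(weight))
        return True

    # -- access ----------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        """(neighbor, weight) pairs in sorted neighbor order."""
        adj = self._g.adj[node]
        return [(x, adj[x]["weight"]) for x in sorted(adj)]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self._g.adj[u][v]["weight"]

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def stats(self) -> dict[str, int]:
        return {"nodes": self.n_nodes, "edges": self.n_edges}

    def to_networkx(self) -> nx.Graph:
        """The underlying networkx graph (shared, do not mutate)."""
        return self._g

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self._g.edges(data=True):
            yield u, v, d["weight"]


@dataclass
class GeneSet:
    """A deduplicated set of gene identifiers with a free-text label."""

    members: set[str]
    label: str = "genes"

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


def read_edge_list(path: str | Path, default_weight: float = 1.0) -> GeneGraph:
    """Load an undirected edge list.

    Duplicate lines (including reversed duplicates) collapse to one edge,
    keeping the first weight seen; self-loop lines are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge list not found: {path}")
    if not (math.isfinite(default_weight) and default_weight > 0):
        raise ValidationError(f"default_weight must be positive and finite, got {default_weight}")
    graph = GeneGraph()
    self_loops = 0
    duplicates = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}")
            u, v = fields[0], fields[1]
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: weight {fields[2]!r} is not a number") from exc
                if not (math.isfinite(w) and w > 0):
                    raise ValidationError(f"{path}:{lineno}: weight must be positive and finite, got {w}")
            else:
                w = default_weight
            if u == v:
                self_loops += 1
                continue
            if not graph.add_edge(u, v, w):
                duplicates += 1
    if self_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, self_loops)
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edge line(s) (first weight kept)", path, duplicates)
    return graph


def read_gene_set(path: str | Path, label: str = "genes") -> GeneSet:
    """Load a one-identifier-per-line gene set; blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene set not found: {path}")
    seen: set[str] = set()
    duplicates = 0
    with path.open() as fh:
        for raw in fh:
            gene = raw.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene in seen:
                duplicates += 1
            else:
                seen.add(gene)
    if duplicates:
        logger.info("%s: removed %d duplicate identifier(s)", path, duplicates)
    if not seen:
        raise ValidationError(f"{path}: gene set is empty")
    return GeneSet(members=seen, label=label)


def restrict_to_graph(genes: GeneSet, graph: GeneGraph) -> GeneSet:
    """Intersect a gene set with the graph's node set; error if nothing is left."""
    kept = genes.members & graph.nodes
    dropped = genes.members - graph.nodes
    if dropped:
        logger.info("dropped %d gene(s) absent from the network: %s", len(dropped), sorted(dropped)[:10])
    if not kept:
        raise ValidationError(f"no gene of set {genes.label!r} is present in the network")
    return GeneSet(members=kept, label=genes.label)


def write_scores(table: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write a ScoredGeneTable as TSV (descending score, ranks 1..n).

    ``table`` must have columns gene/score/rank with unique gene ids.
    Optional comment lines (``# ...``) carry provenance.
    """
    if list(table.columns) != list(SCORE_COLUMNS):
        raise ValidationError(f"score table must have columns {SCORE_COLUMNS}, got {tuple(table.columns)}")
    if table["gene"].duplicated().any():
        raise ValidationError("score table has duplicate gene identifiers")
    out = table.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    path = Path(path)
    try:
        with path.open("w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write("\t".join(SCORE_COLUMNS) + "\n")
            for _, row in out.iterrows():
                fh.write(f"{row['gene']}\t{row['score']:.10g}\t{int(row['rank'])}\n")
    except OSError as exc:
        raise InputError(f"cannot write score table to {path}: {exc}") from exc


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a score TSV written by :func:`write_scores`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"score table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    if list(df.columns) != list(SCORE_COLUMNS):
        raise ParseError(f"{path}: expected columns {SCORE_COLUMNS}, got {tuple(df.columns)}")
    return df


def write_edge_list(graph: GeneGraph, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Dump a graph in the 3-column edge-list format (sorted, deterministic)."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for u, v, w in sorted((min(a, b), max(a, b), w) for a, b, w in graph.edges()):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_gene_set(genes: GeneSet | Iterable[str], path: str | Path, header_comments: Sequence[str] = ()) -> None:
    members = genes.members if isinstance(genes, GeneSet) else set(genes)
    path = Path(path)
    with path.open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for gene in sorted(members):
            fh.write(gene + "\n")
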