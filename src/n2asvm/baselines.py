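"""Comparison scorers: random walk with restart, shortest-path length, and
Euclidean distance.

Each scorer assigns every candidate gene a single real score, oriented so
that HIGHER means more disease-like; that convention lets every method feed
the same AUROC evaluation.  Raw proximity values (path lengths, distances)
are therefore negated on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .embedding import EmbeddingMatrix
from .errors import ConvergenceError, UndefinedMetricError, ValidationError
from .graph_io import GeneGraph, GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RWRParams:
    """Random-walk-with-restart settings: restart probability r in (0,1),
    L1 convergence tolerance, and iteration cap."""

    restart_prob: float = 0.5
    tolerance: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValidationError(f"restart_prob must be in (0,1), got {self.restart_prob}")
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


def _transition_matrix(graph: GeneGraph) -> tuple[list[str], sp.csr_matrix]:
    """Sorted node ids and the column-stochastic operator W^T, where W is the
    row-normalized weighted adjacency (rows of isolated nodes stay zero)."""
    ids = graph.sorted_nodes()
    index = {g: i for i, g in enumerate(ids)}
    rows, cols, vals = [], [], []
    for u in ids:
        nbrs = graph.neighbors(u)
        total = sum(w for _, w in nbrs)
        for x, w in nbrs:
            rows.append(index[u])
            cols.append(index[x])
            vals.append(w / total)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(len(ids), len(ids)))
    return ids, W.T.tocsr()


def _rwr_power_iteration(WT: sp.csr_matrix, source_idx: int, params: RWRParams) -> np.ndarray:
    n = WT.shape[0]
    e = np.zeros(n)
    e[source_idx] = 1.0
    r = params.restart_prob
    pi = e.copy()
    for _ in range(params.max_iter):
        new = r * e + (1.0 - r) * (WT @ pi)
        residual = float(np.abs(new - pi).sum())
        pi = new
        if residual < params.tolerance:
            return pi
    raise ConvergenceError(
        f"RWR did not converge within {params.max_iter} iterations (residual {residual:.3e})")


def rwr_vector(graph: GeneGraph, source: str, params: RWRParams = RWRParams()) -> np.ndarray:
    """Diffusion state of ``source``: the fixed point of
    pi = r*e_source + (1-r)*W^T pi, indexed by sorted node order."""
    ids = graph.sorted_nodes()
    if source not in graph.nodes:
        raise ValidationError(f"source {source!r} is not in the graph")
    idx = ids.index(source)
    if graph.degree(source) == 0:
        e = np.zeros(len(ids))
        e[idx] = 1.0  # all mass stays at the source via restart
        return e
    _, WT = _transition_matrix(graph)
    return _rwr_power_iteration(WT, idx, params)


def rwr_feature_matrix(graph: GeneGraph, params: RWRParams = RWRParams()) -> EmbeddingMatrix:
    """One diffusion-state row per gene (|nodes| columns, sorted node order):
    the network-global feature representation used by the RWA-SVM variant."""
    ids, WT = _transition_matrix(graph)
    n = len(ids)
    M = np.zeros((n, n))
    for i, g in enumerate(ids):
        if graph.degree(g) == 0:
            M[i, i] = 1.0  # isolated: restart keeps all mass at the source
        else:
            M[i] = _rwr_power_iteration(WT, i, params)
    return EmbeddingMatrix(ids=ids, vectors=M)


def rwr_scores(
    graph: GeneGraph,
    positives: GeneSet,
    candidates: Sequence[str],
    params: RWRParams = RWRParams(),
) -> dict[str, float]:
    """Diffusion-proximity score per candidate: the mean over seed genes
    (excluding the candidate itself) of the seed's diffusion state at the
    candidate."""
    ids, WT = _transition_matrix(graph)
    index = {g: i for i, g in enumerate(ids)}
    pos = sorted(positives.members & graph.nodes)
    if not pos:
        raise ValidationError("no positive gene is present in the graph")
    states = {}
    for p in pos:
        if graph.degree(p) == 0:
            e = np.zeros(len(ids))
            e[index[p]] = 1.0
            states[p] = e
        else:
            states[p] = _rwr_power_iteration(WT, index[p], params)
    scores = {}
    for g in candidates:
        if g not in index:
            raise ValidationError(f"candidate {g!r} is not in the graph")
        seeds = [p for p in pos if p != g]
        if not seeds:
            raise UndefinedMetricError(f"no seed gene besides candidate {g!r}")
        scores[g] = float(np.mean([states[p][index[g]] for p in seeds]))
    return scores


def spl_score(
    graph: GeneGraph,
    positives: GeneSet,
    candidate: str,
    _diameter_cache: dict | None = None,
) -> float:
    """Negated mean shortest-path length from the candidate to the known
    disease genes (unweighted BFS).  Positives outside the candidate's
    component contribute (component diameter + 1) so scores stay finite."""
    if candidate not in graph.nodes:
        raise ValidationError(f"candidate {candidate!r} is not in the graph")
    pos = sorted((positives.members & graph.nodes) - {candidate})
    if not pos:
        raise UndefinedMetricError("no positive gene to measure distance to")
    g = graph.to_networkx()
    dist = nx.single_source_shortest_path_length(g, candidate)
    unreachable = [p for p in pos if p not in dist]
    lengths = [dist[p] for p in pos if p in dist]
    if unreachable:
        comp = frozenset(dist)  # candidate's component
        if _diameter_cache is not None and comp in _diameter_cache:
            diam = _diameter_cache[comp]
        else:
            diam = max(nx.eccentricity(g.subgraph(comp)).values()) if len(comp) > 1 else 0
            if _diameter_cache is not None:
                _diameter_cache[comp] = diam
        lengths.extend([diam + 1] * len(unreachable))
    return -float(np.mean(lengths))


def spl_scores(graph: GeneGraph, positives: GeneSet, candidates: Sequence[str]) -> dict[str, float]:
    cache: dict = {}
    return {g: spl_score(graph, positives, g, _diameter_cache=cache) for g in candidates}


def adjacency_features(graph: GeneGraph) -> EmbeddingMatrix:
    """Binary adjacency rows in sorted node order — the default network
    representation for the Euclidean-distance baseline."""
    ids = graph.sorted_nodes()
    index = {g: i for i, g in enumerate(ids)}
    M = np.zeros((len(ids), len(ids)))
    for u, v, _ in graph.edges():
        M[index[u], index[v]] = 1.0
        M[index[v], index[u]] = 1.0
    return EmbeddingMatrix(ids=ids, vectors=M)


def euclid_score(features: EmbeddingMatrix, positives: GeneSet, candidate: str) -> float:
    """Negated mean Euclidean distance between the candidate's feature row
    and each known disease gene's row (candidate excluded from the seeds)."""
    if candidate not in features:
        raise ValidationError(f"candidate {candidate!r} has no feature row")
    pos = sorted(p for p in positives.members if p != candidate)
    if not pos:
        raise UndefinedMetricError("no positive gene to measure distance to")
    rows = features.rows(pos)
    c = features.vector(candidate)
    return -float(np.mean(np.sqrt(np.sum((rows - c) ** 2, axis=1))))


def euclid_scores(features: EmbeddingMatrix, positives: GeneSet, candidates: Sequence[str]) -> dict[str, float]:
    return {g: euclid_score(features, positives, g) for g in candidates}
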