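"""Second-order biased random walks over the gene network.

The walker at node ``v``, having arrived from node ``t``, weights each
neighbor ``x`` of ``v`` by ``alpha(d_tx) * w_vx`` where ``d_tx`` is the
shortest distance between ``t`` and ``x`` (necessarily 0, 1, or 2 when ``x``
is adjacent to ``v``):

    alpha = 1/p  if d_tx = 0   (return to the previous node)
    alpha = 1    if d_tx = 1   (stay in the common neighborhood, BFS-like)
    alpha = 1/q  if d_tx = 2   (move outward, DFS-like)

Large ``p`` discourages backtracking; ``q < 1`` pushes the walk away from
its source.  The first step of each walk, where no previous node exists,
uses the plain first-order distribution ``w_vx / sum w``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .graph_io import GeneGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    """Biased-walk hyperparameters.

    p: return parameter (>0); q: in-out parameter (>0);
    walk_length: nodes per walk; walks_per_node: walks started at each node.
    """

    p: float = 2.0
    q: float = 0.1
    walk_length: int = 80
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValidationError(f"p must be > 0, got {self.p}")
        if not self.q > 0:
            raise ValidationError(f"q must be > 0, got {self.q}")
        if self.walk_length < 1:
            raise ValidationError(f"walk_length must be >= 1, got {self.walk_length}")
        if self.walks_per_node < 1:
            raise ValidationError(f"walks_per_node must be >= 1, got {self.walks_per_node}")


@dataclass(frozen=True)
class WalkState:
    """Current walker position ``current`` and previous position ``prev``
    (None on the first step)."""

    prev: Optional[str]
    current: str


@dataclass
class WalkCorpus:
    """Ordered list of node-id walks plus the parameters that produced them."""

    walks: list[list[str]]
    provenance: WalkParams

    def __len__(self) -> int:
        return len(self.walks)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for walk in self.walks:
                fh.write(" ".join(walk) + "\n")

    @staticmethod
    def load(path: str | Path, provenance: WalkParams | None = None) -> "WalkCorpus":
        walks = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    walks.append(line.split())
        return WalkCorpus(walks=walks, provenance=provenance or WalkParams())


def alpha(d_tx: int, params: WalkParams) -> float:
    """Search bias for a neighbor at distance ``d_tx`` from the previous node."""
    if d_tx == 0:
        return 1.0 / params.p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / params.q
    raise ValidationError(f"d_tx must be 0, 1, or 2, got {d_tx}")


def transition_distribution(
    graph: GeneGraph, state: WalkState, params: WalkParams
) -> dict[str, float]:
    """Normalized next-step distribution over neighbors of ``state.current``.

    With a previous node ``t``, each neighbor ``x`` gets unnormalized mass
    ``alpha(d_tx) * w_vx``; without one, mass is ``w_vx`` (first-order).
    """
    nbrs = graph.neighbors(state.current)
    if not nbrs:
        raise ValidationError(f"node {state.current!r} is isolated; no transition exists")
    t = state.prev
    masses = {}
    for x, w in nbrs:
        if t is None:
            a = 1.0
        elif x == t:
            a = alpha(0, params)
        elif graph.has_edge(t, x):
            a = alpha(1, params)
        else:
            a = alpha(2, params)
        masses[x] = a * w
    total = sum(masses.values())
    return {x: m / total for x, m in masses.items()}


class AliasSampler:
    """Vose alias method: O(n) build, O(1) categorical draws.

    Accepts a mapping or parallel (labels, probs); probabilities must be
    nonnegative and sum to 1 within 1e-9.
    """

    def __init__(self, probs: Mapping[str, float] | None = None,
                 labels: Sequence | None = None, p: Sequence[float] | None = None) -> None:
        if probs is not None:
            labels = list(probs.keys())
            p = np.asarray(list(probs.values()), dtype=float)
        else:
            p = np.asarray(p, dtype=float)
            labels = list(labels)
        if np.any(p < 0):
            raise ValidationError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"probabilities must sum to 1, got {p.sum():.12g}")
        self.labels = labels
        n = len(p)
        scaled = p * n
        self._prob = np.zeros(n)
        self._alias = np.zeros(n, dtype=np.int64)
        small = [i for i in range(n) if scaled[i] < 1.0]
        large = [i for i in range(n) if scaled[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self._prob[s] = scaled[s]
            self._alias[s] = l
            scaled[l] = scaled[l] - (1.0 - scaled[s])
            (small if scaled[l] < 1.0 else large).append(l)
        for i in large + small:
            self._prob[i] = 1.0

    def draw_indices(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        cols = rng.integers(0, len(self._prob), size=size)
        coins = rng.random(size)
        return np.where(coins < self._prob[cols], cols, self._alias[cols])

    def draw(self, rng: np.random.Generator):
        return self.labels[int(self.draw_indices(rng, 1)[0])]

    def draw_many(self, rng: np.random.Generator, size: int) -> list:
        return [self.labels[int(i)] for i in self.draw_indices(rng, size)]


def build_alias_table(probs: Mapping[str, float]) -> AliasSampler:
    """Preprocess a categorical distribution for constant-time sampling."""
    return AliasSampler(probs=probs)


class _IndexedGraph:
    """Integer-indexed adjacency arrays for fast walking; nodes sorted."""

    def __init__(self, graph: GeneGraph) -> None:
        self.ids = graph.sorted_nodes()
        index = {g: i for i, g in enumerate(self.ids)}
        self.nbrs: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        self.nbr_sets: list[frozenset[int]] = []
        for g in self.ids:
            pairs = graph.neighbors(g)
            idx = np.array([index[x] for x, _ in pairs], dtype=np.int64)
            w = np.array([w for _, w in pairs], dtype=float)
            self.nbrs.append(idx)
            self.weights.append(w)
            self.nbr_sets.append(frozenset(int(i) for i in idx))


def _step_probs(ig: _IndexedGraph, prev: int, cur: int, inv_p: float, inv_q: float) -> np.ndarray:
    nbr = ig.nbrs[cur]
    mass = ig.weights[cur].copy()
    prev_set = ig.nbr_sets[prev]
    for k in range(len(nbr)):
        x = int(nbr[k])
        if x == prev:
            mass[k] *= inv_p
        elif x not in prev_set:
            mass[k] *= inv_q
        # d_tx == 1: alpha = 1, mass unchanged
    return mass / mass.sum()


def generate_walks(graph: GeneGraph, params: WalkParams) -> WalkCorpus:
    """Run ``walks_per_node`` biased walks of ``walk_length`` nodes from every
    node (sorted order); isolated nodes yield single-node walks.  Fully
    deterministic given (graph, params.seed)."""
    if graph.n_nodes == 0:
        raise ValidationError("cannot generate walks on an empty graph")
    ig = _IndexedGraph(graph)
    rng = np.random.default_rng(params.seed)
    inv_p, inv_q = 1.0 / params.p, 1.0 / params.q
    walks: list[list[str]] = []
    for u in range(len(ig.ids)):
        for _ in range(params.walks_per_node):
            walk = [u]
            if len(ig.nbrs[u]) == 0:
                walks.append([ig.ids[u]])
                continue
            # first step: first-order distribution w_vx / sum w
            if params.walk_length > 1:
                w = ig.weights[u]
                probs = w / w.sum()
                cum = np.cumsum(probs)
                nxt = int(ig.nbrs[u][np.searchsorted(cum, rng.random())])
                walk.append(nxt)
            while len(walk) < params.walk_length:
                prev, cur = walk[-2], walk[-1]
                probs = _step_probs(ig, prev, cur, inv_p, inv_q)
                cum = np.cumsum(probs)
                nxt = int(ig.nbrs[cur][np.searchsorted(cum, rng.random())])
                walk.append(nxt)
            walks.append([ig.ids[i] for i in walk])
    logger.info("generated %d walks (%d nodes x %d walks/node)",
                len(walks), len(ig.ids), params.walks_per_node)
    return WalkCorpus(walks=walks, provenance=params)
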