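"""Synthetic fixtures with planted ground truth.

A planted-partition (stochastic block model) graph mimics the
guilt-by-association structure of a disease module inside a PPI network:
genes in the same block interact more densely (p_in) than genes across
blocks (p_out).  Block 1 plays the role of the disease module; a subset of
it is revealed as the known positive set and the remainder is kept as
held-out truth, so ranking methods can be scored against genuinely
"undiscovered" disease genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .graph_io import GeneGraph, GeneSet


@dataclass(frozen=True)
class PlantedConfig:
    block_sizes: tuple[int, ...] = (60, 120, 120)
    p_in: float = 0.15
    p_out: float = 0.01
    n_positives: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValidationError("block_sizes must be positive integers")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValidationError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}")
        if not 1 <= self.n_positives <= self.block_sizes[0]:
            raise ValidationError(
                f"n_positives must be in [1, {self.block_sizes[0]}], got {self.n_positives}")


def planted_partition(config: PlantedConfig) -> tuple[GeneGraph, GeneSet, GeneSet]:
    """Sample the planted graph and split block 1 into known positives and
    held-out truth.  Reproducible given config.seed."""
    rng = np.random.default_rng(config.seed)
    sizes = config.block_sizes
    total = sum(sizes)
    width = max(4, len(str(total)))
    ids = [f"G{i:0{width}d}" for i in range(total)]
    block_of = np.repeat(np.arange(len(sizes)), sizes)

    graph = GeneGraph()
    for g in ids:
        graph.add_node(g)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for bi in range(len(sizes)):
        for bj in range(bi, len(sizes)):
            p = config.p_in if bi == bj else config.p_out
            if p == 0.0:
                continue
            if bi == bj:
                a, b = np.triu_indices(sizes[bi], k=1)
                a = a + starts[bi]
                b = b + starts[bi]
            else:
                a, b = np.meshgrid(
                    np.arange(starts[bi], starts[bi + 1]),
                    np.arange(starts[bj], starts[bj + 1]),
                    indexing="ij")
                a, b = a.ravel(), b.ravel()
            keep = rng.random(len(a)) < p
            for u, v in zip(a[keep], b[keep]):
                graph.add_edge(ids[u], ids[v], 1.0)

    block1 = [ids[i] for i in range(total) if block_of[i] == 0]
    chosen = rng.choice(len(block1), size=config.n_positives, replace=False)
    positives = {block1[i] for i in chosen}
    truth = set(block1) - positives
    return (
        graph,
        GeneSet(members=positives, label="positives"),
        GeneSet(members=truth, label="held_out_truth"),
    )


def noise_features(n_rows: int, n_cols: int, seed: int = 0) -> np.ndarray:
    """Pure-noise feature matrix (standard normal): the null control that
    should drive any classifier to chance-level AUROC."""
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("dimensions must be positive")
    return np.random.default_rng(seed).standard_normal((n_rows, n_cols))


def subspace_data(
    n_rows: int, ambient_dim: int, intrinsic_dim: int, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Points on a random ``intrinsic_dim``-dimensional linear subspace of
    ``ambient_dim``-space (orthonormal basis), plus isotropic noise: the
    fixture on which a linear autoencoder must match principal-component
    truncation."""
    if intrinsic_dim >= ambient_dim:
        raise ValidationError("intrinsic_dim must be < ambient_dim")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_rows, intrinsic_dim))
    basis, _ = np.linalg.qr(rng.standard_normal((ambient_dim, intrinsic_dim)))
    X = latent @ basis.T
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
    return X
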