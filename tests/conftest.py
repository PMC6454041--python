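"""Shared fixtures: tiny hand-built graphs, random-graph helpers, and the
(expensive, session-scoped) five-seed end-to-end evaluation on the planted
fixture."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from n2asvm import autoencoder as A
from n2asvm import classify as C
from n2asvm import embedding as E
from n2asvm import walks as W
from n2asvm.baselines import adjacency_features, euclid_scores
from n2asvm.classify import (
    LabeledFeatures, PipelineConfig, fit_final_model, kfold_auroc,
    make_dataset, rank_candidates, sample_negatives,
)
from n2asvm.graph_io import GeneGraph, GeneSet
from n2asvm.seeds import derive_seed
from n2asvm.synthetic import PlantedConfig, planted_partition


def build_graph(edges, nodes=()) -> GeneGraph:
    g = GeneGraph()
    for n in nodes:
        g.add_node(n)
    for e in edges:
        g.add_edge(*e)
    return g


def random_gnp_graph(n: int, p: float, seed: int, weighted: bool = False) -> GeneGraph:
    """Erdos-Renyi graph over G000..; isolated nodes kept."""
    rng = np.random.default_rng(seed)
    ids = [f"N{i:03d}" for i in range(n)]
    g = GeneGraph()
    for gid in ids:
        g.add_node(gid)
    a, b = np.triu_indices(n, k=1)
    keep = rng.random(len(a)) < p
    for u, v in zip(a[keep], b[keep]):
        w = float(rng.uniform(0.5, 2.0)) if weighted else 1.0
        g.add_edge(ids[u], ids[v], w)
    return g


@pytest.fixture
def path_abcd() -> GeneGraph:
    return build_graph([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def weighted_triangle() -> GeneGraph:
    return build_graph([("A", "B", 1.0), ("B", "C", 2.0), ("A", "C", 1.0)])


def fixture_pipeline_config(master_seed: int) -> PipelineConfig:
    """Pipeline parameters scaled to the 300-node planted fixture: 64-dim
    embedding compressed to a 16-dim code."""
    return PipelineConfig(
        embed=E.EmbedParams(dimension=64, window=10, epochs=5),
        ae=A.AEParams(layer_sizes=(64, 16), epochs=200),
        master_seed=master_seed,
    )


def run_planted_study(seed: int) -> dict:
    """One full study on the default planted fixture: embed, reduce, evaluate
    the SVM variants, a label-shuffled null, the adjacency-distance baseline,
    and held-out-gene recovery of the top-10 ranking."""
    cfg = fixture_pipeline_config(seed)
    graph, positives, truth = planted_partition(PlantedConfig(seed=seed))
    corpus = W.generate_walks(graph, dataclasses.replace(cfg.walk, seed=cfg.stage_seed("walks")))
    emb = E.train_sgns(corpus, dataclasses.replace(cfg.embed, seed=cfg.stage_seed("embed")))
    enc = A.train_autoencoder(
        emb.vectors, dataclasses.replace(cfg.ae, seed=cfg.stage_seed("autoencoder")))
    reduced = E.EmbeddingMatrix(ids=emb.ids, vectors=A.encode(enc, emb.vectors))

    negatives = sample_negatives(GeneSet(graph.nodes, "universe"), positives,
                                 cfg.stage_seed("negatives"))
    cvc = dataclasses.replace(cfg.cv, seed=cfg.stage_seed("cv"))
    data_reduced = make_dataset(reduced, positives, negatives)
    data_raw = make_dataset(emb, positives, negatives)

    n2a = kfold_auroc(data_reduced, cfg.svm, cvc).mean_auroc
    n2v = kfold_auroc(data_raw, cfg.svm, cvc).mean_auroc

    labeled = sorted(positives.members) + sorted(negatives.members)
    y = np.array([1] * len(positives.members) + [0] * len(negatives.members))
    ed_scores = euclid_scores(adjacency_features(graph), positives, labeled)
    ed = C.auroc([ed_scores[g] for g in labeled], y)

    rng = np.random.default_rng(derive_seed(seed, "label-shuffle"))
    shuffled = LabeledFeatures(data_reduced.ids, data_reduced.X, rng.permutation(data_reduced.y))
    null = kfold_auroc(shuffled, cfg.svm, cvc).mean_auroc

    model = fit_final_model(data_reduced, cfg.svm, seed=cfg.stage_seed("svm"))
    unlabeled = sorted(graph.nodes - positives.members - negatives.members)
    table = rank_candidates(model, reduced, unlabeled)
    recovered = len(set(table.head(10)["gene"]) & truth.members)

    return {"n2a": n2a, "n2v": n2v, "ed": ed, "null": null, "recovered": recovered,
            "n_genes": graph.n_nodes, "truth_in_unlabeled": len(set(unlabeled) & truth.members)}


@pytest.fixture(scope="session")
def planted_study_5seeds() -> list[dict]:
    return [run_planted_study(seed) for seed in range(5)]
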