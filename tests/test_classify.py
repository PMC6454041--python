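"""classify: negative sampling, dataset assembly, the Mann-Whitney AUROC,
cross-validation, pipeline variants, and ranking."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold

from n2asvm.classify import (
    CVConfig, LabeledFeatures, PipelineConfig, SVMParams, auroc,
    fit_final_model, kfold_auroc, make_dataset, rank_candidates,
    run_pipeline, sample_negatives,
)
from n2asvm.embedding import EmbeddingMatrix
from n2asvm.errors import UndefinedMetricError, ValidationError
from n2asvm.graph_io import GeneSet
from n2asvm.synthetic import PlantedConfig, noise_features, planted_partition

from conftest import fixture_pipeline_config


def brute_force_auroc(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def features_of(n, d, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"g{i:03d}" for i in range(n)]
    return EmbeddingMatrix(ids=ids, vectors=rng.standard_normal((n, d)))


class TestSampleNegatives:
    def test_size_and_disjointness(self):
        universe = GeneSet({f"g{i}" for i in range(10)}, "u")
        pos = GeneSet({"g0", "g1", "g2"}, "p")
        neg = sample_negatives(universe, pos, seed=0)
        assert len(neg) == 3
        assert not neg.members & pos.members

    def test_all_positive_universe_is_error(self):
        u = GeneSet({"a", "b"}, "u")
        with pytest.raises(ValidationError):
            sample_negatives(u, GeneSet({"a", "b"}, "p"), seed=0)

    def test_seeded_determinism_and_variability(self):
        u = GeneSet({f"g{i}" for i in range(50)}, "u")
        pos = GeneSet({"g0", "g1", "g2", "g3", "g4"}, "p")
        assert sample_negatives(u, pos, 7).members == sample_negatives(u, pos, 7).members
        distinct = {frozenset(sample_negatives(u, pos, s).members) for s in range(100)}
        assert len(distinct) > 10


class TestMakeDataset:
    def test_balanced_construction(self):
        f = features_of(10, 4)
        data = make_dataset(f, GeneSet({"g000", "g001", "g002"}, "p"),
                            GeneSet({"g005", "g006", "g007"}, "n"))
        assert list(data.y) == [1, 1, 1, 0, 0, 0]
        assert data.ids == ["g000", "g001", "g002", "g005", "g006", "g007"]

    def test_overlap_rejected(self):
        f = features_of(10, 4)
        with pytest.raises(ValidationError):
            make_dataset(f, GeneSet({"g000"}, "p"), GeneSet({"g000"}, "n"))

    def test_missing_row_names_gene(self):
        f = features_of(5, 4)
        with pytest.raises(ValidationError, match="nope"):
            make_dataset(f, GeneSet({"g000"}, "p"), GeneSet({"nope"}, "n"))


class TestAUROC:
    def test_hand_counted_pairs(self):
        assert auroc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_boundary_cases(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 2], [1, 1])

    def test_equals_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 50))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.standard_normal(n), 1)  # coarse -> ties occur
            assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(30)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        transformed = np.exp(3 * scores) + 2
        assert auroc(scores, labels) == pytest.approx(auroc(transformed, labels))


class TestKFold:
    def test_partition_arithmetic(self):
        data = LabeledFeatures(ids=[f"g{i}" for i in range(40)],
                               X=np.random.default_rng(0).standard_normal((40, 3)),
                               y=np.array([1] * 20 + [0] * 20))
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = []
        for _, test_idx in splitter.split(data.X, data.y):
            assert len(test_idx) == 4
            assert data.y[test_idx].sum() == 2  # 2 positives, 2 negatives
            seen.extend(test_idx)
        assert sorted(seen) == list(range(40))

    def test_perfect_signal_gives_auroc_one(self):
        y = np.array([1] * 20 + [0] * 20)
        X = np.column_stack([y, y]).astype(float)
        data = LabeledFeatures(ids=[f"g{i}" for i in range(40)], X=X, y=y)
        res = kfold_auroc(data, SVMParams(), CVConfig(k=10, seed=0))
        assert res.mean_auroc == 1.0

    def test_pure_noise_is_chance_level(self):
        aurocs = []
        for rep in range(20):
            y = np.array([1] * 100 + [0] * 100)
            X = noise_features(200, 8, seed=rep)
            data = LabeledFeatures(ids=[f"g{i}" for i in range(200)], X=X, y=y)
            aurocs.append(kfold_auroc(data, SVMParams(), CVConfig(k=10, seed=rep)).mean_auroc)
        assert 0.4 <= np.mean(aurocs) <= 0.6

    def test_too_few_samples_per_class(self):
        data = LabeledFeatures(ids=["a", "b", "c", "d"],
                               X=np.zeros((4, 2)), y=np.array([1, 1, 0, 0]))
        with pytest.raises(ValidationError):
            kfold_auroc(data, SVMParams(), CVConfig(k=10))

    def test_reproducible_given_seed(self):
        data = LabeledFeatures(ids=[f"g{i}" for i in range(40)],
                               X=np.random.default_rng(1).standard_normal((40, 5)),
                               y=np.array([1] * 20 + [0] * 20))
        r1 = kfold_auroc(data, SVMParams(), CVConfig(k=5, seed=3))
        r2 = kfold_auroc(data, SVMParams(), CVConfig(k=5, seed=3))
        assert r1.fold_aurocs == r2.fold_aurocs


def small_planted():
    return planted_partition(PlantedConfig(block_sizes=(30, 60, 60), p_in=0.2,
                                           p_out=0.01, n_positives=15, seed=0))


def small_config():
    import n2asvm.autoencoder as A
    import n2asvm.embedding as E
    import n2asvm.walks as W
    return PipelineConfig(
        walk=W.WalkParams(walk_length=30, walks_per_node=5),
        embed=E.EmbedParams(dimension=32, window=5, epochs=3),
        ae=A.AEParams(layer_sizes=(32, 8), epochs=100),
        cv=CVConfig(k=5),
        master_seed=0,
    )


class TestRunPipeline:
    def test_variant_records_differ_only_in_reduction(self):
        graph, pos, _ = small_planted()
        cfg = small_config()
        n2a = run_pipeline(graph, pos, "n2a-svm", cfg)
        n2v = run_pipeline(graph, pos, "n2v-svm", cfg)
        assert n2a.provenance["reduction"] and not n2v.provenance["reduction"]
        assert n2a.provenance["feature_dim"] == 8
        assert n2v.provenance["feature_dim"] == 32
        for key in ("walk", "embed", "svm", "cv", "master_seed"):
            assert n2a.provenance[key] == n2v.provenance[key]

    def test_rwa_variant_reduces_diffusion_features(self):
        graph, pos, _ = small_planted()
        rec = run_pipeline(graph, pos, "rwa-svm", small_config())
        assert rec.provenance["feature_dim"] == 8
        assert rec.mean_auroc > 0.6  # diffusion states carry the planted signal

    def test_baseline_variants_run_without_cv(self):
        graph, pos, _ = small_planted()
        cfg = small_config()
        for variant in ("rwr", "spl", "ed"):
            rec = run_pipeline(graph, pos, variant, cfg)
            assert len(rec.fold_aurocs) == 1
            assert 0.0 <= rec.mean_auroc <= 1.0

    def test_unknown_variant_rejected(self):
        graph, pos, _ = small_planted()
        with pytest.raises(ValidationError):
            run_pipeline(graph, pos, "pca-svm", small_config())

    def test_end_to_end_determinism(self):
        graph, pos, _ = small_planted()
        cfg = small_config()
        r1 = run_pipeline(graph, pos, "n2a-svm", cfg)
        r2 = run_pipeline(graph, pos, "n2a-svm", cfg)
        assert r1.fold_aurocs == r2.fold_aurocs


class TestRanking:
    def test_shape_and_rank_sequence(self):
        f = features_of(20, 4, seed=1)
        y = np.array([1] * 5 + [0] * 5)
        data = LabeledFeatures(ids=f.ids[:10], X=f.vectors[:10], y=y)
        model = fit_final_model(data, SVMParams(), seed=0)
        table = rank_candidates(model, f, f.ids[10:15])
        assert list(table["rank"]) == [1, 2, 3, 4, 5]
        assert set(table["gene"]) == set(f.ids[10:15])
        assert table["score"].is_monotonic_decreasing

    def test_positive_lookalike_ranked_above_negative_lookalike(self):
        rng = np.random.default_rng(2)
        pos_rows = rng.standard_normal((10, 4)) + 3.0
        neg_rows = rng.standard_normal((10, 4)) - 3.0
        ids = [f"p{i}" for i in range(10)] + [f"n{i}" for i in range(10)] + ["cp", "cn"]
        vectors = np.vstack([pos_rows, neg_rows, pos_rows[:1], neg_rows[:1]])
        f = EmbeddingMatrix(ids=ids, vectors=vectors)
        data = LabeledFeatures(ids=ids[:20], X=vectors[:20],
                               y=np.array([1] * 10 + [0] * 10))
        model = fit_final_model(data, SVMParams(), seed=0)
        table = rank_candidates(model, f, ["cp", "cn"]).set_index("gene")
        assert table.loc["cp", "rank"] < table.loc["cn", "rank"]

    def test_duplicate_candidates_rejected(self):
        f = features_of(6, 3)
        data = LabeledFeatures(ids=f.ids[:4], X=f.vectors[:4], y=np.array([1, 1, 0, 0]))
        model = fit_final_model(data, SVMParams(), seed=0)
        with pytest.raises(ValidationError):
            rank_candidates(model, f, ["g004", "g004"])

    def test_tie_break_is_lexicographic(self):
        f = EmbeddingMatrix(ids=["a", "b", "c", "d", "z1", "z2"],
                            vectors=np.array([[1.0], [1.1], [-1.0], [-1.1], [0.5], [0.5]]))
        data = LabeledFeatures(ids=["a", "b", "c", "d"], X=f.vectors[:4],
                               y=np.array([1, 1, 0, 0]))
        model = fit_final_model(data, SVMParams(kernel="linear"), seed=0)
        table = rank_candidates(model, f, ["z2", "z1"])
        assert list(table["gene"]) == ["z1", "z2"]  # equal scores -> id order
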