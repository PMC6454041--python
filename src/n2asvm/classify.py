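"""Classification and evaluation: balanced negative sampling, SVM training,
ten-fold cross-validated AUROC, pipeline variants, and candidate ranking.

The prediction task is binary: known disease genes are positives, an
equal-size random sample of the remaining genes is the negative set.  The
AUROC is computed as the Mann-Whitney statistic (probability a random
positive outscores a random negative, ties counted 1/2), so classifier
decision values and baseline proximity scores are directly comparable.

Pipeline variants:

==========  ============================================================
n2a-svm     biased walks -> SGNS embedding -> autoencoder code -> SVM
n2v-svm     biased walks -> SGNS embedding -> SVM (no reduction)
rwa-svm     RWR diffusion-state features  -> autoencoder code -> SVM
rwr         mean diffusion state from the seed genes, scored directly
spl         negated mean shortest-path length to the seed genes
ed          negated mean Euclidean distance to seed genes (adjacency rows)
==========  ============================================================
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from . import autoencoder as ae_mod
from . import baselines, embedding, walks
from .embedding import EmbeddingMatrix
from .errors import UndefinedMetricError, ValidationError
from .graph_io import GeneGraph, GeneSet
from .seeds import derive_seed

logger = logging.getLogger(__name__)

SVM_VARIANTS = ("n2a-svm", "n2v-svm", "rwa-svm")
BASELINE_VARIANTS = ("rwr", "spl", "ed")
VARIANTS = SVM_VARIANTS + BASELINE_VARIANTS


@dataclass
class LabeledFeatures:
    """Balanced training table: ids, feature rows, binary labels."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.ids) == self.X.shape[0] == len(self.y)):
            raise ValidationError("ids / X / y length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in labeled data")


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")


@dataclass(frozen=True)
class SVMParams:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    probability_outputs: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValidationError(f"kernel must be linear or rbf, got {self.kernel!r}")
        if not self.C > 0:
            raise ValidationError("C must be > 0")


def sample_negatives(all_genes: GeneSet, positives: GeneSet, seed: int) -> GeneSet:
    """Uniform sample, without replacement, of non-positive genes; the
    negative set has the same size as the positive set."""
    pool = sorted(all_genes.members - positives.members)
    n = len(positives.members)
    if len(pool) < n:
        raise ValidationError(
            f"need at least {n} non-positive genes to sample negatives, have {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return GeneSet(members={pool[i] for i in chosen}, label="negatives")


def make_dataset(features: EmbeddingMatrix, positives: GeneSet, negatives: GeneSet) -> LabeledFeatures:
    """Assemble the balanced table: positives then negatives, each sorted."""
    overlap = positives.members & negatives.members
    if overlap:
        raise ValidationError(f"positive and negative sets overlap: {sorted(overlap)[:5]}")
    pos = sorted(positives.members)
    neg = sorted(negatives.members)
    missing = [g for g in pos + neg if g not in features]
    if missing:
        raise ValidationError(f"no feature row for gene(s): {missing[:10]}")
    ids = pos + neg
    X = features.rows(ids)
    y = np.array([1] * len(pos) + [0] * len(neg))
    return LabeledFeatures(ids=ids, X=X, y=y)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC: fraction of (positive, negative) pairs where the
    positive outscores the negative, ties counted as 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _fit_svc(X: np.ndarray, y: np.ndarray, svm: SVMParams, seed: int = 0):
    model = SVC(kernel=svm.kernel, C=svm.C, gamma=svm.gamma, random_state=seed)
    model.fit(X, y)
    return model


@dataclass
class FoldResult:
    fold_aurocs: list[float]
    mean_auroc: float


def kfold_auroc(data: LabeledFeatures, svm: SVMParams, cv: CVConfig) -> FoldResult:
    """Stratified (by default) k-fold cross-validated AUROC; each sample is
    tested exactly once, models see only their training folds."""
    n_pos = int((data.y == 1).sum())
    n_neg = int((data.y == 0).sum())
    if cv.stratified and cv.k > min(n_pos, n_neg):
        raise ValidationError(
            f"k={cv.k} exceeds samples in the smaller class ({min(n_pos, n_neg)})")
    splitter = (StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
                if cv.stratified else
                KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed))
    fold_aurocs = []
    for train_idx, test_idx in splitter.split(data.X, data.y):
        model = _fit_svc(data.X[train_idx], data.y[train_idx], svm, seed=cv.seed)
        scores = model.decision_function(data.X[test_idx])
        fold_aurocs.append(auroc(scores, data.y[test_idx]))
    return FoldResult(fold_aurocs=fold_aurocs, mean_auroc=float(np.mean(fold_aurocs)))


@dataclass
class PipelineConfig:
    """Bundle of every stage's parameters plus the master seed.

    Stage seeds are derived from ``master_seed`` (one independent stream per
    stage) unless ``derive_seeds`` is off, in which case the seeds already
    inside each parameter block are used verbatim.
    """

    walk: walks.WalkParams = field(default_factory=walks.WalkParams)
    embed: embedding.EmbedParams = field(default_factory=embedding.EmbedParams)
    ae: ae_mod.AEParams = field(default_factory=ae_mod.AEParams)
    rwr: baselines.RWRParams = field(default_factory=baselines.RWRParams)
    svm: SVMParams = field(default_factory=SVMParams)
    cv: CVConfig = field(default_factory=CVConfig)
    master_seed: int = 0
    derive_seeds: bool = True

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage) if self.derive_seeds else {
            "walks": self.walk.seed, "embed": self.embed.seed,
            "autoencoder": self.ae.seed, "cv": self.cv.seed,
            "negatives": self.master_seed,
        }.get(stage, self.master_seed)


def _ae_params_for(input_dim: int, ae: ae_mod.AEParams, seed: int) -> ae_mod.AEParams:
    """Adapt the configured encoder widths to the actual feature width: the
    first layer is replaced by input_dim, deeper widths wider than the input
    are dropped."""
    tail = [w for w in ae.layer_sizes[1:] if w < input_dim]
    if not tail:
        raise ValidationError(
            f"autoencoder code width {ae.layer_sizes[-1]} does not fit input dim {input_dim}")
    return dataclasses.replace(ae, layer_sizes=(input_dim, *tail), seed=seed)


def compute_features(graph: GeneGraph, variant: str, config: PipelineConfig) -> EmbeddingMatrix:
    """Feature matrix for an SVM variant (walk embedding and/or autoencoder
    code per the variant table)."""
    if variant not in SVM_VARIANTS:
        raise ValidationError(f"variant {variant!r} has no feature stage")
    if variant in ("n2a-svm", "n2v-svm"):
        wp = dataclasses.replace(config.walk, seed=config.stage_seed("walks"))
        corpus = walks.generate_walks(graph, wp)
        ep = dataclasses.replace(config.embed, seed=config.stage_seed("embed"))
        feats = embedding.train_sgns(corpus, ep)
    else:  # rwa-svm
        feats = baselines.rwr_feature_matrix(graph, config.rwr)
    if variant in ("n2a-svm", "rwa-svm"):
        aep = _ae_params_for(feats.vectors.shape[1], config.ae, config.stage_seed("autoencoder"))
        enc = ae_mod.train_autoencoder(feats.vectors, aep)
        feats = EmbeddingMatrix(ids=feats.ids, vectors=ae_mod.encode(enc, feats.vectors))
    return feats


@dataclass
class EvalRecord:
    variant: str
    mean_auroc: float
    fold_aurocs: list[float]
    provenance: dict


def run_pipeline(
    graph: GeneGraph,
    positives: GeneSet,
    variant: str,
    config: PipelineConfig,
    negatives: Optional[GeneSet] = None,
    features: Optional[EmbeddingMatrix] = None,
) -> EvalRecord:
    """Evaluate one variant end to end on (graph, positives).

    Negatives are sampled fresh (balanced, seeded) unless supplied;
    precomputed ``features`` may be passed to reuse an expensive embedding
    across evaluations of the same variant.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    positives = GeneSet(positives.members & graph.nodes, label=positives.label)
    if not positives.members:
        raise ValidationError("no positive gene is present in the graph")
    if negatives is None:
        negatives = sample_negatives(
            GeneSet(graph.nodes, "universe"), positives, config.stage_seed("negatives"))

    if variant in SVM_VARIANTS:
        if features is None:
            features = compute_features(graph, variant, config)
        data = make_dataset(features, positives, negatives)
        cvc = dataclasses.replace(config.cv, seed=config.stage_seed("cv"))
        result = kfold_auroc(data, config.svm, cvc)
        fold_aurocs, mean_auroc = result.fold_aurocs, result.mean_auroc
        feature_dim = features.vectors.shape[1]
    else:
        labeled = sorted(positives.members) + sorted(negatives.members)
        labels = np.array([1] * len(positives.members) + [0] * len(negatives.members))
        if variant == "rwr":
            scores = baselines.rwr_scores(graph, positives, labeled, config.rwr)
        elif variant == "spl":
            scores = baselines.spl_scores(graph, positives, labeled)
        else:
            feats = features if features is not None else baselines.adjacency_features(graph)
            scores = baselines.euclid_scores(feats, positives, labeled)
        mean_auroc = auroc([scores[g] for g in labeled], labels)
        fold_aurocs = [mean_auroc]
        feature_dim = None

    record = EvalRecord(
        variant=variant,
        mean_auroc=mean_auroc,
        fold_aurocs=fold_aurocs,
        provenance={
            "variant": variant,
            "master_seed": config.master_seed,
            "reduction": variant in ("n2a-svm", "rwa-svm"),
            "feature_dim": feature_dim,
            "n_positives": len(positives.members),
            "n_negatives": len(negatives.members),
            "walk": dataclasses.asdict(config.walk),
            "embed": dataclasses.asdict(config.embed),
            "ae": dataclasses.asdict(config.ae),
            "rwr": dataclasses.asdict(config.rwr),
            "svm": dataclasses.asdict(config.svm),
            "cv": dataclasses.asdict(config.cv),
        },
    )
    logger.info("%s: mean AUROC %.4f over %d fold(s)", variant, mean_auroc, len(fold_aurocs))
    return record


def repeat_evaluation(
    graph: GeneGraph,
    positives: GeneSet,
    variant: str,
    config: PipelineConfig,
    repetitions: int = 10,
) -> list[EvalRecord]:
    """Evaluate one variant under ``repetitions`` fresh negative draws.

    A single balanced negative sample is high-variance, so the runner
    re-samples negatives (and re-seeds the CV split) per repetition while
    reusing the expensive feature computation, which depends only on the
    graph and the base master seed.
    """
    features = None
    if variant in SVM_VARIANTS:
        features = compute_features(graph, variant, config)
    elif variant == "ed":
        features = baselines.adjacency_features(graph)
    records = []
    for rep in range(repetitions):
        rep_cfg = dataclasses.replace(
            config, master_seed=derive_seed(config.master_seed, f"rep:{rep}"))
        rec = run_pipeline(graph, positives, variant, rep_cfg,
                           features=features)
        rec.provenance["repetition"] = rep
        records.append(rec)
    return records


def fit_final_model(data: LabeledFeatures, svm: SVMParams, seed: int = 0):
    """Fit the ranking model on ALL labeled data, with cross-validated
    sigmoid (Platt) probability calibration so scores are probabilities."""
    base = SVC(kernel=svm.kernel, C=svm.C, gamma=svm.gamma, random_state=seed)
    n_splits = min(5, int((data.y == 1).sum()), int((data.y == 0).sum()))
    if n_splits < 2:
        raise ValidationError("probability calibration needs >= 2 samples per class")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    model = CalibratedClassifierCV(base, method="sigmoid", cv=cv, ensemble=False)
    model.fit(data.X, data.y)
    return model


def rank_candidates(model, features: EmbeddingMatrix, candidates: Sequence[str]) -> pd.DataFrame:
    """Score unlabeled genes with the calibrated model and rank them
    (descending probability, ties broken lexicographically by id)."""
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValidationError("duplicate candidate ids")
    X = features.rows(candidates)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    probs = model.predict_proba(X)[:, pos_col]
    table = pd.DataFrame({"gene": candidates, "score": probs})
    table = table.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)[["gene", "score", "rank"]]
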