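"""Two-stage orchestration: embedding training, reference building, LOF decisions.

Stage 1 trains the embedding network on both classes.  Stage 2 extracts
on-sphere features of the NORMAL images of the training split to form the
reference population, calibrates the decision threshold tau on the
validation split's normal features (novelty-mode scores; quantile rule),
and classifies each test image by its LOF score against the reference:
AMD iff score > tau.

The asymmetry is deliberate and mirrors the method: the classifier head
sees both classes during training, but the outlier model only ever sees
normal anatomy — AMD is whatever falls outside the normal density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import BinaryLabel, ImageSet
from .embedding import (
    BackboneSpec,
    EmbeddingModel,
    TrainConfig,
    extract_features,
    train,
)
from .lof import LOF, LOFParams, ReferenceFeatureSet, calibrate_threshold, score_queries
from .metrics import MetricsReport

MIN_CALIBRATION_NORMALS = 5


@dataclass
class PipelineConfig:
    train: TrainConfig = field(default_factory=TrainConfig)
    lof: LOFParams = field(default_factory=LOFParams)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.train.seed:
            self.train = TrainConfig(**{**self.train.__dict__, "seed": self.seed})


@dataclass
class FittedPipeline:
    model: EmbeddingModel
    reference: ReferenceFeatureSet
    threshold: float
    config: PipelineConfig
    history: list[dict] = field(default_factory=list)


@dataclass
class Prediction:
    index: int
    source: str
    score: float
    decision: Optional[BinaryLabel]
    error: Optional[str] = None


def fit(train_images: ImageSet, config: PipelineConfig = PipelineConfig()) -> FittedPipeline:
    """Train the embedding, build the normal-only reference set, calibrate tau."""
    binary = [im.binary_label for im in train_images]
    if BinaryLabel.NORMAL not in binary:
        raise ValueError("training set has no NORMAL images: the reference set would be empty")
    if BinaryLabel.AMD not in binary:
        raise ValueError("training set has no AMD images: the classifier needs both classes")

    model, history, (train_idx, val_idx) = train(train_images, config.train, config.backbone)

    is_normal = np.array([b is BinaryLabel.NORMAL for b in binary])
    ref_idx = train_idx[is_normal[train_idx]]
    if len(ref_idx) <= config.lof.k:
        raise ValueError(
            f"only {len(ref_idx)} normal training images for k={config.lof.k}; "
            "LOF neighborhoods would be ill-defined"
        )
    reference = ReferenceFeatureSet(extract_features(model, train_images[ref_idx]))

    val_normal_idx = val_idx[is_normal[val_idx]]
    calibration_scores = None
    if len(val_normal_idx) >= MIN_CALIBRATION_NORMALS:
        val_feats = extract_features(model, train_images[val_normal_idx])
        scorer = LOF(k=config.lof.k, metric=reference.metric).fit(reference.points)
        calibration_scores = scorer.score_samples(val_feats)
    tau = calibrate_threshold(reference, config.lof, calibration_scores=calibration_scores)
    return FittedPipeline(model=model, reference=reference, threshold=tau,
                          config=config, history=history)


def predict(pipeline: FittedPipeline, test_images: ImageSet) -> list[Prediction]:
    """Score and classify each test image; per-image failures are recorded, not fatal."""
    results: list[Prediction] = []
    ok_idx, feats = [], []
    for i, im in enumerate(test_images):
        try:
            f = pipeline.model.features(im.pixels[None, :, :])[0]
            ok_idx.append(i)
            feats.append(f)
            results.append(Prediction(i, im.source, np.nan, None))
        except Exception as exc:  # isolate unreadable/degenerate images
            results.append(Prediction(i, im.source, np.nan, None, error=str(exc)))
    if feats:
        lof_results = score_queries(
            np.vstack(feats), pipeline.reference, pipeline.config.lof,
            threshold=pipeline.threshold,
        )
        for i, r in zip(ok_idx, lof_results):
            results[i].score = r.score
            results[i].decision = r.decision
    return results


def evaluate(pipeline: FittedPipeline, labeled_test: ImageSet) -> MetricsReport:
    """Full metrics report on a labeled test set (LOF score ranks the ROC)."""
    preds = predict(pipeline, labeled_test)
    ok = [p for p in preds if p.error is None]
    true = [labeled_test[p.index].binary_label for p in ok]
    predicted = [p.decision for p in ok]
    scores = [p.score for p in ok]
    return MetricsReport.from_predictions(true, predicted, scores)
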