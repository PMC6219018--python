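"""End-to-end recognition pipeline and dataset evaluation.

Wires the stages together: moving-average smoothing and thresholding of
both sensor streams, fuzzy c-means middle-axis localisation, symmetry
feature extraction, and the two-stage k-NN decision tree.  Also provides
the default reference model (k-NN exemplars harvested from the synthetic
generator at a fixed seed) and an evaluation report in the style of a
per-weight-class accuracy table whose "average" row is the unweighted mean
of the per-class accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .classify import (
    LegPosture,
    ReferenceModel,
    SleepPosture,
    TrunkPosture,
    build_reference_model,
    classify_legs,
    classify_trunk,
    knn_classify,
)
from .fcm_segment import MiddleAxes, find_leg_middle_axis, find_trunk_middle_point
from .features import (
    LegCounts,
    PostureFeatures,
    QuadrantCounts,
    compute_features,
    segment_legs,
    segment_trunk,
)
from .frames_io import FrameSequence, RunConfig, get_logger
from .preprocess import preprocess_recording

__all__ = [
    "ExtractedFeatures",
    "ClassificationResult",
    "EvaluationReport",
    "extract_features",
    "classify_recording",
    "default_reference_model",
    "evaluate_examples",
    "weight_class_average",
]

logger = get_logger("somnapose.pipeline")

_DEFAULT_MODEL_SEED = 20240  # fixed seed for the shipped reference model
_DEFAULT_MODEL_N_PER_CLASS = 50


@dataclass(frozen=True)
class ExtractedFeatures:
    """Features plus the intermediate segmentation of one recording.

    Either half may be missing (``None``) when the corresponding sensor
    stream was not supplied.
    """

    axes: MiddleAxes | None
    quadrants: QuadrantCounts | None
    leg_axis: int | None
    leg_counts: LegCounts | None

    @property
    def features(self) -> PostureFeatures:
        """Posture features; absent halves contribute zeros."""
        q = self.quadrants or QuadrantCounts(0, 0, 0, 0)
        l = self.leg_counts or LegCounts(0, 0, 0)
        return compute_features(q, l)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of classifying one recording.

    ``label`` is one of the six sleeping postures, or ``None`` when the
    available streams cannot resolve it (e.g. a lateral trunk without a
    thermal stream).  ``partial`` flags any single-stream run.
    """

    label: SleepPosture | None
    trunk: TrunkPosture | None
    legs: LegPosture | None
    trunk_scores: dict
    leg_scores: dict
    features: PostureFeatures
    extracted: ExtractedFeatures
    partial: bool


def extract_features(
    pressure: FrameSequence | None,
    thermal: FrameSequence | None,
    cfg: RunConfig | None = None,
) -> ExtractedFeatures:
    """Run preprocessing and segmentation, returning symmetry features."""
    cfg = cfg or RunConfig()
    pressure_map, thermal_map = preprocess_recording(pressure, thermal, cfg)

    axes = quadrants = None
    if pressure_map is not None:
        axes = find_trunk_middle_point(pressure_map, cfg)
        quadrants = segment_trunk(pressure_map, axes)

    leg_axis = leg_counts = None
    if thermal_map is not None:
        leg_axis, _ = find_leg_middle_axis(thermal_map, cfg)
        leg_counts = segment_legs(thermal_map, leg_axis)

    return ExtractedFeatures(
        axes=axes, quadrants=quadrants, leg_axis=leg_axis, leg_counts=leg_counts
    )


def classify_recording(
    pressure: FrameSequence | None,
    thermal: FrameSequence | None,
    model: ReferenceModel,
    cfg: RunConfig | None = None,
) -> ClassificationResult:
    """Classify one recording with the two-stage decision tree.

    With both streams present this returns one of the six postures.  With
    only the pressure stream, supine/prone still resolve fully; a lateral
    trunk is reported with ``label=None`` (side known, log/fetus not).
    With only the thermal stream, just the log/fetus leg stage runs.
    """
    extracted = extract_features(pressure, thermal, cfg)
    f = extracted.features
    partial = pressure is None or thermal is None

    trunk = legs = None
    trunk_scores: dict = {}
    leg_scores: dict = {}
    if extracted.quadrants is not None:
        trunk, trunk_scores = knn_classify(
            f.trunk, model.trunk_exemplars, model.k, model.weight_exponent
        )
    if extracted.leg_counts is not None:
        legs, leg_scores = knn_classify(
            f.legs, model.leg_exemplars, model.k, model.weight_exponent
        )

    label: SleepPosture | None = None
    if trunk == TrunkPosture.SUPINE:
        label = SleepPosture.SUPINE
    elif trunk == TrunkPosture.PRONE:
        label = SleepPosture.PRONE
    elif trunk is not None and legs is not None:
        side = "left" if trunk == TrunkPosture.LEFT_LATERAL else "right"
        label = SleepPosture(f"{side}_{legs.value}")
    if partial:
        logger.info("partial result: missing %s stream",
                    "pressure" if pressure is None else "thermal")

    return ClassificationResult(
        label=label,
        trunk=trunk,
        legs=legs,
        trunk_scores=trunk_scores,
        leg_scores=leg_scores,
        features=f,
        extracted=extracted,
        partial=partial,
    )


@lru_cache(maxsize=4)
def _cached_default_model(cfg: RunConfig, n_per_class: int, seed: int) -> ReferenceModel:
    from .synth import generate_examples  # deferred to avoid an import cycle

    dataset = []
    for p_seq, t_seq, truth in generate_examples(n_per_class, seed=seed):
        feats = extract_features(p_seq, t_seq, cfg).features
        dataset.append((feats, truth.label))
    return build_reference_model(dataset, k=cfg.knn.k, weight_exponent=cfg.knn.weight_exponent)


def default_reference_model(cfg: RunConfig | None = None) -> ReferenceModel:
    """The reference model shipped with the package.

    Built once per configuration from the synthetic generator (fixed seed,
    50 recordings per posture under default jitter, weight classes
    cycled), then cached.  Supply your own labelled recordings through
    :func:`somnapose.classify.build_reference_model` to replace it.
    """
    cfg = cfg or RunConfig()
    return _cached_default_model(cfg, _DEFAULT_MODEL_N_PER_CLASS, _DEFAULT_MODEL_SEED)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_LABELS = [p.value for p in SleepPosture]


def weight_class_average(per_class_accuracy_pct: dict[str, float]) -> float:
    """Unweighted mean of per-weight-class accuracies, in percent."""
    if not per_class_accuracy_pct:
        raise ValueError("no per-class accuracies to average")
    return float(np.mean(list(per_class_accuracy_pct.values())))


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy report over a labelled dataset.

    ``confusion`` rows are true labels, columns predicted labels (an
    ``unresolved`` column collects recordings the tree could not label).
    Accuracies are percentages; ``average_accuracy`` is the unweighted
    mean over weight classes, matching the convention of a per-weight
    accuracy table with an "Average" row.
    """

    confusion: pd.DataFrame
    per_posture_accuracy: dict[str, float]
    per_weight_accuracy: dict[str, float]
    overall_accuracy: float
    average_accuracy: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "overall_accuracy_pct": self.overall_accuracy,
            "per_posture_accuracy_pct": self.per_posture_accuracy,
            "per_weight_accuracy_pct": self.per_weight_accuracy,
            "average_accuracy_pct": self.average_accuracy,
            "confusion": {
                true: {pred: int(v) for pred, v in row.items() if v}
                for true, row in self.confusion.to_dict(orient="index").items()
            },
        }


def evaluate_examples(
    examples,
    model: ReferenceModel,
    cfg: RunConfig | None = None,
) -> EvaluationReport:
    """Classify labelled examples and tabulate accuracies.

    ``examples`` yields ``(pressure_seq, thermal_seq, truth)`` triples
    where ``truth`` has ``label`` (a :class:`SleepPosture`) and
    ``weight_class`` attributes, as produced by the synthetic generator or
    a labelled manifest.
    """
    cols = _LABELS + ["unresolved"]
    confusion = pd.DataFrame(0, index=_LABELS, columns=cols, dtype=int)
    weight_hits: dict[str, list[int]] = {}
    n = 0
    for p_seq, t_seq, truth in examples:
        result = classify_recording(p_seq, t_seq, model, cfg)
        predicted = result.label.value if result.label is not None else "unresolved"
        confusion.loc[truth.label.value, predicted] += 1
        weight_hits.setdefault(truth.weight_class, []).append(
            int(predicted == truth.label.value)
        )
        n += 1
    if n == 0:
        raise ValueError("no examples to evaluate")

    diag = sum(confusion.loc[lab, lab] for lab in _LABELS)
    row_totals = confusion.sum(axis=1)
    per_posture = {
        lab: 100.0 * confusion.loc[lab, lab] / row_totals[lab]
        for lab in _LABELS
        if row_totals[lab] > 0
    }
    per_weight = {
        wc: 100.0 * float(np.mean(hits)) for wc, hits in sorted(weight_hits.items())
    }
    return EvaluationReport(
        confusion=confusion,
        per_posture_accuracy=per_posture,
        per_weight_accuracy=per_weight,
        overall_accuracy=100.0 * diag / n,
        average_accuracy=weight_class_average(per_weight),
        n=n,
    )
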