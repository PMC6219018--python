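"""Two-stage posture classification.

A decision tree whose branch tests are distance-weighted k-NN votes in two
small feature spaces.  The first stage classifies the trunk symmetry pair
(T_D-RL, T_D-CH) into supine / prone / left lateral / right lateral.
Supine and prone are leaves; a lateral result descends to a second k-NN in
the leg space (L_D-RL, L_MAC) that separates log (straight legs) from
fetus (curled legs), composing one of the six sleeping postures.

Neighbours vote with weight 1/d^p (p = 2 by default); an exemplar at zero
distance decides outright.  The reference exemplars are not part of the
method itself -- any labelled feature set can be supplied -- and a default
model built from the synthetic generator ships with the package (see
:func:`somnapose.synth.default_reference_model`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .features import PostureFeatures

__all__ = [
    "TrunkPosture",
    "LegPosture",
    "SleepPosture",
    "ReferenceModel",
    "knn_classify",
    "classify_trunk",
    "classify_legs",
    "classify_posture",
    "build_reference_model",
    "mirror_symmetrized",
]


class TrunkPosture(str, Enum):
    SUPINE = "supine"
    PRONE = "prone"
    LEFT_LATERAL = "left_lateral"
    RIGHT_LATERAL = "right_lateral"


class LegPosture(str, Enum):
    LOG = "log"
    FETUS = "fetus"


class SleepPosture(str, Enum):
    RIGHT_LOG = "right_log"
    RIGHT_FETUS = "right_fetus"
    SUPINE = "supine"
    PRONE = "prone"
    LEFT_FETUS = "left_fetus"
    LEFT_LOG = "left_log"

    @property
    def trunk(self) -> TrunkPosture:
        return _TRUNK_OF[self]

    @property
    def legs(self) -> LegPosture | None:
        return _LEGS_OF[self]

    def mirrored(self) -> "SleepPosture":
        """Label after a left-right mirror of the subject."""
        return _MIRROR[self]


_TRUNK_OF = {
    SleepPosture.SUPINE: TrunkPosture.SUPINE,
    SleepPosture.PRONE: TrunkPosture.PRONE,
    SleepPosture.LEFT_LOG: TrunkPosture.LEFT_LATERAL,
    SleepPosture.LEFT_FETUS: TrunkPosture.LEFT_LATERAL,
    SleepPosture.RIGHT_LOG: TrunkPosture.RIGHT_LATERAL,
    SleepPosture.RIGHT_FETUS: TrunkPosture.RIGHT_LATERAL,
}
_LEGS_OF = {
    SleepPosture.SUPINE: None,
    SleepPosture.PRONE: None,
    SleepPosture.LEFT_LOG: LegPosture.LOG,
    SleepPosture.RIGHT_LOG: LegPosture.LOG,
    SleepPosture.LEFT_FETUS: LegPosture.FETUS,
    SleepPosture.RIGHT_FETUS: LegPosture.FETUS,
}
_MIRROR = {
    SleepPosture.SUPINE: SleepPosture.SUPINE,
    SleepPosture.PRONE: SleepPosture.PRONE,
    SleepPosture.LEFT_LOG: SleepPosture.RIGHT_LOG,
    SleepPosture.RIGHT_LOG: SleepPosture.LEFT_LOG,
    SleepPosture.LEFT_FETUS: SleepPosture.RIGHT_FETUS,
    SleepPosture.RIGHT_FETUS: SleepPosture.LEFT_FETUS,
}

_LATERAL = (TrunkPosture.LEFT_LATERAL, TrunkPosture.RIGHT_LATERAL)


@dataclass(frozen=True)
class ReferenceModel:
    """Labelled exemplars for the two k-NN stages.

    ``trunk_exemplars``: ((T_D-RL, T_D-CH), TrunkPosture) pairs.
    ``leg_exemplars``: ((L_D-RL, L_MAC), LegPosture) pairs.
    """

    trunk_exemplars: tuple[tuple[tuple[float, float], TrunkPosture], ...]
    leg_exemplars: tuple[tuple[tuple[float, float], LegPosture], ...]
    k: int = 5
    weight_exponent: float = 2.0

    def __post_init__(self) -> None:
        for stage, exemplars, classes in (
            ("trunk", self.trunk_exemplars, list(TrunkPosture)),
            ("leg", self.leg_exemplars, list(LegPosture)),
        ):
            per_class = {cls: 0 for cls in classes}
            for (f1, f2), label in exemplars:
                if not (np.isfinite(f1) and np.isfinite(f2)):
                    raise ValueError(f"{stage} exemplar features must be finite")
                per_class[label] += 1
            for cls, count in per_class.items():
                if count < self.k:
                    raise ValueError(
                        f"{stage} stage needs >= k={self.k} exemplars for class "
                        f"{cls.value!r}, got {count}"
                    )


def knn_classify(
    x: tuple[float, float],
    exemplars: tuple[tuple[tuple[float, float], Enum], ...],
    k: int,
    weight_exponent: float = 2.0,
):
    """Distance-weighted k-NN vote.

    The k nearest exemplars by Euclidean distance vote with weight
    1/d^weight_exponent; class scores are normalised to sum to 1.  A
    zero-distance neighbour decides outright (score 1).  Ties -- in
    distance rank and in top score -- break toward the lower exemplar
    index, making the vote fully deterministic.

    Returns ``(label, scores)`` with ``scores`` a dict keyed by class label.
    """
    if not exemplars:
        raise ValueError("exemplar set must be non-empty")
    if k < 1 or k > len(exemplars):
        raise ValueError(f"need 1 <= k <= {len(exemplars)}, got k={k}")
    q = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("query features must be finite")

    feats = np.array([f for f, _ in exemplars], dtype=float)
    labels = [lab for _, lab in exemplars]
    d = np.sqrt(((feats - q) ** 2).sum(axis=1))

    zero = np.flatnonzero(d == 0.0)
    if zero.size:
        label = labels[int(zero[0])]
        return label, {label: 1.0}

    order = np.argsort(d, kind="stable")[:k]
    weights = 1.0 / d[order] ** weight_exponent
    scores: dict = {}
    first_seen: dict = {}
    for idx, w in zip(order, weights):
        lab = labels[int(idx)]
        scores[lab] = scores.get(lab, 0.0) + float(w)
        first_seen.setdefault(lab, int(idx))
    total = sum(scores.values())
    scores = {lab: s / total for lab, s in scores.items()}
    best = max(scores.values())
    # score tie -> class whose earliest neighbour has the lowest exemplar index
    winners = [lab for lab, s in scores.items() if s == best]
    label = min(winners, key=lambda lab: first_seen[lab])
    return label, scores


def classify_trunk(f: PostureFeatures, model: ReferenceModel) -> TrunkPosture:
    """First stage: trunk posture from the (T_D-RL, T_D-CH) symmetry pair."""
    label, _ = knn_classify(f.trunk, model.trunk_exemplars, model.k, model.weight_exponent)
    return label


def classify_legs(f: PostureFeatures, model: ReferenceModel) -> LegPosture:
    """Second stage: log vs fetus from the (L_D-RL, L_MAC) leg pair."""
    label, _ = knn_classify(f.legs, model.leg_exemplars, model.k, model.weight_exponent)
    return label


def classify_posture(f: PostureFeatures, model: ReferenceModel) -> SleepPosture:
    """Full decision tree: trunk stage, then the leg stage for laterals."""
    trunk = classify_trunk(f, model)
    if trunk == TrunkPosture.SUPINE:
        return SleepPosture.SUPINE
    if trunk == TrunkPosture.PRONE:
        return SleepPosture.PRONE
    legs = classify_legs(f, model)
    side = "left" if trunk == TrunkPosture.LEFT_LATERAL else "right"
    return SleepPosture(f"{side}_{legs.value}")


_MIRROR_TRUNK = {
    TrunkPosture.SUPINE: TrunkPosture.SUPINE,
    TrunkPosture.PRONE: TrunkPosture.PRONE,
    TrunkPosture.LEFT_LATERAL: TrunkPosture.RIGHT_LATERAL,
    TrunkPosture.RIGHT_LATERAL: TrunkPosture.LEFT_LATERAL,
}


def mirror_symmetrized(model: ReferenceModel) -> ReferenceModel:
    """Model augmented with the left-right mirror of every trunk exemplar.

    Mirroring the subject negates T_D-RL and swaps the lateral sides while
    leaving the leg features unchanged, so a mirror-symmetric exemplar set
    guarantees that mirrored inputs receive mirrored labels.  Each exemplar
    is interleaved with its mirror image so that the index-based tie-breaks
    of the vote resolve equivariantly when mirrored queries meet equal
    distances.
    """
    interleaved: list[tuple[tuple[float, float], TrunkPosture]] = []
    for (t_rl, t_ch), label in model.trunk_exemplars:
        interleaved.append(((t_rl, t_ch), label))
        interleaved.append(((-t_rl, t_ch), _MIRROR_TRUNK[label]))
    return ReferenceModel(
        trunk_exemplars=tuple(interleaved),
        leg_exemplars=model.leg_exemplars,
        k=model.k,
        weight_exponent=model.weight_exponent,
    )


def build_reference_model(
    dataset: list[tuple[PostureFeatures, SleepPosture]],
    k: int = 5,
    weight_exponent: float = 2.0,
) -> ReferenceModel:
    """Assemble a two-stage model from labelled features.

    Every example contributes a trunk exemplar; lateral examples also
    contribute a leg exemplar (log/fetus pooled over left and right).
    Raises if any class at either stage has fewer than k exemplars.
    """
    trunk: list[tuple[tuple[float, float], TrunkPosture]] = []
    legs: list[tuple[tuple[float, float], LegPosture]] = []
    for feats, label in dataset:
        trunk.append((feats.trunk, label.trunk))
        if label.legs is not None:
            legs.append((feats.legs, label.legs))
    return ReferenceModel(
        trunk_exemplars=tuple(trunk),
        leg_exemplars=tuple(legs),
        k=k,
        weight_exponent=weight_exponent,
    )
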