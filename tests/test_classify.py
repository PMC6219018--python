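"""Distance-weighted k-NN and the two-stage decision tree."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnapose.classify import (
    LegPosture,
    ReferenceModel,
    SleepPosture,
    TrunkPosture,
    build_reference_model,
    classify_legs,
    classify_posture,
    classify_trunk,
    knn_classify,
    mirror_symmetrized,
)
from somnapose.features import PostureFeatures


def vote_oracle(x, exemplars, k, p):
    """Exhaustive hand computation of the weighted vote."""
    dists = [
        (math.dist(x, f), i, lab) for i, (f, lab) in enumerate(exemplars)
    ]
    for d, i, lab in dists:
        if d == 0.0:
            return lab, {lab: 1.0}
    dists.sort(key=lambda t: (t[0], t[1]))
    scores, first = {}, {}
    for d, i, lab in dists[:k]:
        scores[lab] = scores.get(lab, 0.0) + 1.0 / d**p
        first.setdefault(lab, i)
    total = sum(scores.values())
    scores = {lab: s / total for lab, s in scores.items()}
    best = max(scores.values())
    label = min((lab for lab, s in scores.items() if s == best), key=first.get)
    return label, scores


A, B = LegPosture.LOG, LegPosture.FETUS


class TestKnn:
    def test_single_exemplar(self):
        label, scores = knn_classify((3.0, 4.0), (((0.0, 0.0), A),), k=1)
        assert label is A and scores[A] == 1.0

    def test_zero_distance_dominates(self):
        exemplars = (((0.0, 0.0), A), ((1.0, 1.0), B), ((1.0, -1.0), B))
        label, scores = knn_classify((1.0, 1.0), exemplars, k=3)
        assert label is B and scores == {B: 1.0}

    def test_three_exemplar_hand_computation(self):
        exemplars = (((0.0, 0.0), A), ((4.0, 0.0), B), ((0.0, 3.0), B))
        label, scores = knn_classify((1.0, 1.0), exemplars, k=3, weight_exponent=2.0)
        # weights: A 1/2, B 1/10 + 1/5; A wins 0.5 : 0.3
        assert label is A
        assert scores[A] == pytest.approx(0.5 / 0.8)
        assert scores[B] == pytest.approx(0.3 / 0.8)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 10),
        k=st.integers(1, 10),
        p=st.sampled_from([1.0, 2.0]),
    )
    def test_matches_exhaustive_vote_oracle(self, seed, n, k, p):
        rng = np.random.default_rng(seed)
        k = min(k, n)
        exemplars = tuple(
            ((float(rng.integers(-5, 6)), float(rng.integers(-5, 6))), rng.choice([A, B]))
            for _ in range(n)
        )
        x = (float(rng.integers(-5, 6)), float(rng.integers(-5, 6)))
        got_label, got_scores = knn_classify(x, exemplars, k, p)
        want_label, want_scores = vote_oracle(x, exemplars, k, p)
        assert got_label == want_label
        assert got_scores.keys() == want_scores.keys()
        for lab in want_scores:
            assert got_scores[lab] == pytest.approx(want_scores[lab], abs=1e-12)

    def test_equidistant_tie_goes_to_lower_indexed_exemplar(self):
        exemplars = (((0.0, 1.0), A), ((0.0, -1.0), B))
        label, _ = knn_classify((0.0, 0.0), exemplars, k=2)
        assert label is A
        label, _ = knn_classify((0.0, 0.0), exemplars[::-1], k=2)
        assert label is B

    def test_duplicated_exemplars_keep_scores(self):
        exemplars = (((0.0, 1.0), A), ((2.0, 0.0), B))
        _, base = knn_classify((1.0, 1.0), exemplars, k=2)
        _, dup = knn_classify((1.0, 1.0), exemplars * 2, k=4)
        for lab in base:
            assert dup[lab] == pytest.approx(base[lab])

    def test_validation(self):
        with pytest.raises(ValueError):
            knn_classify((0.0, 0.0), (), k=1)
        with pytest.raises(ValueError):
            knn_classify((0.0, 0.0), (((1.0, 1.0), A),), k=2)


def toy_model(k=1):
    trunk = (
        ((0.0, 0.0), TrunkPosture.SUPINE),
        ((0.0, -14.0), TrunkPosture.PRONE),
        ((-25.0, 0.0), TrunkPosture.LEFT_LATERAL),
        ((25.0, 0.0), TrunkPosture.RIGHT_LATERAL),
    )
    legs = (((0.0, 8.0), LegPosture.LOG), ((6.0, 2.0), LegPosture.FETUS))
    return ReferenceModel(trunk_exemplars=trunk, leg_exemplars=legs, k=k)


class TestDecisionTree:
    @pytest.mark.parametrize(
        "feats, expected",
        [
            ((0, -1, 0, 8), TrunkPosture.SUPINE),
            ((-2, -13, 0, 8), TrunkPosture.PRONE),
            ((-22, 1, 0, 8), TrunkPosture.LEFT_LATERAL),
            ((24, 2, 6, 2), TrunkPosture.RIGHT_LATERAL),
        ],
    )
    def test_trunk_regions(self, feats, expected):
        f = PostureFeatures(*feats)
        assert classify_trunk(f, toy_model()) == expected

    @pytest.mark.parametrize(
        "feats, expected",
        [
            ((0, 0, 0, 8), LegPosture.LOG),  # small L_D-RL, large L_MAC
            ((0, 0, 7, 1), LegPosture.FETUS),  # large L_D-RL, small L_MAC
        ],
    )
    def test_leg_regions(self, feats, expected):
        assert classify_legs(PostureFeatures(*feats), toy_model()) == expected

    @pytest.mark.parametrize(
        "feats, expected",
        [
            ((0, 0, 7, 1), SleepPosture.SUPINE),  # supine leaf ignores legs
            ((0, -14, 7, 1), SleepPosture.PRONE),
            ((-25, 0, 7, 1), SleepPosture.LEFT_FETUS),
            ((-25, 0, 0, 8), SleepPosture.LEFT_LOG),
            ((25, 0, 7, 1), SleepPosture.RIGHT_FETUS),
            ((25, 0, 0, 8), SleepPosture.RIGHT_LOG),
        ],
    )
    def test_tree_composition(self, feats, expected):
        assert classify_posture(PostureFeatures(*feats), toy_model()) == expected


class TestReferenceModel:
    def make_dataset(self, n_per_class=3):
        sig = {
            SleepPosture.SUPINE: (0, 0, 0, 3),
            SleepPosture.PRONE: (0, -14, 0, 3),
            SleepPosture.LEFT_LOG: (-25, 0, 0, 8),
            SleepPosture.LEFT_FETUS: (-25, 0, 6, 2),
            SleepPosture.RIGHT_LOG: (25, 0, 0, 8),
            SleepPosture.RIGHT_FETUS: (25, 0, 6, 2),
        }
        out = []
        for label, base in sig.items():
            for i in range(n_per_class):
                out.append((PostureFeatures(base[0] + i, *base[1:]), label))
        return out

    def test_build_pools_lateral_classes(self):
        model = build_reference_model(self.make_dataset(), k=3)
        assert len(model.trunk_exemplars) == 18
        assert len(model.leg_exemplars) == 12  # laterals only
        trunk_labels = {lab for _, lab in model.trunk_exemplars}
        assert trunk_labels == set(TrunkPosture)

    def test_missing_class_fails_validation(self):
        dataset = [d for d in self.make_dataset() if d[1] != SleepPosture.PRONE]
        with pytest.raises(ValueError, match="prone"):
            build_reference_model(dataset, k=3)

    def test_too_few_exemplars_for_k(self):
        with pytest.raises(ValueError, match=">= k"):
            build_reference_model(self.make_dataset(2), k=3)

    def test_mirror_symmetrized_doubles_trunk_stage(self):
        model = build_reference_model(self.make_dataset(), k=3)
        sym = mirror_symmetrized(model)
        assert len(sym.trunk_exemplars) == 2 * len(model.trunk_exemplars)
        pairs = {(f, lab) for f, lab in sym.trunk_exemplars}
        assert ((-0.0, 0.0), TrunkPosture.SUPINE) in pairs or (
            (0.0, 0.0),
            TrunkPosture.SUPINE,
        ) in pairs
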