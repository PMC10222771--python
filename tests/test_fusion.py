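"""Feature fusion and cross-entropy selection contracts."""

import numpy as np
import pytest

from momofuse.errors import FusionError, ParameterError
from momofuse.fusion import (
    CEMConfig,
    FeatureMask,
    align_and_fuse,
    apply_mask,
    cem_optimize,
    fused_table,
    mask_score,
)


def planted_features(rng, n_per_class=60, n_dims=40, informative=8, shift=1.0):
    """Three classes whose means differ only on the first `informative` dims."""
    X, y = [], []
    for c in range(3):
        block = rng.normal(size=(n_per_class, n_dims))
        block[:, :informative] += shift * (c - 1)
        X.append(block)
        y.extend([c] * n_per_class)
    return np.vstack(X), np.array(y)


class TestAlignAndFuse:
    def test_concatenation_arithmetic(self, rng):
        amb = rng.normal(size=(10, 6))
        mot = rng.normal(size=(10, 36))
        vis = rng.normal(size=(100, 576))
        fused = align_and_fuse(amb, mot, vis, labels=np.zeros(10),
                               vision_times=np.arange(100) * 0.4)
        assert len(fused) == 10
        assert fused[0].vector.shape == (618,)
        assert fused[0].spans == {"ambient": (0, 6), "motion": (6, 42),
                                  "vision": (42, 618)}

    def test_vision_absent_zero_filled_and_flagged(self, rng):
        fused = align_and_fuse(rng.normal(size=(4, 3)), rng.normal(size=(4, 5)),
                               None, labels=np.arange(4))
        assert fused[0].vector.shape == (8,)
        assert "vision" not in fused[0].spans

    def test_window_without_frames_flagged(self, rng):
        vis = rng.normal(size=(10, 7))
        times = np.linspace(0, 3.9, 10)  # all frames inside window 0
        fused = align_and_fuse(rng.normal(size=(3, 2)), rng.normal(size=(3, 4)),
                               vis, labels=np.zeros(3), vision_times=times)
        assert fused[0].missing == ()
        assert fused[1].missing == ("vision",)
        a, b = fused[1].spans["vision"]
        assert np.all(fused[1].vector[a:b] == 0)

    def test_frame_interval_assignment(self, rng):
        # a frame at t=5.2 s belongs to window 1, which covers [4, 8)
        vis = np.ones((1, 2))
        fused = align_and_fuse(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)),
                               vis, labels=np.zeros(3), vision_times=np.array([5.2]))
        assert fused[1].missing == ()
        assert fused[0].missing == ("vision",) and fused[2].missing == ("vision",)

    def test_no_windows_rejected(self):
        with pytest.raises(FusionError):
            align_and_fuse(None, None, None, labels=[])


class TestMaskScore:
    def test_informative_mask_beats_noise_mask(self, rng):
        X, y = planted_features(rng)
        informative = np.zeros(40, bool)
        informative[:8] = True
        assert (mask_score(informative, X, y, "fisher")
                > mask_score(~informative, X, y, "fisher"))

    def test_cv_loss_on_pure_noise_near_chance(self, rng):
        X = rng.normal(size=(150, 10))
        y = np.repeat([0, 1, 2], 50)
        score = mask_score(np.ones(10, bool), X, y, "cv_loss")
        assert -score == pytest.approx(2 / 3, abs=0.1)  # error ~ chance

    def test_empty_mask_rejected(self, rng):
        X, y = planted_features(rng, n_per_class=10)
        with pytest.raises(ParameterError):
            mask_score(np.zeros(40, bool), X, y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ParameterError):
            mask_score(np.ones(5, bool), rng.normal(size=(20, 5)), np.zeros(20))


class TestCemOptimize:
    def test_single_feature_returned_immediately(self, rng):
        X = rng.normal(size=(30, 1))
        y = np.repeat([0, 1], 15)
        mask, _ = cem_optimize(X, y, CEMConfig(seed=0))
        assert mask.include.tolist() == [True]

    def test_same_seed_identical_mask(self, rng):
        X, y = planted_features(rng, n_per_class=30)
        m1, _ = cem_optimize(X, y, CEMConfig(seed=5, iterations=8))
        m2, _ = cem_optimize(X, y, CEMConfig(seed=5, iterations=8))
        assert np.array_equal(m1.include, m2.include)
        assert m1.score == m2.score

    def test_best_score_non_decreasing(self, rng):
        X, y = planted_features(rng, n_per_class=30)
        _, hist = cem_optimize(X, y, CEMConfig(seed=2, iterations=12))
        scores = hist["best_scores"]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_probabilities_stay_off_the_walls(self, rng):
        X, y = planted_features(rng, n_per_class=30)
        _, hist = cem_optimize(X, y, CEMConfig(seed=3, iterations=15))
        for probs in hist["probs"]:
            assert np.all(probs >= 0.01 - 1e-12)
            assert np.all(probs <= 0.99 + 1e-12)

    def test_planted_recovery_single_seed(self, rng):
        X, y = planted_features(rng, n_per_class=60)
        mask, _ = cem_optimize(X, y, CEMConfig(seed=1))
        hits = mask.include[:8].sum()
        precision = hits / max(mask.n_selected, 1)
        recall = hits / 8
        assert precision >= 0.8 and recall >= 0.8


class TestApplyMask:
    def test_identity_mask(self, rng):
        X = rng.normal(size=(5, 7))
        Xr, _ = apply_mask(X, FeatureMask(include=np.ones(7, bool)))
        assert np.array_equal(Xr, X)

    def test_width_after_selection(self, rng):
        X = rng.normal(size=(4, 618))
        include = np.zeros(618, bool)
        include[rng.choice(618, 20, replace=False)] = True
        Xr, _ = apply_mask(X, FeatureMask(include=include))
        assert Xr.shape == (4, 20)

    def test_span_remapping_partitions_reduced_vector(self):
        X = np.zeros((2, 10))
        include = np.array([1, 0, 1, 1, 0, 0, 1, 1, 1, 0], dtype=bool)
        spans = {"ambient": (0, 2), "motion": (2, 6), "vision": (6, 10)}
        Xr, new_spans = apply_mask(X, FeatureMask(include=include), spans)
        assert new_spans == {"ambient": (0, 1), "motion": (1, 3), "vision": (3, 6)}
        assert Xr.shape[1] == 6

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ParameterError):
            apply_mask(rng.normal(size=(3, 5)), FeatureMask(include=np.ones(4, bool)))


def test_fused_table_stacks_vectors_and_labels(rng):
    fused = align_and_fuse(rng.normal(size=(6, 2)), rng.normal(size=(6, 3)),
                           None, labels=np.arange(6))
    X, y = fused_table(fused)
    assert X.shape == (6, 5) and y.tolist() == list(range(6))
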