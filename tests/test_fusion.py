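"""Single-atlas segmentation, STAPLE EM, and multi-atlas fusion."""

import numpy as np
import pytest

from pqctseg.atlas import AtlasSet
from pqctseg.core_raster import LabelMap2D, Raster2D
from pqctseg.evaluation import overlap_metrics
from pqctseg.fusion import (
    StapleState,
    majority_vote,
    segment_multi_atlas,
    segment_single_atlas,
    segment_threshold,
    staple_fuse,
)
from pqctseg.registration import RegistrationConfig


def _fast_config():
    return RegistrationConfig(affine_iterations=40, sdd_iterations=30,
                              ffd_maxiter=25)


def _simulate_raters(seed=1, n=10000, sensitivities=(0.95, 0.85, 0.75),
                     n_classes=5):
    """Raters vote the truth with probability p_k, otherwise uniformly among
    the other classes (the one-vs-rest generative model)."""
    rng = np.random.default_rng(seed)
    truth = rng.choice(n_classes, size=n, p=[0.5, 0.1, 0.1, 0.2, 0.1])
    maps = []
    for p in sensitivities:
        votes = truth.copy()
        miss = np.where(rng.random(n) >= p)[0]
        offsets = rng.integers(1, n_classes, size=miss.size)
        votes[miss] = (truth[miss] + offsets) % n_classes
        maps.append(LabelMap2D(votes.reshape(100, n // 100), 0.5))
    return truth, maps


class TestSegmentSingleAtlas:
    @pytest.mark.parametrize("engine", ["ffd", "sdd"])
    def test_subject_equals_atlas(self, phantom64, engine):
        img, lab = phantom64
        seg = segment_single_atlas(img, img, lab, engine, _fast_config())
        assert seg.shape == img.shape
        for tissue in (1, 2, 3, 4):
            dsc, _, _ = overlap_metrics(seg, lab, tissue)
            assert dsc >= 0.99

    def test_unknown_engine(self, phantom64):
        img, lab = phantom64
        with pytest.raises(ValueError, match="engine"):
            segment_single_atlas(img, img, lab, "syn")


class TestStapleFuse:
    def test_unanimous_raters(self, phantom64):
        _, lab = phantom64
        fused, p, q = staple_fuse([lab, lab, lab])
        assert np.array_equal(fused.labels, lab.labels)
        assert np.allclose(p, 1.0) and np.allclose(q, 1.0)

    def test_parameter_recovery(self):
        truth, maps = _simulate_raters()
        state = StapleState.from_label_maps(maps)
        fused, p, q = staple_fuse(state)
        for k, true_p in enumerate((0.95, 0.85, 0.75)):
            assert np.abs(p[k] - true_p).max() < 0.02
        ll = np.array(state.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-8 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_fusion_beats_noisy_raters(self):
        """One perfect rater + two 30%-noise raters: the fused map has a
        lower error rate than either noisy rater."""
        rng = np.random.default_rng(2)
        n = 10000
        truth = rng.choice(3, size=n, p=[0.6, 0.2, 0.2])
        perfect = truth.copy()
        noisy = []
        for s in range(2):
            votes = truth.copy()
            miss = np.where(rng.random(n) >= 0.7)[0]
            votes[miss] = (truth[miss] + rng.integers(1, 3, miss.size)) % 3
            noisy.append(votes)
        maps = [LabelMap2D(v.reshape(100, 100), 0.5)
                for v in (perfect, *noisy)]
        fused, _, _ = staple_fuse(maps)
        err_fused = (fused.labels.ravel() != truth).mean()
        for v in noisy:
            assert err_fused < (v != truth).mean()

    def test_posteriors_normalize(self):
        _, maps = _simulate_raters(seed=5, n=2000)
        state = StapleState.from_label_maps(maps)
        staple_fuse(state)
        assert np.allclose(state.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_rater_permutation_invariance(self):
        _, maps = _simulate_raters(seed=6, n=4000)
        fused_a, p_a, _ = staple_fuse(maps)
        fused_b, p_b, _ = staple_fuse(maps[::-1])
        assert np.array_equal(fused_a.labels, fused_b.labels)
        assert np.allclose(p_a, p_b[::-1], atol=1e-6)

    def test_constant_rater_clamped(self):
        rng = np.random.default_rng(7)
        truth = rng.choice(2, size=1000)
        good = LabelMap2D(truth.reshape(20, 50), 0.5)
        lazy = LabelMap2D(np.zeros((20, 50), dtype=np.uint8), 0.5)
        _, p, q = staple_fuse([good, good, lazy])
        assert np.all(p[2] >= 0.01) and np.all(p[2] <= 0.99)
        assert np.all(q[2] >= 0.01) and np.all(q[2] <= 0.99)

    def test_needs_two_raters_and_two_classes(self, phantom64):
        _, lab = phantom64
        with pytest.raises(ValueError, match="raters"):
            staple_fuse([lab])
        flat = LabelMap2D(np.zeros((8, 8), dtype=np.uint8), 0.5)
        with pytest.raises(ValueError, match="label codes"):
            staple_fuse([flat, flat])


class TestMajorityVote:
    def test_tie_breaks_to_lowest_code(self):
        a = LabelMap2D(np.full((8, 8), 3, dtype=np.uint8), 0.5)
        b = LabelMap2D(np.full((8, 8), 1, dtype=np.uint8), 0.5)
        fused = majority_vote([a, b])
        assert np.all(fused.labels == 1)

    def test_majority_wins(self):
        a = LabelMap2D(np.full((8, 8), 2, dtype=np.uint8), 0.5)
        b = LabelMap2D(np.full((8, 8), 2, dtype=np.uint8), 0.5)
        c = LabelMap2D(np.full((8, 8), 4, dtype=np.uint8), 0.5)
        assert np.all(majority_vote([a, b, c]).labels == 2)


class TestSegmentMultiAtlas:
    def test_identical_atlases_equal_single(self, phantom64):
        img, lab = phantom64
        aset = AtlasSet(templates=[(img, lab), (img, lab), (img, lab)])
        cfg = _fast_config()
        fused = segment_multi_atlas(img, aset, "sdd", cfg,
                                    include_statistical=False)
        single = segment_single_atlas(img, img, lab, "sdd", cfg)
        assert np.array_equal(fused.labels, single.labels)

    def test_decision_matrix_dimensions(self, phantom64):
        img, lab = phantom64
        aset = AtlasSet(templates=[(img, lab), (img, lab)])
        report = {}
        segment_multi_atlas(img, aset, "sdd", _fast_config(),
                            include_statistical=False, report=report)
        D = report["staple"].decisions
        assert D.shape == (img.values.size, 2)

    def test_needs_two_atlases(self, phantom64):
        img, lab = phantom64
        aset = AtlasSet(templates=[(img, lab)])
        with pytest.raises(ValueError, match="at least 2"):
            segment_multi_atlas(img, aset, include_statistical=False)


class TestThresholdBaseline:
    def test_classifies_pure_tissue_means(self):
        values = np.zeros((8, 8))
        values[0] = 50    # SAT band
        values[1] = 80    # muscle
        values[2] = 300   # trabecular
        values[3] = 1100  # cortical
        out = segment_threshold(Raster2D(values, 0.5))
        assert np.all(out.labels[0] == 4)
        assert np.all(out.labels[1] == 3)
        assert np.all(out.labels[2] == 1)
        assert np.all(out.labels[3] == 2)
        assert np.all(out.labels[4:] == 0)
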