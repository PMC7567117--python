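import numpy as np
import pytest
from scipy import stats

from denoisem.io_formats import ImagePlane
from denoisem.models import ModelSpec, build_model
from denoisem.pairgen import NoisePair
from denoisem.snr_eval import ccc
from denoisem.train_n2n import (
    NormStats,
    TrainConfig,
    TrainHistory,
    augment_pair,
    denormalize_image,
    normalize_image,
    pair_loss,
    pair_loss_grad,
    sample_patch_pairs,
    train,
)
from tests.conftest import make_training_pairs


class TestNormalize:
    def test_two_values(self):
        out, stats_ = normalize_image(np.array([[0.0, 2.0]]))
        np.testing.assert_allclose(out, [[-1.0, 1.0]])
        assert stats_.mean == pytest.approx(1.0)
        assert stats_.std == pytest.approx(1.0)

    def test_idempotent_on_normalized(self, rng):
        x, _ = normalize_image(rng.standard_normal((32, 32)))
        y, stats_ = normalize_image(x)
        np.testing.assert_allclose(y, x, atol=1e-12)
        assert stats_.mean == pytest.approx(0.0, abs=1e-12)
        assert stats_.std == pytest.approx(1.0, rel=1e-12)

    def test_random_plane(self, rng):
        out, _ = normalize_image(rng.normal(5.0, 3.0, (128, 128)))
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_image(np.full((8, 8), 2.0))

    def test_exact_inversion(self, rng):
        data = rng.normal(3.0, 7.0, (16, 16))
        out, stats_ = normalize_image(data)
        np.testing.assert_allclose(denormalize_image(out, stats_), data, rtol=1e-12)

    def test_normstats_requires_positive_std(self):
        with pytest.raises(ValueError):
            NormStats(mean=0.0, std=0.0)


class TestPatchSampling:
    def _pair(self, rng, h, w):
        return NoisePair(
            even=ImagePlane(rng.standard_normal((h, w))),
            odd=ImagePlane(rng.standard_normal((h, w))),
        )

    def test_whole_image_single_position(self, rng):
        pair = self._pair(rng, 64, 64)
        (pa, pb), = sample_patch_pairs(pair, 64, 1, np.random.default_rng(0))
        np.testing.assert_array_equal(pa, pair.even.data)
        np.testing.assert_array_equal(pb, pair.odd.data)

    def test_determinism(self, rng):
        pair = self._pair(rng, 100, 100)
        got1 = sample_patch_pairs(pair, 32, 20, np.random.default_rng(7))
        got2 = sample_patch_pairs(pair, 32, 20, np.random.default_rng(7))
        for (a1, b1), (a2, b2) in zip(got1, got2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)

    def test_aligned_coordinates(self, rng):
        """Patch pairs observe the same location: marker pixels line up."""
        h = w = 80
        marker = np.arange(h * w, dtype=float).reshape(h, w)
        pair = NoisePair(even=ImagePlane(marker), odd=ImagePlane(marker + 1000.0))
        for pa, pb in sample_patch_pairs(pair, 17, 10, np.random.default_rng(1)):
            np.testing.assert_array_equal(pb - pa, np.full((17, 17), 1000.0))

    def test_uniform_marginals(self, rng):
        """Top-left coordinates uniform over the valid grid (chi-square, a=0.01)."""
        pair = self._pair(rng, 150, 150)
        gen = np.random.default_rng(3)
        patches = sample_patch_pairs(pair, 50, 20000, gen)
        # recover coordinates by re-running the generator
        gen2 = np.random.default_rng(3)
        coords = [(int(gen2.integers(0, 101)), int(gen2.integers(0, 101))) for _ in range(20000)]
        rows = np.bincount([c[0] for c in coords], minlength=101)
        cols = np.bincount([c[1] for c in coords], minlength=101)
        assert stats.chisquare(rows).pvalue > 0.01
        assert stats.chisquare(cols).pvalue > 0.01
        assert len(patches) == 20000

    def test_shrink_rule_warns(self, rng):
        pair = self._pair(rng, 30, 30)
        with pytest.warns(UserWarning, match="shrinking"):
            out = sample_patch_pairs(pair, 800, 2, np.random.default_rng(0))
        assert out[0][0].shape == (30, 30)


class TestAugment:
    def test_rotation_four_times_identity(self, rng):
        p = rng.standard_normal((5, 5))
        q = p.copy()
        for _ in range(4):
            q = np.rot90(q, 1)
        np.testing.assert_array_equal(p, q)

    def test_mirror_twice_identity(self, rng):
        p = rng.standard_normal((5, 5))
        np.testing.assert_array_equal(p[:, ::-1][:, ::-1], p)

    def test_dihedral_group_complete(self):
        marked = np.arange(9.0).reshape(3, 3)
        seen = set()
        for seed in range(200):
            pa, _ = augment_pair(marked, marked, np.random.default_rng(seed))
            seen.add(pa.tobytes())
            assert sorted(pa.ravel()) == sorted(marked.ravel())  # pure permutation
        assert len(seen) == 8

    def test_same_transform_both_patches(self, rng):
        a = rng.standard_normal((6, 6))
        b = a * 3.0
        pa, pb = augment_pair(a, b, np.random.default_rng(11))
        np.testing.assert_allclose(pb, pa * 3.0)

    def test_nonsquare_rotation_rejected(self, rng):
        a = rng.standard_normal((4, 6))
        # some seed will draw a 90-degree rotation
        with pytest.raises(ValueError, match="non-square"):
            for seed in range(20):
                augment_pair(a, a, np.random.default_rng(seed))


class TestPairLoss:
    def test_zero_when_equal(self, rng):
        p = rng.standard_normal((8, 8))
        for mode in ("l1", "l2", "l0"):
            assert pair_loss(p, p, mode) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        pred = np.array([0.0, 2.0])
        target = np.array([1.0, 1.0])
        assert pair_loss(pred, target, "l1") == pytest.approx(1.0)
        assert pair_loss(pred, target, "l2") == pytest.approx(1.0)

    def test_mse_ccc_identity(self, rng):
        """MSE == 2 - 2*CCC for zero-mean unit-variance images."""
        a, _ = normalize_image(rng.standard_normal((64, 64)))
        b, _ = normalize_image(rng.standard_normal((64, 64)))
        mse = pair_loss(a, b, "l2")
        assert mse == pytest.approx(2.0 - 2.0 * ccc(a, b), abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pair_loss(np.zeros((2, 2)), np.zeros((3, 3)), "l2")

    def test_l0_positive_and_annealed(self, rng):
        d = rng.standard_normal((8, 8))
        hi = pair_loss(d, np.zeros_like(d), "l0", gamma=2.0)
        lo = pair_loss(d, np.zeros_like(d), "l0", gamma=0.01)
        assert hi > 0 and lo > 0

    def test_grad_matches_finite_difference(self, rng):
        pred = rng.standard_normal((6, 6))
        target = rng.standard_normal((6, 6))
        for mode in ("l1", "l2", "l0"):
            g = pair_loss_grad(pred, target, mode, gamma=1.5)
            eps = 1e-7
            i = (2, 3)
            p2 = pred.copy()
            p2[i] += eps
            fd = (pair_loss(p2, target, mode, gamma=1.5) - pair_loss(pred, target, mode, gamma=1.5)) / eps
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTrain:
    def test_determinism_bitwise(self):
        pairs = make_training_pairs(4, size=48)
        spec = ModelSpec(arch="affine", seed=0)
        cfg = TrainConfig(loss_mode="l2", lr=0.01, epochs=3, batch=2, patch=32, seed=4)
        m1, h1 = train(pairs, spec, cfg)
        m2, h2 = train(pairs, spec, cfg)
        assert h1.train_loss == h2.train_loss
        for p1, p2 in zip(m1.params(), m2.params()):
            assert p1.value.tobytes() == p2.value.tobytes()

    def test_history_length(self):
        pairs = make_training_pairs(2, size=32)
        _, hist = train(pairs, ModelSpec(arch="affine"), TrainConfig(epochs=5, patch=32, seed=0))
        assert len(hist) == 5

    def test_loss_symmetry_under_swap(self):
        pairs = make_training_pairs(4, size=32)
        swapped = [NoisePair(even=p.odd, odd=p.even, source=p.source) for p in pairs]
        cfg = TrainConfig(loss_mode="l2", lr=0.01, epochs=2, batch=2, patch=32, seed=1, augment=False)
        _, h1 = train(pairs, ModelSpec(arch="affine", seed=0), cfg)
        _, h2 = train(swapped, ModelSpec(arch="affine", seed=0), cfg)
        np.testing.assert_allclose(h1.train_loss, h2.train_loss, rtol=1e-6)

    def test_holdout_loss_decreases(self):
        pairs = make_training_pairs(8, size=48, snr_full=0.5)
        holdout = make_training_pairs(2, size=48, snr_full=0.5, seed0=900)
        spec = ModelSpec(arch="unet_small", base_width=8, seed=0)
        cfg = TrainConfig(loss_mode="l2", lr=0.01, epochs=6, batch=4, patch=48, seed=0, holdout=holdout)
        untrained = build_model(spec)
        from denoisem.train_n2n import _holdout_loss, _normalized_pairs

        before = _holdout_loss(untrained, _normalized_pairs(holdout), 48, "l2", 2.0, 1e-8)
        _, hist = train(pairs, spec, cfg)
        assert hist.holdout_loss[-1] < before

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train([], ModelSpec(arch="affine"), TrainConfig())

    def test_nonfinite_loss_aborts(self):
        pairs = make_training_pairs(2, size=32)
        cfg = TrainConfig(loss_mode="l2", lr=1e12, epochs=8, batch=2, patch=32, seed=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            train(pairs, ModelSpec(arch="fcnn", seed=0), cfg)
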