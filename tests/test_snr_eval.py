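import numpy as np
import pytest

from denoisem.io_formats import ImagePlane, MovieStack
from denoisem.snr_eval import (
    Rect,
    RegionPair,
    RegionPairSet,
    ccc,
    dose_titration,
    lowpass_bin,
    lowpass_gaussian,
    read_region_tsv,
    scale_display,
    snr_regions,
    snr_split,
)


class TestCCC:
    def test_self_correlation(self, rng):
        a = rng.standard_normal((16, 16))
        assert ccc(a, a) == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        a = rng.standard_normal((16, 16))
        assert ccc(a, -a) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        assert ccc(np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8])) == pytest.approx(1.0)
        assert ccc(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4])) == pytest.approx(0.8)

    def test_constant_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            ccc(np.full((4, 4), 2.0), rng.standard_normal((4, 4)))


class TestSnrSplit:
    def test_zero_db_at_half(self):
        # orthogonal unit-variance vectors: ccc(a+b, a) = 1/sqrt(2); and the
        # dB formula reduces to 0 exactly when p = 0.5 (x scaled to force it)
        a = np.array([1.0, 1.0, -1.0, -1.0] * 64)
        b = np.array([1.0, -1.0, 1.0, -1.0] * 64)
        x = a + b
        p = ccc(x, a)
        assert p == pytest.approx(np.sqrt(0.5))
        assert snr_split(x, a) == pytest.approx(10 * np.log10(p / (1 - p)))
        # exact construction for p = 0.5: a + sqrt(3) * b
        x2 = a + np.sqrt(3.0) * b
        assert ccc(x2, a) == pytest.approx(0.5)
        assert snr_split(x2, a) == pytest.approx(0.0, abs=1e-9)

    def test_known_p(self, rng):
        # independent Gaussian halves with shared signal: p ~= 0.9
        y = rng.standard_normal(200_000) * 3.0
        x1 = y + rng.standard_normal(y.shape)
        x2 = y + rng.standard_normal(y.shape)
        p = ccc(x1, x2)
        assert p == pytest.approx(0.9, abs=0.01)
        assert snr_split(x1, x2) == pytest.approx(10 * np.log10(p / (1 - p)))
        assert snr_split(x1, x2) == pytest.approx(10 * np.log10(9.0), abs=0.3)

    def test_negative_p_sentinel(self, rng):
        a = rng.standard_normal(5000)
        with pytest.warns(UserWarning, match="non-positive"):
            out = snr_split(a, -a)
        assert out == float("-inf")

    def test_perfect_p_sentinel(self, rng):
        a = rng.standard_normal(5000)
        assert snr_split(a, a) == float("inf")


class TestSnrRegions:
    def _fixture_image(self):
        data = np.zeros((8, 8))
        data[0:2, 0:2] = 3.0  # signal region: all 3s
        data[4:6, 0:2] = [[0.0, 2.0], [0.0, 2.0]]  # background: mean 1, pop var 1
        return ImagePlane(data)

    def _regions(self, n=1):
        items = [
            RegionPair(
                image_name="img",
                pair_id=str(i),
                signal=Rect(0, 0, 2, 2),
                background=Rect(0, 4, 2, 6),
            )
            for i in range(n)
        ]
        return RegionPairSet(items=items)

    def test_hand_computed(self):
        report = snr_regions({"img": self._fixture_image()}, self._regions())
        assert report.mean_db == pytest.approx(10 * np.log10(4.0), abs=1e-9)
        assert report.mean_db == pytest.approx(6.0206, abs=1e-3)

    def test_mean_of_identical_pairs(self):
        single = snr_regions({"img": self._fixture_image()}, self._regions(1)).mean_db
        double = snr_regions({"img": self._fixture_image()}, self._regions(2)).mean_db
        assert double == pytest.approx(single)

    def test_gain_invariance(self):
        img = self._fixture_image()
        scaled = ImagePlane(img.data * 137.25)
        a = snr_regions({"img": img}, self._regions()).mean_db
        b = snr_regions({"img": scaled}, self._regions()).mean_db
        assert b == pytest.approx(a, abs=1e-9)

    def test_zero_variance_error(self):
        data = np.zeros((8, 8))
        data[0:2, 0:2] = 3.0
        data[4:6, 0:2] = 1.0  # constant background
        with pytest.raises(ValueError, match="background variance"):
            snr_regions({"img": ImagePlane(data)}, self._regions())

    def test_out_of_bounds_region(self):
        regions = RegionPairSet(
            items=[RegionPair("img", "0", Rect(0, 0, 2, 2), Rect(6, 6, 12, 12))]
        )
        with pytest.raises(ValueError, match="bounds"):
            snr_regions({"img": self._fixture_image()}, regions)

    def test_tiny_region_rejected(self):
        with pytest.raises(ValueError, match="4 pixels"):
            Rect(0, 0, 1, 2)


class TestLowpassBin:
    def test_constant_unchanged(self):
        img = np.full((32, 32), 3.0)
        np.testing.assert_allclose(lowpass_bin(img, 16), img, atol=1e-10)

    def test_factor_one_identity(self, rng):
        img = rng.standard_normal((32, 32))
        np.testing.assert_allclose(lowpass_bin(img, 1), img, atol=1e-10)

    def test_band_limit(self):
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        hi = np.cos(2 * np.pi * 24 * xx / n)  # above n/(2*4) = 8 cycles
        lo = np.cos(2 * np.pi * 4 * xx / n)  # below the cutoff
        out_hi = lowpass_bin(hi, 4)
        out_lo = lowpass_bin(lo, 4)
        assert np.mean(out_hi**2) < 1e-6 * np.mean(hi**2)
        np.testing.assert_allclose(out_lo, lo, atol=1e-6)

    def test_same_shape(self, rng):
        img = rng.standard_normal((48, 80))
        assert lowpass_bin(img, 16).shape == (48, 80)

    def test_factor_too_large(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            lowpass_bin(rng.standard_normal((8, 8)), 16)


class TestLowpassGaussian:
    def test_constant_unchanged(self):
        img = np.full((32, 32), 2.0)
        np.testing.assert_allclose(lowpass_gaussian(img, 0.125), img, atol=1e-10)

    def test_half_amplitude_at_cutoff(self):
        n = 128
        cutoff = 0.25  # cutoff frequency = 0.125 cycles/px -> 16 cycles over 128
        xx = np.arange(n)
        img = np.cos(2 * np.pi * 16 * xx / n)[None, :].repeat(n, axis=0)
        out = lowpass_gaussian(img, cutoff)
        ratio = out.std() / img.std()
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_large_cutoff_identity(self, rng):
        img = rng.standard_normal((32, 32))
        np.testing.assert_allclose(lowpass_gaussian(img, 50.0), img, atol=1e-3)

    def test_invalid_cutoff(self, rng):
        with pytest.raises(ValueError):
            lowpass_gaussian(rng.standard_normal((8, 8)), 0.0)


class TestDoseTitration:
    def _stack(self, seed=0, frames=40, size=64):
        rng = np.random.default_rng(seed)
        signal = np.tile(rng.standard_normal((size // 8, size // 8)).repeat(8, 0).repeat(8, 1), (1, 1))
        stack = signal[None] + 3.0 * rng.standard_normal((frames, size, size))
        return MovieStack(stack.astype(np.float32))

    def test_snr_increases_with_dose(self):
        table = dose_titration(self._stack(), [0.1, 0.25, 0.5], {"raw": lambda x: x})
        vals = table["raw"].to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_row_and_column_layout(self):
        table = dose_titration(
            self._stack(), [0.25, 0.5], {"raw": lambda x: x, "half": lambda x: 0.5 * x}
        )
        assert list(table.index) == [0.25, 0.5]
        assert list(table.columns) == ["raw", "half"]
        # snr_split is scale-invariant
        np.testing.assert_allclose(table["raw"], table["half"])

    def test_full_fraction_rejected(self):
        with pytest.warns(UserWarning, match="0.5"):
            with pytest.raises(ValueError, match="usable"):
                dose_titration(self._stack(), [1.0], {"raw": lambda x: x})

    def test_tiny_fraction_skipped(self):
        with pytest.warns(UserWarning, match="zero frames"):
            table = dose_titration(self._stack(frames=4), [0.1, 0.5], {"raw": lambda x: x})
        assert list(table.index) == [0.5]


class TestScaleDisplay:
    def test_reference_mean_maps_to_128(self, rng):
        ref = rng.standard_normal((32, 32))
        img = np.full((32, 32), ref.mean())
        np.testing.assert_array_equal(scale_display(img, ref), np.full((32, 32), 128, np.uint8))

    def test_clamp(self, rng):
        ref = rng.standard_normal((16, 16))
        lo = np.full((16, 16), ref.mean() - 100 * ref.std())
        hi = np.full((16, 16), ref.mean() + 100 * ref.std())
        assert set(scale_display(lo, ref).ravel()) == {0}
        assert set(scale_display(hi, ref).ravel()) == {255}

    def test_monotone(self, rng):
        ref = rng.standard_normal((16, 16))
        z = np.linspace(-5, 5, 257)
        img = ref.mean() + z * ref.std()
        buckets = scale_display(img[None, :], ref)[0]
        assert np.all(np.diff(buckets.astype(int)) >= 0)

    def test_constant_reference_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            scale_display(rng.standard_normal((4, 4)), np.full((4, 4), 1.0))


class TestRegionTsv:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "regions.tsv"
        path.write_text(
            "image_name\trole\tpair_id\tx0\ty0\tx1\ty1\n"
            "a.mrc\tsignal\tp1\t0\t0\t4\t4\n"
            "a.mrc\tbackground\tp1\t8\t8\t12\t12\n"
        )
        regions = read_region_tsv(path)
        assert len(regions) == 1
        rp = regions.items[0]
        assert rp.image_name == "a.mrc"
        assert rp.signal == Rect(0, 0, 4, 4)
        assert rp.background == Rect(8, 8, 12, 12)

    def test_missing_role_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "image_name\trole\tpair_id\tx0\ty0\tx1\ty1\n"
            "a.mrc\tsignal\tp1\t0\t0\t4\t4\n"
        )
        with pytest.raises(ValueError, match="exactly one"):
            read_region_tsv(path)

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("image_name\trole\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_region_tsv(path)
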