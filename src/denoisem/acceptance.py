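"""Reference experiments behind the acceptance checks.

Each function here recomputes one verifiable property of the method from
scratch on synthetic data — closed-form oracles on one side, the trained
implementation on the other — and returns the measured quantities. Both
``tests/test_acceptance.py`` and ``scripts/acceptance.py`` call these, so
the numbers asserted and the numbers reported are the same computation.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from denoisem.io_formats import ImagePlane
from denoisem.inference import denoise_image
from denoisem.models import ModelSpec, build_model
from denoisem.pairgen import NoisePair, split_even_odd
from denoisem.snr_eval import ccc, lowpass_bin, snr_split
from denoisem.synthetic_data import (
    NoiseModel,
    expected_pair_snr,
    make_scene_2d,
    noise_sigma_for_snr,
    render_movie,
)
from denoisem.train_n2n import TrainConfig, normalize_image, pair_loss, train


def stationary_gaussian_pairs(n: int, size: int, seed: int, signal_sigma: float = 2.0, amp: float = 8.0) -> List[NoisePair]:
    """Shared smooth Gaussian-process signal plus white noise per half."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        y = ndimage.gaussian_filter(rng.standard_normal((size, size)), signal_sigma) * amp
        a = y + rng.standard_normal((size, size))
        b = y + rng.standard_normal((size, size))
        pairs.append(NoisePair(even=ImagePlane(a), odd=ImagePlane(b), source=f"sg{i}"))
    return pairs


def wiener_normal_equations(pairs: Sequence[NoisePair], k: int = 31) -> Tuple[np.ndarray, float]:
    """Closed-form least-squares (Wiener) kernel + bias on normalized pairs.

    Independent oracle: the design matrix is built by explicit window
    extraction (zero-padded borders, both loss directions) and solved by
    normal equations — no shared code with the training path.
    """
    d = k * k
    A = np.zeros((d + 1, d + 1), dtype=np.float64)
    v = np.zeros(d + 1, dtype=np.float64)
    for pair in pairs:
        na, _ = normalize_image(pair.even)
        nb, _ = normalize_image(pair.odd)
        for src, tgt in ((na, nb), (nb, na)):
            padded = np.pad(src, k // 2).astype(np.float32)
            G = sliding_window_view(padded, (k, k)).reshape(-1, d)
            A[:d, :d] += (G.T @ G).astype(np.float64)
            col = G.sum(axis=0).astype(np.float64)
            A[:d, d] += col
            A[d, :d] += col
            A[d, d] += G.shape[0]
            v[:d] += (G.T @ tgt.reshape(-1).astype(np.float32)).astype(np.float64)
            v[d] += tgt.sum()
    sol = np.linalg.solve(A, v)
    return sol[:d].reshape(k, k), float(sol[d])


def run_wiener_equivalence(seed: int = 0, n_pairs: int = 32, size: int = 128) -> Dict[str, float]:
    """Criterion 1: trained affine-L2 kernel vs normal-equations solution."""
    pairs = stationary_gaussian_pairs(n_pairs, size, seed=seed + 7)
    w_oracle, _ = wiener_normal_equations(pairs)
    spec = ModelSpec(arch="affine", seed=seed)
    cfg = TrainConfig(loss_mode="l2", lr=0.01, epochs=100, batch=4, patch=size, seed=seed, augment=False)
    model, _ = train(pairs, spec, cfg)
    w_model = model.params()[0].value[0, 0].astype(np.float64)
    mass = float(np.abs(w_oracle).sum())
    linf = float(np.abs(w_model - w_oracle).max())
    return {"linf_over_mass": linf / mass, "kernel_mass": mass, "n": n_pairs * size * size}


def run_mean_median(seed: int = 0, n_pairs: int = 8, size: int = 64) -> Dict[str, float]:
    """Criterion 2: constant predictor under L2 -> mean, under L1 -> median."""
    rng = np.random.default_rng(seed + 3)
    pairs = []
    for _ in range(n_pairs):
        a = rng.exponential(1.0, (size, size))  # skewed noise, zero signal
        b = rng.exponential(1.0, (size, size))
        pairs.append(NoisePair(even=ImagePlane(a), odd=ImagePlane(b)))
    targets = np.concatenate(
        [np.concatenate([normalize_image(p.even)[0].ravel(), normalize_image(p.odd)[0].ravel()]) for p in pairs]
    )
    n = targets.size
    sample_mean = float(targets.mean())
    sample_median = float(np.median(targets))
    se_mean = float(targets.std() / np.sqrt(n))
    # SE of the median for an iid sample: 1 / (2 f(median) sqrt(n))
    bw = targets.std() * n ** (-1 / 5)
    f_med = float(np.mean(np.abs(targets - sample_median) < bw) / (2 * bw))
    se_median = 1.0 / (2 * f_med * np.sqrt(n))
    out: Dict[str, float] = {
        "sample_mean": sample_mean,
        "sample_median": sample_median,
        "se_mean": se_mean,
        "se_median": se_median,
        "n": n,
    }
    for mode in ("l2", "l1"):
        spec = ModelSpec(arch="constant", seed=seed)
        cfg = TrainConfig(loss_mode=mode, lr=0.05, epochs=200, batch=4, patch=size, seed=seed, augment=False)
        model, _ = train(pairs, spec, cfg)
        out[f"bias_{mode}"] = float(model.net.layers[0].bias.value[0])
    return out


def run_mse_ccc_identity(seed: int = 0, n_pairs: int = 1000, size: int = 32) -> Dict[str, float]:
    """Criterion 3: MSE == 2 - 2*CCC for normalized image pairs."""
    rng = np.random.default_rng(seed + 11)
    worst = 0.0
    for _ in range(n_pairs):
        a, _ = normalize_image(rng.standard_normal((size, size)))
        b, _ = normalize_image(rng.standard_normal((size, size)))
        mse = pair_loss(a, b, "l2")
        worst = max(worst, abs(mse - (2.0 - 2.0 * ccc(a, b))))
    return {"max_abs_deviation": worst, "n": n_pairs}


def run_snr_consistency(seed: int = 0, sizes: Sequence[int] = (128, 256, 512), replicates: int = 20, frames: int = 20) -> Dict[str, object]:
    """Criterion 4: split-frame estimator vs the analytic pair SNR (~-10 dB)."""
    errors = {}
    last_estimates = []
    for size in sizes:
        errs = []
        for r in range(replicates):
            scene = make_scene_2d(size, size, max(4, size // 16), 5.0, 2.0, seed=seed + 100 * size + r)
            sigma = noise_sigma_for_snr(scene, frames, 0.2)  # pair SNR = 0.1 -> -10 dB
            noise = NoiseModel(kind="gaussian", read_std=sigma, seed=seed + 999 + 100 * size + r)
            stack = render_movie(scene, frames, noise)
            pair = split_even_odd(stack)
            est = snr_split(pair.odd.data, pair.even.data)
            expected = expected_pair_snr(scene, noise, frames)
            errs.append(abs(est - expected))
            if size == sizes[-1]:
                last_estimates.append(est - expected)
        errors[size] = float(np.mean(errs))
    return {
        "mean_abs_error_db": errors,
        "largest_size_bias_db": float(np.mean(last_estimates)),
        "n": replicates,
    }


def region_snr_fixture() -> Tuple[Dict[str, ImagePlane], "RegionPairSet"]:
    from denoisem.snr_eval import Rect, RegionPair, RegionPairSet

    data = np.zeros((8, 8))
    data[0:2, 0:2] = 3.0
    data[4:6, 0:2] = [[0.0, 2.0], [0.0, 2.0]]
    regions = RegionPairSet(
        items=[RegionPair("img", "p1", Rect(0, 0, 2, 2), Rect(0, 4, 2, 6))]
    )
    return {"img": ImagePlane(data)}, regions


def run_stitch_equivalence(seed: int = 0, size: int = 256) -> Dict[str, Dict[str, float]]:
    """Criterion 6: padded patch stitching equals the whole-image pass."""
    rng = np.random.default_rng(seed + 17)
    img = ImagePlane(rng.standard_normal((size, size)))
    results = {}
    for arch, width in (("affine", 1), ("fcnn", 1), ("unet_small", 8), ("unet", 8)):
        model = build_model(ModelSpec(arch=arch, base_width=width, seed=seed + 1))
        if arch == "affine":
            model.params()[0].value[...] = (
                rng.standard_normal((1, 1, 31, 31)) * 0.05
            ).astype(np.float32)
        pad = (model.receptive_field + 1) // 2
        whole = denoise_image(model, img, patch=10 * size, pad=0)
        tiled = denoise_image(model, img, patch=96, pad=pad)
        seam = denoise_image(model, img, patch=96, pad=0)
        results[arch] = {
            "stitch_error": float(np.abs(tiled.data - whole.data).max()),
            "pad0_error": float(np.abs(seam.data - whole.data).max()),
        }
    return results


def run_end_to_end_ordering(
    seed: int = 0,
    n_pairs: int = 64,
    n_holdout: int = 8,
    size: int = 128,
    frames: int = 40,
    epochs: int = 20,
) -> Dict[str, float]:
    """Criterion 7: raw < 16x-binned low-pass < trained small U-net (dB)."""
    pairs, holdout = [], []
    for i in range(n_pairs + n_holdout):
        scene = make_scene_2d(size, size, 8, 6.0, 1.0, seed=seed * 100003 + 1000 + i)
        sigma = noise_sigma_for_snr(scene, frames, 0.1)
        noise = NoiseModel(kind="gaussian", read_std=sigma, seed=seed * 100003 + 2000 + i)
        stack = render_movie(scene, frames, noise)
        (pairs if i < n_pairs else holdout).append(split_even_odd(stack))
    spec = ModelSpec(arch="unet_small", base_width=16, depth=3, seed=seed)
    cfg = TrainConfig(loss_mode="l2", lr=0.001, epochs=epochs, batch=4, patch=96, seed=seed)
    model, history = train(pairs, spec, cfg)
    raw, binned, denoised = [], [], []
    for pair in holdout:
        even = pair.even.data
        raw.append(snr_split(pair.odd.data, even))
        binned.append(snr_split(lowpass_bin(pair.odd.data, 16), even))
        out = denoise_image(model, pair.odd, patch=size, pad=40)
        denoised.append(snr_split(out.data, even))
    return {
        "raw_db": float(np.mean(raw)),
        "lowpass16_db": float(np.mean(binned)),
        "unet_db": float(np.mean(denoised)),
        "final_train_loss": history.train_loss[-1],
        "n": n_pairs,
    }


def run_dose_titration_monotone(seed: int = 0, size: int = 256, frames: int = 40) -> Dict[str, object]:
    """Criterion 8: SNR strictly increases with dose fraction (identity method)."""
    from denoisem.snr_eval import dose_titration

    scene = make_scene_2d(size, size, 16, 5.0, 2.0, seed=seed + 23)
    sigma = noise_sigma_for_snr(scene, frames, 0.4)
    stack = render_movie(scene, frames, NoiseModel(kind="gaussian", read_std=sigma, seed=seed + 29))
    table = dose_titration(stack, [0.1, 0.175, 0.25, 0.375, 0.5], {"raw": lambda x: x})
    values = [float(x) for x in table["raw"]]
    return {"fractions": list(table.index), "snr_db": values, "n": frames}
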