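# denoisem

Self-supervised denoising for cryoEM micrographs and cryoET tomograms.

Detector movies record many short frames of the same specimen. Summing the
even-indexed and odd-indexed frames yields two independent observations of
the identical signal, which is enough to train a denoising network with no
clean targets: the model maps each half to the other, and the symmetric
two-direction loss (L2 → mean-seeking, L1 → median-seeking, smoothed L0 →
mode-seeking) drives it toward the underlying signal. Full-size images are
denoised by normalized, padded patch stitching — with padding of at least
half the model's receptive field, the stitched output equals a whole-image
forward pass. Quality is quantified with two SNR estimators: a split-frame
estimator based on the Pearson correlation `p` between independent halves
(`SNR = p / (1 − p)`, reported as `10·log10(p/(1−p))` dB) and a
region-pair estimator from annotated signal/background rectangles.

The package is pure NumPy/SciPy: the convolutional models (a 31×31 affine
filter, a 3-layer FCNN, small/full 2D U-nets, and a 3D U-net), their
backward passes and the Adagrad training loop are implemented on top of
FFT-based convolutions, so everything runs on a single CPU with fully
deterministic, seeded results.

## Layout

| module | contents |
| --- | --- |
| `denoisem.io_formats` | MRC2014 / TIFF reading and writing (`ImagePlane`, `Volume`, `MovieStack`) |
| `denoisem.pairgen` | even/odd frame splitting, dose fractionation, frame sums, dataset balancing |
| `denoisem.nn` | FFT convolution engine with manual backprop, pooling, upsampling, Adagrad |
| `denoisem.models` | architectures, receptive-field accounting, checkpoints |
| `denoisem.train_n2n` | normalization, patch sampling, dihedral augmentation, losses, training loop |
| `denoisem.inference` | tile planning and padded patch-stitched denoising (2D and 3D) |
| `denoisem.snr_eval` | split-frame and region-pair SNR, low-pass baselines, dose titration, display scaling |
| `denoisem.synthetic_data` | scenes, noise models and rendered movies with analytically known SNR |
| `denoisem.cli` | `denoisem` command-line entry point |

## Command line

```bash
# synthetic movies with known ground truth
denoisem simulate --out fixtures/ --n-pairs 64 --size 128 --frames 40 --snr 0.1 --seed 0

# split movies into even/odd frame-sum pairs
denoisem pairgen --input 'fixtures/movie_*.mrc' --output pairs/ --max-per-dataset 200 --seed 0

# train (defaults: lr 0.001, 100 epochs, batch 4, 800x800 patches)
denoisem train --pairs pairs/ --out model.ckpt --arch unet --loss l1 --seed 0

# denoise micrographs (defaults: 4000x4000 patches with 500 px padding)
denoisem denoise2d in.mrc --model model.ckpt -o out/

# denoise a tomogram (default 96-voxel cubic patches)
denoisem denoise3d vol.mrc --model unet3d.ckpt -o out_vol.mrc

# SNR estimation and dose titration
denoisem snr split --a denoised_odd.mrc --b raw_even.mrc
denoisem snr regions images/ --annotations regions.tsv
denoisem titrate --stack movie.mrc --fractions 0.1,0.175,0.25,0.375,0.5 --model model.ckpt
```

Every subcommand accepts `--config config.yaml` (keys mirror the flags,
explicit flags win) and writes the resolved configuration next to its
outputs. All runs are deterministic given `--seed`.

Region annotations are tab-separated with columns
`image_name  role  pair_id  x0  y0  x1  y1` (role is `signal` or
`background`; coordinates are 0-based, half-open).

## Limits

Frame alignment, CTF estimation, particle picking and reconstruction are
out of scope; pairs are built from unaligned (or externally pre-aligned)
frames. Inference holds whole images in memory — volumes larger than RAM
are not streamed.
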