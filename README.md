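# spidesr

Self-supervised denoising and blind super-resolution for imaging mass
cytometry (IMC) and similar single-shot microscopy, with the full
evaluation suite used to score restoration quality.

IMC images a sample by laser-ablating it one pixel at a time — the tissue
is consumed as it is read, so no field of view can be acquired twice.
That rules out supervised restoration (there are no clean/noisy or
high-/low-resolution image pairs), and this package implements the two
stages that work anyway:

- **Denoising without clean references.** A neighbor sub-sampler splits
  one noisy image `y` into two half-resolution images `g1(y), g2(y)`
  whose paired pixels are 4-adjacent in `y`: nearly identical signal,
  independent noise. A small U-net `U` is trained with

  `L = ‖U(g1(y)) − g2(y)‖² + γ‖U(g1(y)) − g2(y) − (g1(U(y)) − g2(U(y)))‖²`

- **Blind ×4 super-resolution.** The degradation model is
  `I_LR = (K ⊗ I_HR)↓s + n` with an unknown isotropic Gaussian blur `K`.
  A predictor estimates `k₀ = P(I_LR)`; a kernel-conditioned SR network
  renders `I_SR = S(I_LR, k)`; a corrector proposes increments
  `Δk_i = C(I_SR, k_{i−1})`, iterated until `‖Δk_i‖₂` falls below
  tolerance. The final image is rendered with the last kernel.

Everything runs on plain numpy (the layer engine with manual
backpropagation ships in `spidesr.nn`), and a synthetic IMC-like scene
generator makes the whole pipeline testable end-to-end without any data
download. Evaluation covers PSNR, a whole-image-moment SSIM, object-level
cell matching (IoU/F1, extraction accuracy), per-cell marker
quantification with 99th-percentile censoring/normalization, and the
Calinski–Harabasz / Davies–Bouldin clustering indices.

## Worked example

Train the desk-preset blind-SR stack on 64 synthetic scenes and run the
kernel-correction loop on a held-out image:

```python
import numpy as np
from spidesr import (SceneSpec, generate_scene, DegradationConfig,
                     make_training_pairs, PatchSet, BlindSuperResolver)

scenes = [generate_scene(SceneSpec(field_size=64, n_cells=12, seed=i))[0]
          ["nucleus"] for i in range(64)]
pairs = make_training_pairs(PatchSet(scenes), DegradationConfig(scale=4),
                            np.random.default_rng(0))
model = BlindSuperResolver(random_state=0).fit(pairs.train)

hr, lr, k_true = pairs.val[0]
sr, trace = model.enhance(lr, true_kernel=k_true)
```

The trace prints as (true blur width σ = 1.23):

```
iter 0  sigma_est 1.46  |dk|       -  kernel_mse 6.00e-06
iter 1  sigma_est 1.39  |dk| 1.4e-02  kernel_mse 3.21e-06
iter 2  sigma_est 1.39  |dk| 1.0e-03  kernel_mse 3.39e-06
iter 3  sigma_est 1.39  |dk| 7.1e-05  kernel_mse 3.38e-06
converged_at 3
```

The predictor's initial width estimate (1.46) is pulled toward the truth
by the first correction (1.39, kernel MSE roughly halved) and the
increment norm contracts below the 1e-4 tolerance at iteration 3 — well
inside the default budget of 9 iterations. On this validation split the
SR network given the true kernel averages 29.30 dB PSNR against 29.05 dB
for the bicubic ×4 baseline; the fully blind loop averages 28.08 dB,
reflecting the residual width-estimate error of the desk-scale predictor
(see `docs/methods.md`, Known limitations).

Denoising, on 16 noisy scenes (Gaussian noise, std 25 of 255):

```python
from spidesr import NoiseSpec, add_noise, NeighborSubsampleDenoiser, psnr, ssim
noisy = [add_noise(img, NoiseSpec("gaussian", 25.0, seed=100 + i))
         for i, img in enumerate(clean)]
model = NeighborSubsampleDenoiser(epochs=20, random_state=0).fit(noisy)
denoised = model.transform(noisy)
```

```
noisy    PSNR 21.43 dB  SSIM 0.930
denoised PSNR 22.98 dB  SSIM 0.950
```

(Training on the benchmark's 64-scene set raises the gain to several dB;
the numbers above are what the 16-image snippet prints.)

## Command line

```bash
spidesr simulate --out scenes/ --n-images 16 --seed 0
spidesr degrade --input scenes/img_000.tif --out lr.tif --sigma 2.0 --scale 4
spidesr train-denoise --input noisy/ --out denoiser.npz --seed 0
spidesr train-sr --input scenes/ --out blindsr.npz --seed 0
spidesr enhance --model blindsr.npz --input lr.tif --out sr.tif \
        --denoise denoiser.npz --trace trace.json
spidesr evaluate --reference scenes/img_000.tif --test sr.tif
spidesr quantify --mask mask.tif --channels cd45.tif --out cells.csv
spidesr run --out run/ --seed 0        # full pipeline + manifest
```

All commands are deterministic given `--seed`; `run` writes a manifest
(config hash, versions, per-stage seeds) next to its outputs.

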