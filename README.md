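# ilrdd

Prior-driven low-rank denoising for magnitude MR images, with Rician-noise
simulation, PSNR/SSIM evaluation, and diagnostic-concordance statistics for
reading-vs-reference contingency tables.

Magnitude MRI is corrupted by Rician noise — each pixel is
`sqrt((v + n1)^2 + n2^2)` with `n1, n2 ~ N(0, sigma^2)` — which degrades
image quality and, downstream, diagnostic reading.  This package is for
researchers evaluating patch-based MRI denoising and for anyone scoring an
imaging reading against a reference standard (here: knee-osteoarthritis
MRI readings against arthroscopy).

## The algorithm

1. **Patch prior.**  Overlapping `p x p` blocks of clean imagery, with their
   means (DC) removed, are modelled by a Gaussian mixture
   `p(v) = sum_k w_k N(v; mu_k, Sigma_k)` fitted by EM.
2. **Group-wise low-rank contraction.**  Noisy patches are classified to
   mixture components by maximum posterior; the patches of each component
   are stacked into a matrix `R_k = Z_k + N_k`, and the low-rank part is
   estimated from the SVD `R_k = U S V^T` by weighted soft-thresholding
   `s_i' = max(s_i - tau sqrt(d) sigma^2 / (s_i + eps), 0)`, reassembled as
   `Z_k = U S' V^T`.
3. **Reconstruction.**  The image solves
   `min_x (lambda ||y - x||^2 + sum_i ||P_i x - z_i||^2) / sigma^2`,
   i.e. each pixel is the weighted mean of the noisy value and all covering
   patch estimates.  The loop repeats a few times with a decaying residual
   noise level.

A plain low-rank baseline (block-matching groups instead of mixture
classes) isolates the value of the learned prior.  The diagnostics module
computes sensitivity, specificity, accuracy, Cohen's kappa with agreement
bands, and chi-square comparisons of reading accuracies; five knee-MRI
reading tables (n = 198 cartilages each) ship as packaged fixtures.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
import ilrdd
from ilrdd.experiment import ExperimentConfig, train_default_prior

# Learn a K=32 patch prior from clean phantoms (held out from the test image)
cfg = ExperimentConfig(height=128, width=128)
prior = train_default_prior(cfg, master_seed=1)

# Simulate a 3% rice-intensity acquisition and denoise it
clean = ilrdd.generate_phantom(128, 128, 4, 1.0, seed=5)
noisy = ilrdd.add_rician_noise(clean, ilrdd.NoiseSpec(3.0, seed=5))
out = ilrdd.ilrdd_denoise(noisy, prior, ilrdd.DenoiseParams(sigma=0.03))

print("PSNR noisy  %.2f dB" % ilrdd.psnr(clean, noisy))
print("PSNR output %.2f dB" % ilrdd.psnr(clean, out))
print("SSIM output %.4f" % ilrdd.ssim(clean, out))
```

prints

```
PSNR noisy  28.67 dB
PSNR output 30.84 dB
SSIM output 0.9953
```

— the denoiser recovers about 2 dB of peak signal-to-noise ratio at the 3%
noise level, and structural similarity to the clean image rises from
0.9925 to 0.9953.

Scoring a packaged reading table:

```python
summary = ilrdd.summarize(ilrdd.load_fixture_tables()[-1])  # multimodal
print(summary.sensitivity, summary.specificity, summary.accuracy,
      summary.kappa, summary.kappa_band)
```

gives sensitivity 88.62%, specificity 85.33%, accuracy 87.37% and kappa
0.73 ("strong" agreement) for the multimodal reading against arthroscopy.

## Command line

The `ilrdd` console script exposes the pipeline:

```sh
ilrdd simulate --height 128 --width 128 --noise-percent 3 --seed 0 \
      --out-clean clean.png --out-noisy noisy.png
ilrdd train-prior --images dir_of_clean_pngs --components 32 --out prior.npz
ilrdd denoise --in noisy.png --out denoised.png --prior prior.npz --sigma auto
ilrdd evaluate --ref clean.png --test denoised.png --out report.json
ilrdd diagnostics --tables builtin --out summaries.csv
ilrdd experiment --seed 0 --out sweep/
```

Images are 16-bit grayscale PNG or single-slice NIfTI-1; `--sigma auto`
estimates the noise level from the median absolute deviation of a
Laplacian-filtered image.

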