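# denobench

A workbench for benchmarking classical multiscale image denoisers on
medical-style imagery: a Gaussian-pyramid denoiser with level-specific
filters, wavelet-shrinkage baselines, a full-reference quality-metric
suite, exact paired statistical comparison, and a fully seeded synthetic
noise generator — so the whole protocol runs end to end without any
external datasets.

## Who this is for

Researchers evaluating spatial- versus transform-domain denoising on
grayscale or RGB rasters (PNG/TIFF/JPEG) — e.g. X-ray, MRI slices
exported as PNG, or natural images — who need reproducible,
statistically tested comparisons rather than single-image anecdotes.

## The methods

**Gaussian-pyramid (GP) denoising.** The noisy image
`I_n(x,y) = I(x,y) + N(x,y)` is decomposed into a pyramid
`I_{l+1}(x,y) = Σ_i Σ_j G(i,j) I_l(2x+i, 2y+j)` using a normalized
Gaussian kernel `G_σ(x,y) ∝ exp(−(x²+y²)/2σ²)`. Each level is filtered
by a scale-matched filter — bilateral (diameter 5, range σ 7) at the
finest level, 3×3 median at intermediate levels, Gaussian (σ 0.7, 5×5)
at the coarsest — and the stack is reassembled coarse-to-fine, each
level's own low-pass content being replaced by the reconstructed
coarser estimate. Feeding back unfiltered levels reproduces the
original image to 1e-9: the reconstruction is exact by construction.

**Wavelet shrinkage baselines.** Separable 2-D DWT (Haar, db4, coif4,
sym4) into `{LL, LH, HL, HH}` subbands; detail coefficients are
soft-thresholded (`sign(w)·max(|w|−T, 0)`) or hard-thresholded (keep
`|w| ≥ T`) with the universal threshold `T = σ̂ √(2 ln N)`,
`σ̂ = median(|HH₁|)/0.6745`; inverse DWT reconstructs.

**Metrics.** MSE, RMSE, MAE, PSNR (`10 log₁₀(255²/MSE)` dB), windowed
SSIM (k₁ = 0.01, k₂ = 0.03, L = 255), pixel-domain multiscale VIF,
Pratt's figure of merit `FOM = (1/max(N_a,N_b)) Σ 1/(1+αd²)` with
α = 1/9, population SD, and wall time.

**Statistics.** Per-image metric vectors of two methods are compared
with the paired t-test `t = mean(d)/(s_d/√n)` and the **exact**
Wilcoxon signed-rank test: the null distribution is enumerated over all
2ⁿ sign assignments of the ranked |differences|, so for n = 10 images a
clean sweep yields the exact two-sided p = 2/1024 = 0.001953125.

## Worked example

```
denobench bench --out demo --n-images 10 --size 128 --seed 0 \
    --methods wavelet-db4-soft,wavelet-db4-hard,gp
```

prints (abridged):

```
30 metric rows -> demo/metrics.csv
                                pair         t      p_t   W      p_w significance
wavelet-db4-soft vs wavelet-db4-hard -3.245981 0.010062 3.0 0.009766  significant
              wavelet-db4-soft vs gp  3.350480 0.008517 3.0 0.009766  significant
```

Ten 128×128 phantoms get Gaussian noise (σ = 15); each method denoises
all ten; `demo/metrics.csv` holds one row per (image, method) with
PSNR/SSIM/MSE/RMSE/VIF/FOM/MAE/time. The significance table reads: hard
thresholding beat soft by enough to be significant at α = 0.05 (its
smaller signed-rank sum was 3, exact two-sided p = 10/1024 ≈ 0.0098),
and soft-threshold shrinkage in turn beat the pyramid method under this
heavy-noise condition. The first method listed is the baseline of every
pair; negative t means the baseline scored lower.

Other entry points: `denobench simulate` (phantoms + the nine-family
noise taxonomy and a composite camera model), `denobench denoise`,
`denobench evaluate`, `denobench compare`. All commands accept
`--seed`; identical seeds give byte-identical outputs apart from the
timing column.

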