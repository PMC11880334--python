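# burnscope

Burn-wound photographs are hard to assess by eye: clinical judgment of burn
depth is only ~70% accurate and varies between assessors, yet depth and
affected area drive the treatment decision (conservative care vs. excision
and grafting). `burnscope` is an image-analysis toolkit for this problem. It
takes an RGB photograph of a burn sample and produces a burn-depth label
map, texture descriptors, a classifier-assigned severity class, and a
per-sample TBSA report — the share of the sample area occupied by each
depth class.

The pipeline, stage by stage:

1. **Perceptual color transform** — sRGB → CIE 1976 L\*u\*v\* (D65), separating
   luminance L\* from chrominance (u\*, v\*), followed by 5×5 Gaussian
   smoothing (σ = 1.5) of each plane.
2. **Contrast-kinetic enhancement** — the standard Tofts two-compartment
   model C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^(−K^trans (t−τ)/v_e) dτ simulates
   contrast-agent uptake; the L plane is brightened (gamma lift) and
   contrast-stretched in proportion to the normalized uptake at the
   evaluation time.
3. **ACICA + FCM segmentation** — optional FastICA channel unmixing, fuzzy
   C-means clustering of luminance (memberships
   u_ik = 1/Σ_j (d_ik/d_ij)^(2/(m−1))), and region summaries: per-region
   means g(ii), squared adjacent differences, the center mean ḡ, and the
   dispersion Σ(g(ii) − ḡ)².
4. **RR segmentation** — histogram quantization with dark-pixel discard
   (Z_th), peak centers merged within D_th, total nearest-center labeling,
   and the agent percentage.
5. **GLCM texture features** — co-occurrence matrices at offsets
   0°/45°/90°/135°; contrast Σ(i−j)²P(i,j) and correlation
   Σ(i−μᵢ)(j−μⱼ)P(i,j)/(σᵢσⱼ) for the L and chroma planes and their
   squares, plus plane means: a 10-value descriptor.
6. **Classifiers** — a 3-block CNN (32/64/128 filters, 3×3 kernels, 2×2
   max-pool, dropout 0.25), an FNN on the texture descriptor, and a tanh
   RNN over rows of the downsampled L plane; 70/15/15 stratified split,
   50 epochs, seeded augmentation, categorical cross-entropy.
7. **TBSA report** — percent_c = 100·|pixels of class c| / |sample| for
   healthy/superficial/dermal/deep, with per-class L histograms, a pie
   chart and a color-coded overlay.

Clinical burn photographs are protected patient data, so the package ships
a seeded phantom generator: nested-ellipse lesions whose rings are the
burn-depth classes, with class-specific color palettes and texture
granularity that decreases with depth. Phantoms validate the pipeline
mechanics; they make no clinical claim.

## Worked example

```python
from burnscope import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline

img, truth = generate_phantom(PhantomSpec(size=(64, 64), seed=42))
result = run_pipeline(PipelineConfig(), img, sample_id="phantom-42")
for name, pct in result.tbsa.percent.items():
    print(f"{name:12s} {pct:6.2f}%")
```

prints

```
healthy       48.34%
superficial   23.19%
dermal        13.57%
deep          14.89%
```

against ground-truth shares of 50.20 / 19.92 / 14.84 / 15.04 — the
estimates track the generator's mask, and the residual is segmentation
error concentrated in healthy-vs-superficial confusion (their palettes are
closest in color). `examples/` holds one short script per capability
(color transform, kinetics + enhancement, both segmentations, texture
features, classifiers, TBSA), each printing the numbers it computes and a
line on what they mean. A thin CLI mirrors the same stages:

```bash
burnscope simulate --n 9 --seed 1 --size 64 --out scratch/phantoms
burnscope segment --in scratch/phantoms/phantom_000.png --out scratch/seg.png --method acica
burnscope tbsa --labels scratch/phantoms/phantom_000_mask.png --out scratch/report
```

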