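# facegrad

Analysis pipeline for **fine-scale spatial tuning of face-part responses
within face-selective cortex**, with a synthetic-data generator that
plants the organization the analysis is designed to detect.

High-field fMRI can resolve structure *inside* a face-selective region
such as the fusiform face area (pFFA) or occipital face area (OFA). The
question this package addresses: do different face parts (eyes, mouth,
nose, hair, chin) drive systematically different locations along the
region's posterior→anterior axis — e.g. eyes biased posterior, mouth
biased anterior? `facegrad` provides every stage of that analysis for
researchers working with per-condition beta maps or block-design BOLD
time series:

1. **GLM** — boxcar regressors convolved with a gamma HRF
   h(t) = ((t−δ)/τ)²e^{−(t−δ)/τ} (δ = 2.25 s, τ = 1.25 s), OLS betas,
   percent signal change = 100·β/baseline;
2. **ROI definition** — largest connected component of voxels with
   localizer faces > objects at uncorrected p < 0.01, then exclusion of
   vein-contaminated voxels (face PSC > 4%);
3. **Pattern analysis** — z-score normalization across voxels,
   eyes−mouth contrast maps, and removal of the shared spatial profile
   (whole-face or object pattern) by linear regression;
4. **Axis profiles** — orthogonal projection of each vertex onto a
   posterior→anterior anatomical polyline (mid-fusiform or
   occipitotemporal sulcus direction), binned 1-D profiles (mean ± SEM),
   and the **gradient correlation** r = corr(eyes−mouth, position);
5. **Group statistics** — one-sample t on per-subject r (Cohen's
   d = mean/sd), paired condition-amplitude tests, odd/even split-half
   reliability;
6. **CSS pRF control** — compressive spatial summation receptive-field
   model r(t) = gain·(Σ aperture·Gaussian)ⁿ ⊛ HRF with rotating-wedge
   (45°, 32 s/cycle) and expanding/contracting-ring (28 s + 4 s rest)
   apertures, grid + Nelder-Mead fitting, and the R² > 2% inclusion
   filter — used to check that any part gradient is not a retinotopic
   x/y-map gradient in disguise.

The synthetic generator builds cortical grid patches whose condition
betas are a shared baseline pattern + condition-specific linear
gradients along the axis + Gaussian noise, with a face-selective blob
for the localizer and planted vein voxels — so the whole chain is
testable end to end with known ground truth and no data download.

## Worked example

```python
import facegrad as fg

result = fg.run_pipeline(fg.RunConfig(seed=11))
print(result.group.summary())
for s in result.subjects:
    print(f"ROI {len(s.roi)} voxels, gradient r = {s.gradient_r:+.3f}, "
          f"split-half r = {s.split_half_r:.3f}")
```

prints

```
mean r = -0.888, t(5) = -311.43, p = 6.478e-12, Cohen's d = -127.14
ROI 98 voxels, gradient r = -0.896, split-half r = 0.650
ROI 102 voxels, gradient r = -0.891, split-half r = 0.679
ROI 104 voxels, gradient r = -0.882, split-half r = 0.726
ROI 101 voxels, gradient r = -0.877, split-half r = 0.631
ROI 101 voxels, gradient r = -0.891, split-half r = 0.603
ROI 98 voxels, gradient r = -0.890, split-half r = 0.633
```

Six synthetic subjects were simulated with an eyes-posterior /
mouth-anterior gradient planted at subject-level SNR 3, pushed through
the forward block design, re-estimated by the GLM, localized, vein
filtered, normalized, contrasted, and projected onto the axis. Every
subject's eyes−mouth contrast correlates negatively with
posterior→anterior position (eyes biased posterior), the group test is
overwhelmingly significant, and the odd/even split-half reliability of
the contrast maps is ~0.6–0.7, as expected at this noise level. The
same run from the shell, with profile plots and a report bundle:

```bash
facegrad all --seed 11 --out out/
cat out/report.txt
```

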