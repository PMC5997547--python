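# bctseg

Unsupervised four-class tissue classification for dedicated breast CT.

Dedicated breast CT images the pendant, uncompressed breast as a stack
of coronal slices with sub-millimeter isotropic voxels.  Quantifying
its composition — skin, adipose tissue, fibroglandular tissue and
vasculature — feeds breast-density estimation, dose simulation and
tissue-pattern biomarkers, but manual segmentation is impractically
slow.  `bctseg` classifies every voxel into those four classes (plus
background) with no training data and no user-set thresholds, for
researchers working with breast-CT volumes or realistic digital breast
phantoms.

The classifier runs slice by slice:

1. **Skin** — the outer edge comes from a binarized Sobel gradient; the
   skin centerline is extracted as a maximum-convexity height ridge
   (λ₁ < 0 and v₁·∇I ≈ 0 for the Hessian eigenpair, linked by a
   max-intensity walk with forbidden rear directions); skin is then
   grown from the centerline under a double threshold (mean edge / mean
   centerline intensity) and a distance constraint (no farther from the
   centerline than the largest edge-to-centerline distance d), which
   keeps equally bright vessels near the skin out of the class.
2. **Adipose vs dense tissue** — an energy-minimizing active contour
   combining region statistics and edge strength,

   E(t) = (σ²_ext − k)² + |Δσ²_int| + |Δμ_int|⟨I²⟩_int +
          |Δμ_ext|⟨I²⟩_ext + 1/(Σ_C |∇I|),

   initialized from the valley of the bimodal interior histogram, with
   k (the a-priori adipose variance) estimated by a 30-iteration region
   growing from the darkest interior pixel.  The contour grows, expands
   through a 3×3 Gaussian kernel (σ = 0.5), and jumps to disconnected
   structures matching its interior statistics until the energy is null
   (< 1e-3).  Subtracting the result leaves the adipose tissue.
3. **Vessels vs fibroglandular tissue** — per-component shape features
   (intensity variance, circularity 4π·Area/Perimeter², aspect ratio
   min(d)/max(d) of centroid-to-boundary distances, boundary inflection
   count via unit-normal flips ‖ΔN‖² > 1), pooled over the whole
   volume, split by 3-means (two vessel appearances + gland; best of 20
   restarts); finally a 3D continuity criterion keeps a vessel voxel
   only if ≥ 3 of the 9 positions in the previous or next slice of its
   26-neighborhood are vessels.

Evaluation utilities implement Dice, sensitivity, conformity
Kc = 1 − (FP+FN)/TP, Hausdorff and average distance, and a
noise-robustness harness that re-classifies noise-corrupted volumes
against the clean run.  A bundled phantom generator produces synthetic
breast volumes with exact ground truth (see `docs/methods.md`).

## Worked example

```python
from bctseg import PhantomSpec, make_volume, classify_volume, PipelineConfig
from bctseg.metrics import evaluate_labelmaps, format_report

volume, truth = make_volume(PhantomSpec(seed=1))          # 10 x 256 x 256
labels = classify_volume(volume, PipelineConfig(master_seed=1))
print(format_report(evaluate_labelmaps(labels, truth)))
```

prints

```
class           dsc   sensit  conform      hd     avd
adipose         0.988   1.000    0.975    7.00    0.14
fibroglandular  0.991   0.982    0.981   10.05    0.02
skin            0.928   0.865    0.844    1.41    0.14
vasculature     0.998   0.997    0.997    1.00    0.00
```

i.e. on the default noisy phantom (additive Gaussian noise σ = 0.02)
each tissue class agrees with the ground truth at Dice 0.93–1.00, with
boundary discrepancies of at most a few pixels (HD) and well under one
pixel on average (AVD).  Skin is the hardest class: its score is
dominated by the partial-volume air–skin layer, whose darker half sits
at the algorithm's own low threshold.

The same pipeline is scriptable from the shell:

```
bctseg phantom  --output vol.nii.gz --truth gt.nii.gz --seed 1
bctseg classify --input vol.nii.gz --format nifti --output labels.nii.gz --seed 1
bctseg evaluate --pred labels.nii.gz --truth gt.nii.gz
```

Input volumes may be DICOM series, NIfTI or multi-page TIFF; label maps
are written as unsigned 8-bit with codes 0 background, 1 adipose,
2 fibroglandular, 3 skin, 4 vasculature.

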