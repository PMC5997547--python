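# Methods

bctseg classifies every voxel of a dedicated breast-CT volume (coronal
slice stack, sub-millimeter isotropic voxels) as background, adipose,
fibroglandular, skin or vasculature, without training data and without
user-set thresholds.  The pipeline runs slice by slice — skin first,
then the adipose/dense split — and finishes with two volume-level
steps: pooled clustering of the dense components and a through-slice
continuity check on the vasculature.  This note records the model, its
discretization, the constants and the open design choices.

All processing happens on intensities linearly rescaled to [0, 1] over
the whole volume.  Distances are in pixels unless stated otherwise; the
default in-plane pitch is 0.273 mm.

## Skin segmentation

**Outer edge.** The Sobel gradient magnitude is binarized with Otsu's
threshold, filled, and the largest connected region kept.  Because the
binarized Sobel band extends one pixel past the physical air–skin step,
the filled region is trimmed to the intensity foreground (Otsu on
intensity) so the reported boundary sits on the outermost tissue
pixels.  The region boundary is the one-pixel outer edge.

**Centerline.** The skin's mid-layer is brighter than its flanks, so
the centerline is a maximum-convexity height ridge.  Candidates are
found by walking each outer-edge seed uphill (toward the brightest
8-neighbor) to a 1D intensity maximum; a candidate is a ridge point
when the smaller eigenvalue λ₁ of the 2×2 finite-difference Hessian is
negative and the gradient is orthogonal to the corresponding
eigenvector, |v₁·∇I| < ε with the tolerance-to-zero ε = 1e-6.
Derivatives are central differences at unit scale, with no smoothing,
everywhere.  On real CT data, whose intensities are effectively
discrete, the strict tolerance always leaves a few exact hits; on
continuous-valued synthetic images it can reject every candidate, in
which case the 8 candidates with λ₁ < 0 and the smallest projection are
kept — the subsequent linking needs only a few anchors.

Ridge points are linked by a forward and a backward max-intensity walk
from the lexicographically first ridge point.  Three numerical guards
keep the walk on the ridge under noise, none of which changes the
noise-free behavior:

* the walk ranks neighbors by a 3×3 local mean of the image (raw-pixel
  argmax zigzags and wedges the path against its own visited pixels);
* a neighbor is admissible only if its smaller Hessian eigenvalue is
  negative (the path is a ridge) and its intensity is at least the mean
  outer-edge intensity (the centerline lies within the skin);
* rear neighbors relative to the previous step are forbidden — three
  positions after an axis step, five after a diagonal step — and the
  search ends once every ridge point is linked (plus a closure budget),
  or when the path returns to the 8-neighborhood of its start after an
  excursion at least as large as the ridge-point span.

**Region growing.** Skin is grown from the centerline under a double
threshold — t_low = mean outer-edge intensity, t_high = mean centerline
intensity — and a distance constraint: a pixel is accepted only if its
Euclidean distance (exact distance transform) to the centerline is at
most d_max, the largest outer-edge-to-centerline distance.  The
distance constraint is what keeps equally bright vessels or gland
tissue adjacent to the skin out of the skin class.  Centerline pixels
seed the growth; a path pixel darker than t_low (a tracing excursion)
does not.  Thresholds carry a 1e-9 epsilon because on piecewise-constant
images the mean of N identical values differs from the value by an ulp.

## Adipose / dense split (active contour)

The skin-free interior (the region enclosed by the skin ring) is split
into adipose and "dense" (fibroglandular + vessels) by a region+edge
energy-minimizing contour.

**Initialization.** The interior histogram (256 bins, smoothed by a
window-9 moving average) is bimodal: fat vs dense.  The two dominant
modes are regional maxima surviving h-maxima reconstruction (h = 1% of
the peak count); the valley is the minimum between them.  The contour
starts at the interior-most pixel of the largest above-valley
component.  A unimodal histogram means the slice has no dense tissue:
the contour is skipped and the whole interior is adipose.

**A-priori adipose variance k.** From the darkest interior pixel, a
30-iteration region growing accepts pixels between 10% and 90% of the
valley intensity; k is the variance of the grown region (the local
noise power of fat).  If the grown region degenerates (< 10 px), k
falls back to the variance of all below-valley interior pixels.

**Energy.**  With Ω_int the region, Ω_ext the remaining interior and C
the contour band (inner plus outer boundary pixels),

E(t) = (σ²_ext − k)² + |Δσ²_int| + |Δμ_int|·⟨I²⟩_int + |Δμ_ext|·⟨I²⟩_ext
       + 1 / (Σ_C |∇I| + 1e-6)

where Δ denotes the backward difference across iterations (zero at
t = 0), ⟨I²⟩ a per-region mean, and |∇I| the unnormalized Sobel
magnitude.  Each term vanishes (or reaches its floor) at convergence:
the exterior variance matches the adipose prior once only fat remains
outside; the statistics' derivatives vanish when the region stops
changing; and the reciprocal accumulated gradient decays as the contour
locks onto, and gathers, strong edges.  The reciprocal-of-total-gradient
reading of the edge term is deliberate: a per-pixel mean of 1/|∇I|
plateaus at order unity on [0, 1]-normalized images and could never
reach the 1e-3 null threshold.  No term carries a tunable weight.

**Evolution.** Each iteration, boundary-adjacent pixels whose intensity
lies within max(2·std_int, 3·√k) of the interior mean join the region
(√k supplies the tolerance scale when the region statistics are still
degenerate; with k = 0 on noise-free images the rule reduces to exact
membership), and the region is expanded by convolution with a 3×3
Gaussian kernel (σ = 0.5, threshold 0.3 — fills interior holes without
advancing straight fronts).  When growth stalls, the contour propagates
to nearby connected structures whose mean intensity lies within
[μ_int ± σ_int], searching at increasing radius (5 px steps, up to the
image diagonal) so that fragmented gland tissue and isolated vessels
across wide fat gaps are all captured; propagation repeats until
nothing admissible remains anywhere.  The energy is then at its floor;
E < 1e-3 (the printed null threshold) marks convergence, and the
iteration cap (2000) raises a non-convergence error carrying the best
state.  Propagation is attempted even when E is already below
threshold: on the normalized scale the squared-variance term is ~1e-7
when one small vessel remains outside, far below 1e-3, so the energy
alone cannot signal completeness.

Adipose is the interior minus the converged dense mask; slice labels
are a strict partition by construction.

## Vessel / fibroglandular discrimination

Per slice, each 8-connected dense component yields four features:

* intensity variance;
* circularity C = 4π·Area/Perimeter², with the 4-direction Crofton
  perimeter (a raw boundary-pixel count biases C upward by tens of
  percent; note Crofton itself retains a ~13% bias on axis-aligned
  squares — the documented discretization tolerance of that estimator);
* aspect ratio = min/max distance from the center of mass to the
  boundary;
* boundary inflection count: along the traced boundary, the unit normal
  N_k is the normalized change of consecutive unit tangents (equivalent
  to V×(T₂−T₁)×V with V the out-of-plane axis); a point is an
  inflection when ‖N_{k+1} − N_k‖² > 1 (an ideal concavity flip gives
  exactly 4; the threshold 1 keeps discretized flips).

The boundary is the marching-squares subpixel outline, smoothed with a
circular 9-point moving average, with 5-point tangent arcs.  A raster
Moore trace with single-step tangents was rejected after measurement:
±45° step quantization alone produces ‖ΔN‖² ≈ 4 on a clean digital
disk, i.e. false inflections on convex shapes.

Feature rows are pooled over the whole volume — so a slice containing a
single tissue type is still classified correctly — z-scored per
feature, and clustered by 3-means (Lloyd, uniform random initialization
from the data rows, best of 20 restarts by cost, fixed seed).  Roles
follow the qualitative profiles: the cluster maximizing standardized
variance + inflection count is fibroglandular (exactly one); of the two
vessel clusters the one with higher circularity is the circular-section
cluster, the other the tubular one.

**3D continuity.** A voxel classified vasculature keeps the label only
if at least 3 of the 9 positions of its 26-neighborhood in the previous
slice, or at least 3 of the 9 in the next slice, are vasculature (as
labeled by the k-means); otherwise it joins the fibroglandular class.
End slices use their single available side.  The filter never promotes,
so it can only remove vessel false positives — it is what resolves
vessel-shaped gland islets confined to one slice.

## Evaluation metrics

Dice 2|A∩B|/(|A|+|B|); sensitivity TP/(TP+FN); conformity
Kc = 1 − (FP+FN)/TP on (−∞, 1], with a −inf sentinel (never a silent
large negative float) when the masks do not overlap; Hausdorff distance
and the average distance (directed mean-of-minima, larger direction),
both via the exact Euclidean distance transform, in pixels (mm via the
voxel spacing on request).  The noise-robustness harness re-classifies
noise-corrupted copies of a volume and reports each overlap metric as a
percentage of the clean run of the same volume (100% at σ = 0); the two
distances are reported in absolute pixels, since their clean baseline
is identically zero and a ratio is undefined.

## Synthetic phantom

The phantom emulates a coronal breast-CT slice stack with exact labels:
an elliptical skin ring (semi-axes 92×100 px at the default 256² size;
thickness 7 px ≈ 1.9 mm) whose profile is a raised cosine from 0.60 at
the boundaries to 0.85 at mid-thickness, so the centerline ridge
exists; a 1.2-px partial-volume ramp (0.28 → 0.60) at the air–skin
interface, ground-truth skin on its inner half — real boundary pixels
mix air and skin, and without this layer the mean-edge-intensity
threshold rule would structurally reject half of the outermost skin
layer under noise; adipose fill at 0.30; 3 gland blobs (unions of 5–8
eccentric random ellipses, re-jittered per slice, intensity 0.70 with a
±0.05 sinusoidal texture: fibroglandular tissue is heterogeneous, which
is exactly the variance contrast the feature table relies on); 3
vessels at 0.70 (radius 2.5–4.5 px, one with an elongated cross
section) following smooth paths that drift ≲ 0.7 px per slice, keeping
≥ 3 px clear of the inner skin edge; and one decoy — a vessel-like
fibroglandular disk present in exactly one slice, which only the
continuity filter can resolve.  Default additive Gaussian noise is
σ = 0.02 on the normalized scale (intrinsic CT noise at a mid-range
level); the robustness harness adds 0.01–0.04 on top.  An optional
multiplicative cupping field falls quadratically from 1 at the
periphery to 1 − amplitude at the breast centroid.  All randomness
derives from the spec seed; `make_slice(spec, i)` is bit-identical to
slice i of `make_volume(spec)`.

What the phantom does not emulate: reconstruction physics (beam
hardening, scatter, ring artifacts), anatomical texture continuity of
the gland across slices, contrast enhancement, the pectoralis muscle,
and intensity calibration in HU.  Passing the phantom suite therefore
demonstrates the mechanics of each stage under controlled contrast,
noise and shading — not clinical-grade accuracy on patient data.

## Known limitations

* The strict ridge tolerance is calibrated to discrete-intensity data;
  the best-candidate fallback covers continuous-valued images.
* The active-contour update is a monotone region growth; it cannot
  shrink past an over-inclusion (none was observed with the stated
  acceptance rule, but pathological textures could provoke one).
* Vessels darker than, or embedded in, fibroglandular tissue are not
  separable — the features are shape-based and the contour merges
  touching structures into one component.
* The continuity filter assumes ≥ 3 slices and roughly ≤ 1 px/slice
  vessel drift at this resolution; faster-moving vessels lose their
  through-slice support.
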