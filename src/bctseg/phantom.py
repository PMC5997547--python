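"""Synthetic breast-CT phantom generator with exact ground-truth labels.

Every downstream stage of the classifier is exercised against digital
phantoms that emulate a coronal dedicated breast-CT slice:

* a closed elliptical skin ring whose radial intensity profile is a
  raised cosine peaking at mid-thickness (so a height ridge exists at
  the skin centerline), with a darker outermost partial-volume layer
  emulating the air-skin interface;
* a dark adipose interior;
* irregular fibroglandular blobs built as unions of random ellipses
  (jagged boundaries, hence many boundary inflection points) with a
  gentle internal intensity ripple (fibroglandular tissue is
  heterogeneous, adipose and vessels are not);
* circular and elongated vessel cross-sections that persist across
  slices along smooth, slowly drifting 3D paths;
* one "decoy" blob: a small vessel-like disk present in exactly one
  slice, ground-truth fibroglandular, which the through-slice
  continuity filter must reassign;
* optional additive Gaussian noise (sigma on the normalized scale) and
  a radial multiplicative cupping field emulating incomplete scatter
  correction.

All randomness is derived from ``PhantomSpec.seed``; the same spec
always produces bit-identical output, and ``make_slice(spec, i)``
equals slice ``i`` of ``make_volume(spec)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .io_model import (
    ADIPOSE,
    BACKGROUND,
    FIBROGLANDULAR,
    SKIN,
    VASCULATURE,
    ImageSlice,
    LabelMap,
    Volume,
)

DEFAULT_INTENSITY_MEANS = {
    "background": 0.0,
    "adipose": 0.30,
    "fibroglandular": 0.70,
    "skin": 0.85,  # ridge peak at mid-thickness
    "vasculature": 0.70,
}


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic breast volume.

    Intensity ordering must satisfy adipose < {skin, gland, vessel}:
    the classifier assumes dense structures are bright relative to fat.
    """

    shape: tuple[int, int] = (256, 256)
    n_slices: int = 10
    breast_radius: float = 100.0  # semi-major axis, px
    skin_thickness: float = 7.0  # px (~1.9 mm at 273 um voxels), >= 2
    n_gland_blobs: int = 3
    n_vessels: int = 3
    vessel_radius_range: tuple[float, float] = (2.5, 4.5)
    intensity_means: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS))
    skin_base_intensity: float = 0.60  # ring profile at inner/outer boundary
    skin_edge_intensity: float = 0.28  # air side of the partial-volume surface ramp
    gland_texture_amplitude: float = 0.05
    noise_sigma: float = 0.02
    cupping_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.skin_thickness < 2:
            raise SpecError("skin_thickness must be >= 2 px")
        if self.breast_radius > min(self.shape) / 2 - 4:
            raise SpecError(
                f"breast_radius {self.breast_radius} does not fit in shape {self.shape}"
            )
        m = self.intensity_means
        dense = min(m["skin"], m["fibroglandular"], m["vasculature"])
        if not m["adipose"] < dense:
            raise SpecError("intensity ordering must be adipose < skin/gland/vessel")
        if not 0 <= self.noise_sigma:
            raise SpecError("noise_sigma must be >= 0")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(row, col) semi-axes of the outer skin ellipse."""
        return (0.92 * self.breast_radius, self.breast_radius)

    @property
    def center(self) -> tuple[int, int]:
        return (self.shape[0] // 2, self.shape[1] // 2)


# ----------------------------------------------------------------------
# Deterministic geometry plan


def _rng(spec: PhantomSpec, *stream) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *stream])


def _ellipse_mask(shape, center, axes, angle=0.0):
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    di, dj = ii - center[0], jj - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = di * c + dj * s
    v = -di * s + dj * c
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _plan_vessels(spec: PhantomSpec):
    """Per-vessel base position, radius, elongation and smooth 3D path."""
    rng = _rng(spec, 1)
    ar, ac = spec.semi_axes
    ci, cj = spec.center
    t = spec.skin_thickness
    vessels = []
    for v in range(spec.n_vessels):
        theta = np.deg2rad(5 + (v + 0.5) * 110 / max(spec.n_vessels, 1) + rng.uniform(-4, 4))
        rho = rng.uniform(0.30, 0.55)
        r = rng.uniform(*spec.vessel_radius_range)
        base = np.array(
            [ci - rho * (ar - t - 12) * np.cos(theta), cj + rho * (ac - t - 12) * np.sin(theta)]
        )
        if v == 0 and spec.n_vessels >= 2:
            axes = (0.75 * r, 3.2 * r)  # in-plane elongated (tubular) section
        else:
            axes = (r, r)
        orient = rng.uniform(0, np.pi)
        step = rng.uniform(-0.35, 0.35, size=2)
        wobble_dir = rng.normal(size=2)
        wobble_dir /= np.linalg.norm(wobble_dir)
        phase = rng.uniform(0, 2 * np.pi)
        vessels.append(
            dict(base=base, axes=axes, orient=orient, step=step, wobble=wobble_dir, phase=phase)
        )
    return vessels


def _vessel_center(vinfo, s, n_slices):
    drift = vinfo["base"] + s * vinfo["step"]
    wob = 1.2 * np.sin(2 * np.pi * s / max(1.7 * n_slices, 1) + vinfo["phase"])
    return drift + wob * vinfo["wobble"]


def _plan_blob_slots(spec: PhantomSpec):
    rng = _rng(spec, 2)
    slots = []
    for b in range(spec.n_gland_blobs):
        theta = np.deg2rad(
            135 + (b + 0.5) * 220 / max(spec.n_gland_blobs, 1) + rng.uniform(-8, 8)
        )
        rho = rng.uniform(0.20, 0.42)
        slots.append((theta, rho))
    return slots


def _decoy_geometry(spec: PhantomSpec):
    ar, ac = spec.semi_axes
    ci, cj = spec.center
    t = spec.skin_thickness
    theta = np.deg2rad(270.0)
    rho = 0.62
    center = (ci - rho * (ar - t - 12) * np.cos(theta), cj + rho * (ac - t - 12) * np.sin(theta))
    return dict(center=center, radius=3.2, slice_index=spec.n_slices // 2)


# ----------------------------------------------------------------------
# Slice rendering


def make_slice(spec: PhantomSpec, slice_index: int) -> tuple[ImageSlice, LabelMap]:
    """Render one coronal slice and its exact ground-truth label map."""
    if not 0 <= slice_index < spec.n_slices:
        raise SpecError(f"slice_index {slice_index} outside 0..{spec.n_slices - 1}")
    rows, cols = spec.shape
    ci, cj = spec.center
    ar, ac = spec.semi_axes
    t = spec.skin_thickness
    m = spec.intensity_means

    breast = _ellipse_mask(spec.shape, (ci, cj), (ar, ac))
    d_edge = ndimage.distance_transform_edt(breast)
    # partial-volume air-skin layer, thick enough that the whole detected
    # outer boundary falls inside it at every angle
    shell_w = 1.2
    shell = breast & (d_edge <= shell_w)
    skin_body = breast & (d_edge > shell_w) & (d_edge <= t)
    interior = breast & (d_edge > t)
    core = d_edge > t + 3.0  # structures keep a margin from the inner skin edge

    # Vessels ----------------------------------------------------------
    vessel = np.zeros(spec.shape, dtype=bool)
    for vinfo in _plan_vessels(spec):
        c = _vessel_center(vinfo, slice_index, spec.n_slices)
        vessel |= _ellipse_mask(spec.shape, c, vinfo["axes"], vinfo["orient"])
    vessel &= core

    # Decoy: vessel-like disk in exactly one slice, true fibroglandular
    decoy = np.zeros(spec.shape, dtype=bool)
    dg = _decoy_geometry(spec)
    if slice_index == dg["slice_index"]:
        decoy = _ellipse_mask(spec.shape, dg["center"], (dg["radius"], dg["radius"]))
        decoy &= core & ~ndimage.binary_dilation(vessel, iterations=3)

    # Gland blobs: unions of random ellipses, re-jittered per slice ----
    gland = np.zeros(spec.shape, dtype=bool)
    for b, (theta, rho) in enumerate(_plan_blob_slots(spec)):
        rng = _rng(spec, 3, b, slice_index)
        base = np.array(
            [ci - rho * (ar - t - 12) * np.cos(theta), cj + rho * (ac - t - 12) * np.sin(theta)]
        )
        # eccentric, scattered ellipses keep every blob visibly lobulated
        # (fibroglandular tissue is irregular; a near-convex blob would
        # not carry the inflection signature the classifier relies on)
        for _ in range(rng.integers(5, 9)):
            off = rng.uniform(-12, 12, size=2)
            axes = (rng.uniform(7, 16), rng.uniform(3, 7))
            ang = rng.uniform(0, np.pi)
            gland |= _ellipse_mask(spec.shape, base + off, axes, ang)
    gland &= core
    # keep a 2 px adipose moat so components stay separable
    gland &= ~ndimage.binary_dilation(vessel | decoy, iterations=2)

    # Intensities ------------------------------------------------------
    img = np.zeros(spec.shape, dtype=np.float64)
    img[interior] = m["adipose"]
    ii, jj = np.mgrid[0:rows, 0:cols]
    texture = spec.gland_texture_amplitude * np.sin(2 * np.pi * ii / 12.0) * np.sin(
        2 * np.pi * jj / 12.0
    )
    img[gland] = m["fibroglandular"] + texture[gland]
    img[decoy] = m["fibroglandular"]
    img[vessel] = m["vasculature"]
    # skin: raised cosine across the ring, peak mid-thickness
    u = (d_edge[skin_body] - shell_w) / max(t - shell_w, 1.0)
    lo, pk = spec.skin_base_intensity, m["skin"]
    img[skin_body] = lo + (pk - lo) * 0.5 * (1.0 - np.cos(2 * np.pi * u))
    # partial volume: intensity ramps from the air-skin surface value up
    # to the skin base across the shell
    img[shell] = spec.skin_edge_intensity + (lo - spec.skin_edge_intensity) * (
        d_edge[shell] / shell_w
    )

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[interior] = ADIPOSE
    labels[gland] = FIBROGLANDULAR
    labels[decoy] = FIBROGLANDULAR
    labels[vessel] = VASCULATURE
    # the partial-volume ramp is ground-truth skin where skin is the
    # majority constituent (inner half); the air-dominant outer half is
    # background
    labels[skin_body | (shell & (d_edge >= shell_w / 2.0))] = SKIN

    if spec.cupping_amplitude:
        img = _cupping_field(spec) * img
    if spec.noise_sigma:
        rng = _rng(spec, 4, slice_index)
        img = np.clip(img + rng.normal(0.0, spec.noise_sigma, size=img.shape), 0.0, 1.0)

    return ImageSlice(img), LabelMap(labels)


def _cupping_field(spec: PhantomSpec) -> np.ndarray:
    a = spec.cupping_amplitude
    ci, cj = spec.center
    ar, ac = spec.semi_axes
    ii, jj = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    rho = np.sqrt(((ii - ci) / ar) ** 2 + ((jj - cj) / ac) ** 2)
    rho = np.clip(rho, 0.0, 1.0)
    return (1.0 - a) + a * rho**2


def make_volume(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Render the whole stack; see :func:`make_slice` for the content."""
    if spec.n_slices < 3:
        raise SpecError("n_slices must be >= 3 for through-slice continuity")
    imgs, labs = [], []
    for s in range(spec.n_slices):
        sl, lm = make_slice(spec, s)
        imgs.append(sl.data)
        labs.append(lm.data)
    vol = Volume(np.stack(imgs), normalized=True)
    return vol, LabelMap(np.stack(labs))


# ----------------------------------------------------------------------
# Corruption operators


def add_noise(volume: Volume, sigma: float, seed: int | None = None) -> Volume:
    """Add i.i.d. zero-mean Gaussian noise, clipped back to [0, 1]."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if not volume.normalized:
        raise ValueError("add_noise expects a normalized volume")
    if sigma == 0:
        return volume
    rng = np.random.default_rng(seed)
    noisy = np.clip(volume.data + rng.normal(0.0, sigma, size=volume.data.shape), 0.0, 1.0)
    return replace(volume, data=noisy)


def add_cupping(volume: Volume, amplitude: float) -> Volume:
    """Multiply by a smooth radial shading field centered on the breast.

    The field falls from 1 at the periphery to ``1 - amplitude`` at the
    centroid of the foreground (data > 0.05), emulating the cupping left
    by incomplete scatter correction.
    """
    if not 0 <= amplitude <= 0.5:
        raise ValueError(f"amplitude must be in [0, 0.5], got {amplitude}")
    if not volume.normalized:
        raise ValueError("add_cupping expects a normalized volume")
    if amplitude == 0:
        return volume
    data = volume.data
    fg = data > 0.05
    if not fg.any():
        return volume
    idx = np.argwhere(fg)
    centroid = idx.mean(axis=0)
    # in-plane radial field, shared by all slices
    ii, jj = np.mgrid[0 : data.shape[1], 0 : data.shape[2]]
    rr = np.sqrt((ii - centroid[1]) ** 2 + (jj - centroid[2]) ** 2)
    inplane = np.sqrt((idx[:, 1] - centroid[1]) ** 2 + (idx[:, 2] - centroid[2]) ** 2)
    rmax = max(float(inplane.max()), 1.0)
    rho = np.clip(rr / rmax, 0.0, 1.0)
    fld = (1.0 - amplitude) + amplitude * rho**2
    return replace(volume, data=np.clip(data * fld[np.newaxis], 0.0, 1.0))


# ----------------------------------------------------------------------
# Simple analytic ring (centerline test bed)


def make_ring(
    shape: tuple[int, int] = (200, 200),
    radius: float = 70.0,
    thickness: float = 6.0,
    lo: float = 0.45,
    peak: float = 0.85,
    fill: float = 0.30,
    shell: float = 0.28,
    center: tuple[int, int] | None = None,
) -> tuple[ImageSlice, LabelMap]:
    """Circular skin ring with an exactly radial raised-cosine profile.

    Peak intensity sits on the circle ``r == radius``; the profile falls
    to ``lo`` at ``|r - radius| == thickness / 2``, and a thin
    partial-volume layer at ``shell`` intensity wraps the outside (the
    air-skin interface).  The interior is filled at ``fill`` (adipose),
    the exterior is background.  Because the profile depends only on the
    Euclidean radius, pixels on the image axes through the center are
    exact height-ridge points of the discrete image.
    """
    if center is None:
        center = (shape[0] // 2, shape[1] // 2)
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = np.sqrt((ii - center[0]) ** 2 + (jj - center[1]) ** 2)
    half = thickness / 2.0
    ring = np.abs(r - radius) <= half
    shell_ring = (r > radius + half) & (r <= radius + half + 1.2)
    inside = r < radius - half
    img = np.zeros(shape, dtype=np.float64)
    img[inside] = fill
    img[ring] = lo + (peak - lo) * 0.5 * (1.0 + np.cos(np.pi * (r[ring] - radius) / half))
    depth = (radius + half + 1.2 - r[shell_ring]) / 1.2  # 0 at air, 1 at ring
    img[shell_ring] = shell + (lo - shell) * depth
    labels = np.zeros(shape, dtype=np.uint8)
    labels[inside] = ADIPOSE
    # ramp pixels are skin where skin dominates the mixture (inner half)
    labels[ring | (shell_ring & (r <= radius + half + 0.6))] = SKIN
    return ImageSlice(img), LabelMap(labels)
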