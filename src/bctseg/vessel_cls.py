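"""Vessel vs fibroglandular discrimination of dense-tissue components.

After skin and adipose removal, the remaining connected components in
each slice are either vessel cross-sections or fibroglandular islands.
Four features are extracted per 8-connected component:

* intensity variance,
* circularity C = 4 pi Area / Perimeter^2 (Crofton perimeter),
* aspect ratio AR = min(d)/max(d) over the distances d from the center
  of mass to every boundary point,
* number of boundary inflection points: along the traced boundary the
  unit normal N_k is the in-plane unit vector along T2 - T1 (the change
  of consecutive unit tangents, i.e. V x (T2 - T1) x V with V the
  out-of-plane axis); a boundary point is an inflection when
  ||N_{k+1} - N_k||^2 > 1.  At an ideal concavity flip the normal
  reverses, the difference has length 2 and the squared norm is 4; the
  threshold 1 keeps discretized flips.

Vessels look circular (high C, high AR, few inflections, low variance)
or tubular (low C, low AR) while fibroglandular tissue is irregular
(many inflections, high variance), so a 3-cluster k-means on the
feature rows pooled over the *whole volume* separates the two vessel
appearances from the gland class — pooling keeps slices that contain a
single tissue type classifiable.  Finally a through-slice continuity
criterion demotes vessel voxels without support in the adjacent slices:
a voxel stays vasculature only if at least three of the nine
26-neighborhood positions in the previous slice, or at least three of
the nine in the next slice, are vessel voxels.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.cluster import KMeans

from .io_model import Volume

logger = logging.getLogger(__name__)

_S8 = np.ones((3, 3), dtype=int)

ROLE_FIBRO = "fibroglandular"
ROLE_CIRCULAR = "vessel_circular"
ROLE_TUBULAR = "vessel_tubular"


@dataclass
class ComponentFeatures:
    """Feature row of one connected dense component in one slice."""

    slice_index: int
    component_id: int
    variance: float
    circularity: float
    aspect_ratio: float
    n_inflections: int

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.variance, self.circularity, self.aspect_ratio, self.n_inflections],
            dtype=np.float64,
        )


@dataclass
class ClusterModel:
    """Best-of-20-restarts 3-means over standardized feature rows."""

    centroids: np.ndarray  # (3, 4), standardized feature space
    assignment: np.ndarray  # cluster index per feature row
    cost: float
    role_map: dict  # cluster -> role string
    scaler_mean: np.ndarray
    scaler_std: np.ndarray

    def roles(self) -> list[str]:
        return [self.role_map[c] for c in self.assignment]


# ----------------------------------------------------------------------
# Boundary machinery


def component_boundary(mask: np.ndarray, smooth_window: int = 9) -> np.ndarray:
    """Ordered, closed, lightly smoothed subpixel boundary of a mask.

    Marching squares on the padded mask gives an ordered closed outline
    (components touching the image border are closed along it, with a
    warning); a circular moving average of ``smooth_window`` points
    suppresses pixelation so tangents reflect the underlying shape
    rather than the raster grid.
    """
    if _touches_border(mask):
        logger.warning("component touches the image border; boundary closed along it")
    padded = np.pad(mask, 1).astype(np.float64)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    pts = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)
    if n >= smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ext = np.vstack([pts[-(smooth_window // 2):], pts, pts[: smooth_window // 2]])
        pts = np.column_stack(
            [np.convolve(ext[:, d], kernel, mode="valid") for d in range(2)]
        )
    return pts


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def circularity(mask: np.ndarray) -> float:
    """4 pi Area / Perimeter^2 with the 4-direction Crofton perimeter.

    The Crofton estimator approaches the geometric perimeter of digital
    shapes (a pixel-count perimeter would bias C upward by tens of
    percent for disks).
    """
    area = float(mask.sum())
    perim = float(measure.perimeter_crofton(mask, directions=4))
    return 4.0 * np.pi * area / max(perim, 1.0) ** 2


def aspect_ratio(mask: np.ndarray) -> float:
    """min/max distance from the center of mass to the boundary."""
    idx = np.argwhere(mask)
    centroid = idx.mean(axis=0)
    pts = component_boundary(mask)
    d = np.linalg.norm(pts - centroid, axis=1)
    return float(d.min() / d.max())


def boundary_normals(pts: np.ndarray, arc: int = 5) -> np.ndarray:
    """Unit normals N_k = (T2 - T1)/||T2 - T1|| along a closed boundary.

    Tangents T1, T2 are the unit chords over an ``arc``-point window on
    either side of each boundary point.  Rows where the tangents are
    (numerically) equal are NaN: the normal is undefined on straight
    runs.
    """
    t1 = pts - np.roll(pts, arc, axis=0)
    t2 = np.roll(pts, -arc, axis=0) - pts
    t1 /= np.maximum(np.linalg.norm(t1, axis=1, keepdims=True), 1e-12)
    t2 /= np.maximum(np.linalg.norm(t2, axis=1, keepdims=True), 1e-12)
    dt = t2 - t1
    norm = np.linalg.norm(dt, axis=1, keepdims=True)
    out = np.full_like(pts, np.nan)
    ok = norm[:, 0] > 1e-9
    out[ok] = dt[ok] / norm[ok]
    return out


def inflection_count(mask: np.ndarray) -> int:
    """Count boundary points where the unit normal flips concavity.

    The squared norm of the difference of consecutive defined normals
    exceeds 1 exactly where the boundary changes concavity (4 at an
    ideal 180-degree flip); convex shapes score 0.
    """
    pts = component_boundary(mask)
    if len(pts) < 8:
        return 0
    normals = boundary_normals(pts)
    defined = normals[~np.isnan(normals[:, 0])]
    if len(defined) < 2:
        return 0
    dn = np.roll(defined, -1, axis=0) - defined
    return int(np.count_nonzero(np.sum(dn**2, axis=1) > 1.0))


# ----------------------------------------------------------------------
# Feature extraction


def label_dense_components(dense_masks: np.ndarray) -> np.ndarray:
    """8-connected component labels per slice (stacked int array)."""
    dense_masks = np.asarray(dense_masks)
    out = np.zeros(dense_masks.shape, dtype=np.int32)
    for z in range(dense_masks.shape[0]):
        out[z], _ = ndimage.label(dense_masks[z], structure=_S8)
    return out


def extract_features(
    dense_masks: np.ndarray, volume: Volume, labeled: np.ndarray | None = None
) -> list[ComponentFeatures]:
    """One feature row per dense component per slice, pooled volume-wide."""
    dense_masks = np.asarray(dense_masks)
    if labeled is None:
        labeled = label_dense_components(dense_masks)
    rows: list[ComponentFeatures] = []
    for z in range(dense_masks.shape[0]):
        lab = labeled[z]
        n = int(lab.max())
        img = volume.data[z]
        for cid in range(1, n + 1):
            comp = lab == cid
            rows.append(
                ComponentFeatures(
                    slice_index=z,
                    component_id=cid,
                    variance=float(np.var(img[comp])),
                    circularity=circularity(comp),
                    aspect_ratio=aspect_ratio(comp),
                    n_inflections=inflection_count(comp),
                )
            )
    if not rows:
        logger.warning("no dense components anywhere in the volume")
    return rows


def write_feature_table(rows: list[ComponentFeatures], path, roles: list[str] | None = None):
    """Export the feature rows (and cluster roles, if given) as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["slice", "component", "variance", "circularity", "aspect_ratio", "n_inflections"]
        if roles is not None:
            header.append("role")
        w.writerow(header)
        for i, r in enumerate(rows):
            rec = [r.slice_index, r.component_id, r.variance, r.circularity, r.aspect_ratio, r.n_inflections]
            if roles is not None:
                rec.append(roles[i])
            w.writerow(rec)


# ----------------------------------------------------------------------
# Clustering


def kmeans_classify(
    features: list[ComponentFeatures], seed: int = 0, n_restarts: int = 20
) -> ClusterModel:
    """3-means over z-scored feature rows, best of ``n_restarts`` restarts.

    Cluster roles follow the qualitative feature profiles: the gland
    cluster maximizes standardized variance plus inflection count; of
    the remaining two vessel clusters, the one with higher circularity
    is the circular-section cluster, the other the tubular one.  With
    fewer than 3 rows everything is assigned fibroglandular (warning).
    """
    X = np.array([f.as_vector() for f in features], dtype=np.float64)
    if len(X) < 3:
        logger.warning("fewer than 3 components; all assigned fibroglandular")
        n = len(X)
        return ClusterModel(
            centroids=np.zeros((1, 4)),
            assignment=np.zeros(n, dtype=int),
            cost=0.0,
            role_map={0: ROLE_FIBRO},
            scaler_mean=np.zeros(4),
            scaler_std=np.ones(4),
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    km = KMeans(
        n_clusters=3,
        n_init=n_restarts,
        init="random",
        algorithm="lloyd",
        random_state=seed & 0x7FFFFFFF,
    ).fit(Z)
    centroids = km.cluster_centers_
    # variance is column 0, circularity 1, inflections 3
    fibro = int(np.argmax(centroids[:, 0] + centroids[:, 3]))
    others = [c for c in range(3) if c != fibro]
    circ = max(others, key=lambda c: centroids[c, 1])
    tub = next(c for c in others if c != circ)
    role_map = {fibro: ROLE_FIBRO, circ: ROLE_CIRCULAR, tub: ROLE_TUBULAR}
    return ClusterModel(
        centroids=centroids,
        assignment=km.labels_.astype(int),
        cost=float(km.inertia_),
        role_map=role_map,
        scaler_mean=mean,
        scaler_std=std,
    )


def assign_roles(
    features: list[ComponentFeatures],
    model: ClusterModel,
    labeled: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Map cluster roles back to voxels: (vessel mask 3D, fibro mask 3D)."""
    vessel = np.zeros(labeled.shape, dtype=bool)
    fibro = np.zeros(labeled.shape, dtype=bool)
    roles = model.roles()
    for f, role in zip(features, roles):
        comp = labeled[f.slice_index] == f.component_id
        if role == ROLE_FIBRO:
            fibro[f.slice_index] |= comp
        else:
            vessel[f.slice_index] |= comp
    return vessel, fibro


# ----------------------------------------------------------------------
# 3D continuity


def continuity_filter(
    vessel: np.ndarray, fibro: np.ndarray, threshold: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Demote vessel voxels without through-slice support.

    A voxel stays vasculature iff at least ``threshold`` of the nine
    26-neighborhood positions in the previous slice OR at least
    ``threshold`` of the nine in the next slice are vessel voxels (as
    labeled by the k-means, i.e. counted on the input mask).  Demoted
    voxels join the fibroglandular mask; the filter never promotes.
    """
    vessel = np.asarray(vessel, dtype=bool)
    fibro = np.asarray(fibro, dtype=bool)
    if vessel.ndim != 3:
        raise ValueError("continuity_filter expects 3D masks")
    if vessel.shape[0] == 1:
        logger.warning("single-slice volume: all vessel voxels reassigned")
        return np.zeros_like(vessel), fibro | vessel
    counts = np.stack(
        [ndimage.convolve(vessel[z].astype(np.int8), _S8, mode="constant") for z in range(vessel.shape[0])]
    )
    prev = np.zeros_like(counts)
    nxt = np.zeros_like(counts)
    prev[1:] = counts[:-1]
    nxt[:-1] = counts[1:]
    keep = vessel & ((prev >= threshold) | (nxt >= threshold))
    demoted = vessel & ~keep
    return keep, fibro | demoted
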