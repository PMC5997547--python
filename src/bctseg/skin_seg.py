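"""Breast skin segmentation.

Three stages, all on a single normalized coronal slice:

1. **Outer edge** — Sobel gradient magnitude, binarized with Otsu's
   threshold; the largest closed contour (boundary of the filled,
   largest connected foreground region) is kept as the breast outline.
2. **Skin centerline** — a maximum-convexity height ridge.  Candidate
   points are walked uphill from the outer-edge seeds to 1D intensity
   maxima; a candidate is a ridge point when the smaller Hessian
   eigenvalue is negative and the image gradient is orthogonal to its
   eigenvector (|v1 . grad I| below a tolerance-to-zero, default 1e-6).
   Ridge points are then linked into a path by repeatedly stepping to
   the brightest 8-neighbor, with the rear positions of the previous
   step direction forbidden so the path cannot fold back; a forward and
   a backward pass join all ridge points.
3. **Region growing** — double-threshold growth seeded on the
   centerline: a pixel joins the skin if its intensity lies between the
   mean outer-edge intensity (low threshold) and the mean centerline
   intensity (high threshold) and its Euclidean distance to the
   centerline does not exceed d_max, the largest edge-to-centerline
   distance.  The distance constraint keeps equally bright structures
   adjacent to the skin (vessels, gland tissue) out of the skin class.

Gradients and Hessians use central finite differences at unit scale
(no smoothing); this scale is kept constant everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError
from .io_model import ImageSlice

logger = logging.getLogger(__name__)

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class HessianEigen:
    """Sorted eigenpairs (lambda1 <= lambda2) of the 2x2 image Hessian."""

    lambda1: float
    lambda2: float
    v1: np.ndarray
    v2: np.ndarray


@dataclass
class RidgeCriteria:
    """Tolerance-to-zero for the gradient-orthogonality ridge test."""

    tolerance_to_zero: float = 1e-6

    def __post_init__(self):
        if self.tolerance_to_zero <= 0:
            raise ValueError("tolerance_to_zero must be positive")


@dataclass
class Centerline:
    """Ordered 8-connected pixel path through the skin ridge."""

    path: list[tuple[int, int]]
    closed: bool = False
    d_max: float | None = None

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.path:
            idx = np.asarray(self.path)
            m[idx[:, 0], idx[:, 1]] = True
        return m


@dataclass
class SkinThresholds:
    """Double thresholds for skin region growing (t_low <= t_high)."""

    t_low: float
    t_high: float

    def __post_init__(self):
        if self.t_low > self.t_high:
            raise ValueError(f"t_low {self.t_low} > t_high {self.t_high}")


# ----------------------------------------------------------------------
# Outer edge


def breast_region(slice_: ImageSlice) -> np.ndarray:
    """Filled breast foreground: largest region enclosed by Sobel edges.

    The binarized Sobel magnitude spreads one pixel past the physical
    air-skin step on either side, so the filled contour is trimmed to
    the image foreground (Otsu on intensity); the region boundary then
    sits on the outermost tissue pixels rather than on background.
    """
    img = slice_.data
    gi = ndimage.sobel(img, axis=0)
    gj = ndimage.sobel(img, axis=1)
    mag = np.hypot(gi, gj)
    if mag.max() <= 0:
        raise SegmentationError("no gradient in slice (constant image)")
    try:
        thr = threshold_otsu(mag)
        edges = mag > thr
        filled = ndimage.binary_fill_holes(edges)
        filled &= img > threshold_otsu(img)
        filled = ndimage.binary_fill_holes(filled)
    except ValueError as exc:
        raise SegmentationError(f"cannot threshold gradient: {exc}") from exc
    lab, n = ndimage.label(filled, structure=np.ones((3, 3)))
    if n == 0:
        raise SegmentationError("no closed contour found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def detect_outer_edge(slice_: ImageSlice) -> np.ndarray:
    """One-pixel-wide closed outer boundary of the breast (bool mask)."""
    region = breast_region(slice_)
    eroded = ndimage.binary_erosion(region, structure=np.ones((3, 3)), border_value=0)
    edge = region & ~eroded
    if not edge.any():
        raise SegmentationError("degenerate breast region (no boundary)")
    return edge


# ----------------------------------------------------------------------
# Hessian / ridge machinery


def _check_interior(shape, point):
    i, j = point
    if not (1 <= i < shape[0] - 1 and 1 <= j < shape[1] - 1):
        raise ValueError(f"point {point} not interior to image of shape {shape}")


def hessian_eigen(slice_: ImageSlice, point: tuple[int, int]) -> HessianEigen:
    """Eigenpairs of the central finite-difference Hessian at one pixel.

    Eigenvalues are sorted ascending (lambda1 <= lambda2); for a bright
    ridge lambda1 < 0 and v1 points across the ridge.
    """
    img = slice_.data
    _check_interior(img.shape, point)
    i, j = point
    hii = img[i + 1, j] - 2.0 * img[i, j] + img[i - 1, j]
    hjj = img[i, j + 1] - 2.0 * img[i, j] + img[i, j - 1]
    hij = (
        img[i + 1, j + 1] - img[i + 1, j - 1] - img[i - 1, j + 1] + img[i - 1, j - 1]
    ) / 4.0
    H = np.array([[hii, hij], [hij, hjj]])
    w, v = np.linalg.eigh(H)  # ascending eigenvalues, orthonormal columns
    return HessianEigen(float(w[0]), float(w[1]), v[:, 0].copy(), v[:, 1].copy())


def gradient_at(slice_: ImageSlice, point: tuple[int, int]) -> np.ndarray:
    """Central-difference image gradient (d/di, d/dj) at one pixel."""
    img = slice_.data
    _check_interior(img.shape, point)
    i, j = point
    return np.array(
        [(img[i + 1, j] - img[i - 1, j]) / 2.0, (img[i, j + 1] - img[i, j - 1]) / 2.0]
    )


def find_1d_maximum(slice_: ImageSlice, seed: tuple[int, int]) -> tuple[int, int]:
    """Walk uphill toward the 8-neighborhood maximum until a 1D maximum.

    From the seed, repeatedly move to the brightest 8-neighbor while it
    is strictly brighter than the current pixel; the stopping point is a
    1D intensity maximum along the final search direction.  Raises
    ``ValueError`` if the walk leaves the image interior.
    """
    img = slice_.data
    _check_interior(img.shape, seed)
    cur = tuple(seed)
    for _ in range(img.size):
        i, j = cur
        best, best_val = None, img[i, j]
        for di, dj in _N8:
            ni, nj = i + di, j + dj
            if img[ni, nj] > best_val:
                best, best_val = (ni, nj), img[ni, nj]
        if best is None:
            return cur
        _check_interior(img.shape, best)
        cur = best
    return cur  # pragma: no cover - bounded by monotone ascent


def is_ridge_point(
    slice_: ImageSlice, point: tuple[int, int], criteria: RidgeCriteria | None = None
) -> bool:
    """Maximum-convexity height-ridge test at one pixel.

    True iff lambda1 < 0 and the gradient projection onto the
    across-ridge eigenvector is below the tolerance-to-zero.
    """
    criteria = criteria or RidgeCriteria()
    eig = hessian_eigen(slice_, point)
    if eig.lambda1 >= 0:
        return False
    g = gradient_at(slice_, point)
    return abs(float(eig.v1 @ g)) < criteria.tolerance_to_zero


def find_ridge_points(
    slice_: ImageSlice,
    seeds: np.ndarray | list | None = None,
    criteria: RidgeCriteria | None = None,
    fallback: int = 8,
) -> list[tuple[int, int]]:
    """Collect ridge points from outer-edge seeds.

    Each seed is walked to its 1D intensity maximum and kept when it
    passes the strict ridge test.  On real-valued images the exact
    orthogonality condition can reject every candidate; in that case the
    ``fallback`` candidates with negative lambda1 and the smallest
    gradient projection are kept, so the subsequent intensity-based
    linking always has somewhere to start.
    """
    criteria = criteria or RidgeCriteria()
    if seeds is None:
        seeds = np.argwhere(detect_outer_edge(slice_))
    seeds = [tuple(int(v) for v in s) for s in np.asarray(seeds)]
    candidates: dict[tuple[int, int], float] = {}
    for s in seeds:
        try:
            c = find_1d_maximum(slice_, s)
        except ValueError:
            continue
        if c in candidates:
            continue
        try:
            eig = hessian_eigen(slice_, c)
        except ValueError:
            continue
        if eig.lambda1 >= 0:
            continue
        g = gradient_at(slice_, c)
        candidates[c] = abs(float(eig.v1 @ g))
    strict = [p for p, proj in candidates.items() if proj < criteria.tolerance_to_zero]
    if strict:
        return sorted(strict)
    if not candidates:
        raise SegmentationError("no ridge candidates found from the given seeds")
    logger.warning(
        "no candidate met the tolerance-to-zero (%g); keeping the %d best",
        criteria.tolerance_to_zero,
        fallback,
    )
    ranked = sorted(candidates.items(), key=lambda kv: kv[1])
    return sorted(p for p, _ in ranked[:fallback])


# ----------------------------------------------------------------------
# Centerline tracing


def _forbidden(prev_dir: tuple[int, int] | None, step: tuple[int, int]) -> bool:
    """Rear positions w.r.t. the previous step direction are forbidden.

    Axis-aligned previous step: the three strictly-opposite neighbors.
    Diagonal previous step: the five rear neighbors (dot product <= 0).
    """
    if prev_dir is None:
        return False
    dot = prev_dir[0] * step[0] + prev_dir[1] * step[1]
    if dot < 0:
        return True
    diagonal = prev_dir[0] != 0 and prev_dir[1] != 0
    return diagonal and dot == 0


def _walk(
    img,
    start,
    visited,
    prev_dir,
    path_append,
    max_steps,
    close_to=None,
    min_excursion=16,
    ridge_remaining=None,
    closure_budget=None,
    floor=-np.inf,
    admissible=None,
):
    """One directional pass of the max-intensity linking walk.

    Stops when no admissible neighbor remains, when the walk returns to
    the 8-neighborhood of ``close_to`` after having traveled at least
    ``min_excursion`` px away from it (the path has closed on itself;
    the excursion requirement keeps noise loops from closing early), or
    when every ridge point has been linked and the closure budget is
    spent — the search exists to join the ridge points, and walking on
    past them only lets the path stray off the skin.  Pixels darker than
    ``floor`` (the mean outer-edge intensity, i.e. the lower bound of
    skin intensity) are never entered: the centerline lies within the
    skin, and without the bound a noisy walk can slip off the outer
    flank and wander through the background.
    """
    cur = start
    rows, cols = img.shape
    excursion = 0.0
    budget = None
    for step in range(max_steps):
        if ridge_remaining is not None and not ridge_remaining:
            if budget is None:
                budget = closure_budget if closure_budget is not None else 0
            elif budget <= 0:
                return cur, False
            budget -= 1
        i, j = cur
        best, best_val, best_turn = None, -np.inf, -np.inf
        for di, dj in _N8:
            ni, nj = i + di, j + dj
            if not (1 <= ni < rows - 1 and 1 <= nj < cols - 1):
                continue
            if _forbidden(prev_dir, (di, dj)):
                continue
            if (ni, nj) in visited:
                continue
            if admissible is not None and not admissible[ni, nj]:
                continue
            val = img[ni, nj]
            if val < floor:
                continue
            turn = 0.0
            if prev_dir is not None:
                n0 = np.hypot(di, dj) * np.hypot(*prev_dir)
                turn = (di * prev_dir[0] + dj * prev_dir[1]) / n0
            if val > best_val or (val == best_val and turn > best_turn):
                best, best_val, best_turn = (ni, nj), val, turn
        if best is None:
            return cur, False
        prev_dir = (best[0] - i, best[1] - j)
        visited.add(best)
        path_append(best)
        cur = best
        if ridge_remaining is not None:
            ridge_remaining.discard(cur)
        if close_to is not None:
            dist = max(abs(cur[0] - close_to[0]), abs(cur[1] - close_to[1]))
            excursion = max(excursion, dist)
            if excursion >= min_excursion and dist <= 1:
                return cur, True
    return cur, False


def trace_centerline(
    slice_: ImageSlice,
    ridge_points: list | np.ndarray,
    edge: np.ndarray | None = None,
) -> Centerline:
    """Link ridge points into a centerline by max-intensity stepping.

    Starting from the lexicographically first ridge point, the walk
    repeatedly moves to the brightest admissible 8-neighbor (rear
    positions of the previous step forbidden, visited pixels excluded);
    when the forward pass exhausts, a backward pass continues from the
    start in the opposite direction.  The path is closed when its two
    endpoints are 8-adjacent.  If ``edge`` is given, ``d_max`` is the
    largest Euclidean distance from an edge pixel to the centerline.
    """
    pts = [tuple(int(v) for v in p) for p in np.asarray(ridge_points).reshape(-1, 2)]
    if not pts:
        raise SegmentationError("ridge point set is empty")
    # the walk reads a 3x3 local mean: pixel noise would otherwise zigzag
    # the path off the crest and wedge it against its own visited pixels
    img = ndimage.uniform_filter(slice_.data, size=3, mode="nearest")
    # the centerline is a height ridge: the walk may only enter pixels
    # with negative smaller Hessian eigenvalue, which confines it to the
    # crest band and keeps it off the skin flanks and the interior
    hii = np.zeros_like(img)
    hjj = np.zeros_like(img)
    hij = np.zeros_like(img)
    hii[1:-1, :] = img[2:, :] - 2 * img[1:-1, :] + img[:-2, :]
    hjj[:, 1:-1] = img[:, 2:] - 2 * img[:, 1:-1] + img[:, :-2]
    hij[1:-1, 1:-1] = (
        img[2:, 2:] - img[2:, :-2] - img[:-2, 2:] + img[:-2, :-2]
    ) / 4.0
    lam1 = (hii + hjj) / 2.0 - np.sqrt(((hii - hjj) / 2.0) ** 2 + hij**2)
    admissible = lam1 < 0
    for p in pts:
        admissible[p] = True  # ridge points are admissible by definition
    start = min(pts)
    max_steps = 4 * (img.shape[0] + img.shape[1])
    # a genuine closed contour must at least span the ridge point set
    span = max(max(abs(p[0] - start[0]), abs(p[1] - start[1])) for p in pts)
    min_exc = max(16, span)

    forward: list[tuple[int, int]] = [start]
    visited = {start}
    remaining = set(pts) - {start}
    budget = 3 * min_exc
    floor = float(img[edge].mean()) if edge is not None else -np.inf
    _, closed_fwd = _walk(
        img,
        start,
        visited,
        None,
        forward.append,
        max_steps,
        close_to=start,
        min_excursion=min_exc,
        ridge_remaining=remaining,
        closure_budget=budget,
        floor=floor,
        admissible=admissible,
    )

    backward: list[tuple[int, int]] = []
    closed_bwd = False
    if not closed_fwd:
        prev_dir = None
        if len(forward) > 1:
            d0 = (forward[1][0] - start[0], forward[1][1] - start[1])
            prev_dir = (-d0[0], -d0[1])  # continue away from the forward path
        _, closed_bwd = _walk(
            img,
            start,
            visited,
            prev_dir,
            backward.append,
            max_steps,
            close_to=forward[-1],
            min_excursion=min_exc,
            ridge_remaining=remaining,
            closure_budget=budget,
            floor=floor,
            admissible=admissible,
        )

    path = list(reversed(backward)) + forward
    a, b = path[0], path[-1]
    closed = closed_fwd or closed_bwd or (
        len(path) > 3 and max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1
    )

    unlinked = [p for p in pts if p not in visited]
    if unlinked:
        logger.warning("centerline left %d ridge points unlinked", len(unlinked))
        if not closed:
            closed = False

    d_max = None
    if edge is not None:
        cl = Centerline(path).mask(img.shape)
        dist = ndimage.distance_transform_edt(~cl)
        d_max = float(dist[edge].max())
    return Centerline(path=path, closed=closed, d_max=d_max)


# ----------------------------------------------------------------------
# Region growing


def skin_thresholds(slice_: ImageSlice, centerline: Centerline, edge: np.ndarray) -> SkinThresholds:
    """Low = mean outer-edge intensity, high = mean centerline intensity."""
    img = slice_.data
    cl = centerline.mask(img.shape)
    return SkinThresholds(float(img[edge].mean()), float(img[cl].mean()))


def grow_skin(
    slice_: ImageSlice, centerline: Centerline, edge: np.ndarray
) -> np.ndarray:
    """Double-threshold, distance-constrained region growing from the centerline.

    A pixel is skin iff its intensity is within [t_low, t_high] and its
    Euclidean distance to the nearest centerline pixel is <= d_max, and
    it is 8-connected to the centerline through such pixels.  Growth
    stops when no candidate remains.
    """
    if not centerline.path:
        raise SegmentationError("empty centerline")
    img = slice_.data
    cl = centerline.mask(img.shape)
    thr = skin_thresholds(slice_, centerline, edge)
    dist = ndimage.distance_transform_edt(~cl)
    d_max = centerline.d_max
    if d_max is None:
        d_max = float(dist[edge].max())
    # epsilon guards the thresholds against float summation error when a
    # threshold equals the (constant) intensity of the pixels defining it
    eps = 1e-9
    accept = (img >= thr.t_low - eps) & (img <= thr.t_high + eps) & (dist <= d_max)
    # centerline pixels are seeds; those above t_high are the ridge crest
    # and belong to the skin, but a path pixel darker than t_low is a
    # tracing excursion outside the skin and must not seed growth
    seeds = cl & (img >= thr.t_low - eps)
    if not seeds.any():
        raise SegmentationError("no admissible seed on the centerline")
    lab, n = ndimage.label(accept | seeds, structure=np.ones((3, 3)))
    keep = np.unique(lab[seeds])
    keep = keep[keep > 0]
    mask = np.isin(lab, keep)
    if not mask.any():
        raise SegmentationError("skin region growing produced an empty mask")
    return mask


def segment_skin(
    slice_: ImageSlice, criteria: RidgeCriteria | None = None
) -> tuple[np.ndarray, np.ndarray, Centerline]:
    """Full skin stage: returns (skin mask, filled breast region, centerline)."""
    region = breast_region(slice_)
    eroded = ndimage.binary_erosion(region, structure=np.ones((3, 3)), border_value=0)
    edge = region & ~eroded
    ridge = find_ridge_points(slice_, seeds=np.argwhere(edge), criteria=criteria)
    centerline = trace_centerline(slice_, ridge, edge=edge)
    skin = grow_skin(slice_, centerline, edge)
    return skin, region, centerline
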