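"""Adipose vs dense-tissue separation with an energy-minimizing contour.

The skin-free breast interior is split into adipose tissue and "dense"
structures (fibroglandular tissue plus vessels) by a region+edge active
contour:

* **Initialization** is histogram driven.  The interior histogram is
  bimodal (fat vs dense); it is smoothed with a window-9 moving
  average, the two dominant modes are found by morphological
  reconstruction (h-maxima), and the valley minimum between them gives
  a rough binarization.  The contour starts inside the largest
  above-valley component.
* **The a-priori adipose variance k** is estimated by a 30-iteration
  region growing from the darkest interior pixel, accepting pixels
  between 10% and 90% of the valley intensity; k is the intensity
  variance of the grown region.
* **The energy** combines a region term ((exterior variance - k)^2),
  the absolute time-derivatives of the interior variance and of the
  interior/exterior means (each weighted by the corresponding mean
  squared intensity), and an edge term: the reciprocal of the total
  gradient magnitude accumulated along the contour, which decreases as
  the contour locks onto object boundaries.  Every term is zero (or
  minimal) at convergence, and none carries a user-selectable weight.
* **Evolution** advances the boundary into 8-adjacent pixels whose
  intensity matches the interior statistics, smooths/expands the region
  with a 3x3 Gaussian kernel (sigma 0.5), and — when growth stalls with
  the energy still above the 1e-3 null threshold — dilates and jumps to
  nearby connected structures whose mean intensity lies within
  [mean_in +- std_in], overcoming local minima when dense tissue is
  fragmented within the slice.

The final interior mask holds fibroglandular tissue plus vessels;
adipose is obtained by subtracting it (and the skin) from the breast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima

from .errors import ConsistencyError, DegenerateInputError, NonConvergenceError
from .io_model import ImageSlice

logger = logging.getLogger(__name__)

#: regularizer for the inverse-gradient edge term
GRAD_EPS = 1e-6


@dataclass
class HistogramModel:
    """Smoothed interior histogram with its two modes and valley."""

    bins: np.ndarray  # bin centers
    counts: np.ndarray  # smoothed counts
    mode_lo: float
    mode_hi: float
    valley: float

    def __post_init__(self):
        if not self.mode_lo < self.valley < self.mode_hi:
            raise DegenerateInputError(
                f"valley {self.valley} not between modes ({self.mode_lo}, {self.mode_hi})"
            )


@dataclass
class ContourState:
    """Evolving region with the statistics entering the energy."""

    region: np.ndarray
    t: int
    mean_in: float
    mean_out: float
    var_in: float
    var_out: float
    k: float
    prev_mean_in: float
    prev_mean_out: float
    prev_var_in: float
    energy: float = np.nan
    terms: dict = field(default_factory=dict)


@dataclass
class ContourResult:
    mask: np.ndarray
    converged: bool
    n_iter: int
    energy: float
    trace: list  # per-iteration term dicts


# ----------------------------------------------------------------------
# Histogram / initialization


def histogram_valley(
    pixels: np.ndarray, n_bins: int = 256, window: int = 9, h_fraction: float = 0.01
) -> HistogramModel:
    """Find the valley between the two dominant modes of the intensity histogram.

    The histogram (``n_bins`` over [0, 1]) is smoothed with a moving
    average of size ``window``; modes are the regional maxima surviving
    h-maxima reconstruction with ``h = h_fraction * max(counts)``; the
    valley is the minimum smoothed count strictly between the two
    highest modes.  Raises :class:`DegenerateInputError` when fewer than
    two modes survive (unimodal histogram).
    """
    pixels = np.asarray(pixels).ravel()
    if pixels.size < 1000:
        raise DegenerateInputError(f"need >= 1000 pixels, got {pixels.size}")
    counts, edges = np.histogram(pixels, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    kernel = np.ones(window) / window
    smooth = np.convolve(counts.astype(np.float64), kernel, mode="same")
    h = h_fraction * smooth.max()
    peaks_mask = h_maxima(smooth, h)
    lab, n = ndimage.label(peaks_mask)
    if n < 2:
        raise DegenerateInputError("histogram is unimodal; no adipose/dense valley")
    # one representative bin per plateau, ranked by smoothed height
    peak_bins = ndimage.center_of_mass(peaks_mask, lab, index=np.arange(1, n + 1))
    peak_bins = [int(round(c[0])) for c in peak_bins]
    peak_bins.sort(key=lambda b: -smooth[b])
    b1, b2 = sorted(peak_bins[:2])
    valley_bin = b1 + int(np.argmin(smooth[b1 : b2 + 1]))
    return HistogramModel(
        bins=centers,
        counts=smooth,
        mode_lo=float(centers[b1]),
        mode_hi=float(centers[b2]),
        valley=float(centers[valley_bin]),
    )


def initialize_contour(
    slice_: ImageSlice, model: HistogramModel, interior: np.ndarray
) -> tuple[int, int]:
    """Pick a pixel well inside the largest above-valley component.

    The valley binarization is only a rough partition; its largest
    bright component is almost always fibroglandular tissue (vessels are
    small), and the returned pixel maximizes the distance to that
    component's boundary so the initial contour starts fully inside.
    """
    bright = interior & (slice_.data > model.valley)
    lab, n = ndimage.label(bright, structure=np.ones((3, 3)))
    if n == 0:
        raise DegenerateInputError("no component above the histogram valley")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    comp = lab == (1 + int(np.argmax(sizes)))
    dist = ndimage.distance_transform_edt(comp)
    seed = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return (int(seed[0]), int(seed[1]))


def estimate_k(
    slice_: ImageSlice,
    model: HistogramModel,
    interior: np.ndarray,
    n_iterations: int = 30,
    valley_fractions: tuple[float, float] = (0.9, 0.1),
) -> float:
    """A-priori adipose variance from a 30-iteration region growing.

    Growth starts at the darkest interior pixel and accepts pixels whose
    intensity lies between 10% and 90% of the valley intensity.  If the
    grown region is degenerate (< 10 px), k falls back to the variance
    of all below-valley interior pixels.
    """
    img = slice_.data
    if not interior.any():
        raise DegenerateInputError("empty interior")
    lo = min(valley_fractions) * model.valley
    hi = max(valley_fractions) * model.valley
    masked = np.where(interior, img, np.inf)
    seed = np.unravel_index(int(np.argmin(masked)), img.shape)
    band = interior & (img >= lo) & (img <= hi)
    region = np.zeros_like(band)
    region[seed] = True
    struct = np.ones((3, 3), dtype=bool)
    for _ in range(n_iterations):
        frontier = ndimage.binary_dilation(region, structure=struct) & band & ~region
        if not frontier.any():
            break
        region |= frontier
    if region.sum() < 10:
        fallback = interior & (img < model.valley)
        if not fallback.any():
            raise DegenerateInputError("no below-valley pixels for the k fallback")
        logger.warning("k growth degenerate (%d px); using below-valley variance", region.sum())
        return float(np.var(img[fallback]))
    return float(np.var(img[region]))


# ----------------------------------------------------------------------
# Energy


def _contour_band(region: np.ndarray, domain: np.ndarray) -> np.ndarray:
    """Pixels straddling the region boundary (inner + outer layer)."""
    struct = np.ones((3, 3), dtype=bool)
    inner = region & ~ndimage.binary_erosion(region, structure=struct, border_value=0)
    outer = ndimage.binary_dilation(region, structure=struct) & ~region & domain
    return inner | outer


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude (unnormalized kernels, unit scale)."""
    return np.hypot(ndimage.sobel(img, axis=0), ndimage.sobel(img, axis=1))


def contour_energy(
    state: ContourState,
    slice_: ImageSlice,
    domain: np.ndarray,
    grad_mag: np.ndarray | None = None,
) -> float:
    """Global contour energy at iteration t.

    Terms (all dimension-reduced to means so no weights are needed):

    * ``region``   -- (var_out - k)^2: exterior variance matches the
      a-priori adipose variance once only adipose remains outside.
    * ``d_var_in`` -- |backward difference of var_in|.
    * ``d_mean_in`` / ``d_mean_out`` -- |backward difference of the
      mean| times the mean squared intensity of the respective domain.
    * ``edge``     -- 1 / (total gradient magnitude along the contour
      band + eps): decays toward zero as the contour locks onto, and
      accumulates, strong image edges.

    Backward differences are zero at t = 0.  The per-term breakdown is
    stored in ``state.terms``.
    """
    img = slice_.data
    region = state.region
    ext = domain & ~region
    if not region.any() or not ext.any():
        raise DegenerateInputError("contour region must be nonempty and not fill the domain")
    if grad_mag is None:
        grad_mag = gradient_magnitude(img)
    msq_in = float(np.mean(img[region] ** 2))
    msq_out = float(np.mean(img[ext] ** 2))
    band = _contour_band(region, domain)
    terms = {
        "region": (state.var_out - state.k) ** 2,
        "d_var_in": abs(state.var_in - state.prev_var_in),
        "d_mean_in": abs(state.mean_in - state.prev_mean_in) * msq_in,
        "d_mean_out": abs(state.mean_out - state.prev_mean_out) * msq_out,
        "edge": 1.0 / (float(grad_mag[band].sum()) + GRAD_EPS),
    }
    state.terms = terms
    state.energy = float(sum(terms.values()))
    return state.energy


def _stats(img, region, ext):
    return (
        float(img[region].mean()),
        float(img[ext].mean()) if ext.any() else 0.0,
        float(img[region].var()),
        float(img[ext].var()) if ext.any() else 0.0,
    )


def _gaussian_kernel_3x3(sigma: float = 0.5) -> np.ndarray:
    ax = np.arange(-1, 2)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return k / k.sum()


# ----------------------------------------------------------------------
# Evolution


def evolve_contour(
    slice_: ImageSlice,
    seed: tuple[int, int],
    k: float,
    domain: np.ndarray,
    energy_epsilon: float = 1e-3,
    gaussian_sigma: float = 0.5,
    iteration_cap: int = 2000,
    jump_radius_step: float = 5.0,
) -> ContourResult:
    """Grow the contour from ``seed`` until the energy is null.

    Each iteration: (1) boundary-adjacent pixels whose intensity lies
    within ``max(2 std_in, 3 sqrt(k))`` of the interior mean join the
    region; (2) the region is smoothed/expanded by a 3x3 Gaussian kernel
    (holes and stragglers fill in); (3) if nothing changed and the
    energy is still >= ``energy_epsilon``, the region is dilated in
    increasing steps of ``jump_radius_step`` px and propagated to the
    connected structures whose mean intensity lies in
    [mean_in - std_in, mean_in + std_in], jumping over adipose gaps.
    Evolution ends when the energy drops below ``energy_epsilon`` or no
    admissible pixel remains; hitting the cap raises
    :class:`NonConvergenceError` carrying the best state.
    """
    img = slice_.data
    if k < 0:
        raise ValueError("k must be >= 0")
    if not domain[seed]:
        raise DegenerateInputError(f"seed {seed} outside the evolution domain")
    struct = np.ones((3, 3), dtype=bool)
    gk = _gaussian_kernel_3x3(gaussian_sigma)
    grad_mag = gradient_magnitude(img)
    diag = float(np.hypot(*img.shape))

    region = np.zeros_like(domain)
    region[seed] = True
    region = ndimage.binary_dilation(region, structure=struct) & domain
    ext = domain & ~region
    m_in, m_out, v_in, v_out = _stats(img, region, ext)
    state = ContourState(region, 0, m_in, m_out, v_in, v_out, k, m_in, m_out, v_in)
    energy = contour_energy(state, slice_, domain, grad_mag)
    trace = [dict(state.terms, t=0, energy=energy, area=int(region.sum()))]

    for t in range(1, iteration_cap + 1):
        tol = max(2.0 * np.sqrt(max(state.var_in, 0.0)), 3.0 * np.sqrt(k))
        cand = ndimage.binary_dilation(region, structure=struct) & domain & ~region
        grown = cand & (np.abs(img - state.mean_in) <= tol)
        new_region = region | grown
        smoothed = ndimage.convolve(new_region.astype(np.float64), gk, mode="constant")
        new_region |= (smoothed >= 0.3) & domain
        changed = bool((new_region ^ region).any())
        region = new_region

        ext = domain & ~region
        if not ext.any():
            logger.warning("contour filled the whole domain")
            state = ContourState(
                region, t, *_stats(img, region, ext), k, state.mean_in, state.mean_out, state.var_in
            )
            return ContourResult(region, False, t, np.nan, trace)
        m_in, m_out, v_in, v_out = _stats(img, region, ext)
        state = ContourState(
            region, t, m_in, m_out, v_in, v_out, k, state.mean_in, state.mean_out, state.var_in
        )
        energy = contour_energy(state, slice_, domain, grad_mag)
        trace.append(dict(state.terms, t=t, energy=energy, area=int(region.sum())))

        if not changed:
            # the contour stopped expanding: propagate to any remaining
            # structure matching the interior statistics before deciding
            # convergence (squared variance differences are numerically
            # tiny on the normalized scale, so a small remote vessel can
            # leave the energy below threshold while still unclaimed)
            jumped = _jump_propagate(
                img, region, domain, state, tol, jump_radius_step, diag
            )
            if jumped is not None:
                region = jumped
                continue
            # nothing left to capture anywhere; once the backward
            # differences have settled the energy is at its floor
            settled = (
                state.terms["d_var_in"] == 0
                and state.terms["d_mean_in"] == 0
                and state.terms["d_mean_out"] == 0
            )
            if settled:
                return ContourResult(region, energy < energy_epsilon, t, energy, trace)
    raise NonConvergenceError(
        f"contour did not converge within {iteration_cap} iterations", best_state=state
    )


def _jump_propagate(img, region, domain, state, tol, radius_step, diag):
    """Propagate to close structures matching the interior statistics.

    Searches at increasing distance from the current region: fragmented
    gland tissue and isolated vessels are not always connected within a
    slice, so the contour must be able to jump arbitrary adipose gaps.
    Returns the augmented region, or None when no admissible structure
    exists at any radius.
    """
    band = domain & ~region & (np.abs(img - state.mean_in) <= tol)
    if not band.any():
        return None
    lab, n = ndimage.label(band, structure=np.ones((3, 3)))
    means = ndimage.mean(img, lab, index=np.arange(1, n + 1))
    s_in = max(np.sqrt(max(state.var_in, 0.0)), np.sqrt(state.k), 1e-9)
    ok = np.abs(means - state.mean_in) <= s_in
    if not ok.any():
        return None
    dist = ndimage.distance_transform_edt(~region)
    comp_dist = ndimage.minimum(dist, lab, index=np.arange(1, n + 1))
    radius = radius_step
    while radius <= diag + radius_step:
        sel = ok & (comp_dist <= radius)
        if sel.any():
            ids = np.flatnonzero(sel) + 1
            return region | np.isin(lab, ids)
        radius += radius_step
    return None


# ----------------------------------------------------------------------
# Subtraction


def segment_adipose(
    breast: np.ndarray, skin_mask: np.ndarray, dense_mask: np.ndarray
) -> np.ndarray:
    """Adipose = breast interior minus skin minus dense structures.

    The three masks plus background must partition the slice; overlap
    between skin and dense input raises :class:`ConsistencyError`.
    """
    if (skin_mask & dense_mask).any():
        raise ConsistencyError("skin and dense masks overlap")
    if (dense_mask & ~breast).any():
        raise ConsistencyError("dense mask extends outside the breast")
    if (skin_mask & ~breast).any():
        raise ConsistencyError("skin mask extends outside the breast")
    return breast & ~skin_mask & ~dense_mask
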