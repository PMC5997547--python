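"""Slice-by-slice orchestration of the full four-class classifier.

Per slice: skin segmentation (outer edge, ridge centerline, constrained
region growing), then the energy-minimizing contour splits the skin-free
interior into dense structures and adipose tissue.  Volume level: the
dense components of *all* slices are pooled into one feature space, a
3-means separates vessel from fibroglandular components, and the
through-slice continuity criterion finalizes the vasculature.

A slice where a stage degenerates (no closed contour, unimodal
histogram with no bright structure at all, ...) is emitted as
background with the reason logged, and the run continues — mirroring
how non-breast slices are excluded rather than aborting the volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage

from . import adipose_seg, skin_seg, vessel_cls
from .errors import (
    BctsegError,
    DegenerateInputError,
    NonConvergenceError,
    SegmentationError,
)
from .io_model import (
    ADIPOSE,
    FIBROGLANDULAR,
    SKIN,
    VASCULATURE,
    ImageSlice,
    LabelMap,
    Volume,
    normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every constant of the classifier, in one overridable place."""

    tolerance_to_zero: float = 1e-6
    histogram_window: int = 9
    histogram_bins: int = 256
    gaussian_sigma: float = 0.5
    energy_epsilon: float = 1e-3
    k_growth_iterations: int = 30
    valley_fractions: tuple[float, float] = (0.9, 0.1)
    kmeans_restarts: int = 20
    continuity_threshold: int = 3
    master_seed: int = 0
    iteration_cap: int = 2000
    slice_range: tuple[int, int] | None = None  # inclusive

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a plain ``key = value`` config file."""
        kwargs = {}
        valid = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in valid:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = _coerce(val.strip())
        return cls(**kwargs)


def _coerce(text: str):
    if "," in text:
        return tuple(_coerce(t) for t in text.split(","))
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    if text.lower() in ("none", ""):
        return None
    return text


@dataclass
class SliceResult:
    """Provisional per-slice classification (vessels still undivided)."""

    labels: np.ndarray  # 2D provisional codes (dense marked fibroglandular)
    dense: np.ndarray  # 2D bool mask of dense structures
    ok: bool = True
    reason: str = ""
    energy_trace: list = field(default_factory=list)


def classify_slice(slice_: ImageSlice, config: PipelineConfig | None = None) -> SliceResult:
    """Skin -> contour -> adipose for one slice; dense left provisional."""
    config = config or PipelineConfig()
    shape = slice_.data.shape
    empty = np.zeros(shape, dtype=np.uint8)
    criteria = skin_seg.RidgeCriteria(config.tolerance_to_zero)
    try:
        skin, breast, _ = skin_seg.segment_skin(slice_, criteria=criteria)
    except (SegmentationError, DegenerateInputError) as exc:
        logger.warning("slice unclassified at skin stage: %s", exc)
        return SliceResult(empty, np.zeros(shape, bool), ok=False, reason=str(exc))

    skin &= breast  # tracing excursions outside the outline are not skin
    # the interior is the region enclosed by the skin ring: partial-volume
    # surface pixels radially outside the skin are neither interior nor skin
    enclosed = ndimage.binary_fill_holes(skin) & ~skin & breast
    fallback = breast & ~skin
    interior = enclosed if enclosed.sum() >= 0.5 * fallback.sum() else fallback
    trace: list = []
    try:
        model = adipose_seg.histogram_valley(
            slice_.data[interior],
            n_bins=config.histogram_bins,
            window=config.histogram_window,
        )
        seed = adipose_seg.initialize_contour(slice_, model, interior)
        k = adipose_seg.estimate_k(
            slice_,
            model,
            interior,
            n_iterations=config.k_growth_iterations,
            valley_fractions=config.valley_fractions,
        )
        result = adipose_seg.evolve_contour(
            slice_,
            seed,
            k,
            interior,
            energy_epsilon=config.energy_epsilon,
            gaussian_sigma=config.gaussian_sigma,
            iteration_cap=config.iteration_cap,
        )
        dense = result.mask
        trace = result.trace
    except DegenerateInputError as exc:
        # adipose-only interior: no dense structure to contour
        logger.info("no dense tissue on this slice (%s); adipose = interior", exc)
        dense = np.zeros(shape, bool)
    except NonConvergenceError as exc:
        logger.warning("contour did not converge: %s; using best state", exc)
        dense = exc.best_state.region if exc.best_state is not None else np.zeros(shape, bool)

    adipose = adipose_seg.segment_adipose(breast, skin, dense)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[adipose] = ADIPOSE
    labels[dense] = FIBROGLANDULAR  # provisional: vessels not yet split off
    labels[skin] = SKIN
    return SliceResult(labels, dense, ok=True, energy_trace=trace)


def classify_volume(volume: Volume, config: PipelineConfig | None = None) -> LabelMap:
    """Full classifier: per-slice stages, pooled k-means, 3D continuity."""
    config = config or PipelineConfig()
    volume = normalize(volume)
    n = volume.n_slices
    lo, hi = (0, n - 1) if config.slice_range is None else config.slice_range

    labels = np.zeros(volume.data.shape, dtype=np.uint8)
    dense = np.zeros(volume.data.shape, dtype=bool)
    n_ok = 0
    for z in range(n):
        if not lo <= z <= hi:
            continue
        res = classify_slice(volume.get_slice(z), config)
        labels[z] = res.labels
        dense[z] = res.dense
        n_ok += res.ok
    if n_ok == 0:
        raise SegmentationError("no slice could be classified")

    labeled = vessel_cls.label_dense_components(dense)
    features = vessel_cls.extract_features(dense, volume, labeled)
    if features:
        model = vessel_cls.kmeans_classify(
            features, seed=config.master_seed, n_restarts=config.kmeans_restarts
        )
        vessel3d, fibro3d = vessel_cls.assign_roles(features, model, labeled)
        vessel3d, fibro3d = vessel_cls.continuity_filter(
            vessel3d, fibro3d, threshold=config.continuity_threshold
        )
        labels[vessel3d] = VASCULATURE
        labels[fibro3d] = FIBROGLANDULAR
    return LabelMap(labels, spacing=volume.spacing)
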