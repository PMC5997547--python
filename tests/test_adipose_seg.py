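"""Histogram initialization, k estimation, contour energy and evolution."""

import numpy as np
import pytest
from scipy import ndimage

from bctseg import adipose_seg, phantom, skin_seg
from bctseg.adipose_seg import (
    ContourState,
    contour_energy,
    estimate_k,
    evolve_contour,
    gradient_magnitude,
    histogram_valley,
    initialize_contour,
    segment_adipose,
)
from bctseg.errors import ConsistencyError, DegenerateInputError
from bctseg.io_model import ADIPOSE, FIBROGLANDULAR, ImageSlice, SKIN, VASCULATURE
from bctseg.metrics import dsc


def two_class_image(shape=(256, 256), blobs=(((110, 120), 60),), fat=0.3, dense=0.7):
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    domain = np.hypot(ii - shape[0] / 2, jj - shape[1] / 2) < min(shape) / 2 - 8
    img = np.where(domain, fat, 0.0)
    mask = np.zeros(shape, dtype=bool)
    for (ci, cj), r in blobs:
        mask |= np.hypot(ii - ci, jj - cj) <= r
    img[mask] = dense
    return ImageSlice(img), domain, mask


class TestHistogramValley:
    def test_valley_of_asymmetric_mixture(self, rng):
        pix = np.concatenate(
            [rng.normal(0.3, 0.03, 70_000), rng.normal(0.7, 0.03, 30_000)]
        ).clip(0, 1)
        model = histogram_valley(pix)
        assert 0.4 < model.valley < 0.6
        assert model.mode_lo == pytest.approx(0.3, abs=0.02)
        assert model.mode_hi == pytest.approx(0.7, abs=0.02)

    def test_symmetric_mixture_valley_at_midpoint(self, rng):
        pix = np.concatenate(
            [rng.normal(0.35, 0.04, 50_000), rng.normal(0.65, 0.04, 50_000)]
        ).clip(0, 1)
        model = histogram_valley(pix)
        assert model.valley == pytest.approx(0.5, abs=2.0 / 256)

    def test_single_gaussian_is_degenerate(self, rng):
        with pytest.raises(DegenerateInputError):
            histogram_valley(rng.normal(0.5, 0.05, 50_000).clip(0, 1))

    def test_too_few_pixels_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            histogram_valley(rng.uniform(size=500))


class TestInitialization:
    def test_seed_lands_in_largest_bright_component(self, default_spec):
        sl, lab = phantom.make_slice(default_spec, 2)
        skin, breast, _ = skin_seg.segment_skin(sl)
        interior = breast & ~skin
        model = histogram_valley(sl.data[interior])
        seed = initialize_contour(sl, model, interior)
        # the largest dense structure on this slice is a gland blob
        assert lab.data[seed] == FIBROGLANDULAR

    def test_vessel_only_slice_seeds_in_vessel(self):
        sl, domain, mask = two_class_image(blobs=(((128, 140), 6),))
        model = histogram_valley(np.concatenate([sl.data[domain], [0.7] * 400]))
        seed = initialize_contour(sl, model, domain)
        assert mask[seed]

    def test_no_bright_component_is_degenerate(self, rng):
        img = ImageSlice(np.full((64, 64), 0.2))
        model = histogram_valley(
            np.concatenate([rng.normal(0.3, 0.02, 5000), rng.normal(0.7, 0.02, 5000)]).clip(0, 1)
        )
        with pytest.raises(DegenerateInputError):
            initialize_contour(img, model, np.ones((64, 64), bool))


class TestEstimateK:
    @pytest.mark.parametrize("sigma", [0.02, 0.04])
    def test_k_recovers_adipose_noise_variance(self, sigma):
        spec = phantom.PhantomSpec(noise_sigma=sigma)
        sl, lab = phantom.make_slice(spec, 2)
        skin, breast, _ = skin_seg.segment_skin(sl)
        interior = breast & ~skin
        model = histogram_valley(sl.data[interior])
        k = estimate_k(sl, model, interior)
        assert k == pytest.approx(sigma**2, rel=0.25)

    def test_noise_free_k_is_zero(self):
        spec = phantom.PhantomSpec(noise_sigma=0.0)
        sl, _ = phantom.make_slice(spec, 2)
        skin, breast, _ = skin_seg.segment_skin(sl)
        interior = breast & ~skin
        model = histogram_valley(sl.data[interior])
        assert estimate_k(sl, model, interior) == pytest.approx(0.0, abs=1e-12)


class TestContourEnergy:
    @staticmethod
    def _state(img, region, domain, k, prev=None):
        ext = domain & ~region
        m_in, m_out = img[region].mean(), img[ext].mean()
        v_in, v_out = img[region].var(), img[ext].var()
        if prev is None:
            prev = (m_in, m_out, v_in)
        return ContourState(region, 1, m_in, m_out, v_in, v_out, k, *prev)

    def test_region_terms_null_at_converged_ideal_partition(self):
        sl, domain, blob = two_class_image(blobs=(((128, 128), 40),))
        state = self._state(sl.data, blob, domain, k=0.0)
        contour_energy(state, sl, domain)
        assert state.terms["region"] == pytest.approx(0.0, abs=1e-15)
        assert state.terms["d_var_in"] == 0.0
        assert state.terms["d_mean_in"] == 0.0
        assert state.terms["d_mean_out"] == 0.0

    def test_energy_matches_direct_summation_oracle(self, rng):
        sl, domain, blob = two_class_image(blobs=(((120, 130), 30),))
        img = sl.data + rng.normal(0, 0.01, sl.data.shape)
        sl = ImageSlice(np.clip(img, 0, 1))
        region = blob.copy()
        prev = (0.65, 0.31, 0.001)
        state = self._state(sl.data, region, domain, k=1e-4, prev=prev)
        e = contour_energy(state, sl, domain)
        # independent plain-python re-summation of every term
        img = sl.data
        ext = domain & ~region
        grad = gradient_magnitude(img)
        inner = region & ~ndimage.binary_erosion(region, np.ones((3, 3)), border_value=0)
        outer = ndimage.binary_dilation(region, np.ones((3, 3))) & ~region & domain
        band = inner | outer
        expect = (
            (img[ext].var() - 1e-4) ** 2
            + abs(img[region].var() - prev[2])
            + abs(img[region].mean() - prev[0]) * np.mean(img[region] ** 2)
            + abs(img[ext].mean() - prev[1]) * np.mean(img[ext] ** 2)
            + 1.0 / (grad[band].sum() + 1e-6)
        )
        assert e == pytest.approx(expect, abs=1e-9)

    def test_true_partition_is_local_energy_minimum(self):
        """Every single-pixel perturbation of the converged partition raises E."""
        ii, jj = np.mgrid[0:24, 0:24]
        domain = np.ones((24, 24), bool)
        blob = (np.abs(ii - 12) <= 3) & (np.abs(jj - 12) <= 3)
        img = np.where(blob, 0.7, 0.3)
        sl = ImageSlice(img)
        base = self._state(img, blob, domain, k=0.0)
        e0 = contour_energy(base, sl, domain)
        stats0 = (base.mean_in, base.mean_out, base.var_in)
        inner = blob & ~ndimage.binary_erosion(blob, np.ones((3, 3)), border_value=0)
        outer = ndimage.binary_dilation(blob, np.ones((3, 3))) & ~blob
        for p in np.argwhere(inner):
            region = blob.copy()
            region[tuple(p)] = False
            st = self._state(img, region, domain, k=0.0, prev=stats0)
            assert contour_energy(st, sl, domain) > e0
        for p in np.argwhere(outer):
            region = blob.copy()
            region[tuple(p)] = True
            st = self._state(img, region, domain, k=0.0, prev=stats0)
            assert contour_energy(st, sl, domain) > e0

    def test_empty_region_rejected(self):
        sl, domain, _ = two_class_image()
        state = self._state(sl.data, domain, domain, 0.0)  # fills the domain
        with pytest.raises(DegenerateInputError):
            contour_energy(state, sl, domain)


class TestEvolveContour:
    def test_single_blob_captured_and_energy_null(self):
        sl, domain, blob = two_class_image(blobs=(((110, 120), 60),))
        res = evolve_contour(sl, (110, 120), 0.0, domain)
        assert dsc(res.mask, blob) >= 0.98
        assert res.energy < 1e-3
        assert res.converged

    def test_disjoint_blobs_captured_by_jump_propagation(self):
        sl, domain, blobs = two_class_image(blobs=(((90, 90), 40), ((170, 160), 40)))
        res = evolve_contour(sl, (90, 90), 0.0, domain)
        assert dsc(res.mask, blobs) >= 0.95
        assert res.energy < 1e-3

    def test_initialization_robustness_across_blobs(self):
        sl, domain, blobs = two_class_image(blobs=(((90, 90), 40), ((170, 160), 40)))
        a = evolve_contour(sl, (90, 90), 0.0, domain).mask
        b = evolve_contour(sl, (170, 160), 0.0, domain).mask
        assert dsc(a, b) >= 0.98

    def test_energy_trace_time_derivatives_settle(self):
        sl, domain, _ = two_class_image(blobs=(((128, 128), 50),))
        res = evolve_contour(sl, (128, 128), 0.0, domain)
        last = res.trace[-1]
        assert last["d_var_in"] == 0.0
        assert last["d_mean_in"] == 0.0

    def test_negative_k_rejected(self):
        sl, domain, _ = two_class_image()
        with pytest.raises(ValueError):
            evolve_contour(sl, (110, 120), -1.0, domain)


class TestSegmentAdipose:
    def test_phantom_adipose_dice(self, default_spec):
        sl, lab = phantom.make_slice(default_spec, 2)
        skin, breast, _ = skin_seg.segment_skin(sl)
        skin &= breast
        interior = ndimage.binary_fill_holes(skin) & ~skin & breast
        model = histogram_valley(sl.data[interior])
        seed = initialize_contour(sl, model, interior)
        k = estimate_k(sl, model, interior)
        dense = evolve_contour(sl, seed, k, interior).mask
        adipose = segment_adipose(breast, skin, dense)
        assert dsc(adipose, lab.data == ADIPOSE) >= 0.95

    def test_full_dense_interior_leaves_no_adipose(self):
        breast = np.zeros((32, 32), bool)
        breast[4:28, 4:28] = True
        skin = breast & ~ndimage.binary_erosion(breast, np.ones((3, 3)))
        dense = breast & ~skin
        assert not segment_adipose(breast, skin, dense).any()

    def test_masks_partition_the_breast(self):
        breast = np.zeros((32, 32), bool)
        breast[4:28, 4:28] = True
        skin = breast & ~ndimage.binary_erosion(breast, np.ones((3, 3)))
        dense = np.zeros_like(breast)
        dense[10:14, 10:14] = True
        adipose = segment_adipose(breast, skin, dense)
        total = skin.astype(int) + dense.astype(int) + adipose.astype(int)
        assert np.all(total[breast] == 1)
        assert np.all(total[~breast] == 0)

    def test_overlapping_inputs_rejected(self):
        breast = np.ones((8, 8), bool)
        skin = np.zeros_like(breast)
        skin[0] = True
        dense = np.zeros_like(breast)
        dense[0, 0] = True
        with pytest.raises(ConsistencyError):
            segment_adipose(breast, skin, dense)
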