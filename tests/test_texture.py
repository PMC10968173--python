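"""Variogram, fractal fitting, ROI layout and descriptor-vector behaviour."""

import numpy as np
import pytest

from tbtoa.exceptions import (
    BandError,
    DegenerateTextureError,
    LagError,
    ParameterError,
    SizeError,
    StructuralError,
)
from tbtoa.fbm import FbmSpec, generate_fbm_surface
from tbtoa.texture import (
    ROILayout,
    ScaleBands,
    TBTVector,
    TextureImage,
    Variogram,
    build_roi_layout,
    delta_tbt,
    directional_variogram,
    extract_tbt,
    fit_fractal,
    full_index,
    subset_by_compartment,
)


def _embed(patch: np.ndarray) -> tuple[TextureImage, tuple[int, int, int, int]]:
    """Place a small patch in the corner of a legal >=16x16 image."""
    h, w = patch.shape
    canvas = np.zeros((max(16, h), max(16, w)))
    canvas[:h, :w] = patch
    return TextureImage(canvas, pixel_spacing_mm=0.1), (0, 0, h, w)


def brute_force_variogram(patch: np.ndarray, direction: str, lag: int) -> tuple[float, int]:
    """O(n^2) reference: explicit loop over all pixel pairs at one lag."""
    h, w = patch.shape
    total, count = 0.0, 0
    for i in range(h):
        for j in range(w):
            if direction == "HF" and j + lag < w:
                total += (patch[i, j + lag] - patch[i, j]) ** 2
                count += 1
            if direction == "VF" and i + lag < h:
                total += (patch[i + lag, j] - patch[i, j]) ** 2
                count += 1
    return total / count, count


class TestDirectionalVariogram:
    def test_hand_enumerated_two_by_two(self):
        image, roi = _embed(np.array([[0.0, 1.0], [2.0, 3.0]]))
        hf = directional_variogram(image, roi, "HF", 1)
        vf = directional_variogram(image, roi, "VF", 1)
        assert hf.v[0] == pytest.approx(1.0) and hf.n_pairs[0] == 2
        assert vf.v[0] == pytest.approx(4.0) and vf.n_pairs[0] == 2

    def test_constant_roi_gives_zero_variogram(self):
        image, roi = _embed(np.full((8, 8), 7.0))
        vg = directional_variogram(image, roi, "HF", 4)
        assert np.all(vg.v == 0.0)

    @pytest.mark.parametrize("direction", ["HF", "VF"])
    def test_matches_brute_force_pair_enumeration(self, rng, direction):
        for _ in range(20):
            h, w = rng.integers(16, 33, size=2)
            patch = rng.random((h, w)) * 100
            image, roi = _embed(patch)
            extent = w if direction == "HF" else h
            vg = directional_variogram(image, roi, direction, extent - 1)
            for k, lag in enumerate(vg.lags_px):
                v_ref, n_ref = brute_force_variogram(patch, direction, int(lag))
                assert vg.v[k] == pytest.approx(v_ref, rel=1e-12)
                assert vg.n_pairs[k] == n_ref

    def test_translation_invariance_and_scale_equivariance(self, rng):
        patch = rng.random((20, 20)) * 50
        image, roi = _embed(patch)
        shifted, _ = _embed(patch + 123.0)
        scaled, _ = _embed(patch * 3.0)
        base = directional_variogram(image, roi, "VF", 10)
        assert directional_variogram(shifted, roi, "VF", 10).v == pytest.approx(base.v)
        assert directional_variogram(scaled, roi, "VF", 10).v == pytest.approx(9.0 * base.v)

    def test_lag_exceeding_extent_raises(self):
        image, roi = _embed(np.zeros((16, 16)))
        with pytest.raises(LagError):
            directional_variogram(image, roi, "HF", 16)

    def test_roi_outside_image_raises(self, fbm_half):
        with pytest.raises(StructuralError):
            directional_variogram(fbm_half, (250, 250, 32, 32), "HF", 4)


class TestFitFractal:
    def _power_law_variogram(self, exponent: float, spacing: float = 0.05) -> Variogram:
        lags = np.arange(1, 11)
        lags_mm = lags * spacing
        return Variogram("HF", lags, lags_mm, lags_mm**exponent, np.full(10, 100))

    def test_exact_power_law_recovered(self):
        # V(d) = d^0.6 on lags all inside the micro band -> H = 0.3 exactly
        vg = self._power_law_variogram(0.6, spacing=0.02)
        assert fit_fractal(vg, "micro") == pytest.approx(0.3, abs=1e-10)

    def test_fd_is_three_minus_h(self):
        vg = self._power_law_variogram(1.0, spacing=0.02)
        assert fit_fractal(vg, "micro", kind="FD") == pytest.approx(2.5, abs=1e-10)

    def test_band_with_single_lag_raises(self):
        # spacing 0.35: only lag 1 (0.35 mm) falls in the micro band
        vg = self._power_law_variogram(0.8, spacing=0.35)
        with pytest.raises(BandError):
            fit_fractal(vg, "micro")

    def test_zero_variogram_in_band_raises(self):
        lags = np.arange(1, 5)
        vg = Variogram("HF", lags, lags * 0.1, np.zeros(4), np.full(4, 10))
        with pytest.raises(DegenerateTextureError):
            fit_fractal(vg, "micro")

    def test_band_bounds_are_validated(self):
        with pytest.raises(ParameterError):
            ScaleBands(micro_max_mm=0.7)  # crosses the cutoff


class TestRoiLayout:
    def test_tiles_64x256_into_32px_squares(self, layout_2x8):
        assert len(layout_2x8.rois) == 16
        assert all((h, w) == (32, 32) for _, _, h, w in layout_2x8.rois)

    def test_default_compartment_split_is_6_4_6(self, layout_2x8):
        counts = {c: layout_2x8.compartments.count(c) for c in ("medial", "central", "lateral")}
        assert counts == {"medial": 6, "central": 4, "lateral": 6}

    def test_non_16_grid_raises(self):
        with pytest.raises(StructuralError):
            build_roi_layout((0, 0, 96, 256), rows=3, cols=8)

    def test_too_small_bbox_raises(self):
        with pytest.raises(SizeError):
            build_roi_layout((0, 0, 20, 256))

    def test_overlapping_rois_rejected(self):
        rois = [(0, 0, 16, 16)] * 2 + [
            (0, 32 * i, 16, 16) for i in range(1, 15)
        ]
        with pytest.raises(StructuralError):
            ROILayout(tuple(rois), ("medial",) * 6 + ("central",) * 4 + ("lateral",) * 6)


class TestExtractTbt:
    def test_emits_64_descriptors_with_bijective_index(self, fbm_half, layout_2x8):
        vec = extract_tbt(fbm_half, layout_2x8)
        assert len(vec) == 64
        assert set(vec.index) == set(full_index())

    def test_deterministic_on_identical_image(self, fbm_half, layout_2x8):
        a = extract_tbt(fbm_half, layout_2x8)
        b = extract_tbt(fbm_half, layout_2x8)
        assert np.array_equal(a.values, b.values)

    def test_noise_rougher_than_smooth_fbm(self, rng, layout_2x8):
        noise = TextureImage(rng.random((64, 256)) * 65535, pixel_spacing_mm=0.1)
        smooth = generate_fbm_surface(FbmSpec(hurst=0.8, size_px=256, seed=5))
        smooth = TextureImage(smooth.pixels[:64, :], pixel_spacing_mm=0.1)
        h_noise = extract_tbt(noise, layout_2x8).values.mean()
        h_smooth = extract_tbt(smooth, layout_2x8).values.mean()
        assert h_noise < h_smooth


class TestDeltaAndSubsets:
    def _vec(self, fill: float) -> TBTVector:
        return TBTVector(np.full(64, fill), full_index())

    def test_zero_change_and_arithmetic(self):
        v0, v24 = self._vec(0.5), self._vec(0.4)
        assert np.all(delta_tbt(v0, v0).values == 0.0)
        assert delta_tbt(v0, v24).values == pytest.approx(np.full(64, -0.1))

    def test_antisymmetry(self, rng):
        v0 = TBTVector(rng.random(64), full_index())
        v24 = TBTVector(rng.random(64), full_index())
        assert delta_tbt(v0, v24).values == pytest.approx(-delta_tbt(v24, v0).values)

    def test_index_mismatch_raises(self):
        v = self._vec(0.5)
        fd = TBTVector(np.full(64, 2.5), full_index(), descriptor_kind="FD")
        with pytest.raises(StructuralError):
            delta_tbt(v, fd)

    def test_compartment_subsets_partition_the_64(self, layout_2x8, rng):
        v = TBTVector(rng.random(64), full_index())
        sizes = {}
        seen = []
        for comp in ("medial", "central", "lateral"):
            sub = subset_by_compartment(v, layout_2x8, comp)
            sizes[comp] = len(sub)
            seen += list(sub.index)
        assert sizes == {"medial": 24, "central": 16, "lateral": 24}
        assert sorted(seen) == sorted(full_index())
        assert len(subset_by_compartment(v, layout_2x8, "all")) == 64

    def test_unknown_compartment_raises(self, layout_2x8):
        with pytest.raises(ParameterError):
            subset_by_compartment(self._vec(0.5), layout_2x8, "femoral")
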