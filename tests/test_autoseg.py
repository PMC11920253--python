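"""Automatic pre-segmentation: thresholding, region selection, tracing,
nested boundaries, and their invariances."""

import numpy as np
import pytest

from fatseg import autoseg, phantom
from fatseg.autoseg import (
    SegParams,
    adaptive_binarize,
    fill_and_trace,
    largest_valid_region,
    segment_series,
    segment_slice,
)
from fatseg.errors import (
    EmptyMaskError,
    LandmarkError,
    NoValidRegionError,
    ParameterError,
    SegmentationFailure,
)
from fatseg.io_mri import AbdomenSeries, MRISlice

from conftest import small_noise_free_spec, small_spec


def flood_fill_components(mask):
    """Brute-force 8-connected component enumeration (test oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                pixels = []
                while stack:
                    pr, pc = stack.pop()
                    pixels.append((pr, pc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            qr, qc = pr + dr, pc + dc
                            if (0 <= qr < h and 0 <= qc < w
                                    and mask[qr, qc] and not seen[qr, qc]):
                                seen[qr, qc] = True
                                stack.append((qr, qc))
                comps.append(pixels)
    return comps


class TestAdaptiveBinarize:
    def test_constant_image_has_no_bright_pixels(self):
        img = np.full((48, 48), 50.0)
        assert not adaptive_binarize(img, 19, 1.0, "bright").any()

    def test_single_hot_pixel_window3(self):
        # brute-force local-mean check: only the centre exceeds its own
        # 3x3 mean (100 > 100/9); every neighbour sees mean 100/9 > 0
        img = np.zeros((21, 21))
        img[10, 10] = 100.0
        mask = adaptive_binarize(img, 3, 1.0, "bright")
        expected = np.zeros((21, 21), dtype=bool)
        expected[10, 10] = True
        np.testing.assert_array_equal(mask, expected)

    def test_dark_is_exact_complement(self, rng):
        img = rng.uniform(0, 200, (64, 64))
        bright = adaptive_binarize(img, 9, 1.0, "bright")
        dark = adaptive_binarize(img, 9, 1.0, "dark")
        np.testing.assert_array_equal(dark, ~bright)

    @pytest.mark.parametrize("window", [2, 4, 100])
    def test_invalid_windows_rejected(self, window):
        with pytest.raises(ParameterError):
            adaptive_binarize(np.zeros((48, 48)), window)

    def test_scale_equivariance(self, rng):
        img = rng.uniform(0, 200, (64, 64))
        a = adaptive_binarize(img, 11, 1.0, "bright")
        b = adaptive_binarize(img * 3.7, 11, 1.0, "bright")
        np.testing.assert_array_equal(a, b)


class TestLargestValidRegion:
    params = SegParams(min_region_fraction=0.001)

    def test_larger_of_two_valid_blobs_wins(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:10, 5:13] = True  # 40 px
        mask[30:34, 30:33] = True  # 12 px
        region = largest_valid_region(mask, self.params)
        assert region.sum() == 40
        assert region[6, 6] and not region[31, 31]

    def test_equal_size_tie_broken_by_raster_order(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:24, 40:44] = True  # same size, later first pixel (row 20)
        mask[10:14, 10:14] = True  # earliest pixel in row-major order
        region = largest_valid_region(mask, self.params)
        assert region[10, 10] and not region[20, 40]

    def test_elongated_artefact_rejected_for_compact_blob(self):
        # oracle: the 60-px line has an unbounded principal-diameter ratio,
        # the 30-px rectangle is compact; enumeration confirms two comps
        mask = np.zeros((80, 80), dtype=bool)
        mask[2, 5:65] = True  # 1-px-wide line, 60 px
        mask[40:45, 40:46] = True  # 30 px compact
        assert len(flood_fill_components(mask)) == 2
        region = largest_valid_region(mask, self.params)
        assert region.sum() == 30
        assert region[42, 42]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            largest_valid_region(np.zeros((32, 32), dtype=bool), self.params)

    def test_no_valid_region_raises(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[2, 5:65] = True  # only an artefact line
        with pytest.raises(NoValidRegionError):
            largest_valid_region(mask, self.params)


class TestFillAndTrace:
    def test_solid_square_border(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:15, 10:15] = True
        contour, filled = fill_and_trace(mask)
        assert len(contour) == 16  # the 16 border pixels of a 5x5 square
        assert filled.sum() == 25
        np.testing.assert_array_equal(contour.filled((32, 32)), filled)

    def test_annulus_hole_filled_to_solid(self):
        solid = np.zeros((32, 32), dtype=bool)
        solid[10:15, 10:15] = True
        annulus = solid.copy()
        annulus[12, 12] = False
        c_solid, f_solid = fill_and_trace(solid)
        c_ann, f_ann = fill_and_trace(annulus)
        np.testing.assert_array_equal(f_ann, f_solid)
        np.testing.assert_array_equal(c_ann.points, c_solid.points)

    def test_single_pixel_degenerate_contour(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 7] = True
        contour, filled = fill_and_trace(mask)
        assert len(contour) == 1
        assert filled.sum() == 1
        np.testing.assert_array_equal(contour.filled((32, 32)), filled)

    def test_filled_contour_reproduces_mask_on_random_blobs(self, rng):
        from scipy import ndimage as ndi

        for _ in range(20):
            noise = rng.random((48, 48)) < 0.45
            blob = ndi.binary_closing(noise, structure=np.ones((3, 3)))
            labels, n = ndi.label(blob, structure=np.ones((3, 3)))
            if n == 0:
                continue
            largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
            contour, filled = fill_and_trace(largest)
            np.testing.assert_array_equal(contour.filled((48, 48)), filled)


class TestBoundaries:
    def test_outer_contour_matches_analytic_body(self, segmented_small_noise_free):
        series, truth, bsets = segmented_small_noise_free
        spec = small_noise_free_spec()
        for b in bsets:
            scale = spec.slice_scale(b.slice_index)
            a_mm, b_mm = (s * scale for s in spec.body_semiaxes_mm)
            analytic_px = (
                np.pi * (a_mm / 1.104) * (b_mm / 1.104)
            )
            assert b.outer_mask.sum() == pytest.approx(analytic_px, rel=0.02)

    def test_inner_mask_matches_analytic_cavity(self, segmented_small_noise_free):
        series, truth, bsets = segmented_small_noise_free
        for b in bsets:
            cavity = truth.cavity_masks[b.slice_index]
            assert b.inner_mask.sum() == pytest.approx(cavity.sum(), rel=0.02)

    def test_nesting_invariant(self, segmented_small):
        _, _, bsets = segmented_small
        for b in bsets:
            assert not b.failed
            assert b.nesting_ok()

    def test_envelope_strictly_inside_inner(self, segmented_small_noise_free):
        _, _, bsets = segmented_small_noise_free
        for b in bsets:
            assert b.envelope_mask.sum() < b.inner_mask.sum()
            # erosion by disk(3) leaves a margin of at least 1 px everywhere
            from scipy import ndimage as ndi

            grown = ndi.binary_dilation(b.envelope_mask, np.ones((3, 3)))
            assert not np.any(grown & ~b.inner_mask)

    def test_eroded_circle_area(self):
        # circular core radius 50 px eroded by disk(5): area ~ pi * 45^2
        from scipy import ndimage as ndi
        from skimage.morphology import disk

        mask = np.zeros((128, 128), dtype=bool)
        rr = np.arange(128)[:, None] - 63.5
        cc = np.arange(128)[None, :] - 63.5
        mask[rr**2 + cc**2 <= 50.0**2] = True
        eroded = ndi.binary_erosion(mask, structure=disk(5))
        assert eroded.sum() == pytest.approx(np.pi * 45**2, rel=0.03)

    def test_erosion_radius_backoff(self):
        # an absurd erosion radius would empty the cavity; the stepwise
        # back-off must still deliver a non-empty envelope
        spec = small_noise_free_spec(n_slices=1)
        series, truth = phantom.generate_phantom(spec)
        params = SegParams(erosion_radius_px=80)  # exceeds the cavity radius
        b = segment_slice(series[0], params)
        assert not b.failed
        assert b.envelope_mask.sum() > 0
        assert b.envelope_mask.sum() < truth.cavity_masks[0].sum()

    def test_artefact_stripe_excluded_from_body(self):
        spec = small_spec(n_slices=1, artefact=True)
        series, truth = phantom.generate_phantom(spec)
        b = segment_slice(series[0])
        assert not b.failed
        h, w = series.shape
        stripe = np.zeros((h, w), dtype=bool)
        stripe[h - 18:h - 10, w // 6:(5 * w) // 6] = True
        assert not np.any(b.outer_mask & stripe)

    def test_pure_noise_slice_flagged_failed(self, rng):
        pixels = rng.uniform(0, 1, (256, 256))
        sl = MRISlice(pixels=pixels, pixel_spacing_mm=(1.104, 1.104))
        b = segment_slice(sl)
        assert b.failed
        assert b.message

    def test_degenerate_ring_does_not_crash(self):
        spec = small_noise_free_spec(
            sat_inner_semiaxes_mm=(120.0, 95.0), degenerate_ring=True, n_slices=1
        )
        series, _ = phantom.generate_phantom(spec)
        b = segment_slice(series[0])
        assert not b.failed
        assert b.nesting_ok()
        # without a fat ring only a thin residual band (at most about half
        # the local-mean window) can separate inner from outer
        sat_px = (b.outer_mask & ~b.inner_mask).sum()
        assert sat_px < 0.25 * b.outer_mask.sum()

    def test_inner_equals_outer_fallback_warns(self):
        spec = small_noise_free_spec(n_slices=1)
        series, _ = phantom.generate_phantom(spec)
        # an impossibly large size criterion rejects the cavity candidate
        params = SegParams(min_region_fraction=0.9)
        from fatseg.autoseg import inner_sat_boundary, outer_sat_boundary

        with pytest.raises(SegmentationFailure):
            outer_sat_boundary(series[0], params)
        _, outer_mask = outer_sat_boundary(series[0], SegParams())
        contour, filled, warnings = inner_sat_boundary(
            series[0], outer_mask, params
        )
        assert warnings == ("inner_equals_outer",)
        np.testing.assert_array_equal(filled, outer_mask)


class TestSegmentSeries:
    @staticmethod
    def _flat_series(n):
        slices = [
            MRISlice(
                pixels=np.zeros((32, 32)),
                pixel_spacing_mm=(1.0, 1.0),
                slice_location_mm=10.5 * k,
                index=k,
            )
            for k in range(n)
        ]
        return AbdomenSeries(slices=slices)

    def test_landmark_range_inclusive(self):
        series = self._flat_series(40)
        series.landmarks = {2: "PF", 37: "diaphragm"}
        params = SegParams(candidate_windows=(9, 11))
        out = segment_series(series, params)
        assert len(out) == 36
        assert out[0].slice_index == 2 and out[-1].slice_index == 37

    def test_no_landmarks_processes_all(self):
        series = self._flat_series(8)
        out = segment_series(series, SegParams(candidate_windows=(9,)))
        assert len(out) == 8

    def test_out_of_order_landmarks_rejected(self):
        series = self._flat_series(10)
        series.landmarks = {7: "PF", 2: "diaphragm"}
        with pytest.raises(LandmarkError):
            segment_series(series)

    def test_failures_isolated_per_slice(self, small_noise_free_phantom):
        series, _ = small_noise_free_phantom
        corrupted = AbdomenSeries(
            slices=[
                MRISlice(
                    pixels=(np.zeros(series.shape) if k == 1 else s.pixels),
                    pixel_spacing_mm=s.pixel_spacing_mm,
                    slice_location_mm=s.slice_location_mm,
                    slice_thickness_mm=s.slice_thickness_mm,
                    interslice_gap_mm=s.interslice_gap_mm,
                    index=k,
                )
                for k, s in enumerate(series)
            ],
            source_id="corrupted",
        )
        out = segment_series(corrupted)
        assert [b.failed for b in out] == [False, True]

    def test_deterministic_repeat(self, small_phantom):
        series, _ = small_phantom
        a = segment_slice(series[0])
        b = segment_slice(series[0])
        np.testing.assert_array_equal(a.outer.points, b.outer.points)
        np.testing.assert_array_equal(a.inner.points, b.inner.points)
        np.testing.assert_array_equal(a.envelope.points, b.envelope.points)


class TestSegParamsConfig:
    def test_round_trip(self, tmp_path):
        params = SegParams(outer_window=21, erosion_radius_px=2,
                           candidate_windows=(13, 15))
        path = params.to_config(tmp_path / "params.cfg")
        assert SegParams.from_config(path) == params

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"outer_window": 18},
            {"inner_window": 1},
            {"sensitivity": 0.0},
            {"sensitivity": 1.5},
            {"erosion_radius_px": 0},
            {"max_eccentricity": 1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SegParams(**kwargs)


def test_contour_csv_export(tmp_path, segmented_small_noise_free):
    _, _, bsets = segmented_small_noise_free
    path = autoseg.export_contours_csv(bsets, tmp_path / "contours.csv")
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "slice_index,role,vertex_order,row,col"
    roles = {line.split(",")[1] for line in lines[1:]}
    assert roles == {"outer_sat", "inner_sat", "vat_envelope"}
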