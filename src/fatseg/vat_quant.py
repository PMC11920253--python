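"""Per-slice fat quantification and volume integration.

Inside the crude VAT envelope, a per-slice histogram threshold (Otsu on a
256-bin histogram) separates the bimodal in-phase intensity distribution
into lean (below) and fat (at or above the threshold; in-phase images show
fat bright).  SAT area is the pixel count between the outer and inner SAT
boundaries; VAT area is the fat pixel count inside the envelope.  Volumes
integrate areas over slices with effective spacing = thickness + gap
(10.5 mm for the 10.0 mm / 0.5 mm acquisition this pipeline targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .autoseg import BoundarySet
from .errors import InputError, LandmarkError, QuantificationError
from .io_mri import AbdomenSeries, MRISlice

__all__ = [
    "SliceResult",
    "VolumeReport",
    "histogram_fat_threshold",
    "vat_fat_mask",
    "quantify_slice",
    "integrate_volumes",
    "annotate_landmark",
]


@dataclass
class SliceResult:
    """Areas and threshold for one slice.

    Failed slices carry zero areas and are excluded from volume totals.
    The mask/slice references enable later threshold overrides and label
    exports; they are not part of the CSV report.
    """

    slice_index: int
    sat_area_cm2: float = 0.0
    vat_area_cm2: float = 0.0
    threshold: float = 0.0
    threshold_source: str = "automatic"
    landmark: str | None = None
    failed: bool = False
    degenerate_histogram: bool = False
    sat_mask: np.ndarray | None = field(default=None, repr=False)
    vat_mask: np.ndarray | None = field(default=None, repr=False)
    envelope_mask: np.ndarray | None = field(default=None, repr=False)
    slice_ref: MRISlice | None = field(default=None, repr=False)


@dataclass
class VolumeReport:
    """Study-level volumes in litres plus the per-slice table."""

    sat_volume_l: float
    vat_volume_l: float
    tat_volume_l: float
    n_slices_used: int
    effective_slice_spacing_mm: float
    per_slice: list[SliceResult]
    n_slices_failed: int = 0
    source_id: str = ""


def histogram_fat_threshold(intensities: np.ndarray) -> float:
    """Histogram-based fat/lean threshold of envelope intensities.

    Otsu's criterion (maximum between-class variance) on a 256-bin
    histogram; pixels at or above the returned value classify as fat.
    Identical samples are a degenerate histogram: the threshold is placed
    one representable step above the common value so that the fat class is
    conservatively empty.
    """
    values = np.asarray(intensities, dtype=np.float64).ravel()
    if values.size < 2:
        raise InputError("need at least 2 intensity samples for a threshold")
    if values.max() == values.min():
        v = float(values[0])
        return v + np.spacing(np.abs(v) if v != 0 else 1.0)
    return float(threshold_otsu(values, nbins=256))


def _filled_envelope(boundary_set: BoundarySet, shape) -> np.ndarray:
    if boundary_set.envelope_mask is not None:
        return boundary_set.envelope_mask
    return boundary_set.envelope.filled(shape)


def vat_fat_mask(
    mri_slice: MRISlice, envelope, threshold: float
) -> np.ndarray:
    """Fat pixels inside the filled envelope (intensity >= threshold).

    ``envelope`` may be a Contour, a BoundarySet, or a boolean mask.
    Monotone in the threshold: raising it never adds pixels.
    """
    from .autoseg import Contour

    if isinstance(envelope, BoundarySet):
        env = _filled_envelope(envelope, mri_slice.shape)
    elif isinstance(envelope, Contour):
        env = envelope.filled(mri_slice.shape)
    else:
        env = np.asarray(envelope, dtype=bool)
    if not env.any():
        raise InputError("envelope is empty")
    return env & (mri_slice.pixels >= threshold)


def quantify_slice(
    mri_slice: MRISlice,
    boundary_set: BoundarySet,
    threshold_override: float | None = None,
    landmark: str | None = None,
) -> SliceResult:
    """Compute SAT/VAT areas (cm^2) and the fat threshold for one slice.

    SAT area counts pixels between the filled outer and inner boundaries;
    VAT area counts fat pixels inside the envelope.  A failed boundary set
    yields a failed result with zero areas.
    """
    if boundary_set.failed:
        return SliceResult(
            slice_index=boundary_set.slice_index,
            failed=True,
            landmark=landmark,
            slice_ref=mri_slice,
        )
    shape = mri_slice.shape
    outer = boundary_set.outer_mask
    inner = boundary_set.inner_mask
    env = _filled_envelope(boundary_set, shape)
    if outer is None:
        outer = boundary_set.outer.filled(shape)
    if inner is None:
        inner = boundary_set.inner.filled(shape)
    pixel_area = mri_slice.pixel_area_cm2

    sat_mask = outer & ~inner
    sat_area = float(np.count_nonzero(sat_mask)) * pixel_area

    env_values = mri_slice.pixels[env]
    degenerate = bool(env_values.size and env_values.max() == env_values.min())
    if threshold_override is not None:
        threshold = float(threshold_override)
        source = "manual"
    else:
        threshold = histogram_fat_threshold(env_values)
        source = "automatic"
    fat = vat_fat_mask(mri_slice, env, threshold)
    vat_area = float(np.count_nonzero(fat)) * pixel_area

    return SliceResult(
        slice_index=boundary_set.slice_index,
        sat_area_cm2=sat_area,
        vat_area_cm2=vat_area,
        threshold=threshold,
        threshold_source=source,
        landmark=landmark,
        degenerate_histogram=degenerate and threshold_override is None,
        sat_mask=sat_mask,
        vat_mask=fat,
        envelope_mask=env,
        slice_ref=mri_slice,
    )


def quantify_series(
    series: AbdomenSeries, boundary_sets: Sequence[BoundarySet]
) -> list[SliceResult]:
    """Quantify every segmented slice (convenience wrapper)."""
    results = []
    for bset in boundary_sets:
        mri_slice = series[bset.slice_index]
        results.append(
            quantify_slice(
                mri_slice,
                bset,
                landmark=series.landmarks.get(bset.slice_index),
            )
        )
    return results


def integrate_volumes(
    results: Sequence[SliceResult],
    series: AbdomenSeries | None = None,
    effective_spacing_mm: float | None = None,
) -> VolumeReport:
    """Sum per-slice areas into SAT/VAT/TAT volumes in litres.

    volume = sum(area_cm2) * spacing_cm / 1000; the effective spacing is
    thickness + gap, taken from the series unless given explicitly.
    Failed slices contribute zero and are counted separately.
    """
    results = list(results)
    if not results:
        raise QuantificationError("no slice results to integrate")
    if effective_spacing_mm is None:
        if series is None:
            raise InputError("need a series or an explicit effective spacing")
        effective_spacing_mm = series.effective_spacing_mm
    ok = [r for r in results if not r.failed]
    if not ok:
        raise QuantificationError("all slices failed; no volume to report")
    spacing_cm = effective_spacing_mm / 10.0
    sat_ml = sum(r.sat_area_cm2 for r in ok) * spacing_cm
    vat_ml = sum(r.vat_area_cm2 for r in ok) * spacing_cm
    sat_l = sat_ml / 1000.0
    vat_l = vat_ml / 1000.0
    return VolumeReport(
        sat_volume_l=sat_l,
        vat_volume_l=vat_l,
        tat_volume_l=sat_l + vat_l,
        n_slices_used=len(ok),
        effective_slice_spacing_mm=float(effective_spacing_mm),
        per_slice=results,
        n_slices_failed=len(results) - len(ok),
        source_id=series.source_id if series is not None else "",
    )


def annotate_landmark(
    series: AbdomenSeries, slice_index: int, label: str
) -> AbdomenSeries:
    """Attach an anatomical label (PF, FH, diaphragm, vertebral-body code)
    to a slice; re-annotation overwrites.  Returns the updated series."""
    if not label or not label.strip():
        raise InputError("landmark label must be non-empty")
    if not 0 <= slice_index < len(series):
        raise LandmarkError(
            f"slice index {slice_index} outside series of {len(series)} slices"
        )
    series.landmarks[slice_index] = label.strip()
    return series
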