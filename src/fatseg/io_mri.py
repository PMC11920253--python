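"""Reading and writing of abdominal MRI series and segmentation results.

An :class:`AbdomenSeries` is an ordered stack of axial :class:`MRISlice`
objects with physical geometry (in-plane pixel spacing, slice thickness and
interslice gap).  Series can be read from a classic single-frame DICOM
directory or from a NIfTI-1 volume; results are written as CSV reports,
NIfTI label volumes and PNG overlays.

Coordinate convention: pixel indices are row-major and 0-based; contours and
masks live in (row, col) pixel coordinates, and physical units enter only
when areas and volumes are computed.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import (
    DimensionalityError,
    InconsistencyError,
    InputError,
    LandmarkError,
    MetadataError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .vat_quant import SliceResult

__all__ = [
    "MRISlice",
    "AbdomenSeries",
    "read_dicom_series",
    "read_nifti_volume",
    "write_nifti_volume",
    "write_dicom_series",
    "write_results",
    "read_landmark_csv",
]

#: fixed header of the per-slice CSV report
REPORT_COLUMNS = (
    "slice_index",
    "slice_location_mm",
    "sat_area_cm2",
    "vat_area_cm2",
    "threshold",
    "threshold_source",
    "landmark",
    "failed",
)

SUMMARY_COLUMNS = (
    "source_id",
    "n_slices_used",
    "effective_slice_spacing_mm",
    "sat_volume_l",
    "vat_volume_l",
    "tat_volume_l",
)


@dataclass
class MRISlice:
    """One axial MR image with its physical geometry.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in arbitrary MR units.
    pixel_spacing_mm
        (row, col) spacing, both > 0.
    slice_location_mm
        Physical position along the table axis.
    slice_thickness_mm
        Excited slice thickness (> 0).
    interslice_gap_mm
        Gap to the neighbouring slice (>= 0).
    index
        Position in the parent series (0-based).
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_location_mm: float = 0.0
    slice_thickness_mm: float = 10.0
    interslice_gap_mm: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError("slice pixels must be a 2-D array")
        if min(self.pixels.shape) < 32:
            raise InputError(
                f"slice must be at least 32x32, got {self.pixels.shape}"
            )
        if np.any(self.pixels < 0) or not np.all(np.isfinite(self.pixels)):
            raise InputError("slice intensities must be finite and non-negative")
        rs, cs = self.pixel_spacing_mm
        if not (rs > 0 and cs > 0 and np.isfinite(rs) and np.isfinite(cs)):
            raise InputError("pixel spacing components must be positive finite")
        if not self.slice_thickness_mm > 0:
            raise InputError("slice thickness must be positive")
        if self.interslice_gap_mm < 0:
            raise InputError("interslice gap must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2."""
        rs, cs = self.pixel_spacing_mm
        return (rs * cs) / 100.0

    @property
    def effective_spacing_mm(self) -> float:
        """Slice-to-slice spacing = thickness + gap."""
        return self.slice_thickness_mm + self.interslice_gap_mm


@dataclass
class AbdomenSeries:
    """An ordered (caudal to cranial) stack of slices plus landmarks."""

    slices: list[MRISlice]
    landmarks: dict[int, str] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.slices:
            raise InputError("series must contain at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise InconsistencyError(f"slices have differing shapes: {shapes}")
        spacings = {tuple(np.round(s.pixel_spacing_mm, 6)) for s in self.slices}
        if len(spacings) > 1:
            raise InconsistencyError(
                f"slices have differing pixel spacing: {spacings}"
            )
        locs = [s.slice_location_mm for s in self.slices]
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise InconsistencyError(
                "slice locations must be strictly increasing"
            )
        for i, s in enumerate(self.slices):
            s.index = i
        for idx in self.landmarks:
            if not 0 <= idx < len(self.slices):
                raise LandmarkError(
                    f"landmark index {idx} outside series of {len(self.slices)} slices"
                )

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def __getitem__(self, i: int) -> MRISlice:
        return self.slices[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return self.slices[0].pixel_spacing_mm

    @property
    def effective_spacing_mm(self) -> float:
        return self.slices[0].effective_spacing_mm


# ---------------------------------------------------------------------------
# DICOM


def _dicom_location(ds) -> float:
    if getattr(ds, "SliceLocation", None) is not None:
        return float(ds.SliceLocation)
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        return float(ipp[2])
    raise MetadataError(
        f"file {getattr(ds, 'filename', '?')} has neither SliceLocation nor "
        "ImagePositionPatient"
    )


def read_dicom_series(directory_path: str | os.PathLike) -> AbdomenSeries:
    """Read a directory of single-frame DICOM files into a series.

    Slices are ordered by slice location (file names are irrelevant);
    RescaleSlope/Intercept are applied when present; the interslice gap is
    taken as ``SpacingBetweenSlices - SliceThickness`` (clamped at 0) and
    falls back to the location increment when the tag is absent.
    """
    import pydicom

    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # non-DICOM clutter in the directory
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((p, ds))
    if not datasets:
        raise InputError(f"no DICOM files with pixel data in {directory}")

    ref_path, ref = datasets[0]
    if getattr(ref, "PixelSpacing", None) is None:
        raise MetadataError(f"missing PixelSpacing tag in {ref_path.name}")
    ref_spacing = tuple(float(v) for v in ref.PixelSpacing)
    ref_shape = (int(ref.Rows), int(ref.Columns))

    entries = []
    for p, ds in datasets:
        if getattr(ds, "PixelSpacing", None) is None:
            raise MetadataError(f"missing PixelSpacing tag in {p.name}")
        shape = (int(ds.Rows), int(ds.Columns))
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        if shape != ref_shape:
            raise InconsistencyError(
                f"matrix size {shape} of {p.name} differs from {ref_shape} "
                f"of {ref_path.name}"
            )
        if not np.allclose(spacing, ref_spacing, rtol=1e-6):
            raise InconsistencyError(
                f"pixel spacing {spacing} of {p.name} differs from "
                f"{ref_spacing} of {ref_path.name}"
            )
        entries.append((p, ds, _dicom_location(ds)))

    entries.sort(key=lambda e: e[2])
    locations = [e[2] for e in entries]
    for (pa, _, la), (pb, _, lb) in zip(entries, entries[1:]):
        if lb == la:
            raise InconsistencyError(
                f"duplicate slice location {la} mm in {pa.name} and {pb.name}"
            )

    slices = []
    for i, (p, ds, loc) in enumerate(entries):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        arr = np.clip(arr, 0.0, None)  # magnitude images are non-negative
        thickness = float(getattr(ds, "SliceThickness", 0.0)) or None
        between = getattr(ds, "SpacingBetweenSlices", None)
        if thickness is None:
            thickness = 10.0 if between is None else float(between)
        if between is not None:
            gap = max(float(between) - thickness, 0.0)
        elif len(entries) > 1:
            step = locations[1] - locations[0]
            gap = max(step - thickness, 0.0)
        else:
            gap = 0.0
        slices.append(
            MRISlice(
                pixels=arr,
                pixel_spacing_mm=tuple(float(v) for v in ds.PixelSpacing),
                slice_location_mm=loc,
                slice_thickness_mm=thickness,
                interslice_gap_mm=gap,
                index=i,
            )
        )
    source_id = str(getattr(ref, "SeriesInstanceUID", directory.name))
    return AbdomenSeries(slices=slices, source_id=source_id)


def write_dicom_series(
    series: AbdomenSeries, out_dir: str | os.PathLike
) -> list[Path]:
    """Export a series as single-frame secondary-capture DICOM files.

    Intensities are rounded to uint16 (clipped at 0); intended for exercising
    the DICOM reader with synthetic data, not for clinical archiving.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for s in series:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.PatientName = series.source_id or "PHANTOM"
        ds.PatientID = series.source_id or "PHANTOM"
        ds.Rows, ds.Columns = s.shape
        ds.PixelSpacing = [f"{v:.6f}" for v in s.pixel_spacing_mm]
        ds.SliceThickness = f"{s.slice_thickness_mm:.6f}"
        ds.SpacingBetweenSlices = f"{s.effective_spacing_mm:.6f}"
        ds.SliceLocation = f"{s.slice_location_mm:.6f}"
        ds.ImagePositionPatient = ["0", "0", f"{s.slice_location_mm:.6f}"]
        ds.InstanceNumber = s.index + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        arr = np.clip(np.round(s.pixels), 0, 65535).astype(np.uint16)
        ds.PixelData = arr.tobytes()
        path = out / f"slice_{s.index:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti_volume(
    file_path: str | os.PathLike,
    slice_thickness_mm: float | None = None,
    interslice_gap_mm: float = 0.0,
) -> AbdomenSeries:
    """Read a 3-D NIfTI volume; axial slices are taken along the third axis.

    Pixel spacing and slice spacing come from the affine/zooms.  By default
    the whole slice spacing is attributed to the thickness with zero gap;
    pass ``slice_thickness_mm`` to split it explicitly (the gap is then
    ``interslice_gap_mm``).
    """
    import nibabel as nib

    img = nib.load(str(file_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, got {data.ndim}-D data in {file_path}"
        )
    zooms = img.header.get_zooms()[:3]
    step = float(zooms[2])
    if slice_thickness_mm is None:
        thickness, gap = step, 0.0
    else:
        thickness, gap = float(slice_thickness_mm), float(interslice_gap_mm)
    slices = []
    for k in range(data.shape[2]):
        slices.append(
            MRISlice(
                pixels=np.clip(np.asarray(data[:, :, k], dtype=np.float64), 0.0, None),
                pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
                slice_location_mm=k * step,
                slice_thickness_mm=thickness,
                interslice_gap_mm=gap,
                index=k,
            )
        )
    return AbdomenSeries(slices=slices, source_id=Path(file_path).stem)


def write_nifti_volume(
    series: AbdomenSeries, file_path: str | os.PathLike, dtype=np.float64
) -> Path:
    """Write a series as a 3-D NIfTI volume (lossless for float64)."""
    import nibabel as nib

    data = np.stack([s.pixels for s in series], axis=2).astype(dtype)
    rs, cs = series.pixel_spacing_mm
    step = series.effective_spacing_mm
    affine = np.diag([rs, cs, step, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((rs, cs, step))
    nib.save(img, str(file_path))
    return Path(file_path)


# ---------------------------------------------------------------------------
# Results


def _results_to_rows(series: AbdomenSeries, results: Sequence["SliceResult"]):
    for s, r in zip(series, results):
        yield {
            "slice_index": r.slice_index,
            "slice_location_mm": f"{s.slice_location_mm:.3f}",
            "sat_area_cm2": f"{r.sat_area_cm2:.4f}",
            "vat_area_cm2": f"{r.vat_area_cm2:.4f}",
            "threshold": f"{r.threshold:.6f}",
            "threshold_source": r.threshold_source,
            "landmark": series.landmarks.get(r.slice_index, ""),
            "failed": int(r.failed),
        }


def write_results(
    series: AbdomenSeries,
    results: Sequence["SliceResult"],
    out_dir: str | os.PathLike,
    formats: Iterable[str] = ("csv",),
) -> dict[str, Path]:
    """Write per-slice results and a volume summary.

    ``formats`` is a subset of {"csv", "nifti", "png"}.  CSV always produces
    a per-slice report plus a summary file with total volumes in litres;
    "nifti" adds a label volume (0 background, 1 SAT, 2 VAT fat) built from
    the masks stored on the results; "png" adds per-slice overlays.
    """
    from .vat_quant import integrate_volumes

    if not list(results):
        raise InputError("results list is empty")
    if len(results) != len(series):
        raise InputError(
            f"{len(results)} results for {len(series)} slices; need one per slice"
        )
    formats = {f.lower() for f in formats}
    unknown = formats - {"csv", "nifti", "png"}
    if unknown:
        raise InputError(f"unknown output formats: {sorted(unknown)}")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc

    manifest: dict[str, Path] = {}
    # the CSV report and summary are always written
    report_path = out / "slices.csv"
    with open(report_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
        writer.writeheader()
        for row in _results_to_rows(series, results):
            writer.writerow(row)
    manifest["csv"] = report_path

    report = integrate_volumes(results, series)
    summary_path = out / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SUMMARY_COLUMNS)
        writer.writeheader()
        writer.writerow(
            {
                "source_id": series.source_id,
                "n_slices_used": report.n_slices_used,
                "effective_slice_spacing_mm": f"{report.effective_slice_spacing_mm:.3f}",
                "sat_volume_l": f"{report.sat_volume_l:.6f}",
                "vat_volume_l": f"{report.vat_volume_l:.6f}",
                "tat_volume_l": f"{report.tat_volume_l:.6f}",
            }
        )
    manifest["summary"] = summary_path

    if "nifti" in formats:
        import nibabel as nib

        labels = np.zeros(series.shape + (len(series),), dtype=np.uint8)
        for r in results:
            if r.failed:
                continue
            if r.sat_mask is not None:
                labels[:, :, r.slice_index][r.sat_mask] = 1
            if r.vat_mask is not None:
                labels[:, :, r.slice_index][r.vat_mask] = 2
        rs, cs = series.pixel_spacing_mm
        affine = np.diag([rs, cs, series.effective_spacing_mm, 1.0])
        path = out / "labels.nii.gz"
        nib.save(nib.Nifti1Image(labels, affine), str(path))
        manifest["nifti"] = path

    if "png" in formats:
        import imageio.v3 as iio

        png_dir = out / "overlays"
        png_dir.mkdir(exist_ok=True)
        for s, r in zip(series, results):
            hi = np.percentile(s.pixels, 99.5) or 1.0
            gray = np.clip(s.pixels / hi, 0, 1)
            rgb = np.stack([gray] * 3, axis=-1)
            if not r.failed:
                if r.sat_mask is not None:
                    rgb[r.sat_mask] = 0.6 * rgb[r.sat_mask] + 0.4 * np.array([1.0, 1.0, 0.0])
                if r.vat_mask is not None:
                    rgb[r.vat_mask] = 0.6 * rgb[r.vat_mask] + 0.4 * np.array([0.0, 1.0, 0.0])
            path = png_dir / f"slice_{s.index:03d}.png"
            iio.imwrite(path, (rgb * 255).astype(np.uint8))
        manifest["png"] = png_dir

    return manifest


def read_landmark_csv(path: str | os.PathLike) -> dict[int, str]:
    """Read a landmark file with columns ``slice_index,label``."""
    landmarks: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "slice_index" not in reader.fieldnames:
            raise InputError(f"landmark file {path} needs slice_index,label columns")
        for row in reader:
            landmarks[int(row["slice_index"])] = row["label"].strip()
    return landmarks
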