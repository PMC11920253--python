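"""Automatic pre-segmentation of abdominal MR slices.

The pipeline produces, per axial in-phase slice, three nested boundaries:

* a refined **outer SAT contour** (the skin line of the body cross-section),
  from an adaptive local-mean threshold mask (bright polarity), the largest
  shape-consistent connected region, hole filling and boundary tracing;
* a refined **inner SAT contour** (the deep border of the subcutaneous fat
  ring), from the inverted (dark-polarity) adaptive mask restricted to the
  body;
* a crude **VAT envelope**, the visceral cavity mask eroded by a small disk,
  inside which a histogram threshold later separates fat from lean tissue.

All thresholds are relative to the local mean, so segmentation is invariant
to a global rescaling of the intensities.  There is no randomness anywhere
in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.draw import line as draw_line

from .errors import (
    EmptyMaskError,
    LandmarkError,
    NoValidRegionError,
    ParameterError,
    SegmentationFailure,
)
from .io_mri import AbdomenSeries, MRISlice

__all__ = [
    "Contour",
    "BoundarySet",
    "SegParams",
    "adaptive_binarize",
    "largest_valid_region",
    "fill_and_trace",
    "outer_sat_boundary",
    "inner_sat_boundary",
    "vat_envelope_boundary",
    "segment_slice",
    "segment_series",
    "export_contours_csv",
]

ROLES = ("outer_sat", "inner_sat", "vat_envelope")

# relative guard so exact ties (pixel equal to its local mean, the generic
# case inside homogeneous regions) never count as bright, robustly under
# float rounding and global intensity rescaling
_TIE_GUARD = 1e-9

# Moore neighbourhood in clockwise order (row down, col right), starting east
_N8 = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_N8_INDEX = {off: i for i, off in enumerate(_N8)}


@dataclass(frozen=True)
class Contour:
    """Closed pixel-space polygon with a role.

    ``points`` is an (N, 2) integer array of (row, col) vertices in clockwise
    order; the first vertex is logically joined to the last.  A single-pixel
    region yields a degenerate 1-vertex contour.
    """

    points: np.ndarray
    role: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
            raise ValueError("contour needs an (N, 2) array of vertices")
        object.__setattr__(self, "points", np.ascontiguousarray(pts, dtype=np.int64))
        if self.role not in ROLES:
            raise ValueError(f"unknown contour role {self.role!r}")

    def __len__(self) -> int:
        return len(self.points)

    def filled(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the closed polygon and fill its interior.

        Consecutive vertices are joined by 8-connected digital lines; the
        resulting closed curve is filled with 4-connected hole filling, the
        complementary pair that avoids topological paradoxes.  For contours
        traced from a filled region this reproduces that region exactly.
        """
        mask = np.zeros(shape, dtype=bool)
        pts = self.points
        if len(pts) == 1:
            mask[pts[0, 0], pts[0, 1]] = True
            return mask
        closed = np.vstack([pts, pts[:1]])
        for (r0, c0), (r1, c1) in zip(closed[:-1], closed[1:]):
            rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
            mask[rr, cc] = True
        return ndi.binary_fill_holes(mask)

    def shifted(self, dr: int, dc: int) -> "Contour":
        return Contour(self.points + np.array([dr, dc]), self.role)


@dataclass
class BoundarySet:
    """Per-slice triple of nested boundaries (or a flagged failure).

    For successful slices the filled masks satisfy
    ``envelope <= inner <= outer`` as pixel sets.
    """

    slice_index: int
    outer: Contour | None = None
    inner: Contour | None = None
    envelope: Contour | None = None
    outer_mask: np.ndarray | None = None
    inner_mask: np.ndarray | None = None
    envelope_mask: np.ndarray | None = None
    failed: bool = False
    message: str = ""
    warnings: tuple[str, ...] = ()

    @classmethod
    def failure(cls, slice_index: int, message: str) -> "BoundarySet":
        return cls(slice_index=slice_index, failed=True, message=message)

    def nesting_ok(self) -> bool:
        """True iff envelope within inner within outer as pixel sets."""
        if self.failed:
            return False
        return bool(
            not np.any(self.envelope_mask & ~self.inner_mask)
            and not np.any(self.inner_mask & ~self.outer_mask)
        )


@dataclass
class SegParams:
    """Tunable parameters of the automatic pre-segmentation.

    Windows are the side lengths of the square local-mean neighbourhoods
    (odd, in pixels).  The region-consistency criteria reject artefact
    components: a candidate must cover at least ``min_region_fraction`` of
    the image and have a best-fit-ellipse principal-diameter ratio of at
    most ``max_diameter_ratio``.  The VAT envelope candidate is additionally
    required to have eccentricity at most ``max_eccentricity`` and is eroded
    by a disk of ``erosion_radius_px`` pixels.
    """

    outer_window: int = 19
    inner_window: int = 17
    sensitivity: float = 1.0
    min_region_fraction: float = 0.02
    max_diameter_ratio: float = 4.0
    max_eccentricity: float = 0.97
    erosion_radius_px: int = 3
    candidate_windows: tuple[int, ...] = (15, 17, 19, 21)
    exclude_border_touching: bool = True

    def __post_init__(self) -> None:
        for name in ("outer_window", "inner_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ParameterError(f"{name} must be odd and >= 3, got {w}")
        for w in self.candidate_windows:
            if w < 3 or w % 2 == 0:
                raise ParameterError(
                    f"candidate windows must be odd and >= 3, got {w}"
                )
        if not 0 < self.sensitivity <= 1:
            raise ParameterError("sensitivity must lie in (0, 1]")
        if self.erosion_radius_px < 1:
            raise ParameterError("erosion radius must be >= 1")
        if not 0 <= self.max_eccentricity < 1:
            raise ParameterError("max_eccentricity must lie in [0, 1)")

    # -- plain-text config round trip ------------------------------------
    def to_config(self, path: str | Path) -> Path:
        lines = []
        for key, value in vars(self).items():
            if key == "candidate_windows":
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)

    @classmethod
    def from_config(cls, path: str | Path) -> "SegParams":
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            raw = raw.split("#", 1)[0].strip()
            if not raw:
                continue
            key, _, value = raw.partition("=")
            key, value = key.strip(), value.strip()
            if key == "candidate_windows":
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key == "exclude_border_touching":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("outer_window", "inner_window", "erosion_radius_px"):
                kwargs[key] = int(value)
            elif key in (
                "sensitivity",
                "min_region_fraction",
                "max_diameter_ratio",
                "max_eccentricity",
            ):
                kwargs[key] = float(value)
            else:
                raise ParameterError(f"unknown config key {key!r}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# primitive operations


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, MRISlice):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def adaptive_binarize(
    image,
    window: int,
    sensitivity: float = 1.0,
    polarity: str = "bright",
) -> np.ndarray:
    """Adaptive local-mean threshold mask.

    The per-pixel threshold is ``sensitivity`` times the mean intensity over
    the mirror-padded ``window x window`` neighbourhood.  Polarity "bright"
    marks pixels strictly above their threshold, "dark" is the exact
    complement (pixels at or below the threshold).
    """
    img = _as_pixels(image)
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window >= min(img.shape):
        raise ParameterError(
            f"window {window} must be smaller than both image dimensions {img.shape}"
        )
    if polarity not in ("bright", "dark"):
        raise ParameterError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    local_mean = ndi.uniform_filter(img, size=window, mode="mirror")
    threshold = sensitivity * local_mean
    bright = img > threshold * (1.0 + _TIE_GUARD)
    return bright if polarity == "bright" else ~bright


def _component_order(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, size, first raster index), largest first, raster tie-break."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    counts = np.bincount(flat)
    comps = [
        (int(l), int(counts[l]), int(f)) for l, f in zip(ids, first) if l != 0
    ]
    comps.sort(key=lambda t: (-t[1], t[2]))
    return comps


def largest_valid_region(mask: np.ndarray, params: SegParams) -> np.ndarray:
    """Largest 8-connected component passing the consistency criteria.

    Components are examined in decreasing pixel-count order (ties broken by
    the earliest pixel in row-major scan order); the first one that is both
    large enough (``min_region_fraction`` of the image) and compact enough
    (principal-diameter ratio of the best-fit ellipse at most
    ``max_diameter_ratio``) is returned.  Components touching the image
    border are treated as artefacts (noise, aliasing wrap) and rejected
    unless ``exclude_border_touching`` is disabled: the body cross-section
    always lies inside the field of view with an air margin.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask contains no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    props = {p.label: p for p in measure.regionprops(labels)}
    min_size = params.min_region_fraction * mask.size
    border_labels: set[int] = set()
    if params.exclude_border_touching:
        border_labels = set(np.unique(labels[0, :])) | set(
            np.unique(labels[-1, :])
        ) | set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    for lab, size, _first in _component_order(labels):
        if size < min_size:
            # ordered by size, so nothing later can pass either
            break
        if lab in border_labels:
            continue
        p = props[lab]
        minor = p.axis_minor_length
        if minor <= 0:
            continue
        if p.axis_major_length / minor > params.max_diameter_ratio:
            continue
        return labels == lab
    raise NoValidRegionError(
        "no connected component satisfies the size/shape criteria"
    )


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered clockwise outer-boundary pixels of a connected region.

    Moore-neighbour tracing with Jacob's stopping criterion (terminate when
    the first move is about to repeat).  The region must be connected under
    8-connectivity; a single pixel yields a 1-vertex result.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise EmptyMaskError("cannot trace an empty mask")
    h, w = mask.shape
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    contour = [start]
    p = start
    b = (start[0], start[1] - 1)  # west of start is background by construction
    first_move = None
    while True:
        i = _N8_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            j = (i + k) % 8
            q = (p[0] + _N8[j][0], p[1] + _N8[j][1])
            if 0 <= q[0] < h and 0 <= q[1] < w and mask[q]:
                nxt = q
                nb = (p[0] + _N8[(j - 1) % 8][0], p[1] + _N8[(j - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        move = (p, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        p, b = nxt, nb
        contour.append(p)
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.array(contour, dtype=np.int64)


def fill_and_trace(region_mask: np.ndarray, role: str = "outer_sat"):
    """Fill interior holes and trace the outer boundary.

    Returns ``(contour, filled_mask)`` with the guarantee that
    ``contour.filled(shape)`` equals ``filled_mask`` exactly.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise EmptyMaskError("cannot trace an empty region")
    filled = ndi.binary_fill_holes(region_mask)
    points = _moore_trace(filled)
    return Contour(points, role), filled


# ---------------------------------------------------------------------------
# boundary operations


def outer_sat_boundary(mri_slice: MRISlice, params: SegParams | None = None):
    """Outer SAT (skin) contour: bright adaptive mask -> largest valid
    region -> fill and trace.  Returns ``(contour, filled_body_mask)``."""
    params = params or SegParams()
    mask = adaptive_binarize(
        mri_slice, params.outer_window, params.sensitivity, "bright"
    )
    try:
        region = largest_valid_region(mask, params)
    except (EmptyMaskError, NoValidRegionError) as exc:
        raise SegmentationFailure(f"outer SAT boundary: {exc}") from exc
    return fill_and_trace(region, "outer_sat")


def inner_sat_boundary(
    mri_slice: MRISlice,
    outer_filled: np.ndarray,
    params: SegParams | None = None,
):
    """Inner SAT contour from the inverted adaptive mask inside the body.

    Returns ``(contour, filled_mask, warnings)``.  If no dark region exists
    inside the body (lipodystrophy-like slice), the outer boundary is reused
    as the inner one and a warning is recorded instead of failing.
    """
    params = params or SegParams()
    if not np.any(outer_filled):
        raise SegmentationFailure("inner SAT boundary: empty outer mask")
    dark = adaptive_binarize(
        mri_slice, params.inner_window, params.sensitivity, "dark"
    )
    candidate = dark & outer_filled
    try:
        region = largest_valid_region(candidate, params)
    except (EmptyMaskError, NoValidRegionError):
        contour, filled = fill_and_trace(outer_filled, "inner_sat")
        return contour, filled, ("inner_equals_outer",)
    contour, filled = fill_and_trace(region, "inner_sat")
    if np.any(filled & ~outer_filled):  # defensive; holes stay inside the body
        contour, filled = fill_and_trace(filled & outer_filled, "inner_sat")
    return contour, filled, ()


def vat_envelope_boundary(
    mri_slice: MRISlice,
    inner_filled: np.ndarray,
    params: SegParams | None = None,
):
    """Crude VAT envelope: best visceral-cavity candidate, eroded.

    For each candidate window, a dark-polarity mask restricted to the inner
    region proposes the visceral body; its largest component is scored by
    size subject to an eccentricity bound.  The winning candidate is filled
    and eroded by a disk (radius backed off stepwise if erosion would empty
    the mask).  Returns ``(contour, envelope_mask)``.
    """
    params = params or SegParams()
    if not np.any(inner_filled):
        raise SegmentationFailure("VAT envelope: empty inner mask")
    best_mask = None
    best_size = -1
    for window in params.candidate_windows:
        if window >= min(mri_slice.shape):
            continue
        dark = adaptive_binarize(mri_slice, window, params.sensitivity, "dark")
        candidate = dark & inner_filled
        if not candidate.any():
            continue
        labels = measure.label(candidate, connectivity=2)
        lab, size, _ = _component_order(labels)[0]
        comp = labels == lab
        ecc = measure.regionprops(comp.astype(np.uint8))[0].eccentricity
        if ecc > params.max_eccentricity:
            continue
        if size > best_size:
            best_size, best_mask = size, comp
    if best_mask is None:
        raise SegmentationFailure(
            "VAT envelope: no candidate satisfies the eccentricity bound"
        )
    filled = ndi.binary_fill_holes(best_mask)
    # erosion by a Euclidean disk of radius r == (distance to background) > r;
    # one distance transform serves every radius of the back-off
    dist = ndi.distance_transform_edt(filled)
    radius = params.erosion_radius_px
    eroded = dist > radius
    while not eroded.any() and radius > 1:
        radius -= 1
        eroded = dist > radius
    if not eroded.any():
        raise SegmentationFailure("VAT envelope: erosion emptied the mask")
    if measure.label(eroded, connectivity=2).max() > 1:
        # erosion may disconnect; keep the largest piece (raster tie-break)
        labels = measure.label(eroded, connectivity=2)
        lab, _, _ = _component_order(labels)[0]
        eroded = labels == lab
    contour, env_filled = fill_and_trace(eroded, "vat_envelope")
    return contour, env_filled


def segment_slice(mri_slice: MRISlice, params: SegParams | None = None) -> BoundarySet:
    """Compose the three boundary operations for one slice.

    Failures never propagate: a slice that cannot be segmented yields a
    flagged empty :class:`BoundarySet`.
    """
    params = params or SegParams()
    try:
        outer, outer_mask = outer_sat_boundary(mri_slice, params)
        inner, inner_mask, warnings = inner_sat_boundary(
            mri_slice, outer_mask, params
        )
        envelope, env_mask = vat_envelope_boundary(mri_slice, inner_mask, params)
    except SegmentationFailure as exc:
        return BoundarySet.failure(mri_slice.index, str(exc))
    bset = BoundarySet(
        slice_index=mri_slice.index,
        outer=outer,
        inner=inner,
        envelope=envelope,
        outer_mask=outer_mask,
        inner_mask=inner_mask,
        envelope_mask=env_mask,
        warnings=warnings,
    )
    if not bset.nesting_ok():  # defensive; construction guarantees nesting
        return BoundarySet.failure(mri_slice.index, "nesting invariant violated")
    return bset


def landmark_range(series: AbdomenSeries) -> tuple[int, int]:
    """Inclusive slice range between the pelvic-floor and diaphragm
    landmarks; the full series when either landmark is missing."""
    pf = dia = None
    for idx, label in series.landmarks.items():
        key = label.strip().lower()
        if key == "pf":
            pf = idx
        elif key == "diaphragm":
            dia = idx
    if pf is None or dia is None:
        return 0, len(series) - 1
    if pf > dia:
        raise LandmarkError(
            f"pelvic floor (slice {pf}) must not lie above the diaphragm (slice {dia})"
        )
    return pf, dia


def segment_series(
    series: AbdomenSeries, params: SegParams | None = None
) -> list[BoundarySet]:
    """Segment every slice in the landmark range (inclusive).

    Deterministic: identical input and parameters give identical output.
    """
    params = params or SegParams()
    lo, hi = landmark_range(series)
    return [segment_slice(series[i], params) for i in range(lo, hi + 1)]


def export_contours_csv(
    boundary_sets: Sequence[BoundarySet], path: str | Path
) -> Path:
    """Write contour vertices as CSV rows
    (slice_index, role, vertex_order, row, col)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "role", "vertex_order", "row", "col"])
        for bset in boundary_sets:
            if bset.failed:
                continue
            for contour in (bset.outer, bset.inner, bset.envelope):
                for k, (r, c) in enumerate(contour.points):
                    writer.writerow([bset.slice_index, contour.role, k, r, c])
    return Path(path)
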