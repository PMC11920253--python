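"""Programmatic corrections of automatic segmentation results.

Stands in for interactive expert review: a contour segment can be replaced
by a user-supplied polyline (endpoints snapped to the nearest contour
vertices), and the per-slice fat threshold can be overridden, with the VAT
area recomputed.  Accepted edits preserve the nesting invariant
(envelope within inner within outer); rejected edits leave the boundary set
untouched.  All edits can be recorded in an append-only log so that a
manual correction session is replayable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LinearRing

from .autoseg import BoundarySet, Contour, ROLES
from .errors import (
    GeometryError,
    InputError,
    NestingViolationError,
    SnapError,
)
from .vat_quant import SliceResult, vat_fat_mask

__all__ = [
    "ContourEdit",
    "apply_contour_edit",
    "override_threshold",
    "EditLog",
    "load_edit_script",
    "apply_edit_script",
]

DEFAULT_SNAP_PX = 5.0


@dataclass(frozen=True)
class ContourEdit:
    """A replacement polyline for a segment of one contour.

    The polyline endpoints must lie on (or within snap distance of) the
    existing contour; the contour arc between the snapped vertices is
    replaced by the polyline.
    """

    slice_index: int
    role: str
    polyline: np.ndarray  # (N, 2) float (row, col), N >= 2

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InputError(f"unknown contour role {self.role!r}")
        pts = np.asarray(self.polyline, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise InputError("polyline needs at least two (row, col) points")
        if np.allclose(pts[0], pts[-1]):
            raise InputError("polyline endpoints must be distinct")
        object.__setattr__(self, "polyline", pts)


def _is_simple_ring(points: np.ndarray) -> bool:
    """True if the closed polygon is simple (non-self-intersecting)."""
    pts = np.asarray(points, dtype=float)
    # drop consecutive duplicates (pixel-traced contours may contain them
    # after rounding)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    if len(pts) < 3:
        return False
    if np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        return False
    try:
        ring = LinearRing(pts)
    except Exception:
        return False
    return bool(ring.is_valid and ring.is_simple)


def _arc_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _arc_indices(i: int, j: int, n: int) -> list[int]:
    """Vertex indices from i to j inclusive, walking forward with wrap."""
    if j >= i:
        return list(range(i, j + 1))
    return list(range(i, n)) + list(range(0, j + 1))


def _candidate(contour_pts: np.ndarray, i: int, j: int, poly: np.ndarray,
               replace_forward: bool) -> tuple[np.ndarray, float]:
    """Build the polygon that replaces one arc by the polyline.

    ``replace_forward`` replaces the arc walking forward from vertex i to
    vertex j (wrapping); otherwise the complementary arc (j forward to i)
    is replaced.  The polyline runs i -> j.  Returns the new vertex array
    and the geometric length of the replaced arc.
    """
    n = len(contour_pts)
    if replace_forward:
        removed = contour_pts[_arc_indices(i, j, n)]
        kept = contour_pts[_arc_indices(j, i, n)]  # j .. i, stays in place
        body = poly  # i -> j, then kept interior j+1 .. i-1 closes the loop
    else:
        removed = contour_pts[_arc_indices(j, i, n)]
        kept = contour_pts[_arc_indices(i, j, n)]  # i .. j
        body = poly[::-1]  # j -> i, then kept interior i+1 .. j-1 closes
    interior = kept[1:-1]
    new_pts = np.vstack([body, interior]) if len(interior) else body
    return new_pts, _arc_length(removed)


def apply_contour_edit(
    boundary_set: BoundarySet,
    edit: ContourEdit,
    snap_px: float = DEFAULT_SNAP_PX,
) -> BoundarySet:
    """Replace a contour arc by the edit polyline; atomic and validated.

    Endpoints are snapped to the nearest contour vertices.  Of the two arcs
    between the snapped vertices, the one whose replacement yields a simple
    closed polygon is replaced; if both qualify, the shorter arc goes.  The
    resulting boundary set must still satisfy the nesting invariant,
    otherwise the edit is rejected and the original set is returned
    unchanged (an exception is raised; no in-place mutation ever happens).
    """
    if boundary_set.failed:
        raise InputError("cannot edit a failed boundary set")
    contour: Contour = getattr(boundary_set, {"outer_sat": "outer",
                                              "inner_sat": "inner",
                                              "vat_envelope": "envelope"}[edit.role])
    pts = contour.points.astype(float)
    poly = np.round(edit.polyline).astype(np.int64).astype(float)

    d_start = np.linalg.norm(pts - poly[0], axis=1)
    d_end = np.linalg.norm(pts - poly[-1], axis=1)
    i = int(np.argmin(d_start))
    j = int(np.argmin(d_end))
    if d_start[i] > snap_px or d_end[j] > snap_px:
        raise SnapError(
            f"polyline endpoints are {d_start[i]:.1f}/{d_end[j]:.1f} px from "
            f"the contour (snap distance {snap_px} px)"
        )
    if i == j:
        raise SnapError("polyline endpoints snap to the same contour vertex")
    # snap endpoints onto the contour vertices
    poly = poly.copy()
    poly[0] = pts[i]
    poly[-1] = pts[j]

    cand_a, len_a = _candidate(pts, i, j, poly, replace_forward=True)
    cand_b, len_b = _candidate(pts, i, j, poly, replace_forward=False)
    simple_a = _is_simple_ring(cand_a)
    simple_b = _is_simple_ring(cand_b)
    if not simple_a and not simple_b:
        raise GeometryError(
            "neither arc replacement yields a simple closed polygon"
        )
    if simple_a and simple_b:
        new_pts = cand_a if len_a <= len_b else cand_b
    else:
        new_pts = cand_a if simple_a else cand_b

    new_contour = Contour(np.round(new_pts).astype(np.int64), edit.role)
    shape = boundary_set.outer_mask.shape
    new_mask = new_contour.filled(shape)

    masks = {
        "outer_sat": boundary_set.outer_mask,
        "inner_sat": boundary_set.inner_mask,
        "vat_envelope": boundary_set.envelope_mask,
    }
    masks[edit.role] = new_mask
    nested = (
        not np.any(masks["vat_envelope"] & ~masks["inner_sat"])
        and not np.any(masks["inner_sat"] & ~masks["outer_sat"])
    )
    if not nested:
        raise NestingViolationError(
            f"edit of {edit.role} on slice {edit.slice_index} breaks "
            "envelope within inner within outer nesting; original contours kept"
        )
    updates = {
        "outer_sat": {"outer": new_contour, "outer_mask": new_mask},
        "inner_sat": {"inner": new_contour, "inner_mask": new_mask},
        "vat_envelope": {"envelope": new_contour, "envelope_mask": new_mask},
    }[edit.role]
    return replace(boundary_set, **updates)


def override_threshold(
    results: Sequence[SliceResult], slice_index: int, value: float
) -> list[SliceResult]:
    """Set a manual fat threshold on one slice and recompute its VAT area.

    Returns a new result list (the input is not mutated); repeated identical
    calls are idempotent.  Overriding a failed slice is an error.
    """
    results = list(results)
    idx = next(
        (k for k, r in enumerate(results) if r.slice_index == slice_index), None
    )
    if idx is None:
        raise InputError(f"no result for slice {slice_index}")
    old = results[idx]
    if old.failed:
        raise InputError(f"slice {slice_index} failed; nothing to override")
    if old.envelope_mask is None or old.slice_ref is None:
        raise InputError(
            "result lacks the envelope mask / slice reference needed to "
            "recompute the VAT area"
        )
    fat = vat_fat_mask(old.slice_ref, old.envelope_mask, float(value))
    vat_area = float(np.count_nonzero(fat)) * old.slice_ref.pixel_area_cm2
    results[idx] = replace(
        old,
        threshold=float(value),
        threshold_source="manual",
        vat_area_cm2=vat_area,
        vat_mask=fat,
    )
    return results


@dataclass
class EditLog:
    """Append-only record of applied corrections (the audit trail)."""

    entries: list[dict] = field(default_factory=list)

    def record_contour(self, edit: ContourEdit) -> None:
        self.entries.append(
            {
                "kind": "contour",
                "slice_index": edit.slice_index,
                "role": edit.role,
                "polyline": np.asarray(edit.polyline).tolist(),
            }
        )

    def record_threshold(self, slice_index: int, value: float) -> None:
        self.entries.append(
            {"kind": "threshold", "slice_index": slice_index, "value": value}
        )

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.entries, indent=2) + "\n")
        return Path(path)


def load_edit_script(path: str | Path) -> list[dict]:
    """Load a JSON edit script (list of contour/threshold records)."""
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise InputError("edit script must be a JSON list")
    for e in entries:
        if e.get("kind") not in ("contour", "threshold"):
            raise InputError(f"unknown edit kind {e.get('kind')!r}")
    return entries


def apply_edit_script(
    boundary_sets: Sequence[BoundarySet],
    results: Sequence[SliceResult],
    entries: Sequence[dict],
    snap_px: float = DEFAULT_SNAP_PX,
    log: EditLog | None = None,
) -> tuple[list[BoundarySet], list[SliceResult]]:
    """Apply a recorded correction session in order.

    Contour edits update the boundary sets (results for that slice are NOT
    re-quantified automatically; re-run quantify_slice if needed); threshold
    records override per-slice thresholds.  Returns updated copies.
    """
    bsets = list(boundary_sets)
    res = list(results)
    by_index = {b.slice_index: k for k, b in enumerate(bsets)}
    for e in entries:
        if e["kind"] == "contour":
            edit = ContourEdit(
                slice_index=int(e["slice_index"]),
                role=e["role"],
                polyline=np.asarray(e["polyline"], dtype=float),
            )
            k = by_index.get(edit.slice_index)
            if k is None:
                raise InputError(f"no boundary set for slice {edit.slice_index}")
            bsets[k] = apply_contour_edit(bsets[k], edit, snap_px)
            if log is not None:
                log.record_contour(edit)
        else:
            res = override_threshold(res, int(e["slice_index"]), float(e["value"]))
            if log is not None:
                log.record_threshold(int(e["slice_index"]), float(e["value"]))
    return bsets, res
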