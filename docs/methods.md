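# Methods

This note documents the models, parameters and numerical choices behind
`fatseg`, and what the synthetic phantoms do and do not establish about
behaviour on patient data.

## Segmentation model

The pipeline assumes axial in-phase gradient-echo abdominal MR images:
fat bright, lean tissue darker, air background near zero, one body
cross-section per slice lying fully inside the field of view. All
thresholds are *relative* (a multiple of the local mean intensity), so the
segmentation is invariant to global intensity scaling — absolute MR units
carry no information and none is used.

### Adaptive binarization

The per-pixel threshold is `sensitivity × mean` over a square, mirror-padded
neighbourhood. "Bright" marks pixels strictly above the threshold, "dark"
is the exact complement. Two numerical details matter:

* A relative tie guard of 1e-9 is added to the threshold before the
  comparison. A pixel deep inside a homogeneous region equals its own local
  mean *exactly* in exact arithmetic; in floating point the comparison
  would otherwise be decided by rounding noise of the separable mean
  filter, and would not survive intensity rescaling bit-identically. With
  the guard, ties are never bright (and always dark), deterministically.
* The statistic is the plain local mean (not median or Gaussian-weighted):
  it is the cheapest statistic with the required behaviour, and it is the
  only parameter-free choice compatible with the mirror-padded
  uniform-filter implementation. The sensitivity default is 1.00 for both
  polarities.

A consequence worth stating explicitly: a relative threshold cannot
distinguish homogeneous fat from homogeneous lean tissue — both equal
their local mean. The separation instead comes from *window-scale
contrast*: near every fat/lean or tissue/air edge, the local mean is
contaminated by the other tissue over about half a window (8–9 px at the
default 17–19 px windows), producing solid bright bands on the fat side
and solid dark bands on the lean side. The outer boundary is found because
the skin-edge bright band is a closed loop whose filled interior is the
body; the inner boundary because the visceral cavity is one dark component
walled off from the subcutaneous ring by the ring's inner bright band.
The default windows (19 px outer, 17 px inner, candidates 15–21 px) match
this geometry at ~1.1 mm pixels; for substantially different resolutions
they should be scaled accordingly.

### Region-consistency criteria

Candidate components are screened, in decreasing size order with row-major
first-pixel tie-breaking, by three criteria (all exposed in `SegParams`):

* `min_region_fraction` = 0.02 of the image area — rejects speckle;
* `max_diameter_ratio` = 4.0 on the major/minor axis lengths of the
  best-fit ellipse — rejects elongated artefacts (e.g. the bright stripe
  that gradient systems can produce at the image bottom);
* border exclusion (`exclude_border_touching`, default on) — rejects any
  component touching the image edge. The body always sits inside the FOV
  with an air margin, whereas background noise at ~50 % mask density
  percolates into a single image-spanning component that would pass the
  size and shape tests; contact with the border is what betrays it. This
  is what makes a slice with no body at all fail cleanly instead of
  returning a nonsense contour.

The defaults are deliberately permissive about body shape (a ratio of 4
admits very wide habitus) and strict about artefacts.

### Boundary tracing

Contours are ordered pixel polygons produced by Moore-neighbour tracing
(clockwise, Jacob's stopping criterion) on the hole-filled region. The
complementary connectivity pair — 8-connected components and curves,
4-connected hole filling — guarantees `contour.filled(shape)` reproduces
the traced mask exactly, so mask-based and contour-based area computations
can never disagree. A single-pixel region yields a degenerate one-vertex
contour rather than an error.

### VAT envelope

Dark-polarity candidates at several windows are scored inside the inner
mask by component size subject to an eccentricity bound (≤ 0.97); the
winner is filled and eroded. Erosion by a Euclidean disk of radius *r* is
implemented as thresholding the Euclidean distance transform at *r* —
mathematically identical for masks away from the border, and one transform
serves the whole radius back-off (if erosion would empty the mask the
radius steps down to 1 before the slice is declared failed). The default
radius of 3 px (~3 mm) pulls the crude envelope off the inner SAT edge so
the subsequent histogram threshold never sees subcutaneous fat.

Degenerate anatomy is tolerated: if no dark region exists inside the body
(lipodystrophy-like slices), the inner contour falls back to the outer one
with an `inner_equals_outer` warning instead of failing, so VAT can still
be quantified. With a zero-thickness fat ring the dark mask cannot reach
the skin line, leaving a residual SAT band of up to about half a window —
an inherent resolution limit of relative thresholding, not a bug.

## Fat/lean threshold and volumes

Otsu's criterion on a 256-bin histogram of the envelope intensities is
parameter-free and deterministic; classification is `intensity ≥
threshold` (fat bright on in-phase images; the ≥ convention is fixed and
documented). If all envelope intensities are identical the threshold is
placed one representable step above them: the fat class is conservatively
empty and the slice is flagged. Each slice gets its own threshold; the
manual override (`edit.override_threshold`) reproduces the expert's
slider, recomputes the VAT area, and is recorded as
`threshold_source = "manual"`.

Note that between well-separated intensity modes the between-class
variance is flat across empty histogram bins; any bin on that plateau is a
valid maximizer and all of them induce the same pixel partition. Tests
therefore check variance-maximality and partition agreement rather than a
specific plateau bin.

Areas are pixel counts times the physical pixel area (polygon formulas are
never used, keeping areas exactly consistent with the masks). Volumes are
`Σ area × (thickness + gap)`; the default 10.0 mm + 0.5 mm protocol gives
10.5 mm effective spacing, attributing gap tissue to the adjacent slice.
The landmark range (pelvic floor to diaphragm) is inclusive at both ends.

## Contour editing

An edit replaces the contour arc between the snapped polyline endpoints
(snap radius default 5 px, about the precision of a mouse click at this
resolution). Of the two candidate arcs, the one whose replacement yields a
simple polygon is replaced; if both qualify, the geometrically shorter arc
goes — the rule a user drawing a short correction segment expects. Edits
are atomic: the nesting invariant (envelope ⊆ inner ⊆ outer as pixel sets)
is re-validated and a violating edit leaves the boundary set untouched.
Edits apply to final contours only; they do not re-trigger the envelope
erosion. Sessions are serialized as JSON scripts and replayed in order,
giving a reproducible audit trail in place of a GUI.

## Agreement statistics

Subjects are matched by `source_id`, never by row order. The adjusted R²
uses the single-predictor formula 1 − (1 − r²)(n − 1)/(n − 2); the
Bland–Altman SD uses the n − 1 denominator and the conventional 1.96
multiplier for the limits of agreement. With zero-variance differences the
t-test is undefined: p is reported as 1 when the bias is also zero (the
self-comparison identity) and as NaN otherwise, so degenerate comparisons
do not silently claim significance. Dice of two empty masks is defined
as 1.

## Phantom

The phantom emulates the geometry of a 2D double-echo abdominal protocol:
480 × 480 matrix over a 530 mm FOV (1.104 mm pixels), 10.0 mm slices with
0.5 mm gap, ~30–40 slices, with a smooth cranio-caudal taper (0.88 at the
end slices). A subject is an elliptical body (defaults 180 × 140 mm
semi-axes) with a subcutaneous fat ring (inner ellipse 145 × 105 mm,
i.e. a 35 mm ring — a bariatric-cohort habitus) and 4–10 visceral fat
blobs (6–14 mm radius) placed uniformly, non-overlapping, at least 10 mm
clear of the ring inside the cavity. Intensities are bimodal: lean
40 ± 5, fat 130 ± 8 (well separated: the mode distance exceeds three
standard deviations, so the Otsu threshold falls strictly between the
means). Optional extras model known MR nuisances: a second-order
multiplicative bias field (signal varies smoothly across the FOV),
additive Gaussian noise with clipping at zero (magnitude images are
non-negative), and a bright stripe artefact at the image bottom. Geometry
is drawn from a seed that is independent of the noise seed, so
ground-truth masks are exactly noise-invariant; the `noise_free()` preset
(all SDs zero) gives piecewise-constant intensities for exact-recovery
tests.

Cohort ranges (body 160–200 × 120–155 mm, ring 25–45 mm, 30–40 slices)
were chosen once so that every draw is well-posed for the default windows:
the visceral cavity is always the largest dark component (larger than any
interior tie band inside a thick ring) and the skin-edge band always
clears the size criterion.

What the phantom does *not* model: realistic organ shapes and bowel
content (no fatty bowel contamination — on patients this is exactly the
case the manual threshold override exists for), partial-volume fading at
tissue edges, breathing motion, and two-stack intensity steps. Passing the
phantom suite therefore demonstrates the correctness of the machinery
(boundaries, nesting, thresholds, areas, volumes, statistics, determinism)
and its noise/artefact robustness — not clinical accuracy on patient data,
which requires reader validation.

## Problem sizes in the test suite

Unit tests run on 256 × 256 phantoms (same pixel size and windows as the
full geometry, so all window-to-structure relations are preserved); the
acceptance suite and `scripts/acceptance.py` use two full-size 20-subject
cohorts (~690 slices each), the cohort size at which the generator's
habitus variation is representative while a complete run stays at a few
minutes on one CPU.

## Known limitations

* Relative thresholding bounds achievable SAT accuracy near the skin when
  the fat ring is thinner than about half a window (~10 mm).
* The VAT envelope is deliberately crude; its erosion radius trades off
  excluding the SAT ring against losing peripheral VAT. Blobs closer than
  the radius to the cavity wall are partially excluded.
* Otsu assumes a bimodal envelope histogram; slices with almost no
  visceral fat degrade toward an arbitrary split and may need the manual
  override.
* Two-stack acquisitions are merged purely by slice location; no intensity
  harmonization between stacks is applied.
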