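# Methods

This note documents the models, conventions and numerical choices behind
`granulemetry`: what each stage computes, which parameters matter, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Coordinate and intensity conventions

Volumes are arrays indexed `(z, y, x)`; the voxel at index `(k, j, i)` has
its centre at `(k·dz, j·dy, i·dx)` nanometres.  The reference geometry is
the FIB/SEM acquisition pitch, 6.7 × 6.7 × 20 nm³ (`REFERENCE_GEOMETRY`);
every length parameter in the package is physical (nm) and converted
per-axis, so anisotropic stacks need no special handling by the caller.

Grey values carry 8-bit semantics and are **density-coded**: a denser
(more condensed) core has a *higher* grey value, which makes the published
lighter/denser boundary at grey level 190 directly applicable.  Input with
detector polarity (dark cores on bright background) is handled by the
`invert` flag, which maps `g → 255 − g` before any processing.  Grey levels
are comparable only within one imaging run, which is why the classification
threshold is a parameter rather than a constant of nature.

## Dense-core detection (`coredetect`)

The detector implements a five-stage pipeline:

1. **Background and noise.**  The local background is the grey-scale
   morphological opening (erosion, then dilation) with a flat structuring
   element whose physical radius (default 400 nm) exceeds the largest core
   radius, so cores are erased from the estimate while slow illumination
   trends survive.  The default element is an anisotropic *box*, because box
   min/max filters are separable and O(N) per axis; an *ellipsoid* element
   is available (`background_element="ellipsoid"`) and both agree exactly
   with a brute-force min-then-max filter in the test suite.  The box is the
   pragmatic choice at full-volume scale — a dense ellipsoidal footprint of
   this radius costs ~10⁴ operations per voxel.  The noise level is the
   robust scale `1.4826 × MAD` of the residual restricted to voxels at or
   below the residual's median, which keeps the bright cores out of the
   estimate.

2. **Subtraction and smoothing.**  The residual is `max(image − background,
   0)`, Gaussian-smoothed at a physical scale (default 12 nm; per-axis
   sigmas `12/6.7 ≈ 1.8` voxels laterally, `12/20 = 0.6` axially).  The
   scale is chosen well below the smallest core radius so that cores remain
   flat-topped plateaus while single-voxel noise is suppressed.

3. **Baseline rectification and centre candidates.**  A min-filter over n
   samples of noise sits several noise-sd below the true background, so the
   opening-based background is biased low by a *spatially uniform* offset
   and the residual floats on a constant pedestal.  `detect_cores` re-zeroes
   the residual at its median before thresholding; relative quantities
   (prominence multiples, the normalized segmentation threshold) then refer
   to true prominence above background.  Candidates are the 26-connected
   components of residual above `prominence_threshold × noise` (default 6;
   note the MAD-based noise statistic evaluates to ≈0.6 of the true sd, so
   this is ≈3.5 true sd, and smoothing lowers the noise on the residual by
   a further order of magnitude).  One candidate is emitted per component at
   its residual-weighted centroid, with the component maximum as its peak.
   Components are used instead of strict 3×3×3 maxima deliberately: a
   rendered (or real, well-stained) core is a plateau much wider than the
   smoothing scale, and strict maxima on a noisy plateau are numerous and
   arbitrarily placed, whereas a supra-threshold component is exactly one
   maximum of the stated prominence.  Candidates closer than
   `min_separation_nm` (default 120 nm) collapse to the higher-peaked one,
   ties broken by lexicographic voxel order for determinism.

4. **Segmentation.**  Each core is the 26-connected set of voxels with
   residual at or above `k × peak` that contains the candidate centre, with
   `k = 0.5`.  For a sharp-edged core blurred by the smoothing kernel the
   half-height surface tracks the true boundary; the residual curvature bias
   is ≈ `σ²/R` per side (≈1 nm at σ = 12 nm, R = 120 nm), which is the
   dominant — and small — size bias of the pipeline.  Candidates whose
   centre voxel falls below their threshold (e.g. the centroid of a
   membrane ring lands in the clear halo) are dropped as degenerate.
   Detections are deduplicated in descending-peak order: a segment that
   overlaps an already-claimed voxel set is the same core seen twice, not a
   new core.

5. **Filters.**  Explicit rejection rules, all configurable: equivalent
   diameter outside `[100, 800]` nm; centre within a border margin of a
   volume face (default: the core's own equivalent radius — a clipped core
   biases both size and grey); mean contrast over local background below
   3 × noise; and solidity (measured volume over the volume of the
   equivalent sphere) below 0.4, which removes thin arcs of delimiting
   membrane that would otherwise masquerade as small cores.  Dense cores
   are filled condensates with solidity near 1, so the 0.4 floor is
   permissive.

Mean core grey is always measured on the **original** image over the
segmented voxel set, never on the background-subtracted residual.

## Morphometry (`morphometry`)

**Grouping.**  Membrane shells are not segmented (granule contours were
drawn manually in the workflow this package systematizes), so "two cores
within one limiting membrane" is decided by an envelope proxy: two cores
belong to one granule iff their voxel sets, dilated by the envelope radius
(default 50 nm = halo + membrane width), intersect — equivalently their
minimum separation is ≤ 100 nm.  Granules are connected components of this
relation.  With the generator's geometry the rule has clean margins: fused
partner cores sit 60 nm apart, distinct granules at least 130 nm.

**Size.**  The equivalent diameter mirrors the maximal-cross-section
convention: per z-plane area = in-plane voxel count × dx·dy, and
`d = 2·sqrt(A_max/π)` for the largest plane.  Note this is measured on the
dense core(s); the membrane-to-membrane granule diameter exceeds it by
twice the halo + membrane width (100 nm under generator defaults), which is
how phantom recoveries are compared to planted granule diameters.

**Regions.**  The plasma-membrane distance is an anisotropic Euclidean
distance transform of the cell mask in nm.  A granule is *periphery* if its
centre lies within 1 µm of the membrane, else *golgi* if its centre voxel is
inside the Golgi ("basket") mask, else *other*.  Periphery takes precedence
for robustness against invalid annotations, though valid masks cannot
overlap the periphery band.

**Classification and summaries.**  Lighter iff mean core grey < threshold
(default 190); grey exactly at the threshold counts as denser — a single
rule that reproduces the published wild-type counts.  Summaries report per
region × class counts, proportions (percent, one decimal, round-half-up)
and mean ± SEM with the sample sd (n−1).  Distribution comparisons use the
two-sample Kolmogorov–Smirnov test with the asymptotic p-value.

## 3D fusion counting (`fusion3d`)

A fusion event is a granule with ≥ 2 cores (a triplet counts once; none are
expected at the planted rates).  The frequency statistic is the per-cell
mean ± SEM of `1000 × events/granules` — cells are the independent units,
which is the aggregation that reproduces 8.2 ± 0.8 per 1,000 granules from
the per-cell counts 19/2632, 4/532, 22/2253.  Pooling events over pooled
granules would weight cells by size and gives a different number.

## Fluorescence fusion assay (`fluorassay`)

Spots are strict 3×3 local maxima of the rectified residual above
10 × the MAD noise statistic (≈6 true sd), with sub-pixel centres from the
intensity-weighted centroid of the 3×3 neighbourhood around the peak.  The
3×3 centroid systematically shrinks the sub-pixel offset toward the peak
pixel; at the default point-spread sigma of 0.8 px the error stays below
≈0.2 px, comfortably inside the 1 px coincidence gate.  Maxima — not
connected components — are the right primitive here because puncta are
diffraction-limited peaks that may share a supra-threshold region when
5 px apart.

A fusion event is a green/red pair with centre distance strictly < 1 px and
peak-intensity fold-difference strictly < 3 (the crosstalk gate); matching
is one-to-one, greedy by ascending distance.  Greedy matching equals
maximum matching whenever same-channel spots are separated by at least
twice the distance gate (then no spot has two admissible partners); that is
the operating regime of the assay (resolvable puncta) and the regime the
equivalence tests enumerate.  The fusion rate is events over total green
spots; fields are pooled before dividing (a per-field option exists).

## Secretion statistics (`secretionstats`)

The proinsulin/insulin ratio is `100 × proinsulin/insulin` on group means,
round-half-up to one decimal — 5/150 pM → 3.3 %, 78/198 pM → 39.4 %.
`mean_sem` implements the shared mean ± SEM convention, flagging n = 1 as
degenerate (SEM reported 0).  Reports assemble section dictionaries with
deterministic ordering and echo inputs unchanged; the statistical test
applied to any comparison is recorded by name rather than auto-selected.

## Synthetic phantoms (`synth`)

**EM phantoms.**  A granule is rendered as a spherical core at its sampled
grey, a clear halo ring at background level (default width 40 nm), and a
10 nm membrane shell at intermediate grey (default 140).  The cell is a box
inset from the volume faces; the Golgi region is an ellipsoid at the cell
centre, at least 1 µm clear of the boundary so centre-based region labels
are unambiguous.  Placement is sequential rejection sampling (10,000
attempts per granule) with non-partner membrane envelopes kept ≥ 30 nm
apart; infeasible densities raise a placement error naming the region.

Fused doublets are two disjoint cores separated by a 60 nm clear gap inside
one continuous membrane envelope (the union of the two overlapping granule
spheres).  Two choices here are deliberate.  First, the cores do not touch:
the morphological definition of a fusion intermediate is two *distinct*
cores in one membrane, and contiguous cores would be a single blob to any
detector (and to an annotator).  Second, the gap is 60 nm rather than one
halo width (40 nm): with 12 nm smoothing and a 20 nm axial pitch the
sub-threshold dip between cores 40 nm apart is thinner than one z-slice
and discrete sampling can bridge it, fusing the two components; at 60 nm
the dip spans ≈35 nm and is always sampled, while remaining well inside
the 100 nm grouping reach.

Default populations are anchored to the measured wild-type values: granule
diameters (membrane-to-membrane) truncated-normal with mean 344 nm in the
periphery and 280.7 nm in the Golgi region; sds 72 and 59 nm (the printed
SEMs times √n); core grey a two-component mixture at 170 and 215 (sd 8)
straddling the 190 boundary, with lighter-core weights 0.8 % (periphery)
and 11.7 % (Golgi); fused-doublet rate 8 events per 1,000 granules.
Truncation bounds ([210, 600] and [190, 470] nm) keep core diameters above
the detector's 100 nm filter floor.  Sampled core greys are rounded to
integers so that 8-bit quantization preserves them exactly and noise-free
grey recovery is exact.  Noise is additive Gaussian (default sd 5 grey
levels), clipped to [0, 255].

What the phantoms do *not* emulate: SEM texture inside cores and cytoplasm,
charging/curtaining/milling artifacts, membrane deformation, organelles
other than granules, non-ellipsoidal Golgi geometry, and grey-level
gradients within a core.  Passing recovery tests therefore demonstrates
that the measurement chain is unbiased under the stated geometric and
statistical structure — not that detection is solved for arbitrary tissue.

**Fluorescence phantoms.**  Gaussian spots (sigma 0.8 px) on a uniform
background with Gaussian noise; a binomial fraction (default 7.7 %) of
green spots receives a coincident red partner at a truncated-normal offset
(sigma 0.2 px, capped at 0.5 px) with a log-uniform intensity ratio within
2-fold; unpaired red spots are kept ≥ 6 px from every green spot so chance
coincidences are excluded by construction and the planted fraction is the
ground-truth rate.

**Thin sections.**  `simulate_thin_sections` samples a slab through a
sphere with the slab centre uniform over the sphere's extent; the apparent
diameter is the largest cross-section inside the slab — the full diameter
when the slab contains the equator, otherwise the chord
`D·sqrt(1 − (2h/D)²)` at the nearer slab edge.  At zero thickness the mean
apparent diameter is exactly `π/4 · D ≈ 0.785 D`, the classical
underestimation that motivates whole-volume imaging; a slab at least as
thick as the sphere always reports the true diameter.  The centre-uniform
convention (rather than "any intersecting slab position") is what makes
both limits exact.

## Problem sizes

The bundled benchmarks run on one CPU in minutes: the detection benchmark
uses one 512 × 512 × 128 phantom with 200 granules (≈12 s end to end);
parameter recovery pools 20 seeded 512 × 512 × 160 phantoms with 3 Golgi +
35 periphery granules each (≈25 s per phantom) and 20 fluorescence fields
of 300 + 300 spots; the sectioning limit uses 10⁶ sections.  The per-region
counts trade statistical power against runtime; pooled they give ≈700
periphery and ≈60 Golgi granules, enough to resolve the ≈3 nm residual
size bias against its 2-SEM gate and the planted class fractions against
binomial intervals.

## Known limitations

- The equivalent diameter is core-based; converting to granule diameter
  requires the halo + membrane width, which on real data must come from
  annotation or an assumed constant.
- Grey-opening background assumes the background varies on scales larger
  than the structuring radius; strong gradients inside one radius leak into
  the residual.
- The solidity filter assumes compact cores; genuinely crescent-shaped
  cores (not observed in this system) would be rejected.
- Greedy colocalization matching can be sub-optimal in crowded fields where
  same-channel spots sit closer than twice the distance gate.
- The per-cell SEM is meaningless for a single cell and is reported as 0
  with a degeneracy flag.
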