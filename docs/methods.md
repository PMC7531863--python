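# Methods

## Problem setting and assumptions

The tool segments one cell's nucleus, nuclear envelope (NE) and the
surrounding resin background in an SBF-SEM stack.  It assumes:

- a single cell of interest, centred in the 3D crop, possibly surrounded
  by fragments of neighbouring cells at the crop periphery;
- the resin background is brighter than any cellular structure, and the
  NE is darker than both nucleoplasm and cytoplasm;
- intensities are on an 8-bit scale after acquisition-side contrast
  adjustment (16-bit inputs are min-max rescaled per stack on load);
- the stack is aligned (no inter-slice registration is performed).

All processing is per-slice 2D except the overlap propagation, which is
the only place the volumetric structure is used.  Everything is
deterministic; the only random number generator in the package lives in
the phantom generator and is fully seeded.

## Pipeline stages and parameters

**Low-pass filter.** Normalized Gaussian window, size 7, σ = 2 px,
borders by edge replication.  Chosen for the grainy high-frequency noise
of blockface imaging; constants are preserved exactly because the kernel
is normalized.

**Canny edges.** Applied to the filtered slice with scale
`canny_sigma = 2` px (default).  Hysteresis thresholds are fractions of
the 8-bit range: `low = 0.02`, `high = 0.04`.  These were derived from
the gradient budget rather than guessed: after the σ=2 pre-filter plus
the Canny-internal smoothing, the weakest class step the pipeline relies
on (≈50 grey levels, NE against cytoplasm) produces a peak gradient
response of ≈0.057 of range and the strongest (≈80 levels) ≈0.09, while
the gradient of Gaussian pixel noise with σ = 10 grey levels tops out
near 0.011.  The defaults sit between the noise ceiling and the weakest
signal with roughly 2× margin on each side.  All three values are exposed
parameters since real acquisitions differ in contrast.

**Edge dilation.** Pixels within Euclidean distance
`d = max(min_distance, sigma_gain · canny_sigma)` of an edge join the
edge mask (`min_distance = 5`, `sigma_gain = 2`).  The coupling to the
Canny scale expresses that a coarser detector localizes edges more
sparsely and needs a larger reconnection radius; the multiplicative form
with a floor is this package's choice.  Euclidean (not chessboard)
distance keeps the dilation isotropic.

**Superpixels and cleanup.** The complement of the dilated edges is
labelled with 8-connectivity; region size is unrestricted.  Cleanup, in
order: drop border-touching regions (in a tight crop the resin and the
cropped cytoplasm reach the border; the nucleus never does), drop
regions below `min_region_fraction = 0.001` of the slice area, fill
enclosed holes, then smooth with closing-then-opening by a disk of
radius 3.  Cleanup re-clears the one-pixel image frame so no accepted
mask ever touches the border.

**Nucleus selection.** At the central slice (default `n//2`,
overridable) the nucleus is the candidate maximizing
`area / (1 + ‖centroid − image centre‖)` — a single score resolving the
trade-off between "centrally positioned" and "largest".  On every other
slice the union of all candidates overlapping the previously accepted
nucleus by at least `min_overlap_pixels = 1` is accepted; no overlap
means the candidate is a floating island and is discarded.  The
reference is the single adjacent accepted slice, not an accumulated
union, so the rule is symmetric under stack reversal.

**Band reclamation (scale correction).** The superpixel support excludes
the dilated-edge band, so an accepted region systematically
under-covers its structure by `d` plus the one-pixel width of the Canny
chain.  At full acquisition scale (nucleus radius ~700 px) this ~6 px
bias is negligible; at the phantom's desk scale (radius ≤ 65 px) it would
dominate the error budget.  The accepted mask is therefore re-expanded by
`d + 1` px before use.  The same consideration applies to the
background stage below.

**Background segmentation.** Same front end (filter, Canny, dilation,
superpixels), then a region qualifies as background when it is
simultaneously

- *bright*: region mean ≥ `max(Otsu threshold of the slice, floor)` with
  `floor = 140` (≈0.55 of range).  Otsu alone is relative and would
  select the brightest *cellular* region on degenerate or
  contrast-inverted data; the absolute floor encodes that resin is
  bright in absolute terms on contrast-adjusted 8-bit data.  On flat
  slices (Otsu undefined) only the floor applies.
- *large*: area ≥ `background_min_region_fraction = 1e-4` of the slice.
  This is deliberately smaller than the nucleus-side threshold: in a
  tight crop the resin survives only as corner slivers after the edge
  band is subtracted.
- *border-touching* (default on): the resin surrounds the centred cell
  and always reaches the crop boundary.

The excluded edge band is then reclaimed in two steps: every edge pixel
joins its nearest uniform region (nearest-region assignment extends the
selection back to the physical boundaries even where two edge bands
overlap across a narrow resin channel), and band pixels whose *raw*
intensity exceeds the brightness cut and that 8-connect to the selection
are absorbed (a channel narrower than `2(d+1)` has no interior pixels at
all, but its intensity is unambiguous).  Finally a closing (computed on
an edge-replicated pad so the image frame is not eroded) and removal of
enclosed holes smaller than `min_region_fraction` of the slice produce a
uniform background.  Large holes are kept on purpose — the centred cell
itself is an enclosed hole in the resin.

**Four-class composition.** The NE class is a band of
`ne_band_thickness = 5` px straddling the nucleus boundary
(`ceil(t/2)` out, `floor(t/2)` in, Euclidean distance with a half-pixel
contour offset so rasterized areas match analytic annulus areas).  The
true NE of a real annotation is a manual tracing; the band is a
reproducible proxy with configurable thickness.  Priority on conflicts
is fixed: envelope > nucleus > background > cell, which makes the output
a partition by construction.

**Metrics.** Accuracy `(TP+TN)/total` and Jaccard `TP/(TP+FP+FN)` per
slice; multi-class label maps are binarized one-vs-rest.  Both-empty
Jaccard is defined as 1.0 (perfect agreement on absence) — this matters
on pole slices where the nucleus does not exist and the prediction is
correctly empty.  Accuracy ≥ Jaccard always holds (TN only ever helps
accuracy).  Headline summaries (mean/median/min/max) are restricted to
the central slice band, by default the interquartile range `[0.25n,
0.75n]` of slice indices.

## The phantom generator

The phantom emulates the *structure* the algorithm exploits, at desk
scale (default 32 slices of 256×256 standing in for 300 slices of
2000×2000): bright resin (mean 200), a darker cell (120) whose
cross-section reaches the crop border on every slice with resin visible
in the corners, a nucleus (150) bounded by a darker NE band (70, 5 px),
additive Gaussian noise (σ = 10) for graininess, and dark neighbour-cell
fragments clipped to the resin at the borders.  Geometry is ellipsoidal
— cell semi-axes (30, 160, 160) voxels, nucleus (10, 65, 65) — so the
nucleus is absent near both stack poles.  Two optional features exercise
the propagation rules: `lobe_slices` splits the nucleus into two
disjoint lobes that overlap the preceding single cross-section, and
`island` adds a nucleus-intensity blob whose slice range is z-disjoint
from the nucleus (ground-truth class *cell*: it is not part of the
central nucleus and must be discarded).

The tight crop is deliberate and load-bearing: the cleanup rule that
discards border-touching regions is what removes the background and
cytoplasm candidates.  In real acquisitions the cytoplasm is additionally
shattered into small superpixels by organelle edges; the phantom's
cytoplasm is uniform (organelles, chromatin texture and EM physics are
out of scope), so border contact is the mechanism that keeps the
candidate set realistic.  Consequently, passing tests demonstrate the
slice pipeline, the propagation logic and the metric machinery — they do
not demonstrate robustness to organelle clutter, membrane gaps, staining
gradients or registration error, none of which the phantom contains.

Intensity means, noise level and geometry are all validated invariants
of `PhantomSpec` (background strictly brightest, envelope strictly
darkest of the cellular classes, nucleus strictly inside the cell);
identical specs and seeds give voxel-identical stacks.

## Numerical and degenerate-input choices

- Distance thresholds are inclusive (`≤ d`); dilation of an empty mask is
  empty; a constant slice yields no Canny edges and a single superpixel.
- 16→8-bit conversion is linear min-max per stack (not per slice) to
  avoid inter-slice brightness jumps.
- A stack with no accepted nucleus anywhere returns all-empty masks, not
  an error; an all-dark slice has no background.
- Label maps are stored bit-exactly as 8-bit PNG/TIFF with values
  0=background, 1=cell, 2=NE, 3=nucleus; loaders reject anything else.
- The slice where propagation starts defaults to `floor(n/2)`; on a
  mirrored stack with the mirrored start index the output is exactly the
  mirrored output.

## Problem sizes

The bundled test suite and the acceptance script run the full pipeline
on 32×256×256 phantoms (several seconds per volume on one CPU), the
metric and stage oracles on 64×64 instances, and the end-to-end CLI
checks on a 12×128×128 phantom.  These sizes keep each stage's geometry
meaningfully larger than every structuring element while remaining
desk-scale.

## Known limitations

- The NE class is a symmetric boundary band, not a tracing of the true
  bilayer; comparisons against a manual ground truth with a different
  envelope convention require adjusting `ne_band_thickness`.
- The brightness floor assumes contrast-adjusted 8-bit data; raw
  unadjusted acquisitions may need a different floor or the Otsu-only
  setting.
- Propagation is first-order (one adjacent slice); a nucleus that
  vanishes for a full slice and reappears is lost.
- A cell that does not reach the crop border on some slice can leave its
  cytoplasm as a candidate region; the central-position score usually —
  but not provably — prefers the nucleus.
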