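# Methods

This note records the model, the parameter choices that matter, what the
synthetic data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## The detection model

The pipeline treats cell detection as a deterministic rule system on
denoised images rather than a statistical estimation problem.  The
rationale: immunofluorescence staining of lymphoma tissue is extremely
inhomogeneous — a single macrophage can span a wide intensity range — so
no single global threshold separates cells from background.  The
floating-threshold scheme sidesteps this by sweeping the threshold from
bright to dark and testing every connected component at every level.  A
bright cell core surfaces early and accretes dimmer rim pixels as the
threshold falls; the moment its pixel count enters the size window
`[s_min, s_max]` it is tested against two shape rules:

* **Elongation** — the ratio `r(F)` of the principal axes of the
  minimum-area ellipse covering the feature must not exceed `r_max`.
  This is a covering ellipse, not a moment fit: a moment ellipse of a
  non-convex feature does not contain it, and the rule is meant to bound
  the feature's true extent.
* **Convexity** — the filled convex hull may exceed the feature itself
  by at most `c_max` percent (`c/s ≤ 1 + c_max/100`), which rejects
  ramified or ring-shaped components that no cell produces.

Features that pass are written to the segment mask and masked out of the
sweep; features that fail inside the window, and oversized features, are
masked without being written, so nothing is classified twice.  Components
below the window are left alone — they may merge and re-enter later.

One reconstruction choice deserves emphasis: a component that touches
(8-adjacency) pixels that were already masked is *skipped* — left in the
image but never classified.  Such components are the growing rim of an
object that has already been decided.  Without this, the rim of an
accepted cell re-enters the sweep as a ring feature; rings have hull
excess `c/s ≈ 2`, which the published nucleus bound (`c_max = 150`, i.e.
`c/s ≤ 2.5`) does not reject, and each cell accretes several accepted
rings into one oversized detection.  Skipping previously-touched
components makes detection single-shot per object.  The cost is that two
genuinely distinct cells whose binarizations ever become adjacent within
the sweep can shadow one another; on tiles where cells are densely
packed this trade-off would need revisiting.

## Channel recipes and their parameters

| channel | enhancement | size window (px) | r_max | c_max |
|---------|-------------|------------------|-------|-------|
| DAPI, run 1 | c = 0.75, 11×11 | 60–119 | 2.5 | 150 |
| DAPI, run 2 | c = 0.75, 11×11 | 120–180 | 2.5 | 150 |
| Pax5 | c = 0.1, 15×15 | 80–159 | 2.5 | 150 |
| CD14 / CD163 | none | 150–2000 | 4.0 | 300 |

The DAPI and Pax5 rows are the published operating point for nuclei of
lymphoid tissue at 0.45 µm/px.  The macrophage bounds are this package's
defaults (exposed in the config): macrophages are several times larger
than nuclei, lobed and far from convex, hence the wide window and loose
shape bounds.

The second DAPI run keeps only features completely disjoint from the
first run's output, and the Pax5 recipe keeps only features whose pixel
set touches the convex hull of some detected nucleus — the hull rather
than the nucleus itself, because the Pax5 signal (a transcription
factor) fills the nucleus but the two channels' segmentations do not
align pixel-perfectly.  Double-stained macrophages are detected by
convex-hull overlap between the CD14 and CD163 segmentations for the
same reason.

The Narendra–Fitch step rescales each pixel's deviation from its window
mean to a fixed local contrast `c`.  With `c` below 1 this is a
*compressive* normalization: it converts the cartoon's sharp cell edges
into smooth mounds about one window wide.  Detection therefore triggers
at the lower end of the size window for most cells, and the accepted
feature is the bright core of the cell rather than its full footprint —
a property worth knowing when interpreting the masks morphometrically.

## ROF denoising

The cartoon is the exact minimizer of `TV(u) + (w/2)‖u − f‖²` with
forward-difference isotropic TV and replicate boundaries, computed by
fast (Nesterov-accelerated) dual projection with step `1/(8λ)`,
`λ = 1/w`.  Iteration stops when the max-norm change of the primal
iterate falls below `tol` (default `1e-3` relative) or after `max_iter`
(default 400) sweeps; on 8-bit output, residual changes below a tenth of
a grey level are invisible after quantization.  Energy descent, TV
decrease and mean preservation are asserted in the test suite.

The default fidelity weight is `w = 0.05` per grey level.  The choice is
driven by the background: with sensor noise of σ ≈ 10 grey levels, the
cartoon's background must be flat to within the 8-bit quantization step,
otherwise residual one-level bumps survive quantization, get renormalized
to visible contrast by the enhancement step, and become compact
cell-sized "islands" that the geometric rules cannot distinguish from
dim nuclei.  `w = 0.05` (λ = 20) reaches that flatness for σ = 10 while
costing small nuclei only a few grey levels of contrast (TV shrinkage of
a disk of radius ρ is ≈ λ/ρ).  Much stronger denoising is
counterproductive: the TV staircasing artifact then produces *larger*
coherent background plateaus that land inside the size windows.

## Tissue evaluation mask

The evaluation mask marks where there is tissue at all, from the DAPI
cartoon: threshold at 10 grey levels, morphological closing with radius
20 px (implemented with two Euclidean distance transforms), hole
filling, and removal of components below 2000 px.  The threshold sits
between denoised dark glass (a few grey levels once clipped sensor noise
is averaged) and tissue autofluorescence; the closing radius bridges the
gaps between neighbouring nuclei; the minimum area removes stray specks
while keeping single-cell islets.  All three constants are exposed in
the config.  Detection is restricted to this mask by default
(`restrict_to_evalmask`), which is what keeps glass-level fluctuations
out of the object counts.

## Minimum covering ellipse

`r(F)` uses Khachiyan's barycentric coordinate-descent on the feature's
hull vertices, stopping at the dual optimality certificate
`max_j M_j ≤ (d+1)(1+tol)` with `tol = 1e-3`; the axis ratio is read off
the eigenvalues of the dual scatter matrix and is invariant to the final
(1+tol) inflation.  Features whose pixel centers are collinear (including
1- and 2-pixel features) get `r = +∞` and can never be accepted — a
one-pixel-wide line is not a cell.  The test suite cross-checks the
ratio against an independent grid-plus-polish search over orientation
and anisotropy built on exact minimum enclosing circles; note the area
landscape of near-degenerate features is a shallow valley, which is why
the reference search needs the continuous polish stage to make the ratio
identifiable.

Convex hull filling counts pixels whose centers lie inside or on the
hull polygon of the feature's pixel centers, ties broken toward
inclusion, so `c ≥ s` holds by construction (verified against a
point-in-polygon oracle).

## Synthetic tissue generator

The generator emulates what the pipeline needs to be tested against,
with defaults that describe a sparse, well-separated field of cells:

* one elliptical tissue section (axes 0.34–0.42 of the tile edge) of
  dim autofluorescence (10 grey levels) on dark glass (2), under a
  smooth illumination gradient (3) and white Gaussian noise (σ = 10);
* 20 elliptical nuclei per 1,000 × 1,000 tile, realized pixel areas
  uniform in 60–180 px, axis ratio ≤ 2, plateau intensities 120–200,
  center separation ≥ 34 px;
* Pax5 blobs (80–159 px) centered on 8 of the nuclei, plus 3 artifact
  blobs placed at least 45 px from any nucleus (they exercise the
  nucleus-hull gating);
* 6 macrophages as unions of 3–6 jittered disks (radius 11–14 px,
  per-disk intensity jitter ±12) emulating within-cell staining
  inhomogeneity; a configurable fraction is drawn identically in both
  macrophage channels (double-stained);
* cell edges softened with a 0.7 px Gaussian before noise is added.

All randomness flows from a single integer seed through one NumPy
generator, so tiles are bit-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: densely packed, touching cells (real DLBCL
tissue is contiguous cell carpet, where the skip-adjacent rule and the
two-run disjointness are stressed much harder); chromatin texture inside
nuclei; point-spread blur and vignetting; spatial correlation of noise;
partial cells at tile borders (cells are placed away from borders).
Object-level scoring matches predictions to truth greedily by
intersection-over-union with a default threshold of 0.3, reflecting that
rule-based masks capture cell cores rather than exact boundaries.

## Degenerate inputs and ties

Constant images are fixed points of both denoising and enhancement
(windows with σ = 0 return the window mean).  Blank channels produce
empty masks but the full 19-file tile folder is still written.
Components are visited in raster order of their first pixel, so logs and
outputs are reproducible; masks are written as 1-bit PNGs and round-trip
losslessly.  Border-touching features are kept but counted in the log.
The RGB-to-grey conversion uses the Euclidean norm of the RGB vector
clipped at 255; an unclipped rescaling variant is available, since on
single-channel fluorescence exports (at most one nonzero RGB channel per
pixel) the two coincide.

## Problem sizes used in the tests

The acceptance tests run one full 1,000 × 1,000 tile through the entire
pipeline at threshold step 1 (the dataset-layout and parameter-recovery
checks), twenty 240 × 240 tiles for rule conformance at step 2, and
small fixtures elsewhere; these sizes keep the whole suite comfortably
inside a few minutes while still exercising the full-scale code path
once.

## Known limitations

* The exact ROF weight and macrophage rule bounds used for the published
  reference dataset are not public; this package's defaults are its own
  calibrated operating point, so published masks are reproduced in kind,
  not bit-exactly.
* The two-run DAPI design contributes little under the compressive
  enhancement described above: most nuclei are accepted by run 1 while
  growing through the 60–119 px window, and run 2's candidates are then
  discarded as overlapping.  The merged output is correct (each nucleus
  once), but run attribution differs from a sharp-threshold reading of
  the recipe.
* Counts are single detections per object by construction; the pipeline
  does not split merged cells, and densely clustered nuclei will
  undercount.
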