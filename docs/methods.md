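# Methods

## The assay and the computational problem

In co-cultures of biliary epithelial cells (BEC) with CD8⁺ T cells, a
fraction of the T cells becomes fully internalised within BEC, forming
cell-in-cell structures. In multi-channel fluorescence fields of view the
internalised state has two optical signatures that distinguish it from a T
cell merely sitting on top of an epithelial cell:

1. **Cytoplasm displacement.** An enclosed T cell displaces the host's
   cytoplasmic dye (CellTracker Green), so the BEC channel shows a dark,
   roughly cell-sized hole at the T cell's position.
2. **Membrane-label shielding.** A medium-borne surface label (wheat-germ
   agglutinin, WGA-AF680) stains every membrane exposed to the medium.
   Attached and free T cells therefore carry a bright membrane rim; an
   enclosed cell is shielded by the host's membrane and carries none.

`cicsquant` turns these signatures into a deterministic object-masking
cascade and reports, per field, the internalised count per 100 BEC — the
assay's primary readout — together with per-object size and eccentricity.

## The detection cascade

For a field with channels (bec, tcell, membrane), `run_cascade` executes:

1. **BEC objects** — primary-object detection on the BEC channel with hole
   filling enabled. Hole filling is load-bearing: the holes *are* the
   internalised cells, and the next step only retains T cells inside BEC
   footprints if those footprints cover the holes.
2. **On-BEC T cells** — the T-cell channel is masked (zeroed) outside BEC
   footprints and T-cell objects are detected in the masked image. Free
   T cells disappear here; T cells partially on a BEC survive as clipped
   remnants and are removed by the eccentricity filter (below).
3. **Membrane exclusion** — the membrane channel is masked to the on-BEC
   T-cell footprints and membrane-label objects are detected there (with a
   10 px minimum area to suppress speckle). A T cell is membrane-positive —
   and deleted — when detected membrane objects cover at least
   `membrane_overlap_fraction` (default 0.05) of its footprint. The
   fraction is deliberately small: any genuine rim covers far more than 5 %
   of a cell, while shielded cells have exactly zero membrane signal.
4. **Cytoplasm-displacement test** — each surviving T cell's footprint is
   compared against the thresholded BEC signal (same smoothed image and
   threshold as step 1). A cell with above-threshold BEC signal over at
   least `cytoplasm_overlap_cutoff` (default 0.5) of its footprint is *on
   top of* intact cytoplasm; the remainder are displacing it. The 0.5
   default splits partial-overlap cases symmetrically and is configurable.
5. **Remnant filter** — after masking steps, objects with second-moment
   eccentricity above `max_eccentricity` (default **0.92**) are removed.
   Intact cells are compact (the generator's axis ratios ≥ 0.7 give
   eccentricity ≤ 0.71); clipped remnants are elongated and exceed the
   cutoff.

Survivors are classed internalised, giving the monotone exclusion chain
internalised ⊆ membrane-negative ⊆ on-BEC ⊆ all detected T cells, which
holds on every input by construction.

The acidification assay (`quantify_lysosome_association`) reuses the same
cascade; the membrane channel is optional there because the Lysotracker
experiment runs without a surface label, and surface cells are excluded by
the displacement test alone. A cell is lysosome-associated when at least
one acidification object detected in the lysosome channel is assigned to it
by parent/child relation — strictly overlap-based, no proximity distance.

## Segmentation primitives

`identify_primary_objects` is Gaussian smoothing (σ = 1 px by default) →
threshold → optional hole filling → connected components or shape-based
declumping (watershed on the smoothed distance transform seeded at local
maxima) → equivalent-diameter range filter → border policy → contiguous
relabel. Otsu is the default threshold; a `threshold_floor` bounds it from
below so that a near-empty masked image (for example the T-cell channel
masked to BEC areas in a field with no on-BEC cells) is not split at a
noise-level threshold — without the floor, Otsu on pure noise marks half
the pixels foreground. The default floors (50–60 intensity counts) sit
between the generator's background (10 counts) and foreground (200–240
counts) levels; for other data they are configurable per channel, and a
fixed threshold is available for exact tests. A constant image under Otsu
yields an empty map with a warning rather than an error.

Eccentricity is that of the ellipse with the same normalised second central
moments as the footprint (0 = circle, → 1 = line). Degenerate objects are
defined so filtering is total: single-pixel objects have eccentricity 0,
collinear multi-pixel objects 1 — both fall out of the moment definition
itself. `relate_objects` assigns each child to the parent sharing the most
pixels, ties to the lowest parent label for determinism. Coordinates are
0-based (row, col) with pixel centres at integer positions.

## The synthetic generator

`generate_field` renders the four channels from parametric geometry and
returns the per-cell truth table used as the oracle in every detection
test. Design choices:

* **BEC as perturbed ellipses** (radius modulated by 2nd–4th angular
  harmonics, amplitudes 2–8 %), not disks, so hole-filling and declumping
  logic is exercised on irregular outlines. BEC are placed non-overlapping
  with bounded rejection sampling; overcrowded requests raise a
  `PlacementError` naming the limiting count.
* **Holes are punched before PSF blur**, so blurred hole edges resemble the
  real displacement rings.
* **Attached cells add T-cell signal on top of intact BEC signal** without
  suppressing it — the two classes differ only by membrane label and
  cytoplasm displacement, exactly the contrasts the cascade uses.
* **Noise model**: Poisson on the rendered intensities (treated as photon
  counts), then additive Gaussian read noise, then clipping at zero. Both
  are off by default so exactness tests have a deterministic target;
  `noisy_spec()` is the default noisy condition (Poisson + SD 2 read
  noise, i.e. SNR ≈ 14 at the 200-count foreground).
* **Default geometry**: 640 × 640 px fields at 0.65 µm/px (typical 10–20×
  high-content optics; the acquisition metadata of the original assay is
  not public, so this is a declared choice, not an inference). BEC radii
  20–30 px (13–20 µm), T-cell semi-major axes 5–8 px (3–5 µm, i.e. 7–10 µm
  cell diameter), axis ratios 0.7–1, membrane rims 2.5 px wide.
* **Counts**: 10 BEC with 4 internalised, 3 attached and 5 free T cells per
  default field; batch generation draws per-field internalised counts
  uniformly from a closed range, with per-field seeds derived from one
  master seed so whole batches are bit-reproducible.
* **Lysosome channel**: 2.5 px puncta scattered in BEC cytoplasm (kept off
  all T-cell footprints with a 4 px guard band, so stray puncta can never
  flip an association call) plus one punctum centred, with ±1 px jitter, on
  `round(fraction × n_internalized)` of the internalised cells.

What the generator does **not** emulate: uneven illumination, autofluorescence
texture, cell debris, touching/overlapping T cells, partially internalised
(in-progress) events, z-dependent defocus, or photobleaching. Passing the
synthetic benchmarks therefore demonstrates that the cascade's logic is
correct and noise-robust under these geometries, not that the default
segmentation parameters transfer to any particular microscope's data —
on real data the per-channel thresholds and diameter ranges are the knobs
to recalibrate, via the YAML config.

## Quantification and statistics

* `per_100_bec` = 100 × n_internalised / n_BEC, undefined (flagged, field
  excluded from aggregation) when no BEC is detected.
* Aggregation hierarchy is field → well (arithmetic mean; a well is one
  technical repeat) → condition.
* Fold change divides by the arithmetic mean of the control (vehicle)
  condition's values, so the control's own fold changes average 1 and the
  operation is scale-invariant.
* `compare_groups` offers two-tailed Student's t (pooled variance), paired
  t, Mann–Whitney U, and Wilcoxon. Normality is not auto-tested; the caller
  chooses parametric vs non-parametric. Identical paired samples return
  statistic 0 and p = 1 by convention (the t statistic is otherwise 0/0).
  No multiple-comparison correction is applied by default.
* `validate_counts` regresses pipeline counts on reference counts by
  ordinary least squares and reports slope, intercept and r².

## Benchmark experiment sizes

The `validation` module fixes the benchmark conditions: 20 noiseless and 50
noisy fields with 10 BEC and 0–8 internalised / 0–6 attached / 0–6 free
cells each; 20 noisy zero-internalisation fields for the false-positive
rate; and 30 large fields (1024 px, 36 BEC) spanning true counts 0–30 for
the detected-vs-true regression. Centroid matching uses a 3 px ceiling on
clean fields and 5 px under noise.

## Known limitations

* Classification is per-2-D-field; full 3-D enclosure is not confirmed.
* A T cell internalised across the footprint-union of two touching BEC is
  assigned by maximal overlap, not tested for single-parent enclosure.
* The membrane-positivity and displacement cutoffs (5 %, 50 %) are
  operational definitions; the underlying assay literature specifies the
  detection-then-deletion logic but no numeric fractions.
* Default thresholds assume foreground/background contrast comparable to
  the generator's (≈ 20:1); low-contrast data needs per-channel tuning.
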