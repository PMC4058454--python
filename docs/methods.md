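# Methods

## The detection model

The pipeline treats phase-contrast cell detection as a *composition*
problem: no single homogeneity criterion holds across a frame, but each
classic operator works inside a domain prepared for it.

**Maximum ROI.** The medium is smooth while cell interiors are full of
minor structure, so edge density separates "near a cell" from
background. The gradient is the averaged 2×2 forward-difference stencil

    gx = (f[r, c+1] − f[r, c] + f[r+1, c+1] − f[r+1, c]) / 2
    gy = (f[r+1, c] − f[r, c] + f[r+1, c+1] − f[r, c+1]) / 2

with magnitude `√(gx² + gy²)` and direction `arctan2(gx, gy)` (the
two-argument form keeps the direction finite where `gy = 0`). Canny maps
are computed at scales 1, 1/2 and 1/4 (local-mean downsampling), the
coarse maps are upsampled by nearest neighbour, and the merge is logical
OR — the only sum that preserves binarity, and monotone: adding a scale
never removes a pixel. The morphological flow is close(disk r=3) → fill
holes → erode(disk r=2) → area-open; hole filling is required to turn
closed edge rings into solid regions. The mask is *permissive by
contract*: it must cover essentially all cell pixels (verified ≥ 99 % on
every test scene) and may include background, which later stages ignore.

**Reference images.** Level-1 thresholds read the n-fold Gaussian blur
`S_n = [G(σ)]^n * I` with n = 20, σ = 1.0, kernel truncated at radius 5
and renormalized to unit sum (preserving the mean); borders are handled
by reflection so repeated application does not darken the frame. n
applications of the kernel equal one application of its n-fold
self-convolution, so `S_n` approximates a Gaussian blur of scale σ√n —
approximately only, because of truncation; the measured mean deviation
from a direct σ√20 blur is ~2e-6 on [0,1] images, and the test tolerance
is 1e-3. The second reference is grayscale opening-by-reconstruction
then closing-by-reconstruction (disk r=5), which flattens texture
without displacing contours.

**Local multilevel Otsu.** Each 8-connected ROI region is thresholded
independently: three thresholds over a 256-bin histogram on [0, 1]
maximize the between-class variance Σ P_c·(μ_c − μ)², found by
*exhaustive* search. The search is exact: candidate thresholds are
restricted to occupied histogram bins, their +1/+2 shifts and {0, 1, 2},
a set that provably contains the lexicographically smallest maximizer
over the full 256³ triple space (each threshold of a minimal optimal
triple is the last occupied bin of its class, or one past the previous
threshold when its class is empty). Ties break toward the smallest
triple; thresholds are reported as upper bin edges `(b+1)/256`. Regions
with fewer than four distinct values are mapped wholly to the dark class
rather than aborting the run. Classes are dark A1 / prone-dark A2 /
bright A3 / prone-bright A4, and always partition the region exactly.

**Hierarchy and mergence.** A section's 8-connected components can be
re-partitioned against a different reference (A_iA_j notation), capped
at depth 3 — deeper digs produce no usable patches. The textual algebra
(`sel(3.1@original)`, `union`, `holes`, `ws`) exists so strategies are
serializable configuration rather than code. Default layer bindings go
coarse→fine: level 1 reads `gauss20`, level 2 `graymorph`, level 3 the
original; all overridable. The `holes` operator returns background
4-connected components not touching the border — the hollow cell bodies
enclosed by bright halo rings. Mergence dilates hole-derived layers by a
2 px disk (holes sit strictly inside their rings), ORs layers with
first-listed priority for overlap attribution, clips to `M_ROI`, and
drops fragments under 30 px (the minimum admissible cell area). The
default flow emits one raw result per configured strategy for manual
picking; the opt-in `pick="auto"` scores results by mean patch solidity
× count of plausibly sized patches and is a labelled heuristic, not part
of the method.

**Watershed.** Adherent patches are split by watershed on the negated
Euclidean distance transform with markers at its local maxima at least
`min_seed_distance = 10` px apart. The distance transform is smoothed
(σ = 1) before peak detection: rasterized blobs produce plateau maxima
that would otherwise oversegment single convex cells. Every connected
component is guaranteed one marker (the distance argmax) even when peak
detection returns none, so labels always partition the mask exactly.

**Patch filter.** Candidates are described by area, perimeter,
eccentricity, solidity, extent, mean/sd intensity, mean Sobel gradient,
and a uniform LBP histogram (P=8, R=1, 10 bins, L1-normalized, computed
on the 8-bit-quantized patch bounding box and accumulated over patch
pixels). An RBF SVM on standardized features classifies cell vs
non-cell; C is chosen from {1, 10, 100} by 3-fold stratified CV with a
fixed shuffle seed. Training labels come from synthetic ground truth — a
patch is positive iff ≥ 50 % of its pixels lie inside one true cell —
because no labelled real data exists for this pipeline; this supervision
choice is the main caveat when transferring the filter to real frames.

**Scoring.** Cell-level segmentation accuracy is the fraction of
ground-truth cells matched one-to-one by predicted patches, greedy by
descending IoU with threshold 0.5 (ties by label ids, so matching is
deterministic); precision is reported alongside because spurious patches
do not reduce accuracy. Sequence accuracy is the unweighted mean of
frame accuracies.

## Synthetic study conditions

The generator renders, measurably, exactly the image properties the
method exploits; defaults (chosen once as the package's reference
conditions):

| parameter | default | meaning |
|---|---|---|
| frame | 640 × 640 px | keeps the cell-size-to-blur-scale ratio of full-size microscope frames |
| n_cells | 20 | moderately crowded field |
| adhesion_fraction | 0.3 | fraction of cells placed in touching pairs |
| cell radius | 26–38 px | normal stage; mitotic cells ×0.7, rounder |
| background mean / sd | 0.5 / 0.01 | smooth medium with weak noise |
| speckle_sd | 0.08 | zero-mean interior texture (≥ 2× background gradient) |
| halo_gain | 0.25 | additive ring over the outer 2 px and 2 px outside |
| interior offset | −0.035 | residual shade-off (mitosis +0.025, apoptosis −0.04) |
| optics_sigma | 0.5 | final smoothing standing in for the optical transfer |

The frame size matters: with cells an order of magnitude smaller than
real ones relative to the n = 20 blur (σ_eff ≈ 4.5 px), the blurred
interior becomes a radial gradient and local Otsu slices cells into
annuli — the regime the method was never meant for. 640 px frames with
26–38 px cells reproduce the intended regime at a quarter of the
original pixel count.

Per-cell speckle is drawn zero-mean *exactly* (empirically demeaned), so
the interior-mean contract (within ±0.05 of the medium) holds for every
cell and seed; the illumination ramp (±0.008) and stage offsets leave
margin. Adhesion is realized as touching pairs via exclusive painting:
overlapping rasters are assigned to the earlier cell, so the later cell
acquires a shared boundary. Aspect ratios are ≥ 0.78, matching rounded
epithelial morphology; this also keeps the distance-transform ridge of a
single cell shorter than `min_seed_distance`, so default watershed does
not split singletons.

What the generator does **not** model: the physical optics (no
point-spread function or phase reconstruction), debris and dust,
illumination flicker, out-of-focus cells, confluent sheets (adhesion
beyond pairs), and cell-to-cell texture variation beyond the three stage
archetypes. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under the stated appearance contracts —
not performance on real microscope data.

## Numerical choices

- All intensities live on [0, 1] floats regardless of source bit depth
  (8/16-bit rescaled by 2^depth − 1; RGB collapsed by BT.601 luminance).
- Coordinates are (row, col), 0-based; the gradient's x is the column
  axis.
- Otsu bins: 256 equal bins on [0, 1]; pixels are *classified* by
  comparison to the reported thresholds (`v ≤ t1` → class 1, …), which
  agrees with the binning except exactly at bin edges.
- Canny hysteresis auto mode: high = Otsu threshold of the smoothed
  Sobel magnitude, low = 0.4·high; explicit thresholds are fractions of
  the maximum magnitude.
- Watershed determinism: peaks from the smoothed distance transform,
  ordered by scan order; relabelling is sequential, so label ids are
  stable across runs.
- Degenerate inputs: empty masks are valid everywhere (empty ROI, empty
  class, empty hole set); 1-pixel patches get perimeter 4 and a
  single-code LBP histogram.
- Problem sizes: tests and the acceptance script use 640 px scenes, 4
  training + 10 evaluation scenes — large enough that every contract is
  measurable, small enough to re-run casually.

## Known limitations

- The SVM filter is trained and evaluated on the same synthetic
  distribution; held-out accuracy (~89–96 %) does not transfer to real
  frames without retraining on hand-labelled patches.
- The composite strategy is a good default for halo-ringed, shade-off
  cells but strategy choice is per-dataset by design; there is no
  automatic strategy search beyond the labelled heuristic score.
- Patches approximate cell bodies, not exact boundaries; boundary-
  accuracy metrics are out of scope, and the matcher deliberately scores
  detection (IoU ≥ 0.5), not contour fidelity.
- Very small or low-contrast cells (< ~30 px area, interior offset ≪
  speckle) fall below the dark-section signal and are missed.
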