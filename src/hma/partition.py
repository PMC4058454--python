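"""Local multilevel Otsu classification and watershed splitting.

Each 8-connected ROI region is thresholded *independently*: a region's
histogram contains mostly cell material, so three Otsu thresholds separate
it into four intensity sections -- dark (A1), prone-dark (A2), bright (A3)
and prone-bright (A4) -- even when the global histogram would not.
Thresholds maximize the between-class variance over a 256-bin histogram on
[0, 1], found by exhaustive search with ties broken toward the
lexicographically smallest threshold triple.

Adherent patches are split by marker-controlled watershed on the negated
distance transform, with markers at distance-transform maxima separated by
a minimum seed distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import segmentation

from .errors import DegenerateRegionError, ParameterError
from .image_io import as_float_image
from .roi import RoiMask

N_BINS = 256

#: class codes: 0 background, 1 dark .. 4 prone-bright
CLASS_NAMES = {0: "background", 1: "dark", 2: "prone-dark", 3: "bright", 4: "prone-bright"}


@dataclass
class ClassMap:
    """Per-pixel section label in {0..4} plus each region's threshold triple."""

    labels: np.ndarray
    thresholds_per_region: dict[int, tuple[float, ...]] = field(default_factory=dict)


@dataclass
class LabelMap:
    """Positive-integer labels 1..n_labels over 8-connected supports."""

    labels: np.ndarray
    n_labels: int


def _bin_indices(values: np.ndarray) -> np.ndarray:
    return np.minimum((np.clip(values, 0.0, 1.0) * N_BINS).astype(np.int64), N_BINS - 1)


def _candidate_bins(occupied: np.ndarray) -> np.ndarray:
    """Threshold-bin candidates that contain the lexicographically smallest
    maximizer of between-class variance over the full 0..255 space.

    For any partition of the occupied bins into ordered classes, the
    smallest triple realizing it puts each threshold either at an occupied
    bin (the last bin of its class) or, for an empty class, one past the
    previous threshold; hence occupied bins, their +1/+2 shifts, and
    {0, 1, 2} for empty leading classes suffice.
    """
    cand = np.concatenate([occupied, occupied + 1, occupied + 2, [0, 1, 2]])
    return np.unique(cand[cand < N_BINS])


def multilevel_otsu(values, k: int = 3) -> tuple[float, ...]:
    """k thresholds maximizing between-class variance over a 256-bin histogram.

    Thresholds are reported as the upper edge ``(bin + 1) / 256`` of their
    bin on the [0, 1] scale, sorted ascending.  Requires at least ``k + 1``
    distinct values; callers map degenerate regions wholly to the dark class.
    """
    if k not in (1, 2, 3):
        raise ParameterError("k must be 1, 2 or 3")
    vals = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(vals).size < k + 1:
        raise DegenerateRegionError(
            f"need more than {k} distinct values for {k} thresholds"
        )
    counts = np.bincount(_bin_indices(vals), minlength=N_BINS).astype(np.float64)
    occupied = np.nonzero(counts)[0]
    cand = _candidate_bins(occupied)

    # cumulative zeroth and first moments; class score S^2 / P with bin
    # index as the gray value (affine to bin centers, same argmax)
    P = np.concatenate([[0.0], np.cumsum(counts)])
    S = np.concatenate([[0.0], np.cumsum(counts * np.arange(N_BINS))])

    def score(a, b):
        """Between-class contribution of the class spanning bins a..b."""
        p = P[b + 1] - P[a]
        s = S[b + 1] - S[a]
        return np.where(p > 0, s * s / np.maximum(p, 1.0), 0.0)

    m = cand.size
    if k == 1:
        tot = score(0, cand) + score(cand + 1, N_BINS - 1)
        best = int(np.argmax(tot))
        bins = (int(cand[best]),)
    elif k == 2:
        g1, g2 = np.meshgrid(cand, cand, indexing="ij")
        tot = score(0, g1) + score(g1 + 1, g2) + score(g2 + 1, N_BINS - 1)
        tot[g1 >= g2] = -np.inf
        best = np.unravel_index(int(np.argmax(tot)), tot.shape)
        bins = (int(cand[best[0]]), int(cand[best[1]]))
    else:
        g2, g3 = np.meshgrid(cand, cand, indexing="ij")
        invalid23 = g2 >= g3
        mid = score(g2 + 1, g3)
        tail = score(g3 + 1, N_BINS - 1)
        best_val = -np.inf
        best_bins = (0, 1, 2)
        for i in range(m):
            t1 = int(cand[i])
            head = score(0, t1) + score(t1 + 1, g2)
            tot = head + mid + tail
            tot[invalid23 | (t1 >= g2)] = -np.inf
            j = int(np.argmax(tot))  # row-major = lexicographic in (t2, t3)
            val = tot.flat[j]
            if val > best_val:  # strict: earlier (smaller) t1 wins ties
                best_val = val
                r, c = divmod(j, m)
                best_bins = (t1, int(cand[r]), int(cand[c]))
        bins = best_bins
    return tuple((b + 1) / N_BINS for b in bins)


def classify_values(values: np.ndarray, thresholds: tuple[float, ...]) -> np.ndarray:
    """Bin values into classes 1..k+1: class 1 iff v <= t1, etc."""
    cls = np.ones(values.shape, dtype=np.uint8)
    for t in thresholds:
        cls += (values > t).astype(np.uint8)
    return cls


def local_otsu_classify(reference, roi: RoiMask, k: int = 3) -> ClassMap:
    """Apply multilevel Otsu to each ROI region independently.

    Every region gets its own threshold triple from its own reference
    intensities; regions with fewer than ``k + 1`` distinct values are
    mapped wholly to the dark class (1).  Pixels outside the ROI stay 0.
    """
    ref = as_float_image(reference)
    if ref.shape != roi.mask.shape:
        raise ParameterError(
            f"reference shape {ref.shape} != ROI shape {roi.mask.shape}"
        )
    labels = np.zeros(ref.shape, dtype=np.uint8)
    thresholds: dict[int, tuple[float, ...]] = {}
    for rid in roi.region_ids:
        sel = roi.regions == rid
        vals = ref[sel]
        try:
            t = multilevel_otsu(vals, k=k)
        except DegenerateRegionError:
            labels[sel] = 1
            thresholds[rid] = ()
            continue
        labels[sel] = classify_values(vals, t)
        thresholds[rid] = t
    return ClassMap(labels=labels, thresholds_per_region=thresholds)


def class_select(cm: ClassMap, classes) -> np.ndarray:
    """Boolean mask of the pixels whose section label is in ``classes``."""
    classes = set(classes)
    if not classes <= {1, 2, 3, 4}:
        raise ParameterError(f"class ids must be within 1..4, got {sorted(classes)}")
    if not classes:
        return np.zeros(cm.labels.shape, dtype=bool)
    return np.isin(cm.labels, sorted(classes))


def _relabel_sequential(labels: np.ndarray) -> LabelMap:
    out, _, _ = segmentation.relabel_sequential(labels)
    return LabelMap(labels=out.astype(np.int32), n_labels=int(out.max(initial=0)))


def watershed_split(mask, min_seed_distance: int = 10) -> LabelMap:
    """Split a binary mask into cell-sized labels by marker-based watershed.

    Elevation is the negated Euclidean distance transform (lightly smoothed
    to suppress rasterization plateaus); markers are its local maxima at
    least ``min_seed_distance`` apart, with a guaranteed marker per
    connected component.  Labels partition the mask exactly and each label
    support is 8-connected.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LabelMap(labels=np.zeros(mask.shape, dtype=np.int32), n_labels=0)
    dist = ndi.distance_transform_edt(mask)
    dist_s = ndi.gaussian_filter(dist, 1.0, mode="constant")
    comp, n_comp = ndi.label(mask, structure=np.ones((3, 3)))
    coords = skfeature.peak_local_max(
        dist_s,
        min_distance=min_seed_distance,
        labels=comp,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # guarantee one seed per component
    seeded = set(np.unique(comp[markers > 0]))
    next_id = coords.shape[0] + 1
    for cid in range(1, n_comp + 1):
        if cid not in seeded:
            inside = comp == cid
            flat = np.argmax(np.where(inside, dist_s, -1.0))
            markers.flat[flat] = next_id
            next_id += 1
    labels = segmentation.watershed(-dist_s, markers, mask=mask, connectivity=2)
    return _relabel_sequential(labels)
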