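"""Maximum region-of-interest (ROI) extraction from multi-scale edge maps.

In phase contrast images the cell interior is densely textured while the
medium is smooth, so gradient information alone separates "somewhere near a
cell" from background.  The maximum ROI mask is deliberately permissive: it
must cover every cell event, and may include background, because all later
stages operate only inside it.

The flow: Canny edge maps at full, half and quarter resolution are merged
(logical OR after nearest-neighbour upsampling) into one edge map, which is
then closed, hole-filled, eroded and area-opened into the mask, whose
8-connected components are the local regions that the partition stage
thresholds independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, morphology, transform

from .errors import ParameterError
from .image_io import as_float_image

SCALES = (1.0, 0.5, 0.25)


@dataclass
class GradientField:
    """Forward-difference gradient on the 2x2 stencil.

    ``gx``/``gy`` live on the (height-1) x (width-1) valid grid:
    each entry averages the two forward differences across a 2x2
    neighbourhood and halves the sum.  ``direction`` is
    ``arctan2(gx, gy)`` in radians.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


@dataclass
class EdgeMaps:
    """Binary edge maps per scale, all at full resolution, plus their merge."""

    per_scale: dict[float, np.ndarray]
    merged: np.ndarray


@dataclass
class RoiMask:
    """The maximum ROI: a boolean mask and its 8-connected regions."""

    mask: np.ndarray
    regions: np.ndarray = field(repr=False)  # int label raster, 0 = outside
    m: int = 0

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, self.m + 1))


def finite_difference_gradient(image) -> GradientField:
    """Edge-strength gradient from averaged 2x2 forward differences.

    With x as column and y as row,
    ``gx = (f[r, c+1] - f[r, c] + f[r+1, c+1] - f[r+1, c]) / 2`` and
    symmetrically for ``gy``; the magnitude is the Euclidean norm of the
    two components.
    """
    img = as_float_image(image)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ParameterError("gradient needs an image of at least 2x2 pixels")
    gx = (img[:-1, 1:] - img[:-1, :-1] + img[1:, 1:] - img[1:, :-1]) / 2.0
    gy = (img[1:, :-1] - img[:-1, :-1] + img[1:, 1:] - img[:-1, 1:]) / 2.0
    magnitude = np.hypot(gx, gy)
    direction = np.arctan2(gx, gy)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, direction=direction)


def _smoothed_magnitude(img: np.ndarray, sigma: float) -> np.ndarray:
    smoothed = ndi.gaussian_filter(img, sigma, mode="reflect")
    return np.hypot(filters.sobel_h(smoothed), filters.sobel_v(smoothed))


def canny_edges(
    image,
    sigma: float = 1.0,
    low: float | None = None,
    high: float | None = None,
) -> np.ndarray:
    """Canny edge detection with automatic hysteresis thresholds.

    ``low``/``high`` are fractions of the maximum smoothed gradient
    magnitude (0 < low < high < 1).  In auto mode (both None) the high
    threshold is the Otsu threshold of the gradient magnitudes and
    ``low = 0.4 * high``.
    """
    img = as_float_image(image)
    mag = _smoothed_magnitude(img, sigma)
    mag_max = float(mag.max())
    if mag_max == 0.0:
        return np.zeros(img.shape, dtype=bool)
    if low is None and high is None:
        high_abs = float(filters.threshold_otsu(mag))
        low_abs = 0.4 * high_abs
    elif low is None or high is None:
        raise ParameterError("give both low and high thresholds, or neither")
    else:
        if not 0.0 < low < high < 1.0:
            raise ParameterError(
                f"thresholds must satisfy 0 < low < high < 1, got {low}, {high}"
            )
        low_abs, high_abs = low * mag_max, high * mag_max
    return feature.canny(
        img, sigma=sigma, low_threshold=low_abs, high_threshold=high_abs
    )


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    return transform.downscale_local_mean(img, (factor, factor))


def _upsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = transform.resize(
        mask.astype(np.float64), shape, order=0, anti_aliasing=False, mode="edge"
    )
    return out > 0.5


def multiscale_edge_map(
    image, canny_params: dict[float, dict] | None = None
) -> EdgeMaps:
    """Canny at scales 1, 1/2 and 1/4, merged at full resolution.

    Coarse-scale binary maps are upsampled by nearest neighbour; the merge
    of binary maps is their logical OR, so adding a scale can only add
    edge pixels.
    """
    img = as_float_image(image)
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise ParameterError(
            "image too small for the 1/4-scale edge map (need >= 32x32)"
        )
    canny_params = canny_params or {}
    per_scale: dict[float, np.ndarray] = {}
    for scale in SCALES:
        factor = int(round(1 / scale))
        small = img if factor == 1 else _downsample(img, factor)
        edges = canny_edges(small, **canny_params.get(scale, {}))
        per_scale[scale] = (
            edges if factor == 1 else _upsample_mask(edges, img.shape)
        )
    merged = np.zeros(img.shape, dtype=bool)
    for mask in per_scale.values():
        merged |= mask
    return EdgeMaps(per_scale=per_scale, merged=merged)


def area_open(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


def build_max_roi(
    edges: EdgeMaps | np.ndarray,
    close_radius: int = 3,
    erode_radius: int = 2,
    min_region_area: int = 150,
) -> RoiMask:
    """Turn the merged edge map into the maximum ROI mask.

    Morphological flow: close with a disk, fill holes, erode with a disk,
    open by area, then label 8-connected regions.  The default area
    threshold suits the package's 320 px study frames; on full-size
    (~1000 px) microscope frames with large cells a value around 500 px
    plays the same role.
    """
    merged = edges.merged if isinstance(edges, EdgeMaps) else np.asarray(edges, bool)
    work = morphology.closing(merged, morphology.disk(close_radius))
    work = ndi.binary_fill_holes(work)
    work = morphology.erosion(work, morphology.disk(erode_radius))
    work = area_open(work, min_region_area)
    regions, m = ndi.label(work, structure=np.ones((3, 3)))
    return RoiMask(mask=work, regions=regions, m=int(m))


def max_roi_from_image(
    image,
    canny_params: dict[float, dict] | None = None,
    close_radius: int = 3,
    erode_radius: int = 2,
    min_region_area: int = 150,
) -> RoiMask:
    """Convenience: multi-scale edges then morphological flow in one call."""
    edges = multiscale_edge_map(image, canny_params)
    return build_max_roi(
        edges,
        close_radius=close_radius,
        erode_radius=erode_radius,
        min_region_area=min_region_area,
    )
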