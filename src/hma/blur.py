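"""Reference images: iterated Gaussian blurring and grayscale morphology.

The local thresholding stages never read the raw frame directly; they read
*reference images* in which the intracellular speckle has been fused into
consistent patches.  Two families are provided: the n-fold application of
a truncated Gaussian kernel (default n = 20, sigma = 1.0, radius = 5), and
grayscale opening/closing by reconstruction, which flattens texture while
preserving region contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .errors import ConfigError, ParameterError
from .image_io import as_float_image


def gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    """Truncated, renormalized 1-D Gaussian; its outer product with itself
    is the 2-D kernel (truncation to a square support keeps it separable)."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if radius < int(np.ceil(2 * sigma)):
        raise ParameterError(
            f"radius {radius} too small for sigma {sigma}; need >= ceil(2*sigma)"
        )
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def iterated_gaussian(
    image, sigma: float = 1.0, n: int = 20, radius: int = 5
) -> np.ndarray:
    """Convolve an image n times with the truncated normalized Gaussian.

    n = 0 returns the input unchanged; borders are handled by reflection.
    n applications of the kernel equal one application of its n-fold
    self-convolution, so the result approximates a single Gaussian blur of
    scale ``sigma * sqrt(n)`` (approximate only because of truncation).
    """
    if n < 0:
        raise ParameterError("n must be nonnegative")
    img = as_float_image(image).copy()
    if n == 0:
        return img
    k1 = gaussian_kernel_1d(sigma, radius)
    for _ in range(n):
        img = ndi.convolve1d(img, k1, axis=0, mode="reflect")
        img = ndi.convolve1d(img, k1, axis=1, mode="reflect")
    return img


def graymorph_reference(
    image, open_radius: int = 5, close_radius: int = 5
) -> np.ndarray:
    """Grayscale opening-by-reconstruction then closing-by-reconstruction.

    Removes bright structures narrower than the opening disk and dark ones
    narrower than the closing disk without displacing remaining edges; the
    output range never exceeds the input range.
    """
    if open_radius < 1 or close_radius < 1:
        raise ParameterError("radii must be >= 1")
    img = as_float_image(image)
    eroded = morphology.erosion(img, morphology.disk(open_radius))
    opened = morphology.reconstruction(eroded, img, method="dilation")
    dilated = morphology.dilation(opened, morphology.disk(close_radius))
    closed = morphology.reconstruction(dilated, opened, method="erosion")
    return closed


@dataclass
class ReferenceStack:
    """Ordered, uniquely named reference layers sharing the source shape."""

    layers: list[tuple[str, np.ndarray, dict]]

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.layers]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate layer names: {names}")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.layers]

    def get(self, name: str) -> np.ndarray:
        for layer_name, image, _ in self.layers:
            if layer_name == name:
                return image
        raise ConfigError(f"no reference layer named {name!r}; have {self.names}")


DEFAULT_STACK_CONFIG: list[dict] = [
    {"name": "original", "kind": "original"},
    {"name": "gauss20", "kind": "gaussian", "n": 20, "sigma": 1.0, "radius": 5},
    {
        "name": "graymorph",
        "kind": "graymorph",
        "base": "gauss20",
        "open_radius": 5,
        "close_radius": 5,
    },
]


def build_reference_stack(image, config: list[dict] | None = None) -> ReferenceStack:
    """Build the reference stack; the default is original / gauss20 / graymorph.

    Each config entry is a dict with a unique ``name`` and a ``kind`` of
    ``original``, ``gaussian`` (params n, sigma, radius) or ``graymorph``
    (params base layer name, open_radius, close_radius).
    """
    img = as_float_image(image)
    config = DEFAULT_STACK_CONFIG if config is None else config
    if not config:
        raise ConfigError("reference stack config lists no layers")
    layers: list[tuple[str, np.ndarray, dict]] = []

    def lookup(name: str) -> np.ndarray:
        for lname, limg, _ in layers:
            if lname == name:
                return limg
        raise ConfigError(f"graymorph base layer {name!r} not built yet")

    for entry in config:
        try:
            name, kind = entry["name"], entry["kind"]
        except KeyError as exc:
            raise ConfigError(f"layer spec missing {exc} field: {entry}") from exc
        if kind == "original":
            out = img.copy()
            prov = {"kind": "original"}
        elif kind == "gaussian":
            n = int(entry.get("n", 20))
            sigma = float(entry.get("sigma", 1.0))
            radius = int(entry.get("radius", 5))
            out = iterated_gaussian(img, sigma=sigma, n=n, radius=radius)
            prov = {"kind": "gaussian", "n": n, "sigma": sigma, "radius": radius}
        elif kind == "graymorph":
            base = entry.get("base", "original")
            open_radius = int(entry.get("open_radius", 5))
            close_radius = int(entry.get("close_radius", 5))
            out = graymorph_reference(
                lookup(base) if layers else img,
                open_radius=open_radius,
                close_radius=close_radius,
            )
            prov = {
                "kind": "graymorph",
                "base": base,
                "open_radius": open_radius,
                "close_radius": close_radius,
            }
        else:
            raise ConfigError(f"unknown reference layer kind {kind!r}")
        layers.append((name, out, prov))
    return ReferenceStack(layers=layers)
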