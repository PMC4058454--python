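"""Hierarchical patch extraction and mergence: the strategy algebra.

After the first local Otsu pass, every section (A1..A4) can itself be
re-partitioned: its 8-connected components become new local regions and
receive their own threshold triples against a (possibly different)
reference layer.  Nested selections are written with dotted class paths --
``sel(2.1)`` is the dark section of the prone-dark section (A2A1) -- and
combined with a small algebra:

* ``sel(PATH[@LAYER])`` -- select a (nested) class, optionally naming the
  reference layer for the deepest re-partition;
* ``union(E, E, ...)`` -- pixelwise OR;
* ``holes(E)`` -- interior background components fully enclosed by the
  mask (the hollow cell bodies inside bright-section rings);
* ``ws(E)`` -- watershed split of the mask (support unchanged).

Recursion is capped at depth 3: deeper digs yield no usable patches.
A strategy's top-level union members are its *layers*; the mergence step
dilates hole-derived layers slightly, ORs the layers with first-listed
priority for overlaps, clips to the maximum ROI and drops tiny fragments,
producing the raw segmentation result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .blur import ReferenceStack, build_reference_stack
from .errors import ConfigError, ParameterError, StrategyParseError
from .image_io import as_float_image
from .partition import ClassMap, class_select, local_otsu_classify, watershed_split
from .roi import RoiMask, area_open, max_roi_from_image

MAX_DEPTH = 3

#: default reference layer per re-partition level: coarse to fine
DEFAULT_LEVEL_LAYERS = {1: "gauss20", 2: "graymorph", 3: "original"}


# ---------------------------------------------------------------------------
# expression tree


@dataclass(frozen=True)
class Select:
    path: tuple[int, ...]
    layer: str | None = None

    def __str__(self) -> str:
        p = ".".join(str(c) for c in self.path)
        return f"sel({p}@{self.layer})" if self.layer else f"sel({p})"


@dataclass(frozen=True)
class Union:
    children: tuple

    def __str__(self) -> str:
        return "union(" + ", ".join(str(c) for c in self.children) + ")"


@dataclass(frozen=True)
class Holes:
    child: object

    def __str__(self) -> str:
        return f"holes({self.child})"


@dataclass(frozen=True)
class Ws:
    child: object

    def __str__(self) -> str:
        return f"ws({self.child})"


StrategyExpr = Select | Union | Holes | Ws


# ---------------------------------------------------------------------------
# parser (recursive descent)

_TOKEN = re.compile(r"\s*([a-z]+|\(|\)|,|[0-9.]+(?:@[A-Za-z_][A-Za-z0-9_]*)?)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise StrategyParseError(f"bad character at {text[pos:pos + 10]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _parse_path(token: str, known_layers) -> Select:
    layer = None
    if "@" in token:
        token, layer = token.split("@", 1)
        if known_layers is not None and layer not in known_layers:
            raise StrategyParseError(
                f"unknown layer {layer!r}; known layers: {sorted(known_layers)}"
            )
    parts = token.split(".")
    try:
        path = tuple(int(p) for p in parts)
    except ValueError:
        raise StrategyParseError(f"malformed class path {token!r}") from None
    if len(path) > MAX_DEPTH:
        raise StrategyParseError(
            f"class path {token!r} exceeds the depth limit of {MAX_DEPTH}"
        )
    if not path or any(c not in (1, 2, 3, 4) for c in path):
        raise StrategyParseError(f"class ids must be 1..4 in path {token!r}")
    return Select(path=path, layer=layer)


def parse_strategy(text: str, known_layers=None) -> StrategyExpr:
    """Parse a strategy string; printing the tree normalizes whitespace."""
    tokens = _tokenize(text)
    pos = 0

    def expect(tok: str) -> None:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos] != tok:
            got = tokens[pos] if pos < len(tokens) else "<end>"
            raise StrategyParseError(f"expected {tok!r}, got {got!r} in {text!r}")
        pos += 1

    def parse_expr() -> StrategyExpr:
        nonlocal pos
        if pos >= len(tokens):
            raise StrategyParseError(f"unexpected end of expression in {text!r}")
        head = tokens[pos]
        pos += 1
        if head == "sel":
            expect("(")
            if pos >= len(tokens):
                raise StrategyParseError(f"unexpected end after sel( in {text!r}")
            node = _parse_path(tokens[pos], known_layers)
            pos += 1
            expect(")")
            return node
        if head == "union":
            expect("(")
            children = [parse_expr()]
            while pos < len(tokens) and tokens[pos] == ",":
                pos += 1
                children.append(parse_expr())
            expect(")")
            return Union(children=tuple(children))
        if head in ("holes", "ws"):
            expect("(")
            child = parse_expr()
            expect(")")
            return Holes(child) if head == "holes" else Ws(child)
        raise StrategyParseError(f"unknown operator {head!r} in {text!r}")

    expr = parse_expr()
    if pos != len(tokens):
        raise StrategyParseError(f"trailing input {tokens[pos:]} in {text!r}")
    return expr


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class LayerContext:
    """Everything a strategy needs: base classification, references, ROI.

    ``cache`` memoizes re-partitions by (class path, layer name); cached
    entries are reproducible, so two evaluations of the same path are
    bit-identical.
    """

    base_class_map: ClassMap
    reference_stack: ReferenceStack
    roi: RoiMask
    level_layers: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEVEL_LAYERS))
    min_seed_distance: int = 10
    k: int = 3
    cache: dict = field(default_factory=dict)

    def layer_for_level(self, level: int) -> str:
        name = self.level_layers.get(level)
        if name is None:
            raise ConfigError(f"no reference layer bound for level {level}")
        return name


def _subroi_from_mask(mask: np.ndarray) -> RoiMask:
    regions, m = ndi.label(mask, structure=np.ones((3, 3)))
    return RoiMask(mask=mask, regions=regions, m=int(m))


def repartition(ctx: LayerContext, path: tuple[int, ...], layer: str | None = None) -> ClassMap:
    """ClassMap re-partitioning the region named by ``path``.

    ``path = ()`` is the base classification.  For a nonempty path, the
    parent class mask is resolved recursively (with the default layer
    bindings), its 8-connected components become local regions, and each
    is thresholded against the named reference layer.  Results are cached
    by (path, layer).
    """
    if len(path) >= MAX_DEPTH:
        raise ParameterError(f"re-partition beyond depth {MAX_DEPTH}: {path}")
    if not path:
        return ctx.base_class_map
    layer = layer or ctx.layer_for_level(len(path) + 1)
    key = (tuple(path), layer)
    if key in ctx.cache:
        return ctx.cache[key]
    parent_cm = repartition(ctx, path[:-1])
    parent_mask = class_select(parent_cm, {path[-1]})
    if not parent_mask.any():
        cm = ClassMap(labels=np.zeros(parent_mask.shape, dtype=np.uint8))
    else:
        subroi = _subroi_from_mask(parent_mask)
        cm = local_otsu_classify(ctx.reference_stack.get(layer), subroi, k=ctx.k)
    ctx.cache[key] = cm
    return cm


def extract_holes(mask) -> np.ndarray:
    """Interior holes: background 4-connected components not touching the
    image border, i.e. fully enclosed by the mask."""
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_fill_holes(mask) & ~mask


def resolve_select(ctx: LayerContext, node: Select) -> np.ndarray:
    cm = repartition(ctx, node.path[:-1], layer=node.layer if len(node.path) > 1 else None)
    if len(node.path) == 1 and node.layer is not None and node.layer != ctx.layer_for_level(1):
        raise ConfigError(
            "a depth-1 selection reads the base classification; its layer "
            f"binding {node.layer!r} conflicts with level 1 = "
            f"{ctx.layer_for_level(1)!r}"
        )
    return class_select(cm, {node.path[-1]})


def evaluate_strategy(expr: StrategyExpr | str, ctx: LayerContext) -> np.ndarray:
    """Evaluate an expression to a binary mask, clipped to the maximum ROI."""
    if isinstance(expr, str):
        expr = parse_strategy(expr, known_layers=ctx.reference_stack.names)
    return _evaluate(expr, ctx) & ctx.roi.mask


def _evaluate(expr: StrategyExpr, ctx: LayerContext) -> np.ndarray:
    if isinstance(expr, Select):
        return resolve_select(ctx, expr)
    if isinstance(expr, Union):
        out = np.zeros(ctx.roi.mask.shape, dtype=bool)
        for child in expr.children:
            out |= _evaluate(child, ctx)
        return out
    if isinstance(expr, Holes):
        return extract_holes(_evaluate(expr.child, ctx))
    if isinstance(expr, Ws):
        return watershed_split(
            _evaluate(expr.child, ctx), min_seed_distance=ctx.min_seed_distance
        ).labels > 0
    raise ConfigError(f"unknown expression node {expr!r}")


# ---------------------------------------------------------------------------
# mergence


@dataclass
class RawResult:
    """Merged raw segmentation mask with per-layer provenance."""

    mask: np.ndarray
    contributing_layers: list[tuple[str, np.ndarray]]
    strategy_id: str
    attribution: np.ndarray | None = field(default=None, repr=False)


def _is_hole_layer(expr: StrategyExpr) -> bool:
    return isinstance(expr, Holes)


def merge_to_raw(
    layer_masks: list[tuple[StrategyExpr | str, np.ndarray]],
    dilate_holes: int = 2,
    roi: RoiMask | None = None,
    min_fragment: int = 30,
    strategy_id: str = "",
) -> RawResult:
    """Merge informative layers into the raw segmentation result.

    Hole-derived layers are dilated by a small disk (the hollow areas sit
    strictly inside their rings and need expanding); layers are ORed with
    first-listed priority recorded in ``attribution``; the merge is clipped
    to the maximum ROI and fragments below ``min_fragment`` px are dropped.
    """
    if not layer_masks:
        raise ConfigError("merge_to_raw needs at least one layer")
    shape = np.asarray(layer_masks[0][1]).shape
    merged = np.zeros(shape, dtype=bool)
    attribution = np.zeros(shape, dtype=np.int32)
    processed: list[tuple[str, np.ndarray]] = []
    for i, (expr, mask) in enumerate(layer_masks, start=1):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ParameterError("all layer masks must share one shape")
        node = parse_strategy(expr) if isinstance(expr, str) else expr
        if _is_hole_layer(node) and dilate_holes > 0:
            mask = morphology.dilation(mask, morphology.disk(dilate_holes))
        if roi is not None:
            mask = mask & roi.mask
        attribution[mask & ~merged] = i
        merged |= mask
        processed.append((str(node), mask))
    merged = area_open(merged, min_fragment)
    attribution[~merged] = 0
    return RawResult(
        mask=merged,
        contributing_layers=processed,
        strategy_id=strategy_id,
        attribution=attribution,
    )


# ---------------------------------------------------------------------------
# shipped strategies and the full extraction pipeline

#: The composite mergence strategy: dark section, hollow bodies inside the
#: bright/prone-bright rings (re-partitioned), and the dark sub-sections of
#: the bright sections.
COMPOSITE_STRATEGY = (
    "union(sel(1), holes(union(sel(3.3), sel(3.4))), sel(3.1), "
    "holes(union(sel(4.3), sel(4.4))), sel(4.1), sel(4.2))"
)

DEFAULT_STRATEGIES: dict[str, str] = {
    "composite": COMPOSITE_STRATEGY,
    "dark-core": "union(sel(1), sel(2.1))",
    "dark-and-hollow": "union(sel(1), sel(2.1), holes(union(sel(2.3), sel(2.4))))",
}


def build_context(image, config=None) -> LayerContext:
    """Run ROI + reference-stack + base classification for one image."""
    from .config import RunConfig  # local import to avoid a cycle

    cfg = config or RunConfig()
    img = as_float_image(image)
    roi = max_roi_from_image(
        img,
        canny_params={s: {"sigma": cfg.canny_sigma} for s in (1.0, 0.5, 0.25)},
        close_radius=cfg.close_radius,
        erode_radius=cfg.erode_radius,
        min_region_area=cfg.min_region_area,
    )
    stack = build_reference_stack(img, cfg.reference_stack)
    base_cm = local_otsu_classify(stack.get(cfg.level_layers[1]), roi, k=cfg.k)
    return LayerContext(
        base_class_map=base_cm,
        reference_stack=stack,
        roi=roi,
        level_layers=dict(cfg.level_layers),
        min_seed_distance=cfg.min_seed_distance,
        k=cfg.k,
    )


def run_strategies(image, strategies=None, config=None) -> list[RawResult]:
    """Full extraction per strategy: ROI, references, base classification,
    strategy evaluation and mergence; one RawResult per strategy.

    ``strategies`` maps strategy ids to expression strings (or is a list of
    strings, which are used as their own ids).
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if strategies is None:
        strategies = dict(cfg.strategies)
    if isinstance(strategies, (list, tuple)):
        strategies = {s: s for s in strategies}
    if not strategies:
        raise ConfigError("need at least one strategy")
    ctx = build_context(image, cfg)
    results = []
    for sid, text in strategies.items():
        expr = parse_strategy(text, known_layers=ctx.reference_stack.names)
        members = list(expr.children) if isinstance(expr, Union) else [expr]
        layer_masks = [(m, evaluate_strategy(m, ctx)) for m in members]
        results.append(
            merge_to_raw(
                layer_masks,
                dilate_holes=cfg.dilate_holes,
                roi=ctx.roi,
                min_fragment=cfg.min_fragment,
                strategy_id=sid,
            )
        )
    return results


def score_raw_result(raw: RawResult, min_area: int = 60, max_area: int = 2500) -> float:
    """Opt-in heuristic score for automatic strategy picking: mean patch
    solidity times the count of patches in a plausible cell-area range.
    The default flow emits all results for manual inspection instead."""
    from skimage import measure

    labels, n = ndi.label(raw.mask, structure=np.ones((3, 3)))
    if n == 0:
        return 0.0
    props = measure.regionprops(labels)
    solid = [p.solidity for p in props if min_area <= p.area <= max_area]
    if not solid:
        return 0.0
    return float(np.mean(solid) * len(solid))
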