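"""Strategy grammar, hole extraction, recursive evaluation, mergence."""

import numpy as np
import pytest

from hma.errors import StrategyParseError
from hma.hierarchy import (
    COMPOSITE_STRATEGY,
    DEFAULT_STRATEGIES,
    Holes,
    Select,
    Union,
    build_context,
    evaluate_strategy,
    extract_holes,
    merge_to_raw,
    parse_strategy,
    repartition,
    run_strategies,
)
from hma.partition import class_select
from .oracles import flood_fill_holes


class TestParser:
    def test_simple_select(self):
        expr = parse_strategy("sel(1)")
        assert expr == Select(path=(1,))

    def test_nested_holes_union(self):
        expr = parse_strategy("holes(union(sel(2.3), sel(2.4)))")
        assert isinstance(expr, Holes)
        assert expr.child == Union(
            children=(Select(path=(2, 3)), Select(path=(2, 4)))
        )

    def test_layer_binding(self):
        expr = parse_strategy("sel(3.1@original)", known_layers=["original"])
        assert expr == Select(path=(3, 1), layer="original")
        with pytest.raises(StrategyParseError):
            parse_strategy("sel(3.1@nope)", known_layers=["original"])

    @pytest.mark.parametrize(
        "bad",
        [
            "sel(1.2.3.4)",  # depth 4
            "sel(5)",  # unknown class id
            "sel()",
            "union(sel(1)",  # unbalanced
            "frob(sel(1))",  # unknown operator
            "sel(1) sel(2)",  # trailing input
        ],
    )
    def test_rejects_malformed(self, bad):
        with pytest.raises(StrategyParseError):
            parse_strategy(bad)

    def test_round_trip_normalizes_whitespace(self):
        text = "union( sel(1),holes( union(sel(2.3) , sel(2.4)) ) )"
        expr = parse_strategy(text)
        assert parse_strategy(str(expr)) == expr

    def test_composite_strategy_parses(self):
        expr = parse_strategy(COMPOSITE_STRATEGY)
        assert isinstance(expr, Union)
        assert len(expr.children) == 6


class TestExtractHoles:
    def test_solid_disk_no_holes(self, disk_image):
        _, mask = disk_image
        assert not extract_holes(mask).any()

    def test_annulus_hole_is_interior_disk(self):
        yy, xx = np.mgrid[:64, :64]
        r = np.hypot(yy - 32, xx - 32)
        ring = (r <= 20) & (r >= 14)
        holes = extract_holes(ring)
        np.testing.assert_array_equal(holes, r < 14)

    def test_matches_flood_fill_oracle_on_random_masks(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(0)
        for _ in range(20):
            noise = ndi.gaussian_filter(rng.normal(size=(64, 64)), 3)
            mask = noise > np.quantile(noise, 0.6)
            np.testing.assert_array_equal(
                extract_holes(mask), flood_fill_holes(mask)
            )

    def test_holes_of_holes_empty(self):
        yy, xx = np.mgrid[:64, :64]
        r = np.hypot(yy - 32, xx - 32)
        ring = (r <= 20) & (r >= 14)
        assert not extract_holes(extract_holes(ring)).any()


@pytest.fixture(scope="module")
def ctx(scene_factory):
    return build_context(scene_factory(1).image.pixels)


class TestEvaluate:
    def test_base_select_equals_class_select(self, ctx):
        got = evaluate_strategy("sel(1)", ctx)
        np.testing.assert_array_equal(
            got, class_select(ctx.base_class_map, {1}) & ctx.roi.mask
        )

    def test_repartition_partitions_parent_class(self, ctx):
        parent = class_select(ctx.base_class_map, {2})
        cm = repartition(ctx, (2,))
        assert (cm.labels > 0).sum() == parent.sum()
        assert not (cm.labels > 0)[~parent].any()

    def test_repartition_deterministic_and_cached(self, ctx):
        a = repartition(ctx, (3,))
        b = repartition(ctx, (3,))
        assert a is b  # cache hit
        fresh = build_context_like(ctx)
        c = repartition(fresh, (3,))
        np.testing.assert_array_equal(a.labels, c.labels)

    def test_union_idempotent(self, ctx):
        single = evaluate_strategy("sel(1)", ctx)
        double = evaluate_strategy("union(sel(1), sel(1))", ctx)
        np.testing.assert_array_equal(single, double)

    def test_union_commutative(self, ctx):
        ab = evaluate_strategy("union(sel(1), sel(3.1))", ctx)
        ba = evaluate_strategy("union(sel(3.1), sel(1))", ctx)
        np.testing.assert_array_equal(ab, ba)

    def test_composite_equals_or_of_members(self, ctx):
        expr = parse_strategy(COMPOSITE_STRATEGY)
        whole = evaluate_strategy(expr, ctx)
        acc = np.zeros_like(whole)
        for child in expr.children:
            acc |= evaluate_strategy(child, ctx)
        np.testing.assert_array_equal(whole, acc)

    def test_results_contained_in_roi(self, ctx):
        for text in DEFAULT_STRATEGIES.values():
            mask = evaluate_strategy(text, ctx)
            assert not (mask & ~ctx.roi.mask).any()

    def test_empty_class_repartition_empty(self, ctx):
        # dig into a path then once more; depth-3 paths always evaluate
        mask = evaluate_strategy("sel(1.1.1)", ctx)
        assert mask.shape == ctx.roi.mask.shape

    def test_depth_limit_enforced(self, ctx):
        from hma.errors import ParameterError

        with pytest.raises(ParameterError):
            repartition(ctx, (1, 1, 1))  # would re-partition a depth-3 node


def build_context_like(ctx):
    from hma.hierarchy import LayerContext

    return LayerContext(
        base_class_map=ctx.base_class_map,
        reference_stack=ctx.reference_stack,
        roi=ctx.roi,
        level_layers=ctx.level_layers,
    )


class TestMerge:
    def test_single_layer_identity(self, ctx):
        mask = evaluate_strategy("sel(1)", ctx)
        raw = merge_to_raw([("sel(1)", mask)], roi=ctx.roi, min_fragment=1)
        np.testing.assert_array_equal(raw.mask, mask & ctx.roi.mask)

    def test_disjoint_layers_attributed(self):
        a = np.zeros((32, 32), dtype=bool)
        b = np.zeros((32, 32), dtype=bool)
        a[4:10, 4:10] = True
        b[20:26, 20:26] = True
        raw = merge_to_raw([("sel(1)", a), ("sel(2)", b)], min_fragment=1)
        np.testing.assert_array_equal(raw.mask, a | b)
        assert np.all(raw.attribution[a] == 1)
        assert np.all(raw.attribution[b] == 2)

    def test_overlap_goes_to_first_layer(self):
        a = np.zeros((32, 32), dtype=bool)
        b = np.zeros((32, 32), dtype=bool)
        a[4:12, 4:12] = True
        b[8:16, 8:16] = True
        raw = merge_to_raw([("sel(1)", a), ("sel(2)", b)], min_fragment=1)
        assert np.all(raw.attribution[a] == 1)
        assert np.all(raw.attribution[b & ~a] == 2)

    def test_hole_layers_dilated_but_capped_by_roi(self, ctx):
        expr = "holes(union(sel(3.3), sel(3.4)))"
        mask = evaluate_strategy(expr, ctx)
        raw = merge_to_raw(
            [(expr, mask)], dilate_holes=2, roi=ctx.roi, min_fragment=1
        )
        assert not (raw.mask & ~ctx.roi.mask).any()
        if mask.any():
            assert raw.mask.sum() >= mask.sum()


class TestRunStrategies:
    def test_three_strategies_differ(self, scene_factory):
        scene = scene_factory(1)
        results = run_strategies(scene.image.pixels)
        assert len(results) == 3
        masks = [r.mask for r in results]
        assert not np.array_equal(masks[0], masks[1])
        assert not np.array_equal(masks[0], masks[2])

    def test_all_raw_results_inside_roi(self, scene_factory):
        scene = scene_factory(2)
        ctx = build_context(scene.image.pixels)
        results = run_strategies(scene.image.pixels)
        for raw in results:
            assert not (raw.mask & ~ctx.roi.mask).any()

    def test_single_strategy_singleton(self, scene_factory):
        scene = scene_factory(1)
        results = run_strategies(scene.image.pixels, strategies=["sel(1)"])
        assert len(results) == 1
        assert results[0].strategy_id == "sel(1)"
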