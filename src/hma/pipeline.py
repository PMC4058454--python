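"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` chains the stages -- maximum ROI, reference stack, local
Otsu, hierarchical extraction and mergence, watershed splitting, SVM
filtering, optional evaluation -- writes every intermediate layer next to
the final label map, and records the exact configuration used, so any
panel of the intermediate imagery can be regenerated from files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import PatchFilterModel, compute_features, filter_patches, split_raw
from .config import RunConfig
from .errors import HmaError
from .evaluate import MatchReport, match_cells
from .hierarchy import RawResult, build_context, evaluate_strategy, merge_to_raw, parse_strategy, score_raw_result
from .hierarchy import Union as UnionExpr
from .image_io import (
    IntensityImage,
    as_float_image,
    read_grayscale,
    write_grayscale,
    write_label_map,
    write_mask,
)
from .partition import LabelMap

logger = logging.getLogger("hma")


@dataclass
class PipelineResult:
    raw_results: list[RawResult]
    picked: str
    candidates: LabelMap
    final: LabelMap
    report: MatchReport | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _stage(timings: dict[str, float], name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            timings[name] = round(dt, 4)
            logger.info("stage %-12s %.2fs", name, dt)

    return _T()


def run_pipeline(
    image,
    config: RunConfig | None = None,
    gt: np.ndarray | None = None,
    model: PatchFilterModel | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full detection pipeline on one image.

    ``image`` may be a path, an :class:`IntensityImage` or a bare array.
    When ``model`` is None and the config names no model file, the raw
    watershed candidates pass through unfiltered.  When ``gt`` is given a
    cell-level match report is appended.  All outputs (masks, label maps,
    provenance JSON, the exact config) are written under ``out_dir`` when
    given.
    """
    cfg = config or RunConfig()
    if isinstance(image, (str, Path)):
        image = read_grayscale(image)
    img = as_float_image(image)
    timings: dict[str, float] = {}

    with _stage(timings, "context"):
        ctx = build_context(img, cfg)
    raw_results: list[RawResult] = []
    with _stage(timings, "strategies"):
        for sid, text in cfg.strategies.items():
            expr = parse_strategy(text, known_layers=ctx.reference_stack.names)
            members = list(expr.children) if isinstance(expr, UnionExpr) else [expr]
            layer_masks = [(m, evaluate_strategy(m, ctx)) for m in members]
            raw_results.append(
                merge_to_raw(
                    layer_masks,
                    dilate_holes=cfg.dilate_holes,
                    roi=ctx.roi,
                    min_fragment=cfg.min_fragment,
                    strategy_id=sid,
                )
            )
    if cfg.pick == "auto":
        picked = max(raw_results, key=score_raw_result).strategy_id
    else:
        picked = raw_results[0].strategy_id
    raw = next(r for r in raw_results if r.strategy_id == picked)

    with _stage(timings, "split"):
        candidates = split_raw(raw, min_seed_distance=cfg.min_seed_distance)
    logger.info("candidate patches: %d", candidates.n_labels)

    if model is None and cfg.model_path:
        model = PatchFilterModel.load(cfg.model_path)
    with _stage(timings, "filter"):
        if model is not None and candidates.n_labels > 0:
            feats = compute_features(candidates, img)
            final = filter_patches(candidates, feats, model)
        else:
            final = candidates
    logger.info("final patches: %d", final.n_labels)

    report = None
    if gt is not None:
        with _stage(timings, "evaluate"):
            report = match_cells(final, gt)
        logger.info(
            "cell-level accuracy %.3f precision %.3f",
            report.accuracy,
            report.precision,
        )

    result = PipelineResult(
        raw_results=raw_results,
        picked=picked,
        candidates=candidates,
        final=final,
        report=report,
        timings=timings,
    )
    if out_dir is not None:
        _write_outputs(result, ctx, cfg, img, Path(out_dir))
    return result


def _write_outputs(result, ctx, cfg, img, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")
    write_mask(ctx.roi.mask, out / "roi_mask.png")
    for name, layer, _prov in ctx.reference_stack.layers:
        write_grayscale(layer, out / f"ref_{name}.tif")
    write_label_map(
        ctx.base_class_map.labels.astype(np.int32), out / "base_classes.tif"
    )
    provenance = {
        "picked": result.picked,
        "timings": result.timings,
        "strategies": {},
    }
    for raw in result.raw_results:
        write_mask(raw.mask, out / f"raw_{raw.strategy_id}.png")
        provenance["strategies"][raw.strategy_id] = [
            expr for expr, _ in raw.contributing_layers
        ]
    write_label_map(result.candidates.labels, out / "candidates.tif")
    write_label_map(result.final.labels, out / "final.tif")
    if result.report is not None:
        (out / "report.json").write_text(
            json.dumps(result.report.to_dict(), indent=2) + "\n"
        )
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
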