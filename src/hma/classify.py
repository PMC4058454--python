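"""Patch filtering: remove non-cell patches with a trained SVM.

The raw mergence result still contains redundant patches (halo debris,
background slivers).  Each candidate patch -- a watershed label of the raw
mask -- is described by morphological features (area, perimeter,
eccentricity, solidity, extent), intensity statistics, mean gradient
magnitude and a uniform local-binary-pattern texture histogram (P = 8
neighbours, R = 1, 10 bins, L1-normalized), then classified cell /
non-cell by an RBF support-vector machine trained on synthetic scenes
whose ground truth supplies the labels: a patch is a positive example iff
at least half of its pixels lie inside one ground-truth cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import filters, measure
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError, TrainingError
from .hierarchy import COMPOSITE_STRATEGY, RawResult, run_strategies
from .image_io import as_float_image
from .partition import LabelMap, watershed_split

LBP_P, LBP_R = 8, 1
LBP_BINS = LBP_P + 2  # uniform method: P + 2 codes

FEATURE_COLUMNS = [
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "extent",
    "mean_intensity",
    "std_intensity",
    "mean_gradient",
    *[f"lbp_{i}" for i in range(LBP_BINS)],
]


def split_raw(raw: RawResult, min_seed_distance: int = 10) -> LabelMap:
    """Watershed-split the raw mask into candidate cell patches."""
    return watershed_split(raw.mask, min_seed_distance=min_seed_distance)


def compute_features(labels: LabelMap | np.ndarray, image) -> pd.DataFrame:
    """One feature row per patch label, indexed by label id.

    The LBP histogram is computed on the patch's (1-px padded) bounding
    box and accumulated over the patch pixels only.  One-pixel patches get
    degenerate but finite features (perimeter 4, a single LBP code).
    """
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    img = as_float_image(image)
    if lab.shape != img.shape:
        raise ParameterError(f"label shape {lab.shape} != image shape {img.shape}")
    grad = np.hypot(filters.sobel_h(img), filters.sobel_v(img))
    rows = []
    index = []
    for prop in measure.regionprops(lab, intensity_image=img):
        r0, c0, r1, c1 = prop.bbox
        r0p, c0p = max(r0 - 1, 0), max(c0 - 1, 0)
        r1p, c1p = min(r1 + 1, img.shape[0]), min(c1 + 1, img.shape[1])
        # LBP wants integer gray levels; 8-bit quantization is standard
        box = np.clip(np.rint(img[r0p:r1p, c0p:c1p] * 255), 0, 255).astype(np.uint8)
        codes = skfeature.local_binary_pattern(box, LBP_P, LBP_R, method="uniform")
        inside = lab[r0p:r1p, c0p:c1p] == prop.label
        hist = np.bincount(
            codes[inside].astype(np.int64), minlength=LBP_BINS
        ).astype(np.float64)
        hist /= max(hist.sum(), 1.0)
        patch_pixels = lab == prop.label
        perimeter = float(prop.perimeter) if prop.perimeter > 0 else 4.0
        rows.append(
            [
                float(prop.area),
                perimeter,
                float(prop.eccentricity),
                float(prop.solidity),
                float(prop.extent),
                float(prop.intensity_mean),
                float(img[patch_pixels].std()),
                float(grad[patch_pixels].mean()),
                *hist.tolist(),
            ]
        )
        index.append(int(prop.label))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=index)


@dataclass
class PatchFilterModel:
    """Trained cell / non-cell patch classifier with its scaling baked in."""

    pipeline: Pipeline
    feature_columns: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if features.empty:
            return np.zeros(0, dtype=bool)
        X = features[self.feature_columns].to_numpy()
        return self.pipeline.predict(X).astype(bool)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "pipeline": self.pipeline,
                "feature_columns": self.feature_columns,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchFilterModel":
        payload = joblib.load(path)
        return cls(
            pipeline=payload["pipeline"],
            feature_columns=payload["feature_columns"],
            metadata=payload["metadata"],
        )


def label_patches_by_gt(
    labels: LabelMap, gt: np.ndarray, min_overlap: float = 0.5
) -> np.ndarray:
    """Supervision rule: positive iff >= min_overlap of the patch's pixels
    lie inside a single ground-truth cell."""
    lab = labels.labels
    y = np.zeros(labels.n_labels, dtype=bool)
    for i in range(1, labels.n_labels + 1):
        sel = lab == i
        inside = gt[sel]
        inside = inside[inside > 0]
        if inside.size == 0:
            continue
        top = np.bincount(inside).max()
        y[i - 1] = top / sel.sum() >= min_overlap
    return y


def _patches_for_scene(scene, config):
    raws = run_strategies(
        scene.image, strategies={"composite": COMPOSITE_STRATEGY}, config=config
    )
    cfg_msd = config.min_seed_distance if config is not None else 10
    labels = split_raw(raws[0], min_seed_distance=cfg_msd)
    feats = compute_features(labels, scene.image)
    return labels, feats


def train_filter(
    scenes,
    config=None,
    seed: int = 0,
    min_overlap: float = 0.5,
) -> PatchFilterModel:
    """Train the patch filter on synthetic scenes with known ground truth.

    The last scene is held out for the reported accuracy; hyperparameters
    come from a small C-grid under 3-fold cross-validation with a fixed
    shuffle seed.
    """
    from .config import RunConfig

    scenes = list(scenes)
    if len(scenes) < 2:
        raise TrainingError("need at least 2 scenes (one is held out)")
    config = config or RunConfig()
    X_parts, y_parts = [], []
    held_labels = held_feats = held_scene = None
    for i, scene in enumerate(scenes):
        labels, feats = _patches_for_scene(scene, config)
        y = label_patches_by_gt(labels, scene.gt_labels, min_overlap=min_overlap)
        if i == len(scenes) - 1:
            held_labels, held_feats, held_scene = labels, feats, scene
            held_y = y
        else:
            X_parts.append(feats)
            y_parts.append(y)
    X = pd.concat(X_parts).to_numpy()
    y = np.concatenate(y_parts)
    if np.unique(y).size < 2:
        raise TrainingError(
            "training patches are single-class; widen the scene set"
        )
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", gamma="scale"))]
    )
    n_min = int(np.bincount(y.astype(int)).min())
    if n_min >= 2:
        search = GridSearchCV(
            pipe,
            {"svc__C": [1.0, 10.0, 100.0]},
            cv=StratifiedKFold(
                n_splits=min(3, n_min), shuffle=True, random_state=seed % (2**31)
            ),
            n_jobs=1,
        )
        search.fit(X, y)
        best = search.best_estimator_
        best_c = float(search.best_params_["svc__C"])
    else:  # too few minority examples to cross-validate
        pipe.set_params(svc__C=10.0)
        best = pipe.fit(X, y)
        best_c = 10.0
    model = PatchFilterModel(
        pipeline=best,
        feature_columns=FEATURE_COLUMNS,
        metadata={
            "seed": int(seed),
            "n_samples": int(y.size),
            "n_positive": int(y.sum()),
            "best_C": best_c,
        },
    )
    if held_feats is not None and not held_feats.empty:
        pred = model.predict(held_feats)
        model.metadata["heldout_accuracy"] = float((pred == held_y).mean())
        model.metadata["heldout_n"] = int(held_y.size)
    return model


def filter_patches(
    labels: LabelMap, features: pd.DataFrame, model: PatchFilterModel
) -> LabelMap:
    """Drop patches predicted non-cell; renumber survivors 1..n.

    Surviving regions keep their exact pixel sets -- the filter never adds
    or moves pixels.
    """
    if len(features) != labels.n_labels:
        raise ParameterError(
            f"{len(features)} feature rows for {labels.n_labels} labels"
        )
    keep = model.predict(features)
    keep_ids = [int(i) for i, k in zip(features.index, keep) if k]
    out = np.zeros_like(labels.labels)
    for new_id, old_id in enumerate(sorted(keep_ids), start=1):
        out[labels.labels == old_id] = new_id
    return LabelMap(labels=out, n_labels=len(keep_ids))
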