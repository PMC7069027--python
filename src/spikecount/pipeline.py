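"""End-to-end orchestration: configuration, training, counting, evaluation.

Binds the five computational stages into the full workflow:

    scenes/images -> color indices -> superpixels -> (labels) -> classifier
                  -> spike mask -> morphology -> count -> evaluation

All stages are deterministic given the configuration and its seeds; a run
manifest (JSON) records the configuration snapshot, seeds, outputs and
per-stage wall-clock so any run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import counting
from .classify import (
    CVReport,
    TrainedModel,
    build_zoo,
    baseline_threshold_segment,
    fit_model,
    predict_mask,
    select_best,
    train_and_score,
)
from .counting import CountParams, CountResult, EvalResult, evaluate
from .features import SPIKE, image_features
from .superpixels import (
    DEFAULT_COMPACTNESS,
    aggregate_features,
    assign_labels,
    scale_n,
    slic_segment,
)
from .synthetic import SceneConfig, generate_dataset

__all__ = [
    "PipelineConfig",
    "TrainConfig",
    "RunManifest",
    "load_config",
    "dump_config",
    "run_train",
    "run_count",
    "run_evaluate",
    "segment_image",
    "save_model",
    "load_model",
]

_VERSION = "0.1.0"


@dataclass(frozen=True)
class TrainConfig:
    n_scenes: int = 6
    crop_size: int | None = 250  # None: use whole scenes
    crops_per_scene: int = 5
    label_threshold: float = 0.8
    zoo_subset: tuple[str, ...] | None = None  # None: all 12
    n_folds: int = 5
    seed: int = 0


def _default_counting() -> CountParams:
    # counting parameters matched to the default synthetic geometry
    # (spike width 24-38 px, superpixel ~11 px across): opening at a quarter
    # spike width smooths classification raggedness, the area floor is below
    # half the smallest spike, and the tangent window and suppression
    # distance span a junction smear (~ one spike width); 40 deg sits under
    # the leaning-spike elbows (55-80 deg, measured lower after smear) while
    # scale validation inside count_inflections rejects boundary wiggle
    return CountParams(
        open_radius=5,
        min_area=1200,
        window=12,
        angle_threshold=40.0,
        min_separation=25,
        spur_length=24,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run.

    The defaults target the default synthetic-scene geometry (972 x 1296
    frame, spikes 120-200 px long).  ``superpixel_n = 10000`` keeps 2-3
    superpixels across a spike there; pass ``superpixel_n=None`` to fall
    back to area-proportional scaling (appropriate for full-size 2592 x 1944
    photographs), and ``scale_counting_params=True`` to rescale the area
    parameters with frame size.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    compactness: float = DEFAULT_COMPACTNESS
    superpixel_n: int | None = 10_000
    counting: CountParams = field(default_factory=_default_counting)
    scale_counting_params: bool = False
    baseline: bool = False


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{name: data[name] for name in names if name in data})


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    nested = {"scene": SceneConfig, "train": TrainConfig, "counting": CountParams}
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if key in nested:
            value = _tupleize(_from_dict(nested[key], value), nested[key])
        kwargs[key] = value
    if "train" in kwargs and isinstance(kwargs["train"].zoo_subset, list):
        kwargs["train"] = replace(
            kwargs["train"], zoo_subset=tuple(kwargs["train"].zoo_subset)
        )
    return PipelineConfig(**kwargs)


def _tupleize(obj, cls):
    # YAML lists arrive as lists; range-like fields are tuples
    updates = {}
    for f in dataclasses.fields(cls):
        v = getattr(obj, f.name)
        if isinstance(v, list):
            updates[f.name] = tuple(v)
    return replace(obj, **updates) if updates else obj


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    version: str = _VERSION

    def save(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=default)


# ---------------------------------------------------------------------------
# stage helpers


def _superpixel_records(image: np.ndarray, config: PipelineConfig):
    features = image_features(image)
    h, w = image.shape[:2]
    if config.superpixel_n:
        # superpixel_n is stated for the configured scene frame; smaller
        # inputs (training crops) get a count proportional to area so the
        # superpixel size stays the same everywhere
        frame = config.scene.image_height * config.scene.image_width
        n = max(round(config.superpixel_n * (h * w) / frame), 16)
    else:
        n = scale_n(h, w)
    spmap = slic_segment(image, n=n, m=config.compactness)
    records = aggregate_features(spmap, features)
    return features, spmap, records


def _training_records(config: PipelineConfig):
    """Labeled superpixel records pooled over training crops."""
    scenes = generate_dataset(
        config.train.n_scenes, config.scene, base_seed=config.train.seed
    )
    rng = np.random.Generator(np.random.PCG64(config.train.seed + 7919))
    records = []
    for image, truth in scenes:
        spike_mask = truth.class_map == SPIKE
        crops = _crop_boxes(image.shape[:2], config.train, rng)
        for r0, c0, hs, ws in crops:
            sub = image[r0 : r0 + hs, c0 : c0 + ws]
            sub_mask = spike_mask[r0 : r0 + hs, c0 : c0 + ws]
            _, spmap, recs = _superpixel_records(sub, config)
            records.extend(
                assign_labels(
                    recs, spmap, sub_mask, threshold=config.train.label_threshold
                )
            )
    return records


def _crop_boxes(shape, train: TrainConfig, rng) -> list[tuple[int, int, int, int]]:
    h, w = shape
    if train.crop_size is None or train.crop_size >= min(h, w):
        return [(0, 0, h, w)]  # whole frame
    size = train.crop_size
    return [
        (
            int(rng.integers(0, h - size + 1)),
            int(rng.integers(0, w - size + 1)),
            size,
            size,
        )
        for _ in range(train.crops_per_scene)
    ]


# ---------------------------------------------------------------------------
# public stages


def run_train(
    config: PipelineConfig,
) -> tuple[TrainedModel, list[CVReport], pd.DataFrame]:
    """Assemble labeled training records, score the zoo, fit the best spec.

    Returns the fitted model, the per-spec cross-validation reports, and a
    table of mean accuracies in zoo order.
    """
    records = _training_records(config)
    zoo = build_zoo()
    if config.train.zoo_subset:
        wanted = set(config.train.zoo_subset)
        zoo = [s for s in zoo if s.code in wanted]
        if not zoo:
            raise ValueError(f"zoo subset matched nothing: {config.train.zoo_subset}")
    reports = [
        train_and_score(
            records, spec, n_folds=config.train.n_folds, seed=config.train.seed
        )
        for spec in zoo
    ]
    best_code = select_best(reports)
    best_spec = next(s for s in zoo if s.code == best_code)
    model = fit_model(records, best_spec)
    table = pd.DataFrame(
        {
            "classifier": [r.spec_code for r in reports],
            "mean_accuracy_pct": [100 * r.mean_accuracy for r in reports],
            "n_samples": [r.n_samples for r in reports],
        }
    )
    return model, reports, table


def segment_image(
    image: np.ndarray, model: TrainedModel, config: PipelineConfig
) -> np.ndarray:
    """Predict the binary spike mask of one image with a trained model."""
    _, spmap, records = _superpixel_records(image, config)
    return predict_mask(model, records, spmap)


def count_one(
    image: np.ndarray, model: TrainedModel, config: PipelineConfig
) -> CountResult:
    mask = segment_image(image, model, config)
    params = config.counting
    if config.scale_counting_params:
        params = params.scaled(*image.shape[:2])
    return counting.count_image(mask, params)


def run_count(
    config: PipelineConfig,
    model: TrainedModel,
    images: list[tuple[str, np.ndarray]],
) -> pd.DataFrame:
    """Count spikes in each (image_id, image) pair; returns the counts table."""
    rows = []
    for image_id, image in images:
        result = count_one(image, model, config)
        rows.append((image_id, result.n_region, result.n_point, result.total))
    return pd.DataFrame(rows, columns=["image_id", "n_region", "n_point", "total"])


def run_count_baseline(
    config: PipelineConfig, images: list[tuple[str, np.ndarray]]
) -> pd.DataFrame:
    """Pixel-threshold control path: Otsu on Eg and Dgr, then the same count."""
    rows = []
    for image_id, image in images:
        mask = baseline_threshold_segment(image_features(image))
        params = config.counting
        if config.scale_counting_params:
            params = params.scaled(*image.shape[:2])
        result = counting.count_image(mask, params)
        rows.append((image_id, result.n_region, result.n_point, result.total))
    return pd.DataFrame(rows, columns=["image_id", "n_region", "n_point", "total"])


def run_evaluate(
    counts: pd.DataFrame,
    manual: pd.DataFrame,
    group_col: str | None = None,
) -> tuple[pd.DataFrame, dict[str, EvalResult]]:
    """Join automatic and manual counts on image_id and evaluate.

    ``manual`` needs columns image_id and manual_count (optionally a group
    column for per-treatment summaries).  Returns the per-image table and a
    dict of EvalResults keyed by group name plus "pooled".
    """
    missing = set(counts["image_id"]) ^ set(manual["image_id"])
    if missing:
        raise ValueError(f"unmatched image ids: {sorted(missing)}")
    merged = counts.merge(manual, on="image_id")
    merged["A"] = [
        counting.accuracy(c, a)
        for c, a in zip(merged["total"], merged["manual_count"])
    ]
    results: dict[str, EvalResult] = {}
    pairs = list(zip(merged["total"], merged["manual_count"]))
    results["pooled"] = evaluate(pairs)
    if group_col is not None:
        for name, grp in merged.groupby(group_col):
            results[str(name)] = evaluate(
                list(zip(grp["total"], grp["manual_count"]))
            )
    return merged, results


# ---------------------------------------------------------------------------
# file I/O


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "spec_code": model.spec_code,
            "feature_names": model.feature_names,
            "pipeline": model.pipeline,
            "version": _VERSION,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(
        spec_code=blob["spec_code"],
        pipeline=blob["pipeline"],
        feature_names=tuple(blob["feature_names"]),
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as 8-bit RGB (16-bit inputs are rescaled with a warning)."""
    import warnings

    img = Image.open(path)
    arr = np.asarray(img)
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit image rescaled to 8-bit", stacklevel=2)
        arr = (arr / 257.0).round().astype(np.uint8)
    if arr.ndim == 2:
        raise ValueError(f"{path}: expected an RGB image, got a single channel")
    return arr[..., :3]


def write_scene(
    out_dir: str | Path, scene_id: str, image: np.ndarray, truth
) -> dict[str, str]:
    """Write a scene image, class map, instance map and truth row files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    img_path = out_dir / f"{scene_id}.png"
    Image.fromarray(image).save(img_path)
    paths["image"] = str(img_path)

    cls = Image.fromarray(truth.class_map, mode="P")
    cls.putpalette([120, 80, 40, 40, 160, 40, 200, 190, 60] + [0] * (768 - 9))
    cls_path = out_dir / f"{scene_id}_classes.png"
    cls.save(cls_path)
    paths["class_map"] = str(cls_path)

    # indexed instance map: 0 = none, i+1 = spike i (topmost wins on overlap)
    inst = np.zeros(truth.class_map.shape, dtype=np.uint16)
    for i, mask in enumerate(truth.instance_masks):
        inst[mask] = i + 1
    inst_path = out_dir / f"{scene_id}_instances.png"
    Image.fromarray(inst).save(inst_path)
    paths["instances"] = str(inst_path)
    return paths
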