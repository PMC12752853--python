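"""Image and run-directory I/O.

Pixel values are never rescaled on read: an 8/16-bit integer or float file
comes back as the same numbers in float64.  Normalization, when needed, is
an explicit pipeline step (the offset mode of the box-counting config).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .bemd import SiftConfig
from .classify import SvmConfig, cross_validate, decision_threshold
from .multifractal import BoxCountingConfig
from .pipeline import PipelineConfig, batch_extract, export_feature_table
from .synthetic import CascadeSpec, TwoClassDatasetSpec, generate_two_class_dataset

logger = logging.getLogger(__name__)

__all__ = ["read_image", "write_image", "RunConfig", "run_pipeline", "load_run_config"]

_SUPPORTED = {".png", ".tif", ".tiff", ".pgm"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF/PGM as float64, values preserved."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise IOError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        raise IOError(
            f"{path} is a multi-channel image; convert it to grayscale "
            "explicitly before analysis (values are never silently mixed)"
        )
    return np.asarray(arr, dtype=np.float64)


def write_image(path: str | Path, image: np.ndarray) -> Path:
    """Write float data as 32-bit TIFF, or quantized 16-bit PNG/PGM.

    PNG/PGM are integer formats: float input is linearly mapped onto the
    uint16 range (the TIFF route is lossless and preferred for modes).
    """
    path = Path(path)
    img = np.asarray(image)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, img.astype(np.float32))
    elif suffix in (".png", ".pgm"):
        if np.issubdtype(img.dtype, np.integer):
            iio.imwrite(path, img.astype(np.uint16))
        else:
            lo, hi = float(img.min()), float(img.max())
            scale = 65535.0 / (hi - lo) if hi > lo else 0.0
            iio.imwrite(path, ((img - lo) * scale).astype(np.uint16))
    else:
        raise IOError(f"unsupported output format {suffix!r}")
    return path


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    synth: TwoClassDatasetSpec | None = None
    manifest_path: str | None = None  # CSV path,label — used when synth is None
    out_dir: str = "run"
    log_level: str = "INFO"


def _spec_from_dict(d: dict) -> TwoClassDatasetSpec:
    def cascade(sub: dict) -> CascadeSpec:
        return CascadeSpec(
            weights=tuple(sub["weights"]),
            depth=int(sub["depth"]),
            randomize_placement=bool(sub.get("randomize_placement", True)),
            seed=int(sub.get("seed", 0)),
        )

    kwargs = {}
    for key in ("n_per_class", "background_amplitude", "noise_sd", "seed"):
        if key in d:
            kwargs[key] = d[key]
    if "class_a" in d:
        kwargs["class_a"] = cascade(d["class_a"])
    if "class_b" in d:
        kwargs["class_b"] = cascade(d["class_b"])
    return TwoClassDatasetSpec(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; omitted sections keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sift = SiftConfig(**raw.get("sift", {}))
    boxes_raw = dict(raw.get("boxes", {}))
    if "box_sizes" in boxes_raw:
        boxes_raw["box_sizes"] = tuple(boxes_raw["box_sizes"])
    if "q_grid" in boxes_raw:
        boxes_raw["q_grid"] = tuple(boxes_raw["q_grid"])
    boxes = BoxCountingConfig(**boxes_raw)
    pipe_raw = raw.get("pipeline", {})
    pipeline = PipelineConfig(
        sift=sift,
        boxes=boxes,
        modes_to_use=tuple(pipe_raw.get("modes_to_use", PipelineConfig().modes_to_use)),
        features_per_mode=tuple(
            pipe_raw.get("features_per_mode", PipelineConfig().features_per_mode)
        ),
    )
    svm_raw = dict(raw.get("svm", {}))
    for key in ("c_range", "gamma_range"):
        if key in svm_raw:
            svm_raw[key] = tuple(svm_raw[key])
    svm = SvmConfig(**svm_raw)
    synth = _spec_from_dict(raw["synth"]) if "synth" in raw else None
    return RunConfig(
        pipeline=pipeline,
        svm=svm,
        synth=synth,
        manifest_path=raw.get("manifest"),
        out_dir=raw.get("out_dir", "run"),
        log_level=raw.get("log_level", "INFO"),
    )


def _load_manifest(path: str | Path) -> tuple[list, list[str]]:
    df = pd.read_csv(path)
    if not {"path", "label"} <= set(df.columns):
        raise ValueError("manifest CSV needs 'path' and 'label' columns")
    base = Path(path).parent
    samples = []
    ids = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        samples.append((read_image(p), int(row["label"])))
        ids.append(p.stem)
    return samples, ids


def run_pipeline(config: RunConfig) -> Path:
    """synth (optional) -> features -> CV classification -> threshold rule.

    Everything lands in one run directory with a manifest recording the
    config, seeds and per-stage timing, so the run is reproducible from the
    directory alone.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.synth is not None:
        samples = generate_two_class_dataset(config.synth)
        ids = [f"synth_{i:04d}" for i in range(len(samples))]
        manifest = [(s.image, s.label) for s in samples]
        seeds = {"master_seed": config.synth.seed,
                 "per_image": [list(s.seed_key) for s in samples]}
    elif config.manifest_path:
        manifest, ids = _load_manifest(config.manifest_path)
        seeds = {}
    else:
        raise ValueError("run config needs either a synth spec or a manifest path")
    timing["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        table = batch_extract(manifest, config.pipeline, ids=ids)
    except ValueError as exc:
        raise RuntimeError(f"[features] {exc}") from exc
    export_feature_table(table, out / "features.csv", config.pipeline, seeds=seeds)
    timing["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        report = cross_validate(table, config.svm)
    except ValueError as exc:
        raise RuntimeError(f"[classify] {exc}") from exc
    timing["classify"] = time.perf_counter() - t0

    np.savetxt(out / "roc_points.csv", report.roc_points,
               delimiter=",", header="fpr,tpr", comments="")
    report_json = {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "precision": report.precision,
        "f1": report.f1,
        "auc": report.auc,
        "confusion": vars(report.confusion),
        "details": report.details,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2))

    # threshold rule on the first-mode apex exponent, when available
    rule_json = None
    col = "bimf_1_alpha0"
    if col in table.columns:
        healthy = table.loc[table["label"] == 0, col].dropna()
        path_vals = table.loc[table["label"] == 1, col].dropna()
        if len(healthy) and len(path_vals):
            rule = decision_threshold(healthy, path_vals)
            rule_json = {"threshold": rule.threshold, "feature": list(rule.feature),
                         "direction": rule.direction}
            (out / "threshold_rule.json").write_text(json.dumps(rule_json, indent=2))

    manifest_json = {
        "config": {
            "sift": vars(config.pipeline.sift).copy(),
            "boxes": {
                "box_sizes": list(config.pipeline.boxes.box_sizes),
                "q_grid": [float(q) for q in config.pipeline.boxes.q_grid],
                "min_r2": config.pipeline.boxes.min_r2,
                "offset_mode": config.pipeline.boxes.offset_mode,
            },
            "modes_to_use": list(config.pipeline.modes_to_use),
            "features_per_mode": list(config.pipeline.features_per_mode),
            "svm": {**vars(config.svm),
                    "c_range": list(config.svm.c_range),
                    "gamma_range": list(config.svm.gamma_range)},
        },
        "seeds": seeds,
        "timing_s": timing,
        "versions": _versions(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_json, indent=2))
    return out


def _versions() -> dict:
    import sklearn
    import scipy
    import skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
    }
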