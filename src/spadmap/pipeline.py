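"""End-to-end orchestration: correct -> segment -> extract -> model -> map.

The pipeline mirrors the acquisition software's processing order: gray
levels are calibrated to reflectance against the board, the plant is
segmented by MDVI-Otsu-CDL, per-plant mean spectra feed the UVE-PLS SPAD
model, and predictions are rendered as a pseudo-color map. Training
(:func:`run_train`) and prediction (:func:`run_predict`) write
machine-readable reports plus a run log with a config hash and stage
timings, so every field run is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__ as _version
from .calibration import (
    CalibrationModel,
    Rect,
    apply_calibration,
    extract_board_reading,
    fit_calibration,
)
from .chemometrics import (
    SpectraTable,
    evaluate,
    pls_fit,
    pls_select_components,
    spxy_split,
    uve_select,
)
from .cube import SpectralCube, write_mask
from .errors import TooFewSamples
from .mapping import SpadModel, predict_map, render_pseudocolor
from .segmentation import segment_plant

__all__ = [
    "PipelineConfig",
    "run_train",
    "run_predict",
    "validate_report",
    "TRAIN_REPORT_SCHEMA",
    "PREDICT_REPORT_SCHEMA",
]


@dataclass
class PipelineConfig:
    """Operating point of the pipeline; defaults are the published choices.

    alpha 2.5 (optimal modified coefficient), 8-connectivity, UVE threshold
    1.0, 2:1 calibration:validation split, 0-60 SPAD rendering range.
    ``use_reflectance=False`` segments the raw grayscale cube instead of the
    calibrated one.
    """

    profile_path: str | None = None
    alpha: float = 2.5
    connectivity: int = 8
    window: int = 3
    uve_threshold: float = 1.0
    split_ratio: tuple[int, int] = (2, 1)
    color_range: tuple[float, float] = (0.0, 60.0)
    output_dir: str = "."
    mode: str = "predict"
    use_reflectance: bool = True
    uve_noise_augment: bool = False

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["split_ratio"] = list(self.split_ratio)
        doc["color_range"] = list(self.color_range)
        return doc

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        doc["split_ratio"] = tuple(doc.get("split_ratio", (2, 1)))
        doc["color_range"] = tuple(doc.get("color_range", (0.0, 60.0)))
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


TRAIN_REPORT_SCHEMA = {
    "n_cal": int, "n_val": int, "n_components": int,
    "selected_wavelengths": list, "rmsecv": list,
    "calibration": dict, "validation": dict,
}
PREDICT_REPORT_SCHEMA = {
    "mean_spad": float, "min": float, "max": float, "n_pixels": int,
    "otsu_threshold": int, "component_count": int,
    "largest_component_area": int, "alpha": float,
}
_METRICS_KEYS = {"r2": float, "rmse": float, "rpd": float, "n": int, "grade": str}


def validate_report(report: dict, schema: dict) -> None:
    """Check required keys and types; raises ValueError on mismatch."""
    for key, typ in schema.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, "
                             f"expected {typ.__name__}")
    for section in ("calibration", "validation"):
        if section in schema:
            for key, typ in _METRICS_KEYS.items():
                if key not in report[section]:
                    raise ValueError(f"report[{section!r}] missing {key!r}")


def _write_log(out_dir: Path, config: PipelineConfig, seed, timings: dict) -> None:
    log = {
        "spadmap_version": _version,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": seed,
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))


def run_train(
    config: PipelineConfig,
    table: SpectraTable,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[dict, dict]:
    """Fit the UVE-PLS SPAD model from a spectra table.

    SPXY split at ``split_ratio`` -> component count by LOO on the full
    calibration spectra -> UVE at ``uve_threshold`` -> component count
    re-selected on the retained bands -> final PLS fit -> metrics on both
    sets. Returns ``(model_bundle, report)``; writes ``model.json``,
    ``fit_report.json`` and ``run_log.json`` when ``out_dir`` is given.
    """
    if table.n_samples < 3:
        raise TooFewSamples(f"need at least 3 samples, got {table.n_samples}")
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    cal_ids, val_ids = spxy_split(table, ratio=config.split_ratio)
    cal, val = table.subset(cal_ids), table.subset(val_ids)
    timings["spxy_split"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    k_full, _ = pls_select_components(cal.X, cal.y)
    uve = uve_select(
        cal.X, cal.y, n_components=k_full,
        wavelengths=table.wavelengths,
        threshold=config.uve_threshold,
        noise_augment=config.uve_noise_augment,
        random_state=seed,
    )
    sel = uve.selected_indices
    timings["uve"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    best_k, rmsecv = pls_select_components(cal.X[:, sel], cal.y)
    pls = pls_fit(cal.X[:, sel], cal.y, best_k, wavelengths=uve.selected_wavelengths)
    timings["pls"] = time.perf_counter() - t0

    cal_metrics = evaluate(cal.y, pls.predict(cal.X[:, sel]))
    val_metrics = evaluate(val.y, pls.predict(val.X[:, sel]))

    # Collapse to a sparse wavelength-indexed linear model for mapping.
    intercept = float(pls.y_mean - pls.x_mean @ pls.coefficients)
    spad_model = SpadModel(
        terms={wl: float(c) for wl, c in zip(uve.selected_wavelengths, pls.coefficients)},
        intercept=intercept,
        provenance=f"UVE-PLS fit, {len(sel)} bands, {best_k} PCs",
    )
    bundle = {
        "schema_version": 1,
        "spad_model": json.loads(spad_model.to_json()),
        "pls": {
            "n_components": pls.n_components,
            "x_mean": pls.x_mean.tolist(),
            "y_mean": pls.y_mean,
            "coefficients": pls.coefficients.tolist(),
            "training_wavelengths": list(pls.training_wavelengths),
        },
        "uve": {
            "reliability_index": uve.reliability_index.tolist(),
            "threshold": uve.threshold,
            "selected_wavelengths": list(uve.selected_wavelengths),
        },
        "wavelengths": list(table.wavelengths),
    }
    report = {
        "n_cal": cal.n_samples,
        "n_val": val.n_samples,
        "n_components": best_k,
        "selected_wavelengths": list(uve.selected_wavelengths),
        "rmsecv": [float(v) for v in rmsecv],
        "calibration": dataclasses.asdict(cal_metrics),
        "validation": dataclasses.asdict(val_metrics),
    }
    validate_report(report, TRAIN_REPORT_SCHEMA)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "model.json").write_text(json.dumps(bundle, indent=2))
        (out / "fit_report.json").write_text(json.dumps(report, indent=2))
        _write_log(out, config, seed, timings)
    return bundle, report


def run_predict(
    config: PipelineConfig,
    cube: SpectralCube,
    model: SpadModel,
    calibration: CalibrationModel | None = None,
    board_boxes: list[Rect] | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Segment, predict, and map one cube; returns the summary report.

    A grayscale cube needs either a fitted ``calibration`` or
    ``board_boxes`` (the board is then read from the cube itself). When
    ``out_dir`` is given, writes mask.png, spad.tif (32-bit values),
    map.png, summary.json and run_log.json — intermediates always written
    for auditability.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if cube.value_kind == "grayscale" and config.use_reflectance:
        if calibration is None:
            if board_boxes is None:
                raise ValueError("need a calibration model or board boxes")
            calibration = fit_calibration(
                extract_board_reading(cube, board_boxes), wavelengths=cube.wavelengths
            )
        work = apply_calibration(cube, calibration)
    else:
        work = cube
    timings["calibrate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seg = segment_plant(
        work, alpha=config.alpha, window=config.window, connectivity=config.connectivity
    )
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    spad = predict_map(work, seg.precision_mask, model)
    rgb = render_pseudocolor(spad, config.color_range)
    timings["map"] = time.perf_counter() - t0

    report = {
        **spad.summary(),
        "otsu_threshold": seg.otsu_threshold,
        "component_count": seg.component_count,
        "largest_component_area": seg.largest_component_area,
        "alpha": float(config.alpha),
    }
    validate_report(report, PREDICT_REPORT_SCHEMA)

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mask(out / "mask.png", seg.precision_mask)
        tifffile.imwrite(out / "spad.tif", spad.values.astype(np.float32))
        iio.imwrite(out / "map.png", rgb)
        (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_log(out, config, seed, timings)
    return report
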