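"""End-to-end orchestration: screening -> compensation -> segmentation ->
features -> optional classification, with JSON-friendly reporting."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import classify, compensation, features, screening, segmentation
from .errors import InvalidInputError, LaryqError

log = logging.getLogger(__name__)

FRAME_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; YAML round-trippable."""

    input_path: str = "."
    output_dir: str | None = None
    target_luma: float = compensation.DEFAULT_TARGET_LUMA
    red_threshold: float = screening.RED_THRESHOLD
    sharpness_method: str = "smd"
    snake_min_iter: int = 13
    snake_max_iter: int = 41
    glcm_levels: int = 8
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class StageRecord:
    name: str
    ok: bool
    seconds: float
    detail: dict = field(default_factory=dict)
    error: str | None = None


@dataclass
class Report:
    """Machine-readable record of a pipeline run."""

    config: PipelineConfig
    stages: list[StageRecord] = field(default_factory=list)
    selected_frame: int | None = None
    features: dict | None = None
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "stages": [asdict(s) for s in self.stages],
            "selected_frame": self.selected_frame,
            "features": self.features,
            "failed_stage": self.failed_stage,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_frames(input_path: str | Path) -> list[np.ndarray]:
    """Frames from a directory (sorted lexicographically) or a single file."""
    path = Path(input_path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in FRAME_EXTENSIONS
        )
        if not files:
            raise InvalidInputError(f"no frames found in {path}")
        return [np.asarray(iio.imread(p))[..., :3] for p in files]
    if path.is_file():
        return [np.asarray(iio.imread(path))[..., :3]]
    raise InvalidInputError(f"unreadable input {path}")


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def run_pipeline(config: PipelineConfig) -> Report:
    """Run every stage in order, recording failures without raising."""
    report = Report(config=config)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, func):
        if report.failed_stage is not None:
            return None
        t0 = time.perf_counter()
        try:
            result, detail = func()
        except (LaryqError, OSError) as exc:
            report.stages.append(
                StageRecord(name, False, time.perf_counter() - t0, error=str(exc))
            )
            report.failed_stage = name
            log.error("stage %s failed: %s", name, exc)
            return None
        report.stages.append(
            StageRecord(name, True, time.perf_counter() - t0, detail=detail)
        )
        return result

    frames = stage("load", lambda: (read_frames(config.input_path), {}))

    def _screen():
        rep = screening.sharpness_report(frames, config.red_threshold)
        surviving = rep.surviving
        if not surviving:
            raise InvalidInputError("all frames filtered out by screening")
        return surviving, {
            "n_frames": len(frames),
            "surviving": surviving,
            "red_fraction": rep.red_fraction,
            "variance": rep.variance,
            "smd": rep.smd,
        }

    surviving = stage("screening", _screen)

    def _select():
        idx = screening.select_sharpest(
            frames, surviving, method=config.sharpness_method
        )
        report.selected_frame = idx
        return idx, {"index": idx, "method": config.sharpness_method}

    selected = stage("selection", _select)

    def _compensate():
        img = compensation.histogram_shift(
            frames[selected], target=config.target_luma
        )
        pre = float(compensation.luma(frames[selected]).mean())
        return img, {"pre_mean_luma": pre, "target": config.target_luma}

    compensated = stage("compensation", _compensate)

    def _segment():
        regions = segmentation.segment_regions(compensated)
        if outdir:
            for name, mask in regions.as_dict().items():
                write_mask(outdir / f"mask_{name}.png", mask)
        areas = {k: int(v.sum()) for k, v in regions.as_dict().items()}
        return regions, {"areas": areas}

    regions = stage("segmentation", _segment)

    def _features():
        vec = features.extract_features(compensated, regions)
        report.features = {k: float(v) for k, v in vec.items()}
        return vec, {"n_features": len(vec)}

    stage("features", _features)

    if outdir:
        report.to_json(outdir / "report.json")
    return report


def classify_cohort(
    table, labels, seed: int = 0, folds: int = 10, top_k: int = 5
) -> dict:
    """Balanced Fisher-select-then-SVM evaluation of a labelled cohort."""
    idx = classify.balanced_subsample(table.to_numpy(), labels, seed=seed)
    sub = table.iloc[idx]
    sub_labels = np.asarray(labels)[idx]
    scores, selected = features.rank_features(sub, sub_labels, top_k=top_k)
    metrics, fold_metrics = classify.svm_cv(
        sub[selected].to_numpy(), sub_labels, k=folds, seed=seed
    )
    return {
        "selected_features": selected,
        "fisher_scores": {s.feature: s.f for s in scores},
        "metrics": metrics.as_dict(),
        "folds": [m.as_dict() for m in fold_metrics],
    }


def grade_severity_cohort(table, labels, rsi, seed: int = 0, folds: int = 10) -> dict:
    """Stratified BPNN severity evaluation of the LPR rows of a cohort."""
    labels = np.asarray(labels)
    rsi = np.asarray(rsi)
    lpr_mask = labels == "LPR"
    if lpr_mask.sum() == 0:
        raise InvalidInputError("no LPR rows in cohort")
    x = table.loc[lpr_mask, list(features.SELECTED_FEATURES)].to_numpy()
    severity = np.array([classify.rsi_to_severity(int(s)) for s in rsi[lpr_mask]])
    config = classify.SeverityConfig(seed=seed)
    accs, mean_acc = classify.stratified_cv(x, severity, config, k=folds)
    return {"fold_accuracies": accs, "average_accuracy": mean_acc}
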