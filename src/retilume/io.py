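"""Image I/O, run configuration and batch orchestration.

Images are PNG/JPEG/TIFF rasters, held in memory as H×W×3 uint8 arrays
(grayscale promoted, alpha dropped, 16-bit rescaled — each with a warning).
Enhanced outputs are written as PNG by default so that the quality metrics
are reproducible bit-for-bit.
"""

from __future__ import annotations

import glob
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .dominance import RetinaNotFoundError
from .enhancement import BilateralParams, ClaheParams, EnhanceConfig, enhance_image
from .metrics import report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_image", "save_image", "run_enhance", "run_metrics"]

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """One batch run: input globs, output directory, pipeline tunables."""

    inputs: tuple[str, ...]
    out_dir: str
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    save_stages: bool = False
    report_path: str | None = None
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "schema": CONFIG_SCHEMA_VERSION,
            "inputs": list(self.inputs),
            "out_dir": self.out_dir,
            "save_stages": self.save_stages,
            "report_path": self.report_path,
            "log_level": self.log_level,
            "enhance": {
                "theta": self.enhance.theta,
                "crop_luminance_threshold": self.enhance.crop_luminance_threshold,
                "clip_percent": self.enhance.clip_percent,
                "stage1_clahe": asdict(self.enhance.stage1_clahe),
                "stage2_clahe": asdict(self.enhance.stage2_clahe),
                "bilateral": asdict(self.enhance.bilateral),
                "white": [self.enhance.white.xn, self.enhance.white.yn, self.enhance.white.zn],
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if payload.get("schema") != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema: {payload.get('schema')!r}")
        from .colorspace import WhitePoint

        enh = payload.get("enhance", {})
        stage1 = enh.get("stage1_clahe", {})
        stage2 = enh.get("stage2_clahe", {})
        for d in (stage1, stage2):
            if "tile_grid" in d:
                d["tile_grid"] = tuple(d["tile_grid"])
        config = EnhanceConfig(
            theta=enh.get("theta", EnhanceConfig.theta),
            crop_luminance_threshold=enh.get("crop_luminance_threshold", 0.04),
            clip_percent=enh.get("clip_percent", 0.01),
            stage1_clahe=ClaheParams(**stage1),
            stage2_clahe=ClaheParams(**stage2),
            bilateral=BilateralParams(**enh.get("bilateral", {})),
            white=WhitePoint(*enh["white"]) if "white" in enh else EnhanceConfig().white,
        )
        return cls(
            inputs=tuple(payload["inputs"]),
            out_dir=payload["out_dir"],
            enhance=config,
            save_stages=payload.get("save_stages", False),
            report_path=payload.get("report_path"),
            log_level=payload.get("log_level", "INFO"),
        )


def load_image(path: str | Path) -> np.ndarray:
    """Load a raster image as an H×W×3 uint8 RGB array.

    Grayscale is promoted to 3 channels; an alpha channel is dropped with a
    warning; 16-bit data is rescaled to 8-bit with a warning.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path}: unsupported image layout with shape {arr.shape}")
    if arr.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", path)
        arr = arr[..., :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 1, 3 or 4 channels, got {arr.shape[2]}")
    if arr.dtype == np.uint16:
        logger.warning("%s: rescaling 16-bit data to 8-bit", path)
        arr = np.round(arr.astype(float) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(float)), 0, 255).astype(np.uint8)
    return arr


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB image; PNG/TIFF are lossless."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def _expand_inputs(patterns: tuple[str, ...]) -> list[Path]:
    paths: list[Path] = []
    for pattern in patterns:
        matches = sorted(glob.glob(pattern))
        if not matches and Path(pattern).exists():
            matches = [pattern]
        paths.extend(Path(p) for p in matches)
    return paths


def run_enhance(config: RunConfig) -> tuple[int, pd.DataFrame]:
    """Enhance every input image; write PNGs and the per-image metric CSV.

    Each row pairs the cropped input with the final enhanced image and
    records the dominance outcome; a summary row of per-column means (id
    ``mean``) is appended.  Unreadable or all-dark images are logged and
    skipped; the exit status is non-zero only when no image succeeds.
    """
    paths = _expand_inputs(config.inputs)
    if not paths:
        raise FileNotFoundError(f"no input images match {config.inputs}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    enh_config = config.enhance
    if config.save_stages:
        enh_config = replace(enh_config, keep_intermediates=True)

    rows: list[dict] = []
    for path in paths:
        try:
            image = load_image(path)
            result = enhance_image(image, enh_config)
        except (RetinaNotFoundError, ValueError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        stem = path.stem
        save_image(result.image, out_dir / f"{stem}.enhanced.png")
        if config.save_stages and result.intermediates is not None:
            save_image(result.intermediates["stage1"], out_dir / f"{stem}.stage1.png")
            save_image(result.intermediates["final"], out_dir / f"{stem}.stage2.png")
        rep = report(result.crop.image, result.image, image_id=stem)
        row: dict = {"id": stem}
        row["sigma_sq"] = result.dominance.sigma_sq
        row["selected_channel"] = result.dominance.selected_channel
        row.update({k: v for k, v in rep.to_row().items() if k != "id"})
        rows.append(row)

    if not rows:
        logger.error("all %d input images failed", len(paths))
        return 1, pd.DataFrame()

    frame = pd.DataFrame(rows)
    numeric = frame.select_dtypes("number").mean()
    summary = {"id": "mean", "selected_channel": ""} | numeric.to_dict()
    frame = pd.concat([frame, pd.DataFrame([summary])], ignore_index=True)
    if config.report_path:
        Path(config.report_path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(config.report_path, index=False)
    return 0, frame


def run_metrics(
    ref_patterns: tuple[str, ...], test_patterns: tuple[str, ...], report_path: str | None = None
) -> pd.DataFrame:
    """Pair reference/test images by filename order and evaluate the metric suite."""
    refs = _expand_inputs(ref_patterns)
    tests = _expand_inputs(test_patterns)
    if not refs or len(refs) != len(tests):
        raise ValueError(f"reference/test counts differ or empty: {len(refs)} vs {len(tests)}")
    rows = []
    for ref_path, test_path in zip(refs, tests):
        rep = report(load_image(ref_path), load_image(test_path), image_id=ref_path.stem)
        rows.append(rep.to_row())
    frame = pd.DataFrame(rows)
    numeric = frame.select_dtypes("number").mean()
    frame = pd.concat([frame, pd.DataFrame([{"id": "mean"} | numeric.to_dict()])], ignore_index=True)
    if report_path:
        frame.to_csv(report_path, index=False)
    return frame
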