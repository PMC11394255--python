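"""End-to-end pipeline: images and response tables in, artifacts out.

``run_pipeline`` applies the clock sweep to each input image (JSON result
+ annotated overlay PNG) and scores each response table (report CSV in
the printed-table layout, paired-test summary JSON, ROC pair CSV and
figure).  Every run writes a manifest (config echo, package and library
versions, seed, input checksums) from which it can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .clocksweep import OverlayAnnotation, radial_profile, render_overlay, sweep_statistic
from .readerstats import (
    ResponseTable,
    build_study_report,
    paired_test,
    plot_roc_pairs,
    roc_pair_points,
)
from .segmentation import SegmentationError, segment_lesion, to_grayscale

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "InputError",
    "TableFormatError",
    "EXIT_CODES",
    "sweep_image",
    "score_responses",
]

log = logging.getLogger("dermibc")


class InputError(ValueError):
    """An input file is missing or unreadable."""


class TableFormatError(ValueError):
    """A response-table CSV is malformed (missing column, unknown label)."""


# distinct process exit codes per failure class (used by the CLI)
EXIT_CODES = {
    "config": 2,
    "input": 3,
    "table": 4,
    "segmentation": 5,
}

THRESHOLD_METHODS = ("otsu", "fixed")
SIDEDNESS = ("two", "one")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs shared by every pipeline stage.

    ``n_angles`` is the clock-face resolution of the sweep (>= 36);
    ``smoothing_window`` (odd, in samples) steadies the max-variation
    hand; ``threshold_method`` is "otsu" or "fixed" (with
    ``threshold_value``); ``sidedness`` selects the paired-test tail.
    """

    n_angles: int = 360
    smoothing_window: int = 5
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    sidedness: str = "two"
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("ibc_output"))

    def __post_init__(self):
        if self.n_angles < 36:
            raise ValueError(f"n_angles must be >= 36, got {self.n_angles}")
        if self.smoothing_window % 2 == 0 or not (
            1 <= self.smoothing_window < self.n_angles
        ):
            raise ValueError(
                "smoothing_window must be odd and smaller than n_angles, got "
                f"{self.smoothing_window}"
            )
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ValueError(f"threshold_method must be one of {THRESHOLD_METHODS}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("threshold_method 'fixed' requires threshold_value")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        return d


def _read_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB") if im.mode not in ("L", "I;16", "F") else im
            return np.asarray(im, dtype=float)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc


def sweep_image(path: str | Path, config: PipelineConfig, risk: float | None = None):
    """Segment one image, run the clock sweep, and build the overlay."""
    path = Path(path)
    gray = to_grayscale(_read_image(path))
    threshold = config.threshold_value if config.threshold_method == "fixed" else None
    mask = segment_lesion(gray, threshold=threshold, n_angles=config.n_angles)
    profile = radial_profile(gray, mask)
    result = sweep_statistic(profile, smoothing_window=config.smoothing_window)
    overlay = render_overlay(gray, mask, result, OverlayAnnotation(risk_score=risk))
    return gray, mask, profile, result, overlay


def _load_response_table(path: Path) -> ResponseTable:
    if not path.exists():
        raise InputError(f"response table not found: {path}")
    try:
        return ResponseTable.from_csv(path)
    except ValueError as exc:
        raise TableFormatError(f"malformed response table {path}: {exc}") from exc


def score_responses(table: ResponseTable, config: PipelineConfig) -> dict:
    """Report, ROC pairs and paired-test summary for one response table."""
    report = build_study_report(table)
    points = roc_pair_points(report)
    per_reader = report.drop(index="Mean")
    summary = {"sidedness": config.sidedness, "n_readers": len(per_reader)}
    for metric, wo, wi in [
        ("sensitivity", "sens_without", "sens_with"),
        ("specificity", "spec_without", "spec_with"),
        ("dprime", "dprime_without", "dprime_with"),
    ]:
        cmp = paired_test(
            per_reader[wo], per_reader[wi], sidedness=config.sidedness, metric=metric
        )
        summary[metric] = {
            "mean_without": float(report.loc["Mean", wo]),
            "mean_with": float(report.loc["Mean", wi]),
            "mean_increase": cmp.mean_diff,
            "sd_increase": cmp.sd_diff,
            "t": cmp.t_statistic,
            "df": cmp.df,
            "p_value": cmp.p_value,
        }
    return {"report": report, "roc_points": points, "summary": summary}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import matplotlib
    import PIL
    import scipy
    import skimage

    from . import __version__

    return {
        "dermibc": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "pillow": PIL.__version__,
        "matplotlib": matplotlib.__version__,
    }


def run_pipeline(
    config: PipelineConfig,
    images: list[str | Path] = (),
    responses: list[str | Path] = (),
    risk_scores: dict | None = None,
) -> dict:
    """Run every stage on the given inputs and write artifacts to disk.

    Per image: ``<stem>_sweep.json`` (full-precision clock-sweep result)
    and ``<stem>_overlay.png``.  Per response table: ``<stem>_report.csv``
    (printed-table rounding), ``<stem>_roc.csv``, ``<stem>_roc.png`` and
    ``<stem>_summary.json``.  Always: ``manifest.json``.  Returns the
    in-memory results keyed the same way.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    risk_scores = risk_scores or {}
    manifest = {
        "config": config.to_dict(),
        "versions": _versions(),
        "seed": config.seed,
        "inputs": {},
    }
    results: dict = {"images": {}, "responses": {}}

    for image_path in map(Path, images):
        log.info("clock sweep: %s", image_path)
        if not image_path.exists():
            raise InputError(f"image not found: {image_path}")
        manifest["inputs"][str(image_path)] = _sha256(image_path)
        risk = risk_scores.get(image_path.stem)
        _, mask, profile, result, overlay = sweep_image(image_path, config, risk=risk)
        json_path = out_dir / f"{image_path.stem}_sweep.json"
        json_path.write_text(result.to_json(indent=2, sort_keys=True) + "\n")
        Image.fromarray(overlay).save(out_dir / f"{image_path.stem}_overlay.png")
        results["images"][image_path.stem] = result
        log.info(
            "  delta/mean = %.4f (delta %.2f, mean %.2f)",
            result.statistic,
            result.delta,
            result.mean_brightness,
        )

    for table_path in map(Path, responses):
        log.info("scoring response table: %s", table_path)
        manifest["inputs"][str(table_path)] = _sha256(table_path)
        table = _load_response_table(table_path)
        scored = score_responses(table, config)
        stem = table_path.stem
        scored["report"].to_csv(out_dir / f"{stem}_report.csv")
        scored["roc_points"].to_csv(out_dir / f"{stem}_roc.csv")
        plot_roc_pairs(scored["roc_points"], out_dir / f"{stem}_roc.png")
        (out_dir / f"{stem}_summary.json").write_text(
            json.dumps(scored["summary"], indent=2, sort_keys=True) + "\n"
        )
        results["responses"][stem] = scored
        log.info(
            "  mean d' %.2f -> %.2f (increase %.4f, p = %.4g)",
            scored["summary"]["dprime"]["mean_without"],
            scored["summary"]["dprime"]["mean_with"],
            scored["summary"]["dprime"]["mean_increase"],
            scored["summary"]["dprime"]["p_value"],
        )

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    results["manifest"] = manifest
    return results
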