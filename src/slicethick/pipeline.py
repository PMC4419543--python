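"""Batch workflow: image -> thickness record -> study report.

This module chains the stages of the measurement procedure -- calibrate,
binarize, crop, align, measure -- into single calls suitable for scripting
over a directory of cross-section images, and assembles labelled measurement
tables into the study-level summary (error table, ANOVA, Tukey letters).

In the interactive workflow the user crops the slice by hand, which also
discards stray debris in the field.  The batch equivalent is the
``keep_largest`` step: retain only the largest connected foreground
component before estimating the axis, so isolated noise speckles cannot
perturb the principal-axis fit or the width statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .errors import SliceThickError, ValidationError
from .geometry import AxisEndpoints, RectROI, align_vertical, crop, estimate_axis
from .preprocessing import BinaryMask, GrayImage, binarize, load_image
from .stats import one_way_anova, overall_error, summarize_combos, tukey_grouping, two_way_anova
from .thickness import ThicknessResult, auto_segments, measure_slice

__all__ = ["RunConfig", "measure_image", "run_measure", "run_study", "keep_largest_component"]

logger = logging.getLogger("slicethick")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch measurement run."""

    pixel_size: float
    threshold_method: str = "isodata"
    threshold: float | None = None
    polarity: str | None = None
    roi: RectROI | None = None
    axis: AxisEndpoints | None = None
    n_segments: int = 3
    segment_fraction: float = 0.1
    keep_largest: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.n_segments < 3:
            raise ValidationError("n_segments must be >= 3")

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "threshold_method": self.threshold_method,
            "threshold": self.threshold,
            "polarity": self.polarity,
            "n_segments": self.n_segments,
            "segment_fraction": self.segment_fraction,
            "keep_largest": self.keep_largest,
            "seed": self.seed,
        }


def keep_largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 8-connected foreground component."""
    labels = cc_label(mask.pixels, connectivity=2)
    if labels.max() == 0:
        raise ValidationError("mask has no foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(counts.argmax())
    return BinaryMask(
        (labels == biggest).astype(np.uint8), mask.pixel_size, source_id=mask.source_id
    )


def measure_image(
    image: GrayImage | str | Path,
    config: RunConfig | None = None,
    **config_kwargs,
) -> ThicknessResult:
    """Full measurement of one cross-section image.

    ``image`` may be a loaded :class:`GrayImage` or a path (then
    ``config.pixel_size`` calibrates it).  Steps: threshold and orient the
    mask, optional crop, keep the largest component, align the principal
    axis vertically (PCA estimate, or the manual endpoints in
    ``config.axis``), place the measurement segments, and summarise.
    """
    if config is None:
        if isinstance(image, GrayImage):
            config_kwargs.setdefault("pixel_size", image.pixel_size)
        config = RunConfig(**config_kwargs)
    if not isinstance(image, GrayImage):
        image = load_image(image, config.pixel_size)
    mask = binarize(
        image,
        method=config.threshold_method,
        threshold=config.threshold,
        polarity=config.polarity,
    )
    if config.roi is not None:
        mask = crop(mask, config.roi)
    if config.keep_largest:
        mask = keep_largest_component(mask)
    axis = config.axis if config.axis is not None else estimate_axis(mask)
    aligned = align_vertical(mask, axis)
    segments = auto_segments(aligned, n=config.n_segments, fraction=config.segment_fraction)
    return measure_slice(aligned, segments)


def run_measure(paths, config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Measure a batch of images; failures are logged and skipped, never
    silently dropped.

    Returns
    -------
    table : DataFrame
        One row per successfully measured image (source_id, mean_um, sd_um,
        cv, irregular, n_segments).
    failures : list of dict
        One entry per failed input with the error message.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("no input images given")
    rows, failures = [], []
    for path in paths:
        try:
            result = measure_image(path, config)
        except (SliceThickError, OSError) as exc:
            logger.error("failed to measure %s: %s", path, exc)
            failures.append({"path": str(path), "error": str(exc)})
            continue
        rec = result.to_dict()
        rec["segment_values"] = json.dumps(rec["segment_values"])
        rows.append(rec)
        if result.irregular:
            logger.warning("irregular slice %s: cv=%.3f", path, result.cv)
    table = pd.DataFrame(
        rows,
        columns=["source_id", "mean_um", "sd_um", "cv", "irregular", "n_segments", "segment_values"],
    )
    return table, failures


def run_study(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Study-level report from a labelled slice table.

    ``records`` needs columns ``tissue, step_size_um, speed_mm_s,
    thickness_um``.  Per tissue: the cell summary (n/mean/SD/error%), the
    overall error, and -- where the design allows -- ANOVA (two-way with
    interaction when both step and speed vary, one-way when only step does)
    plus Tukey letters.  Single-cell tissues get their summary with the
    inferential parts marked skipped.
    """
    missing = [
        c for c in ("tissue", "step_size_um", "speed_mm_s", "thickness_um")
        if c not in records.columns
    ]
    if missing:
        raise ValidationError(f"unlabelled records: missing columns {missing}")
    combos = summarize_combos(records)
    overall = overall_error(combos)
    report = {
        "combos": combos,
        "overall": overall,
        "anova": {},
        "tukey": {},
        "skipped": [],
    }
    for tissue, sub in records.groupby("tissue", sort=False):
        n_steps = sub["step_size_um"].nunique()
        n_speeds = sub["speed_mm_s"].nunique()
        try:
            if n_steps >= 2 and n_speeds >= 2:
                report["anova"][tissue] = two_way_anova(sub)
                report["tukey"][tissue] = tukey_grouping(sub, by_cell=True, alpha=alpha)
            elif n_steps >= 2:
                report["anova"][tissue] = one_way_anova(sub)
                report["tukey"][tissue] = tukey_grouping(sub, alpha=alpha)
            else:
                raise ValidationError("single cell: no factor varies")
        except ValidationError as exc:
            logger.warning("ANOVA skipped for %s: %s", tissue, exc)
            report["skipped"].append({"tissue": tissue, "reason": str(exc)})
    return report


def study_report_to_json(report: dict) -> str:
    """Serialise a :func:`run_study` report to JSON (tables as records)."""
    payload = {
        "combos": report["combos"].to_dict(orient="records"),
        "overall": report["overall"].to_dict(orient="records"),
        "anova": {
            t: tab.reset_index(names="effect").to_dict(orient="records")
            for t, tab in report["anova"].items()
        },
        "tukey": {
            t: {
                "groups": [
                    {
                        "group": g,
                        "mean": tk.means[g],
                        "letters": "".join(sorted(tk.letters[g])),
                    }
                    for g in tk.groups
                ],
                "alpha": tk.alpha,
            }
            for t, tk in report["tukey"].items()
        },
        "skipped": report["skipped"],
    }
    return json.dumps(payload, indent=2, default=float)
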