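"""The thickness statistic: mean per-row foreground width in micrometres.

On a mask whose slice band is vertical, every pixel row crosses the band once,
so the foreground count of a row is the local slice width in pixels.  For a
rectangular segment the statistic is

    thickness = (sum of pixel values in segment / number of pixel rows) x pixel_size

i.e. the mean per-row width converted to micrometres.  A slice is measured on
at least three such segments; the result is reported as mean +/- SD with a
quality flag raised when the coefficient of variation (SD/mean) exceeds 0.25,
which marks a highly irregular slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySegmentWarning, IrregularSliceWarning, ValidationError
from .geometry import RectROI
from .preprocessing import BinaryMask

__all__ = [
    "ThicknessResult",
    "segment_thickness",
    "measure_slice",
    "auto_segments",
    "CV_WARNING_THRESHOLD",
]

#: coefficient-of-variation bound above which a slice is flagged irregular
CV_WARNING_THRESHOLD = 0.25


@dataclass(frozen=True)
class ThicknessResult:
    """Per-slice thickness summary.

    ``sd`` is the sample standard deviation (n-1 denominator) of the
    per-segment values unless a different ``ddof`` was requested at
    measurement time; ``cv = sd/mean``; ``irregular`` is True when
    ``cv > 0.25``.
    """

    segment_values: tuple[float, ...]
    mean: float
    sd: float
    cv: float
    irregular: bool
    source_id: str = ""

    @property
    def n_segments(self) -> int:
        return len(self.segment_values)

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "mean_um": self.mean,
            "sd_um": self.sd,
            "cv": self.cv,
            "irregular": self.irregular,
            "n_segments": self.n_segments,
            "segment_values": list(self.segment_values),
        }


def segment_thickness(mask: BinaryMask, segment: RectROI) -> float:
    """Thickness of one rectangular segment, in micrometres.

    The segment must span the full slice width: every row's foreground run
    has to lie inside the segment's columns, otherwise the per-row count
    underestimates the width.  A segment with no foreground at all returns
    0 um and emits :class:`EmptySegmentWarning` so damaged inputs surface in
    QC without aborting a batch.
    """
    if not segment.within(mask.shape):
        raise ValidationError(f"segment {segment} outside mask bounds {mask.shape}")
    sub = mask.pixels[
        segment.row_start : segment.row_end, segment.col_start : segment.col_end
    ]
    total = float(sub.sum())
    if total == 0:
        warnings.warn(
            f"segment rows [{segment.row_start},{segment.row_end}) contains no "
            "foreground; thickness reported as 0",
            EmptySegmentWarning,
            stacklevel=2,
        )
        return 0.0
    return total / segment.n_rows * mask.pixel_size


def measure_slice(
    mask: BinaryMask,
    segments: list[RectROI],
    ddof: int = 1,
    warn: bool = True,
) -> ThicknessResult:
    """Measure a slice on >= 3 segments and summarise as mean +/- SD.

    Parameters
    ----------
    segments : list of RectROI
        At least three rectangular segments of the aligned mask (the minimum
        measurement protocol).
    ddof : int
        Delta degrees of freedom for the SD; 1 (sample SD) by default, 0 for
        the population formula.
    warn : bool
        Emit :class:`IrregularSliceWarning` when CV > 0.25.  The flag is set
        in the result either way; the warning never aborts a run.
    """
    if len(segments) < 3:
        raise ValidationError(
            f"need at least 3 segments, got {len(segments)} (three-segment protocol)"
        )
    values = tuple(segment_thickness(mask, seg) for seg in segments)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=ddof))
    cv = sd / mean if mean > 0 else float("nan")
    irregular = bool(cv > CV_WARNING_THRESHOLD)
    if irregular and warn:
        warnings.warn(
            f"irregular slice: CV = {cv:.3f} > {CV_WARNING_THRESHOLD}",
            IrregularSliceWarning,
            stacklevel=2,
        )
    return ThicknessResult(values, mean, sd, cv, irregular, source_id=mask.source_id)


def auto_segments(mask: BinaryMask, n: int = 3, fraction: float = 0.1) -> list[RectROI]:
    """Place ``n`` disjoint full-width horizontal bands along the slice.

    A batch replacement for dragging three rectangles by hand: the bands each
    cover ``fraction`` of the foreground's row extent and are centred at
    evenly spaced stations along it (n=3 puts them at 25%, 50% and 75%).
    """
    if n < 3:
        raise ValidationError(f"need n >= 3 segments, got {n}")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    fg_rows = np.where(mask.pixels.any(axis=1))[0]
    if fg_rows.size == 0:
        raise ValidationError("mask has no foreground; cannot place segments")
    rmin, rmax = int(fg_rows[0]), int(fg_rows[-1])
    extent = rmax - rmin + 1
    height = max(1, int(round(fraction * extent)))
    segments: list[RectROI] = []
    for i in range(1, n + 1):
        center = rmin + extent * i / (n + 1)
        start = int(round(center - height / 2))
        start = max(rmin, min(start, rmax + 1 - height))
        segments.append(RectROI(start, start + height, 0, mask.shape[1]))
    for a, b in zip(segments, segments[1:]):
        if b.row_start < a.row_end:
            raise ValidationError(
                f"foreground extent of {extent} rows cannot host {n} disjoint "
                f"bands of {height} rows; reduce fraction or n"
            )
    return segments
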