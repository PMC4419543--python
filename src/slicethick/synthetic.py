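"""Synthetic cross-section images and study tables with known ground truth.

Real cross-section photos show one dark, roughly rectangular band (the slice
seen edge-on) on a bright agarose field, at an arbitrary orientation, with
somewhat ragged edges and sensor noise.  :func:`generate_band` emulates
exactly that and hands back the exact label mask, so every pipeline stage can
be tested against a known truth without microscope data.

The band model: a rectangle of ``true_width`` x ``length`` pixels whose long
axis sits at ``angle`` degrees from vertical.  Edge roughness is per-row
independent uniform jitter of each edge, offset ~ U(-roughness, +roughness):
the simplest model with a closed-form expectation -- the expected per-row
width (and hence the expected measured thickness) equals ``true_width``
exactly.  Intensity noise is additive Gaussian.

:func:`generate_study` emulates the slice-level measurement table of a
sectioning study (several tissues x step sizes x speeds, >= 6 slices per
cell) by drawing per-slice thicknesses from normal distributions with stated
cell means and SDs.  Normality is an assumption of the fixture, not a claim
about tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import BinaryMask, GrayImage

__all__ = ["BandSpec", "generate_band", "generate_study"]


@dataclass(frozen=True)
class BandSpec:
    """Parameters of one synthetic slice-band image.

    ``angle`` is measured from vertical, in degrees; ``edge_roughness`` is
    the maximum per-row uniform jitter of each edge in pixels; ``fg_level``
    and ``bg_level`` are the band and field intensities (the band is darker
    in real photos, but any contrast works); ``noise_sd`` is the SD of
    additive Gaussian intensity noise.
    """

    true_width: float = 12.0
    length: float = 120.0
    angle: float = 0.0
    edge_roughness: float = 0.0
    fg_level: float = 40.0
    bg_level: float = 200.0
    noise_sd: float = 0.0
    canvas: tuple[int, int] = (200, 200)
    pixel_size: float = 8.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_width < 1:
            raise ValidationError("true_width must be >= 1 px")
        if self.length < 3 * self.true_width:
            raise ValidationError("length must be >= 3 x true_width")
        if self.fg_level == self.bg_level:
            raise ValidationError("fg_level and bg_level must differ")
        if self.noise_sd < 0 or self.edge_roughness < 0:
            raise ValidationError("noise_sd and edge_roughness must be >= 0")
        if len(self.canvas) != 2 or min(self.canvas) < 2:
            raise ValidationError("canvas must be (rows, cols) with both >= 2")


def _band_corners(spec: BandSpec) -> np.ndarray:
    """(row, col) corners of the jitter-padded band rectangle."""
    rows, cols = spec.canvas
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    th = np.deg2rad(spec.angle)
    u = np.array([np.cos(th), np.sin(th)])  # along axis
    v = np.array([-np.sin(th), np.cos(th)])  # across axis
    half_l = spec.length / 2.0
    half_w = spec.true_width / 2.0 + spec.edge_roughness
    center = np.array([r0, c0])
    return np.array(
        [center + sl * half_l * u + sw * half_w * v for sl in (-1, 1) for sw in (-1, 1)]
    )


def generate_band(spec: BandSpec) -> tuple[GrayImage, BinaryMask, dict]:
    """Render one synthetic cross-section image plus its ground-truth mask.

    Returns
    -------
    image : GrayImage
        Band at ``fg_level`` on a ``bg_level`` field, plus Gaussian noise.
    truth : BinaryMask
        Exact label grid (band pixels = 1) before any noise.
    metadata : dict
        Ground truth for assertions: the true width and angle, the expected
        measured width (equal to ``true_width`` under the symmetric jitter
        model), and the foreground pixel count.

    Identical specs (including seed) produce bit-identical output.
    """
    rows, cols = spec.canvas
    corners = _band_corners(spec)
    if (
        corners[:, 0].min() < 0
        or corners[:, 0].max() > rows - 1
        or corners[:, 1].min() < 0
        or corners[:, 1].max() > cols - 1
    ):
        raise ValidationError(
            f"band (corners {corners.round(1).tolist()}) exceeds canvas {spec.canvas}"
        )

    rng = np.random.default_rng(spec.seed)
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    th = np.deg2rad(spec.angle)
    rr, cc = np.indices((rows, cols), dtype=float)
    t = (rr - r0) * np.cos(th) + (cc - c0) * np.sin(th)  # along-axis coord
    s = -(rr - r0) * np.sin(th) + (cc - c0) * np.cos(th)  # across-axis coord

    n_stations = int(np.ceil(spec.length)) + 1
    if spec.edge_roughness > 0:
        jit_left = rng.uniform(-spec.edge_roughness, spec.edge_roughness, n_stations)
        jit_right = rng.uniform(-spec.edge_roughness, spec.edge_roughness, n_stations)
    else:
        jit_left = np.zeros(n_stations)
        jit_right = np.zeros(n_stations)

    inside_len = np.abs(t) <= spec.length / 2.0
    station = np.clip((t + spec.length / 2.0).astype(int), 0, n_stations - 1)
    left = -spec.true_width / 2.0 - jit_left[station]
    right = spec.true_width / 2.0 + jit_right[station]
    band = inside_len & (s >= left) & (s < right)

    pixels = np.full((rows, cols), float(spec.bg_level))
    pixels[band] = float(spec.fg_level)
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, (rows, cols))

    source_id = f"synthetic-band-w{spec.true_width}-a{spec.angle}-seed{spec.seed}"
    image = GrayImage(pixels, spec.pixel_size, source_id=source_id)
    truth = BinaryMask(band.astype(np.uint8), spec.pixel_size, source_id=source_id)
    metadata = {
        "true_width_px": spec.true_width,
        "expected_width_px": spec.true_width,  # symmetric jitter: mean contribution 0
        "expected_width_um": spec.true_width * spec.pixel_size,
        "angle_deg": spec.angle,
        "foreground_count": int(band.sum()),
        "seed": spec.seed,
    }
    return image, truth, metadata


def generate_study(design, seed: int = 0) -> pd.DataFrame:
    """Draw a slice-level thickness table from a cell-mean/SD design.

    Parameters
    ----------
    design : iterable of (tissue, step_size_um, speed_mm_s, mean_um, sd_um, n)
        One entry per step-size x speed cell actually measured; ``n`` slices
        are drawn per cell from N(mean, sd^2).
    seed : int
        Seed for the single RNG used across all cells (reproducible tables).

    Returns
    -------
    DataFrame with columns ``tissue, step_size_um, speed_mm_s, thickness_um``.
    """
    rng = np.random.default_rng(seed)
    records = []
    for tissue, step, speed, mean, sd, n in design:
        if n < 2:
            raise ValidationError(f"cell ({tissue}, {step}, {speed}): need n >= 2, got {n}")
        if sd < 0:
            raise ValidationError(f"cell ({tissue}, {step}, {speed}): sd must be >= 0")
        draws = rng.normal(mean, sd, int(n)) if sd > 0 else np.full(int(n), float(mean))
        for v in draws:
            records.append(
                {
                    "tissue": tissue,
                    "step_size_um": step,
                    "speed_mm_s": speed,
                    "thickness_um": float(v),
                }
            )
    return pd.DataFrame.from_records(records)
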