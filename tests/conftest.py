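import numpy as np
import pytest

from slicethick.preprocessing import BinaryMask


def make_band_mask(
    rows: int = 200,
    cols: int = 60,
    width: int = 12,
    row_start: int = 10,
    row_end: int | None = None,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Axis-aligned vertical band: `width` foreground columns centred in the
    canvas, spanning rows [row_start, row_end)."""
    if row_end is None:
        row_end = rows - 10
    px = np.zeros((rows, cols), dtype=np.uint8)
    c0 = (cols - width) // 2
    px[row_start:row_end, c0 : c0 + width] = 1
    return BinaryMask(px, pixel_size)


def brute_force_mean_row_width(pixels: np.ndarray) -> float:
    """Independent oracle: count foreground pixels row by row with a loop."""
    widths = []
    for row in pixels:
        count = 0
        for v in row:
            if v == 1:
                count += 1
        widths.append(count)
    return sum(widths) / len(widths)


@pytest.fixture
def band_mask() -> BinaryMask:
    return make_band_mask()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
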