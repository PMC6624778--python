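"""Binary raster plots of standardized signals.

An averaged epoch is standardized to zero mean / unit sample variance,
scaled by the integer image-scale ``gamma`` and floored:

    v[n] = floor(gamma * (x[n] - mean) / sd),   sd with denominator n_max - 1

The plot places a white (255) pixel for sample ``n`` (1-based) at column
``gamma * n`` and joins consecutive samples with classic 8-connected
integer Bresenham segments, on a black (0) canvas whose height is tight to
the plotted ordinate range plus one all-black padding pixel on each side
(so finite-difference gradients have support at the extremes).

Row indices grow with the standardized value, so on screen (row 0 on top) a
positive deflection renders *downward*; only consistency between
calibration and query plots matters, and the convention is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError


@dataclass
class StandardizedSignal:
    """Integer standardized-and-scaled signal with its scaling bookkeeping."""

    values: np.ndarray  # int64, length n_max
    mean_uV: float
    sd_uV: float
    gamma: int


@dataclass
class PlotImage:
    """Binary signal plot.

    ``pixels`` holds 0 (black) or 255 (white); ``zero_row`` is the image row
    where the standardized value 0 falls (the keypoint ordinate).
    """

    pixels: np.ndarray  # uint8, (height, width)
    zero_row: int
    gamma: int
    n_max: int

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def standardize(x: np.ndarray, gamma: int) -> StandardizedSignal:
    """Standardize and scale one averaged epoch to integer ordinates.

    Raises :class:`DegenerateSignalError` on constant input (zero sample
    variance); callers may skip the corresponding location.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal of at least 2 samples")
    if gamma <= 0:
        raise ValueError("gamma must be a positive integer")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSignalError("constant signal cannot be standardized")
    values = np.floor(gamma * (x - mean) / sd).astype(np.int64)
    return StandardizedSignal(values, mean, sd, int(gamma))


def zero_offset(values: np.ndarray) -> int:
    """Vertical offset placing the signal's zero inside the canvas:
    ``floor((max - min) / 2) - floor((max + min) / 2)``.

    For integer inputs this evaluates exactly to ``-min`` (the two floors
    share parity), which is what centres the ordinates at zero minimum.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty signal")
    mx = int(values.max())
    mn = int(values.min())
    return (mx - mn) // 2 - (mx + mn) // 2


def bresenham(x0: int, y0: int, x1: int, y1: int) -> list[tuple[int, int]]:
    """Classic 8-connected integer Bresenham line, endpoints included."""
    points = []
    dx, dy = abs(x1 - x0), -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    x, y = x0, y0
    while True:
        points.append((x, y))
        if x == x1 and y == y1:
            return points
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x += sx
        if e2 <= dx:
            err += dx
            y += sy


def render_plot(sig: StandardizedSignal) -> PlotImage:
    """Rasterize a standardized signal into a binary plot image."""
    values = sig.values
    gamma = sig.gamma
    n_max = values.size
    z = zero_offset(values)
    mn = int(values.min())
    mx = int(values.max())
    width = gamma * n_max + 1
    height = (mx - mn + 1) + 2  # tight range plus 1 padding pixel per side
    pixels = np.zeros((height, width), dtype=np.uint8)

    # sample n (1-based) at column gamma*n; ordinate v+z mapped to row
    # (v + z) - (mn + z) + 1 = v - mn + 1 (mn + z == 0 for integer inputs)
    cols = gamma * np.arange(1, n_max + 1)
    rows = values - mn + 1
    for n in range(n_max - 1):
        for cx, cy in bresenham(int(cols[n]), int(rows[n]),
                                int(cols[n + 1]), int(rows[n + 1])):
            pixels[cy, cx] = 255
    pixels[int(rows[-1]), int(cols[-1])] = 255  # single-segment edge case
    zero_row = z + 1  # ordinate 0 + z, shifted by the padding row
    return PlotImage(pixels, int(zero_row), gamma, n_max)


def save_png(image: PlotImage, path) -> None:
    """Debug dump of a plot image as PNG (requires pillow; not used by the
    decoding pipeline)."""
    from PIL import Image

    Image.fromarray(image.pixels, mode="L").save(path)
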