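"""Histogram of gradient orientations of a signal-plot patch.

The descriptor summarizes the pixel-gradient field around a keypoint
``p_k = (x, y)`` with a 4x4 grid of spatial blocks of ``3 s`` pixels each
(patch extent ``12 s``) and 8 angular bins of 45 degrees.  Every pixel
contributes its gradient magnitude, shared among the (up to) eight adjacent
(block-row, block-col, angle) cells by trilinear interpolation:

    h(theta, i, j) = 3 s * sum_p  w_ang(angle(p) - theta)
                               * w(vx - c_j) * w(vy - c_i) * |J(p)|

with v = (p - p_k) / (3 s), spatial bin centres
c in {-3/2, -1/2, 1/2, 3/2}, the triangular kernel w(z) = max(0, 1 - |z|),
and the circular angular kernel
w_ang(a) = sum_{r in -1,0,1} w(8 a / 2 pi + 8 r).  The histogram is
flattened block-row-major (index = 8 * (4 i + j) + theta/45) into the
128-coordinate descriptor.  Gradients are plain finite differences; no
Gaussian window, no keypoint detection and no orientation assignment are
used — the keypoint is fixed by the flash timing, and scale is set
analytically from the patch-coverage relations below.

Angles are measured from the +x axis (increasing column) with +y pointing
down the image rows, mapped to [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import RunConfig
from .errors import EmptyPatchError
from .plotting import PlotImage

BIN_CENTERS = np.array([-1.5, -0.5, 0.5, 1.5])
THETAS = np.arange(0, 360, 45)


@dataclass(frozen=True)
class Keypoint:
    """Patch centre (pixel column ``x``, pixel row ``y``) and scale ``s``;
    the patch spans ``12 s`` pixels."""

    x: int
    y: int
    s: int


@dataclass
class GradientField:
    """Per-pixel gradient magnitude and angle (degrees in [0, 360))."""

    magnitude: np.ndarray
    angle: np.ndarray  # meaningless where magnitude == 0

    @property
    def shape(self):
        return self.magnitude.shape


@dataclass
class Descriptor:
    """128-coordinate orientation histogram, block-row-major layout."""

    h: np.ndarray  # float64, length 128
    normalized: bool = False

    def as_grid(self) -> np.ndarray:
        """View as (block_row, block_col, angle_bin)."""
        return self.h.reshape(4, 4, 8)


# ---------------------------------------------------------------------------
# patch-scale selection
# ---------------------------------------------------------------------------

def patch_scale(gamma: int, lambda_s: float, fs: float,
                delta_uV: float) -> tuple[float, float]:
    """Patch scales covering ``lambda_s`` seconds horizontally and
    ``delta_uV`` microvolts vertically:

        s_x = gamma * lambda * fs / 12,      s_y = gamma * delta_uV / 12
    """
    return gamma * lambda_s * fs / 12.0, gamma * delta_uV / 12.0


def resolve_scale(s_x: float, s_y: float, tol: float = 0.1) -> int:
    """Common integer patch scale; the two directions must agree within
    ``tol`` before rounding."""
    if abs(s_x - s_y) > tol:
        raise ValueError(
            f"horizontal ({s_x:.3f}) and vertical ({s_y:.3f}) patch scales "
            f"differ by more than {tol}"
        )
    return int(round((s_x + s_y) / 2.0))


def patch_amplitude_coverage(s: int, gamma: int) -> float:
    """Peak-to-peak amplitude (microvolts) the patch height spans: 12 s / gamma."""
    return 12.0 * s / gamma


def patch_time_coverage(s: int, gamma: int, fs: float) -> float:
    """Time span (seconds) the patch width covers: 12 s / (gamma * fs)."""
    return 12.0 * s / (gamma * fs)


def default_keypoint(image: PlotImage, cfg: RunConfig) -> Keypoint:
    """Fixed keypoint at column ``floor(0.55 * target_fs * gamma)`` — just
    past the expected evoked-response peak so the patch straddles the whole
    transient — and at the signal-zero row of the plot."""
    x = int(np.floor(0.55 * cfg.target_fs * cfg.gamma))
    return Keypoint(x, image.zero_row, cfg.s)


# ---------------------------------------------------------------------------
# gradient field and histogram
# ---------------------------------------------------------------------------

def gradient_field(image) -> GradientField:
    """Finite-difference gradient field of a plot image.

    Central differences on interior pixels, one-sided at the borders.
    """
    pixels = image.pixels if isinstance(image, PlotImage) else image
    I = np.asarray(pixels, dtype=float)
    if I.ndim != 2 or min(I.shape) < 3:
        raise ValueError("image must be at least 3x3")
    jx = np.empty_like(I)
    jy = np.empty_like(I)
    jx[:, 1:-1] = (I[:, 2:] - I[:, :-2]) / 2.0
    jx[:, 0] = I[:, 1] - I[:, 0]
    jx[:, -1] = I[:, -1] - I[:, -2]
    jy[1:-1, :] = (I[2:, :] - I[:-2, :]) / 2.0
    jy[0, :] = I[1, :] - I[0, :]
    jy[-1, :] = I[-1, :] - I[-2, :]
    magnitude = np.hypot(jx, jy)
    angle = np.degrees(np.arctan2(jy, jx)) % 360.0
    return GradientField(magnitude, angle)


def angular_weight(alpha_deg: np.ndarray) -> np.ndarray:
    """Circular triangular weight of an angular difference (degrees).

    Implements sum_{r=-1..1} w(8 a / 2 pi + 8 r) with a in radians, i.e.
    w over the difference measured in units of the 45-degree bin width.
    """
    t = np.asarray(alpha_deg, dtype=float) / 45.0
    acc = np.zeros_like(t)
    for r in (-1, 0, 1):
        acc += np.maximum(0.0, 1.0 - np.abs(t + 8.0 * r))
    return acc


def hist_descriptor(field: GradientField, kp: Keypoint) -> Descriptor:
    """Accumulate the trilinearly-interpolated orientation histogram.

    The sum formally runs over every image pixel; pixels whose spatial
    weights all vanish (normalized offset beyond the support) are skipped,
    which is mathematically identical.  Pixels outside the image contribute
    zero.  A keypoint whose 12s x 12s patch misses the image entirely raises
    :class:`EmptyPatchError`.
    """
    H, W = field.shape
    s = kp.s
    half = 6 * s
    if kp.x + half < 0 or kp.x - half > W - 1 or kp.y + half < 0 or kp.y - half > H - 1:
        raise EmptyPatchError(
            f"patch of extent {12 * s} at ({kp.x}, {kp.y}) does not "
            f"intersect a {H}x{W} image"
        )
    # support of the spatial weights: |v| < 2.5  <=>  |offset| < 7.5 s
    reach = int(np.ceil(7.5 * s))
    x_lo, x_hi = max(0, kp.x - reach), min(W - 1, kp.x + reach)
    y_lo, y_hi = max(0, kp.y - reach), min(H - 1, kp.y + reach)
    if x_lo > x_hi or y_lo > y_hi:
        return Descriptor(np.zeros(128))

    mag = field.magnitude[y_lo:y_hi + 1, x_lo:x_hi + 1]
    ang = field.angle[y_lo:y_hi + 1, x_lo:x_hi + 1]
    ys, xs = np.mgrid[y_lo:y_hi + 1, x_lo:x_hi + 1]
    vx = (xs - kp.x) / (3.0 * s)
    vy = (ys - kp.y) / (3.0 * s)

    keep = mag.ravel() > 0
    vx, vy = vx.ravel()[keep], vy.ravel()[keep]
    mag, ang = mag.ravel()[keep], ang.ravel()[keep]

    wx = np.maximum(0.0, 1.0 - np.abs(vx[:, None] - BIN_CENTERS[None, :]))
    wy = np.maximum(0.0, 1.0 - np.abs(vy[:, None] - BIN_CENTERS[None, :]))
    wang = angular_weight(ang[:, None] - THETAS[None, :])
    # h[i, j, b]: block row i follows vy, block col j follows vx
    h = 3.0 * s * np.einsum("pi,pj,pb,p->ijb", wy, wx, wang, mag)
    return Descriptor(h.reshape(128))


def normalize_descriptor(d: Descriptor, mode: str = "max") -> Descriptor:
    """Scale a descriptor into [-1, 1].

    ``"max"`` divides by the maximum absolute entry (raw histograms are
    nonnegative, so the result lies in [0, 1]); ``"l2"`` divides by the
    Euclidean norm.  The zero descriptor maps to itself; normalization is
    idempotent in value.
    """
    if d.normalized:
        raise ValueError("descriptor is already normalized")
    if mode == "max":
        denom = float(np.max(np.abs(d.h)))
    elif mode == "l2":
        denom = float(np.linalg.norm(d.h))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0.0:
        return Descriptor(d.h.copy(), normalized=True)
    return Descriptor(d.h / denom, normalized=True)
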