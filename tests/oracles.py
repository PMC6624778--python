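"""Independent brute-force reference implementations used only by tests.

Each oracle restates the defining formulas with explicit loops, without
sharing any code path with the package implementation.
"""

import numpy as np

SPATIAL_CENTERS = (-1.5, -0.5, 0.5, 1.5)
THETAS = (0, 45, 90, 135, 180, 225, 270, 315)


def brute_force_descriptor(mag, ang, x, y, s):
    """Triple-loop orientation histogram: pixels x blocks x angle bins."""
    H, W = mag.shape
    h = np.zeros((4, 4, 8))
    for py in range(H):
        for px in range(W):
            m = float(mag[py, px])
            if m == 0.0:
                continue
            vx = (px - x) / (3.0 * s)
            vy = (py - y) / (3.0 * s)
            for i, ci in enumerate(SPATIAL_CENTERS):
                wy = max(0.0, 1.0 - abs(vy - ci))
                if wy == 0.0:
                    continue
                for j, cj in enumerate(SPATIAL_CENTERS):
                    wx = max(0.0, 1.0 - abs(vx - cj))
                    if wx == 0.0:
                        continue
                    a = float(ang[py, px])
                    for b, theta in enumerate(THETAS):
                        wang = sum(
                            max(0.0, 1.0 - abs((a - theta) / 45.0 + 8.0 * r))
                            for r in (-1, 0, 1)
                        )
                        if wang:
                            h[i, j, b] += 3.0 * s * wang * wx * wy * m
    return h.reshape(128)


def naive_mean(segments):
    """Per-point arithmetic-mean loop over a (k, 12, n, C) stack."""
    k, L, n, C = segments.shape
    out = np.zeros((L, n, C))
    for l in range(L):
        for t in range(n):
            for c in range(C):
                acc = 0.0
                for i in range(k):
                    acc += segments[i, l, t, c]
                out[l, t, c] = acc / k
    return out


def nbnn_bruteforce(queries, templates, k, metric="cosine"):
    """Explicit sort-all-distances k-NBNN decision."""
    scores = []
    for q in queries:
        ds = []
        for t in templates:
            if metric == "cosine":
                nq, nt = np.linalg.norm(q), np.linalg.norm(t)
                ds.append(1.0 - float(q @ t) / (nq * nt) if nq > 0 and nt > 0
                          else 1.0)
            else:
                ds.append(float(((np.asarray(q) - np.asarray(t)) ** 2).sum()))
        ds.sort()
        scores.append(sum(ds[: min(k, len(ds))]))
    row = 1 + int(np.argmin(scores[:6]))
    col = 7 + int(np.argmin(scores[6:]))
    return row, col, scores


def dense_line_pixels(x0, y0, x1, y1):
    """Naive line rasterization: dense parametric sampling plus rounding."""
    steps = 10 * max(abs(x1 - x0), abs(y1 - y0), 1)
    ts = np.linspace(0.0, 1.0, steps + 1)
    xs = np.rint(x0 + ts * (x1 - x0)).astype(int)
    ys = np.rint(y0 + ts * (y1 - y0)).astype(int)
    return set(zip(xs.tolist(), ys.tolist()))
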