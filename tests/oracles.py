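"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit pixel loops, exhaustive
scans, closed-form normal equations — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np


def sliding_median_oracle(image: np.ndarray, kernel: int) -> np.ndarray:
    """Per-pixel median of the kernel x kernel reflected neighborhood."""
    img = np.asarray(image, dtype=np.float64)
    pad_lo = (kernel - 1) // 2
    pad_hi = kernel // 2
    # edge policy: reflect including the edge pixel (numpy "symmetric")
    padded = np.pad(img, ((pad_lo, pad_hi), (pad_lo, pad_hi)), mode="symmetric")
    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = np.median(padded[r : r + kernel, c : c + kernel])
    return out


def manders_oracle(ch1, ch2, domain=None, thr1=0.0, thr2=0.0):
    """M1/M2 by explicit per-pixel summation loops."""
    a = np.asarray(ch1, float)
    b = np.asarray(ch2, float)
    if domain is None:
        domain = np.ones(a.shape, bool)
    num1 = den1 = num2 = den2 = 0.0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            if not domain[r, c]:
                continue
            den1 += a[r, c]
            den2 += b[r, c]
            if b[r, c] > thr2:
                num1 += a[r, c]
            if a[r, c] > thr1:
                num2 += b[r, c]
    return num1 / den1, num2 / den2


def ols_slope_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept via the normal equations, solved with linalg."""
    X = np.stack([np.ones_like(x, dtype=float), np.asarray(x, float)], axis=1)
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    return float(beta[1]), float(beta[0])


def region_mean_oracle(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity over a mask by explicit accumulation."""
    total = 0.0
    n = 0
    img = np.asarray(image, float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if mask[r, c]:
                total += img[r, c]
                n += 1
    return total / n


def min_distance_oracle(point, mask) -> float:
    """Exhaustive minimum distance from a point to any True pixel."""
    r0, c0 = point
    best = np.inf
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                best = min(best, np.hypot(r - r0, c - c0))
    return best


def and_count_oracle(a, b) -> int:
    """Pixel count of the mask intersection by explicit loop."""
    n = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            if a[r, c] and b[r, c]:
                n += 1
    return n


def above_threshold_oracle(image, threshold) -> set:
    """Set of (row, col) with intensity strictly above the threshold."""
    out = set()
    img = np.asarray(image, float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if img[r, c] > threshold:
                out.add((r, c))
    return out


def annulus_pixel_count_oracle(shape, center, r_in, r_out) -> int:
    """|{p : r_in <= dist(p, center) <= r_out}| by exhaustive scan."""
    cr, cc = center
    n = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if r_in <= np.hypot(r - cr, c - cc) <= r_out:
                n += 1
    return n


def ray_width_oracle(ext_mask, int_mask, center, n_angles=360) -> float:
    """Mean (external - internal) radius by per-angle ray casting.

    For each angle, march outward from the center and record the last
    radius still inside each mask; angles where either ray misses are
    skipped.
    """
    cr, cc = center
    max_r = int(np.hypot(*ext_mask.shape))
    widths = []
    for k in range(n_angles):
        ang = 2 * np.pi * k / n_angles
        dr, dc = np.sin(ang), np.cos(ang)
        r_ext = r_int = None
        for rad in np.arange(0, max_r, 0.25):
            rr = int(round(cr + rad * dr))
            cc_ = int(round(cc + rad * dc))
            if not (0 <= rr < ext_mask.shape[0] and 0 <= cc_ < ext_mask.shape[1]):
                break
            if ext_mask[rr, cc_]:
                r_ext = rad
            if int_mask[rr, cc_]:
                r_int = rad
        if r_ext is not None and r_int is not None:
            widths.append(r_ext - r_int)
    return float(np.mean(widths))
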