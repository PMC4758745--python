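"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-pixel / per-element Python loops,
deliberately sharing no code path with the package implementation, so that
mask rasterization, metric computation and rank statistics can be checked
against exhaustive recomputation.
"""

from __future__ import annotations

import math

import numpy as np


def ellipse_mask_oracle(cx, cy, a, b, rotation_deg, shape):
    """Per-pixel evaluation of the rotated-ellipse inequality at pixel centres.

    Mirrors the documented membership contract, including its 1e-12 boundary
    slack.
    """
    rows, cols = shape
    mask = np.zeros((rows, cols), dtype=bool)
    theta = math.radians(rotation_deg)
    for r in range(rows):
        for c in range(cols):
            dx, dy = c - cx, r - cy
            u = dx * math.cos(theta) + dy * math.sin(theta)
            v = -dx * math.sin(theta) + dy * math.cos(theta)
            mask[r, c] = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-12
    return mask


def polygon_fill_oracle(curve, shape):
    """Even-odd ray-casting point-in-polygon test at every pixel centre.

    ``curve`` is the densely sampled closed boundary, shape (n, 2) of (x, y).
    """
    rows, cols = shape
    xs = [float(p[0]) for p in curve]
    ys = [float(p[1]) for p in curve]
    n = len(xs)
    mask = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            inside = False
            px, py = float(c), float(r)
            j = n - 1
            for i in range(n):
                if (ys[i] > py) != (ys[j] > py):
                    x_cross = xs[j] + (py - ys[j]) * (xs[i] - xs[j]) / (ys[i] - ys[j])
                    if px < x_cross:
                        inside = not inside
                j = i
            mask[r, c] = inside
    return mask


def set_difference_oracle(mask, exclusion_masks):
    """Loop-based set difference over pixel coordinates."""
    out = np.zeros_like(mask, dtype=bool)
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not any(ex[r, c] for ex in exclusion_masks):
                out[r, c] = True
    return out


def peripheral_mask_oracle(mask, centroid, fraction):
    """Re-derivation of the radial-depth band, with loops.

    Mirrors the documented definition: 1-degree angular bins whose radial
    extents are taken over the circular 3-bin window around each bin.
    """
    cx, cy = centroid
    members = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    lo_bin = [math.inf] * 360
    hi_bin = [-math.inf] * 360
    info = []
    for r, c in members:
        dx, dy = c - cx, r - cy
        radius = math.hypot(dx, dy)
        angle = math.degrees(math.atan2(dy, dx)) % 360.0
        b = min(int(angle), 359)
        info.append((r, c, radius, b))
        lo_bin[b] = min(lo_bin[b], radius)
        hi_bin[b] = max(hi_bin[b], radius)
    out = np.zeros_like(mask, dtype=bool)
    for r, c, radius, b in info:
        window = [(b - 1) % 360, b, (b + 1) % 360]
        lo = min(lo_bin[w] for w in window)
        hi = max(hi_bin[w] for w in window)
        thickness = hi - lo
        depth = 0.0 if thickness <= 1e-9 else (hi - radius) / thickness
        if depth <= fraction + 1e-12:
            out[r, c] = True
    return out


def nuclear_metrics_oracle(pixels, mask, exclusion_masks=()):
    """Loop-based max / mean / count over member-and-not-excluded pixels."""
    vals = []
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not any(ex[r, c] for ex in exclusion_masks):
                vals.append(float(pixels[r, c]))
    return max(vals), sum(vals) / len(vals), len(vals)


def percent_opaque_oracle(pixels, mask, threshold, exclusion_masks=()):
    opaque = total = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not any(ex[r, c] for ex in exclusion_masks):
                total += 1
                if pixels[r, c] > threshold:
                    opaque += 1
    return 100.0 * opaque / total


def pooled_percent_oracle(slices, threshold):
    """``slices`` is a list of (pixels, mask) pairs; counts pooled then divided."""
    opaque = total = 0
    for pixels, mask in slices:
        rows, cols = mask.shape
        for r in range(rows):
            for c in range(cols):
                if mask[r, c]:
                    total += 1
                    if pixels[r, c] > threshold:
                        opaque += 1
    return 100.0 * opaque / total


def pooled_max_oracle(eye_pixel_lists):
    best = -math.inf
    for eye in eye_pixel_lists:
        for v in np.asarray(eye).ravel():
            best = max(best, float(v))
    return best


def average_ranks_oracle(values):
    """Average ranks (ties share the mean rank), by explicit sorting."""
    values = [float(v) for v in values]
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def spearman_rho_oracle(x, y):
    """Pearson correlation of average ranks, from first principles."""
    rx = average_ranks_oracle(x)
    ry = average_ranks_oracle(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def median_min_max_oracle(values):
    """Sort-based median / min / max."""
    s = sorted(float(v) for v in values)
    n = len(s)
    median = s[n // 2] if n % 2 == 1 else 0.5 * (s[n // 2 - 1] + s[n // 2])
    return median, s[0], s[-1]
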