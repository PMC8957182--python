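"""Numba kernel for normalized cross-correlation block matching.

Computes, for every mesh point, the full NCC plane between a block
around the point in frame A and every integer offset within the search
window in frame B. Kept separate so the tracking module stays readable
and the kernel stays trivially testable against a brute-force oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ncc_planes"]


@njit(cache=True)
def _ncc_planes_impl(f0, f1, cx, cy, half, sr, planes, covs, ok):
    h, w = f0.shape
    n_points = cx.shape[0]
    b = 2 * half + 1
    n = b * b
    for p in range(n_points):
        x0 = cx[p] - half
        y0 = cy[p] - half
        if x0 - sr < 0 or y0 - sr < 0 or x0 + b + sr > w or y0 + b + sr > h:
            ok[p] = False
            continue
        tsum = 0.0
        tsq = 0.0
        for i in range(b):
            for j in range(b):
                v = f0[y0 + i, x0 + j]
                tsum += v
                tsq += v * v
        tvar = tsq - tsum * tsum / n
        if tvar < 1e-10:
            ok[p] = False
            continue
        ok[p] = True
        for dy in range(-sr, sr + 1):
            for dx in range(-sr, sr + 1):
                s1 = 0.0
                s2 = 0.0
                cr = 0.0
                for i in range(b):
                    yy = y0 + dy + i
                    for j in range(b):
                        vw = f1[yy, x0 + dx + j]
                        s1 += vw
                        s2 += vw * vw
                        cr += vw * f0[y0 + i, x0 + j]
                wvar = s2 - s1 * s1 / n
                cov = cr - s1 * tsum / n
                if wvar < 1e-10:
                    c = -1.0
                else:
                    c = cov / np.sqrt(wvar * tvar)
                planes[p, dy + sr, dx + sr] = c
                covs[p, dy + sr, dx + sr] = cov


def ncc_planes(
    f0: np.ndarray,
    f1: np.ndarray,
    centers_xy: np.ndarray,
    half: int,
    search_radius: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NCC and covariance planes for all points.

    Returns ``planes`` (NCC values), ``covs`` (the mean-removed
    cross-covariance numerator, whose peak shape is free of the local
    window-variance gradient and therefore better suited to sub-pixel
    fitting), each of shape (n_points, 2*sr+1, 2*sr+1), and a boolean
    ``ok`` flag per point (False when the block leaves the image or the
    template has no variance; the corresponding planes are undefined).
    """
    f0 = np.ascontiguousarray(f0, dtype=np.float64)
    f1 = np.ascontiguousarray(f1, dtype=np.float64)
    cx = np.ascontiguousarray(np.round(centers_xy[..., 0]).ravel(), dtype=np.int64)
    cy = np.ascontiguousarray(np.round(centers_xy[..., 1]).ravel(), dtype=np.int64)
    n_points = cx.shape[0]
    side = 2 * search_radius + 1
    planes = np.full((n_points, side, side), -2.0, dtype=np.float64)
    covs = np.full((n_points, side, side), -2.0, dtype=np.float64)
    ok = np.zeros(n_points, dtype=np.bool_)
    _ncc_planes_impl(f0, f1, cx, cy, half, search_radius, planes, covs, ok)
    return planes, covs, ok
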