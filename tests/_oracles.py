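"""Independent scalar oracles used by the test suite.

Everything here is written as plain per-pair loops with elementwise
formulas, deliberately sharing no code with the vectorized package
implementations they are used to check.
"""

import math

import numpy as np


def _cross(a, b):
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _norm(a):
    return math.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2)


def _angle(u, v):
    return math.atan2(_norm(_cross(u, v)), _dot(u, v))


def scalar_force_closure(positions, normals, i, j):
    cpt, cpi = positions[i], positions[j]
    ft = tuple(-x for x in normals[i])
    fi = tuple(-x for x in normals[j])
    axis_ti = tuple(cpi[k] - cpt[k] for k in range(3))
    axis_it = tuple(cpt[k] - cpi[k] for k in range(3))
    return _angle(ft, axis_ti) + _angle(fi, axis_it)


def scalar_torque(positions, com, mass_g, gravity, i, j):
    neg_fg = (0.0, 0.0, mass_g / 1000.0 * gravity)  # N, upward
    total = (0.0, 0.0, 0.0)
    for cp in (positions[i], positions[j]):
        lever = tuple((com[k] - cp[k]) / 1000.0 for k in range(3))  # m
        t = _cross(lever, neg_fg)
        total = tuple(total[k] + t[k] for k in range(3))
    return _norm(total)


def scalar_nga(positions, nga, i, j):
    axis = tuple(positions[j][k] - positions[i][k] for k in range(3))
    return _angle(nga, axis)


def scalar_aperture(positions, threshold, i, j):
    d = _norm(tuple(positions[j][k] - positions[i][k] for k in range(3)))
    return 0.0 if d < threshold else d - threshold


def scalar_visibility(positions, hand, i, j):
    """Occluded fraction: points strictly on the hand's side of the 2D
    line through the projected contacts."""
    ax, ay = positions[i][0], positions[i][1]
    bx, by = positions[j][0], positions[j][1]
    dx, dy = bx - ax, by - ay
    if math.hypot(dx, dy) < 1e-9:  # coincident projections
        ux, uy = hand[0] - ax, hand[1] - ay
        dx, dy = -uy, ux
    h = math.hypot(dx, dy)
    dx, dy = dx / h, dy / h
    hand_side = dx * (hand[1] - ay) - dy * (hand[0] - ax)
    if abs(hand_side) <= 1e-6:  # hand on the line: occludes nothing
        return 0.0
    s = 1.0 if hand_side >= 0 else -1.0
    occluded = 0
    for p in positions:
        c = dx * (p[1] - ay) - dy * (p[0] - ax)  # signed distance, mm
        if c * s > 1e-6:
            occluded += 1
    return occluded / len(positions)


def scalar_normalize(values):
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0 for _ in values]
    return [(v - lo) / (hi - lo) for v in values]


def brute_force_nearest(point, candidates):
    best, best_d = -1, float("inf")
    for k, c in enumerate(candidates):
        d = _norm(tuple(point[i] - c[i] for i in range(3)))
        if d < best_d:
            best, best_d = k, d
    return best, best_d


def brute_force_medoid(vectors):
    """Index of the member with minimal summed 6D distance to the rest."""
    best, best_sum = -1, float("inf")
    for i, vi in enumerate(vectors):
        total = 0.0
        for vj in vectors:
            total += math.sqrt(sum((a - b) ** 2 for a, b in zip(vi, vj)))
        if total < best_sum:
            best, best_sum = i, total
    return best


def brute_force_min_pair(values, mask):
    """Unmasked (row, col) with the smallest value, by exhaustive scan."""
    best, best_v = None, float("inf")
    n = len(values)
    for i in range(n):
        for j in range(n):
            if mask[i][j]:
                continue
            if values[i][j] < best_v:
                best, best_v = (i, j), values[i][j]
    return best, best_v


def voxel_com(inside_fn, bounds, step=1.0):
    """Brute-force uniform-density CoM by voxel enumeration."""
    (x0, x1), (y0, y1), (z0, z1) = bounds
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    zs = np.arange(z0 + step / 2, z1, step)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    occ = pts[inside_fn(pts)]
    return occ.mean(axis=0)


def spearman(a, b):
    """Spearman rank correlation, plain implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def ranks(x):
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        r[order] = np.arange(len(x), dtype=float)
        # average ranks of ties
        for v in np.unique(x):
            m = x == v
            r[m] = r[m].mean()
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = math.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom) if denom else 0.0
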