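"""Naive brute-force reference implementations used as independent oracles.

Deliberately slow and simple: nested loops and exhaustive enumeration, kept
independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def box_offsets(radii_zyx):
    rz, ry, rx = radii_zyx
    return [
        (dz, dy, dx)
        for dz in range(-rz, rz + 1)
        for dy in range(-ry, ry + 1)
        for dx in range(-rx, rx + 1)
    ]


def ellipsoid_offsets(radii_zyx):
    rz, ry, rx = radii_zyx
    return [
        (dz, dy, dx)
        for dz, dy, dx in box_offsets(radii_zyx)
        if (dz / rz) ** 2 + (dy / ry) ** 2 + (dx / rx) ** 2 <= 1.0
    ]


def _min_filter(data, offsets):
    out = np.empty_like(data, dtype=float)
    nz, ny, nx = data.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                vals = [
                    data[z + dz, y + dy, x + dx]
                    for dz, dy, dx in offsets
                    if 0 <= z + dz < nz and 0 <= y + dy < ny and 0 <= x + dx < nx
                ]
                out[z, y, x] = min(vals)
    return out


def _max_filter(data, offsets):
    out = np.empty_like(data, dtype=float)
    nz, ny, nx = data.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                vals = [
                    data[z + dz, y + dy, x + dx]
                    for dz, dy, dx in offsets
                    if 0 <= z + dz < nz and 0 <= y + dy < ny and 0 <= x + dx < nx
                ]
                out[z, y, x] = max(vals)
    return out


def brute_force_opening(data, offsets):
    """Grey opening: erosion (min) then dilation (max) over the same element."""
    return _max_filter(_min_filter(np.asarray(data, dtype=float), offsets), offsets)


def brute_force_flood(mask, seed):
    """26-connected component of ``mask`` containing ``seed`` (BFS)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask[seed]:
        return set()
    shape = mask.shape
    seen = {seed}
    frontier = [seed]
    neighbours = [
        d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
    ]
    while frontier:
        z, y, x = frontier.pop()
        for dz, dy, dx in neighbours:
            p = (z + dz, y + dy, x + dx)
            if (
                0 <= p[0] < shape[0]
                and 0 <= p[1] < shape[1]
                and 0 <= p[2] < shape[2]
                and p not in seen
                and mask[p]
            ):
                seen.add(p)
                frontier.append(p)
    return seen


def brute_force_ks(sample_a, sample_b):
    """sup |ECDF_a - ECDF_b| over every observed value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return best


def max_matching_count(candidate_pairs, n_green, n_red):
    """Maximum-cardinality one-to-one matching by exhaustive recursion."""
    pairs = list(candidate_pairs)

    def rec(i, used_g, used_r):
        if i == len(pairs):
            return 0
        best = rec(i + 1, used_g, used_r)
        g, r = pairs[i]
        if g not in used_g and r not in used_r:
            best = max(best, 1 + rec(i + 1, used_g | {g}, used_r | {r}))
        return best

    return rec(0, frozenset(), frozenset())


def chord_mean_ratio():
    """Analytic mean of D*sqrt(1-u^2)/D for u uniform on (-1, 1): pi/4."""
    return math.pi / 4.0
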