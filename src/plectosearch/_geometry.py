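"""Low-level geometry kernels (numba-compiled).

Writhe of a closed polygonal curve is computed with the exact pairwise
solid-angle method for straight segments (Klenin & Langowski's method 1a):
the Gauss double integral over a pair of non-adjacent segments has a closed
form in terms of four spherical dihedral angles, with the sign of the
crossing taken from (r34 x r12) . r13.  Right-handed crossings count
positive.  The method is exact for polygons, so it serves as its own
oracle against high-resolution quadrature on smooth curves.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _pair_solid_angle(p1, p2, q1, q2):
    """Gauss-integral contribution (both integration orders) of segment pair
    (p1->p2, q1->q2), divided by 4*pi.  Zero for coplanar/degenerate pairs."""
    r13x = q1[0] - p1[0]
    r13y = q1[1] - p1[1]
    r13z = q1[2] - p1[2]
    r14x = q2[0] - p1[0]
    r14y = q2[1] - p1[1]
    r14z = q2[2] - p1[2]
    r23x = q1[0] - p2[0]
    r23y = q1[1] - p2[1]
    r23z = q1[2] - p2[2]
    r24x = q2[0] - p2[0]
    r24y = q2[1] - p2[1]
    r24z = q2[2] - p2[2]
    r12x = p2[0] - p1[0]
    r12y = p2[1] - p1[1]
    r12z = p2[2] - p1[2]
    r34x = q2[0] - q1[0]
    r34y = q2[1] - q1[1]
    r34z = q2[2] - q1[2]

    # n1 = r13 x r14, n2 = r14 x r24, n3 = r24 x r23, n4 = r23 x r13
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x

    m1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    m2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    m3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    m4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    eps = 1e-12
    if m1 < eps or m2 < eps or m3 < eps or m4 < eps:
        return 0.0

    d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
    d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (m2 * m3)
    d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (m3 * m4)
    d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (m4 * m1)
    d12 = min(1.0, max(-1.0, d12))
    d23 = min(1.0, max(-1.0, d23))
    d34 = min(1.0, max(-1.0, d34))
    d41 = min(1.0, max(-1.0, d41))
    omega = (np.arcsin(d12) + np.arcsin(d23)
             + np.arcsin(d34) + np.arcsin(d41))

    # crossing sign: (r34 x r12) . r13
    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    s = cx * r13x + cy * r13y + cz * r13z
    if s > 0.0:
        sign = 1.0
    elif s < 0.0:
        sign = -1.0
    else:
        sign = 0.0
    return omega * sign / (4.0 * np.pi)


@njit(cache=True, fastmath=True, inline="always")
def _pair_solid_angle_idx(A, i, i2, B, j, j2):
    """Same contribution as :func:`_pair_solid_angle`, reading the segment
    endpoints A[i]->A[i2] and B[j]->B[j2] by index (no row views)."""
    p1x = A[i, 0]
    p1y = A[i, 1]
    p1z = A[i, 2]
    p2x = A[i2, 0]
    p2y = A[i2, 1]
    p2z = A[i2, 2]
    q1x = B[j, 0]
    q1y = B[j, 1]
    q1z = B[j, 2]
    q2x = B[j2, 0]
    q2y = B[j2, 1]
    q2z = B[j2, 2]

    r13x = q1x - p1x
    r13y = q1y - p1y
    r13z = q1z - p1z
    r14x = q2x - p1x
    r14y = q2y - p1y
    r14z = q2z - p1z
    r23x = q1x - p2x
    r23y = q1y - p2y
    r23z = q1z - p2z
    r24x = q2x - p2x
    r24y = q2y - p2y
    r24z = q2z - p2z
    r12x = p2x - p1x
    r12y = p2y - p1y
    r12z = p2z - p1z
    r34x = q2x - q1x
    r34y = q2y - q1y
    r34z = q2z - q1z

    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x

    m1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    m2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    m3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    m4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    eps = 1e-12
    if m1 < eps or m2 < eps or m3 < eps or m4 < eps:
        return 0.0

    d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
    d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (m2 * m3)
    d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (m3 * m4)
    d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (m4 * m1)
    d12 = min(1.0, max(-1.0, d12))
    d23 = min(1.0, max(-1.0, d23))
    d34 = min(1.0, max(-1.0, d34))
    d41 = min(1.0, max(-1.0, d41))
    omega = (np.arcsin(d12) + np.arcsin(d23)
             + np.arcsin(d34) + np.arcsin(d41))

    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    s = cx * r13x + cy * r13y + cz * r13z
    if s > 0.0:
        sign = 1.0
    elif s < 0.0:
        sign = -1.0
    else:
        sign = 0.0
    return omega * sign / (4.0 * np.pi)


@njit(cache=True)
def _adjacent(i, j, n):
    d = abs(i - j)
    if d > n - d:
        d = n - d
    return d < 2


@njit(cache=True)
def writhe_full(centers):
    """Writhe of the closed polygon through ``centers`` (exact Gauss sum)."""
    n = centers.shape[0]
    total = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 1, n):
            if _adjacent(i, j, n):
                continue
            total += _pair_solid_angle_idx(centers, i, i2,
                                           centers, j, (j + 1) % n)
    return 2.0 * total


@njit(cache=True)
def writhe_changed_sum(centers, changed):
    """Sum of pair contributions over unordered pairs touching a changed
    segment (changed: boolean mask over segment indices).  Differencing two
    such sums before/after a move gives the writhe change, because pairs of
    jointly-rotated segments are invariant under the rigid arc rotation."""
    n = centers.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if not (changed[i] or changed[j]):
                continue
            if _adjacent(i, j, n):
                continue
            total += _pair_solid_angle_idx(centers, i, (i + 1) % n,
                                           centers, j, (j + 1) % n)
    return 2.0 * total


@njit(cache=True)
def min_distance_to_moved(centers, moved, min_sep):
    """Minimum distance between any moved bead and any bead at circular
    index separation >= min_sep (moved: boolean mask over beads)."""
    n = centers.shape[0]
    best = 1e30
    for i in range(n):
        if not moved[i]:
            continue
        for j in range(n):
            if moved[j] and j <= i:
                continue  # moved-moved pairs counted once
            d = abs(i - j)
            if d > n - d:
                d = n - d
            if d < min_sep:
                continue
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < best:
                best = r
    return best


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about unit ``axis`` by ``angle`` radians."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])
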