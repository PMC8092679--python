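"""Numba-compiled numerical kernels for the rod-like chain simulator.

Everything in here operates on bare ``(N, 3)`` float64 vertex arrays of a
closed equilateral chain; the object-level API lives in :mod:`parbsbm.polymer`
and :mod:`parbsbm.mc`.  The Gauss-integral contribution of a pair of straight
segments follows the closed form of Klenin & Langowski (2000), method 1a.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "pair_omega",
    "writhe_full",
    "local_writhe_profile",
    "segment_min_dist2",
    "min_nonadjacent_dist",
    "run_moves",
]


@njit(cache=True, fastmath=True)
def _clamp(x):
    if x > 1.0:
        return 1.0
    if x < -1.0:
        return -1.0
    return x


@njit(cache=True, fastmath=True)
def pair_omega(p1x, p1y, p1z, p2x, p2y, p2z,
               q1x, q1y, q1z, q2x, q2y, q2z):
    """Solid-angle contribution Ω of segment pair (p1→p2, q1→q2).

    The writhe of a closed polygon is (4π)⁻¹ Σ_{i≠j} Ω_ij.  Coplanar pairs
    (including adjacent segments of a chain) contribute exactly 0.
    """
    # relative vectors
    r13x, r13y, r13z = q1x - p1x, q1y - p1y, q1z - p1z
    r14x, r14y, r14z = q2x - p1x, q2y - p1y, q2z - p1z
    r23x, r23y, r23z = q1x - p2x, q1y - p2y, q1z - p2z
    r24x, r24y, r24z = q2x - p2x, q2y - p2y, q2z - p2z

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

    a1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    a2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    a3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    a4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if a1 < 1e-14 or a2 < 1e-14 or a3 < 1e-14 or a4 < 1e-14:
        return 0.0  # coplanar or degenerate pair

    s = (math.asin(_clamp((n1x * n2x + n1y * n2y + n1z * n2z) / (a1 * a2)))
         + math.asin(_clamp((n2x * n3x + n2y * n3y + n2z * n3z) / (a2 * a3)))
         + math.asin(_clamp((n3x * n4x + n3y * n4y + n3z * n4z) / (a3 * a4)))
         + math.asin(_clamp((n4x * n1x + n4y * n1y + n4z * n1z) / (a4 * a1))))

    # sign((r34 x r12) . r13)
    r12x, r12y, r12z = p2x - p1x, p2y - p1y, p2z - p1z
    r34x, r34y, r34z = q2x - q1x, q2y - q1y, q2z - q1z
    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    sgn = cx * r13x + cy * r13y + cz * r13z
    if sgn > 0.0:
        return s
    elif sgn < 0.0:
        return -s
    return 0.0


@njit(cache=True)
def writhe_full(v):
    """Writhe of the closed polygon ``v`` ((N, 3) vertices), in turns."""
    n = v.shape[0]
    tot = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closure
            j2 = (j + 1) % n
            tot += pair_omega(v[i, 0], v[i, 1], v[i, 2],
                              v[i2, 0], v[i2, 1], v[i2, 2],
                              v[j, 0], v[j, 1], v[j, 2],
                              v[j2, 0], v[j2, 1], v[j2, 2])
    return tot / (2.0 * math.pi)


@njit(cache=True)
def local_writhe_profile(v, m):
    """Local writhe wr(i) = (2π)⁻¹ Σ_{j=i−m/2}^{i+m/2} Ω_ij, periodic in i."""
    n = v.shape[0]
    half = m // 2
    # at full window (m == n) the offsets −n/2 and +n/2 alias the same
    # segment; drop the lower end to count the antipodal pair once
    start = -half + 1 if m == n else -half
    out = np.zeros(n)
    for i in range(n):
        i2 = (i + 1) % n
        acc = 0.0
        for dj in range(start, half + 1):
            j = (i + dj) % n
            if j == i or j == (i - 1) % n or j == i2:
                continue  # self and adjacent contribute 0
            j2 = (j + 1) % n
            acc += pair_omega(v[i, 0], v[i, 1], v[i, 2],
                              v[i2, 0], v[i2, 1], v[i2, 2],
                              v[j, 0], v[j, 1], v[j, 2],
                              v[j2, 0], v[j2, 1], v[j2, 2])
        out[i] = acc / (2.0 * math.pi)
    return out


@njit(cache=True, fastmath=True)
def segment_min_dist2(p1x, p1y, p1z, p2x, p2y, p2z,
                      q1x, q1y, q1z, q2x, q2y, q2z):
    """Squared minimum distance between segments p1–p2 and q1–q2 (Ericson)."""
    d1x, d1y, d1z = p2x - p1x, p2y - p1y, p2z - p1z
    d2x, d2y, d2z = q2x - q1x, q2y - q1y, q2z - q1z
    rx, ry, rz = p1x - q1x, p1y - q1y, p1z - q1z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    c = d1x * rx + d1y * ry + d1z * rz
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > 1e-12:
        s = (b * f - c * e) / denom
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = -c / a
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    elif t > 1.0:
        t = 1.0
        s = (b - c) / a
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    cx = p1x + d1x * s - (q1x + d2x * t)
    cy = p1y + d1y * s - (q1y + d2y * t)
    cz = p1z + d1z * s - (q1z + d2z * t)
    return cx * cx + cy * cy + cz * cz


@njit(cache=True)
def min_nonadjacent_dist(v):
    """Minimum center-line distance over all non-adjacent segment pairs."""
    n = v.shape[0]
    best = 1e300
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            j2 = (j + 1) % n
            d2 = segment_min_dist2(v[i, 0], v[i, 1], v[i, 2],
                                   v[i2, 0], v[i2, 1], v[i2, 2],
                                   v[j, 0], v[j, 1], v[j, 2],
                                   v[j2, 0], v[j2, 1], v[j2, 2])
            if d2 < best:
                best = d2
    return math.sqrt(best)


@njit(cache=True)
def _rotate_about_axis(v, out, i0, nrot, ax, ay, az, ang, ox, oy, oz, n):
    """Rodrigues rotation of ``nrot`` vertices starting at i0+1 (periodic)."""
    ca = math.cos(ang)
    sa = math.sin(ang)
    for k in range(nrot):
        idx = (i0 + 1 + k) % n
        px = v[idx, 0] - ox
        py = v[idx, 1] - oy
        pz = v[idx, 2] - oz
        dot = ax * px + ay * py + az * pz
        cx = ay * pz - az * py
        cy = az * px - ax * pz
        cz = ax * py - ay * px
        out[k, 0] = ox + px * ca + cx * sa + ax * dot * (1.0 - ca)
        out[k, 1] = oy + py * ca + cy * sa + ay * dot * (1.0 - ca)
        out[k, 2] = oz + pz * ca + cz * sa + az * dot * (1.0 - ca)


@njit(cache=True)
def _segments_adjacent(s, t, n):
    d = (s - t) % n
    return d == 0 or d == 1 or d == n - 1


@njit(cache=True)
def run_moves(v, kappa, c_tw, d_lk, wr0, rand, max_span, max_angle,
              min_dist2, max_dwr, check_overlap):
    """Metropolis crankshaft loop on the closed chain ``v`` (modified in place).

    Parameters
    ----------
    v : (N, 3) vertices, updated in place.
    kappa : per-joint bending constant (k_BT).
    c_tw : torsional prefactor 2π²C/L (k_BT per turn²).
    d_lk : Lk − Lk0 (turns), constant during the loop.
    wr0 : current writhe of ``v`` (turns).
    rand : (n_moves, 4) uniforms — site, span, angle, acceptance.
    max_span : M, maximum number of rotated cylinders.
    max_angle : rotation amplitude (radians).
    min_dist2 : squared hard-core center-line distance (4 nm)² = 16.
    max_dwr : reject moves with |ΔWr| above this (strand-passage guard).
    check_overlap : whether to enforce self-avoidance.

    Returns ``(wr, n_accepted)``.
    """
    n = v.shape[0]
    n_moves = rand.shape[0]
    wr = wr0
    acc = 0
    new = np.empty((max_span, 3))
    for step in range(n_moves):
        i = int(rand[step, 0] * n)
        if i >= n:
            i = n - 1
        span = 1 + int(rand[step, 1] * max_span)
        if span > max_span:
            span = max_span
        j = (i + span) % n
        nrot = span - 1
        if nrot == 0:
            acc += 1  # identity move
            continue
        ax = v[j, 0] - v[i, 0]
        ay = v[j, 1] - v[i, 1]
        az = v[j, 2] - v[i, 2]
        anorm = math.sqrt(ax * ax + ay * ay + az * az)
        if anorm < 1e-12:
            continue
        ax /= anorm
        ay /= anorm
        az /= anorm
        ang = (2.0 * rand[step, 2] - 1.0) * max_angle
        _rotate_about_axis(v, new, i, nrot, ax, ay, az, ang,
                           v[i, 0], v[i, 1], v[i, 2], n)

        # bending-energy change: only joints at vertices i and j are affected
        im1 = (i - 1) % n
        i1 = (i + 1) % n
        jm1 = (j - 1) % n
        j1 = (j + 1) % n
        l2 = ((v[i1, 0] - v[i, 0]) ** 2 + (v[i1, 1] - v[i, 1]) ** 2
              + (v[i1, 2] - v[i, 2]) ** 2)
        # old cosines
        cos_i_old = ((v[i, 0] - v[im1, 0]) * (v[i1, 0] - v[i, 0])
                     + (v[i, 1] - v[im1, 1]) * (v[i1, 1] - v[i, 1])
                     + (v[i, 2] - v[im1, 2]) * (v[i1, 2] - v[i, 2])) / l2
        cos_j_old = ((v[j, 0] - v[jm1, 0]) * (v[j1, 0] - v[j, 0])
                     + (v[j, 1] - v[jm1, 1]) * (v[j1, 1] - v[j, 1])
                     + (v[j, 2] - v[jm1, 2]) * (v[j1, 2] - v[j, 2])) / l2
        cos_i_new = ((v[i, 0] - v[im1, 0]) * (new[0, 0] - v[i, 0])
                     + (v[i, 1] - v[im1, 1]) * (new[0, 1] - v[i, 1])
                     + (v[i, 2] - v[im1, 2]) * (new[0, 2] - v[i, 2])) / l2
        cos_j_new = ((v[j, 0] - new[nrot - 1, 0]) * (v[j1, 0] - v[j, 0])
                     + (v[j, 1] - new[nrot - 1, 1]) * (v[j1, 1] - v[j, 1])
                     + (v[j, 2] - new[nrot - 1, 2]) * (v[j1, 2] - v[j, 2])) / l2
        de_bend = kappa * ((cos_i_old - cos_i_new) + (cos_j_old - cos_j_new))

        # moved segments are i .. i+span-1 (mod N); all others are static
        if check_overlap:
            ok = True
            for ms in range(span):
                s_idx = (i + ms) % n
                # endpoints of moved segment in proposed coordinates
                if ms == 0:
                    ax1, ay1, az1 = v[i, 0], v[i, 1], v[i, 2]
                else:
                    ax1, ay1, az1 = new[ms - 1, 0], new[ms - 1, 1], new[ms - 1, 2]
                if ms == span - 1:
                    bx1, by1, bz1 = v[j, 0], v[j, 1], v[j, 2]
                else:
                    bx1, by1, bz1 = new[ms, 0], new[ms, 1], new[ms, 2]
                for t_off in range(span, n):
                    t_idx = (i + t_off) % n
                    if _segments_adjacent(s_idx, t_idx, n):
                        continue
                    t2 = (t_idx + 1) % n
                    d2 = segment_min_dist2(
                        ax1, ay1, az1, bx1, by1, bz1,
                        v[t_idx, 0], v[t_idx, 1], v[t_idx, 2],
                        v[t2, 0], v[t2, 1], v[t2, 2])
                    if d2 < min_dist2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue

        # writhe change: only moved-vs-static pairs change under the rigid
        # rotation (moved-moved and static-static pair contributions invariant)
        d_omega = 0.0
        for ms in range(span):
            s_idx = (i + ms) % n
            if ms == 0:
                ax1, ay1, az1 = v[i, 0], v[i, 1], v[i, 2]
            else:
                ax1, ay1, az1 = new[ms - 1, 0], new[ms - 1, 1], new[ms - 1, 2]
            if ms == span - 1:
                bx1, by1, bz1 = v[j, 0], v[j, 1], v[j, 2]
            else:
                bx1, by1, bz1 = new[ms, 0], new[ms, 1], new[ms, 2]
            ox1, oy1, oz1 = v[s_idx, 0], v[s_idx, 1], v[s_idx, 2]
            s2 = (s_idx + 1) % n
            ox2, oy2, oz2 = v[s2, 0], v[s2, 1], v[s2, 2]
            for t_off in range(span, n):
                t_idx = (i + t_off) % n
                if _segments_adjacent(s_idx, t_idx, n):
                    continue
                t2 = (t_idx + 1) % n
                d_omega += pair_omega(
                    ax1, ay1, az1, bx1, by1, bz1,
                    v[t_idx, 0], v[t_idx, 1], v[t_idx, 2],
                    v[t2, 0], v[t2, 1], v[t2, 2])
                d_omega -= pair_omega(
                    ox1, oy1, oz1, ox2, oy2, oz2,
                    v[t_idx, 0], v[t_idx, 1], v[t_idx, 2],
                    v[t2, 0], v[t2, 1], v[t2, 2])
        d_wr = d_omega / (2.0 * math.pi)
        if abs(d_wr) > max_dwr:
            continue  # likely strand passage; Lk would not be conserved

        dtw_old = d_lk - wr
        dtw_new = d_lk - (wr + d_wr)
        de = de_bend + c_tw * (dtw_new * dtw_new - dtw_old * dtw_old)
        if de <= 0.0 or rand[step, 3] < math.exp(-de):
            for k in range(nrot):
                idx = (i + 1 + k) % n
                v[idx, 0] = new[k, 0]
                v[idx, 1] = new[k, 1]
                v[idx, 2] = new[k, 2]
            wr += d_wr
            acc += 1
    return wr, acc
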