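"""Numba kernel for the twistable worm-like-chain Monte Carlo.

The whole Metropolis loop runs compiled.  Moves:

* twist transfer -- move a Gaussian twist quantum between two random
  junctions (conserves total twist exactly, no geometry change); this is
  the fast torsional degree of freedom that lets twist stress diffuse
  along the circle.
* crankshaft -- rigid rotation of a sub-arc about the chord through its
  anchor beads.  Small arcs relax locally; occasional large arcs (up to
  half the circle) provide the collective buckling that converts twist
  into writhe.  The writhe change is computed exactly from the polygonal
  Gauss sum over (moved x unmoved) segment pairs -- pairs rotated together
  contribute unchanged -- and the twist increments of the rotated arc are
  shifted uniformly by -2*pi*dWr/m so Lk = Tw + Wr is invariant.
* single-bead displacement -- local roughening, accepted only while the
  two touched bonds stay within tolerance of the rise.

Excluded volume (hard core between beads at circular separation >= ev_sep)
is checked for moved beads at the half-way and full rotation angle, which
vetoes strand passage at these amplitudes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._geometry import _pair_solid_angle_idx

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def _seg_pair_sum_delta(old_c, new_c, n, lo, m):
    """Sum over (arc segment, outside segment) pairs of the Gauss
    contribution, new minus old.  Arc segments are lo..lo+m-1 (mod n)."""
    delta = 0.0
    for a in range(m):
        i = (lo + a) % n
        i2 = (i + 1) % n
        for j in range(n):
            # skip arc segments and pairs sharing a vertex
            da = (j - lo) % n
            if da < m:
                continue
            d = abs(i - j)
            if d > n - d:
                d = n - d
            if d < 2:
                continue
            j2 = (j + 1) % n
            delta += (_pair_solid_angle_idx(new_c, i, i2, new_c, j, j2)
                      - _pair_solid_angle_idx(old_c, i, i2, old_c, j, j2))
    return 2.0 * delta


@njit(cache=True, fastmath=True)
def _ev_ok(centers, n, first_moved, n_moved, ev_sep, ev_diam2):
    """Hard-core check of moved beads (first_moved..+n_moved-1 mod n)
    against beads at circular separation >= ev_sep."""
    for a in range(n_moved):
        i = (first_moved + a) % n
        for j in range(n):
            db = (j - first_moved) % n
            if db < n_moved and db >= a:
                continue  # moved-moved pairs once; also skips j == i
            d = abs(i - j)
            if d > n - d:
                d = n - d
            if d < ev_sep:
                continue
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            if dx * dx + dy * dy + dz * dz < ev_diam2:
                return False
    return True


@njit(cache=True)
def _bend_at(centers, n, k, kappa):
    p0 = centers[(k - 1) % n]
    p1 = centers[k % n]
    p2 = centers[(k + 1) % n]
    ax = p1[0] - p0[0]
    ay = p1[1] - p0[1]
    az = p1[2] - p0[2]
    bx = p2[0] - p1[0]
    by = p2[1] - p1[1]
    bz = p2[2] - p1[2]
    na = np.sqrt(ax * ax + ay * ay + az * az)
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    c = (ax * bx + ay * by + az * bz) / (na * nb)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return kappa * (1.0 - c)


@njit(cache=True)
def _rotate_arc(centers, out, n, lo, m, axis_x, axis_y, axis_z, angle):
    """Rotate beads lo+1..lo+m-1 (mod n) about the axis through bead lo."""
    c = np.cos(angle)
    s = np.sin(angle)
    C = 1.0 - c
    ox = centers[lo % n, 0]
    oy = centers[lo % n, 1]
    oz = centers[lo % n, 2]
    r00 = c + axis_x * axis_x * C
    r01 = axis_x * axis_y * C - axis_z * s
    r02 = axis_x * axis_z * C + axis_y * s
    r10 = axis_y * axis_x * C + axis_z * s
    r11 = c + axis_y * axis_y * C
    r12 = axis_y * axis_z * C - axis_x * s
    r20 = axis_z * axis_x * C - axis_y * s
    r21 = axis_z * axis_y * C + axis_x * s
    r22 = c + axis_z * axis_z * C
    for a in range(1, m):
        i = (lo + a) % n
        x = centers[i, 0] - ox
        y = centers[i, 1] - oy
        z = centers[i, 2] - oz
        out[i, 0] = ox + r00 * x + r01 * y + r02 * z
        out[i, 1] = oy + r10 * x + r11 * y + r12 * z
        out[i, 2] = oz + r20 * x + r21 * y + r22 * z


@njit(cache=True)
def run_mc(centers, twist, n_steps, frame_interval,
           frames_out, twists_out,
           kappa, ct, phi0, ev_sep, ev_diam,
           crank_amp, large_arc_prob, max_arc, disp_amp, rise, bond_tol,
           twist_move_prob, disp_move_prob, twist_quantum, seed):
    """Run the Metropolis loop in place; record frames every
    ``frame_interval`` accepted-or-rejected steps.  Returns
    (n_accept, n_attempt, n_accept_first, n_attempt_first) with the
    *_first counters covering the initial 2000 steps."""
    np.random.seed(seed)
    n = centers.shape[0]
    ev_diam2 = ev_diam * ev_diam
    scratch = centers.copy()
    n_accept = 0
    n_attempt = 0
    n_accept_first = 0
    n_attempt_first = 0
    frame_idx = 0
    lo_bond = rise * (1.0 - bond_tol)
    hi_bond = rise * (1.0 + bond_tol)

    for step in range(1, n_steps + 1):
        u = np.random.random()
        accepted = False
        n_attempt += 1

        if u < twist_move_prob:
            # --- twist transfer between two random junctions
            j1 = np.random.randint(0, n)
            j2 = np.random.randint(0, n)
            if j1 != j2:
                dq = np.random.normal(0.0, twist_quantum)
                t1 = twist[j1]
                t2 = twist[j2]
                d_e = ct * (((t1 - dq - phi0) ** 2 + (t2 + dq - phi0) ** 2)
                            - ((t1 - phi0) ** 2 + (t2 - phi0) ** 2))
                if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                    twist[j1] = t1 - dq
                    twist[j2] = t2 + dq
                    accepted = True
        elif u < twist_move_prob + disp_move_prob:
            # --- single-bead displacement
            k = np.random.randint(0, n)
            dx = np.random.normal(0.0, disp_amp)
            dy = np.random.normal(0.0, disp_amp)
            dz = np.random.normal(0.0, disp_amp)
            scratch[k, 0] = centers[k, 0] + dx
            scratch[k, 1] = centers[k, 1] + dy
            scratch[k, 2] = centers[k, 2] + dz
            ok = True
            for nb in ((k - 1) % n, (k + 1) % n):
                bx = scratch[k, 0] - centers[nb, 0]
                by = scratch[k, 1] - centers[nb, 1]
                bz = scratch[k, 2] - centers[nb, 2]
                ln = np.sqrt(bx * bx + by * by + bz * bz)
                if ln < lo_bond or ln > hi_bond:
                    ok = False
            if ok:
                ok = _ev_ok(scratch, n, k, 1, ev_sep, ev_diam2)
            if ok:
                d_wr = _seg_pair_sum_delta(centers, scratch, n,
                                           (k - 1) % n, 2)
                jm1 = (k - 1) % n
                dtw = TWO_PI * d_wr / 2.0
                old_e = (_bend_at(centers, n, k - 1, kappa)
                         + _bend_at(centers, n, k, kappa)
                         + _bend_at(centers, n, k + 1, kappa)
                         + ct * ((twist[jm1] - phi0) ** 2
                                 + (twist[k] - phi0) ** 2))
                new_e = (_bend_at(scratch, n, k - 1, kappa)
                         + _bend_at(scratch, n, k, kappa)
                         + _bend_at(scratch, n, k + 1, kappa)
                         + ct * ((twist[jm1] - dtw - phi0) ** 2
                                 + (twist[k] - dtw - phi0) ** 2))
                d_e = new_e - old_e
                if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                    centers[k, 0] = scratch[k, 0]
                    centers[k, 1] = scratch[k, 1]
                    centers[k, 2] = scratch[k, 2]
                    twist[jm1] -= dtw
                    twist[k] -= dtw
                    accepted = True
            if not accepted:
                scratch[k, 0] = centers[k, 0]
                scratch[k, 1] = centers[k, 1]
                scratch[k, 2] = centers[k, 2]
        else:
            # --- crankshaft rotation of an arc
            if np.random.random() < large_arc_prob:
                m = np.random.randint(max_arc, n // 2 + 1)
            else:
                m = np.random.randint(3, max_arc + 1)
            lo = np.random.randint(0, n)
            hi = (lo + m) % n
            ax = centers[hi, 0] - centers[lo, 0]
            ay = centers[hi, 1] - centers[lo, 1]
            az = centers[hi, 2] - centers[lo, 2]
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            if norm > 1e-9:
                ax /= norm
                ay /= norm
                az /= norm
                angle = (np.random.random() * 2.0 - 1.0) * crank_amp
                ok = True
                # half-way and full-angle excluded-volume checks
                _rotate_arc(centers, scratch, n, lo, m, ax, ay, az, 0.5 * angle)
                if not _ev_ok(scratch, n, (lo + 1) % n, m - 1, ev_sep, ev_diam2):
                    ok = False
                if ok:
                    _rotate_arc(centers, scratch, n, lo, m, ax, ay, az, angle)
                    if not _ev_ok(scratch, n, (lo + 1) % n, m - 1,
                                  ev_sep, ev_diam2):
                        ok = False
                if ok:
                    d_wr = _seg_pair_sum_delta(centers, scratch, n, lo, m)
                    dtw = TWO_PI * d_wr / m
                    old_e = (_bend_at(centers, n, lo, kappa)
                             + _bend_at(centers, n, hi, kappa))
                    new_e = (_bend_at(scratch, n, lo, kappa)
                             + _bend_at(scratch, n, hi, kappa))
                    for a in range(m):
                        j = (lo + a) % n
                        t = twist[j]
                        old_e += ct * (t - phi0) ** 2
                        new_e += ct * (t - dtw - phi0) ** 2
                    d_e = new_e - old_e
                    if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                        for a in range(1, m):
                            j = (lo + a) % n
                            centers[j, 0] = scratch[j, 0]
                            centers[j, 1] = scratch[j, 1]
                            centers[j, 2] = scratch[j, 2]
                        for a in range(m):
                            j = (lo + a) % n
                            twist[j] -= dtw
                        accepted = True
                # restore scratch to current coordinates
                for a in range(1, m):
                    j = (lo + a) % n
                    scratch[j, 0] = centers[j, 0]
                    scratch[j, 1] = centers[j, 1]
                    scratch[j, 2] = centers[j, 2]

        if accepted:
            n_accept += 1
        if step <= 2000:
            n_attempt_first += 1
            if accepted:
                n_accept_first += 1
        if frame_interval > 0 and step % frame_interval == 0:
            if frame_idx < frames_out.shape[0]:
                for i in range(n):
                    frames_out[frame_idx, i, 0] = centers[i, 0]
                    frames_out[frame_idx, i, 1] = centers[i, 1]
                    frames_out[frame_idx, i, 2] = centers[i, 2]
                    twists_out[frame_idx, i] = twist[i]
                frame_idx += 1

    return n_accept, n_attempt, n_accept_first, n_attempt_first
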