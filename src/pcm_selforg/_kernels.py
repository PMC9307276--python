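"""Compiled per-step kernels for the simulation engine.

These functions implement the inner loops of one time step over the
structure-of-arrays world state (see :mod:`pcm_selforg.engine`).  They are
deliberately free of Python objects so numba can compile them; all
randomness is passed in as pre-drawn arrays so the caller's single generator
stays the only source of stochasticity.

The physical laws duplicated here in loop form (point–segment distance,
linear force–velocity, slip-bond unbinding, harmonic confinement/sterics,
linearized bending, length projection) are the same ones exposed per-object
in :mod:`mechanics`, :mod:`filaments` and :mod:`motors`; the test suite
cross-checks the two paths against each other.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F_GROW_STATE, F_SHRINK_STATE, F_CAP_STATE = 0, 1, 2


@njit(cache=True)
def bind_motors(u, bead_pos, m_host, m_off, m_species, m_bound, m_target,
                m_absc, sp_p_on, sp_range, fil_alive, fil_nv, fil_xy,
                fil_last, fil_owner, seg):
    """Binding attempts of free motor hands to the nearest in-range filament."""
    H = m_host.shape[0]
    NF = fil_alive.shape[0]
    # per-filament bounding boxes for quick rejection
    bb = np.empty((NF, 4))
    for f in range(NF):
        if not fil_alive[f]:
            continue
        n = fil_nv[f]
        xmin = xmax = fil_xy[f, 0, 0]
        ymin = ymax = fil_xy[f, 0, 1]
        for j in range(1, n):
            x = fil_xy[f, j, 0]
            y = fil_xy[f, j, 1]
            if x < xmin:
                xmin = x
            if x > xmax:
                xmax = x
            if y < ymin:
                ymin = y
            if y > ymax:
                ymax = y
        bb[f, 0] = xmin
        bb[f, 1] = xmax
        bb[f, 2] = ymin
        bb[f, 3] = ymax
    for h in range(H):
        if m_bound[h]:
            continue
        sp = m_species[h]
        if u[h] >= sp_p_on[sp]:
            continue
        rng_ = sp_range[sp]
        ax = bead_pos[m_host[h], 0] + m_off[h, 0]
        ay = bead_pos[m_host[h], 1] + m_off[h, 1]
        best_d2 = rng_ * rng_
        best_f = -1
        best_s = 0.0
        for f in range(NF):
            if not fil_alive[f] or fil_owner[f] == m_host[h]:
                continue
            if (ax < bb[f, 0] - rng_ or ax > bb[f, 1] + rng_
                    or ay < bb[f, 2] - rng_ or ay > bb[f, 3] + rng_):
                continue
            n = fil_nv[f]
            for j in range(n - 1):
                px = fil_xy[f, j, 0]
                py = fil_xy[f, j, 1]
                qx = fil_xy[f, j + 1, 0]
                qy = fil_xy[f, j + 1, 1]
                dx = qx - px
                dy = qy - py
                L2 = dx * dx + dy * dy
                if L2 < 1e-24:
                    t = 0.0
                else:
                    t = ((ax - px) * dx + (ay - py) * dy) / L2
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                ex = ax - (px + t * dx)
                ey = ay - (py + t * dy)
                d2 = ex * ex + ey * ey
                if d2 < best_d2:
                    best_d2 = d2
                    best_f = f
                    rest = fil_last[f] if j == n - 2 else seg
                    best_s = j * seg + t * rest
        if best_f >= 0:
            m_bound[h] = True
            m_target[h] = best_f
            m_absc[h] = best_s


@njit(cache=True)
def bind_adhesive(u, bead_pos, a_host, a_off, a_bound, a_target, a_absc,
                  p_on, hand_range, s_host, s_off, s_dir, stub_len,
                  s_start, s_count, bead_radius):
    """Binding attempts of free adhesive hands to the nearest foreign stub.

    Stubs are stored contiguously per host bead (``s_start``/``s_count``),
    so candidate beads are rejected with one distance check before their
    stubs are examined.
    """
    A = a_host.shape[0]
    B = s_start.shape[0]
    for h in range(A):
        if a_bound[h] or u[h] >= p_on:
            continue
        ax = bead_pos[a_host[h], 0] + a_off[h, 0]
        ay = bead_pos[a_host[h], 1] + a_off[h, 1]
        best_d2 = hand_range * hand_range
        best_s = -1
        best_t = 0.0
        for b in range(B):
            if b == a_host[h] or s_count[b] == 0:
                continue
            reach = hand_range + stub_len + bead_radius[b]
            dxb = ax - bead_pos[b, 0]
            if dxb > reach or dxb < -reach:
                continue
            dyb = ay - bead_pos[b, 1]
            if dyb > reach or dyb < -reach:
                continue
            for s in range(s_start[b], s_start[b] + s_count[b]):
                bx = bead_pos[b, 0] + s_off[s, 0]
                by = bead_pos[b, 1] + s_off[s, 1]
                t = (ax - bx) * s_dir[s, 0] + (ay - by) * s_dir[s, 1]
                if t < 0.0:
                    t = 0.0
                elif t > stub_len:
                    t = stub_len
                ex = ax - (bx + t * s_dir[s, 0])
                ey = ay - (by + t * s_dir[s, 1])
                d2 = ex * ex + ey * ey
                if d2 < best_d2:
                    best_d2 = d2
                    best_s = s
                    best_t = t
        if best_s >= 0:
            a_bound[h] = True
            a_target[h] = best_s
            a_absc[h] = best_t


@njit(cache=True)
def _fil_point(fil_xy, fil_nv, fil_last, f, s, seg):
    """Rest-abscissa -> (point, unit tangent, segment index, fraction)."""
    n = fil_nv[f]
    j = int(s / seg)
    if j > n - 2:
        j = n - 2
    if j < 0:
        j = 0
    rest = fil_last[f] if j == n - 2 else seg
    frac = (s - j * seg) / rest if rest > 1e-12 else 0.0
    if frac < 0.0:
        frac = 0.0
    elif frac > 1.0:
        frac = 1.0
    px = fil_xy[f, j, 0]
    py = fil_xy[f, j, 1]
    dx = fil_xy[f, j + 1, 0] - px
    dy = fil_xy[f, j + 1, 1] - py
    norm = np.sqrt(dx * dx + dy * dy)
    if norm < 1e-12:
        tx, ty = 1.0, 0.0
    else:
        tx, ty = dx / norm, dy / norm
    return px + frac * dx, py + frac * dy, tx, ty, j, frac


@njit(cache=True)
def update_motors(u, dt, bead_pos, m_host, m_off, m_species, m_bound,
                  m_target, m_absc, sp_v0, sp_Fs, sp_koff0, sp_Fd,
                  fil_alive, fil_nv, fil_xy, fil_last, seg, k_link):
    """Walk bound motors toward the minus end; stochastic and end unbinding."""
    H = m_host.shape[0]
    for h in range(H):
        if not m_bound[h]:
            continue
        f = m_target[h]
        rest_len = (fil_nv[f] - 2) * seg + fil_last[f]
        if not fil_alive[f] or m_absc[h] > rest_len + 1e-9:
            m_bound[h] = False
            m_target[h] = -1
            m_absc[h] = 0.0
            continue
        ax = bead_pos[m_host[h], 0] + m_off[h, 0]
        ay = bead_pos[m_host[h], 1] + m_off[h, 1]
        px, py, tx, ty, j, frac = _fil_point(fil_xy, fil_nv, fil_last, f,
                                             m_absc[h], seg)
        fx = k_link * (px - ax)  # spring force on the host bead
        fy = k_link * (py - ay)
        F_mag = np.sqrt(fx * fx + fy * fy)
        F_par = -(fx * tx + fy * ty)  # load opposing minus-end motion
        sp = m_species[h]
        v = sp_v0[sp] * (1.0 - F_par / sp_Fs[sp])
        if v < 0.0:
            v = 0.0
        elif v > sp_v0[sp]:
            v = sp_v0[sp]
        m_absc[h] -= v * dt
        if m_absc[h] <= 0.0:
            m_bound[h] = False
            m_target[h] = -1
            m_absc[h] = 0.0
            continue
        koff = sp_koff0[sp] * np.exp(F_mag / sp_Fd[sp])
        if u[h] < -np.expm1(-koff * dt):
            m_bound[h] = False
            m_target[h] = -1
            m_absc[h] = 0.0


@njit(cache=True)
def update_adhesive(u, dt, bead_pos, a_host, a_off, a_bound, a_target,
                    a_absc, koff0, Fd, s_host, s_off, s_dir, k_link):
    """Force-dependent unbinding of bound adhesive hands (no stepping)."""
    A = a_host.shape[0]
    for h in range(A):
        if not a_bound[h]:
            continue
        s = a_target[h]
        ax = bead_pos[a_host[h], 0] + a_off[h, 0]
        ay = bead_pos[a_host[h], 1] + a_off[h, 1]
        px = bead_pos[s_host[s], 0] + s_off[s, 0] + a_absc[h] * s_dir[s, 0]
        py = bead_pos[s_host[s], 1] + s_off[s, 1] + a_absc[h] * s_dir[s, 1]
        F = k_link * np.sqrt((px - ax) ** 2 + (py - ay) ** 2)
        koff = koff0 * np.exp(F / Fd)
        if u[h] < -np.expm1(-koff * dt):
            a_bound[h] = False
            a_target[h] = -1


@njit(cache=True)
def dynamic_instability(u_cat, dt, fil_alive, fil_nv, fil_xy, fil_last,
                        fil_state, fil_tip_force, p_cat, v_grow, v_shrink,
                        F_grow, L_max, L_min, seg):
    """Catastrophe sampling, load-dependent growth, shrinkage, removal."""
    NF = fil_alive.shape[0]
    for f in range(NF):
        if not fil_alive[f]:
            continue
        n = fil_nv[f]
        dx = fil_xy[f, n - 1, 0] - fil_xy[f, n - 2, 0]
        dy = fil_xy[f, n - 1, 1] - fil_xy[f, n - 2, 1]
        norm = np.sqrt(dx * dx + dy * dy)
        if norm < 1e-12:
            tx, ty = 1.0, 0.0
        else:
            tx, ty = dx / norm, dy / norm
        load = -(fil_tip_force[f, 0] * tx + fil_tip_force[f, 1] * ty)
        if load < 0.0:
            load = 0.0
        state = fil_state[f]
        if state != F_SHRINK_STATE and u_cat[f] < p_cat:
            state = F_SHRINK_STATE
        elif state == F_GROW_STATE:
            delta = v_grow * np.exp(-load / F_grow) * dt
            rest_len = (n - 2) * seg + fil_last[f]
            room = L_max - rest_len
            if delta >= room:
                delta = room if room > 0.0 else 0.0
                state = F_CAP_STATE
            fil_xy[f, n - 1, 0] += delta * tx
            fil_xy[f, n - 1, 1] += delta * ty
            fil_last[f] += delta
            while fil_last[f] > seg:
                tipx = fil_xy[f, n - 1, 0]
                tipy = fil_xy[f, n - 1, 1]
                fil_xy[f, n - 1, 0] = fil_xy[f, n - 2, 0] + seg * tx
                fil_xy[f, n - 1, 1] = fil_xy[f, n - 2, 1] + seg * ty
                fil_xy[f, n, 0] = tipx
                fil_xy[f, n, 1] = tipy
                fil_last[f] -= seg
                n += 1
                fil_nv[f] = n
        if state == F_SHRINK_STATE:
            fil_last[f] -= v_shrink * dt
            fil_xy[f, n - 1, 0] -= v_shrink * dt * tx
            fil_xy[f, n - 1, 1] -= v_shrink * dt * ty
            if fil_last[f] <= 0.0:
                if n > 2:
                    n -= 1
                    fil_nv[f] = n
                    fil_last[f] += seg
                else:
                    fil_last[f] = 1e-6
            if (n - 2) * seg + fil_last[f] <= L_min:
                fil_alive[f] = False
        fil_state[f] = state


@njit(cache=True)
def accumulate_forces(bead_F, fil_F, bead_pos, bead_radius,
                      m_host, m_off, m_bound, m_target, m_absc,
                      a_host, a_off, a_bound, a_target, a_absc,
                      s_host, s_off, s_dir,
                      site_host, site_off, site_pos,
                      fil_alive, fil_nv, fil_xy, fil_last, fil_tip_force,
                      seg, k_link, k_conf, k_steric, R,
                      f_link, f_link_bb, f_anchor, f_conf_b, f_conf_v,
                      f_steric):
    """Accumulate all explicit forces (already ETD-scaled) into bead_F/fil_F."""
    bead_F[:] = 0.0
    fil_F[:] = 0.0
    B = bead_pos.shape[0]
    # motor links
    for h in range(m_host.shape[0]):
        if not m_bound[h]:
            continue
        f = m_target[h]
        if not fil_alive[f]:
            continue
        ax = bead_pos[m_host[h], 0] + m_off[h, 0]
        ay = bead_pos[m_host[h], 1] + m_off[h, 1]
        px, py, tx, ty, j, frac = _fil_point(fil_xy, fil_nv, fil_last, f,
                                             m_absc[h], seg)
        fx = f_link * k_link * (px - ax)
        fy = f_link * k_link * (py - ay)
        bead_F[m_host[h], 0] += fx
        bead_F[m_host[h], 1] += fy
        fil_F[f, j, 0] -= fx * (1.0 - frac)
        fil_F[f, j, 1] -= fy * (1.0 - frac)
        fil_F[f, j + 1, 0] -= fx * frac
        fil_F[f, j + 1, 1] -= fy * frac
    # adhesive links
    for h in range(a_host.shape[0]):
        if not a_bound[h]:
            continue
        s = a_target[h]
        ax = bead_pos[a_host[h], 0] + a_off[h, 0]
        ay = bead_pos[a_host[h], 1] + a_off[h, 1]
        px = bead_pos[s_host[s], 0] + s_off[s, 0] + a_absc[h] * s_dir[s, 0]
        py = bead_pos[s_host[s], 1] + s_off[s, 1] + a_absc[h] * s_dir[s, 1]
        fx = f_link_bb * k_link * (px - ax)
        fy = f_link_bb * k_link * (py - ay)
        bead_F[a_host[h], 0] += fx
        bead_F[a_host[h], 1] += fy
        bead_F[s_host[s], 0] -= fx
        bead_F[s_host[s], 1] -= fy
    # minus-end anchor springs (bead-hosted sites)
    for f in range(fil_alive.shape[0]):
        if not fil_alive[f] or site_host[f] < 0:
            continue
        b = site_host[f]
        sx = bead_pos[b, 0] + site_off[f, 0]
        sy = bead_pos[b, 1] + site_off[f, 1]
        fx = f_anchor * k_link * (sx - fil_xy[f, 0, 0])
        fy = f_anchor * k_link * (sy - fil_xy[f, 0, 1])
        fil_F[f, 0, 0] += fx
        fil_F[f, 0, 1] += fy
        bead_F[b, 0] -= fx
        bead_F[b, 1] -= fy
    # confinement
    for b in range(B):
        r = np.sqrt(bead_pos[b, 0] ** 2 + bead_pos[b, 1] ** 2)
        over = r + bead_radius[b] - R
        if over > 0.0 and r > 1e-12:
            sc = -f_conf_b * k_conf * over / r
            bead_F[b, 0] += sc * bead_pos[b, 0]
            bead_F[b, 1] += sc * bead_pos[b, 1]
    for f in range(fil_alive.shape[0]):
        if not fil_alive[f]:
            continue
        for j in range(fil_nv[f]):
            r = np.sqrt(fil_xy[f, j, 0] ** 2 + fil_xy[f, j, 1] ** 2)
            over = r - R
            if over > 0.0 and r > 1e-12:
                sc = -f_conf_v * k_conf * over / r
                fil_F[f, j, 0] += sc * fil_xy[f, j, 0]
                fil_F[f, j, 1] += sc * fil_xy[f, j, 1]
    # bead-bead sterics
    for i in range(B):
        for j in range(i + 1, B):
            contact = bead_radius[i] + bead_radius[j]
            dx = bead_pos[i, 0] - bead_pos[j, 0]
            if dx > contact or dx < -contact:
                continue
            dy = bead_pos[i, 1] - bead_pos[j, 1]
            if dy > contact or dy < -contact:
                continue
            d2 = dx * dx + dy * dy
            if d2 >= contact * contact:
                continue
            d = np.sqrt(d2)
            if d < 1e-9:
                d = 1e-9
            mag = f_steric * k_steric * (contact - d) / d
            fx = mag * dx
            fy = mag * dy
            bead_F[i, 0] += fx
            bead_F[i, 1] += fy
            bead_F[j, 0] -= fx
            bead_F[j, 1] -= fy
    # record plus-end force for the next step's growth load
    for f in range(fil_alive.shape[0]):
        if fil_alive[f]:
            n = fil_nv[f]
            fil_tip_force[f, 0] = fil_F[f, n - 1, 0]
            fil_tip_force[f, 1] = fil_F[f, n - 1, 1]


@njit(cache=True)
def integrate(dt, kT, bead_pos, bead_drag, bead_F, noise_beads,
              fil_alive, fil_nv, fil_xy, fil_last, fil_F, noise_verts,
              vert_drag, bend_pad, site_host, site_pos, seg, n_project):
    """Langevin update, implicit bending, length projection, seed pinning."""
    B = bead_pos.shape[0]
    for b in range(B):
        sn = np.sqrt(2.0 * kT * dt / bead_drag[b])
        bead_pos[b, 0] += dt * bead_F[b, 0] / bead_drag[b] + sn * noise_beads[b, 0]
        bead_pos[b, 1] += dt * bead_F[b, 1] / bead_drag[b] + sn * noise_beads[b, 1]
    V = fil_xy.shape[1]
    tmp = np.empty((V, 2))
    sn = np.sqrt(2.0 * kT * dt / vert_drag)
    for f in range(fil_alive.shape[0]):
        if not fil_alive[f]:
            continue
        n = fil_nv[f]
        for j in range(n):
            tmp[j, 0] = fil_xy[f, j, 0] + dt * fil_F[f, j, 0] / vert_drag \
                + sn * noise_verts[f, j, 0]
            tmp[j, 1] = fil_xy[f, j, 1] + dt * fil_F[f, j, 1] / vert_drag \
                + sn * noise_verts[f, j, 1]
        for i in range(n):
            accx = 0.0
            accy = 0.0
            for j in range(n):
                m = bend_pad[n, i, j]
                accx += m * tmp[j, 0]
                accy += m * tmp[j, 1]
            fil_xy[f, i, 0] = accx
            fil_xy[f, i, 1] = accy
        # pairwise length projection (Gauss-Seidel sweeps)
        pinned = site_host[f] < 0
        for _ in range(n_project):
            for j in range(n - 1):
                rest = fil_last[f] if j == n - 2 else seg
                dx = fil_xy[f, j + 1, 0] - fil_xy[f, j, 0]
                dy = fil_xy[f, j + 1, 1] - fil_xy[f, j, 1]
                dist = np.sqrt(dx * dx + dy * dy)
                if dist < 1e-12:
                    continue
                corr = (dist - rest) / dist
                if j == 0 and pinned:
                    fil_xy[f, 1, 0] -= corr * dx
                    fil_xy[f, 1, 1] -= corr * dy
                else:
                    fil_xy[f, j, 0] += 0.5 * corr * dx
                    fil_xy[f, j, 1] += 0.5 * corr * dy
                    fil_xy[f, j + 1, 0] -= 0.5 * corr * dx
                    fil_xy[f, j + 1, 1] -= 0.5 * corr * dy
        if pinned:
            fil_xy[f, 0, 0] = site_pos[f, 0]
            fil_xy[f, 0, 1] = site_pos[f, 1]
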