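"""Compiled inner loop of the Euler integrator.

The kernel repeats the exact arithmetic of :func:`chiralring.dynamics.forces`
and the explicit Euler update in a single pass over flat connectivity
arrays, and returns to Python as soon as any unmasked, non-refractory bond
drops below the T1 threshold so that all topological changes are handled by
the (interpreted, well-tested) mesh engine. The pure-numpy step remains the
reference implementation; equality of the two paths is asserted in the test
suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["euler_substeps"]


@njit(cache=False)
def euler_substeps(
    pos,            # (V, 2) float64, updated in place
    eta,            # (V,) float64
    wall,           # (V,) int64: 0 bulk, 1 outer, 2 inner
    bond_v,         # (B, 2) int64
    bond_f,         # (B,) float64
    bond_delta,     # (B,) float64
    bond_last_t1,   # (B,) int64, in integrator steps
    candidate,      # (B,) bool: bond may trigger a T1 exit
    loop_v,         # (L,) int64
    loop_next,      # (L,) int64
    loop_prev,      # (L,) int64
    loop_cell,      # (L,) int64
    n_cells,        # int
    k_a, k_p, a0, l0, gamma_c, theta0, k_out, k_in, r_out, r_in,
    fluctuation,    # bool
    t0,             # float: time at entry
    dt,             # float
    step0,          # int: integrator step count at entry
    n_steps,        # int: how many substeps to attempt
    epsilon,        # float T1 threshold
    refractory,     # int, in integrator steps
):
    """Run up to ``n_steps`` Euler steps; exit early on a T1 trigger.

    Returns ``(done, trigger_bond)`` where ``trigger_bond`` is -1 when all
    steps completed without a junction crossing the threshold.
    """
    n_v = pos.shape[0]
    n_b = bond_v.shape[0]
    n_l = loop_v.shape[0]
    area = np.empty(n_cells)
    perim = np.empty(n_cells)
    elen = np.empty(n_l)
    fx = np.empty(n_v)
    fy = np.empty(n_v)
    two_pi = 2.0 * math.pi

    for it in range(n_steps):
        t = t0 + it * dt
        for c in range(n_cells):
            area[c] = 0.0
            perim[c] = 0.0
        for i in range(n_v):
            fx[i] = 0.0
            fy[i] = 0.0
        for s in range(n_l):
            i = loop_v[s]
            j = loop_v[loop_next[s]]
            cr = pos[i, 0] * pos[j, 1] - pos[j, 0] * pos[i, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            e = math.sqrt(dx * dx + dy * dy)
            elen[s] = e
            c = loop_cell[s]
            area[c] += 0.5 * cr
            perim[c] += e
        for s in range(n_l):
            i = loop_v[s]
            sp = loop_prev[s]
            pv = loop_v[sp]
            nv = loop_v[loop_next[s]]
            c = loop_cell[s]
            ca = -(k_a / a0) * (area[c] / a0 - 1.0)
            fx[i] += ca * 0.5 * (pos[nv, 1] - pos[pv, 1])
            fy[i] += ca * 0.5 * (pos[pv, 0] - pos[nv, 0])
            cp = -(k_p / l0) * (perim[c] - l0)
            ep = elen[sp]
            en = elen[s]
            fx[i] += cp * ((pos[i, 0] - pos[pv, 0]) / ep + (pos[i, 0] - pos[nv, 0]) / en)
            fy[i] += cp * ((pos[i, 1] - pos[pv, 1]) / ep + (pos[i, 1] - pos[nv, 1]) / en)
        for b in range(n_b):
            k = bond_v[b, 0]
            l = bond_v[b, 1]
            dx = pos[l, 0] - pos[k, 0]
            dy = pos[l, 1] - pos[k, 1]
            bl = math.sqrt(dx * dx + dy * dy)
            mx = 0.5 * (pos[k, 0] + pos[l, 0])
            my = 0.5 * (pos[k, 1] + pos[l, 1])
            # orientation clockwise from the local outward radius
            theta = math.atan2(dx, dy) - math.atan2(mx, my)
            cth = math.cos(theta - theta0)
            g = gamma_c * cth * cth
            if fluctuation:
                cf = math.cos(0.5 * two_pi * bond_f[b] * t + bond_delta[b])
                g *= cf * cf
            ux = g * dx / bl
            uy = g * dy / bl
            fx[k] += ux
            fy[k] += uy
            fx[l] -= ux
            fy[l] -= uy
        for i in range(n_v):
            w = wall[i]
            if w != 0:
                r = math.sqrt(pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1])
                if w == 1:
                    cw = -k_out * (r - r_out) / r
                else:
                    cw = -k_in * (r - r_in) / r
                fx[i] += cw * pos[i, 0]
                fy[i] += cw * pos[i, 1]
        for i in range(n_v):
            pos[i, 0] += dt * fx[i] / eta[i]
            pos[i, 1] += dt * fy[i] / eta[i]

        step = step0 + it + 1
        trigger = -1
        shortest = epsilon
        for b in range(n_b):
            if not candidate[b]:
                continue
            if step - bond_last_t1[b] <= refractory:
                continue
            k = bond_v[b, 0]
            l = bond_v[b, 1]
            dx = pos[l, 0] - pos[k, 0]
            dy = pos[l, 1] - pos[k, 1]
            bl = math.sqrt(dx * dx + dy * dy)
            if bl < shortest:
                shortest = bl
                trigger = b
        if trigger >= 0:
            return it + 1, trigger
    return n_steps, -1
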