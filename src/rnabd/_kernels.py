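"""Numba-compiled inner loops for force evaluation and free-draining BD.

Everything here works in internal units (Angstrom, ps, kBT) on plain
arrays; the object layer lives in :mod:`rnabd.forcefield` and
:mod:`rnabd.bd`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def accumulate_forces(coords, si, sj, s_le, s_H, nbi, nbj, eps_lj, sigma_lj,
                      rc2, eshift, forces):
    """Spring + Lennard-Jones forces; returns total potential energy (kBT).

    ``rc2 <= 0`` means the full (untruncated) LJ; otherwise pairs beyond
    ``sqrt(rc2)`` are skipped and ``eshift`` (the LJ value at the cutoff)
    is subtracted so the truncated potential is continuous.
    """
    n = coords.shape[0]
    for k in range(n):
        forces[k, 0] = 0.0
        forces[k, 1] = 0.0
        forces[k, 2] = 0.0
    energy = 0.0
    for s in range(si.shape[0]):
        i = si[s]
        j = sj[s]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = r - s_le[s]
        energy += 0.5 * s_H[s] * dl * dl
        f = -s_H[s] * dl / r  # force on j along +d, on i along -d
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    sig2 = sigma_lj * sigma_lj
    four_eps = 4.0 * eps_lj
    for p in range(nbi.shape[0]):
        i = nbi[p]
        j = nbj[p]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if rc2 > 0.0 and r2 > rc2:
            continue
        inv_r2 = 1.0 / r2
        inv = sig2 * inv_r2
        s6 = inv * inv * inv
        s12 = s6 * s6
        energy += four_eps * (s12 - s6) - eshift
        f = 6.0 * four_eps * (2.0 * s12 - s6) * inv_r2  # dV/dr * (-1/r)
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    return energy


@njit(cache=True, fastmath=True)
def bd_nohi_chunk(coords, si, sj, s_le, s_H, nbi, nbj, eps_lj, sigma_lj,
                  rc2, eshift, drift, noise, step0, snapshot_every, snaps, isnap0):
    """One chunk of free-draining Ermak-McCammon steps.

    ``noise`` holds the pre-scaled Gaussian displacements (variance
    ``2 D0 dt`` per coordinate) for each step of the chunk; the drift is
    ``(D0 dt / kBT) F``.  Snapshots (state after the step) are written when
    the global step index hits a multiple of ``snapshot_every``.  Returns
    ``(bad_step, next_snapshot_slot)`` where ``bad_step`` is the first step
    at which a spring exceeded 3 l_e, or -1.
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    isnap = isnap0
    for t in range(noise.shape[0]):
        accumulate_forces(coords, si, sj, s_le, s_H, nbi, nbj,
                          eps_lj, sigma_lj, rc2, eshift, forces)
        for k in range(n):
            coords[k, 0] += drift * forces[k, 0] + noise[t, k, 0]
            coords[k, 1] += drift * forces[k, 1] + noise[t, k, 1]
            coords[k, 2] += drift * forces[k, 2] + noise[t, k, 2]
        gstep = step0 + t + 1
        if snapshot_every > 0 and gstep % snapshot_every == 0:
            for s in range(si.shape[0]):
                i = si[s]
                j = sj[s]
                dx = coords[j, 0] - coords[i, 0]
                dy = coords[j, 1] - coords[i, 1]
                dz = coords[j, 2] - coords[i, 2]
                if dx * dx + dy * dy + dz * dz > 9.0 * s_le[s] * s_le[s]:
                    return gstep, isnap
            if isnap < snaps.shape[0]:
                for k in range(n):
                    snaps[isnap, k, 0] = coords[k, 0]
                    snaps[isnap, k, 1] = coords[k, 1]
                    snaps[isnap, k, 2] = coords[k, 2]
                isnap += 1
    return -1, isnap


@njit(cache=True)
def rpy_fill(coords, sigma, d0, out):
    """Rotne-Prager-Yamakawa mobility supermatrix (3N x 3N, A^2/ps).

    Diagonal blocks are ``D0 I``; off-diagonal blocks use the far-field RPY
    form for r >= 2 sigma and the overlap-regularised form for r < 2 sigma,
    so the matrix is positive definite for every configuration with
    non-coincident beads.
    """
    n = coords.shape[0]
    for a in range(3 * n):
        for b in range(3 * n):
            out[a, b] = 0.0
    for i in range(n):
        out[3 * i, 3 * i] = d0
        out[3 * i + 1, 3 * i + 1] = d0
        out[3 * i + 2, 3 * i + 2] = d0
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r >= 2.0 * sigma:
                # D0 * (3 sigma / 4 r) [(1 + 2 sigma^2/3r^2) I + (1 - 2 sigma^2/r^2) rr]
                pre = d0 * 0.75 * sigma / r
                ciso = pre * (1.0 + 2.0 * sigma * sigma / (3.0 * r2))
                crr = pre * (1.0 - 2.0 * sigma * sigma / r2) / r2
            else:
                ciso = d0 * (1.0 - 9.0 * r / (32.0 * sigma))
                crr = d0 * (3.0 / (32.0 * sigma)) / r
            e = np.empty(3)
            e[0] = dx
            e[1] = dy
            e[2] = dz
            for a in range(3):
                for b in range(3):
                    val = crr * e[a] * e[b]
                    if a == b:
                        val += ciso
                    out[3 * i + a, 3 * j + b] = val
                    out[3 * j + a, 3 * i + b] = val
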