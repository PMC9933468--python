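"""Numba kernels for the segmented anisotropic Yukawa energy sums.

All kernels return energies WITHOUT the ``Z^2 lambda / M^2`` prefactor;
callers multiply by ``PotentialParams.prefactor``. Segment pairs beyond the
segment cutoff are dropped (the truncation rule of the model), and rod
pairs whose center separation exceeds ``1 + segment cutoff`` are skipped
wholesale.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "central_pair_energies",
    "rod_site_energy",
    "total_energy_periodic",
]


@njit(cache=True, fastmath=True, inline="always")
def _sinhc(x):
    ax = abs(x)
    if ax < 1e-4:
        x2 = x * x
        return 1.0 + x2 / 6.0 + x2 * x2 / 120.0
    return np.sinh(x) / x


@njit(cache=True, fastmath=True, inline="always")
def _pair_energy(dx, dy, dz, v1x, v1y, v1z, v2x, v2y, v2z, offs, kappa, khalf, rc_seg2):
    """Segment-truncated pair energy for rod-center separation (dx,dy,dz)."""
    M = offs.shape[0]
    u = 0.0
    for i in range(M):
        six = dx - offs[i] * v1x
        siy = dy - offs[i] * v1y
        siz = dz - offs[i] * v1z
        for j in range(M):
            sx = six + offs[j] * v2x
            sy = siy + offs[j] * v2y
            sz = siz + offs[j] * v2z
            r2 = sx * sx + sy * sy + sz * sz
            if r2 > rc_seg2 or r2 == 0.0:
                continue
            r = np.sqrt(r2)
            x1 = khalf * (v1x * sx + v1y * sy + v1z * sz) / r
            x2 = khalf * (v2x * sx + v2y * sy + v2z * sz) / r
            u += np.exp(-kappa * r) / r * _sinhc(x1) * _sinhc(x2)
    return u


@njit(cache=True, fastmath=True)
def central_pair_energies(rel_pos, orient, v0, offs, kappa, khalf, rc_seg2, rc_rod2):
    """Per-neighbor pair energies of a central rod at the origin.

    rel_pos : (N, 3) neighbor centers relative to the central rod.
    orient  : (N, 3) neighbor orientation unit vectors.
    v0      : (3,) central-rod orientation.
    Returns (N,) energies; neighbors beyond the rod cutoff get 0.
    """
    n = rel_pos.shape[0]
    out = np.zeros(n)
    for q in range(n):
        dx = rel_pos[q, 0]
        dy = rel_pos[q, 1]
        dz = rel_pos[q, 2]
        if dx * dx + dy * dy + dz * dz > rc_rod2:
            continue
        out[q] = _pair_energy(
            dx, dy, dz, v0[0], v0[1], v0[2],
            orient[q, 0], orient[q, 1], orient[q, 2],
            offs, kappa, khalf, rc_seg2,
        )
    return out


@njit(cache=True, fastmath=True)
def rod_site_energy(pos_i, v_i, i, pos, orient, box, offs, kappa, khalf, rc_seg2, rc_rod, nimg):
    """Energy of rod ``i`` held at trial state (pos_i, v_i) in a periodic box.

    Sums over all other rods and over all periodic images within the rod
    cutoff (valid for boxes smaller than twice the cutoff), plus half the
    interaction of the rod with its own images. The difference of two calls
    (new minus old state) is the exact local Metropolis energy change.
    """
    n = pos.shape[0]
    rc_rod2 = rc_rod * rc_rod
    e = 0.0
    for q in range(n):
        if q == i:
            # the rod's own images translate and rotate with it
            d0x = 0.0
            d0y = 0.0
            d0z = 0.0
            ox, oy, oz = v_i[0], v_i[1], v_i[2]
        else:
            d0x = pos[q, 0] - pos_i[0]
            d0y = pos[q, 1] - pos_i[1]
            d0z = pos[q, 2] - pos_i[2]
            ox, oy, oz = orient[q, 0], orient[q, 1], orient[q, 2]
        for ax in range(-nimg[0], nimg[0] + 1):
            dx = d0x + ax * box[0]
            for ay in range(-nimg[1], nimg[1] + 1):
                dy = d0y + ay * box[1]
                for az in range(-nimg[2], nimg[2] + 1):
                    if q == i and ax == 0 and ay == 0 and az == 0:
                        continue
                    dz = d0z + az * box[2]
                    if dx * dx + dy * dy + dz * dz > rc_rod2:
                        continue
                    w = 0.5 if q == i else 1.0
                    e += w * _pair_energy(
                        dx, dy, dz, v_i[0], v_i[1], v_i[2],
                        ox, oy, oz,
                        offs, kappa, khalf, rc_seg2,
                    )
    return e


@njit(cache=True, fastmath=True)
def total_energy_periodic(pos, orient, box, offs, kappa, khalf, rc_seg2, rc_rod, nimg):
    """Total interaction energy per periodic cell (each pair counted once)."""
    n = pos.shape[0]
    rc_rod2 = rc_rod * rc_rod
    e = 0.0
    for p in range(n):
        for q in range(p, n):
            d0x = pos[q, 0] - pos[p, 0]
            d0y = pos[q, 1] - pos[p, 1]
            d0z = pos[q, 2] - pos[p, 2]
            for ax in range(-nimg[0], nimg[0] + 1):
                dx = d0x + ax * box[0]
                for ay in range(-nimg[1], nimg[1] + 1):
                    dy = d0y + ay * box[1]
                    for az in range(-nimg[2], nimg[2] + 1):
                        if p == q and ax == 0 and ay == 0 and az == 0:
                            continue
                        dz = d0z + az * box[2]
                        if dx * dx + dy * dy + dz * dz > rc_rod2:
                            continue
                        # p<q pairs appear once here and once with the
                        # opposite image index in the (q,p) ordering that is
                        # not visited, so they carry full weight; p==q image
                        # pairs appear for both +n and -n and carry half.
                        w = 0.5 if p == q else 1.0
                        e += w * _pair_energy(
                            dx, dy, dz,
                            orient[p, 0], orient[p, 1], orient[p, 2],
                            orient[q, 0], orient[q, 1], orient[q, 2],
                            offs, kappa, khalf, rc_seg2,
                        )
    return e


def image_counts(box: np.ndarray, rc_rod: float) -> np.ndarray:
    """Number of periodic images per axis needed to cover the rod cutoff."""
    return (np.floor(rc_rod / np.asarray(box, dtype=float)).astype(np.int64) + 1)


@njit(cache=True, fastmath=True)
def build_neighbor_list(pos, box, rc_list, nimg):
    """Verlet list over rod centers including periodic image shifts.

    Returns CSR arrays (start, q_idx, shifts): for rod i the neighbor
    entries are q_idx[start[i]:start[i+1]] with absolute shift vectors
    shifts[...]; entries include the rod's own images (q == i, shift != 0).
    """
    n = pos.shape[0]
    rc2 = rc_list * rc_list
    counts = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        c = 0
        for q in range(n):
            d0x = pos[q, 0] - pos[i, 0]
            d0y = pos[q, 1] - pos[i, 1]
            d0z = pos[q, 2] - pos[i, 2]
            for ax in range(-nimg[0], nimg[0] + 1):
                dx = d0x + ax * box[0]
                for ay in range(-nimg[1], nimg[1] + 1):
                    dy = d0y + ay * box[1]
                    for az in range(-nimg[2], nimg[2] + 1):
                        if q == i and ax == 0 and ay == 0 and az == 0:
                            continue
                        dz = d0z + az * box[2]
                        if dx * dx + dy * dy + dz * dz <= rc2:
                            c += 1
        counts[i + 1] = c
    start = np.cumsum(counts)
    total = start[n]
    q_idx = np.empty(total, dtype=np.int64)
    shifts = np.empty((total, 3))
    for i in range(n):
        k = start[i]
        for q in range(n):
            d0x = pos[q, 0] - pos[i, 0]
            d0y = pos[q, 1] - pos[i, 1]
            d0z = pos[q, 2] - pos[i, 2]
            for ax in range(-nimg[0], nimg[0] + 1):
                dx = d0x + ax * box[0]
                for ay in range(-nimg[1], nimg[1] + 1):
                    dy = d0y + ay * box[1]
                    for az in range(-nimg[2], nimg[2] + 1):
                        if q == i and ax == 0 and ay == 0 and az == 0:
                            continue
                        dz = d0z + az * box[2]
                        if dx * dx + dy * dy + dz * dz <= rc2:
                            q_idx[k] = q
                            shifts[k, 0] = ax * box[0]
                            shifts[k, 1] = ay * box[1]
                            shifts[k, 2] = az * box[2]
                            k += 1
    return start, q_idx, shifts


@njit(cache=True, fastmath=True)
def rod_energy_from_list(pos_i, v_i, i, pos, orient, start, q_idx, shifts,
                         offs, kappa, khalf, rc_seg2, rc_rod2):
    """Local energy of rod i at trial state (pos_i, v_i) using its Verlet
    list (self-image entries weighted 1/2, as in :func:`rod_site_energy`)."""
    e = 0.0
    for k in range(start[i], start[i + 1]):
        q = q_idx[k]
        if q == i:
            # self-image: separation is the lattice shift itself and both
            # partners carry the trial orientation
            dx = shifts[k, 0]
            dy = shifts[k, 1]
            dz = shifts[k, 2]
            ox, oy, oz = v_i[0], v_i[1], v_i[2]
        else:
            dx = pos[q, 0] + shifts[k, 0] - pos_i[0]
            dy = pos[q, 1] + shifts[k, 1] - pos_i[1]
            dz = pos[q, 2] + shifts[k, 2] - pos_i[2]
            ox, oy, oz = orient[q, 0], orient[q, 1], orient[q, 2]
        if dx * dx + dy * dy + dz * dz > rc_rod2:
            continue
        w = 0.5 if q == i else 1.0
        e += w * _pair_energy(
            dx, dy, dz, v_i[0], v_i[1], v_i[2],
            ox, oy, oz,
            offs, kappa, khalf, rc_seg2,
        )
    return e
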