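"""Orientational order parameters and pair correlations.

The nematic (uniaxial) order parameter S is the largest eigenvalue of the
traceless symmetric tensor Q = (3 <v (x) v> - I)/2 (Maier-Saupe
normalization: S = 1 for perfect alignment, 0 for isotropy); the biaxial
order parameter B is the difference between the two subsequent eigenvalues.
Head-tail symmetry is automatic since Q is even in v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import RodConfiguration

__all__ = [
    "OrderParameters",
    "PairCorrelation",
    "q_tensor_order",
    "pair_correlation",
    "mean_tilt_deg",
    "layer_twist_deg",
]


@dataclass(frozen=True)
class OrderParameters:
    S: float
    B: float
    eigenvalues: tuple[float, float, float]  # sorted descending, sum = 0


@dataclass(frozen=True)
class PairCorrelation:
    bin_edges: np.ndarray
    g: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def q_tensor_order(orientations: np.ndarray) -> OrderParameters:
    """Uniaxial and biaxial order parameters of a set of unit vectors."""
    v = np.atleast_2d(np.asarray(orientations, dtype=float))
    if len(v) < 2:
        raise ValueError("need at least two orientation vectors")
    if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-8):
        raise ValueError("orientation vectors must be unit length")
    q = 1.5 * (v[:, :, None] * v[:, None, :]).mean(axis=0) - 0.5 * np.eye(3)
    ev = np.linalg.eigvalsh(q)[::-1]
    return OrderParameters(float(ev[0]), float(ev[1] - ev[2]), tuple(float(e) for e in ev))


def pair_correlation(
    config: RodConfiguration,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> PairCorrelation:
    """Radial distribution function over rod centers (minimum image).

    Normalized by the ideal-gas shell counts of the periodic box, so
    g -> 1 at large r for homogeneous states.
    """
    if config.box is None:
        raise ValueError("pair_correlation needs a periodic box")
    box = config.box
    half_min = float(box.min()) / 2.0
    if r_max is None:
        r_max = half_min
    if r_max > half_min + 1e-12:
        raise ValueError(f"r_max={r_max} exceeds half the smallest box edge {half_min}")
    pos = config.positions
    n = len(pos)
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    iu = np.triu_indices(n, k=1)
    r = r[iu]
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, edges = np.histogram(r, bins=edges)
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_pairs_ideal = 0.5 * n * (n - 1) * shell_vol / config.volume
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(n_pairs_ideal > 0, hist / n_pairs_ideal, 0.0)
    return PairCorrelation(edges, g)


def mean_tilt_deg(orientations: np.ndarray) -> float:
    """Mean polar (tilt) angle in degrees, folded by head-tail symmetry
    onto [0, 90]."""
    v = np.atleast_2d(np.asarray(orientations, dtype=float))
    cz = np.clip(np.abs(v[:, 2]), 0.0, 1.0)
    return float(np.degrees(np.arccos(cz)).mean())


def _slab_director(v: np.ndarray) -> np.ndarray:
    q = 1.5 * (v[:, :, None] * v[:, None, :]).mean(axis=0) - 0.5 * np.eye(3)
    w, vec = np.linalg.eigh(q)
    return vec[:, -1]


def layer_directors(config: RodConfiguration, n_layers: int) -> np.ndarray:
    """Per-layer directors (principal Q-tensor axes) of a layered state.

    Rods are clustered into ``n_layers`` z-slabs after shifting the origin
    to the widest periodic gap in the z coordinates, so a crystal whose
    layers straddle the box boundary is still sliced correctly.
    """
    if config.box is None:
        raise ValueError("layer analysis needs a periodic box")
    lz = float(config.box[2])
    z = config.positions[:, 2] % lz
    zs = np.sort(z)
    gaps = np.diff(np.concatenate([zs, [zs[0] + lz]]))
    z0 = zs[int(np.argmax(gaps))] + gaps.max() / 2.0
    idx = np.minimum((((z - z0) % lz) / lz * n_layers).astype(int), n_layers - 1)
    dirs = []
    for k in range(n_layers):
        v = config.orientations[idx == k]
        if len(v) < 2:
            raise ValueError(f"layer {k} has fewer than 2 rods")
        dirs.append(_slab_director(v))
    return np.array(dirs)


def layer_twist_deg(config: RodConfiguration, n_layers: int) -> float:
    """Twist angle per layer of the best-fitting heliconical field.

    Layer directors are headless, so azimuth steps alone cannot separate a
    cholesteric twist of 60 deg from a heliconical twist of 120 deg (whose
    orientation VECTORS alternate the sign of v_z between layers). Instead
    the measured directors are fitted, as axes, against ideal heliconical
    fields v_k = (sin phi cos(psi0 + k*theta1), sin phi sin(psi0 + k*theta1),
    cos phi) over a grid of (theta1, psi0), using the measured mean tilt;
    the returned theta1 in [0, 180] minimizes the axis misalignment, with
    the two mirror chiralities (theta1 and 360 - theta1), degenerate for
    achiral rods, folded together.
    """
    dirs = layer_directors(config, n_layers)
    phi = math.radians(mean_tilt_deg(config.orientations))
    sp, cp = math.sin(phi), math.cos(phi)
    best = (math.inf, 0.0)
    for theta1 in np.arange(0.0, 360.0, 1.0):
        for psi0 in np.arange(0.0, 360.0, 5.0):
            psi = np.radians(psi0 + theta1 * np.arange(n_layers))
            ideal = np.column_stack([sp * np.cos(psi), sp * np.sin(psi), np.full(n_layers, cp)])
            err = float(np.sum(1.0 - np.abs(np.einsum("ij,ij->i", ideal, dirs))))
            if err < best[0]:
                best = (err, float(theta1))
    t = best[1]
    return min(t, 360.0 - t) if t > 0 else 0.0
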