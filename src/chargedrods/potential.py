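"""Segment-segment and rod-rod interaction energies.

A rod of length ``a`` (the internal length unit) carrying ``Z`` effective
elementary charges is discretized into ``M`` collinear segments of length
``a/M``, each carrying a charge ``Z/M``. Two segments interact through the
far-field linearized Poisson-Boltzmann (Debye-Hueckel) potential of two
uniformly charged line segments,

    beta*u_ij = (Z/M)^2 * lambda * exp(-kappa r_ij)/r_ij
                * sigma(x_i) * sigma(x_j),

with ``sigma(x) = sinh(x)/x`` and ``x_k = (kappa a / 2M) (v_k . r_hat_ij)``,
where ``r_ij`` is the center-to-center separation of the two segments,
``v_k`` the orientation unit vector of the parent rod and ``lambda`` the
energy length scale (the Bjerrum length for energies in units of k_B T).
The form is valid in the far field, i.e. for separations large compared to
both the screening length and the segment length; the anisotropy factors are
even in ``x``, so all energies respect rod head-tail symmetry, and the
interaction is purely repulsive.

All lengths are reduced by the rod length ``a``; the inverse screening
length enters as ``kappa_star = kappa*a``. Energies are reported in units of
``Z^2 lambda / a``, i.e. as ``beta*u * a / (Z^2 l_B)`` when ``lambda`` is
the Bjerrum length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PotentialParams",
    "SegmentPair",
    "segment_offsets",
    "segment_pair_energy",
    "rod_pair_energy",
    "truncation_radii",
    "sinhc",
]


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the segmented anisotropic Yukawa rod model.

    Parameters
    ----------
    kappa_star : float
        Reduced inverse screening length ``kappa * a`` (> 0).
    M : int
        Number of segments per rod (>= 1); segment charge is ``Z/M`` and
        segment length ``1/M`` in reduced units.
    Z : float
        Total valency per rod. Energies carry a ``Z**2`` prefactor; the
        default ``Z = 1`` together with ``lambda_ref = 1`` yields energies
        in the reduced unit ``Z^2 l_B / a``.
    lambda_ref : float
        Energy length scale ``lambda`` in units of the rod length
        (``l_B / a`` for energies in k_B T).
    n_trunc : int
        Truncation integer of the cutoff rule (>= 1).
    a_nm : float
        Physical rod length in nm, kept as metadata only; all internal
        lengths are reduced by ``a``.
    """

    kappa_star: float
    M: int = 15
    Z: float = 1.0
    lambda_ref: float = 1.0
    n_trunc: int = 10
    a_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_star <= 0:
            raise ValueError(f"kappa_star must be > 0, got {self.kappa_star}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.n_trunc < 1:
            raise ValueError(f"n_trunc must be >= 1, got {self.n_trunc}")
        if self.lambda_ref <= 0 or self.a_nm <= 0:
            raise ValueError("lambda_ref and a_nm must be positive")

    @property
    def segment_charge(self) -> float:
        return self.Z / self.M

    @property
    def segment_length(self) -> float:
        return 1.0 / self.M

    @property
    def prefactor(self) -> float:
        """Overall energy prefactor ``Z^2 lambda / M^2`` (reduced units)."""
        return self.Z**2 * self.lambda_ref / self.M**2

    @property
    def kappa_half_segment(self) -> float:
        """Anisotropy-factor scale ``kappa* * (a/M) / 2``."""
        return 0.5 * self.kappa_star / self.M


@dataclass(frozen=True)
class SegmentPair:
    """Geometry of one segment-segment pair.

    ``r_ij`` is the center-to-center separation vector from segment *i* to
    segment *j*; ``v_i``/``v_j`` are the parent rods' orientation unit
    vectors.
    """

    r_ij: np.ndarray
    v_i: np.ndarray
    v_j: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_ij, dtype=float)
        if np.linalg.norm(r) == 0.0:
            raise ValueError("segment pair at zero separation")
        for name, v in (("v_i", self.v_i), ("v_j", self.v_j)):
            if abs(np.linalg.norm(np.asarray(v, dtype=float)) - 1.0) > 1e-8:
                raise ValueError(f"{name} is not a unit vector")


def sinhc(x: float) -> float:
    """``sinh(x)/x``, even in x, with a stable small-argument expansion."""
    ax = abs(x)
    if ax < 1e-4:
        x2 = x * x
        return 1.0 + x2 / 6.0 + x2 * x2 / 120.0
    return math.sinh(x) / x


def segment_offsets(M: int) -> np.ndarray:
    """Segment-center offsets along the rod axis.

    M equidistant centers with spacing ``1/M``, symmetric about the rod
    center: ``(k - (M+1)/2)/M`` for k = 1..M. The outermost centers sit at
    ``+-(M-1)/(2M)``, i.e. half a segment length inside the rod ends.
    """
    k = np.arange(1, M + 1, dtype=float)
    return (k - (M + 1) / 2.0) / M


def segment_pair_energy(pair: SegmentPair, params: PotentialParams) -> float:
    """Reduced interaction energy of a single segment pair.

    Strictly positive, decays as ``exp(-kappa r)`` and is invariant under
    the head-tail flip of either rod and under the exchange
    ``(i, j, r) -> (j, i, -r)``.
    """
    r_vec = np.asarray(pair.r_ij, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError("segment pair at zero separation")
    rhat = r_vec / r
    kh = params.kappa_half_segment
    x_i = kh * float(np.dot(np.asarray(pair.v_i, dtype=float), rhat))
    x_j = kh * float(np.dot(np.asarray(pair.v_j, dtype=float), rhat))
    return params.prefactor * math.exp(-params.kappa_star * r) / r * sinhc(x_i) * sinhc(x_j)


def rod_pair_energy(
    pos_p: np.ndarray,
    v_p: np.ndarray,
    pos_q: np.ndarray,
    v_q: np.ndarray,
    params: PotentialParams,
) -> float:
    """Total (untruncated) interaction energy between two rods.

    The double sum of :func:`segment_pair_energy` over all ``M x M`` segment
    pairs; rod self-energies are excluded by construction. Raises if any
    segment pair coincides.
    """
    pos_p = np.asarray(pos_p, dtype=float)
    pos_q = np.asarray(pos_q, dtype=float)
    v_p = np.asarray(v_p, dtype=float)
    v_q = np.asarray(v_q, dtype=float)
    offs = segment_offsets(params.M)
    seg_p = pos_p[None, :] + offs[:, None] * v_p[None, :]
    seg_q = pos_q[None, :] + offs[:, None] * v_q[None, :]
    d = seg_q[None, :, :] - seg_p[:, None, :]  # (M, M, 3)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    if np.any(r == 0.0):
        raise ValueError("coincident segments between the two rods")
    rhat = d / r[:, :, None]
    kh = params.kappa_half_segment
    x_p = kh * np.einsum("k,ijk->ij", v_p, rhat)
    x_q = kh * np.einsum("k,ijk->ij", v_q, rhat)
    u = np.exp(-params.kappa_star * r) / r * _sinhc_arr(x_p) * _sinhc_arr(x_q)
    return params.prefactor * float(u.sum())


def _sinhc_arr(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = 1.0 + xs * xs / 6.0
    xl = x[~small]
    out[~small] = np.sinh(xl) / xl
    return out


def truncation_radii(params: PotentialParams, rho_star: float) -> tuple[float, float]:
    """Segment- and rod-level cutoff distances.

    The segment-segment potential is truncated at
    ``n_trunc/kappa* + 1.5 (rho*)^(-1/3)``; rod pairs whose centers are
    farther apart than ``1 +`` that distance cannot contribute and are
    skipped entirely. The two terms keep enough neighbors both at long
    screening lengths and at high densities.
    """
    if rho_star <= 0:
        raise ValueError(f"rho_star must be > 0, got {rho_star}")
    segment_cutoff = params.n_trunc / params.kappa_star + 1.5 * rho_star ** (-1.0 / 3.0)
    return segment_cutoff, 1.0 + segment_cutoff
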