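"""Stacked hexagonal crystals with heliconical orientation fields.

Crystals are built as triangular (hexagonal) layers in the xy-plane with
in-plane spacing ``l_xy*``, stacked along z with layer spacing ``l_z*``
fixed by the reduced number density ``rho* = rho a^3``:

    hexagonal layers:   l_z* = 2 / (sqrt(3) rho* l_xy*^2)
    square-based layers: l_z* = 1 / (rho* l_xy*^2)

Successive layers repeat in registry (AAA), alternate between the two
close-packing interstitial registries (ABA, hcp-like) or cycle through all
three (ABC, fcc-like). Rod orientations are uniform within a layer and
follow a heliconical field: polar (tilt) angle ``phi`` shared by all layers
and azimuth ``psi_k = theta2 + k*theta1`` for layer k, so ``theta1`` is the
twist per layer and ``theta2`` the start angle. ``phi = 0`` gives a
unidirectional (nematic-like) crystal, ``phi = 90`` with ``theta1 != 0`` a
cholesteric-like one, intermediate tilts with twist a heliconical smectic C.

Angles are degrees in all public interfaces; lengths are in units of the
rod length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STACKINGS",
    "LatticeSpec",
    "OrientationField",
    "RodConfiguration",
    "layer_orientation",
    "build_lattice",
    "build_periodic_supercell",
    "shell_distances",
]

#: registry sequence and in-plane geometry per stacking label
STACKINGS = ("AAA", "ABA", "ABC", "cubicAAA", "cubicABA")

_REGISTRY = {
    "AAA": (0,),
    "ABA": (0, 1),
    "ABC": (0, 1, 2),
    "cubicAAA": (0,),
    "cubicABA": (0, 1),
}


@dataclass(frozen=True)
class LatticeSpec:
    """A crystal lattice candidate: stacking type, spacing and density."""

    stacking: str
    l_xy_star: float
    rho_star: float
    n_stack: int = 0  # 0 = extent chosen from the interaction cutoff

    def __post_init__(self) -> None:
        if self.stacking not in STACKINGS:
            raise ValueError(f"unknown stacking {self.stacking!r}; choose from {STACKINGS}")
        if self.l_xy_star <= 0 or self.rho_star <= 0:
            raise ValueError("l_xy_star and rho_star must be positive")

    @property
    def hexagonal(self) -> bool:
        return not self.stacking.startswith("cubic")

    @property
    def l_z_star(self) -> float:
        """Layer spacing from the fixed-density constraint."""
        if self.hexagonal:
            return 2.0 / (math.sqrt(3.0) * self.rho_star * self.l_xy_star**2)
        return 1.0 / (self.rho_star * self.l_xy_star**2)

    @property
    def stacking_period(self) -> int:
        return len(_REGISTRY[self.stacking])

    def in_plane_vectors(self) -> np.ndarray:
        """Primitive in-plane lattice vectors, shape (2, 2).

        The triangular lattice is oriented with its nearest-neighbor bonds
        at 30/90/150 degrees from the x-axis, so the azimuth origin
        (psi = 0, the x-axis) points along a next-nearest-neighbor
        direction: an in-plane rod with psi = 0 faces the second-neighbor
        shell end-on (at sqrt(3) l_xy) and passes the nearest neighbors at
        a lateral offset of l_xy/2.
        """
        l = self.l_xy_star
        if self.hexagonal:
            h = 0.5 * math.sqrt(3.0) * l
            return np.array([[h, 0.5 * l], [0.0, l]])
        return np.array([[l, 0.0], [0.0, l]])

    def registry_shift(self, layer: int) -> np.ndarray:
        """In-plane shift of a layer's lattice relative to an A layer."""
        reg = _REGISTRY[self.stacking][layer % self.stacking_period]
        l = self.l_xy_star
        if self.hexagonal:
            # centroid of the (0, a1, a2) triangle
            base = np.array([l * math.sqrt(3.0) / 6.0, 0.5 * l])
        else:
            base = np.array([0.5 * l, 0.5 * l])
        return reg * base


@dataclass(frozen=True)
class OrientationField:
    """Heliconical orientation field (all angles in degrees)."""

    phi: float = 0.0
    theta1: float = 0.0
    theta2: float = 0.0

    def twist_period(self) -> int | None:
        """Number of layers after which the azimuth repeats (None if never)."""
        t = self.theta1 % 360.0
        if t == 0.0:
            return 1
        for p in range(1, 721):
            if abs((p * t) % 360.0) < 1e-9 or abs((p * t) % 360.0 - 360.0) < 1e-9:
                return p
        return None


@dataclass
class RodConfiguration:
    """Rod centers, orientation unit vectors and (optionally) a periodic box."""

    positions: np.ndarray
    orientations: np.ndarray
    box: np.ndarray | None = None
    periodic: bool = False

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
            self.orientations = self.orientations.reshape(0, 3)
        if self.positions.shape != self.orientations.shape or self.positions.shape[1] != 3:
            raise ValueError("positions and orientations must both have shape (N, 3)")
        if len(self.orientations):
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("orientation vectors must be unit length")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive edge lengths")
        if self.periodic:
            if self.box is None:
                raise ValueError("periodic configuration requires a box")
            self.positions = self.positions % self.box

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        if self.box is None:
            raise ValueError("no box defined")
        return float(np.prod(self.box))

    def copy(self) -> "RodConfiguration":
        return RodConfiguration(
            self.positions.copy(), self.orientations.copy(),
            None if self.box is None else self.box.copy(), self.periodic,
        )


def layer_orientation(k: int, fld: OrientationField) -> np.ndarray:
    """Orientation unit vector of layer ``k``:
    ``(sin phi cos psi_k, sin phi sin psi_k, cos phi)`` with
    ``psi_k = theta2 + k*theta1``."""
    phi = math.radians(fld.phi)
    psi = math.radians(fld.theta2 + k * fld.theta1)
    return np.array([math.sin(phi) * math.cos(psi), math.sin(phi) * math.sin(psi), math.cos(phi)])


def _in_plane_points(spec: LatticeSpec, radius: float) -> np.ndarray:
    """All in-plane lattice points within ``radius`` of the origin (2D)."""
    a = spec.in_plane_vectors()
    # conservative integer ranges for both hexagonal and square cells
    nmax = int(math.ceil(radius / spec.l_xy_star * 2.0)) + 2
    i = np.arange(-nmax, nmax + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pts = ii.reshape(-1, 1) * a[0] + jj.reshape(-1, 1) * a[1]
    keep = np.einsum("ij,ij->i", pts, pts) <= radius * radius
    return pts[keep]


def build_lattice(
    spec: LatticeSpec,
    fld: OrientationField,
    extent: float,
    central_env: int = 0,
) -> RodConfiguration:
    """Finite spherical cluster around a central rod at the origin.

    All rods whose centers lie within ``extent`` (the rod-level cutoff) of
    the central rod are generated, including the central rod itself (always
    the first entry, at the origin). ``central_env`` selects which layer of
    the periodic structure the central rod occupies, shifting both the
    registry sequence and the azimuth accordingly; averaging the central-rod
    energy over all distinct environments recovers the bulk energy per
    particle.
    """
    l_z = spec.l_z_star
    kmax = int(math.floor(extent / l_z)) + 1
    pos_blocks = [np.zeros((1, 3))]
    ori_blocks = [layer_orientation(central_env, fld)[None, :]]
    shift0 = spec.registry_shift(central_env)
    for k in range(-kmax, kmax + 1):
        z = k * l_z
        if abs(z) > extent:
            continue
        r_in_plane = math.sqrt(max(extent * extent - z * z, 0.0)) + 1e-9
        pts = _in_plane_points(spec, r_in_plane + spec.l_xy_star)
        shift = spec.registry_shift(central_env + k) - shift0
        xy = pts + shift
        r2 = np.einsum("ij,ij->i", xy, xy)
        keep = r2 + z * z <= extent * extent * (1 + 1e-12)
        if k == 0:
            keep &= r2 > 1e-18  # drop the central site itself
        xy = xy[keep]
        if not len(xy):
            continue
        block = np.empty((len(xy), 3))
        block[:, :2] = xy
        block[:, 2] = z
        pos_blocks.append(block)
        v = layer_orientation(central_env + k, fld)
        ori_blocks.append(np.broadcast_to(v, (len(xy), 3)))
    return RodConfiguration(np.vstack(pos_blocks), np.vstack(ori_blocks))


def build_periodic_supercell(
    spec: LatticeSpec,
    fld: OrientationField,
    n_x: int,
    n_y: int,
    n_z: int,
) -> RodConfiguration:
    """Cuboid periodic supercell commensurate with lattice and twist.

    Hexagonal layers use a rectangular two-rod cell of dimensions
    ``l_xy x sqrt(3) l_xy``; square-based layers a one-rod ``l_xy x l_xy``
    cell. ``n_z`` must be a multiple of the stacking period and, for tilted
    fields, of the twist period so orientations wrap seamlessly across the
    z boundary. The number density of the result equals ``rho*`` exactly.
    """
    if n_x < 1 or n_y < 1 or n_z < 1:
        raise ValueError("supercell repeats must be positive")
    if n_z % spec.stacking_period != 0:
        raise ValueError(
            f"n_z={n_z} incommensurate with stacking period {spec.stacking_period}"
        )
    tilted = abs(math.sin(math.radians(fld.phi))) > 1e-12
    if tilted:
        frac = (n_z * fld.theta1 / 360.0) % 1.0
        if min(frac, 1.0 - frac) > 1e-9:
            raise ValueError(
                f"n_z={n_z} incommensurate with twist angle theta1={fld.theta1}"
            )
    l = spec.l_xy_star
    l_z = spec.l_z_star
    if spec.hexagonal:
        cell = np.array([math.sqrt(3.0) * l, l])
        basis = np.array([[0.0, 0.0], [0.5 * math.sqrt(3.0) * l, 0.5 * l]])
    else:
        cell = np.array([l, l])
        basis = np.array([[0.0, 0.0]])
    box = np.array([n_x * cell[0], n_y * cell[1], n_z * l_z])
    positions = []
    orientations = []
    for k in range(n_z):
        shift = spec.registry_shift(k)
        v = layer_orientation(k, fld)
        for ix in range(n_x):
            for iy in range(n_y):
                for b in basis:
                    xy = (np.array([ix * cell[0], iy * cell[1]]) + b + shift) % box[:2]
                    positions.append([xy[0], xy[1], k * l_z])
                    orientations.append(v)
    return RodConfiguration(np.array(positions), np.array(orientations), box=box, periodic=True)


def shell_distances(spec: LatticeSpec, fld: OrientationField, extent: float, decimals: int = 9) -> np.ndarray:
    """Sorted unique center-to-center neighbor distances of the ideal lattice."""
    cfg = build_lattice(spec, fld, extent)
    d = np.linalg.norm(cfg.positions[1:], axis=1)
    return np.unique(np.round(d[d <= extent], decimals))
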