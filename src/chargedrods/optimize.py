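"""Lattice energy-per-particle evaluation and ground-state searches.

The energy per particle of a candidate crystal is the interaction energy of
one central rod with all rods inside the rod-level cutoff, averaged over
the distinct layer environments of the structure (stacking registry x
orientation twist). Because all structures are compared at equal density,
no 1/2 double-counting factor is applied; the convention is internal and
cancels in every relative quantity.

Scans over the in-plane spacing ``l_xy*`` (at fixed density, so the layer
spacing co-varies) and over the tilt angle ``phi`` (with ``l_xy*``
re-optimized at every tilt) locate primary and secondary minima and the
barriers between them. Within the studied parameter span the global
minimizer is always a unidirectional (phi = 0) close-packed stacking (ABC
or ABA); tilted AAA structures with a 120 deg twist per layer host the
heliconical local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize_scalar

from ._kernels import central_pair_energies
from .lattice import LatticeSpec, OrientationField, build_lattice
from .potential import PotentialParams, segment_offsets, truncation_radii

__all__ = [
    "EnergyBreakdown",
    "Minimum",
    "ScanResult",
    "energy_per_particle",
    "scan_lxy",
    "scan_tilt",
    "find_ground_state",
    "closest_end_separation",
    "default_lxy_bracket",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Reduced energies per particle, in units of ``Z^2 l_B / a``.

    ``u_total = u_intra + u_inter``; ``u_shell`` maps the (rounded) center
    distance of each neighbor shell to its energy contribution and
    ``u_first`` is the nearest shell's share.
    """

    u_total: float
    u_intra: float
    u_inter: float
    u_shell: dict[float, float] = dc_field(default_factory=dict)
    n_rods: int = 0

    @property
    def u_first(self) -> float:
        if not self.u_shell:
            return 0.0
        return self.u_shell[min(self.u_shell)]


@dataclass(frozen=True)
class Minimum:
    location: float
    energy: float
    classification: str  # "primary" (lowest) then "secondary", ...


@dataclass
class ScanResult:
    """A 1-D energy scan: grid, energies, refined minima and barriers."""

    param_name: str
    grid: np.ndarray
    energies: np.ndarray
    minima: list[Minimum]
    barriers: list[dict] = dc_field(default_factory=list)
    meta: dict = dc_field(default_factory=dict)

    @property
    def primary(self) -> Minimum:
        if not self.minima:
            raise ValueError("scan found no interior minimum")
        return self.minima[0]

    def minimum_near(self, x: float, max_dist: float | None = None) -> Minimum:
        """The refined minimum closest to ``x`` (optionally within max_dist)."""
        if not self.minima:
            raise ValueError("scan found no interior minimum")
        best = min(self.minima, key=lambda m: abs(m.location - x))
        if max_dist is not None and abs(best.location - x) > max_dist:
            raise ValueError(f"no minimum within {max_dist} of {x}")
        return best

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({self.param_name: self.grid, "u_total": self.energies})


def _environments(spec: LatticeSpec, fld: OrientationField) -> int:
    """Number of distinct layer environments to average over.

    A hexagonal AAA stack with a twist that is a multiple of 60 deg has a
    screw symmetry (translate one layer + rotate about the stacking axis),
    so a single environment suffices; otherwise the period is the least
    common multiple of the stacking and twist periods (capped for safety).
    """
    tilted = abs(math.sin(math.radians(fld.phi))) > 1e-12
    tw = fld.twist_period() if tilted else 1
    if tw is None:
        tw = 6
    if spec.stacking == "AAA" and (not tilted or abs(fld.theta1 % 60.0) < 1e-9):
        return 1
    return min(math.lcm(spec.stacking_period, tw), 6)


def energy_per_particle(
    spec: LatticeSpec,
    fld: OrientationField,
    params: PotentialParams,
    rho_star: float | None = None,
    shells: bool = True,
) -> EnergyBreakdown:
    """Bulk energy per particle of an ideal crystal + orientation field.

    Builds the spherical cluster of all rods within the rod cutoff of a
    central rod, sums the truncated pair interactions, and averages over
    one central rod per distinct layer environment. The intra/inter split
    assigns each partner rod by layer membership; shells are binned by the
    rounded center-to-center distance.
    """
    rho = spec.rho_star if rho_star is None else rho_star
    rc_seg, rc_rod = truncation_radii(params, rho)
    offs = segment_offsets(params.M)
    kh = params.kappa_half_segment
    n_env = _environments(spec, fld)
    tot = intra = inter = 0.0
    shell_acc: dict[float, float] = {}
    n_rods = 0
    for env in range(n_env):
        cfg = build_lattice(spec, fld, rc_rod, central_env=env)
        rel = np.ascontiguousarray(cfg.positions[1:])
        ori = np.ascontiguousarray(cfg.orientations[1:])
        v0 = np.ascontiguousarray(cfg.orientations[0])
        e = central_pair_energies(
            rel, ori, v0, offs, params.kappa_star, kh, rc_seg * rc_seg, rc_rod * rc_rod
        )
        e *= params.prefactor
        z = rel[:, 2]
        same_layer = np.abs(z) < 0.5 * spec.l_z_star
        tot += float(e.sum())
        intra += float(e[same_layer].sum())
        inter += float(e[~same_layer].sum())
        n_rods = max(n_rods, len(rel) + 1)
        if shells:
            d = np.round(np.linalg.norm(rel, axis=1), 6)
            dists, inverse = np.unique(d, return_inverse=True)
            sums = np.bincount(inverse, weights=e)
            for dist, s in zip(dists, sums):
                if s != 0.0:
                    shell_acc[float(dist)] = shell_acc.get(float(dist), 0.0) + float(s)
    tot /= n_env
    intra /= n_env
    inter /= n_env
    shell_acc = {k: v / n_env for k, v in sorted(shell_acc.items())}
    return EnergyBreakdown(tot, intra, inter, shell_acc, n_rods)


def default_lxy_bracket(rho_star: float) -> tuple[float, float]:
    """Bracket for l_xy* scans, scaled with the mean spacing rho*^(-1/3).

    Wide enough that both flanks rise (intraplane repulsion at small l_xy*,
    interplane at large l_xy* where the layers collapse onto each other).
    """
    s = rho_star ** (-1.0 / 3.0)
    return 0.35 * s, 3.3 * s


def _grid_local_minima(grid: np.ndarray, u: np.ndarray) -> list[int]:
    """Indices of strict interior local minima of a sampled curve."""
    idx = []
    for i in range(1, len(grid) - 1):
        if u[i] <= u[i - 1] and u[i] <= u[i + 1] and (u[i] < u[i - 1] or u[i] < u[i + 1]):
            # skip plateaus already claimed
            if idx and idx[-1] == i - 1 and u[i] == u[i - 1]:
                continue
            idx.append(i)
    return idx


def _classify(minima: list[tuple[float, float]]) -> list[Minimum]:
    ranked = sorted(minima, key=lambda m: m[1])
    names = ["primary", "secondary"] + [f"rank{r}" for r in range(3, len(ranked) + 1)]
    return [Minimum(loc, en, names[r]) for r, (loc, en) in enumerate(ranked)]


def scan_lxy(
    stacking: str,
    fld: OrientationField,
    params: PotentialParams,
    rho_star: float,
    bracket: tuple[float, float] | None = None,
    n_grid: int = 60,
    refine_rtol: float = 1e-4,
    keep_within_factor: float = 100.0,
) -> ScanResult:
    """Energy-per-particle curve over the in-plane spacing at fixed density.

    A coarse grid (the curves can have two minima separated by a barrier)
    followed by bounded local refinement around each interior minimum.
    Raises if no interior minimum lies within the bracket. Shallow ripples
    far up the flanks (more than ``keep_within_factor`` times the lowest
    grid energy) are not treated as competing minima.
    """
    lo, hi = bracket if bracket is not None else default_lxy_bracket(rho_star)
    grid = np.linspace(lo, hi, n_grid)

    def u_of(lxy: float) -> float:
        spec = LatticeSpec(stacking, float(lxy), rho_star)
        return energy_per_particle(spec, fld, params, shells=False).u_total

    energies = np.array([u_of(x) for x in grid])
    idxs = _grid_local_minima(grid, energies)
    u_floor = energies.min()
    idxs = [i for i in idxs if energies[i] <= keep_within_factor * u_floor]
    if not idxs:
        raise ValueError(
            f"no interior minimum of u(l_xy*) in bracket {lo:.4g}..{hi:.4g}; "
            "widen the bracket instead of extrapolating"
        )
    refined: list[tuple[float, float]] = []
    for i in idxs:
        res = minimize_scalar(
            u_of,
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": refine_rtol * grid[i]},
        )
        refined.append((float(res.x), float(res.fun)))
    minima = _classify(refined)
    barriers = []
    order = sorted(range(len(idxs)), key=lambda j: idxs[j])
    for a, b in zip(order[:-1], order[1:]):
        i0, i1 = idxs[a], idxs[b]
        u_top = float(energies[i0 : i1 + 1].max())
        u_shallow = max(refined[a][1], refined[b][1])
        barriers.append(
            {
                "between": (refined[a][0], refined[b][0]),
                "u_top": u_top,
                "delta_u_barrier": u_top - u_shallow,
            }
        )
    return ScanResult("l_xy_star", grid, energies, minima, barriers,
                      meta={"stacking": stacking, "field": fld, "rho_star": rho_star})


def scan_tilt(
    structures: list[tuple[str, float]],
    params: PotentialParams,
    rho_star: float,
    phi_grid: np.ndarray | None = None,
    lxy_bracket: tuple[float, float] | None = None,
    n_grid_lxy: int = 60,
) -> dict:
    """Tilt-angle scans with the in-plane spacing re-optimized at each tilt.

    ``structures`` is a list of (stacking, theta1) pairs. Returns per-
    structure :class:`ScanResult` curves (u at the optimal l_xy* for each
    phi) plus the lower envelope across structures. Local minima are refined
    parabolically on the grid.
    """
    if phi_grid is None:
        phi_grid = np.arange(0.0, 90.0 + 1e-9, 2.5)
    phi_grid = np.asarray(phi_grid, dtype=float)
    curves: dict[tuple[str, float], ScanResult] = {}
    for stacking, theta1 in structures:
        us = np.empty_like(phi_grid)
        lxys = np.empty_like(phi_grid)
        for j, phi in enumerate(phi_grid):
            fld = OrientationField(phi=float(phi), theta1=theta1, theta2=0.0)
            sc = scan_lxy(stacking, fld, params, rho_star,
                          bracket=lxy_bracket, n_grid=n_grid_lxy)
            us[j] = sc.primary.energy
            lxys[j] = sc.primary.location
        minima = _phi_minima(phi_grid, us)
        curves[(stacking, theta1)] = ScanResult(
            "phi", phi_grid, us, minima,
            meta={"stacking": stacking, "theta1": theta1, "rho_star": rho_star,
                  "lxy_opt": lxys},
        )
    all_u = np.vstack([c.energies for c in curves.values()])
    env_u = all_u.min(axis=0)
    envelope = ScanResult("phi", phi_grid, env_u, _phi_minima(phi_grid, env_u),
                          meta={"envelope_of": list(curves)})
    barriers = _envelope_barriers(phi_grid, env_u, envelope.minima)
    envelope.barriers = barriers
    return {"curves": curves, "envelope": envelope}


def _phi_minima(phi: np.ndarray, u: np.ndarray) -> list[Minimum]:
    """Interior minima of a tilt curve, parabolically refined on the grid.

    The endpoint phi = 0 is included when the curve rises away from it
    (it is a symmetry point, u(phi) = u(-phi))."""
    pts: list[tuple[float, float]] = []
    if len(u) >= 2 and u[0] < u[1]:
        pts.append((float(phi[0]), float(u[0])))
    for i in _grid_local_minima(phi, u):
        x0, x1, x2 = phi[i - 1], phi[i], phi[i + 1]
        y0, y1, y2 = u[i - 1], u[i], u[i + 1]
        denom = (y0 - 2 * y1 + y2)
        if denom > 0:
            dx = 0.5 * (y0 - y2) / denom * (x1 - x0)
            dx = float(np.clip(dx, -(x1 - x0), x2 - x1))
        else:
            dx = 0.0
        pts.append((float(x1 + dx), float(y1)))
    if len(u) >= 2 and u[-1] < u[-2]:
        pts.append((float(phi[-1]), float(u[-1])))
    return _classify(pts)


def _envelope_barriers(phi: np.ndarray, u: np.ndarray, minima: list[Minimum]) -> list[dict]:
    out = []
    locs = sorted(m.location for m in minima)
    by_loc = {m.location: m for m in minima}
    for a, b in zip(locs[:-1], locs[1:]):
        sel = (phi >= a) & (phi <= b)
        if not sel.any():
            continue
        u_top = float(u[sel].max())
        u_shallow = max(by_loc[a].energy, by_loc[b].energy)
        out.append({"between": (a, b), "u_top": u_top, "delta_u_barrier": u_top - u_shallow})
    return out


DEFAULT_CANDIDATE_THETA1 = (0.0, 60.0, 120.0, 180.0)


def find_ground_state(
    rho_star: float,
    kappa_star: float,
    params: PotentialParams | None = None,
    stackings: tuple[str, ...] = ("AAA", "ABA", "ABC"),
    theta1_set: tuple[float, ...] = DEFAULT_CANDIDATE_THETA1,
    phi_grid: np.ndarray | None = None,
    n_grid_lxy: int = 30,
    tie_rtol: float = 1e-3,
) -> dict:
    """Global minimizer over the candidate crystal/orientation set.

    Evaluates every (stacking, theta1, phi) candidate with the in-plane
    spacing optimized at fixed density and returns the best one; ABA/ABC
    (and any other) candidates within ``tie_rtol`` of the winner are
    reported alongside as co-minima. phi = 0 candidates are twist-
    independent and evaluated once per stacking.
    """
    if params is None:
        params = PotentialParams(kappa_star=kappa_star)
    elif params.kappa_star != kappa_star:
        raise ValueError("params.kappa_star must match kappa_star")
    if phi_grid is None:
        phi_grid = np.array([0.0, 10.0, 25.0, 45.0, 60.0, 75.0, 80.0, 90.0])
    entries = []
    for stacking in stackings:
        for phi in phi_grid:
            t1s = (0.0,) if abs(math.sin(math.radians(phi))) < 1e-12 else theta1_set
            for theta1 in t1s:
                fld = OrientationField(phi=float(phi), theta1=float(theta1))
                sc = scan_lxy(stacking, fld, params, rho_star, n_grid=n_grid_lxy)
                m = sc.primary
                entries.append(
                    {"stacking": stacking, "phi": float(phi), "theta1": float(theta1),
                     "l_xy_star": m.location, "u_total": m.energy}
                )
    entries.sort(key=lambda d: d["u_total"])
    best = entries[0]
    co = [e for e in entries[1:]
          if e["u_total"] <= best["u_total"] * (1 + tie_rtol)
          and not (e["stacking"] == best["stacking"] and e["phi"] == best["phi"])]
    spec = LatticeSpec(best["stacking"], best["l_xy_star"], rho_star)
    fld = OrientationField(phi=best["phi"], theta1=best["theta1"])
    breakdown = energy_per_particle(spec, fld, params)
    return {"spec": spec, "field": fld, "breakdown": breakdown,
            "entry": best, "co_minima": co, "table": entries}


def closest_end_separation(spec: LatticeSpec | float) -> float:
    """Closest end-segment separation when rod ends pierce a hexagonal
    end-plane from the other side: ``l_xy* sqrt(3) / 4``."""
    lxy = spec.l_xy_star if isinstance(spec, LatticeSpec) else float(spec)
    if lxy < 0:
        raise ValueError("l_xy_star must be non-negative")
    return lxy * math.sqrt(3.0) / 4.0
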