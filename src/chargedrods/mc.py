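"""Zero- and finite-temperature Metropolis Monte Carlo for charged rods.

The ensemble is NVT in a periodic cuboid box. One MC step is either N
single-rod trials (translation, rotation about a random axis, or a combined
displacement-rotation, accepted or rejected jointly) or 9 isochoric
box-dimension trials: one box length is displaced uniformly within +-0.5%,
a second of the remaining two is adjusted to conserve the volume and the
third is left unchanged, with all rod centers rescaled affinely.

At zero temperature only energy-lowering moves are accepted (stochastic
greedy descent, the energy trace is non-increasing); at finite reduced
temperature T the standard Metropolis rule ``min(1, exp(-du/T))`` applies,
with symmetric proposals so detailed balance holds. Translation and
rotation amplitudes are adapted toward a 20-50% acceptance rate during the
first 300 steps of each block (adjusting every 10th step) and held fixed
for the remainder of the block; blocks repeat over the run.

Local energy changes are evaluated from the moved rod's interactions only,
through a Verlet neighbor list over rod centers that includes explicit
periodic image shifts — exact for boxes smaller than the interaction
cutoff, where minimum image would not be.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import (
    build_neighbor_list,
    image_counts,
    rod_energy_from_list,
    rod_site_energy,
    total_energy_periodic,
)
from .lattice import RodConfiguration
from .observables import q_tensor_order
from .potential import PotentialParams, segment_offsets, truncation_radii

__all__ = [
    "MCConfig",
    "MCTrace",
    "metropolis_accept",
    "single_rod_move",
    "box_move",
    "tune_step_sizes",
    "run_mc",
    "MOVE_KINDS",
]

MOVE_KINDS = ("translate", "rotate", "combined")


@dataclass(frozen=True)
class MCConfig:
    """Run parameters for :func:`run_mc`.

    ``temperature_reduced`` is k_B T in the reduced energy unit
    (``Z^2 l_B / a``); 0 selects greedy descent. ``box_move_every`` = n
    schedules one 9-attempt box step after every n particle steps (0
    disables box moves even if enabled).
    """

    temperature_reduced: float = 0.0
    n_steps: int = 1000
    move_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # translate, rotate, combined
    box_moves_enabled: bool = False
    box_move_every: int = 10
    box_move_fraction: float = 0.005  # +-0.5% length displacement
    delta_translate: float = 0.05
    delta_rotate_deg: float = 10.0
    tune_block: int = 300
    tune_interval: int = 10
    block_length: int = 1000
    target_acceptance: tuple[float, float] = (0.20, 0.50)
    seed: int = 0
    record_every: int = 1
    order_every: int = 10
    snapshot_every: int = 0
    plateau_window: int = 0  # T=0 early stop: no relative decrease over this many steps
    plateau_rtol: float = 1e-7
    debug_check_every: int = 0  # accepted moves between full-energy assertions
    skin: float = 0.3

    def __post_init__(self) -> None:
        if self.temperature_reduced < 0:
            raise ValueError("temperature_reduced must be >= 0")
        if self.delta_translate <= 0 or self.delta_rotate_deg <= 0:
            raise ValueError("step sizes must be strictly positive")
        if self.n_steps < 0 or self.tune_block < 0 or self.tune_interval < 1:
            raise ValueError("invalid step counts")
        lo, hi = self.target_acceptance
        if not (0 < lo < hi < 1):
            raise ValueError("target_acceptance must satisfy 0 < lo < hi < 1")
        if any(w < 0 for w in self.move_weights) or sum(self.move_weights) <= 0:
            raise ValueError("move_weights must be non-negative with positive sum")


@dataclass
class MCTrace:
    """Per-step records of an MC run."""

    steps: np.ndarray
    u_per_rod: np.ndarray
    box: np.ndarray  # (n_records, 3)
    acceptance: dict[str, float]
    order_steps: np.ndarray
    S: np.ndarray
    B: np.ndarray
    snapshots: list[tuple[int, RodConfiguration]] = field(default_factory=list)
    final_configuration: RodConfiguration | None = None
    final_step_sizes: dict[str, float] = field(default_factory=dict)
    n_steps_run: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"step": self.steps, "u_per_rod": self.u_per_rod,
             "Lx": self.box[:, 0], "Ly": self.box[:, 1], "Lz": self.box[:, 2]}
        )


def perturb_configuration(
    state: RodConfiguration,
    rng: np.random.Generator,
    pos_sigma: float = 0.005,
    orient_sigma_deg: float = 2.0,
) -> RodConfiguration:
    """Tiny Gaussian jitter on positions and orientations.

    A perfect crystal is a stationary point of every single-rod move by
    symmetry, so greedy (T = 0) descent started from the exact lattice
    accepts nothing even when the structure is collectively unstable. An
    infinitesimal symmetry-breaking perturbation seeds the instability,
    exactly as thermal noise would.
    """
    pos = state.positions + rng.normal(0.0, pos_sigma, state.positions.shape)
    v = state.orientations + rng.normal(0.0, math.radians(orient_sigma_deg), state.orientations.shape)
    v /= np.linalg.norm(v, axis=1)[:, None]
    return RodConfiguration(pos, v, None if state.box is None else state.box.copy(), state.periodic)


def metropolis_accept(delta_u: float, temperature_reduced: float, rng: np.random.Generator) -> bool:
    """Acceptance rule: strict descent at T = 0, Metropolis otherwise."""
    if temperature_reduced < 0:
        raise ValueError("temperature must be >= 0")
    if temperature_reduced == 0.0:
        return delta_u < 0.0
    if delta_u <= 0.0:
        return True
    return rng.random() < math.exp(-delta_u / temperature_reduced)


def _random_rotation(v: np.ndarray, delta_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate v about a uniformly random axis by an angle uniform in
    (0, delta]; the proposal is symmetric."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, delta_rad)
    c, s = math.cos(angle), math.sin(angle)
    vn = v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)
    return vn / np.linalg.norm(vn)


class _Engine:
    """Mutable MC state: configuration, energies, neighbor list, counters."""

    def __init__(self, state: RodConfiguration, config: MCConfig, params: PotentialParams):
        if not state.periodic or state.box is None:
            raise ValueError("run_mc requires a periodic configuration with a box")
        self.cfg = config
        self.params = params
        self.pos = state.positions.copy()
        self.orient = state.orientations.copy()
        self.box = state.box.copy()
        self.n = len(self.pos)
        self.rho = self.n / float(np.prod(self.box))
        self.rc_seg, self.rc_rod = truncation_radii(params, self.rho)
        self.offs = segment_offsets(params.M)
        self.kh = params.kappa_half_segment
        self.rng = np.random.default_rng(config.seed)
        self.delta_t = min(config.delta_translate, self._max_delta_t)
        self.delta_r = math.radians(config.delta_rotate_deg)
        self.acc_disp = np.zeros(self.n)
        self._rebuild_list()
        self.u_total = self._full_energy()
        self.window = {k: [0, 0] for k in MOVE_KINDS}
        self.totals = {k: [0, 0] for k in MOVE_KINDS + ("box",)}
        self.accepted_since_check = 0

    # -- energies -----------------------------------------------------
    def _full_energy(self, pos=None, box=None) -> float:
        pos = self.pos if pos is None else pos
        box = self.box if box is None else box
        nimg = image_counts(box, self.rc_rod)
        e = total_energy_periodic(
            np.ascontiguousarray(pos), np.ascontiguousarray(self.orient),
            np.ascontiguousarray(box), self.offs, self.params.kappa_star,
            self.kh, self.rc_seg**2, self.rc_rod, nimg,
        )
        return float(e) * self.params.prefactor

    def _rebuild_list(self) -> None:
        # positions are wrapped only here: a trial never sees a rod
        # teleported across the box relative to its neighbor list
        self.pos %= self.box
        nimg = image_counts(self.box, self.rc_rod + self.cfg.skin)
        self.nl_start, self.nl_q, self.nl_shift = build_neighbor_list(
            np.ascontiguousarray(self.pos), np.ascontiguousarray(self.box),
            self.rc_rod + self.cfg.skin, nimg,
        )
        self.acc_disp[:] = 0.0

    @property
    def _max_delta_t(self) -> float:
        """Translation amplitude cap keeping trials inside the Verlet skin."""
        return min(float(self.box.min()) / 2.0, self.cfg.skin / (2.0 * math.sqrt(3.0)))

    def local_energy(self, i: int, pos_i: np.ndarray, v_i: np.ndarray) -> float:
        e = rod_energy_from_list(
            pos_i, v_i, i, self.pos, self.orient,
            self.nl_start, self.nl_q, self.nl_shift,
            self.offs, self.params.kappa_star, self.kh,
            self.rc_seg**2, self.rc_rod**2,
        )
        return float(e) * self.params.prefactor

    # -- moves --------------------------------------------------------
    def particle_trial(self, kind: str) -> None:
        margin = self.cfg.skin - math.sqrt(3.0) * self.delta_t
        if 2.0 * self.acc_disp.max() > margin:
            self._rebuild_list()
        i = int(self.rng.integers(self.n))
        pos_old = self.pos[i].copy()
        v_old = self.orient[i].copy()
        pos_new, v_new = pos_old, v_old
        if kind in ("translate", "combined"):
            # unwrapped: periodicity is handled by the image shifts
            pos_new = pos_old + self.rng.uniform(-self.delta_t, self.delta_t, 3)
        if kind in ("rotate", "combined"):
            v_new = _random_rotation(v_old, self.delta_r, self.rng)
        e_old = self.local_energy(i, pos_old, v_old)
        e_new = self.local_energy(i, pos_new, v_new)
        du = e_new - e_old
        self.window[kind][0] += 1
        self.totals[kind][0] += 1
        if metropolis_accept(du, self.cfg.temperature_reduced, self.rng):
            self.pos[i] = pos_new
            self.orient[i] = v_new
            self.u_total += du
            self.window[kind][1] += 1
            self.totals[kind][1] += 1
            self.acc_disp[i] += float(np.linalg.norm(pos_new - pos_old))
            self.accepted_since_check += 1
            if self.cfg.debug_check_every and self.accepted_since_check >= self.cfg.debug_check_every:
                self._debug_check()

    def box_trial(self) -> None:
        a = int(self.rng.integers(3))
        remaining = [d for d in range(3) if d != a]
        b = remaining[int(self.rng.integers(2))]
        f = 1.0 + self.rng.uniform(-self.cfg.box_move_fraction, self.cfg.box_move_fraction)
        scale = np.ones(3)
        scale[a] = f
        scale[b] = 1.0 / f
        new_box = self.box * scale
        self.totals["box"][0] += 1
        if new_box.min() < self.rc_seg * 0.25:
            warnings.warn("box move rejected: edge shrank below a quarter segment cutoff")
            return
        new_pos = self.pos * scale
        u_new = self._full_energy(pos=new_pos, box=new_box)
        du = u_new - self.u_total
        if metropolis_accept(du, self.cfg.temperature_reduced, self.rng):
            self.pos = new_pos
            self.box = new_box
            self.u_total = u_new
            self.totals["box"][1] += 1
            self._rebuild_list()

    def _debug_check(self) -> None:
        u_ref = self._full_energy()
        if not math.isclose(u_ref, self.u_total, rel_tol=1e-8, abs_tol=1e-10):
            raise AssertionError(
                f"local-update energy {self.u_total} drifted from full recompute {u_ref}"
            )
        self.u_total = u_ref
        self.accepted_since_check = 0

    # -- tuning -------------------------------------------------------
    def tune(self) -> None:
        lo, hi = self.cfg.target_acceptance
        for kind in MOVE_KINDS:
            att, acc = self.window[kind]
            if att == 0:
                continue
            rate = acc / att
            factor = 1.25 if rate > hi else (0.8 if rate < lo else 1.0)
            if factor != 1.0:
                if kind in ("translate", "combined"):
                    self.delta_t = min(max(self.delta_t * factor, 1e-8), self._max_delta_t)
                if kind in ("rotate", "combined"):
                    self.delta_r = min(max(self.delta_r * factor, 1e-8), math.pi)
            self.window[kind] = [0, 0]

    def configuration(self) -> RodConfiguration:
        return RodConfiguration(self.pos.copy(), self.orient.copy(), self.box.copy(), periodic=True)


def single_rod_move(
    state: RodConfiguration,
    kind: str,
    delta_translate: float,
    delta_rotate_deg: float,
    rng: np.random.Generator,
    params: PotentialParams,
) -> tuple[RodConfiguration, float]:
    """One symmetric single-rod proposal and its exact local energy change.

    Convenience API over the engine internals (the proposal is NOT
    accepted/rejected here). Returns the proposed configuration and du.
    """
    if kind not in MOVE_KINDS:
        raise ValueError(f"kind must be one of {MOVE_KINDS}")
    if state.box is None or not state.periodic:
        raise ValueError("single_rod_move requires a periodic configuration")
    rho = len(state) / state.volume
    rc_seg, rc_rod = truncation_radii(params, rho)
    offs = segment_offsets(params.M)
    nimg = image_counts(state.box, rc_rod)
    i = int(rng.integers(len(state)))
    pos_new = state.positions[i].copy()
    v_new = state.orientations[i].copy()
    if kind in ("translate", "combined"):
        pos_new = (pos_new + rng.uniform(-delta_translate, delta_translate, 3)) % state.box
    if kind in ("rotate", "combined"):
        v_new = _random_rotation(v_new, math.radians(delta_rotate_deg), rng)
    args = (i, state.positions, state.orientations, state.box, offs,
            params.kappa_star, params.kappa_half_segment, rc_seg**2, rc_rod, nimg)
    e_old = rod_site_energy(state.positions[i], state.orientations[i], *args)
    e_new = rod_site_energy(pos_new, v_new, *args)
    du = (float(e_new) - float(e_old)) * params.prefactor
    out = state.copy()
    out.positions[i] = pos_new
    out.orientations[i] = v_new
    return out, du


def box_move(
    state: RodConfiguration,
    rng: np.random.Generator,
    params: PotentialParams,
    fraction: float = 0.005,
) -> tuple[RodConfiguration, float]:
    """One isochoric box-dimension proposal (volume conserved exactly).

    Returns the proposed configuration (rod centers rescaled affinely in
    the two changed dimensions) and the full energy change.
    """
    if state.box is None or not state.periodic:
        raise ValueError("box_move requires a periodic configuration")
    rho = len(state) / state.volume
    rc_seg, rc_rod = truncation_radii(params, rho)
    offs = segment_offsets(params.M)
    a = int(rng.integers(3))
    b = [d for d in range(3) if d != a][int(rng.integers(2))]
    f = 1.0 + rng.uniform(-fraction, fraction)
    scale = np.ones(3)
    scale[a] = f
    scale[b] = 1.0 / f

    def total(pos, box):
        nimg = image_counts(box, rc_rod)
        return float(
            total_energy_periodic(
                np.ascontiguousarray(pos), np.ascontiguousarray(state.orientations),
                np.ascontiguousarray(box), offs, params.kappa_star,
                params.kappa_half_segment, rc_seg**2, rc_rod, nimg,
            )
        ) * params.prefactor

    u_old = total(state.positions, state.box)
    new_box = state.box * scale
    new_pos = state.positions * scale
    du = total(new_pos, new_box) - u_old
    out = RodConfiguration(new_pos, state.orientations.copy(), new_box, periodic=True)
    return out, du


def tune_step_sizes(
    acceptance_rate: float,
    step_size: float,
    target: tuple[float, float] = (0.20, 0.50),
    factors: tuple[float, float] = (0.8, 1.25),
    bounds: tuple[float, float] = (1e-8, math.inf),
) -> float:
    """Multiplicative step-size adjustment toward the target acceptance
    band: shrink below the band, grow above it, unchanged inside."""
    lo, hi = target
    down, up = factors
    if acceptance_rate < lo:
        step_size *= down
    elif acceptance_rate > hi:
        step_size *= up
    return min(max(step_size, bounds[0]), bounds[1])


def run_mc(state: RodConfiguration, config: MCConfig, params: PotentialParams) -> MCTrace:
    """Run Metropolis MC from ``state`` and record energy, box, order
    parameters and (optionally) snapshots. The input state is not modified;
    the final configuration is attached to the trace."""
    eng = _Engine(state, config, params)
    weights = np.asarray(config.move_weights, dtype=float)
    weights = weights / weights.sum()
    rec_steps, rec_u, rec_box = [], [], []
    ord_steps, ord_s, ord_b = [], [], []
    snapshots: list[tuple[int, RodConfiguration]] = []
    particle_steps = 0
    step = 0
    for step in range(1, config.n_steps + 1):
        do_box = (
            config.box_moves_enabled
            and config.box_move_every > 0
            and step % (config.box_move_every + 1) == 0
        )
        if do_box:
            for _ in range(9):
                eng.box_trial()
        else:
            for _ in range(eng.n):
                kind = MOVE_KINDS[int(eng.rng.choice(3, p=weights))]
                eng.particle_trial(kind)
            particle_steps += 1
            block_pos = (particle_steps - 1) % config.block_length
            if block_pos < config.tune_block and (block_pos + 1) % config.tune_interval == 0:
                eng.tune()
        if step % config.record_every == 0:
            rec_steps.append(step)
            rec_u.append(eng.u_total / eng.n)
            rec_box.append(eng.box.copy())
        if config.order_every and step % config.order_every == 0:
            op = q_tensor_order(eng.orient)
            ord_steps.append(step)
            ord_s.append(op.S)
            ord_b.append(op.B)
        if config.snapshot_every and step % config.snapshot_every == 0:
            snapshots.append((step, eng.configuration()))
        if (
            config.temperature_reduced == 0.0
            and config.plateau_window
            and len(rec_u) > config.plateau_window
        ):
            drop = rec_u[-config.plateau_window - 1] - rec_u[-1]
            if drop < config.plateau_rtol * abs(rec_u[-1]):
                break
    acceptance = {
        k: (v[1] / v[0] if v[0] else float("nan")) for k, v in eng.totals.items()
    }
    return MCTrace(
        steps=np.array(rec_steps, dtype=int),
        u_per_rod=np.array(rec_u),
        box=np.array(rec_box) if rec_box else np.zeros((0, 3)),
        acceptance=acceptance,
        order_steps=np.array(ord_steps, dtype=int),
        S=np.array(ord_s),
        B=np.array(ord_b),
        snapshots=snapshots,
        final_configuration=eng.configuration(),
        final_step_sizes={"translate": eng.delta_t, "rotate_deg": math.degrees(eng.delta_r)},
        n_steps_run=step,
    )
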