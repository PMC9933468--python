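"""Ready-made simulation protocols built from the library modules."""

from __future__ import annotations

import numpy as np

from .lattice import LatticeSpec, OrientationField, build_periodic_supercell
from .mc import MCConfig, run_mc, perturb_configuration
from .observables import layer_twist_deg, mean_tilt_deg
from .optimize import scan_lxy
from .potential import PotentialParams

__all__ = ["heliconical_relaxation"]


def heliconical_relaxation(
    kappa_star: float = 20.0,
    rho_star: float = 10.0,
    M: int = 7,
    n_trunc: int = 6,
    cells: tuple[int, int, int] = (4, 6, 6),
    n_steps: int = 1500,
    seed: int = 1,
    temperature_reduced: float = 0.0,
) -> dict:
    """Stability test of the cholesteric crystal (tilt 90 deg, twist 60 deg).

    Builds the lattice-optimized AAA crystal with an in-plane cholesteric
    orientation field (phi = 90, theta1 = 60), applies an infinitesimal
    symmetry-breaking jitter, and runs greedy (T = 0 by default) Metropolis
    MC with translation, rotation, combined and isochoric box moves. The
    cholesteric crystal is unstable and relaxes to a heliconical phase:
    mean tilt near 75 deg with a 120 deg twist per layer (3-layer pitch).

    Returns a dict with the optimized start, the MC trace and the measured
    final tilt (degrees) and per-layer twist (degrees).
    """
    params = PotentialParams(kappa_star=kappa_star, M=M, n_trunc=n_trunc)
    fld = OrientationField(phi=90.0, theta1=60.0)
    sc = scan_lxy("AAA", fld, params, rho_star, n_grid=40)
    spec = LatticeSpec("AAA", sc.primary.location, rho_star)
    n_x, n_y, n_z = cells
    crystal = build_periodic_supercell(spec, fld, n_x, n_y, n_z)
    rng = np.random.default_rng(seed)
    start = perturb_configuration(crystal, rng)
    mcc = MCConfig(
        temperature_reduced=temperature_reduced,
        n_steps=n_steps,
        box_moves_enabled=True,
        delta_rotate_deg=20.0,
        seed=seed,
        record_every=10,
        order_every=100,
        plateau_window=100,
        plateau_rtol=1e-8,
    )
    trace = run_mc(start, mcc, params)
    final = trace.final_configuration
    return {
        "params": params,
        "l_xy_star": sc.primary.location,
        "start": start,
        "trace": trace,
        "final": final,
        "tilt_deg": mean_tilt_deg(final.orientations),
        "twist_deg": layer_twist_deg(final, n_z),
    }
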