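"""Monte Carlo engine: acceptance rule, local updates, box moves, descent."""

import math

import numpy as np
import pytest

from chargedrods._kernels import image_counts, total_energy_periodic
from chargedrods.lattice import LatticeSpec, OrientationField, RodConfiguration, build_periodic_supercell
from chargedrods.mc import (
    MCConfig,
    _random_rotation,
    box_move,
    metropolis_accept,
    perturb_configuration,
    run_mc,
    single_rod_move,
    tune_step_sizes,
)
from chargedrods.potential import PotentialParams, segment_offsets, truncation_radii


def total_energy(state, params):
    rc_seg, rc_rod = truncation_radii(params, len(state) / state.volume)
    nimg = image_counts(state.box, rc_rod)
    e = total_energy_periodic(
        np.ascontiguousarray(state.positions), np.ascontiguousarray(state.orientations),
        np.ascontiguousarray(state.box), segment_offsets(params.M), params.kappa_star,
        params.kappa_half_segment, rc_seg**2, rc_rod, nimg,
    )
    return float(e) * params.prefactor


@pytest.fixture()
def small_crystal():
    spec = LatticeSpec("AAA", 0.5, 10.0)
    return build_periodic_supercell(spec, OrientationField(phi=30.0, theta1=0.0), 2, 3, 3)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert metropolis_accept(-1.0, 0.0, rng)
        assert metropolis_accept(-1.0, 5.0, rng)

    def test_strict_descent_at_zero_temperature(self, rng):
        assert not metropolis_accept(1e-12, 0.0, rng)
        assert not metropolis_accept(0.0, 0.0, rng)

    def test_finite_temperature_frequency(self, rng):
        """du = ln(2) T is accepted half the time."""
        t = 0.7
        du = math.log(2.0) * t
        hits = sum(metropolis_accept(du, t, rng) for _ in range(20000))
        assert hits / 20000 == pytest.approx(0.5, abs=0.01)

    def test_negative_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, -0.1, rng)


class TestSingleRodMove:
    def test_local_update_equals_full_recompute(self, small_crystal, rng):
        """The local energy change of any single-rod move matches the
        difference of two from-scratch total energies."""
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        state = perturb_configuration(small_crystal, rng, 0.02, 5.0)
        u_old = total_energy(state, params)
        for kind in ("translate", "rotate", "combined"):
            for _ in range(6):
                new_state, du = single_rod_move(state, kind, 0.08, 25.0, rng, params)
                du_ref = total_energy(new_state, params) - u_old
                assert du == pytest.approx(du_ref, rel=1e-9, abs=1e-13)

    def test_zero_amplitude_move_has_zero_energy_change(self, small_crystal, rng):
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        _, du = single_rod_move(small_crystal, "translate", 1e-300, 10.0, rng, params)
        assert du == pytest.approx(0.0, abs=1e-12)

    def test_rotation_preserves_unit_norm(self, rng):
        v = np.array([0.0, 0.0, 1.0])
        for _ in range(100):
            v = _random_rotation(v, 0.8, rng)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_kind_rejected(self, small_crystal, rng):
        params = PotentialParams(kappa_star=10.0, M=3)
        with pytest.raises(ValueError):
            single_rod_move(small_crystal, "teleport", 0.1, 10.0, rng, params)


class TestBoxMove:
    def test_volume_conserved(self, small_crystal, rng):
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        v_old = small_crystal.volume
        for _ in range(10):
            new_state, _ = box_move(small_crystal, rng, params)
            assert abs(new_state.volume - v_old) / v_old < 1e-12

    def test_identity_scale_has_zero_energy_change(self, small_crystal, rng):
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        _, du = box_move(small_crystal, rng, params, fraction=1e-300)
        assert du == pytest.approx(0.0, abs=1e-12)

    def test_energy_change_matches_full_recompute(self, small_crystal, rng):
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        u_old = total_energy(small_crystal, params)
        new_state, du = box_move(small_crystal, rng, params)
        assert du == pytest.approx(total_energy(new_state, params) - u_old, rel=1e-10, abs=1e-14)


class TestTuning:
    def test_monotone_adjustment_rules(self):
        assert tune_step_sizes(0.80, 1.0) == pytest.approx(1.25)
        assert tune_step_sizes(0.35, 1.0) == pytest.approx(1.0)
        assert tune_step_sizes(0.05, 1.0) == pytest.approx(0.8)

    def test_bounds_respected(self):
        assert tune_step_sizes(0.9, 1.0, bounds=(1e-8, 1.1)) == pytest.approx(1.1)
        assert tune_step_sizes(0.0, 2e-8, bounds=(1e-8, 1.0)) >= 1e-8


class TestRunMC:
    def test_zero_temperature_energy_never_increases(self, small_crystal, rng):
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        start = perturb_configuration(small_crystal, rng, 0.03, 8.0)
        cfg = MCConfig(temperature_reduced=0.0, n_steps=40, seed=3, record_every=1,
                       box_moves_enabled=True, debug_check_every=50)
        trace = run_mc(start, cfg, params)
        assert np.all(np.diff(trace.u_per_rod) <= 1e-13)

    def test_identical_seed_gives_identical_trace(self, small_crystal):
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        cfg = MCConfig(temperature_reduced=2e-4, n_steps=25, seed=11, record_every=1)
        t1 = run_mc(small_crystal, cfg, params)
        t2 = run_mc(small_crystal, cfg, params)
        assert np.array_equal(t1.u_per_rod, t2.u_per_rod)
        assert np.array_equal(t1.final_configuration.positions, t2.final_configuration.positions)

    def test_optimized_ground_state_is_stationary_under_descent(self):
        """The lattice-optimized unidirectional ABC crystal survives greedy
        descent unchanged: every single-rod proposal is uphill."""
        from chargedrods.optimize import scan_lxy

        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        lxy = scan_lxy("ABC", OrientationField(), params, 10.0, n_grid=30).primary.location
        crystal = build_periodic_supercell(
            LatticeSpec("ABC", lxy, 10.0), OrientationField(), 2, 3, 3
        )
        cfg = MCConfig(temperature_reduced=0.0, n_steps=15, seed=5, record_every=1)
        trace = run_mc(crystal, cfg, params)
        assert trace.u_per_rod[-1] == pytest.approx(trace.u_per_rod[0], rel=1e-12)
        assert trace.acceptance["translate"] == pytest.approx(0.0, abs=1e-12) or math.isnan(
            trace.acceptance["translate"]
        )

    def test_two_rod_sampling_matches_boltzmann_quadrature(self):
        """Finite-T sampling of a two-rod periodic toy reproduces the
        center-separation distribution from direct grid quadrature of the
        Boltzmann weight."""
        params = PotentialParams(kappa_star=5.0, M=1, n_trunc=10)
        box = np.array([1.2, 1.2, 1.2])
        v = np.array([0.0, 0.0, 1.0])
        temp = 0.05
        nb = 6
        r_edges = np.linspace(0.0, 0.6, nb + 1)

        def pair_state(delta):
            pos = np.array([[0.1, 0.1, 0.1], [0.1, 0.1, 0.1] + delta])
            return RodConfiguration(pos, np.array([v, v]), box=box, periodic=True)

        # exact reference: relative displacement uniform over the box
        n = 20
        grid = (np.arange(n) + 0.5) / n * box[0]
        ref_hist = np.zeros(nb)
        for dx in grid:
            for dy in grid:
                for dz in grid:
                    d = np.array([dx, dy, dz])
                    u = total_energy(pair_state(d), params)
                    dmin = d - box * np.round(d / box)
                    r = np.linalg.norm(dmin)
                    k = np.searchsorted(r_edges, r) - 1
                    if 0 <= k < nb:
                        ref_hist[k] += math.exp(-u / temp)
        ref_p = ref_hist / ref_hist.sum()

        cfg = MCConfig(temperature_reduced=temp, n_steps=4000, seed=17,
                       move_weights=(1.0, 0.0, 0.0), record_every=1,
                       order_every=0, snapshot_every=1, tune_block=0)
        trace = run_mc(pair_state(np.array([0.3, 0.0, 0.0])), cfg, params)
        rs = []
        for _, snap in trace.snapshots[500:]:
            d = snap.positions[1] - snap.positions[0]
            dmin = d - box * np.round(d / box)
            rs.append(np.linalg.norm(dmin))
        hist, _ = np.histogram(rs, bins=r_edges)
        p = hist / hist.sum()
        assert np.abs(p - ref_p).max() < 0.06

    def test_heating_disorders_and_raises_energy(self, rng):
        """Far above the lattice barriers the crystal melts: energy and
        orientational disorder both increase; quenching then lowers the
        energy again without recovering the crystal."""
        params = PotentialParams(kappa_star=10.0, M=3, n_trunc=4)
        spec = LatticeSpec("ABC", 0.33, 10.0)
        crystal = build_periodic_supercell(spec, OrientationField(), 2, 3, 3)
        u0 = total_energy(crystal, params) / len(crystal)
        hot = run_mc(
            crystal,
            MCConfig(temperature_reduced=50.0 * u0, n_steps=150, seed=9,
                     box_moves_enabled=False, record_every=5, order_every=25),
            params,
        )
        assert hot.u_per_rod[-1] > u0
        assert hot.S[-1] < 0.7
        quench = run_mc(
            hot.final_configuration,
            MCConfig(temperature_reduced=0.0, n_steps=120, seed=10, record_every=5,
                     order_every=30, plateau_window=15, plateau_rtol=1e-6),
            params,
        )
        assert quench.u_per_rod[-1] < hot.u_per_rod[-1]
        assert quench.u_per_rod[-1] > u0 * 0.999  # disordered state stays above the crystal


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        MCConfig(temperature_reduced=-1.0)
    with pytest.raises(ValueError):
        MCConfig(delta_translate=0.0)
    with pytest.raises(ValueError):
        MCConfig(target_acceptance=(0.6, 0.5))
    with pytest.raises(ValueError):
        MCConfig(move_weights=(0.0, 0.0, 0.0))
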