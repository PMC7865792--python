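"""Langevin engine: initialization, thermostat, integrator correctness
(force consistency, NVE conservation, Boltzmann sampling), replicas."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from chromoblock.engine import (SimulationConfig, SimulationState, anneal,
                                compute_forces_and_energy, init_conformation,
                                run, run_replicas, simulate_chain)
from chromoblock.model import (Container, ForceFieldParams, build_topology,
                               container_radius, fene_energy, pair_energy,
                               total_energy_brute_force)
from chromoblock.synth import SynthConfig, generate_annotation

from conftest import make_chain


@pytest.fixture(scope="module")
def small_system():
    beads = generate_annotation(SynthConfig(n_beads=40, seed=2))
    params = ForceFieldParams()
    container = Container(radius=container_radius(40))
    topo = build_topology(beads, params)
    return beads, params, container, topo


class TestInitConformation:
    def test_deterministic(self, small_system):
        beads, params, container, _ = small_system
        a = init_conformation(beads, container, seed=5)
        b = init_conformation(beads, container, seed=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_constructive_postconditions(self, small_system):
        beads, params, container, _ = small_system
        st = init_conformation(beads, container, seed=8)
        r = np.linalg.norm(st.coordinates, axis=1)
        assert np.all(r < container.radius)
        # pairwise separations >= 0.8
        d = np.linalg.norm(st.coordinates[:, None] - st.coordinates[None],
                           axis=2)
        np.fill_diagonal(d, 10.0)
        assert d.min() >= 0.8
        # consecutive beads exactly 1 sigma apart
        steps = np.linalg.norm(np.diff(st.coordinates, axis=0), axis=1)
        np.testing.assert_allclose(steps, 1.0, atol=1e-9)

    def test_too_small_container_raises(self, small_system):
        beads, *_ = small_system
        from chromoblock.engine import SimulationError
        with pytest.raises(SimulationError):
            init_conformation(beads, Container(radius=1.5), seed=0,
                              max_restarts=3)


class TestAnneal:
    def test_zero_steps_sets_target_directly(self, small_system):
        beads, params, container, topo = small_system
        st = init_conformation(beads, container, seed=1)
        cfg = SimulationConfig(n_steps=1000, anneal_steps=0, seed=1)
        out = anneal(st, topo, container, params, cfg)
        assert out.temperature == 1.0

    def test_final_target_is_one(self, small_system):
        beads, params, container, topo = small_system
        st = init_conformation(beads, container, seed=1)
        cfg = SimulationConfig(n_steps=10_000, anneal_steps=5_000, seed=1)
        out = anneal(st, topo, container, params, cfg)
        assert out.temperature == 1.0

    def test_kinetic_temperature_near_target(self, small_system):
        """Equipartition: measured kinetic temperature within 5% of the
        thermostat target after annealing."""
        beads, params, container, topo = small_system
        st = init_conformation(beads, container, seed=3)
        cfg = SimulationConfig(n_steps=100_000, anneal_steps=20_000,
                               snapshot_interval=1_000, seed=3)
        anneal(st, topo, container, params, cfg)
        traj = run(st, topo, container, params, cfg)
        measured = traj.kinetic_temperature[20:].mean()
        assert measured == pytest.approx(1.0, rel=0.05)


class TestRun:
    def test_frame_count(self, small_system):
        beads, params, container, topo = small_system
        st = init_conformation(beads, container, seed=4)
        cfg = SimulationConfig(n_steps=50_000, anneal_steps=0,
                               snapshot_interval=7_000, seed=4)
        anneal(st, topo, container, params, cfg)
        traj = run(st, topo, container, params, cfg)
        assert traj.n_frames == 50_000 // 7_000

    def test_containment_and_fene_bounds_all_frames(self, small_system):
        beads, params, container, topo = small_system
        st = init_conformation(beads, container, seed=6)
        cfg = SimulationConfig(n_steps=60_000, anneal_steps=10_000,
                               snapshot_interval=2_000, seed=6)
        anneal(st, topo, container, params, cfg)
        traj = run(st, topo, container, params, cfg)
        for f in range(traj.n_frames):
            r = np.linalg.norm(traj.frames[f], axis=1)
            assert np.all(r < container.radius)
            bonds = np.linalg.norm(np.diff(traj.frames[f], axis=0), axis=1)
            assert np.all(bonds < params.fene_R0)

    def test_deterministic_given_seed(self, small_system):
        beads, params, container, topo = small_system
        cfg = SimulationConfig(n_steps=20_000, seed=9)
        t1 = simulate_chain(beads, params, cfg, container)
        t2 = simulate_chain(beads, params, cfg, container)
        np.testing.assert_array_equal(t1.frames, t2.frames)


class TestForceCorrectness:
    def test_forces_match_numerical_gradient(self):
        """Analytic forces equal the numerical gradient of the potential
        to <= 1e-6 relative error on random small configurations."""
        rng = np.random.default_rng(12)
        beads = make_chain("FPFPFPFP", boundaries={0, 3, 7}, lads={1, 5})
        params = ForceFieldParams()
        container = Container(radius=4.0)
        topo = build_topology(beads, params)
        for _ in range(3):
            coords = _valid_config(rng, 8, container, params)
            forces, _ = compute_forces_and_energy(coords, topo, container,
                                                  params)
            h = 1e-6
            num = np.zeros_like(coords)
            for i in range(8):
                for k in range(3):
                    for sign in (+1, -1):
                        c = coords.copy()
                        c[i, k] += sign * h
                        _, e = compute_forces_and_energy(c, topo, container,
                                                         params)
                        num[i, k] -= sign * e / (2 * h)
            scale = max(1.0, float(np.abs(forces).max()))
            assert np.abs(num - forces).max() / scale < 1e-6

    def test_engine_energy_matches_brute_force_oracle(self):
        """Engine total potential equals the term-wise O(N^2) oracle to
        <= 1e-10 relative error on random <=12-bead configurations."""
        rng = np.random.default_rng(21)
        params = ForceFieldParams()
        container = Container(radius=4.0)
        for n, classes in [(6, "FFFPPP"), (12, "FPFFPPPFFPPP")]:
            beads = make_chain(classes, boundaries={0, n - 1},
                               lads={n - 1})
            topo = build_topology(beads, params)
            for _ in range(3):
                coords = _valid_config(rng, n, container, params)
                _, e_engine = compute_forces_and_energy(
                    coords, topo, container, params)
                e_oracle = total_energy_brute_force(coords, topo,
                                                    container, params)
                assert abs(e_engine - e_oracle) <= \
                    1e-10 * max(1.0, abs(e_oracle))

    def test_nve_energy_conservation(self):
        """With the thermostat off and dt reduced 10x, total energy drifts
        by <= 1e-4 energy units per 1e4 steps for a 10-bead chain.

        The chain is cooled until no pair sits near the interaction cutoff:
        the truncated-shifted pair potential (as the model defines it) has
        a force discontinuity at rc, so energy is only conserved while no
        pair crosses it.  A cold compact chain isolates integrator quality
        from that model property.
        """
        beads = make_chain("FFFFFPPPPP", boundaries={0, 9})
        params = ForceFieldParams()
        container = Container(radius=container_radius(10))
        topo = build_topology(beads, params)
        st = init_conformation(beads, container, seed=2, temperature=1.0)
        pre = SimulationConfig(n_steps=40_000, anneal_steps=30_000,
                               anneal_from=1.0, anneal_to=0.02, seed=2)
        anneal(st, topo, container, params, pre)
        nve_cfg = SimulationConfig(n_steps=30_000, dt=0.001,
                                   snapshot_interval=1_000, seed=2)
        traj = run(st, topo, container, params, nve_cfg, nve=True)
        energy = traj.potential_energy + traj.kinetic_energy
        drift = np.abs(energy - energy[0]).max()
        assert drift <= 1e-4 * (nve_cfg.n_steps / 10_000)


class TestBoltzmannSampling:
    def test_two_bead_bond_length_matches_quadrature(self):
        """Mean FENE+LJ bond length matches the 1D Boltzmann average
        computed by numerical quadrature, within 2%."""
        params = ForceFieldParams()
        beads = make_chain("FF")
        topo = build_topology(beads, params)
        container = Container(radius=30.0)

        def u(r):
            return (fene_energy(r, params)
                    + pair_energy(r, params.eps_ff, params.rc_pair))

        z0 = quad(lambda r: r ** 2 * math.exp(-u(r)), 0.3, 1.499)[0]
        z1 = quad(lambda r: r ** 3 * math.exp(-u(r)), 0.3, 1.499)[0]
        r_theory = z1 / z0

        st = SimulationState(
            coordinates=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            velocities=np.zeros((2, 3)), step=0, temperature=1.0)
        cfg = SimulationConfig(n_steps=400_000, snapshot_interval=100,
                               seed=17)
        traj = run(st, topo, container, params, cfg)
        r_sim = np.linalg.norm(traj.frames[200:, 0] - traj.frames[200:, 1],
                               axis=1).mean()
        assert r_sim == pytest.approx(r_theory, rel=0.02)

    def test_free_chain_center_of_mass_diffuses(self):
        """With all attractions off, the chain's center of mass performs
        free diffusion: MSD grows linearly with D ~ kT/(N*gamma*m)."""
        params = ForceFieldParams(eps_pp=0.0, eps_ff=0.0, eps_pf=0.0,
                                  eps_lc=0.0, eps_pb=0.0, eps_fb=0.0)
        n = 4
        beads = make_chain("FFPP")
        topo = build_topology(beads, params)
        container = Container(radius=150.0)
        st = SimulationState(
            coordinates=np.column_stack([np.arange(n) - n / 2,
                                         np.zeros(n), np.zeros(n)]),
            velocities=np.zeros((n, 3)), step=0, temperature=1.0)
        # pure-FENE bonds (no excluded volume) explore close to the
        # divergence length, so the step is kept small
        cfg = SimulationConfig(n_steps=400_000, dt=0.002,
                               snapshot_interval=500, seed=23)
        traj = run(st, topo, container, params, cfg)
        com = traj.frames.mean(axis=1)
        dt_frame = 500 * cfg.dt
        # time-origin averaged MSD at two lags
        msd = {}
        for lag in (20, 40):
            d = com[lag:] - com[:-lag]
            msd[lag] = (d ** 2).sum(axis=1).mean()
        d_theory = 1.0 / (n * cfg.friction)
        d_hat = msd[40] / (6 * 40 * dt_frame)
        assert 0.5 * d_theory < d_hat < 2.0 * d_theory
        # linear growth: doubling the lag roughly doubles the MSD
        assert 1.4 < msd[40] / msd[20] < 2.6


class TestReplicas:
    def test_distinct_and_reproducible(self, small_system):
        beads, params, container, _ = small_system
        cfg = SimulationConfig(n_steps=20_000, n_replicas=2, seed=31)
        a = run_replicas(beads, params, cfg, container)
        b = run_replicas(beads, params, cfg, container)
        assert len(a) == 2
        assert not np.array_equal(a[0].frames, a[1].frames)
        np.testing.assert_array_equal(a[0].frames, b[0].frames)
        np.testing.assert_array_equal(a[1].frames, b[1].frames)

    def test_four_replicas_by_default(self):
        assert SimulationConfig().n_replicas == 4


def _valid_config(rng, n, container, params):
    """Random connected configuration with no pair near a potential cutoff
    or the FENE divergence (keeps numerical gradients well-defined)."""
    cutoffs = (params.rc_pair, params.rc_wall_other, params.rc_wall_lad)
    while True:
        coords = [np.array([0.0, 0.0, 0.0])]
        for _ in range(n - 1):
            step = rng.normal(size=3)
            step *= (0.95 + 0.1 * rng.random()) / np.linalg.norm(step)
            coords.append(coords[-1] + step)
        coords = np.array(coords)
        coords -= coords.mean(axis=0)
        d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        iu = np.triu_indices(n, 1)
        pd = d[iu]
        wall_d = container.radius - np.linalg.norm(coords, axis=1)
        ok = (pd.min() > 0.85
              and np.all(np.abs(pd[:, None]
                                - np.array(cutoffs)) > 1e-3)
              and np.all(np.abs(wall_d[:, None]
                                - np.array(cutoffs)) > 1e-3)
              and np.all(np.diff(
                  [np.linalg.norm(coords[i + 1] - coords[i])
                   for i in range(n - 1)]) < 0.4)
              and np.all(wall_d > 0.3))
        if ok:
            return coords
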