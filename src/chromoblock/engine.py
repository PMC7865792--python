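"""Langevin-dynamics engine for the block-copolymer chromatin model.

The integrator is a BAOAB splitting of underdamped Langevin dynamics in
reduced units (m = 1, k_B = 1, lengths in σ0, energies in ε0, time in τ0).
A simulation starts from a random self-avoiding walk confined to the
spherical container, anneals the thermostat from 5 T0 down to 1 T0, and then
runs at 1 T0 with snapshots saved at a fixed stride.  Desk-scale defaults
(10⁶-step order) are native; production-scale protocols are exported to
LAMMPS instead (see ``chromoblock.lammps``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from . import _kernels as K
from .annotation import BeadAnnotation
from .model import Container, ForceFieldParams, Topology, build_topology

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "Trajectory",
    "init_conformation",
    "anneal",
    "run",
    "run_replicas",
    "SimulationError",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and protocol parameters (reduced units)."""

    dt: float = 0.01                  # τ0
    n_steps: int = 2_000_000          # production steps at 1 T0
    anneal_from: float = 5.0          # T0
    anneal_to: float = 1.0            # T0
    anneal_steps: int | None = None   # default: 10% of n_steps
    friction: float = 0.25            # 1/τ0
    snapshot_interval: int = 10_000   # steps
    n_replicas: int = 4
    seed: int = 0
    neighbor_skin: float = 0.45       # σ0
    noise_stride: int = 4             # OU substep every this many steps

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.anneal_from < self.anneal_to:
            raise ValueError("anneal_from must be >= anneal_to")
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")
        if self.noise_stride < 1:
            raise ValueError("noise_stride must be >= 1")

    @property
    def resolved_anneal_steps(self) -> int:
        if self.anneal_steps is not None:
            return self.anneal_steps
        return self.n_steps // 10


@dataclass
class SimulationState:
    coordinates: np.ndarray   # (n, 3) in σ0
    velocities: np.ndarray    # (n, 3)
    step: int
    temperature: float        # thermostat target, T0 units


@dataclass
class Trajectory:
    """Snapshots of one replica plus per-frame scalars."""

    frames: np.ndarray        # (n_frames, n, 3)
    frame_steps: np.ndarray   # (n_frames,)
    potential_energy: np.ndarray
    kinetic_energy: np.ndarray
    kinetic_temperature: np.ndarray
    beads: list[BeadAnnotation]
    container: Container
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# array preparation
# ---------------------------------------------------------------------------

def _topology_arrays(topology: Topology, params: ForceFieldParams):
    types = np.array([0 if c == "F" else 1 for c in topology.bead_class],
                     dtype=np.int64)
    eps_matrix = np.array([[params.eps_ff, params.eps_pf],
                           [params.eps_pf, params.eps_pp]])
    bond_i = np.array([i for i, _ in topology.backbone_bonds], dtype=np.int64)
    bond_j = np.array([j for _, j in topology.backbone_bonds], dtype=np.int64)
    bb_i = np.array([i for i, _, _ in topology.boundary_bonds],
                    dtype=np.int64)
    bb_j = np.array([j for _, j, _ in topology.boundary_bonds],
                    dtype=np.int64)
    bb_eps = np.array([params.eps_fb if c == "F-TAD" else params.eps_pb
                       for _, _, c in topology.boundary_bonds])
    is_lad = topology.is_lad.astype(np.bool_)
    return types, eps_matrix, bond_i, bond_j, bb_i, bb_j, bb_eps, is_lad


def compute_forces_and_energy(coords: np.ndarray, topology: Topology,
                              container: Container,
                              params: ForceFieldParams
                              ) -> tuple[np.ndarray, float]:
    """One-shot force/energy evaluation (all pairs listed; used by tests)."""
    (types, eps_matrix, bond_i, bond_j, bb_i, bb_j, bb_eps,
     is_lad) = _topology_arrays(topology, params)
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    pair_i = ii.astype(np.int64)
    pair_j = jj.astype(np.int64)
    pair_eps = eps_matrix[types[pair_i], types[pair_j]]
    forces = np.empty_like(coords)
    st = K.compute_forces(coords, forces, pair_eps, params.rc_pair,
                          bond_i, bond_j, params.fene_K, params.fene_R0,
                          bb_i, bb_j, bb_eps, is_lad, container.radius,
                          params.eps_lc, params.rc_wall_lad,
                          params.eps_wall_rep, params.rc_wall_other,
                          pair_i, pair_j, len(pair_i))
    if st != K.STATUS_OK:
        raise SimulationError("rejected configuration (FENE overstretch "
                              "or bead outside container)")
    energy = K.potential_energy(coords, types, eps_matrix, params.rc_pair,
                                bond_i, bond_j, params.fene_K, params.fene_R0,
                                bb_i, bb_j, bb_eps, is_lad, container.radius,
                                params.eps_lc, params.rc_wall_lad,
                                params.eps_wall_rep, params.rc_wall_other,
                                pair_i, pair_j, len(pair_i))
    return forces, float(energy)


# ---------------------------------------------------------------------------
# initial conformation
# ---------------------------------------------------------------------------

def init_conformation(beads: Sequence[BeadAnnotation], container: Container,
                      seed: int, min_separation: float = 0.8,
                      wall_margin: float = 1.0,
                      temperature: float = 5.0,
                      max_restarts: int = 50) -> SimulationState:
    """Random self-avoiding walk per chain inside the sphere.

    Consecutive beads are 1 σ0 apart; any candidate closer than
    ``min_separation`` to an already-placed bead, or within ``wall_margin``
    of the wall, is rejected.  Velocities are Maxwell–Boltzmann at
    ``temperature`` (the annealing start).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    chain_ids = [b.chain_id for b in beads]
    n = len(beads)
    r_max = container.radius - wall_margin
    if r_max <= 0:
        raise SimulationError("container too small for placement margin")

    placed = np.empty((n, 3))
    n_placed = 0
    for _ in range(max_restarts):
        n_placed = 0
        ok = True
        idx = 0
        while idx < n and ok:
            cid = chain_ids[idx]
            chain_len = sum(1 for c in chain_ids if c == cid)
            start = _random_point_in_sphere(rng, r_max * 0.9)
            placed[n_placed] = start
            n_placed += 1
            idx += 1
            for _k in range(1, chain_len):
                accepted = False
                for _try in range(500):
                    step = _random_unit(rng)
                    cand = placed[n_placed - 1] + step
                    if np.linalg.norm(cand) > r_max:
                        continue
                    prev = placed[:n_placed]
                    d2 = np.sum((prev - cand) ** 2, axis=1)
                    if np.min(d2) < min_separation ** 2:
                        continue
                    accepted = True
                    break
                if not accepted:
                    ok = False
                    break
                placed[n_placed] = cand
                n_placed += 1
                idx += 1
        if ok and n_placed == n:
            vel = rng.normal(0.0, np.sqrt(temperature), size=(n, 3))
            return SimulationState(coordinates=placed.copy(),
                                   velocities=vel, step=0,
                                   temperature=temperature)
    raise SimulationError(
        "failed to place the self-avoiding walk; try a larger container")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_point_in_sphere(rng: np.random.Generator,
                            radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            return p


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

_STATUS_MSG = {
    K.STATUS_FENE: "FENE overstretch or wall escape at step {step} "
                   "(timestep too large?)",
    K.STATUS_NAN: "non-finite coordinates at step {step}",
}


def _integrate(state: SimulationState, topology: Topology,
               container: Container, params: ForceFieldParams,
               config: SimulationConfig, n_steps: int,
               t_start: float, t_end: float, seed: int,
               snapshots: bool, nve: bool = False,
               limit_steps: int = 0,
               limit_dmax: float = 0.05) -> Trajectory | None:
    (types, eps_matrix, bond_i, bond_j, bb_i, bb_j, bb_eps,
     is_lad) = _topology_arrays(topology, params)
    n = state.coordinates.shape[0]
    snap = config.snapshot_interval if snapshots else 0
    n_frames = n_steps // snap if snap else 0
    frames = np.empty((max(n_frames, 1), n, 3))
    frame_steps = np.zeros(max(n_frames, 1), dtype=np.int64)
    log_pe = np.zeros(max(n_frames, 1))
    log_ke = np.zeros(max(n_frames, 1))
    log_temp = np.zeros(max(n_frames, 1))

    gamma = 0.0 if nve else config.friction
    pair_cap = max(64 * n, 8192)
    pos = state.coordinates
    vel = state.velocities
    forces = np.empty((n, 3))
    pos_ref = np.empty((n, 3))
    pair_i = np.empty(pair_cap, dtype=np.int64)
    pair_j = np.empty(pair_cap, dtype=np.int64)
    pair_eps = np.empty(pair_cap)

    # noise drawn outside the kernel in blocks (PCG64 is much faster than
    # the kernel-internal generator); block structure is part of the
    # deterministic seed contract
    block = 2000
    stride = config.noise_stride
    rng = np.random.Generator(np.random.PCG64(seed))
    noise = np.empty((block // stride + 1) * 3 * n)
    n_written = 0
    step0 = 0
    while step0 < n_steps:
        nb = min(block, n_steps - step0)
        if gamma > 0.0:
            # number of OU substeps in this block (global steps step0..)
            n_o = len(range(step0 + (-step0) % stride,
                            step0 + nb, stride))
            if n_o > 0:
                rng.standard_normal(out=noise[:n_o * 3 * n])
        pos_block, vel_block = pos.copy(), vel.copy()
        st, fail_step, n_written = K.integrate_block(
            pos, vel, forces, pos_ref, pair_i, pair_j, pair_eps,
            step0, nb, n_steps, config.dt, gamma, stride, t_start, t_end,
            types, eps_matrix, params.rc_pair, config.neighbor_skin,
            bond_i, bond_j, params.fene_K, params.fene_R0,
            bb_i, bb_j, bb_eps, is_lad, container.radius,
            params.eps_lc, params.rc_wall_lad,
            params.eps_wall_rep, params.rc_wall_other,
            noise, snap, frames, frame_steps, log_pe, log_ke, log_temp,
            n_written, limit_steps, limit_dmax)
        if st == K.STATUS_OVERFLOW:
            pair_cap *= 2
            pair_i = np.empty(pair_cap, dtype=np.int64)
            pair_j = np.empty(pair_cap, dtype=np.int64)
            pair_eps = np.empty(pair_cap)
            pos[:], vel[:] = pos_block, vel_block
            continue  # redo this block with a larger list
        if st != K.STATUS_OK:
            raise SimulationError(_STATUS_MSG[st].format(step=fail_step))
        step0 += nb

    state.step += n_steps
    state.temperature = t_end
    if not snapshots:
        return None
    return Trajectory(frames=frames[:n_written],
                      frame_steps=frame_steps[:n_written],
                      potential_energy=log_pe[:n_written],
                      kinetic_energy=log_ke[:n_written],
                      kinetic_temperature=log_temp[:n_written],
                      beads=[], container=container, seed=seed)


def anneal(state: SimulationState, topology: Topology, container: Container,
           params: ForceFieldParams,
           config: SimulationConfig) -> SimulationState:
    """Ramp the thermostat linearly from ``anneal_from`` to ``anneal_to``.

    With ``anneal_steps == 0`` the target is set directly without dynamics.
    """
    steps = config.resolved_anneal_steps
    if steps == 0:
        state.temperature = config.anneal_to
        return state
    _integrate(state, topology, container, params, config, steps,
               config.anneal_from, config.anneal_to,
               seed=_derive_seed(config.seed, 1), snapshots=False,
               limit_steps=steps)
    return state


def run(state: SimulationState, topology: Topology, container: Container,
        params: ForceFieldParams, config: SimulationConfig,
        nve: bool = False, seed: int | None = None) -> Trajectory:
    """Production run at constant ``anneal_to`` temperature.

    ``nve`` disables the thermostat (energy-conservation testing).
    Snapshots every ``snapshot_interval`` steps; frame count is
    floor(n_steps / snapshot_interval).
    """
    t = state.temperature if nve else config.anneal_to
    traj = _integrate(state, topology, container, params, config,
                      config.n_steps, t, t,
                      seed=_derive_seed(config.seed, 2)
                      if seed is None else seed,
                      snapshots=True, nve=nve)
    assert traj is not None
    return traj


def _derive_seed(master: int, salt: int) -> int:
    return int(np.random.SeedSequence([master, salt]).generate_state(1)[0]
               & 0x7FFFFFFF)


def simulate_chain(beads: Sequence[BeadAnnotation], params: ForceFieldParams,
                   config: SimulationConfig, container: Container,
                   topology: Topology | None = None,
                   replica_seed: int | None = None) -> Trajectory:
    """Init → anneal → run for one replica; the common full pipeline."""
    if topology is None:
        topology = build_topology(beads, params)
    seed = config.seed if replica_seed is None else replica_seed
    rep_cfg = dc_replace(config, seed=seed)
    state = init_conformation(beads, container,
                              seed=_derive_seed(seed, 0),
                              temperature=config.anneal_from)
    anneal(state, topology, container, params, rep_cfg)
    traj = run(state, topology, container, params, rep_cfg)
    traj.beads = list(beads)
    traj.seed = seed
    return traj


def run_replicas(beads: Sequence[BeadAnnotation], params: ForceFieldParams,
                 config: SimulationConfig,
                 container: Container | None = None) -> list[Trajectory]:
    """Independent replicas with seeds derived from the master seed.

    Each replica is fully determined by its derived seed, so results do not
    depend on execution order.
    """
    if config.n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if container is None:
        from .model import container_radius
        container = Container(radius=container_radius(len(beads)))
    topology = build_topology(beads, params)
    rep_seeds = [int(s & 0x7FFFFFFF) for s in
                 np.random.SeedSequence(config.seed).generate_state(
                     config.n_replicas)]
    return [simulate_chain(beads, params, config, container,
                           topology=topology, replica_seed=s)
            for s in rep_seeds]
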