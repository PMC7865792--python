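"""Force field, topology and container of the block-copolymer chromatin model.

Reduced units throughout: lengths in σ0 (one bead diameter, 150 nm), energies
in ε0 = k_B·T0 (~2.6 kJ/mol at T0 = 308 K), time in τ0 = σ0·sqrt(m/ε0) with
bead mass m = 1.

Terms
-----
* FENE backbone bonds between consecutive beads:
  U(r) = −0.5·K·R0²·ln(1 − (r/R0)²), divergent at r = R0.
* Truncated-and-shifted Lennard-Jones between every bead pair, with a
  class-dependent well depth (ε_PP ≥ ε_FF ≥ ε_PF) and cutoff 1.3 σ0 so an
  attraction exists only between beads effectively in contact.
* Harmonic bonds ε_b·r² (zero rest length) between consecutive TAD-boundary
  beads; F-TAD bonds are stiffer than P-TAD bonds (ε_FB > ε_PB).
* A spherical wall: LAD beads feel an attractive LJ toward the nearest wall
  point (strength ε_LC, cutoff 1.3 σ0); all other beads a purely repulsive
  WCA wall (cutoff 2^(1/6) σ0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import BeadAnnotation

__all__ = [
    "ForceFieldParams",
    "Topology",
    "Container",
    "fene_energy",
    "pair_energy",
    "boundary_bond_energy",
    "wall_energy",
    "build_topology",
    "container_radius",
    "total_energy_brute_force",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

# Physical constants for the unit bookkeeping only (never enter the dynamics).
KB_J_PER_K = 1.380649e-23
AVOGADRO = 6.02214076e23


def thermal_energy_kJ_per_mol(T_kelvin: float = 308.0) -> float:
    """k_B·T per mole in kJ/mol; ~2.6 at body temperature."""
    return KB_J_PER_K * T_kelvin * AVOGADRO / 1000.0


@dataclass(frozen=True)
class ForceFieldParams:
    """All interaction strengths and the unit system.

    Defaults are the reference parameter set (single-chromosome study);
    ``validate()`` enforces the physically motivated orderings rather than
    the constructor, so parameter sweeps outside the reference ranges remain
    possible when deliberate.
    """

    eps_pp: float = 4.6      # P–P pair well depth, ε0
    eps_ff: float = 4.3      # F–F pair well depth, ε0
    eps_pf: float = 3.0      # F–P pair well depth, ε0
    eps_pb: float = 0.2      # P-TAD boundary-bond stiffness, ε0/σ0²
    eps_fb: float = 0.4      # F-TAD boundary-bond stiffness, ε0/σ0²
    eps_lc: float = 6.7      # LAD–wall well depth, ε0
    eps_wall_rep: float = 1.0  # repulsive wall strength (WCA; any ε works)
    sigma0_nm: float = 150.0
    rc_pair: float = 1.3     # σ0
    rc_wall_lad: float = 1.3  # σ0
    rc_wall_other: float = WCA_CUTOFF  # σ0
    fene_K: float = 30.0     # ε0/σ0²
    fene_R0: float = 1.5     # σ0
    T0_kelvin: float = 308.0

    def validate(self) -> None:
        if not (self.eps_pp >= self.eps_ff >= self.eps_pf):
            raise ValueError("expected ordering eps_pp >= eps_ff >= eps_pf")
        if not (self.eps_fb > self.eps_pb):
            raise ValueError("expected eps_fb > eps_pb")
        for name in ("eps_pb", "eps_fb"):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5) ε0")
        if not 6.0 <= self.eps_lc <= 8.0:
            raise ValueError("eps_lc must lie in [6.0, 8.0] ε0")
        for name in ("eps_pp", "eps_ff", "eps_pf"):
            v = getattr(self, name)
            if not 3.0 <= v <= 5.0:
                raise ValueError(f"{name} must lie in [3.0, 5.0] ε0")

    def pair_eps(self, class_i: str, class_j: str) -> float:
        if class_i == class_j:
            return self.eps_ff if class_i == "F" else self.eps_pp
        return self.eps_pf

    @property
    def eps0_kJ_per_mol(self) -> float:
        return thermal_energy_kJ_per_mol(self.T0_kelvin)


# ---------------------------------------------------------------------------
# Potential terms (scalar; the engine carries vectorised numba twins)
# ---------------------------------------------------------------------------

def fene_energy(r: float, params: ForceFieldParams | None = None,
                K: float | None = None, R0: float | None = None) -> float:
    """FENE bond energy; +inf at or beyond the divergence length R0."""
    if params is None:
        params = ForceFieldParams()
    K = params.fene_K if K is None else K
    R0 = params.fene_R0 if R0 is None else R0
    if r < 0:
        raise ValueError("r must be non-negative")
    if r >= R0:
        return math.inf
    return -0.5 * K * R0 * R0 * math.log(1.0 - (r / R0) ** 2)


def pair_energy(r: float, eps: float, rc: float) -> float:
    """Truncated-and-shifted LJ: zero at and beyond rc, continuous there."""
    if r <= 0:
        return math.inf
    if r >= rc:
        return 0.0
    inv6 = (1.0 / r) ** 6
    inv6c = (1.0 / rc) ** 6
    return 4.0 * eps * (inv6 * inv6 - inv6 - (inv6c * inv6c - inv6c))


def lj_well_depth(eps: float, rc: float = 1.3) -> float:
    """U(rc) − U(2^(1/6) σ0): depth of the truncated-shifted well."""
    return pair_energy(rc, eps, rc) - pair_energy(WCA_CUTOFF, eps, rc)


def boundary_bond_energy(r: float, eps_b: float) -> float:
    """Harmonic TAD-boundary bond, zero rest length: U = ε_b·r²."""
    return eps_b * r * r


def wall_energy(d: float, is_lad: bool,
                params: ForceFieldParams | None = None) -> float:
    """Energy of a bead at distance ``d`` (σ0) from the spherical wall.

    LAD beads are attracted (LJ, cutoff 1.3 σ0); all others are repelled
    (WCA, cutoff 2^(1/6) σ0).  d ≤ 0 (at or outside the wall) is divergent.
    """
    if params is None:
        params = ForceFieldParams()
    if d <= 0:
        return math.inf
    if is_lad:
        return pair_energy(d, params.eps_lc, params.rc_wall_lad)
    return pair_energy(d, params.eps_wall_rep, params.rc_wall_other)


# ---------------------------------------------------------------------------
# Topology and container
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Bond lists and per-bead interaction classes derived from annotation.

    ``backbone_bonds``: FENE bonds between consecutive same-chain beads.
    ``boundary_bonds``: (i, j, 'F-TAD' | 'P-TAD') between consecutive
    TAD-boundary beads of the same chain.
    ``bead_class`` / ``is_lad`` / ``chain_id`` are per-bead arrays.
    """

    backbone_bonds: list[tuple[int, int]]
    boundary_bonds: list[tuple[int, int, str]]
    bead_class: np.ndarray    # '<U1' array of 'F'/'P'
    is_lad: np.ndarray        # bool
    chain_id: np.ndarray      # int

    @property
    def n_beads(self) -> int:
        return len(self.bead_class)

    def pair_class(self, i: int, j: int) -> str:
        a, b = sorted((self.bead_class[i], self.bead_class[j]))
        return {"FF": "FF", "PP": "PP", "FP": "PF"}[a + b]

    def wall_class(self, i: int) -> str:
        return "LAD-attractive" if self.is_lad[i] else "repulsive"


@dataclass(frozen=True)
class Container:
    """Spherical confinement of radius R (σ0) at volume fraction phi."""

    radius: float
    phi: float = 0.05

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def container_radius(n_beads: int, phi: float = 0.05,
                     override: float | None = None) -> float:
    """Sphere radius (σ0) holding ``n_beads`` at volume fraction ``phi``.

    Bead volume convention: a sphere of diameter σ0, so
    R = (n·(σ0/2)³/φ)^(1/3).  ``override`` pins R directly (used to match a
    published radius when the bead-volume convention differs).
    """
    if override is not None:
        if override <= 0:
            raise ValueError("override radius must be positive")
        return float(override)
    if n_beads < 1:
        raise ValueError("need at least one bead")
    if not 0.0 < phi < 0.74:
        raise ValueError("phi must lie in (0, 0.74)")
    return float((n_beads * 0.5 ** 3 / phi) ** (1.0 / 3.0))


def build_topology(beads: Sequence[BeadAnnotation],
                   params: ForceFieldParams | None = None) -> Topology:
    """Derive the bonded topology from a sorted bead annotation.

    FENE bonds join consecutive beads of the same chain; harmonic bonds join
    consecutive TAD-boundary beads of the same chain, classed F-TAD when
    strictly more than half of the spanned beads (endpoints included) are F,
    else P-TAD.
    """
    beads = list(beads)
    order = sorted(range(len(beads)),
                   key=lambda k: (beads[k].chain_id, beads[k].bin_index))
    if order != list(range(len(beads))):
        raise ValueError("beads must be sorted by (chain, bin)")

    chain_ids = np.array([b.chain_id for b in beads])
    for cid in np.unique(chain_ids):
        if (chain_ids == cid).sum() < 2:
            raise ValueError(f"chain {cid} has fewer than 2 beads")

    backbone = [(i, i + 1) for i in range(len(beads) - 1)
                if beads[i].chain_id == beads[i + 1].chain_id]

    boundary_bonds = []
    b_idx = [i for i, b in enumerate(beads) if b.is_tad_boundary]
    for i, j in zip(b_idx, b_idx[1:]):
        if beads[i].chain_id != beads[j].chain_id:
            continue
        span = beads[i:j + 1]
        n_f = sum(1 for b in span if b.domain_class == "F")
        cls = "F-TAD" if 2 * n_f > len(span) else "P-TAD"
        boundary_bonds.append((i, j, cls))

    return Topology(
        backbone_bonds=backbone,
        boundary_bonds=boundary_bonds,
        bead_class=np.array([b.domain_class for b in beads]),
        is_lad=np.array([b.is_lad for b in beads], dtype=bool),
        chain_id=chain_ids,
    )


def total_energy_brute_force(coords: np.ndarray, topology: Topology,
                             container: Container,
                             params: ForceFieldParams) -> float:
    """Term-wise O(N²) total potential energy; the independent oracle for
    the engine's vectorised evaluation."""
    n = topology.n_beads
    e = 0.0
    for i, j in topology.backbone_bonds:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e += fene_energy(r, params)
    for i, j, cls in topology.boundary_bonds:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        eps_b = params.eps_fb if cls == "F-TAD" else params.eps_pb
        e += boundary_bond_energy(r, eps_b)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            eps = params.pair_eps(topology.bead_class[i],
                                  topology.bead_class[j])
            e += pair_energy(r, eps, params.rc_pair)
    for i in range(n):
        d = container.radius - float(np.linalg.norm(coords[i]))
        e += wall_energy(d, bool(topology.is_lad[i]), params)
    return e
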