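"""LAMMPS export: data file plus input script for the production protocol.

The native engine is meant for desk-scale runs; the published protocol
(2×10⁸ steps) is exported here for LAMMPS.  Atom types encode (class, LAD):
1 = F, 2 = P, 3 = F·LAD, 4 = P·LAD.  Bond types: 1 = FENE backbone,
2 = F-TAD boundary, 3 = P-TAD boundary.  The harmonic boundary bond
ε_b·r² maps onto LAMMPS ``bond_style harmonic`` with K = ε_b and r0 = 0;
the FENE bond is exported with its LJ part zeroed since the type-dependent
pair potential already acts on bonded neighbours (special_bonds lj 1 1 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Container, ForceFieldParams, Topology

__all__ = ["export_lammps", "parse_lammps_data"]

ATOM_TYPE = {("F", False): 1, ("P", False): 2, ("F", True): 3, ("P", True): 4}
BOND_TYPE = {"backbone": 1, "F-TAD": 2, "P-TAD": 3}


def export_lammps(topology: Topology, container: Container,
                  params: ForceFieldParams, outdir: str | Path,
                  coords: np.ndarray | None = None,
                  n_steps: int = 200_000_000,
                  anneal_steps: int = 20_000_000,
                  dump_interval: int = 10_000,
                  seed: int = 1) -> tuple[Path, Path]:
    """Write ``chromatin.data`` and ``chromatin.in`` into ``outdir``.

    ``coords`` defaults to a straight line per chain (LAMMPS minimization /
    annealing relaxes it); pass engine-initialized coordinates for a
    self-avoiding start.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = topology.n_beads
    if coords is None:
        coords = _default_coords(topology)
    if coords.shape != (n, 3):
        raise ValueError("coords shape mismatch")

    data_path = outdir / "chromatin.data"
    _write_data(data_path, topology, container, params, coords)
    script_path = outdir / "chromatin.in"
    _write_script(script_path, container, params, n_steps, anneal_steps,
                  dump_interval, seed)
    return data_path, script_path


def _default_coords(topology: Topology) -> np.ndarray:
    coords = np.zeros((topology.n_beads, 3))
    chains = topology.chain_id
    for k, cid in enumerate(np.unique(chains)):
        idx = np.where(chains == cid)[0]
        coords[idx, 0] = np.arange(len(idx)) - len(idx) / 2.0
        coords[idx, 1] = 1.5 * k
    return coords


def _write_data(path: Path, topology: Topology, container: Container,
                params: ForceFieldParams, coords: np.ndarray) -> None:
    n = topology.n_beads
    bonds = ([(BOND_TYPE["backbone"], i, j)
              for i, j in topology.backbone_bonds]
             + [(BOND_TYPE[c], i, j)
                for i, j, c in topology.boundary_bonds])
    L = container.radius + 1.0
    lines = [
        "LAMMPS data file: block-copolymer chromatin model (reduced units)",
        "",
        f"{n} atoms",
        f"{len(bonds)} bonds",
        "",
        "4 atom types",
        "3 bond types",
        "",
        f"{-L:.6f} {L:.6f} xlo xhi",
        f"{-L:.6f} {L:.6f} ylo yhi",
        f"{-L:.6f} {L:.6f} zlo zhi",
        "",
        "Masses",
        "",
        "1 1.0",
        "2 1.0",
        "3 1.0",
        "4 1.0",
        "",
        "Atoms # molecular",
        "",
    ]
    for i in range(n):
        at = ATOM_TYPE[(str(topology.bead_class[i]),
                        bool(topology.is_lad[i]))]
        mol = int(topology.chain_id[i]) + 1
        x, y, z = coords[i]
        lines.append(f"{i + 1} {mol} {at} {x:.8f} {y:.8f} {z:.8f}")
    lines += ["", "Bonds", ""]
    for b, (bt, i, j) in enumerate(bonds, start=1):
        lines.append(f"{b} {bt} {i + 1} {j + 1}")
    path.write_text("\n".join(lines) + "\n")


def _write_script(path: Path, container: Container,
                  params: ForceFieldParams, n_steps: int, anneal_steps: int,
                  dump_interval: int, seed: int) -> None:
    p = params
    wca = 2.0 ** (1.0 / 6.0)
    eps = {  # pair coeff per atom-type pair; types 1/3 are F, 2/4 are P
        (1, 1): p.eps_ff, (1, 3): p.eps_ff, (3, 3): p.eps_ff,
        (2, 2): p.eps_pp, (2, 4): p.eps_pp, (4, 4): p.eps_pp,
        (1, 2): p.eps_pf, (1, 4): p.eps_pf, (2, 3): p.eps_pf,
        (3, 4): p.eps_pf,
    }
    lines = [
        "# Block-copolymer chromatin model: annealing + production run",
        "units lj",
        "atom_style molecular",
        "boundary f f f",
        "read_data chromatin.data",
        "",
        "# FENE backbone (LJ part zeroed: pair potential covers 1-2 pairs)",
        "bond_style hybrid fene harmonic",
        f"bond_coeff 1 fene {p.fene_K} {p.fene_R0} 0.0 1.0",
        f"bond_coeff 2 harmonic {p.eps_fb} 0.0",
        f"bond_coeff 3 harmonic {p.eps_pb} 0.0",
        "special_bonds lj 1.0 1.0 1.0",
        "",
        f"pair_style lj/cut {p.rc_pair}",
        "pair_modify shift yes",
    ]
    for (a, b), e in sorted(eps.items()):
        lines.append(f"pair_coeff {a} {b} {e} 1.0 {p.rc_pair}")
    lines += [
        "",
        f"region nucleus sphere 0 0 0 {container.radius} side in",
        "# LAD beads (types 3,4): attractive wall; others: repulsive",
        "group lads type 3 4",
        "group nonlads type 1 2",
        f"fix wall_lad lads wall/region nucleus lj126 "
        f"{p.eps_lc} 1.0 {p.rc_wall_lad}",
        f"fix wall_rep nonlads wall/region nucleus lj126 "
        f"{p.eps_wall_rep} 1.0 {wca:.8f}",
        "",
        "neighbor 0.3 bin",
        "neigh_modify every 1 delay 0 check yes",
        f"timestep 0.01",
        "",
        "fix integrate all nve",
        f"fix thermo_anneal all langevin 5.0 1.0 1.0 {seed}",
        f"run {anneal_steps}",
        "unfix thermo_anneal",
        f"fix thermo all langevin 1.0 1.0 1.0 {seed + 1}",
        "",
        f"dump traj all custom {dump_interval} traj.lammpstrj id type x y z",
        "dump_modify traj sort id",
        f"thermo {dump_interval}",
        f"run {n_steps}",
    ]
    path.write_text("\n".join(lines) + "\n")


def parse_lammps_data(path: str | Path) -> dict:
    """Parse a data file written by ``export_lammps`` back into topology
    pieces (0-based indices); the round-trip identity check."""
    text = Path(path).read_text().splitlines()
    section = None
    atoms = {}
    bonds = []
    for line in text:
        stripped = line.split("#")[0].strip()
        if not stripped:
            continue
        if stripped.startswith(("Masses", "Atoms", "Bonds", "Velocities")):
            section = stripped.split()[0]
            continue
        if section == "Atoms":
            parts = stripped.split()
            aid = int(parts[0])
            atoms[aid] = {
                "mol": int(parts[1]),
                "type": int(parts[2]),
                "xyz": (float(parts[3]), float(parts[4]), float(parts[5])),
            }
        elif section == "Bonds":
            parts = stripped.split()
            bonds.append((int(parts[1]), int(parts[2]) - 1,
                          int(parts[3]) - 1))
    n = len(atoms)
    order = sorted(atoms)
    inv_atom = {v: k for k, v in ATOM_TYPE.items()}
    bead_class = np.array([inv_atom[atoms[i]["type"]][0] for i in order])
    is_lad = np.array([inv_atom[atoms[i]["type"]][1] for i in order])
    chain_id = np.array([atoms[i]["mol"] - 1 for i in order])
    coords = np.array([atoms[i]["xyz"] for i in order])
    backbone = [(i, j) for t, i, j in bonds if t == BOND_TYPE["backbone"]]
    boundary = [(i, j, "F-TAD" if t == BOND_TYPE["F-TAD"] else "P-TAD")
                for t, i, j in bonds if t != BOND_TYPE["backbone"]]
    return {
        "n_atoms": n,
        "bead_class": bead_class,
        "is_lad": is_lad,
        "chain_id": chain_id,
        "coords": coords,
        "backbone_bonds": backbone,
        "boundary_bonds": boundary,
    }
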