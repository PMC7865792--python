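"""Trajectory I/O: extended-XYZ text frames and an HDF5 container.

The XYZ species column carries the bead class with LAD marking (F, P, FL,
PL); the comment line stores the step number and container radius, so a
trajectory file is self-describing enough to re-run the analysis.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .annotation import BeadAnnotation
from .engine import Trajectory
from .model import Container

__all__ = ["write_xyz", "read_xyz", "write_hdf5", "read_hdf5"]


def _species(b: BeadAnnotation) -> str:
    return b.domain_class + ("L" if b.is_lad else "")


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        n = traj.n_beads
        species = [_species(b) for b in traj.beads] if traj.beads \
            else ["X"] * n
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"step={traj.frame_steps[f]} "
                     f"radius={traj.container.radius:.8f}\n")
            for i in range(n):
                x, y, z = traj.frames[f, i]
                fh.write(f"{species[i]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read frames back: (frames, frame_steps, container_radius)."""
    frames = []
    steps = []
    radius = 0.0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            fields = dict(kv.split("=") for kv in comment.split())
            steps.append(int(fields.get("step", len(frames))))
            radius = float(fields.get("radius", 0.0))
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append(coords)
    return np.array(frames), np.array(steps), radius


def write_hdf5(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=traj.frames, compression="gzip")
        h5.create_dataset("frame_steps", data=traj.frame_steps)
        h5.create_dataset("potential_energy", data=traj.potential_energy)
        h5.create_dataset("kinetic_energy", data=traj.kinetic_energy)
        h5.create_dataset("kinetic_temperature",
                          data=traj.kinetic_temperature)
        h5.attrs["container_radius"] = traj.container.radius
        h5.attrs["container_phi"] = traj.container.phi
        h5.attrs["seed"] = traj.seed
        if traj.beads:
            h5.create_dataset(
                "bead_class",
                data=np.array([b.domain_class for b in traj.beads], "S1"))
            h5.create_dataset(
                "is_lad", data=np.array([b.is_lad for b in traj.beads]))
            h5.create_dataset(
                "is_tad_boundary",
                data=np.array([b.is_tad_boundary for b in traj.beads]))
            h5.create_dataset(
                "chain_id", data=np.array([b.chain_id for b in traj.beads]))


def read_hdf5(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        container = Container(radius=float(h5.attrs["container_radius"]),
                              phi=float(h5.attrs["container_phi"]))
        beads = []
        if "bead_class" in h5:
            cls = [c.decode() for c in h5["bead_class"][:]]
            lad = h5["is_lad"][:]
            tad = h5["is_tad_boundary"][:]
            cid = h5["chain_id"][:]
            beads = [BeadAnnotation(chain_id=int(cid[i]), bin_index=i,
                                    domain_class=cls[i],
                                    is_lad=bool(lad[i]),
                                    is_tad_boundary=bool(tad[i]),
                                    source_bp_start=i * 100_000)
                     for i in range(len(cls))]
        return Trajectory(
            frames=h5["frames"][:],
            frame_steps=h5["frame_steps"][:],
            potential_energy=h5["potential_energy"][:],
            kinetic_energy=h5["kinetic_energy"][:],
            kinetic_temperature=h5["kinetic_temperature"][:],
            beads=beads,
            container=container,
            seed=int(h5.attrs["seed"]),
        )
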