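"""Conformation and trajectory I/O: XYZ, PDB (one pseudo-atom per bead).

XYZ round-trips bit-exactly at the printed precision; PDB export writes one
C1' pseudo-atom per nucleotide with residue numbering equal to strand
position, which most molecular viewers display as a bead chain.
"""

from __future__ import annotations

import numpy as np

from .bd import Trajectory
from .geometry import Conformation

__all__ = ["write_xyz", "read_xyz", "write_xyz_trajectory", "write_pdb"]


def write_xyz(conf, path, comment: str = "rnabd conformation") -> None:
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    with open(path, "w") as fh:
        _write_xyz_frame(fh, coords, comment)


def _write_xyz_frame(fh, coords, comment) -> None:
    fh.write(f"{len(coords)}\n{comment}\n")
    for x, y, z in coords:
        fh.write(f"C {x:.3f} {y:.3f} {z:.3f}\n")


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.snapshots):
            _write_xyz_frame(fh, frame, f"t = {t:.1f} ps")


def read_xyz(path) -> Conformation:
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        coords = np.array([
            [float(v) for v in fh.readline().split()[1:4]] for _ in range(n)
        ])
    return Conformation(coords)


def write_pdb(conf, path, chain_id: str = "A") -> None:
    from Bio.PDB import PDBIO, StructureBuilder

    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("bead")
    sb.init_model(0)
    sb.init_chain(chain_id)
    sb.init_seg("    ")
    for k, xyz in enumerate(coords, start=1):
        sb.init_residue("  N", " ", k, " ")
        sb.init_atom("C1'", np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                     "C1'", k, element="C")
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))
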