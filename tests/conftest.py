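"""Shared fixtures: hand-written PDB text and small topology builders."""

import numpy as np
import pytest

from bindkin.featurize import Topology, Trajectory


def pdb_line(record, serial, name, resname, chain, resseq, x, y, z,
             element, altloc=" ", occupancy=1.0):
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


@pytest.fixture
def write_pdb(tmp_path):
    def _write(lines, name="test.pdb"):
        path = tmp_path / name
        path.write_text("".join(lines) + "END\n")
        return path

    return _write


def make_topology(entries, ligand_resname=None):
    """entries: list of (name, element, resseq, resname, chain)."""
    name, element, resseq, resname, chain = (np.array(x) for x in zip(*entries))
    _, inv = np.unique(
        [f"{c}|{r}" for c, r in zip(chain, resseq)], return_inverse=True
    )
    # dense residue index preserving file order
    order = {}
    res_index = np.empty(len(entries), dtype=int)
    for i, key in enumerate(f"{c}|{r}" for c, r in zip(chain, resseq)):
        if key not in order:
            order[key] = len(order)
        res_index[i] = order[key]
    top = Topology(
        name=name, element=element, res_index=res_index,
        res_seq=resseq.astype(int), res_name=resname, chain_id=chain,
    )
    if ligand_resname:
        top.set_ligand_by_resname(ligand_resname)
    return top


@pytest.fixture
def simple_system():
    """One GLY residue (N, CA, C) plus a single-nitrogen ligand.

    Returns a builder: give the ligand position and get a Trajectory.
    """

    def _build(ligand_positions):
        entries = [
            ("N", "N", 1, "GLY", "A"),
            ("CA", "C", 1, "GLY", "A"),
            ("C", "C", 1, "GLY", "A"),
            ("N1", "N", 10, "LIG", "L"),
        ]
        top = make_topology(entries, ligand_resname="LIG")
        lig = np.atleast_2d(np.asarray(ligand_positions, dtype=float))
        frames = []
        for pos in lig:
            frames.append(
                np.array(
                    [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [3.0, 0.0, 0.0], pos]
                )
            )
        return Trajectory(top, np.array(frames))

    return _build
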