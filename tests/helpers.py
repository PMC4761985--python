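"""Shared test helpers: PDB fixture text, random structures, and the
brute-force neighbor-search oracle.

The oracle is written independently of the package's extraction path
(pure-python nested loops, its own atom tables) so that agreement with
``extract_pairs`` is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np

from polarframe import Atom, Residue, build_ideal_residue, random_rigid_transform

# --- independent tables for the oracle (deliberately re-stated) -----------

_ORACLE_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_ORACLE_DEFINING = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("CD", "CE", "NZ"),
}
_ORACLE_ANCHORS = {"ARG": ("CZ", "NH1", "NH2"), "LYS": ("NZ", "CE", "CD")}


def brute_force_pairs(residues, central_type, cutoff):
    """All (central_index, neighbor_index) -> min_dist by exhaustive scan."""
    out = {}
    for i, central in enumerate(residues):
        if central.res_type != central_type:
            continue
        names = {a.name for a in central.atoms}
        if not all(n in names for n in _ORACLE_ANCHORS[central_type]):
            continue
        defin = [a.xyz for a in central.atoms if a.name in _ORACLE_DEFINING[central_type]]
        if not defin:
            continue
        for j, nb in enumerate(residues):
            if j == i or nb.res_type == "GLY":
                continue
            best = math.inf
            for a in nb.atoms:
                if a.name in _ORACLE_BACKBONE:
                    continue
                for d in defin:
                    dist = math.dist(tuple(a.xyz), tuple(d))
                    if dist < best:
                        best = dist
            if best <= cutoff:
                out[(i, j)] = best
    return out


# --- fixture builders ------------------------------------------------------

def atom_line(serial, name, res, chain, seq, xyz, occ=1.0, altloc=" ",
              element=None, record="ATOM  "):
    """Format one fixed-width PDB ATOM record (test-local formatter)."""
    el = element if element is not None else name.lstrip("0123456789")[0]
    pname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {pname}{altloc}{res:<3s} {chain}{seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{20.0:6.2f}"
        f"          {el:>2s}"
    )


def residue_pdb_text(residue, serial_start=1, record="ATOM  "):
    lines = []
    for k, a in enumerate(residue.atoms):
        lines.append(
            atom_line(
                serial_start + k, a.name, residue.res_type, residue.chain_id,
                residue.seq_num, a.xyz, occ=a.occupancy,
                altloc=a.altloc or " ", element=a.element, record=record,
            )
        )
    return "\n".join(lines) + "\n"


_NEIGHBOR_ATOMS = {
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "SER": ("CB", "OG"),
    "VAL": ("CB", "CG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "GLY": (),
}


def random_blob_residue(rng, res_type, chain_id="A", seq_num=50):
    """A residue with the right atom names at random positions in a blob.

    Geometric realism is irrelevant for search-correctness tests; only
    atom naming and spatial spread matter.
    """
    center = rng.uniform(-8.0, 8.0, size=3)
    atoms = [
        Atom(name=n, element=n[0], xyz=center + rng.normal(scale=1.5, size=3))
        for n in _NEIGHBOR_ATOMS[res_type]
    ]
    # glycine and friends still need backbone atoms to be a residue at all
    for n in ("N", "CA", "C", "O"):
        atoms.append(Atom(name=n, element=n[0], xyz=center + rng.normal(scale=1.5, size=3)))
    return Residue(res_type=res_type, chain_id=chain_id, seq_num=seq_num, atoms=atoms)


def random_structure(seed, n_neighbors=8):
    """One ideal Arg + one ideal Lys under random poses, plus random
    neighbor residues scattered in and out of contact range."""
    rng = np.random.default_rng(seed)
    residues = []
    arg = build_ideal_residue("ARG", seq_num=10)
    lys = build_ideal_residue("LYS", 1.5, seq_num=30)
    lys = lys.transformed(lambda x: x + np.array([12.0, 0.0, 0.0]))
    pose = random_rigid_transform(rng)
    residues.append(arg.transformed(pose.apply))
    residues.append(lys.transformed(pose.apply))
    types = list(_NEIGHBOR_ATOMS)
    for k in range(n_neighbors):
        res_type = types[int(rng.integers(len(types)))]
        residues.append(
            random_blob_residue(rng, res_type, seq_num=50 + k).transformed(pose.apply)
        )
    return residues
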