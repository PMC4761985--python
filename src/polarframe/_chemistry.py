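"""Static amino-acid chemistry tables shared across the package.

Atom naming follows PDB v3 conventions. Only heavy atoms are listed;
hydrogens are dropped at parse time and never re-enter the pipeline.
"""

from __future__ import annotations

#: The 20 standard amino acids (3-letter codes).
STANDARD_AA: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Backbone heavy atoms excluded from every side-chain selection.
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

#: Side-chain heavy atoms per residue type. CB counts as side chain.
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

#: Central-residue atoms against which neighbor distances are measured.
#: For Arg this is the guanidinium plus NE; for Lys the terminal CD-CE-NZ.
DEFINING_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("CD", "CE", "NZ"),
}

#: Neighbor residue types considered around a central Arg/Lys: every
#: standard amino acid except glycine (which has no side chain).
NON_GLY_TYPES: tuple[str, ...] = tuple(sorted(STANDARD_AA - {"GLY"}))

#: Named atom-class selectors used by the shell filters and density maps.
#: Maps selector name -> residue type -> atom-name set. A residue type
#: absent from a selector simply contributes no atoms.
ATOM_SELECTORS: dict[str, dict[str, frozenset[str]]] = {
    "sidechain-heavy": {rt: frozenset(a) for rt, a in SIDE_CHAIN_ATOMS.items() if a},
    "sidechain-C": {
        rt: frozenset(n for n in atoms if n.startswith("C"))
        for rt, atoms in SIDE_CHAIN_ATOMS.items()
        if any(n.startswith("C") for n in atoms)
    },
    "carboxylate-O": {
        "ASP": frozenset({"OD1", "OD2"}),
        "GLU": frozenset({"OE1", "OE2"}),
    },
    "amide-O": {"ASN": frozenset({"OD1"}), "GLN": frozenset({"OE1"})},
    "amide-N": {"ASN": frozenset({"ND2"}), "GLN": frozenset({"NE2"})},
    "hydroxyl-O": {
        "SER": frozenset({"OG"}),
        "THR": frozenset({"OG1"}),
        "TYR": frozenset({"OH"}),
    },
    "S": {"MET": frozenset({"SD"}), "CYS": frozenset({"SG"})},
    "indole-N": {"TRP": frozenset({"NE1"})},
}


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a PDB heavy-atom name.

    Heavy side-chain/backbone atom names start with the element letter
    (C, N, O, S); leading digits (as in some hydrogen names) are stripped.
    """
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()
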