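"""Reading and writing of chain lists, PDB files and per-pair files.

The domain model is deliberately small: an :class:`Atom` is a named point
with occupancy/altloc metadata, a :class:`Residue` is a typed atom
collection, and a :class:`ChainRecord` identifies one culled chain.  All
PDB parsing and formatting goes through gemmi; this module only applies
the pipeline's selection policies on top (model 1 only, standard amino
acids, hydrogens dropped, altlocs resolved to the highest-occupancy
conformer).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

from ._chemistry import BACKBONE_ATOMS, STANDARD_AA, element_of
from .errors import ChainNotFoundError

logger = logging.getLogger(__name__)

# First token of a Pisces data line: 4-char PDB id (leading digit) + chain.
_CHAIN_TOKEN = re.compile(r"^\d[A-Za-z0-9]{3}[A-Za-z0-9]+$")


@dataclass(frozen=True)
class ChainRecord:
    """One culled PDB chain (Pisces-style list entry)."""

    pdb_id: str
    chain_id: str

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise ValueError(f"pdb_id must have 4 characters, got {self.pdb_id!r}")
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")


@dataclass
class Atom:
    """A heavy atom: PDB name, element symbol and Cartesian position (A)."""

    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    """A standard amino-acid residue with resolved (unique-name) atoms."""

    res_type: str
    chain_id: str
    seq_num: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.res_type} {self.seq_num}: no atom {name!r}")

    def has_atoms(self, names: Iterable[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def coords(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.atom(n).xyz for n in names])

    def transformed(self, fn) -> "Residue":
        """Return a copy with ``fn`` applied to every atom position."""
        return replace(
            self,
            atoms=[replace(a, xyz=fn(a.xyz)) for a in self.atoms],
        )


def parse_chain_list(text: str, errors: list[str] | None = None) -> list[ChainRecord]:
    """Parse Pisces-style chain-list text into :class:`ChainRecord` rows.

    The first whitespace-delimited token of each data line is a PDB-ID
    plus chain string (e.g. ``1ABCA``).  Header lines (token not matching
    the id pattern) are skipped; malformed tokens shorter than 5
    characters are collected into ``errors`` (and logged) rather than
    aborting the parse.
    """
    records: list[ChainRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        token = tokens[0]
        if len(token) < 5:
            msg = f"line {lineno}: malformed chain token {token!r}"
            logger.warning(msg)
            if errors is not None:
                errors.append(msg)
            continue
        if not _CHAIN_TOKEN.match(token):
            continue  # header line
        records.append(ChainRecord(pdb_id=token[:4].lower(), chain_id=token[4:]))
    return records


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken
    by alphabetical altloc code."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or (a.occupancy, _neg_ord(a.altloc)) > (
            prev.occupancy,
            _neg_ord(prev.altloc),
        ):
            by_name[a.name] = a
    return list(by_name.values())


def _neg_ord(altloc: str) -> int:
    # Higher key wins in the comparison above, so negate the code point
    # to prefer alphabetically-earlier altlocs on occupancy ties.
    return -ord(altloc) if altloc else 0


def _convert_residue(res: gemmi.Residue, chain_id: str) -> Residue | None:
    if res.name not in STANDARD_AA:
        return None
    if res.het_flag == "H":  # HETATM (incl. waters, MSE): excluded
        return None
    atoms: list[Atom] = []
    for at in res:
        if at.element.is_hydrogen:
            continue
        try:
            atoms.append(
                Atom(
                    name=at.name,
                    element=at.element.name if at.element.name != "X" else element_of(at.name),
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    altloc=at.altloc if at.altloc != "\x00" else "",
                )
            )
        except ValueError as exc:  # unreadable record: skip, keep going
            logger.warning("skipping atom in %s %s: %s", res.name, res.seqid.num, exc)
    if not atoms:
        return None
    return Residue(
        res_type=res.name,
        chain_id=chain_id,
        seq_num=res.seqid.num,
        icode=res.seqid.icode.strip() or "",
        atoms=_resolve_altlocs(atoms),
    )


def load_chain(pdb_text: str, chain_id: str) -> list[Residue]:
    """Read one chain from PDB-format text.

    Returns the standard amino-acid residues of the named chain, model 1
    only, hydrogens dropped, altlocs resolved to a single conformer, and
    HETATM records (waters, modified residues) excluded.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ChainNotFoundError(f"chain {chain_id!r} not found (empty structure)")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain {chain_id!r} not found")
    residues = []
    for res in chain:
        conv = _convert_residue(res, chain_id)
        if conv is not None:
            residues.append(conv)
    return residues


def load_all_residues(pdb_text: str) -> list[Residue]:
    """Read every standard amino-acid residue of model 1, all chains."""
    st = gemmi.read_pdb_string(pdb_text)
    residues: list[Residue] = []
    if len(st) == 0:
        return residues
    for chain in st[0]:
        for res in chain:
            conv = _convert_residue(res, chain.name)
            if conv is not None:
                residues.append(conv)
    return residues


def residues_to_pdb_string(residues: Sequence[Residue], *, side_chain_only: bool = False) -> str:
    """Format residues as PDB ATOM records (via gemmi, 3-decimal coords)."""
    st = gemmi.Structure()
    st.name = "polarframe"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in residues:
        chain = chains.get(r.chain_id)
        if chain is None:
            chain = gemmi.Chain(r.chain_id)
            chains[r.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = r.res_type
        gres.het_flag = "A"  # always ATOM records, never HETATM
        gres.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
        atoms = r.side_chain_atoms() if side_chain_only else r.atoms
        for a in atoms:
            if a.element in ("H", "D"):
                continue
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element)
            gat.pos = gemmi.Position(*a.xyz)
            gat.occ = a.occupancy
            gres.add_atom(gat)
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    return st.make_pdb_string(opts)


def write_pair_file(pair) -> str:
    """Serialize an interaction pair (canonical frame) to PDB-like text.

    Only side-chain heavy atoms of both residues are written; backbone
    N/CA/C/O/OXT and hydrogens never appear in pair files.
    """
    return residues_to_pdb_string([pair.central, pair.neighbor], side_chain_only=True)


def read_pair_file(pdb_text: str) -> list[Residue]:
    """Re-read a per-pair file written by :func:`write_pair_file`."""
    return load_all_residues(pdb_text)


def pair_file_name(pair) -> str:
    """Canonical pair-file name: <pdbid>_<chain>_<central><seq>_<neighbor><seq>.pdb."""
    p = pair.provenance
    suffix = "_nhswap" if getattr(pair, "nh_swapped", False) else ""
    return (
        f"{p.pdb_id or 'xxxx'}_{p.chain_id}_"
        f"{pair.central.res_type}{p.central_seq}_"
        f"{pair.neighbor.res_type}{p.neighbor_seq}{suffix}.pdb"
    )
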