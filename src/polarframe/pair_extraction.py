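"""Extraction of central-Arg/Lys interaction pairs from parsed chains.

For every central arginine or lysine, every non-glycine residue whose
side chain comes within the distance cutoff (default 5 A) of the central
defining-atom set (Arg: NE, CZ, NH1, NH2; Lys: CD, CE, NZ) yields one
:class:`InteractionPair`, with both residues expressed in the canonical
frame.  The neighbor search uses a k-d tree; its contract is exactness,
which the test suite checks against a brute-force all-pairs scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._chemistry import DEFINING_ATOMS, NON_GLY_TYPES
from .canonical_frame import FrameDefinition, RigidTransform, to_canonical_frame
from .errors import MissingAnchorError
from .structure_io import Residue

logger = logging.getLogger(__name__)

__all__ = [
    "Provenance",
    "InteractionPair",
    "ExtractionReport",
    "extract_pairs",
    "count_interactions",
    "count_table_to_tsv",
]


@dataclass(frozen=True)
class Provenance:
    pdb_id: str
    chain_id: str
    central_seq: int
    neighbor_seq: int


@dataclass
class InteractionPair:
    """A central residue and one neighbor, both in the canonical frame."""

    central: Residue
    neighbor: Residue
    min_dist: float
    provenance: Provenance
    transform: RigidTransform | None = None
    nh_swapped: bool = False  # symmetrized duplicate with NH1/NH2 exchanged


@dataclass
class ExtractionReport:
    """Per-run accounting: every skipped residue has a recorded reason."""

    centrals_seen: int = 0
    centrals_used: int = 0
    skipped: list[str] = field(default_factory=list)

    def skip(self, reason: str) -> None:
        logger.warning(reason)
        self.skipped.append(reason)


def defining_coords(residue: Residue, mode: str = "defining") -> np.ndarray:
    """Coordinates of the central atoms distances are measured against.

    ``mode="defining"`` uses the terminal defining-atom set;
    ``mode="all-sidechain"`` uses every side-chain heavy atom.
    """
    if mode == "defining":
        names = [n for n in DEFINING_ATOMS[residue.res_type]]
        present = {a.name for a in residue.atoms}
        return np.array([residue.atom(n).xyz for n in names if n in present])
    if mode == "all-sidechain":
        return np.array([a.xyz for a in residue.side_chain_atoms()])
    raise ValueError(f"unknown distance mode {mode!r}")


def extract_pairs(
    residues: Sequence[Residue],
    frame: FrameDefinition,
    cutoff: float = 5.0,
    *,
    pdb_id: str = "",
    distance_mode: str = "defining",
    exclude_seq_delta: int = 0,
    method: str = "pinned",
    symmetrize_nh: bool = False,
    include_backbone_neighbors: bool = False,
    report: ExtractionReport | None = None,
) -> list[InteractionPair]:
    """Find all interaction pairs for central residues of ``frame.res_type``.

    Parameters
    ----------
    residues:
        Residues of one chain (the default search is within-chain).
    frame:
        Canonical-frame definition selecting the central residue type.
    cutoff:
        Maximum distance (A) between a neighbor side-chain heavy atom and
        the central defining-atom set.
    exclude_seq_delta:
        If > 0, neighbors with ``|seq_num difference| <= k`` are excluded
        (sequence-adjacent residues are included by default).
    symmetrize_nh:
        For Arg centrals, additionally emit each pair with the NH1/NH2
        labels exchanged (for label-free densities; off by default since
        deposited NH labels carry reportable signal).
    include_backbone_neighbors:
        Also consider neighbor backbone heavy atoms in the distance
        search (off by default: the survey is side-chain-only).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if report is None:
        report = ExtractionReport()

    # candidate neighbor side-chain atoms, flattened with residue index
    cand_xyz: list[np.ndarray] = []
    cand_res: list[int] = []
    for i, res in enumerate(residues):
        if res.res_type == "GLY":
            continue
        atoms = res.atoms if include_backbone_neighbors else res.side_chain_atoms()
        for a in atoms:
            cand_xyz.append(a.xyz)
            cand_res.append(i)
    pairs: list[InteractionPair] = []
    tree = cKDTree(np.asarray(cand_xyz)) if cand_xyz else None
    cand_xyz_arr = np.asarray(cand_xyz) if cand_xyz else np.empty((0, 3))
    cand_res_arr = np.asarray(cand_res, dtype=int) if cand_res else np.empty(0, dtype=int)

    for ci, central in enumerate(residues):
        if central.res_type != frame.res_type:
            continue
        report.centrals_seen += 1
        if not central.has_atoms(frame.anchor_atoms):
            report.skip(
                f"{pdb_id} {central.chain_id} {central.res_type}{central.seq_num}: "
                "missing anchor atom(s), skipped"
            )
            continue
        try:
            dcoords = defining_coords(central, distance_mode)
        except KeyError:
            dcoords = np.empty((0, 3))
        if dcoords.size == 0:
            report.skip(
                f"{pdb_id} {central.chain_id} {central.res_type}{central.seq_num}: "
                "no defining atoms, skipped"
            )
            continue
        report.centrals_used += 1
        if tree is None:
            continue
        # min distance from each candidate atom to the defining set
        hit_res: dict[int, float] = {}
        for d in dcoords:
            idx = tree.query_ball_point(d, cutoff)
            if not idx:
                continue
            dists = np.linalg.norm(cand_xyz_arr[idx] - d, axis=1)
            for j, dist in zip(idx, dists):
                if dist > cutoff:
                    continue
                ri = int(cand_res_arr[j])
                if dist < hit_res.get(ri, np.inf):
                    hit_res[ri] = float(dist)
        for ri in sorted(hit_res):
            neighbor = residues[ri]
            if ri == ci:
                continue
            if (
                exclude_seq_delta > 0
                and neighbor.chain_id == central.chain_id
                and abs(neighbor.seq_num - central.seq_num) <= exclude_seq_delta
            ):
                continue
            try:
                c_t, (n_t,), tf = to_canonical_frame(
                    central, [neighbor], frame, method=method
                )
            except MissingAnchorError as exc:
                report.skip(str(exc))
                continue
            prov = Provenance(
                pdb_id=pdb_id,
                chain_id=central.chain_id,
                central_seq=central.seq_num,
                neighbor_seq=neighbor.seq_num,
            )
            pairs.append(
                InteractionPair(
                    central=c_t, neighbor=n_t, min_dist=hit_res[ri],
                    provenance=prov, transform=tf,
                )
            )
            if symmetrize_nh and frame.res_type == "ARG":
                swapped = _swap_nh_labels(central)
                c_s, (n_s,), tf_s = to_canonical_frame(
                    swapped, [neighbor], frame, method=method
                )
                pairs.append(
                    InteractionPair(
                        central=c_s, neighbor=n_s, min_dist=hit_res[ri],
                        provenance=prov, transform=tf_s, nh_swapped=True,
                    )
                )
    return pairs


def _swap_nh_labels(res: Residue) -> Residue:
    exchange = {"NH1": "NH2", "NH2": "NH1"}
    return replace(
        res, atoms=[replace(a, name=exchange.get(a.name, a.name)) for a in res.atoms]
    )


def count_interactions(pairs: Iterable[InteractionPair]) -> pd.DataFrame:
    """Tally pairs into a (central type x 19 non-Gly neighbor types) table.

    Returns a DataFrame with rows ARG, LYS and one column per neighbor
    type; every cell is a non-negative count and the grand total equals
    the number of pairs.
    """
    table = pd.DataFrame(
        0, index=["ARG", "LYS"], columns=list(NON_GLY_TYPES), dtype=int
    )
    for p in pairs:
        table.loc[p.central.res_type, p.neighbor.res_type] += 1
    return table


def count_table_to_tsv(table: pd.DataFrame) -> str:
    """Long-format TSV (central_type, neighbor_type, n_pairs) with marginals."""
    lines = ["central_type\tneighbor_type\tn_pairs"]
    for central in table.index:
        for neighbor in table.columns:
            lines.append(f"{central}\t{neighbor}\t{table.loc[central, neighbor]}")
        lines.append(f"{central}\tTOTAL\t{int(table.loc[central].sum())}")
    lines.append(f"ALL\tTOTAL\t{int(table.values.sum())}")
    return "\n".join(lines) + "\n"
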