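"""Synthetic PDB fixtures with known ground truth.

Every pipeline stage can be exercised without downloading structures:
this module builds ideal central Arg/Lys residues whose anchor atoms sit
exactly on the canonical reference coordinates, plants neighbor side
chains whose contact atom lies at a controlled (r, theta, psi) in the
canonical frame, moves the whole assembly by a seeded random rigid pose,
and emits PDB-format text together with a ground-truth ledger.

Population generation mixes three angular components — axial caps
(above/below the plane), equatorial bands (in-plane, with azimuthal
modes at the guanidinium N-H sector directions by default), and a
uniform-sphere control — so the qualitative Arg-vs-Lys segregation of
non-polar and polar contacts can be planted and recovered.

Geometry realism is deliberately limited to what the frame analysis
needs: anchor geometry is exact, remaining atoms sit at fixed idealized
positions, and neighbor side chains extend radially outward from their
contact atom.  Rotamer realism, packing and waters are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._chemistry import SIDE_CHAIN_ATOMS, element_of
from .canonical_frame import FRAME_REGISTRY, RigidTransform
from .errors import ConfigurationError, StericClashError
from .polar_analysis import polar_to_cartesian
from .structure_io import Atom, Residue, residues_to_pdb_string

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "AxialCap",
    "EquatorialBand",
    "UniformSphere",
    "PopulationSpec",
    "PopulationResult",
    "build_ideal_residue",
    "plant_pair",
    "generate_population",
    "write_population",
    "random_rigid_transform",
    "arg_like_population",
    "lys_like_population",
]

#: Minimum allowed distance between heavy atoms of *different* residues.
CLASH_LIMIT = 1.5

#: Default anchor scale (frame units -> A) per central type.
DEFAULT_ANCHOR_SCALE = {"ARG": 1.33, "LYS": 1.0}

#: Conventional contact atom per neighbor type (terminal functional atom).
DEFAULT_CONTACT_ATOM = {
    "ALA": "CB", "ARG": "NH1", "ASN": "OD1", "ASP": "OD1", "CYS": "SG",
    "GLN": "OE1", "GLU": "OE1", "HIS": "NE2", "ILE": "CD1", "LEU": "CD1",
    "LYS": "NZ", "MET": "SD", "PHE": "CZ", "PRO": "CG", "SER": "OG",
    "THR": "OG1", "TRP": "NE1", "TYR": "OH", "VAL": "CG1",
}

# Idealized non-anchor coordinates (canonical frame, A).  Bonded
# distances are realistic (~1.2-1.55 A); anchors are appended scaled.
_ARG_FIXED = {
    "NE": (-1.33, 0.0, 0.0),
    "CD": (-2.146, 1.210, 0.0),
    "CG": (-3.55, 1.05, 0.60),
    "CB": (-4.30, 2.25, 1.05),
    "CA": (-5.66, 2.12, 1.74),
    "N": (-6.71, 1.80, 0.80),
    "C": (-6.05, 3.41, 2.51),
    "O": (-5.32, 3.80, 3.42),
}
_LYS_FIXED = {
    "CG": (-2.63, 1.10, 0.72),
    "CB": (-3.35, 2.40, 0.95),
    "CA": (-4.80, 2.35, 1.45),
    "N": (-5.72, 1.95, 0.38),
    "C": (-5.25, 3.70, 2.05),
    "O": (-4.62, 4.18, 3.00),
}
_FIXED_COORDS = {"ARG": _ARG_FIXED, "LYS": _LYS_FIXED}


def build_ideal_residue(
    res_type: str,
    bond_scale: float | None = None,
    *,
    chain_id: str = "A",
    seq_num: int = 10,
) -> Residue:
    """Ideal central residue in its own canonical frame.

    Anchor atoms sit exactly at ``reference_coords * bond_scale`` (the
    guanidinium plane is exactly z = 0 for Arg); the remaining side-chain
    and backbone atoms sit at fixed idealized positions.
    """
    res_type = res_type.upper()
    frame = FRAME_REGISTRY.get(res_type)
    if frame is None:
        raise ConfigurationError(f"no frame definition for residue type {res_type!r}")
    scale = DEFAULT_ANCHOR_SCALE[res_type] if bond_scale is None else float(bond_scale)
    if scale <= 0:
        raise ConfigurationError("bond_scale must be positive")
    atoms: list[Atom] = []
    anchor_names = set(frame.anchor_atoms)
    for name, ref in zip(frame.anchor_atoms, frame.reference):
        atoms.append(Atom(name=name, element=element_of(name), xyz=np.asarray(ref) * scale))
    for name, xyz in _FIXED_COORDS[res_type].items():
        if name in anchor_names:
            continue
        atoms.append(Atom(name=name, element=element_of(name), xyz=np.array(xyz)))
    return Residue(res_type=res_type, chain_id=chain_id, seq_num=seq_num, atoms=atoms)


def random_rigid_transform(rng: np.random.Generator, box: float = 20.0) -> RigidTransform:
    """Seeded random pose: rotation uniform over SO(3) (normalized
    Gaussian quaternion) and translation uniform in a ``box``-A cube."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-box / 2.0, box / 2.0, size=3)
    return RigidTransform(rotation=R, translation=t)


@dataclass(frozen=True)
class PlantSpec:
    """One planted pair: a contact atom at (r, theta, psi) in the frame."""

    central_type: str = "ARG"
    neighbor_type: str = "LEU"
    contact_atom: str | None = None
    r: float = 3.5
    theta: float = 45.0
    psi: float = 0.0
    pose_seed: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ConfigurationError("r must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ConfigurationError("theta must be in [0, 180]")
        if not -180.0 < self.psi <= 180.0:
            raise ConfigurationError("psi must be in (-180, 180]")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")


@dataclass
class PlantedPair:
    """A generated structure in two forms: full-precision residues and
    PDB text (whose coordinates are quantized to 1e-3 A by the format)."""

    central: "Residue"
    neighbor: "Residue"
    pdb_text: str
    truth: "GroundTruth"

    @property
    def residues(self) -> list["Residue"]:
        return [self.central, self.neighbor]


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, recorded alongside each generated structure."""

    central_type: str
    neighbor_type: str
    contact_atom: str
    r: float
    theta: float
    psi: float
    expected_min_dist: float
    central_seq: int
    neighbor_seq: int
    component: str = ""


def _neighbor_residue(
    neighbor_type: str,
    contact_atom: str,
    contact_pos: np.ndarray,
    *,
    chain_id: str = "A",
    seq_num: int = 20,
) -> Residue:
    """Neighbor residue whose contact atom sits at ``contact_pos``;
    all other atoms extend radially outward (strictly farther from the
    frame origin and from the central defining set)."""
    names = SIDE_CHAIN_ATOMS.get(neighbor_type)
    if names is None or not names:
        raise ConfigurationError(f"cannot plant neighbor of type {neighbor_type!r}")
    if contact_atom not in names:
        raise ConfigurationError(
            f"{contact_atom!r} is not a side-chain atom of {neighbor_type}"
        )
    u = contact_pos / np.linalg.norm(contact_pos)
    atoms = [Atom(name=contact_atom, element=element_of(contact_atom), xyz=contact_pos)]
    others = [n for n in names if n != contact_atom] + ["CA", "N", "C", "O"]
    for k, name in enumerate(others, start=1):
        atoms.append(
            Atom(name=name, element=element_of(name), xyz=contact_pos + 1.6 * k * u)
        )
    return Residue(res_type=neighbor_type, chain_id=chain_id, seq_num=seq_num, atoms=atoms)


def _min_interresidue_dist(a: Residue, b: Residue) -> float:
    pa = np.array([at.xyz for at in a.atoms])
    pb = np.array([at.xyz for at in b.atoms])
    return float(np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)))


def plant_pair(
    spec: PlantSpec,
    rng: np.random.Generator | None = None,
    *,
    component: str = "",
) -> PlantedPair:
    """Generate one structure with a neighbor planted at (r, theta, psi).

    The ideal central residue is built in its canonical frame, the
    neighbor's contact atom is placed at the requested spherical-polar
    position, optional isotropic Gaussian jitter is added, and the whole
    assembly is moved by a seeded random rigid pose.  Returns the posed
    residues, the PDB text and the ground truth (including the expected
    minimum distance from the contact atom to the defining-atom set).
    """
    if rng is None:
        rng = np.random.default_rng(spec.pose_seed)
    central = build_ideal_residue(spec.central_type, seq_num=10)
    contact_atom = spec.contact_atom or DEFAULT_CONTACT_ATOM[spec.neighbor_type]
    contact_pos = polar_to_cartesian(spec.r, spec.theta, spec.psi)
    neighbor = _neighbor_residue(spec.neighbor_type, contact_atom, contact_pos, seq_num=20)

    if _min_interresidue_dist(central, neighbor) < CLASH_LIMIT:
        raise StericClashError(
            f"contact atom at r={spec.r}, theta={spec.theta}, psi={spec.psi} "
            f"clashes with the central {spec.central_type} (< {CLASH_LIMIT} A)"
        )

    from .pair_extraction import defining_coords  # local import avoids cycle

    dcoords = defining_coords(central)
    dists = np.linalg.norm(dcoords - contact_pos, axis=1)
    expected_min = float(np.min(dists))
    # the contact atom must be the unique closest neighbor atom
    for a in neighbor.atoms[1:]:
        d = float(np.min(np.linalg.norm(dcoords - a.xyz, axis=1)))
        if d <= expected_min:
            raise StericClashError(
                f"planted geometry not monotone: atom {a.name} as close as contact"
            )

    if spec.jitter_sd > 0:
        central = central.transformed(
            lambda xyz: xyz + rng.normal(scale=spec.jitter_sd, size=3)
        )
        neighbor = neighbor.transformed(
            lambda xyz: xyz + rng.normal(scale=spec.jitter_sd, size=3)
        )
    pose = random_rigid_transform(rng)
    central = central.transformed(pose.apply)
    neighbor = neighbor.transformed(pose.apply)

    truth = GroundTruth(
        central_type=spec.central_type,
        neighbor_type=spec.neighbor_type,
        contact_atom=contact_atom,
        r=spec.r,
        theta=spec.theta,
        psi=spec.psi,
        expected_min_dist=expected_min,
        central_seq=10,
        neighbor_seq=20,
        component=component,
    )
    return PlantedPair(
        central=central,
        neighbor=neighbor,
        pdb_text=residues_to_pdb_string([central, neighbor]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# population generation


@dataclass(frozen=True)
class AxialCap:
    """Above/below-plane component: theta inside a polar cap, psi uniform."""

    weight: float = 1.0
    cap_deg: float = 45.0
    neighbor_type: str = "LEU"
    contact_atom: str | None = None
    label: str = "axial"

    def draw_angles(self, rng: np.random.Generator) -> tuple[float, float]:
        u = rng.uniform(np.cos(np.radians(self.cap_deg)), 1.0)
        theta = float(np.degrees(np.arccos(u)))
        if rng.random() < 0.5:
            theta = 180.0 - theta
        psi = float(rng.uniform(-180.0, 180.0))
        return theta, psi if psi != -180.0 else 180.0


@dataclass(frozen=True)
class EquatorialBand:
    """In-plane component: theta in 90 +/- band, psi clustered at modes.

    The default psi modes (60, -60, 180 deg) are the three N-H sector
    directions of the guanidinium in the canonical frame, mimicking
    in-plane hydrogen-bonding geometry; the spread is Gaussian.
    """

    weight: float = 1.0
    band_deg: float = 20.0
    psi_modes: tuple[float, ...] = (60.0, -60.0, 180.0)
    psi_sd: float = 15.0
    neighbor_type: str = "ASP"
    contact_atom: str | None = None
    label: str = "equatorial"

    def draw_angles(self, rng: np.random.Generator) -> tuple[float, float]:
        theta = float(rng.uniform(90.0 - self.band_deg, 90.0 + self.band_deg))
        mode = self.psi_modes[rng.integers(len(self.psi_modes))]
        psi = float(mode + rng.normal(scale=self.psi_sd))
        psi = ((psi + 180.0) % 360.0) - 180.0
        return theta, psi if psi != -180.0 else 180.0


@dataclass(frozen=True)
class UniformSphere:
    """Isotropic control component: directions uniform on the sphere."""

    weight: float = 1.0
    neighbor_type: str = "LEU"
    contact_atom: str | None = None
    label: str = "uniform"

    def draw_angles(self, rng: np.random.Generator) -> tuple[float, float]:
        u = rng.uniform(-1.0, 1.0)
        theta = float(np.degrees(np.arccos(u)))
        psi = float(rng.uniform(-180.0, 180.0))
        return theta, psi if psi != -180.0 else 180.0


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of angular components defining a synthetic population."""

    n_pairs: int
    components: tuple = (AxialCap(),)
    central_type: str = "ARG"
    r_range: tuple[float, float] = (3.0, 4.5)
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ConfigurationError("n_pairs must be positive")
        total = sum(c.weight for c in self.components)
        if not self.components or abs(total - 1.0) > 1e-9:
            raise ConfigurationError("component weights must sum to 1")
        if not 0 < self.r_range[0] < self.r_range[1]:
            raise ConfigurationError("r_range must satisfy 0 < lo < hi")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["components"] = [
            {"kind": type(c).__name__, **asdict(c)} for c in self.components
        ]
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class PopulationResult:
    """Generated structures plus the ground-truth ledger."""

    names: list[str]
    pairs: list[PlantedPair]
    spec: PopulationSpec
    ledger: pd.DataFrame = field(init=False)

    @property
    def pdb_texts(self) -> list[str]:
        return [p.pdb_text for p in self.pairs]

    @property
    def truths(self) -> list[GroundTruth]:
        return [p.truth for p in self.pairs]

    def __post_init__(self) -> None:
        rows = []
        for name, t in zip(self.names, self.truths):
            row = asdict(t)
            row["name"] = name
            rows.append(row)
        cols = [
            "name", "component", "central_type", "neighbor_type", "contact_atom",
            "r", "theta", "psi", "expected_min_dist", "central_seq", "neighbor_seq",
        ]
        self.ledger = pd.DataFrame(rows, columns=cols)


def generate_population(spec: PopulationSpec) -> PopulationResult:
    """Draw ``n_pairs`` planted structures from the mixture.

    Fully deterministic: a fixed seed yields byte-identical PDB text and
    an identical ledger across runs.  Draws that would clash sterically
    (contact radius too small for the sampled direction) are retried
    with a fresh direction from the same stream.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components], dtype=float)
    weights /= weights.sum()
    names, planted = [], []
    for i in range(spec.n_pairs):
        # the component is drawn once per pair; steric retries redraw only
        # the angles within it, so mixture weights are honored exactly
        k = int(rng.choice(len(spec.components), p=weights))
        comp = spec.components[k]
        for _attempt in range(100):
            theta, psi = comp.draw_angles(rng)
            r = float(rng.uniform(*spec.r_range))
            plant = PlantSpec(
                central_type=spec.central_type,
                neighbor_type=comp.neighbor_type,
                contact_atom=comp.contact_atom,
                r=r,
                theta=theta,
                psi=psi,
                jitter_sd=spec.jitter_sd,
            )
            try:
                pair = plant_pair(plant, rng, component=comp.label)
                break
            except StericClashError:
                continue
        else:
            raise StericClashError(
                f"could not place pair {i} without a clash after 100 attempts"
            )
        names.append(f"synth_{i:05d}")
        planted.append(pair)
    return PopulationResult(names=names, pairs=planted, spec=spec)


def write_population(result: PopulationResult, out_dir: str | Path) -> Path:
    """Write PDB files, the ground-truth ledger CSV, and the echoed spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, text in zip(result.names, result.pdb_texts):
        (out / f"{name}.pdb").write_text(text)
    result.ledger.to_csv(out / "ledger.csv", index=False)
    (out / "population_spec.json").write_text(result.spec.to_json() + "\n")
    return out


def arg_like_population(
    n_pairs: int = 1000,
    seed: int = 0,
    axial_weight: float = 0.6,
) -> PopulationSpec:
    """Arg-like study condition: non-polar contacts axial (Leu carbons
    above/below the guanidinium plane), polar contacts equatorial (Asp
    carboxylate oxygens in-plane at the N-H directions)."""
    return PopulationSpec(
        n_pairs=n_pairs,
        components=(
            AxialCap(weight=axial_weight, neighbor_type="LEU", label="axial-nonpolar"),
            EquatorialBand(
                weight=1.0 - axial_weight, neighbor_type="ASP", label="equatorial-polar"
            ),
        ),
        central_type="ARG",
        seed=seed,
    )


def lys_like_population(
    n_pairs: int = 1000,
    seed: int = 0,
    nonpolar_weight: float = 0.6,
) -> PopulationSpec:
    """Lys-like study condition: both non-polar and polar contacts
    spherically uniform around the terminal amino group."""
    return PopulationSpec(
        n_pairs=n_pairs,
        components=(
            UniformSphere(weight=nonpolar_weight, neighbor_type="LEU", label="uniform-nonpolar"),
            UniformSphere(weight=1.0 - nonpolar_weight, neighbor_type="ASP", label="uniform-polar"),
        ),
        central_type="LYS",
        seed=seed,
    )
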