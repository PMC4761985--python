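"""Spherical-polar analysis of canonical-frame neighbor atoms.

Conventions (degrees throughout): theta is the angle from the +z axis,
so 90 deg lies in the x-y plane (the guanidinium plane for Arg) and
180 deg is the -z direction; psi is the rotation about z measured from
+x, in (-180, 180].  The polar origin is the frame origin atom (CZ for
Arg, NZ for Lys), while distance cutoffs are measured against the
defining-atom set — the two deliberately differ, and the choice of
origin atom does affect the resulting distributions.

Note that equal-area distortion is inherent in a psi x theta plot: bins
near theta = 0 or 180 deg subtend less solid angle than equatorial bins.
Density maps therefore carry raw counts by default, with an optional
1/sin(theta) solid-angle weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._chemistry import ATOM_SELECTORS
from .errors import ConfigurationError, UndefinedFractionError
from .pair_extraction import InteractionPair, Provenance, defining_coords
from .structure_io import Atom

__all__ = [
    "PolarPoint",
    "DensityMap",
    "spherical_polar",
    "polar_to_cartesian",
    "closest_atom_polar",
    "shell_filter",
    "resolve_selector",
    "build_density",
    "axial_fraction",
    "subsample_pairs",
    "polar_points_to_frame",
]


@dataclass(frozen=True)
class PolarPoint:
    """One neighbor atom in spherical-polar coordinates (r in A, angles deg)."""

    r: float
    theta: float
    psi: float
    atom_name: str
    neighbor_res_type: str
    min_dist: float = float("nan")
    provenance: Provenance | None = None


def spherical_polar(xyz: Sequence[float]) -> tuple[float, float, float]:
    """(x,y,z) -> (r, theta, psi) in the frame's convention.

    r is the Euclidean norm; theta = arccos(z/r) in degrees; psi =
    atan2(y, x) in degrees.  On the z-axis (and at the origin) psi is
    defined as 0; at the origin theta is defined as 0.
    """
    x, y, z = (float(v) for v in xyz)
    r = float(np.sqrt(x * x + y * y + z * z))
    if r == 0.0:
        return 0.0, 0.0, 0.0
    theta = float(np.degrees(np.arccos(np.clip(z / r, -1.0, 1.0))))
    if x == 0.0 and y == 0.0:
        return r, theta, 0.0
    psi = float(np.degrees(np.arctan2(y, x)))
    if psi <= -180.0:
        psi = 180.0
    return r, theta, psi


def polar_to_cartesian(r: float, theta: float, psi: float) -> np.ndarray:
    """Inverse of :func:`spherical_polar` (angles in degrees)."""
    th, ps = np.radians(theta), np.radians(psi)
    return np.array(
        [
            r * np.sin(th) * np.cos(ps),
            r * np.sin(th) * np.sin(ps),
            r * np.cos(th),
        ]
    )


def _neighbor_distances(pair: InteractionPair, mode: str = "defining") -> list[tuple[float, Atom]]:
    """(min distance to the defining set, atom) for each neighbor side-chain atom."""
    dcoords = defining_coords(pair.central, mode)
    out = []
    for a in pair.neighbor.side_chain_atoms():
        d = float(np.min(np.linalg.norm(dcoords - a.xyz, axis=1)))
        out.append((d, a))
    return out


def closest_atom_polar(
    pair: InteractionPair,
    cutoff: float = 6.0,
    *,
    distance_mode: str = "defining",
) -> PolarPoint | None:
    """Polar coordinates of the closest neighbor heavy atom, or None.

    The closest atom is the neighbor side-chain heavy atom with minimal
    distance to the central defining-atom set (ties broken by atom-name
    order); its (r, theta, psi) are measured from the frame origin.
    Returns None when every neighbor atom lies beyond ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cand = _neighbor_distances(pair, distance_mode)
    if not cand:
        return None
    d, atom = min(cand, key=lambda t: (t[0], t[1].name))
    if d > cutoff:
        return None
    r, theta, psi = spherical_polar(atom.xyz)
    return PolarPoint(
        r=r,
        theta=theta,
        psi=psi,
        atom_name=atom.name,
        neighbor_res_type=pair.neighbor.res_type,
        min_dist=d,
        provenance=pair.provenance,
    )


Selector = Callable[[str, str], bool]


def resolve_selector(selector) -> Selector:
    """Turn a selector spec into a predicate(res_type, atom_name).

    Accepts a registered selector name (e.g. ``"carboxylate-O"``), a
    ``"RES:atom"``/``"RES:selector"`` string restricted to one residue
    type, or a callable.
    """
    if callable(selector):
        return selector
    if not isinstance(selector, str):
        raise ConfigurationError(f"bad selector {selector!r}")
    if ":" in selector:
        res_type, sub = selector.split(":", 1)
        res_type = res_type.upper()
        if sub in ATOM_SELECTORS:
            table = ATOM_SELECTORS[sub]
            return lambda rt, an: rt == res_type and an in table.get(rt, frozenset())
        # explicit atom-name list, comma separated
        names = frozenset(s.strip().upper() for s in sub.split(","))
        return lambda rt, an: rt == res_type and an in names
    if selector in ATOM_SELECTORS:
        table = ATOM_SELECTORS[selector]
        return lambda rt, an: an in table.get(rt, frozenset())
    raise ConfigurationError(f"unknown atom selector {selector!r}")


def shell_filter(
    pair: InteractionPair,
    atom_selector,
    d_min: float,
    d_max: float,
    *,
    distance_mode: str = "defining",
) -> list[tuple[Atom, float]]:
    """Neighbor atoms of a class within a half-open distance shell.

    Returns (atom, distance) for neighbor atoms matching the selector
    whose minimum distance to the defining set lies in (d_min, d_max].
    Half-open intervals make consecutive shells (e.g. 3.75 A and 4.5 A)
    partition the atoms exactly once.
    """
    if not 0 <= d_min < d_max:
        raise ValueError("require 0 <= d_min < d_max")
    pred = resolve_selector(atom_selector)
    rt = pair.neighbor.res_type
    out = []
    for d, atom in _neighbor_distances(pair, distance_mode):
        if pred(rt, atom.name) and d_min < d <= d_max:
            out.append((atom, d))
    return out


@dataclass
class DensityMap:
    """2-D histogram of polar points over the psi x theta angular grid."""

    psi_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray  # shape (n_psi_bins, n_theta_bins)
    weighted: bool
    n_points: int

    @property
    def psi_centers(self) -> np.ndarray:
        return 0.5 * (self.psi_edges[:-1] + self.psi_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def theta_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.T,
            index=pd.Index(self.theta_centers, name="theta_deg"),
            columns=pd.Index(self.psi_centers, name="psi_deg"),
        )


def build_density(
    points: Iterable[PolarPoint],
    psi_bin: float = 5.0,
    theta_bin: float = 5.0,
    solid_angle_weighting: bool = False,
) -> DensityMap:
    """Bin polar points into a psi x theta density map.

    Bin widths must divide 360 and 180 degrees.  With solid-angle
    weighting each bin count is divided by sin(theta_center), guarded
    below by sin(theta_bin / 2), compensating the smaller Cartesian
    volume subtended near the poles.
    """
    if psi_bin <= 0 or theta_bin <= 0 or 360 % psi_bin or 180 % theta_bin:
        raise ValueError("bin widths must be positive divisors of 360 and 180")
    psi_edges = np.arange(-180.0, 180.0 + psi_bin / 2, psi_bin)
    theta_edges = np.arange(0.0, 180.0 + theta_bin / 2, theta_bin)
    pts = list(points)
    if pts:
        psi = np.array([p.psi for p in pts])
        theta = np.array([p.theta for p in pts])
        counts, _, _ = np.histogram2d(psi, theta, bins=[psi_edges, theta_edges])
    else:
        counts = np.zeros((len(psi_edges) - 1, len(theta_edges) - 1))
    n = len(pts)
    if solid_angle_weighting:
        centers = 0.5 * (theta_edges[:-1] + theta_edges[1:])
        guard = np.sin(np.radians(theta_bin / 2.0))
        w = np.maximum(np.sin(np.radians(centers)), guard)
        counts = counts / w[np.newaxis, :]
    else:
        counts = counts.astype(int)
    return DensityMap(
        psi_edges=psi_edges,
        theta_edges=theta_edges,
        counts=counts,
        weighted=solid_angle_weighting,
        n_points=n,
    )


def axial_fraction(points: Iterable[PolarPoint], theta_cap: float = 45.0) -> float:
    """Fraction of points in the axial caps (theta < cap or > 180 - cap).

    Quantifies the above/below-plane vs in-plane segregation of neighbor
    atoms: an isotropic population gives 1 - cos(cap) (~0.293 for a
    45-degree cap), an all-axial population gives 1.
    """
    if not 0 < theta_cap < 90:
        raise ValueError("theta_cap must be in (0, 90) degrees")
    thetas = np.array([p.theta for p in points])
    if thetas.size == 0:
        raise UndefinedFractionError("axial fraction over an empty point set")
    axial = (thetas < theta_cap) | (thetas > 180.0 - theta_cap)
    return float(axial.mean())


def subsample_pairs(
    pairs: Sequence,
    max_n: int = 4000,
    policy: str = "first",
    seed: int | None = None,
) -> list:
    """Cap a pair list at ``max_n`` entries.

    ``policy="first"`` keeps the first ``max_n`` in extraction order (the
    default convention for large interaction classes); ``policy="random"``
    draws a seeded sample without replacement, preserving order.
    """
    if max_n <= 0:
        raise ValueError("max_n must be positive")
    pairs = list(pairs)
    if len(pairs) <= max_n:
        return pairs
    if policy == "first":
        return pairs[:max_n]
    if policy == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(pairs), size=max_n, replace=False))
        return [pairs[i] for i in idx]
    raise ValueError(f"unknown subsample policy {policy!r}")


def polar_points_to_frame(points: Iterable[PolarPoint]) -> pd.DataFrame:
    """Tabulate polar points (one row per closest atom) for CSV export."""
    rows = []
    for p in points:
        prov = p.provenance
        rows.append(
            {
                "pdb_id": prov.pdb_id if prov else "",
                "chain": prov.chain_id if prov else "",
                "central_seq": prov.central_seq if prov else -1,
                "neighbor_seq": prov.neighbor_seq if prov else -1,
                "neighbor_res_type": p.neighbor_res_type,
                "atom": p.atom_name,
                "r": p.r,
                "theta": p.theta,
                "psi": p.psi,
                "min_dist": p.min_dist,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pdb_id", "chain", "central_seq", "neighbor_seq",
            "neighbor_res_type", "atom", "r", "theta", "psi", "min_dist",
        ],
    )
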