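"""Spherical-polar conventions, density maps and segregation summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polarframe import (
    ARG_FRAME,
    Atom,
    ConfigurationError,
    PlantSpec,
    PolarPoint,
    Residue,
    UndefinedFractionError,
    axial_fraction,
    build_density,
    build_ideal_residue,
    closest_atom_polar,
    extract_pairs,
    plant_pair,
    polar_to_cartesian,
    shell_filter,
    spherical_polar,
    subsample_pairs,
)


class TestSphericalPolar:
    @pytest.mark.parametrize(
        "xyz, expected",
        [
            ((1, 0, 0), (1.0, 90.0, 0.0)),
            ((0, 0, -1), (1.0, 180.0, 0.0)),
            ((0, 0, 2), (2.0, 0.0, 0.0)),
            ((0, 3, 0), (3.0, 90.0, 90.0)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_axis_conventions(self, xyz, expected):
        r, theta, psi = spherical_polar(xyz)
        assert (r, theta, psi) == pytest.approx(expected, abs=1e-12)

    @given(
        st.tuples(
            st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
        ).filter(lambda v: np.linalg.norm(v) > 1e-6)
    )
    def test_round_trip_to_cartesian(self, xyz):
        r, theta, psi = spherical_polar(xyz)
        assert 0 <= theta <= 180 and -180 < psi <= 180
        np.testing.assert_allclose(polar_to_cartesian(r, theta, psi), xyz, atol=1e-9)

    @given(
        st.tuples(
            st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
        ).filter(lambda v: np.linalg.norm(np.asarray(v)[:2]) > 1e-6)
    )
    def test_z_reflection_maps_theta_only(self, xyz):
        x, y, z = xyz
        r1, t1, p1 = spherical_polar((x, y, z))
        r2, t2, p2 = spherical_polar((x, y, -z))
        assert r2 == pytest.approx(r1, abs=1e-9)
        assert t2 == pytest.approx(180.0 - t1, abs=1e-9)
        assert p2 == pytest.approx(p1, abs=1e-9)


def _pair_with_neighbor_atoms(atoms, res_type="LEU"):
    """Canonical-frame pair with a hand-placed neighbor for unit tests."""
    from polarframe.pair_extraction import InteractionPair, Provenance

    central = build_ideal_residue("ARG")
    neighbor = Residue(res_type=res_type, chain_id="A", seq_num=20, atoms=atoms)
    dmin = min(
        float(np.min(np.linalg.norm(
            np.array([central.atom(n).xyz for n in ("NE", "CZ", "NH1", "NH2")])
            - a.xyz, axis=1)))
        for a in neighbor.side_chain_atoms()
    )
    return InteractionPair(
        central=central, neighbor=neighbor, min_dist=dmin,
        provenance=Provenance("test", "A", 10, 20),
    )


class TestClosestAtomPolar:
    def test_planted_contact_atom_recovered(self):
        planted = plant_pair(
            PlantSpec(r=3.5, theta=20.0, psi=45.0, pose_seed=8)
        )
        (pair,) = extract_pairs(planted.residues, ARG_FRAME, 5.0)
        point = closest_atom_polar(pair)
        assert point.atom_name == planted.truth.contact_atom
        assert point.r == pytest.approx(3.5, abs=1e-6)
        assert point.theta == pytest.approx(20.0, abs=1e-6)
        assert point.psi == pytest.approx(45.0, abs=1e-6)

    def test_equal_distance_tie_broken_by_atom_name(self):
        # CD1 and CD2 both exactly 4 A from CZ, symmetric about the plane
        atoms = [
            Atom(name="CD2", element="C", xyz=np.array([0.0, 0.0, -4.0])),
            Atom(name="CD1", element="C", xyz=np.array([0.0, 0.0, 4.0])),
        ]
        point = closest_atom_polar(_pair_with_neighbor_atoms(atoms))
        assert point.atom_name == "CD1"

    def test_all_atoms_beyond_cutoff_returns_none(self):
        atoms = [Atom(name="CD1", element="C", xyz=np.array([0.0, 0.0, 7.5]))]
        assert closest_atom_polar(_pair_with_neighbor_atoms(atoms), 6.0) is None


class TestShellFilter:
    def test_half_open_interval_membership(self):
        atoms = [
            Atom(name="CD1", element="C", xyz=np.array([0.0, 0.0, 4.0])),
            Atom(name="CD2", element="C", xyz=np.array([0.0, 0.0, 3.75])),
        ]
        pair = _pair_with_neighbor_atoms(atoms)
        got = shell_filter(pair, "sidechain-C", 3.75, 4.5)
        names = [a.name for a, _ in got]
        assert names == ["CD1"]  # 3.75 itself is excluded at the open end
        assert shell_filter(pair, "sidechain-C", 3.5, 3.75)[0][0].name == "CD2"

    def test_carboxylate_selector_returns_only_od_atoms(self):
        atoms = [
            Atom(name="OD1", element="O", xyz=np.array([3.0, 0.0, 0.0])),
            Atom(name="OD2", element="O", xyz=np.array([0.0, 3.2, 0.0])),
            Atom(name="CG", element="C", xyz=np.array([0.0, 0.0, 3.1])),
        ]
        pair = _pair_with_neighbor_atoms(atoms, res_type="ASP")
        got = shell_filter(pair, "carboxylate-O", 0.0, 3.5)
        assert sorted(a.name for a, _ in got) == ["OD1", "OD2"]

    def test_unknown_selector_is_configuration_error(self):
        pair = _pair_with_neighbor_atoms(
            [Atom(name="CD1", element="C", xyz=np.array([0.0, 0.0, 4.0]))]
        )
        with pytest.raises(ConfigurationError):
            shell_filter(pair, "no-such-class", 0.0, 4.5)


def _points(thetas, psis=None, r=3.5):
    psis = psis if psis is not None else np.zeros(len(thetas))
    return [
        PolarPoint(r=r, theta=float(t), psi=float(p), atom_name="CD1",
                   neighbor_res_type="LEU")
        for t, p in zip(thetas, psis)
    ]


class TestDensityMap:
    def test_empty_input_gives_zero_map(self):
        dmap = build_density([])
        assert dmap.counts.shape == (72, 36)
        assert dmap.counts.sum() == 0 and dmap.n_points == 0

    def test_unweighted_counts_conserved(self, rng):
        pts = _points(rng.uniform(0, 180, 500), rng.uniform(-179, 180, 500))
        dmap = build_density(pts)
        assert dmap.counts.sum() == 500 == dmap.n_points

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            build_density([], psi_bin=7.0)

    def test_in_plane_population_concentrates_at_90(self, rng):
        thetas = rng.uniform(88.0, 92.0, 400)
        dmap = build_density(_points(thetas, rng.uniform(-179, 180, 400)))
        marginal = dmap.theta_marginal()
        centers = dmap.theta_centers
        hot = marginal > 0
        assert np.all(np.abs(centers[hot] - 90.0) <= 5.0)

    def test_uniform_sphere_weighted_map_is_flat(self):
        rng = np.random.default_rng(2024)
        n = 100_000
        z = rng.uniform(-1, 1, n)
        thetas = np.degrees(np.arccos(z))
        psis = rng.uniform(-180, 180, n)
        dmap = build_density(_points(thetas, psis), solid_angle_weighting=True)
        # per-bin expected raw count from exact solid angles
        th_edges = np.radians(dmap.theta_edges)
        cap = np.cos(th_edges[:-1]) - np.cos(th_edges[1:])
        lam = n * (5.0 / 360.0) * cap / 2.0  # (psi fraction) * (z fraction)
        w = np.maximum(np.sin(np.radians(dmap.theta_centers)),
                       np.sin(np.radians(2.5)))
        raw = dmap.counts * w[np.newaxis, :]
        resid = np.abs(raw - lam[np.newaxis, :]) / np.sqrt(lam[np.newaxis, :])
        # 4 sigma is the per-bin noise scale; across ~2600 bins the max of
        # that many Poisson draws routinely grazes it, so flatness is
        # asserted as (a) a per-bin 4-sigma exceedance rate at the noise
        # level and (b) a Bonferroni-corrected bound on the worst bin.
        n_bins = resid.size
        assert (resid > 4.0).sum() <= max(3, int(0.005 * n_bins))
        assert resid.max() <= 6.0


class TestAxialFraction:
    def test_all_polar_points_axial(self):
        assert axial_fraction(_points([0.0] * 10), 45.0) == 1.0

    def test_all_equatorial_points_not_axial(self):
        assert axial_fraction(_points([90.0] * 10), 45.0) == 0.0

    def test_uniform_sphere_matches_cap_area(self):
        rng = np.random.default_rng(7)
        z = rng.uniform(-1, 1, 20_000)
        frac = axial_fraction(_points(np.degrees(np.arccos(z))), 45.0)
        expected = 1.0 - np.cos(np.radians(45.0))
        assert frac == pytest.approx(expected, abs=0.01)

    def test_empty_input_raises(self):
        with pytest.raises(UndefinedFractionError):
            axial_fraction([], 45.0)


class TestSubsample:
    def test_under_limit_returns_everything(self):
        assert subsample_pairs(list(range(3000)), 4000) == list(range(3000))

    def test_first_policy_keeps_extraction_order(self):
        out = subsample_pairs(list(range(5000)), 4000, policy="first")
        assert out == list(range(4000))

    def test_random_policy_is_seeded_and_order_preserving(self):
        a = subsample_pairs(list(range(5000)), 100, policy="random", seed=3)
        b = subsample_pairs(list(range(5000)), 100, policy="random", seed=3)
        assert a == b == sorted(a)
        assert len(set(a)) == 100
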