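import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepion.geometry import (
    GeometryError,
    HBondCriteria,
    assign_protons,
    detect_hbonds,
    dihedral,
    distance,
    angle,
    find_pseudocycle,
    kabsch_rmsd,
    side_chain_orientation,
    topology_of,
    Pseudocycle,
)
from pepion.systems import Conformer
from pepion.synth import build_peptide, make_template, place_ion

from conftest import random_rigid_motion


# --------------------------------------------------------------------------
# dihedrals

def oracle_dihedral(p1, p2, p3, p4):
    """Independent dihedral via plane normals and a cross-product sign."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((1, 1, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0)) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        assert dihedral((1, 1, 0), (0, 0, 0), (1, 0, 0), (2, -1, 0)) == pytest.approx(180.0)

    def test_sixty_degree_reference_point(self):
        c, s = np.cos(np.radians(60)), np.sin(np.radians(60))
        got = dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), (c, s, 1))
        assert got == pytest.approx(60.0, abs=1e-9)

    def test_matches_cross_product_oracle_on_random_points(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                got = dihedral(*pts)
            except GeometryError:
                continue
            assert got == pytest.approx(oracle_dihedral(*pts), abs=1e-8)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3)) * 2
        ref = dihedral(*pts)
        for _ in range(20):
            R, t = random_rigid_motion(rng)
            moved = pts @ R.T + t
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)

    def test_degenerate_geometry_errors(self):
        with pytest.raises(GeometryError, match="undefined dihedral"):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(GeometryError, match="undefined dihedral"):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (-1, 0, 0))

    @given(st.floats(-179.999, 180.0))
    @settings(max_examples=50, deadline=None)
    def test_builder_round_trip_any_angle(self, tors):
        c, s = np.cos(np.radians(tors)), np.sin(np.radians(tors))
        pts = np.array([(1, 0, 0), (0, 0, 0), (0, 0, 1.5), (c, s, 1.5)])
        assert dihedral(*pts) == pytest.approx(tors, abs=1e-6)


# --------------------------------------------------------------------------
# hydrogen bonds

def oracle_hbonds(conf, crit):
    """Exhaustive triple loop over (donor, hydrogen, acceptor)."""
    P = conf.positions
    els = conf.elements
    protons = assign_protons(conf)
    found = set()
    for h, asg in protons.items():
        if asg.heavy is None or els[asg.heavy] not in ("N", "O", "S"):
            continue
        for a in range(len(conf)):
            if a == asg.heavy or els[a] not in ("N", "O", "S"):
                continue
            d_ha = distance(P[h], P[a])
            d_da = distance(P[asg.heavy], P[a])
            if not (crit.min_d_ha <= d_ha <= crit.max_d_ha):
                continue
            if d_da > crit.max_d_da or d_ha >= d_da:
                continue
            if angle(P[asg.heavy], P[h], P[a]) < crit.min_angle:
                continue
            found.add((asg.heavy, h, a))
    return found


class TestHydrogenBonds:
    def test_textbook_bond_detected(self):
        conf = Conformer(
            ["N", "H", "O"],
            [[0, 0, 0], [1.0, 0, 0], [2.95, 0.25, 0]],  # d_HA ~ 1.97, angle ~ 173
            meta={},
        )
        bonds = detect_hbonds(conf)
        assert len(bonds) == 1
        hb = bonds[0]
        assert (hb.donor, hb.hydrogen, hb.acceptor) == (0, 1, 2)
        assert hb.d_ha < hb.d_da

    def test_bent_contact_rejected(self):
        conf = Conformer(
            ["N", "H", "O"],
            [[0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]],     # angle 90 deg
            meta={},
        )
        assert detect_hbonds(conf) == []

    def test_matches_exhaustive_oracle_on_suite_conformers(self, suite_seed1):
        crit = HBondCriteria()
        checked = 0
        for sid in sorted(suite_seed1):
            for conf in suite_seed1[sid].ensemble:
                got = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(conf, crit)}
                assert got == oracle_hbonds(conf, crit), sid
                checked += 1
            if checked > 120:
                break
        assert checked > 50

    def test_sorted_by_contact_distance(self, suite_seed1):
        for sid in list(sorted(suite_seed1))[:30]:
            for conf in suite_seed1[sid].ensemble:
                d = [b.d_ha for b in detect_hbonds(conf)]
                assert d == sorted(d)


class TestAssignProtons:
    def test_nearest_heavy_atom_wins(self):
        conf = Conformer(["N", "O", "H"], [[0, 0, 0], [2.6, 0, 0], [1.0, 0, 0]])
        asg = assign_protons(conf)[2]
        assert asg.heavy == 0 and asg.flag is None

    def test_shared_proton_flagged_within_band(self):
        conf = Conformer(["O", "N", "H"], [[0, 0, 0], [2.45, 0, 0], [1.20, 0, 0]])
        # d(H-O)=1.20, d(H-N)=1.25: within the 0.15 A band
        assert assign_protons(conf, shared_band=0.1)[2].flag == "shared"

    def test_orphan_flagged_beyond_cutoff(self):
        conf = Conformer(["C", "H"], [[0, 0, 0], [3.0, 0, 0]])
        assert assign_protons(conf)[1].flag == "orphan"

    def test_matches_brute_force_on_suite(self, suite_seed1):
        rng = np.random.default_rng(0)
        sids = rng.choice(sorted(suite_seed1), size=10, replace=False)
        for sid in sids:
            conf = suite_seed1[sid].ensemble.conformers[0]
            asg = assign_protons(conf)
            heavies = conf.heavy_indices()
            for i, el in enumerate(conf.elements):
                if el != "H":
                    continue
                d = [distance(conf.positions[i], conf.positions[j]) for j in heavies]
                nearest = heavies[int(np.argmin(d))]
                if min(d) <= 1.3:
                    assert asg[i].heavy == nearest


# --------------------------------------------------------------------------
# pseudocycles and orientation

class TestPseudocycles:
    def test_c5_ring_has_five_members(self):
        conf = build_peptide(make_template("Ala", "capped"), phi=-160.0, psi=160.0)
        topo = topology_of(conf)
        from pepion.geometry import C5_CRITERIA
        hb = [b for b in detect_hbonds(conf, C5_CRITERIA)
              if b.donor == topo.get("N") and b.acceptor == topo.get("O")][0]
        ring = find_pseudocycle(conf, hb)
        assert ring.size == 5 and ring.closure == "hydrogen_bond"

    def test_c7_ring_has_seven_members(self):
        conf = build_peptide(make_template("Ala", "capped"), phi=-83.0, psi=66.0)
        topo = topology_of(conf)
        hb = [b for b in detect_hbonds(conf)
              if b.donor == topo.get("N_next") and b.acceptor == topo.get("O_prev")][0]
        ring = find_pseudocycle(conf, hb)
        assert ring.size == 7

    def test_cation_bridge_closes_seven_ring(self):
        conf = build_peptide(make_template("Ala", "capped"), phi=60.0, psi=40.0)
        conf = place_ion(conf, "carbonyl_bridge", 2.35, "Ca")
        topo = topology_of(conf)
        ring = find_pseudocycle(
            conf, (topo.require("ion"), topo.require("O_prev"), topo.require("O")))
        assert ring.size == 7 and ring.closure == "cation_bridge"
        assert topo.require("ion") in ring.members

    def test_disconnected_atoms_raise(self):
        conf = Conformer(["O", "H", "O"], [[0, 0, 0], [1, 0, 0], [9, 0, 0]])
        from pepion.geometry import HydrogenBond
        hb = HydrogenBond(0, 1, 2, 8.0, 9.0, 160.0)
        with pytest.raises(GeometryError, match="no ring"):
            find_pseudocycle(conf, hb)


class TestSideChainOrientation:
    def _ring_conformer(self, theta_deg):
        """A planar 5-ring in z=0 with CA at a vertex and CB tilted by theta
        from the plane normal."""
        ring = np.array([
            [1.0, 0, 0], [0.3, 0.95, 0], [-0.8, 0.6, 0], [-0.8, -0.6, 0],
            [0.3, -0.95, 0],
        ])
        t = np.radians(theta_deg)
        cb = ring[0] + 1.5 * np.array([np.sin(t), 0.0, np.cos(t)])
        pos = np.vstack([ring, cb])
        return Conformer(["C", "C", "C", "C", "C", "C"], pos)

    @pytest.mark.parametrize("theta, expected", [
        (0.0, "axial"), (90.0, "equatorial"), (44.0, "axial"), (46.0, "equatorial"),
    ])
    def test_threshold_at_45_degrees(self, theta, expected):
        conf = self._ring_conformer(theta)
        ring = Pseudocycle(list(range(5)), "hydrogen_bond", 5)
        assert side_chain_orientation(conf, ring, 0, 5) == expected

    def test_glycine_has_no_side_chain(self):
        conf = self._ring_conformer(0.0)
        ring = Pseudocycle(list(range(5)), "hydrogen_bond", 5)
        with pytest.raises(GeometryError, match="no side chain"):
            side_chain_orientation(conf, ring, 0, None)


# --------------------------------------------------------------------------
# RMSD

def oracle_rmsd(a, b):
    """Grid search over rotations (independent of the SVD solver)."""
    pa = a.positions - a.positions.mean(axis=0)
    pb = b.positions - b.positions.mean(axis=0)

    def rmsd_for(euler):
        al, be, ga = euler
        ca_, sa = np.cos(al), np.sin(al)
        cb_, sb = np.cos(be), np.sin(be)
        cg, sg = np.cos(ga), np.sin(ga)
        rz1 = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
        ry = np.array([[cb_, 0, sb], [0, 1, 0], [-sb, 0, cb_]])
        rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
        R = rz1 @ ry @ rz2
        return np.sqrt(np.mean(np.sum((pb @ R.T - pa) ** 2, axis=1)))

    from scipy.optimize import minimize
    grid = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    best = None
    for al in grid:
        for be in np.linspace(0, np.pi, 5):
            for ga in grid:
                v = rmsd_for((al, be, ga))
                if best is None or v < best[0]:
                    best = (v, (al, be, ga))
    res = minimize(rmsd_for, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return float(res.fun)


class TestKabschRmsd:
    def test_identical_structures_are_zero(self):
        c = Conformer(["C", "N", "O"], [[0, 0, 0], [1.4, 0, 0], [2.0, 1.1, 0]])
        assert kabsch_rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(6, 3)) * 2
        a = Conformer(["C"] * 6, pos)
        R, t = random_rigid_motion(rng)
        b = Conformer(["C"] * 6, pos @ R.T + t)
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(9)
        a = Conformer(["C"] * 5, rng.normal(size=(5, 3)))
        b = Conformer(["C"] * 5, rng.normal(size=(5, 3)))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_matches_rotation_grid_oracle(self):
        base = np.array([[0, 0, 0], [1.5, 0, 0], [0.7, 1.3, 0], [0.7, 0.4, 1.2]])
        displaced = base.copy()
        displaced[3] += [0.6, -0.8, 0.0]          # 1 A displacement
        rng = np.random.default_rng(11)
        R, t = random_rigid_motion(rng)
        a = Conformer(["C", "N", "O", "S"], base)
        b = Conformer(["C", "N", "O", "S"], displaced @ R.T + t)
        assert kabsch_rmsd(a, b) == pytest.approx(oracle_rmsd(a, b), abs=1e-3)

    def test_mismatched_elements_raise(self):
        a = Conformer(["C", "N"], [[0, 0, 0], [1.4, 0, 0]])
        b = Conformer(["C", "O"], [[0, 0, 0], [1.4, 0, 0]])
        with pytest.raises(GeometryError, match="mismatched atoms"):
            kabsch_rmsd(a, b)
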