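import hashlib
from pathlib import Path

import numpy as np
import pytest

from pepion.geometry import backbone_torsions, distance, topology_of
from pepion.systems import Conformer
from pepion.synth import (
    basin_hop_search,
    build_peptide,
    default_toy_params,
    generate_benchmark_suite,
    generate_labeled_ensembles,
    make_template,
    place_ion,
    toy_energy,
)
from pepion.synth.builder import BuildError
from pepion.synth.toyenergy import EnergyError

from conftest import random_rigid_motion


class TestBuilder:
    @pytest.mark.parametrize("phi, psi", [(-150.0, 150.0), (-83.0, 66.0), (60.0, 40.0)])
    def test_requested_torsions_are_realized(self, phi, psi):
        conf = build_peptide(make_template("Ala", "capped"), phi=phi, psi=psi)
        tors = backbone_torsions(conf, topology_of(conf))
        assert tors.phi == pytest.approx(phi, abs=1e-6)
        assert tors.psi == pytest.approx(psi, abs=1e-6)

    def test_chi_round_trip(self):
        conf = build_peptide(make_template("Ser", "capped"), phi=-83.0, psi=66.0,
                             chis=(47.5,))
        tors = backbone_torsions(conf, topology_of(conf))
        assert tors.chi == [pytest.approx(47.5, abs=1e-6)]

    def test_glycine_has_no_side_chain(self):
        conf = build_peptide(make_template("Gly", "capped"), phi=-83.0, psi=66.0)
        topo = topology_of(conf)
        assert topo.get("CB") is None and topo.chi == []

    def test_out_of_interval_torsion_rejected(self):
        with pytest.raises(BuildError, match="outside"):
            build_peptide(make_template("Ala", "capped"), phi=200.0, psi=0.0)

    def test_no_close_nonbonded_contacts_in_panel(self):
        for lig in ("Ala", "Ser", "Asn", "LysH"):
            conf = build_peptide(make_template(lig, "capped"), phi=-83.0, psi=66.0)
            P = conf.positions
            d = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
            np.fill_diagonal(d, 10.0)
            assert d.min() > 0.7


class TestPlaceIon:
    def test_bridge_distances_are_symmetric(self):
        conf = build_peptide(make_template("Ala", "capped"), phi=60.0, psi=40.0)
        conf = place_ion(conf, "carbonyl_bridge", 2.3, "Ca")
        topo = topology_of(conf)
        P = conf.positions
        ion = topo.require("ion")
        for role in ("O_prev", "O"):
            assert 2.25 <= distance(P[ion], P[topo.require(role)]) <= 2.35

    def test_carboxylate_site_yields_salt_bridge(self):
        from pepion.classify import classify_ion_amino_acid
        t = make_template("Ala", "free", "zwitterionic")
        conf = place_ion(build_peptide(t, params={"psic": 180.0, "am": 0.0}),
                         "carboxylate", 2.3, "Ca")
        topo = topology_of(conf)
        assert classify_ion_amino_acid(conf, topo, topo.require("ion")).label == "salt_bridge"

    def test_thiol_side_chain_site_nearest_ligand_is_sulfur(self):
        from pepion.coordination import coordination_shell
        t = make_template("Cys", "free", "neutral")
        conf = build_peptide(t, params={"psic": 0.0, "ho": 180.0, "am": 0.0, "chi1": 180.0})
        conf = place_ion(conf, "side_chain", 2.5, "Hg")
        topo = topology_of(conf)
        shell = coordination_shell(conf, topo.require("ion"), 3.2)
        assert shell.entries[0].element == "S"

    def test_missing_site_atoms_rejected(self):
        conf = build_peptide(make_template("Ala", "capped"), phi=60.0, psi=40.0)
        with pytest.raises(BuildError, match="missing atom role"):
            place_ion(conf, "side_chain", 2.5, "Ca")  # Ala has no ligating group

    def test_unreachable_bridge_distance_rejected(self):
        conf = build_peptide(make_template("Ala", "capped"), phi=-160.0, psi=160.0)
        with pytest.raises(BuildError, match="shorter than half"):
            place_ion(conf, "carbonyl_bridge", 1.0, "Ca")


class TestToyEnergy:
    def _pair(self, r):
        return Conformer(["N", "O"], [[0, 0, 0], [r, 0, 0]],
                         meta={"charges": [1.0, -1.0]})

    def test_opposite_charges_prefer_shorter_distance(self, toy_params):
        assert toy_energy(self._pair(3.0), toy_params) < toy_energy(self._pair(4.0), toy_params)

    def test_isolated_atom_is_zero(self, toy_params):
        conf = Conformer(["Ca"], [[0, 0, 0]], meta={"charges": [2.0]})
        assert toy_energy(conf, toy_params) == 0.0

    def test_untyped_conformer_rejected(self, toy_params):
        with pytest.raises(EnergyError, match="untyped"):
            toy_energy(Conformer(["N", "O"], [[0, 0, 0], [3, 0, 0]]), toy_params)

    def test_matches_hand_summed_pairwise_terms(self, toy_params):
        # widely separated atoms: no bonds, no H-bond wells, no exclusions
        p = toy_params
        els = ["N", "O", "C"]
        pos = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 5.0, 0]])
        q = [0.5, -0.5, 0.3]
        conf = Conformer(els, pos, meta={"charges": q})
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.linalg.norm(pos[i] - pos[j])
                expected += p.coulomb_k_ev_a * q[i] * q[j] / (p.dielectric * r)
                sig = 0.5 * (p.lj_sigma_a[els[i]] + p.lj_sigma_a[els[j]])
                sr6 = (sig / r) ** 6
                expected += 4 * p.lj_epsilon_ev * (sr6**2 - sr6)
        assert toy_energy(conf, p) == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, toy_params):
        conf = build_peptide(make_template("Ser", "capped"), phi=-83.0, psi=66.0)
        ref = toy_energy(conf, toy_params)
        rng = np.random.default_rng(4)
        for _ in range(5):
            R, t = random_rigid_motion(rng)
            moved = Conformer(conf.elements, conf.positions @ R.T + t,
                              meta=dict(conf.meta))
            assert toy_energy(moved, toy_params) == pytest.approx(ref, abs=1e-9)


class TestBasinHop:
    def test_same_seed_reproduces_identical_ensembles(self):
        t = make_template("Cys", "free", "neutral")
        a = basin_hop_search(t, n_steps=6, seed=5)
        b = basin_hop_search(t, n_steps=6, seed=5)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.energy == cb.energy
            assert np.array_equal(ca.positions, cb.positions)

    def test_single_step_yields_single_minimum(self):
        t = make_template("Ala", "free", "neutral")
        assert len(basin_hop_search(t, n_steps=1, seed=0)) == 1

    def test_one_torsion_search_finds_the_deep_wells(self, toy_params):
        """Grid-scan oracle over a single chi torsion vs the stochastic search."""
        t = make_template("Ser", "capped")
        frozen = {"phi": -83.0, "psi": 66.0}
        energies = []
        for chi in np.arange(-179.0, 181.0, 1.0):
            c = build_peptide(t, params={**frozen, "chi1": float(chi)}, check_clash=False)
            energies.append((float(chi), toy_energy(c, toy_params)))
        wells = []
        for i in range(len(energies)):
            e_prev = energies[i - 1][1]
            e_next = energies[(i + 1) % len(energies)][1]
            if energies[i][1] < e_prev and energies[i][1] < e_next:
                wells.append(energies[i][0])
        assert len(wells) >= 2
        ens = basin_hop_search(t, n_steps=30, step_deg=120.0, seed=0, frozen=frozen)
        found = [backbone_torsions(c, topology_of(c)).chi[0] for c in ens]
        deepest = sorted(wells, key=lambda w: dict(energies)[round(w)])[:2]
        for w in deepest:
            assert any(abs(f - w) < 8.0 for f in found), (w, found)


class TestSuiteGuarantees:
    @pytest.mark.parametrize("seed", [11, 29])
    def test_guarantees_hold_across_seeds(self, seed):
        from pepion.classify import classify_conformer
        from pepion.coordination import cation_o_histogram, count_modes
        from pepion.energetics import binding_energy, build_hierarchy

        suite = generate_labeled_ensembles(seed=seed)
        hier = {sid: build_hierarchy(le.ensemble) for sid, le in suite.items()}
        # per-conformer label recovery
        for sid, le in suite.items():
            d = le.ensemble.system
            for conf, lab in zip(le.ensemble, le.labels):
                got = classify_conformer(conf, topology_of(conf), d.backbone,
                                         d.complexation)
                assert got.label == lab, (sid, conf.meta.get("recipe"))
        # contraction and binding order
        for sid, h in hier.items():
            d = h.system
            if d.complexation == "none":
                continue
            bare = hier[f"{d.ligand_name}_{d.backbone}_none"]
            assert len(h) < len(bare), sid
        for sid, le in suite.items():
            if not sid.endswith("_none"):
                continue
            lig_bb = sid[: -len("_none")]
            e_lig = hier[sid].global_minimum.energy
            eb = {ion: binding_energy(hier[f"{lig_bb}_{ion}"].global_minimum.energy,
                                      e_lig, 0.0)
                  for ion in ("Ba", "Sr", "Ca", "Pb", "Cd", "Hg")}
            assert eb["Ba"] < eb["Sr"] < eb["Ca"] < eb["Cd"] < eb["Hg"], sid
            assert eb["Ca"] == eb["Pb"], sid
        # distance modality
        def pool(ion):
            return [hier[sid].global_minimum for sid in hier
                    if sid.endswith(f"_{ion}")]
        assert count_modes(cation_o_histogram(pool("Hg"))) == 2
        assert count_modes(cation_o_histogram(pool("Cd"))) == 1

    def test_fixed_seed_writes_byte_identical_suites(self, tmp_path):
        def digest(root: Path) -> str:
            h = hashlib.sha256()
            for f in sorted(root.rglob("*")):
                if f.is_file():
                    h.update(f.relative_to(root).as_posix().encode())
                    h.update(f.read_bytes())
            return h.hexdigest()

        a = generate_benchmark_suite(7, tmp_path / "a", ligands=("Ala", "Cys"))
        b = generate_benchmark_suite(7, tmp_path / "b", ligands=("Ala", "Cys"))
        assert digest(a) == digest(b)

    def test_suite_round_trips_through_extxyz(self, small_suite):
        from pepion.io import read_extxyz
        ens = read_extxyz(small_suite / "Ala_capped_Ca" / "ensemble.extxyz")
        assert len(ens) == 1
        conf = ens[0].conformers[0]
        assert conf.meta["label"] in ("iC7eq", "iC7ax", "other")
        assert topology_of(conf).get("ion") is not None
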