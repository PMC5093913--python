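"""Backbone structure-type classification and rotamer tables.

Free amino acids are assigned one of three basic backbone conformations —
type I (neutral, backbone N-H donating to the carbonyl O), type II (neutral,
carboxyl O-H donating to the backbone N) or zwitterionic (acidic proton on a
nitrogen, carboxylate deprotonated).  Cation complexes of free amino acids
are salt-bridge (zwitterionic backbone, cation on the carboxylate) or
charge-solvated (neutral backbone, cation on the amino N and a carbonyl O).
Dipeptides form the hydrogen-bonded C5 or C7 pseudocycles (C7 split into
axial/equatorial side-chain orientation), and their cation complexes the
cation-closed incomplete-C7 ring iC7ax / iC7eq.  Anything else is ``other``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    C5_CRITERIA,
    GeometryError,
    HBondCriteria,
    TopologyMap,
    assign_protons,
    backbone_torsions,
    detect_hbonds,
    distance,
    find_pseudocycle,
    side_chain_orientation,
)
from .systems import CATIONS, Conformer, Ensemble
from .toxicity import ion_reference

LABELS = (
    "typeI", "typeII", "zwitterionic", "charge_solvated", "salt_bridge",
    "C5", "C7ax", "C7eq", "iC7ax", "iC7eq", "other",
)

#: the short intramolecular 5-ring contacts of free amino acids are strongly
#: bent; like the C5 motif they are detected with a relaxed angular criterion
FREE_RING_CRITERIA = HBondCriteria(max_d_ha=2.5, max_d_da=3.5, min_angle=100.0)

#: oxygen radius proxy + slack added to the ion's Shannon radius
CUTOFF_O_RADIUS_A = 1.52
CUTOFF_SLACK_A = 0.4


class ClassifyError(ValueError):
    pass


@dataclass
class BackboneClass:
    label: str
    evidence: list[tuple[str, float | str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ClassifyError(f"unknown label {self.label!r}")


def coordination_cutoff(ion: str, overrides: dict[str, float] | None = None) -> float:
    """Per-ion cation-ligand coordination cutoff in Angstrom."""
    if overrides and ion in overrides:
        return overrides[ion]
    return ion_reference(ion).shannon_radius_pm / 100.0 + CUTOFF_O_RADIUS_A + CUTOFF_SLACK_A


def _backbone_carboxyl_protons(conf, topo, protons) -> list[int]:
    o_idx = {topo.require("O"), topo.require("O2")}
    return [h for h, a in protons.items() if a.heavy in o_idx]


def _n_protons_on(protons, idx: int) -> int:
    return sum(1 for a in protons.values() if a.heavy == idx)


def classify_free_amino_acid(conf: Conformer, topo: TopologyMap) -> BackboneClass:
    """Assign type I / type II / zwitterionic / other to a bare free amino acid."""
    for role in ("N", "CA", "C", "O", "O2"):
        topo.require(role)
    protons = assign_protons(conf)
    n_idx = topo.require("N")
    carboxyl_h = _backbone_carboxyl_protons(conf, topo, protons)

    if not carboxyl_h:
        # deprotonated backbone carboxylate: zwitterionic if an acidic proton
        # sits on the backbone amino N or on a basic side-chain nitrogen
        n_on_backbone = _n_protons_on(protons, n_idx)
        if n_on_backbone >= 3:
            return BackboneClass("zwitterionic", [("protons_on_backbone_N", n_on_backbone)])
        for i, el in enumerate(conf.elements):
            if el == "N" and i != n_idx and _n_protons_on(protons, i) >= 3:
                return BackboneClass(
                    "zwitterionic",
                    [("side_chain_donor_N", i), ("protons_on_side_chain_N", 3)],
                )
        return BackboneClass("other", [("reason", "deprotonated but no acidic proton found")])

    hbonds = detect_hbonds(conf, FREE_RING_CRITERIA, proton_map=protons)
    oh_donors = {protons[h].heavy for h in carboxyl_h}
    for hb in hbonds:
        if hb.donor in oh_donors and hb.acceptor == n_idx:
            return BackboneClass(
                "typeII",
                [("d_HA", round(hb.d_ha, 3)), ("angle_DHA", round(hb.angle_dha, 1))],
            )
    o_idx = topo.require("O")
    o2_idx = topo.require("O2")
    for hb in hbonds:
        if hb.donor == n_idx and hb.acceptor in (o_idx, o2_idx):
            return BackboneClass(
                "typeI",
                [("d_HA", round(hb.d_ha, 3)), ("angle_DHA", round(hb.angle_dha, 1))],
            )
    return BackboneClass("other", [("reason", "no backbone ring hydrogen bond")])


def _require_cation(conf: Conformer, ion_index: int) -> str:
    el = conf.elements[ion_index]
    if el not in CATIONS:
        raise ClassifyError(f"atom {ion_index} ({el}) is not a registered cation")
    return el


def classify_ion_amino_acid(
    conf: Conformer,
    topo: TopologyMap,
    ion_index: int,
    cutoff_overrides: dict[str, float] | None = None,
) -> BackboneClass:
    """Salt-bridge vs charge-solvated assignment for free amino acid + cation."""
    ion = _require_cation(conf, ion_index)
    cutoff = coordination_cutoff(ion, cutoff_overrides)
    protons = assign_protons(conf)
    carboxyl_h = _backbone_carboxyl_protons(conf, topo, protons)
    P = conf.positions
    d_o = min(
        distance(P[ion_index], P[topo.require("O")]),
        distance(P[ion_index], P[topo.require("O2")]),
    )
    d_n = distance(P[ion_index], P[topo.require("N")])
    if not carboxyl_h and d_o <= cutoff:
        return BackboneClass(
            "salt_bridge",
            [("d_ion_O", round(d_o, 3)), ("cutoff", round(cutoff, 3))],
        )
    if carboxyl_h and d_n <= cutoff and d_o <= cutoff:
        return BackboneClass(
            "charge_solvated",
            [("d_ion_N", round(d_n, 3)), ("d_ion_O", round(d_o, 3)),
             ("cutoff", round(cutoff, 3))],
        )
    return BackboneClass("other", [("d_ion_O", round(d_o, 3)), ("d_ion_N", round(d_n, 3))])


def classify_dipeptide(conf: Conformer, topo: TopologyMap) -> BackboneClass:
    """C5 / C7ax / C7eq assignment for a bare dipeptide."""
    for role in ("C_prev", "O_prev", "N", "H_N", "CA", "C", "O", "N_next", "H_next"):
        if topo.get(role) is None:
            raise ClassifyError(f"missing cap atom role {role!r}")
    protons = assign_protons(conf)
    c5 = [
        hb for hb in detect_hbonds(conf, C5_CRITERIA, proton_map=protons)
        if hb.donor == topo.get("N") and hb.acceptor == topo.get("O")
    ]
    c7 = [
        hb for hb in detect_hbonds(conf, proton_map=protons)
        if hb.donor == topo.get("N_next") and hb.acceptor == topo.get("O_prev")
    ]
    pick = None
    if c5 and c7:
        pick = "C5" if c5[0].d_ha <= c7[0].d_ha else "C7"
    elif c5:
        pick = "C5"
    elif c7:
        pick = "C7"
    if pick == "C5":
        return BackboneClass(
            "C5", [("d_HA", round(c5[0].d_ha, 3)), ("angle_DHA", round(c5[0].angle_dha, 1))]
        )
    if pick == "C7":
        ring = find_pseudocycle(conf, c7[0])
        cb = topo.get("CB")
        if cb is None:
            return BackboneClass(
                "other", [("reason", "7-ring present but no side chain for ax/eq")]
            )
        orient = side_chain_orientation(conf, ring, topo.require("CA"), cb)
        return BackboneClass(
            "C7ax" if orient == "axial" else "C7eq",
            [("d_HA", round(c7[0].d_ha, 3)), ("ring_size", ring.size),
             ("orientation", orient)],
        )
    return BackboneClass("other", [("reason", "no C5 or C7 hydrogen bond")])


def classify_dipeptide_ion(
    conf: Conformer,
    topo: TopologyMap,
    ion_index: int,
    cutoff_overrides: dict[str, float] | None = None,
) -> BackboneClass:
    """iC7ax / iC7eq assignment for a dipeptide-cation complex.

    The cation must bridge the acetyl oxygen and the residue carbonyl oxygen,
    closing the otherwise incomplete 7-membered pseudocycle.
    """
    ion = _require_cation(conf, ion_index)
    cutoff = coordination_cutoff(ion, cutoff_overrides)
    o_prev = topo.require("O_prev")
    o_res = topo.require("O")
    P = conf.positions
    d1 = distance(P[ion_index], P[o_prev])
    d2 = distance(P[ion_index], P[o_res])
    if d1 <= cutoff and d2 <= cutoff:
        ring = find_pseudocycle(conf, (ion_index, o_prev, o_res))
        cb = topo.get("CB")
        if cb is None:
            return BackboneClass(
                "other", [("reason", "cation-closed ring but no side chain for ax/eq")]
            )
        orient = side_chain_orientation(conf, ring, topo.require("CA"), cb)
        return BackboneClass(
            "iC7ax" if orient == "axial" else "iC7eq",
            [("d_ion_Oprev", round(d1, 3)), ("d_ion_O", round(d2, 3)),
             ("ring_size", ring.size), ("orientation", orient)],
        )
    return BackboneClass("other", [("d_ion_Oprev", round(d1, 3)), ("d_ion_O", round(d2, 3))])


def classify_conformer(
    conf: Conformer,
    topo: TopologyMap,
    backbone: str,
    complexation: str,
    cutoff_overrides: dict[str, float] | None = None,
) -> BackboneClass:
    """Dispatch to the appropriate classifier for a system's conformer."""
    ion_index = topo.get("ion")
    if complexation != "none" and ion_index is None:
        raise ClassifyError("complexed system but no ion in topology")
    if backbone == "free":
        if complexation == "none":
            return classify_free_amino_acid(conf, topo)
        return classify_ion_amino_acid(conf, topo, ion_index, cutoff_overrides)
    if complexation == "none":
        return classify_dipeptide(conf, topo)
    return classify_dipeptide_ion(conf, topo, ion_index, cutoff_overrides)


# ---------------------------------------------------------------------------
# Ramachandran quadrants

@dataclass(frozen=True)
class Quadrant:
    index: str                # "I" | "II" | "III" | "IV"
    boundary: bool = False


def quadrant(phi: float, psi: float) -> Quadrant:
    """Sign-quadrant of a (phi, psi) pair.

    I: phi>0, psi>0; II: phi<0, psi>0; III: phi<0, psi<0; IV: phi>0, psi<0.
    Values of 0 or +/-180 sit on a quadrant border; they are assigned to the
    adjacent quadrant in the clockwise sense and flagged as boundary.
    """
    for v in (phi, psi):
        if not (-180.0 <= v <= 180.0):
            raise ClassifyError(f"angle {v} outside principal interval")
    on_boundary = phi in (0.0, 180.0, -180.0) or psi in (0.0, 180.0, -180.0)
    # fold +/-180 onto -180 (west border) and resolve clockwise: a border ray
    # belongs to the quadrant that follows it when sweeping clockwise
    p = -180.0 if abs(phi) == 180.0 else phi
    s = -180.0 if abs(psi) == 180.0 else psi
    if p == 0.0:
        p = 1.0 if s >= 0 else -1.0          # phi=0: I if psi>0 (cw from +psi ray), III if psi<0
    if s == 0.0:
        s = -1.0 if p > 0 else 1.0           # psi=0: IV if phi>0, II if phi<0
    if p > 0 and s > 0:
        q = "I"
    elif p < 0 and s > 0:
        q = "II"
    elif p < 0 and s < 0:
        q = "III"
    else:
        q = "IV"
    return Quadrant(q, on_boundary)


# ---------------------------------------------------------------------------
# rotamer tables

BOLTZMANN_EV_PER_K = 8.617333262e-5

CHI_BINS = ("g+", "t", "g-")


def chi_bin(chi_deg: float) -> str:
    """gauche+/trans/gauche- binning: g+ (0,120], t (120,-120], g- (-120,0]."""
    if 0.0 < chi_deg <= 120.0:
        return "g+"
    if -120.0 < chi_deg <= 0.0:
        return "g-"
    return "t"


@dataclass
class RotamerTable:
    """Per side chain: chi-bin tuple -> count and Boltzmann-weighted frequency."""

    energy_window_ev: float
    temperature_k: float
    entries: dict[str, dict[tuple[str, ...], dict[str, float]]] = field(default_factory=dict)


def derive_rotamer_table(
    ensembles: list[Ensemble],
    energy_window_ev: float = math.inf,
    temperature_k: float = 300.0,
) -> RotamerTable:
    """Bin side-chain torsions of low-energy conformers into rotamer classes.

    Conformers within ``energy_window_ev`` of each system's minimum are
    counted; frequencies are Boltzmann weights of the relative energies at
    ``temperature_k``, normalised per side chain.
    """
    from .geometry import topology_of

    table = RotamerTable(energy_window_ev, temperature_k)
    kt = BOLTZMANN_EV_PER_K * temperature_k
    weights: dict[str, dict[tuple[str, ...], float]] = {}
    for ens in ensembles:
        e0 = min(c.energy for c in ens)
        kept = [c for c in ens if c.energy - e0 <= energy_window_ev]
        if not kept:
            raise ClassifyError(f"empty energy window for {ens.system_id}")
        name = ens.system.ligand_name
        bucket = table.entries.setdefault(name, {})
        wbucket = weights.setdefault(name, {})
        for conf in kept:
            topo = topology_of(conf)
            if not topo.chi:
                continue
            tors = backbone_torsions(conf, topo)
            key = tuple(chi_bin(x) for x in tors.chi)
            entry = bucket.setdefault(key, {"count": 0, "frequency": 0.0})
            entry["count"] += 1
            wbucket[key] = wbucket.get(key, 0.0) + math.exp(-(conf.energy - e0) / kt)
    for name, wbucket in weights.items():
        z = sum(wbucket.values())
        for key, w in wbucket.items():
            table.entries[name][key]["frequency"] = w / z
    return table
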