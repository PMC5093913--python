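"""Internal-coordinate residue templates and toy-potential parameters.

Templates are Z-matrix-like row lists: each atom is placed from a bond length,
a bond angle, and a torsion relative to three previously placed atoms.  Side
chains are simplified united-atom surrogates (no aliphatic hydrogens; polar
hydrogens explicit) — the analysis operates on geometric and energetic
structure, not element-exact residues, so classes rather than chemistry must
be faithful.

Torsion specs in a row are either a fixed float (degrees), a parameter name
(``"phi"``, ``"psi"``, ``"chi1"``, ``"psic"``, ...), or a ``(param, offset)``
pair resolved at build time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# L-configuration constant: torsion CB-CA-C-N (capped: CB-CA-C1-N1 via refs)
# chosen so that the classic C7 region (phi ~ -83, psi ~ +66) places the side
# chain equatorial to the 7-ring and its mirror places it axial.
CHIRALITY_TORSION = 122.0


@dataclass(frozen=True)
class ZRow:
    name: str
    element: str
    refs: tuple[str, ...]            # () for the first atom, then 1-3 names
    dist: float = 0.0
    ang: float = 0.0
    tors: float | str | tuple[str, float] = 0.0
    charge: float = 0.0


@dataclass
class ResidueTemplate:
    """One buildable molecular form of a panel ligand."""

    name: str                        # e.g. "Ser", "LysH"
    backbone: str                    # "free" | "capped"
    form: str                        # "neutral" | "zwitterionic" | "capped"
    rows: list[ZRow]
    chi_names: list[str]             # ordered side-chain torsion parameter names
    default_params: dict[str, float]
    roles: dict[str, str]            # topology role -> atom name
    terminal_group: str              # side-chain terminal group type
    sc_ligand: str | None = None     # side-chain atom able to ligate a cation

    @property
    def atom_names(self) -> list[str]:
        return [r.name for r in self.rows]

    def index(self, name: str) -> int:
        return self.atom_names.index(name)


@dataclass
class IonParams:
    charge: float
    radius_a: float                  # effective toy radius, Angstrom
    hg_like: bool = False            # enables the two-short-ligand term


@dataclass
class ToyEnergyParams:
    """Parameters of the screened Coulomb + LJ + H-bond toy potential."""

    dielectric: float = 4.0
    coulomb_k_ev_a: float = 14.3996          # e^2 / (4 pi eps0), eV * Angstrom
    lj_epsilon_ev: float = 0.004
    lj_sigma_a: dict[str, float] = field(default_factory=lambda: {
        "H": 1.6, "C": 3.2, "N": 3.0, "O": 2.9, "S": 3.4,
        "Ca": 2.4, "Sr": 2.8, "Ba": 3.2, "Cd": 2.3, "Pb": 2.4, "Hg": 2.45,
    })
    hbond_depth_ev: float = 0.35
    hbond_r0_a: float = 1.9
    hbond_width_a: float = 0.45
    # two-short-ligand attraction (covalency surrogate) for Hg-like ions
    hg_depth_ev: float = 1.2
    hg_r0_a: float = 2.08
    hg_width_a: float = 0.25
    ions: dict[str, IonParams] = field(default_factory=lambda: {
        # toy effective radii follow the packaged Shannon ordering
        # (Ca < Sr < Ba); Pb is deliberately set equal to Ca so the Ca/Pb
        # binding series coincide exactly, and Hg carries the extra
        # short-range term instead of a smaller radius.
        "Ca": IonParams(2.0, 1.00),
        "Sr": IonParams(2.0, 1.18),
        "Ba": IonParams(2.0, 1.35),
        "Cd": IonParams(2.0, 0.95),
        "Pb": IonParams(2.0, 1.00),
        "Hg": IonParams(2.0, 1.02, hg_like=True),
    })
    #: mean cation-oxygen contact distance = radius + this offset (O proxy)
    contact_offset_a: float = 1.35

    def contact_distance(self, ion: str) -> float:
        return self.ions[ion].radius_a + self.contact_offset_a


def default_toy_params() -> ToyEnergyParams:
    return ToyEnergyParams()


# ---------------------------------------------------------------------------
# backbone row sets

def _free_backbone(zwitterionic: bool) -> list[ZRow]:
    """Free amino-acid backbone: H2N-CHR-COOH (or H3N+ / COO-)."""
    n_q, h_q = (-0.30, 0.33) if zwitterionic else (-0.40, 0.25)
    o_q, o2_q = (-0.55, -0.55) if zwitterionic else (-0.45, -0.40)
    rows = [
        ZRow("N", "N", (), charge=n_q),
        ZRow("CA", "C", ("N",), 1.46, charge=0.10),
        ZRow("C", "C", ("CA", "N"), 1.52, 110.0, charge=0.45 if zwitterionic else 0.50),
        # "psic" orients the carboxyl plane relative to the amine
        ZRow("O", "O", ("C", "CA", "N"), 1.24, 123.0, "psic", charge=o_q),
        ZRow("O2", "O", ("C", "CA", "N"), 1.30, 113.0, ("psic", 180.0), charge=o2_q),
        ZRow("HN1", "H", ("N", "CA", "C"), 1.02, 109.5, "am", charge=h_q),
        ZRow("HN2", "H", ("N", "CA", "C"), 1.02, 109.5, ("am", 120.0), charge=h_q),
    ]
    if zwitterionic:
        rows.append(ZRow("HN3", "H", ("N", "CA", "C"), 1.04, 109.5, ("am", 240.0), charge=h_q))
    else:
        # carboxyl proton; "ho" torsion H-O2-C-CA
        rows.append(ZRow("HO", "H", ("O2", "C", "CA"), 0.99, 108.0, "ho", charge=0.42))
    return rows


def _capped_backbone() -> list[ZRow]:
    """Dipeptide backbone: CH3-CO-NH-CHR-CO-NH-CH3 (united methyls)."""
    return [
        ZRow("CM0", "C", (), charge=0.00),
        ZRow("C0", "C", ("CM0",), 1.52, charge=0.50),
        ZRow("O0", "O", ("C0", "CM0"), 1.23, 121.0, charge=-0.50),
        ZRow("N1", "N", ("C0", "CM0", "O0"), 1.35, 115.0, 180.0, charge=-0.40),
        ZRow("H1", "H", ("N1", "C0", "O0"), 1.01, 119.0, 180.0, charge=0.30),
        ZRow("CA", "C", ("N1", "C0", "O0"), 1.45, 122.0, 0.0, charge=0.10),
        ZRow("C1", "C", ("CA", "N1", "C0"), 1.52, 110.0, "phi", charge=0.50),
        ZRow("O1", "O", ("C1", "CA", "N1"), 1.23, 121.0, ("psi", 180.0), charge=-0.50),
        ZRow("N2", "N", ("C1", "CA", "N1"), 1.35, 115.0, "psi", charge=-0.40),
        ZRow("H2", "H", ("N2", "C1", "CA"), 1.01, 119.0, 0.0, charge=0.30),
        ZRow("CM2", "C", ("N2", "C1", "CA"), 1.45, 122.0, 180.0, charge=0.00),
    ]


def _cb_row(backbone: str) -> ZRow:
    if backbone == "free":
        return ZRow("CB", "C", ("CA", "C", "N"), 1.53, 110.0, CHIRALITY_TORSION)
    return ZRow("CB", "C", ("CA", "C1", "N1"), 1.53, 110.0, CHIRALITY_TORSION)


# ---------------------------------------------------------------------------
# side chains (attached at CB; chi1 = N-CA-CB-X)

def _side_chain(ligand: str, backbone: str) -> tuple[list[ZRow], list[str], str, str | None]:
    """Rows, chi parameter names, terminal group type, ligating atom."""
    n = "N" if backbone == "free" else "N1"
    ca_refs = ("CB", "CA", n)
    if ligand == "Gly":
        return [], [], "none", None
    rows = [_cb_row(backbone)]
    if ligand == "Ala":
        return rows, [], "methyl", None
    if ligand == "Val":
        rows += [
            ZRow("CG1", "C", ca_refs, 1.53, 111.0, "chi1"),
            ZRow("CG2", "C", ca_refs, 1.53, 111.0, ("chi1", 120.0)),
        ]
        return rows, ["chi1"], "methyl", None
    if ligand == "Ser":
        rows += [
            ZRow("OG", "O", ca_refs, 1.42, 110.0, "chi1", charge=-0.40),
            ZRow("HG", "H", ("OG", "CB", "CA"), 0.98, 108.0, 180.0, charge=0.40),
        ]
        return rows, ["chi1"], "hydroxyl", "OG"
    if ligand in ("Asp", "AspH"):
        rows += [ZRow("CG", "C", ca_refs, 1.52, 112.0, "chi1",
                      charge=0.45 if ligand == "Asp" else 0.50)]
        oq = -0.70 if ligand == "Asp" else -0.45
        rows += [
            ZRow("OD1", "O", ("CG", "CB", "CA"), 1.25, 120.0, "chi2", charge=oq),
            ZRow("OD2", "O", ("CG", "CB", "CA"), 1.25, 120.0, ("chi2", 180.0),
                 charge=oq if ligand == "Asp" else -0.40),
        ]
        if ligand == "AspH":
            rows.append(ZRow("HD", "H", ("OD2", "CG", "CB"), 0.99, 108.0, 180.0, charge=0.40))
        group = "carboxylate" if ligand == "Asp" else "carboxylic_acid"
        return rows, ["chi1", "chi2"], group, "OD1"
    if ligand == "Asn":
        rows += [
            ZRow("CG", "C", ca_refs, 1.52, 112.0, "chi1", charge=0.50),
            ZRow("OD1", "O", ("CG", "CB", "CA"), 1.23, 121.0, "chi2", charge=-0.50),
            ZRow("ND2", "N", ("CG", "CB", "CA"), 1.33, 116.0, ("chi2", 180.0), charge=-0.40),
            ZRow("HD1", "H", ("ND2", "CG", "OD1"), 1.01, 119.0, 180.0, charge=0.25),
            ZRow("HD2", "H", ("ND2", "CG", "OD1"), 1.01, 119.0, 0.0, charge=0.25),
        ]
        return rows, ["chi1", "chi2"], "amide", "OD1"
    if ligand in ("Lys", "LysH"):
        nzq, hzq = (-0.50, 0.25) if ligand == "Lys" else (-0.10, 0.35)
        rows += [
            ZRow("CG", "C", ca_refs, 1.53, 112.0, "chi1"),
            ZRow("NZ", "N", ("CG", "CB", "CA"), 1.48, 111.0, "chi2", charge=nzq),
            ZRow("HZ1", "H", ("NZ", "CG", "CB"), 1.02, 109.5, 60.0, charge=hzq),
            ZRow("HZ2", "H", ("NZ", "CG", "CB"), 1.02, 109.5, 180.0, charge=hzq),
        ]
        if ligand == "LysH":
            rows.append(ZRow("HZ3", "H", ("NZ", "CG", "CB"), 1.02, 109.5, -60.0, charge=hzq))
        group = "amine" if ligand == "Lys" else "ammonium"
        return rows, ["chi1", "chi2"], group, "NZ"
    if ligand == "Cys":
        rows += [
            ZRow("SG", "S", ca_refs, 1.81, 112.0, "chi1", charge=-0.25),
            ZRow("HG", "H", ("SG", "CB", "CA"), 1.34, 96.0, 180.0, charge=0.15),
        ]
        return rows, ["chi1"], "thiol", "SG"
    raise ValueError(f"no template for ligand {ligand!r}")


# roles shared by every template of one backbone type
_FREE_ROLES = {"N": "N", "CA": "CA", "C": "C", "O": "O", "O2": "O2"}
_CAPPED_ROLES = {
    "CM_prev": "CM0", "C_prev": "C0", "O_prev": "O0", "N": "N1", "H_N": "H1",
    "CA": "CA", "C": "C1", "O": "O1", "N_next": "N2", "H_next": "H2",
    "C_next": "CM2", "CA_prev": "CM0",
}


def make_template(ligand: str, backbone: str, form: str = "neutral") -> ResidueTemplate:
    """Build the template for one panel ligand / backbone / protonation form.

    ``ligand`` is the short name with protomer suffix (``"Asp"``, ``"AspH"``,
    ``"LysH"``, ...).  For free backbones ``form`` selects ``"neutral"`` or
    ``"zwitterionic"``; capped backbones have a single form.
    """
    sc_rows, chi_names, group, sc_ligand = _side_chain(ligand, backbone)
    if backbone == "free":
        if form not in ("neutral", "zwitterionic"):
            raise ValueError(f"unknown free-backbone form {form!r}")
        rows = _free_backbone(zwitterionic=(form == "zwitterionic")) + sc_rows
        defaults = {"psic": 0.0, "am": 60.0}
        if form == "neutral":
            defaults["ho"] = 0.0
        roles = dict(_FREE_ROLES)
    elif backbone == "capped":
        form = "capped"
        rows = _capped_backbone() + sc_rows
        defaults = {"phi": -83.0, "psi": 66.0}
        roles = dict(_CAPPED_ROLES)
    else:
        raise ValueError(f"unknown backbone {backbone!r}")
    for c in chi_names:
        defaults[c] = 180.0
    names = [r.name for r in rows]
    if "CB" in names:
        roles["CB"] = "CB"
    if sc_ligand:
        roles["SC_LIG"] = sc_ligand
    return ResidueTemplate(
        name=ligand, backbone=backbone, form=form, rows=rows,
        chi_names=chi_names, default_params=defaults, roles=roles,
        terminal_group=group, sc_ligand=sc_ligand,
    )
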