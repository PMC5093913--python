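"""Geometric measurements on conformers.

Distances, IUPAC torsion angles, hydrogen-bond detection, proton-to-heavy-atom
assignment, hydrogen-bonded / cation-bridged pseudocycle tracing, side-chain
axial/equatorial orientation, and Kabsch RMSD.

Conventions
-----------
* Torsions are signed IUPAC dihedrals in the interval (-180, 180] degrees.
* Pseudocycle size counts the ring's heavy atoms plus the closing hydrogen or
  cation, which reproduces the customary C5 / C7 naming of backbone motifs.
* RMSD is minimised over proper rotations and translations only; it is
  symmetric in its arguments but, over conformations with permutational
  symmetry, not a metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .systems import CATIONS, Conformer

# Covalent radii (Angstrom, Cordero 2008) for bond perception via distance
# cutoffs; only elements that occur in scope need to be listed.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
    "Ca": 1.76, "Sr": 1.95, "Ba": 2.15, "Cd": 1.44, "Pb": 1.46, "Hg": 1.32,
}
BOND_TOLERANCE_A = 0.45  # added to the sum of covalent radii

HBOND_ELEMENTS = frozenset({"N", "O", "S"})


class GeometryError(ValueError):
    pass


@dataclass
class TorsionAngles:
    """Backbone and side-chain torsions in degrees, (-180, 180]."""

    phi: float | None
    psi: float | None
    chi: list[float] = field(default_factory=list)
    omega: float | None = None


@dataclass
class HydrogenBond:
    donor: int
    hydrogen: int
    acceptor: int
    d_ha: float
    d_da: float
    angle_dha: float
    ring_size: int | None = None

    def __post_init__(self) -> None:
        if not (self.d_ha < self.d_da):
            raise GeometryError("H...A must be shorter than D...A")
        if not (0.0 <= self.angle_dha <= 180.0):
            raise GeometryError("D-H-A angle outside [0, 180]")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (all must hold).

    ``min_d_ha`` excludes covalent H-acceptor contacts from detection.
    """

    max_d_ha: float = 2.5
    max_d_da: float = 3.5
    min_angle: float = 120.0
    min_d_ha: float = 1.1


#: Relaxed H...A cutoff for the long C5 backbone contact.
C5_CRITERIA = HBondCriteria(max_d_ha=2.7, max_d_da=3.6, min_angle=95.0)


@dataclass
class Pseudocycle:
    members: list[int]          # ordered around the ring
    closure: str                # "hydrogen_bond" | "cation_bridge"
    size: int

    def __post_init__(self) -> None:
        if self.size != len(self.members):
            raise GeometryError("size must equal the number of ring members")


@dataclass
class ProtonAssignment:
    heavy: int | None
    distance: float | None
    flag: str | None = None     # None | "shared" | "orphan"


@dataclass
class TopologyMap:
    """Names the structurally meaningful atoms of a conformer.

    ``roles`` maps role names (``N``, ``CA``, ``C``, ``O``, ``O2``, ``CB``,
    ``C_prev``/``O_prev`` for the acetyl cap, ``N_next``/``H_next``/``C_next``
    for the amide cap, ``ion``, ...) to 0-based atom indices.  ``chi`` lists
    the atom quadruples defining each side-chain torsion in order.
    """

    roles: dict[str, int] = field(default_factory=dict)
    chi: list[tuple[int, int, int, int]] = field(default_factory=list)

    def get(self, role: str) -> int | None:
        return self.roles.get(role)

    def require(self, role: str) -> int:
        if role not in self.roles:
            raise GeometryError(f"topology map lacks required role {role!r}")
        return self.roles[role]

    def serialize(self) -> str:
        parts = [f"{k}:{v}" for k, v in sorted(self.roles.items())]
        token = ";".join(parts)
        if self.chi:
            token += "|" + ";".join("-".join(map(str, q)) for q in self.chi)
        return token

    @classmethod
    def deserialize(cls, token: str) -> "TopologyMap":
        roles_part, _, chi_part = token.partition("|")
        roles = {}
        for item in roles_part.split(";"):
            if item:
                k, v = item.split(":")
                roles[k] = int(v)
        chi = []
        if chi_part:
            for quad in chi_part.split(";"):
                a, b, c, d = (int(x) for x in quad.split("-"))
                chi.append((a, b, c, d))
        return cls(roles, chi)

    def validate(self, natoms: int) -> None:
        for k, v in self.roles.items():
            if not (0 <= v < natoms):
                raise GeometryError(f"role {k!r} references out-of-range atom {v}")
        for quad in self.chi:
            for v in quad:
                if not (0 <= v < natoms):
                    raise GeometryError(f"chi torsion references out-of-range atom {v}")


def topology_of(conf: Conformer) -> TopologyMap:
    """Recover a conformer's topology map from its metadata."""
    token = conf.meta.get("topology")
    if not token:
        raise GeometryError("conformer carries no topology metadata")
    topo = token if isinstance(token, TopologyMap) else TopologyMap.deserialize(token)
    topo.validate(len(conf))
    return topo


# ---------------------------------------------------------------------------
# basic measurements

def distance(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("undefined angle: coincident points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed IUPAC dihedral p1-p2-p3-p4 in degrees, in (-180, 180].

    cis (eclipsed) arrangements give 0, trans gives 180.  Invariant under
    rigid rotation and translation.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    for b in (b0, b1, b2):
        if np.linalg.norm(b) < 1e-10:
            raise GeometryError("undefined dihedral: coincident consecutive points")
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("undefined dihedral: collinear consecutive points")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def backbone_torsions(conf: Conformer, topo: TopologyMap) -> TorsionAngles:
    """Compute phi, psi, omega and the side-chain chi torsions.

    phi = C_prev-N-CA-C and psi = N-CA-C-N_next; missing cap atoms yield
    missing angles rather than errors (free amino acids have no phi).
    """
    topo.validate(len(conf))
    P = conf.positions

    def dih(*roles: str) -> float | None:
        idx = [topo.get(r) for r in roles]
        if any(i is None for i in idx):
            return None
        return dihedral(*(P[i] for i in idx))

    phi = dih("C_prev", "N", "CA", "C")
    psi = dih("N", "CA", "C", "N_next")
    omega = dih("CA_prev", "C_prev", "N", "CA")
    chis = []
    for quad in topo.chi:
        chis.append(dihedral(*(P[i] for i in quad)))
    return TorsionAngles(phi=phi, psi=psi, chi=chis, omega=omega)


# ---------------------------------------------------------------------------
# bond perception, protons, hydrogen bonds

def covalent_bonds(conf: Conformer, include_cations: bool = False) -> list[tuple[int, int]]:
    """Distance-cutoff bond list (sum of covalent radii + tolerance)."""
    bonds = []
    P = conf.positions
    els = conf.elements
    for i in range(len(conf)):
        if not include_cations and els[i] in CATIONS:
            continue
        ri = COVALENT_RADII.get(els[i])
        if ri is None:
            raise GeometryError(f"no covalent radius for element {els[i]!r}")
        for j in range(i + 1, len(conf)):
            if not include_cations and els[j] in CATIONS:
                continue
            rj = COVALENT_RADII[els[j]]
            if distance(P[i], P[j]) <= ri + rj + BOND_TOLERANCE_A:
                bonds.append((i, j))
    return bonds


def assign_protons(
    conf: Conformer,
    covalent_cutoff: float = 1.3,
    shared_band: float = 0.15,
) -> dict[int, ProtonAssignment]:
    """Assign each hydrogen to its nearest heavy atom.

    A hydrogen whose two nearest heavy atoms lie within ``shared_band`` of each
    other is flagged ``"shared"`` (the shared acidic proton between the
    carboxyl and amino functions); one with no heavy atom within
    ``covalent_cutoff`` is flagged ``"orphan"``.
    """
    heavies = conf.heavy_indices()
    if heavies.size == 0:
        raise GeometryError("no heavy atoms")
    out: dict[int, ProtonAssignment] = {}
    P = conf.positions
    for i, el in enumerate(conf.elements):
        if el != "H":
            continue
        d = np.linalg.norm(P[heavies] - P[i], axis=1)
        order = np.argsort(d, kind="stable")
        nearest = int(heavies[order[0]])
        dist0 = float(d[order[0]])
        if dist0 > covalent_cutoff:
            out[i] = ProtonAssignment(None, None, "orphan")
            continue
        flag = None
        if order.size > 1 and float(d[order[1]]) - dist0 <= shared_band:
            flag = "shared"
        out[i] = ProtonAssignment(nearest, dist0, flag)
    return out


def detect_hbonds(
    conf: Conformer,
    criteria: HBondCriteria | None = None,
    proton_map: dict[int, ProtonAssignment] | None = None,
) -> list[HydrogenBond]:
    """Find intramolecular hydrogen bonds D-H...A (D, A in {N, O, S}).

    Every returned bond satisfies all three criteria (H...A and D...A
    distances, D-H-A angle); the list is sorted by the H...A distance.
    """
    crit = criteria or HBondCriteria()
    protons = proton_map or assign_protons(conf)
    P = conf.positions
    els = conf.elements
    acceptors = [
        i for i, e in enumerate(els)
        if e in HBOND_ELEMENTS
    ]
    bonds: list[HydrogenBond] = []
    for h, asg in protons.items():
        if asg.heavy is None or els[asg.heavy] not in HBOND_ELEMENTS:
            continue
        d = asg.heavy
        for a in acceptors:
            if a == d:
                continue
            d_ha = distance(P[h], P[a])
            if d_ha > crit.max_d_ha or d_ha < crit.min_d_ha:
                continue
            d_da = distance(P[d], P[a])
            if d_da > crit.max_d_da or not d_ha < d_da:
                continue
            ang = angle(P[d], P[h], P[a])
            if ang < crit.min_angle:
                continue
            bonds.append(HydrogenBond(d, h, a, d_ha, d_da, ang))
    bonds.sort(key=lambda b: b.d_ha)
    return bonds


# ---------------------------------------------------------------------------
# pseudocycles and side-chain orientation

def _heavy_graph(conf: Conformer) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(len(conf))}
    for i, j in covalent_bonds(conf):
        if conf.elements[i] == "H" or conf.elements[j] == "H":
            continue
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _shortest_path(adj: dict[int, set[int]], start: int, goal: int) -> list[int] | None:
    from collections import deque

    prev: dict[int, int] = {start: start}
    q = deque([start])
    while q:
        u = q.popleft()
        if u == goal:
            path = [u]
            while path[-1] != start:
                path.append(prev[path[-1]])
            return path[::-1]
        for v in sorted(adj[u]):
            if v not in prev:
                prev[v] = u
                q.append(v)
    return None


def find_pseudocycle(
    conf: Conformer,
    closure: HydrogenBond | tuple[int, int, int],
) -> Pseudocycle:
    """Trace the ring closed by a hydrogen bond or by a bridging cation.

    For an H-bond closure the ring is the covalent heavy-atom path from donor
    to acceptor plus the hydrogen; for a cation bridge ``(ion, o1, o2)`` it is
    the path between the two bridged oxygens plus the cation.  Size counts
    heavy ring members plus the closing H or cation, reproducing the C5 / C7
    naming convention.
    """
    adj = _heavy_graph(conf)
    if isinstance(closure, HydrogenBond):
        path = _shortest_path(adj, closure.donor, closure.acceptor)
        if path is None or len(path) < 2:
            raise GeometryError("no ring: donor and acceptor not covalently connected")
        members = path + [closure.hydrogen]
        return Pseudocycle(members, "hydrogen_bond", len(members))
    ion, o1, o2 = closure
    if conf.elements[ion] not in CATIONS:
        raise GeometryError(f"atom {ion} is not a registered cation")
    path = _shortest_path(adj, o1, o2)
    if path is None or len(path) < 2:
        raise GeometryError("no ring: bridged oxygens not covalently connected")
    members = path + [ion]
    return Pseudocycle(members, "cation_bridge", len(members))


def ring_plane_normal(conf: Conformer, pseudocycle: Pseudocycle) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring members."""
    pts = conf.positions[pseudocycle.members]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    return vt[-1]


def side_chain_orientation(
    conf: Conformer,
    pseudocycle: Pseudocycle,
    ca_index: int,
    cb_index: int | None,
    threshold_deg: float = 45.0,
) -> str:
    """Classify the side chain as ``"axial"`` or ``"equatorial"``.

    The angle theta between the CA->CB vector and the normal of the ring's
    least-squares plane decides: theta < 45 deg means the side chain points
    along the ring axis (axial), otherwise it lies in the ring plane
    (equatorial).
    """
    if cb_index is None:
        raise GeometryError("no side chain (Gly has no C-beta)")
    if len(pseudocycle.members) < 4:
        raise GeometryError("pseudocycle too small for a plane fit")
    normal = ring_plane_normal(conf, pseudocycle)
    v = conf.positions[cb_index] - conf.positions[ca_index]
    nv = np.linalg.norm(v)
    if nv < 1e-10:
        raise GeometryError("degenerate CA->CB vector")
    cosang = abs(float(np.dot(v / nv, normal)))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return "axial" if theta < threshold_deg else "equatorial"


# ---------------------------------------------------------------------------
# superposition

def kabsch_rmsd(a: Conformer, b: Conformer, heavy_only: bool = False) -> float:
    """Minimal RMSD between two conformers over proper rotations + translation.

    Requires identical element sequences; symmetric in its arguments.
    """
    if a.elements != b.elements:
        raise GeometryError("mismatched atoms: element sequences differ")
    idx = a.heavy_indices() if heavy_only else np.arange(len(a))
    pa = a.positions[idx] - a.positions[idx].mean(axis=0)
    pb = b.positions[idx] - b.positions[idx].mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(idx)))
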