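"""Internal-to-Cartesian construction of template conformers and ion placement.

Atoms are placed sequentially (NeRF-style): each new atom D is positioned from
a bond length to C, a bond angle D-C-B, and a torsion D-C-B-A, so that the
measured IUPAC torsion equals the requested one to numerical precision.
"""

from __future__ import annotations

import numpy as np

from ..geometry import GeometryError, TopologyMap, covalent_bonds, dihedral, wrap_angle
from ..systems import CATIONS, Conformer
from .templates import ResidueTemplate

MIN_NONBONDED_A = 0.7


class BuildError(ValueError):
    pass


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise BuildError("degenerate reference geometry")
    return v / n


def _place(c: np.ndarray, b: np.ndarray, a: np.ndarray,
           dist: float, ang_deg: float, tors_deg: float) -> np.ndarray:
    """Place atom D given refs C (bond), B (angle D-C-B), A (torsion D-C-B-A)."""
    theta = np.radians(ang_deg)
    phi = np.radians(tors_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(a - b, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -dist * np.cos(theta),
        -dist * np.sin(theta) * np.cos(phi),
        -dist * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _resolve_torsion(spec, params: dict[str, float]) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if isinstance(spec, str):
        if spec not in params:
            raise BuildError(f"missing torsion parameter {spec!r}")
        return params[spec]
    name, offset = spec
    if name not in params:
        raise BuildError(f"missing torsion parameter {name!r}")
    return wrap_angle(params[name] + offset)


def build_peptide(
    template: ResidueTemplate,
    phi: float | None = None,
    psi: float | None = None,
    chis: tuple[float, ...] = (),
    params: dict[str, float] | None = None,
    check_clash: bool = True,
) -> Conformer:
    """Realize a template at the requested torsions.

    ``phi``/``psi`` apply to capped templates; ``chis`` supplies side-chain
    torsions in template order; ``params`` overrides any named torsion
    parameter (``psic``, ``ho``, ``am``, ...).  Requested angles must lie in
    (-180, 180].  The returned conformer carries the topology map, per-atom
    toy charges and atom names in its metadata.
    """
    p = dict(template.default_params)
    if params:
        p.update(params)
    if phi is not None:
        p["phi"] = phi
    if psi is not None:
        p["psi"] = psi
    if chis:
        if len(chis) > len(template.chi_names):
            raise BuildError("more chi values than side-chain torsions")
        for name, val in zip(template.chi_names, chis):
            p[name] = val
    for key, val in p.items():
        if not (-180.0 < val <= 180.0):
            raise BuildError(f"torsion {key}={val} outside (-180, 180]")

    names = template.atom_names
    index = {n: i for i, n in enumerate(names)}
    pos = np.zeros((len(names), 3))
    for i, row in enumerate(template.rows):
        if i == 0:
            pos[i] = (0.0, 0.0, 0.0)
        elif i == 1:
            pos[i] = pos[index[row.refs[0]]] + (row.dist, 0.0, 0.0)
        elif i == 2:
            c = pos[index[row.refs[0]]]
            b = pos[index[row.refs[1]]]
            theta = np.radians(row.ang)
            bc = _unit(b - c)
            perp = np.array([-bc[1], bc[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            perp = _unit(perp)
            pos[i] = c + row.dist * (np.cos(theta) * bc + np.sin(theta) * perp)
        else:
            c = pos[index[row.refs[0]]]
            b = pos[index[row.refs[1]]]
            a = pos[index[row.refs[2]]]
            tors = _resolve_torsion(row.tors, p)
            pos[i] = _place(c, b, a, row.dist, row.ang, tors)
            got = dihedral(pos[i], c, b, a)
            if abs(wrap_angle(got - tors)) > 1e-6:
                raise BuildError(
                    f"torsion placement failed for {row.name}: {got} != {tors}"
                )

    elements = [r.element for r in template.rows]
    charges = [r.charge for r in template.rows]
    roles = {role: index[atom] for role, atom in template.roles.items()}
    chi_quads: list[tuple[int, int, int, int]] = []
    for cname in template.chi_names:
        row = next(r for r in template.rows if r.tors == cname)
        a3, a2, a1 = (index[r] for r in row.refs)
        chi_quads.append((a1, a2, a3, index[row.name]))
    topo = TopologyMap(roles, chi_quads)
    conf = Conformer(
        elements, pos, energy=None,
        meta={
            "topology": topo.serialize(),
            "charges": charges,
            "atom_names": list(names),
            "template": f"{template.name}/{template.backbone}/{template.form}",
        },
    )
    if check_clash:
        _check_clashes(conf)
    return conf


def _check_clashes(conf: Conformer) -> None:
    bonded = set()
    for i, j in covalent_bonds(conf, include_cations=True):
        bonded.add((i, j))
    P = conf.positions
    for i in range(len(conf)):
        for j in range(i + 1, len(conf)):
            if (i, j) in bonded:
                continue
            if np.linalg.norm(P[i] - P[j]) < MIN_NONBONDED_A:
                raise BuildError(
                    f"clash: atoms {i} and {j} closer than {MIN_NONBONDED_A} A"
                )


# ---------------------------------------------------------------------------
# ion placement

ION_SITES = ("carbonyl_bridge", "carboxylate", "amine_carbonyl", "side_chain")


def _site_atoms(conf: Conformer, site: str) -> list[int]:
    from ..geometry import topology_of

    topo = topology_of(conf)
    need = {
        "carbonyl_bridge": ("O_prev", "O"),
        "carboxylate": ("O", "O2"),
        "amine_carbonyl": ("N", "O"),
        "side_chain": ("SC_LIG",),
    }
    if site not in need:
        raise BuildError(f"unknown ion site {site!r}")
    idx = []
    for role in need[site]:
        i = topo.get(role)
        if i is None:
            raise BuildError(f"site {site!r} requires missing atom role {role!r}")
        idx.append(i)
    return idx


def place_ion(
    conf: Conformer,
    site: str,
    distance_a: float,
    ion: str = "Ca",
) -> Conformer:
    """Attach a divalent cation at a named binding site.

    For two-atom sites the ion is placed on the outward bisector plane so both
    ligand distances equal ``distance_a``; for a single-atom site it sits at
    ``distance_a`` along the outward direction.  The new conformer gains an
    ``ion`` topology role and a +2 toy charge.
    """
    if ion not in CATIONS:
        raise BuildError(f"unknown cation {ion!r}")
    from ..geometry import topology_of

    lig = _site_atoms(conf, site)
    P = conf.positions
    heavy = conf.heavy_indices()
    centroid = P[heavy].mean(axis=0)
    if len(lig) == 2:
        l1, l2 = P[lig[0]], P[lig[1]]
        mid = 0.5 * (l1 + l2)
        w = _unit(l2 - l1)
        u0 = mid - centroid
        u0 = u0 - np.dot(u0, w) * w
        if np.linalg.norm(u0) < 1e-8:
            u0 = np.cross(w, [0.0, 0.0, 1.0])
            if np.linalg.norm(u0) < 1e-8:
                u0 = np.cross(w, [0.0, 1.0, 0.0])
        u = _unit(u0)
        h = 0.5 * np.linalg.norm(l2 - l1)
        if distance_a <= h:
            raise BuildError(
                f"requested distance {distance_a} A shorter than half the "
                f"ligand separation ({h:.2f} A)"
            )
        x = mid + np.sqrt(distance_a**2 - h**2) * u
    else:
        l1 = P[lig[0]]
        x = l1 + distance_a * _unit(l1 - centroid)

    topo = topology_of(conf)
    new = Conformer(
        conf.elements + [ion],
        np.vstack([P, x]),
        conf.energy,
        dict(conf.meta),
    )
    topo.roles["ion"] = len(conf)
    new.meta["topology"] = topo.serialize()
    if "charges" in new.meta:
        new.meta["charges"] = list(new.meta["charges"]) + [2.0]
    if "atom_names" in new.meta:
        new.meta["atom_names"] = list(new.meta["atom_names"]) + [ion]
    return new
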