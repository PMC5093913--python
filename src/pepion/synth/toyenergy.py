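"""Toy interaction potential for synthetic ensembles.

Total energy (eV) = screened Coulomb over nonbonded pairs + Lennard-Jones +
an explicit hydrogen-bond well + (for Hg-like ions) a short-range attraction
toward the two nearest oxygens, emulating the covalency-driven contraction of
two ligand distances.  All terms depend only on internal distances and
angles, so the energy is invariant under rigid motion.
"""

from __future__ import annotations

import numpy as np

from ..geometry import HBondCriteria, covalent_bonds, detect_hbonds
from ..systems import CATIONS, Conformer
from .templates import ToyEnergyParams, default_toy_params


class EnergyError(ValueError):
    pass


def _exclusions(conf: Conformer) -> set[tuple[int, int]]:
    """1-2 and 1-3 pairs over the covalent graph (cations never excluded)."""
    adj: dict[int, set[int]] = {i: set() for i in range(len(conf))}
    for i, j in covalent_bonds(conf):
        adj[i].add(j)
        adj[j].add(i)
    excl: set[tuple[int, int]] = set()
    for i, j in ((i, j) for i in adj for j in adj[i] if i < j):
        excl.add((i, j))
    for k in adj:
        for i in adj[k]:
            for j in adj[k]:
                if i < j:
                    excl.add((i, j))
    return excl


def toy_energy(conf: Conformer, params: ToyEnergyParams | None = None) -> float:
    """Evaluate the toy potential for a typed conformer.

    Atom charges must be present in ``conf.meta['charges']`` (the builder
    provides them); an untyped conformer raises ``EnergyError``.
    """
    p = params or default_toy_params()
    charges = conf.meta.get("charges")
    if charges is None or len(charges) != len(conf):
        raise EnergyError("untyped atom: conformer carries no per-atom charges")
    q = np.asarray(charges, dtype=float)
    if len(conf) == 1:
        return 0.0
    P = conf.positions
    els = conf.elements
    excl = _exclusions(conf)

    e = 0.0
    for i in range(len(conf)):
        si = p.lj_sigma_a.get(els[i])
        if si is None:
            raise EnergyError(f"untyped atom: no LJ sigma for element {els[i]!r}")
        for j in range(i + 1, len(conf)):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(P[i] - P[j]))
            if r < 1e-6:
                raise EnergyError("coincident atoms")
            e += p.coulomb_k_ev_a * q[i] * q[j] / (p.dielectric * r)
            sig = 0.5 * (si + p.lj_sigma_a[els[j]])
            # ion-ligand contacts sit at the toy contact distance; place the
            # LJ minimum there so Coulomb sets the trend, LJ only the wall
            if els[i] in CATIONS or els[j] in CATIONS:
                ion = els[i] if els[i] in CATIONS else els[j]
                sig = (p.ions[ion].radius_a + p.contact_offset_a) * 2 ** (-1 / 6)
            sr6 = (sig / r) ** 6
            e += 4.0 * p.lj_epsilon_ev * (sr6 * sr6 - sr6)

    # hydrogen-bond wells (gaussian in the H...A distance, detected with a
    # slightly relaxed geometric criterion so long C5-type contacts count)
    for hb in detect_hbonds(conf, HBondCriteria(max_d_ha=2.8, max_d_da=3.8, min_angle=95.0)):
        ang_fac = np.cos(np.radians(180.0 - hb.angle_dha)) ** 2
        e -= p.hbond_depth_ev * ang_fac * np.exp(
            -((hb.d_ha - p.hbond_r0_a) / p.hbond_width_a) ** 2
        )

    # Hg-like two-short-ligand term
    for i, el in enumerate(els):
        if el in CATIONS and p.ions[el].hg_like:
            o_idx = [j for j, e2 in enumerate(els) if e2 == "O"]
            if o_idx:
                d = np.linalg.norm(P[o_idx] - P[i], axis=1)
                for r in np.sort(d)[:2]:
                    e -= p.hg_depth_ev * np.exp(-((r - p.hg_r0_a) / p.hg_width_a) ** 2)
    return float(e)
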