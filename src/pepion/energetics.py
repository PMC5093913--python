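"""Energy hierarchies, binding energies, and cross-ion trend statistics.

Binding energies follow the convention

    E_bind = E(ligand, global min) + E(ion) - E(complex, global min)

so a positive value means the bound complex lies below the separated
constituents and "strongest to weakest" sorts descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .geometry import kabsch_rmsd
from .systems import Conformer, Ensemble, SystemDescriptor

#: eV -> kJ/mol conversion used throughout (the customary rounding in which
#: ~4 eV corresponds to ~400 kJ/mol)
EV_TO_KJ_PER_MOL = 96.485


class EnergeticsError(ValueError):
    pass


@dataclass
class HierarchyEntry:
    conformer: Conformer
    rel_ev: float
    rel_kj_mol: float
    rank: int


@dataclass
class EnergyHierarchy:
    system: SystemDescriptor
    entries: list[HierarchyEntry]
    dedup_threshold_a: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def global_minimum(self) -> Conformer:
        return self.entries[0].conformer


def build_hierarchy(ensemble: Ensemble, dedup_threshold_a: float = 0.3) -> EnergyHierarchy:
    """Deduplicate and sort an ensemble into an energy hierarchy.

    Conformers within the heavy-atom RMSD threshold of a lower-energy
    conformer are merged (the lowest-energy representative is kept), the rest
    are sorted ascending with relative energies in eV and kJ/mol.
    """
    if len(ensemble) == 0:
        raise EnergeticsError("empty ensemble")
    for c in ensemble:
        if c.energy is None:
            raise EnergeticsError(f"conformer without energy in {ensemble.system_id}")
    ordered = sorted(ensemble.conformers, key=lambda c: c.energy)
    kept: list[Conformer] = []
    for cand in ordered:
        if any(kabsch_rmsd(cand, ref, heavy_only=True) <= dedup_threshold_a for ref in kept):
            continue
        kept.append(cand)
    e0 = kept[0].energy
    entries = [
        HierarchyEntry(c, c.energy - e0, (c.energy - e0) * EV_TO_KJ_PER_MOL, rank)
        for rank, c in enumerate(kept)
    ]
    return EnergyHierarchy(ensemble.system, entries, dedup_threshold_a)


def count_conformers(hierarchy: EnergyHierarchy, window_ev: float = math.inf) -> int:
    """Number of hierarchy entries within ``window_ev`` of the global minimum."""
    if window_ev < 0:
        raise EnergeticsError("window must be non-negative")
    return sum(1 for e in hierarchy.entries if e.rel_ev <= window_ev)


def binding_energy(
    e_complex_min: float,
    e_ligand_min: float,
    e_ion: float,
) -> float:
    """E_bind = (E_ligand + E_ion) - E_complex, in eV (positive = bound)."""
    return (e_ligand_min + e_ion) - e_complex_min


@dataclass
class BindingRecord:
    system: SystemDescriptor
    ion: str
    e_bind_ev: float
    complex_min_class: str | None = None


@dataclass
class TrendTable:
    """Ligand x ion binding-energy matrix with derived rank statistics."""

    matrix: pd.DataFrame                      # index: ligand key, columns: ions
    records: list[BindingRecord] = field(default_factory=list)

    def ions(self) -> list[str]:
        return list(self.matrix.columns)

    def ligands(self) -> list[str]:
        return list(self.matrix.index)


def build_trend_table(records: list[BindingRecord], backbone: str | None = None) -> TrendTable:
    """Assemble per-(ligand, ion) binding records into a trend matrix.

    Ligand keys carry the protomer suffix (Glu and GluH are separate rows).
    """
    recs = [r for r in records if backbone is None or r.system.backbone == backbone]
    if not recs:
        raise EnergeticsError("no binding records")
    data: dict[str, dict[str, float]] = {}
    for r in recs:
        key = r.system.ligand_name if backbone else f"{r.system.ligand_name}_{r.system.backbone}"
        data.setdefault(key, {})[r.ion] = r.e_bind_ev
    mat = pd.DataFrame(data).T.sort_index()
    return TrendTable(mat, recs)


def affinity_ranking(table: TrendTable, ion: str) -> tuple[list[str], bool]:
    """Ligands sorted by descending binding energy to ``ion``.

    Ties are broken lexicographically; the returned flag is True if any tie
    occurred.  Missing entries raise, naming the offending ligands.
    """
    if ion not in table.matrix.columns:
        raise EnergeticsError(f"missing ion column {ion!r}")
    col = table.matrix[ion]
    missing = sorted(col[col.isna()].index)
    if missing:
        raise EnergeticsError(f"missing binding entries for {ion}: {missing}")
    ordered = sorted(col.index, key=lambda lig: (-col[lig], lig))
    has_tie = col.duplicated(keep=False).any()
    return ordered, bool(has_tie)


def ion_ordering(table: TrendTable, ligand: str) -> tuple[list[str], bool]:
    """Ions sorted by descending binding energy to ``ligand`` (ties flagged)."""
    if ligand not in table.matrix.index:
        raise EnergeticsError(f"missing ligand row {ligand!r}")
    row = table.matrix.loc[ligand]
    missing = sorted(row[row.isna()].index)
    if missing:
        raise EnergeticsError(f"missing binding entries for {ligand}: {missing}")
    ordered = sorted(row.index, key=lambda i: (-row[i], i))
    has_tie = row.duplicated(keep=False).any()
    return ordered, bool(has_tie)


def rank_concordance(series_a: dict[str, float], series_b: dict[str, float]) -> dict:
    """Kendall tau-b between two per-ligand binding series.

    Also reports the maximum absolute binding-energy deviation between the
    series (the quantity behind the calcium/lead mimicry observation).
    """
    keys_a, keys_b = set(series_a), set(series_b)
    if keys_a != keys_b:
        raise EnergeticsError(
            f"mismatched ligand sets: {sorted(keys_a ^ keys_b)} not shared"
        )
    if len(keys_a) < 2:
        raise EnergeticsError("need at least 2 ligands")
    keys = sorted(keys_a)
    a = np.array([series_a[k] for k in keys])
    b = np.array([series_b[k] for k in keys])
    tau = float(kendalltau(a, b, variant="b").statistic)
    return {"tau": tau, "max_abs_dev_ev": float(np.max(np.abs(a - b))), "n": len(keys)}


def contraction_report(
    bare_hierarchies: dict[str, EnergyHierarchy],
    ion_hierarchies: dict[str, EnergyHierarchy],
) -> pd.DataFrame:
    """Per-system conformer-count contraction upon cation coordination.

    Keys of ``ion_hierarchies`` are matched to bare systems by ligand name and
    backbone.  Unmatched ion systems are listed in the frame's attrs, not
    fatal; an empty intersection raises.
    """
    bare_by_key = {
        (h.system.ligand_name, h.system.backbone): h for h in bare_hierarchies.values()
    }
    rows = []
    unmatched = []
    for sys_id, ih in sorted(ion_hierarchies.items()):
        key = (ih.system.ligand_name, ih.system.backbone)
        bh = bare_by_key.get(key)
        if bh is None:
            unmatched.append(sys_id)
            continue
        rows.append({
            "system": sys_id,
            "ligand": key[0],
            "backbone": key[1],
            "ion": ih.system.complexation,
            "bare_count": len(bh),
            "ion_count": len(ih),
            "ratio": len(ih) / len(bh),
        })
    if not rows:
        raise EnergeticsError("no matched bare/ion system pairs")
    df = pd.DataFrame(rows)
    df.attrs["unmatched"] = unmatched
    df.attrs["total_bare"] = int(df["bare_count"].sum())
    df.attrs["total_ion"] = int(df["ion_count"].sum())
    return df
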