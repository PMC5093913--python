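"""Literature reference values for the six divalent cations and the
binding-energy / acute-toxicity rank correlation.

The packaged table carries Shannon octahedral ionic radii, standard hydration
enthalpies, and median lethal doses (LD50) of the chloride salts, each with a
citation string.  LD50 ranges (Ba) are kept as intervals; the correlation uses
the geometric mean of the interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .systems import CATIONS


@dataclass(frozen=True)
class IonReference:
    ion: str
    shannon_radius_pm: float
    hydration_enthalpy_kJ_mol: float
    chloride_ld50_mg_kg: tuple[float, float]   # (low, high); equal if a point
    citation: str

    def __post_init__(self) -> None:
        if self.shannon_radius_pm <= 0:
            raise ValueError("radius must be positive")
        low, high = self.chloride_ld50_mg_kg
        if not (0 < low <= high):
            raise ValueError("LD50 interval must satisfy 0 < low <= high")

    @property
    def ld50_point(self) -> float:
        """Geometric mean of the LD50 interval (mg/kg)."""
        low, high = self.chloride_ld50_mg_kg
        return float(np.sqrt(low * high))


def load_reference_table(path: str | None = None) -> dict[str, IonReference]:
    """Load the packaged (or a user-supplied) ion reference CSV."""
    if path is None:
        src = resources.files("pepion.data").joinpath("ion_reference.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out: dict[str, IonReference] = {}
    for _, row in df.iterrows():
        out[row["ion"]] = IonReference(
            ion=row["ion"],
            shannon_radius_pm=float(row["shannon_radius_pm"]),
            hydration_enthalpy_kJ_mol=float(row["hydration_enthalpy_kJ_mol"]),
            chloride_ld50_mg_kg=(float(row["ld50_low_mg_kg"]), float(row["ld50_high_mg_kg"])),
            citation=str(row["citation"]),
        )
    return out


_TABLE: dict[str, IonReference] | None = None


def ion_reference(ion: str) -> IonReference:
    """Reference record for one of the six study cations."""
    global _TABLE
    if ion not in CATIONS:
        raise KeyError(f"unknown ion {ion!r}; expected one of {CATIONS}")
    if _TABLE is None:
        _TABLE = load_reference_table()
    return _TABLE[ion]


def _kendall(x: np.ndarray, y: np.ndarray) -> float:
    tau = kendalltau(x, y, variant="b").statistic
    return float(tau)


def toxicity_correlation(
    binding_means_per_ion: dict[str, float],
    ld50_table: dict[str, float] | None = None,
    exclusions: tuple[str, ...] = (),
) -> dict:
    """Rank-correlate mean binding energies with acute LD50 values.

    Returns the Kendall tau-b between mean binding energy and LD50 over the
    retained ions (a negative tau means stronger binders are more acutely
    toxic), plus a leave-one-out scan flagging the ion whose removal most
    increases |tau| — the trend outlier.
    """
    ions = [i for i in binding_means_per_ion if i not in exclusions]
    if len(ions) < 3:
        raise ValueError(f"need at least 3 ions after exclusions, got {len(ions)}")
    if ld50_table is None:
        ld50_table = {i: ion_reference(i).ld50_point for i in ions}
    e = np.array([binding_means_per_ion[i] for i in ions])
    t = np.array([ld50_table[i] for i in ions])
    tau = _kendall(e, t)
    loo: dict[str, float] = {}
    for k, ion in enumerate(sorted(ions)):
        keep = [i for i in ions if i != ion]
        if len(keep) < 2:
            continue
        idx = [ions.index(i) for i in keep]
        loo[ion] = _kendall(e[idx], t[idx])
    outlier = max(sorted(loo), key=lambda i: abs(loo[i]) - abs(tau))
    return {
        "ions": sorted(ions),
        "tau": tau,
        "leave_one_out_tau": loo,
        "outlier": outlier,
        "outlier_tau_gain": abs(loo[outlier]) - abs(tau),
        "ld50_mg_kg": {i: float(ld50_table[i]) for i in ions},
        "binding_mean_ev": {i: float(binding_means_per_ion[i]) for i in ions},
    }
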