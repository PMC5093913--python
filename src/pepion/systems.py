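"""System taxonomy and in-memory containers for conformer ensembles.

The study grid covers 20 proteinogenic side chains attached to two backbone
types (free termini or acetyl/amino-methyl capped, the "dipeptide" form), each
either isolated or in complex with one of six divalent cations, for a total of
20 x 2 x 7 = 280 molecular systems at the default protonation level.  Side
chains with an alternative protonation state (Arg/ArgH, Lys/LysH, His/HisH,
Asp/AspH, Glu/GluH) contribute one extra protomer per backbone/complexation
combination when protomers are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

CANONICAL_SIDE_CHAINS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: side chains with a second protonation state considered in the study;
#: the variant is the H-form (ArgH, LysH, HisH, AspH, GluH).
PROTOMER_REGISTRY: dict[str, str] = {
    "Arg": "protonated",
    "Lys": "protonated",
    "His": "protonated",
    "Asp": "protonated",
    "Glu": "protonated",
}

CATIONS: tuple[str, ...] = ("Ca", "Ba", "Sr", "Cd", "Pb", "Hg")
COMPLEXATIONS: tuple[str, ...] = ("none",) + CATIONS
BACKBONES: tuple[str, ...] = ("free", "capped")
PROTOMERS: tuple[str, ...] = ("default", "protonated", "deprotonated")

# Element symbols accepted by the readers/builders (main-group + the study's
# cations + common transition metals; enough for any conformer in scope).
VALID_ELEMENTS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn""".split()
)


class SystemError_(ValueError):
    """Invalid system descriptor or ensemble."""


@dataclass(frozen=True, order=True)
class SystemDescriptor:
    """Identifies one molecular system of the study grid."""

    side_chain: str
    protomer: str = "default"
    backbone: str = "free"
    complexation: str = "none"

    def __post_init__(self) -> None:
        if self.side_chain not in CANONICAL_SIDE_CHAINS:
            raise SystemError_(f"unknown side chain {self.side_chain!r}")
        if self.protomer not in PROTOMERS:
            raise SystemError_(f"unknown protomer {self.protomer!r}")
        if self.protomer != "default" and self.side_chain not in PROTOMER_REGISTRY:
            raise SystemError_(
                f"{self.side_chain} has no registered alternative protomer"
            )
        if self.backbone not in BACKBONES:
            raise SystemError_(f"unknown backbone {self.backbone!r}")
        if self.complexation not in COMPLEXATIONS:
            raise SystemError_(f"unknown complexation {self.complexation!r}")

    @property
    def ligand_name(self) -> str:
        """Short name with the protomer suffix, e.g. ``LysH``."""
        return self.side_chain + ("H" if self.protomer == "protonated" else "")

    @property
    def system_id(self) -> str:
        return f"{self.ligand_name}_{self.backbone}_{self.complexation}"

    @classmethod
    def from_id(cls, system_id: str) -> "SystemDescriptor":
        try:
            ligand, backbone, complexation = system_id.split("_")
        except ValueError as exc:
            raise SystemError_(f"malformed system id {system_id!r}") from exc
        protomer = "default"
        side_chain = ligand
        if ligand.endswith("H") and ligand[:-1] in PROTOMER_REGISTRY:
            side_chain, protomer = ligand[:-1], "protonated"
        return cls(side_chain, protomer, backbone, complexation)


def enumerate_systems(
    include_protomers: bool = False,
    side_chain: str | None = None,
    backbone: str | None = None,
    complexation: str | None = None,
    registry: Mapping[str, str] | None = None,
) -> list[SystemDescriptor]:
    """Enumerate the study grid in deterministic (lexicographic) order.

    With ``include_protomers`` off the grid is exactly 20 side chains x
    2 backbones x 7 complexation states = 280 descriptors.  With the flag on,
    each registry entry adds its alternative protomer for every backbone /
    complexation combination.  Optional keyword filters restrict the output.
    """
    registry = PROTOMER_REGISTRY if registry is None else dict(registry)
    out: list[SystemDescriptor] = []
    for sc in CANONICAL_SIDE_CHAINS:
        protomers = ["default"]
        if include_protomers and sc in registry:
            protomers.append(registry[sc])
        for prot in protomers:
            for bb in BACKBONES:
                for cx in COMPLEXATIONS:
                    out.append(SystemDescriptor(sc, prot, bb, cx))
    if side_chain is not None:
        out = [d for d in out if d.side_chain == side_chain]
    if backbone is not None:
        out = [d for d in out if d.backbone == backbone]
    if complexation is not None:
        out = [d for d in out if d.complexation == complexation]
    return sorted(out)


@dataclass(frozen=True)
class Atom:
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.element not in VALID_ELEMENTS:
            raise SystemError_(f"invalid element symbol {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SystemError_("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class Conformer:
    """One geometry with an optional total energy (eV) and provenance metadata.

    Coordinates are stored as an (N, 3) float array in Angstrom; atom order is
    stable through read/write round trips.
    """

    def __init__(
        self,
        elements: Iterable[str],
        positions: np.ndarray,
        energy: float | None = None,
        meta: dict | None = None,
    ) -> None:
        self.elements: list[str] = list(elements)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3).copy()
        if len(self.elements) != len(self.positions):
            raise SystemError_("element list and coordinate array disagree")
        if len(self.elements) < 1:
            raise SystemError_("conformer has no atoms")
        for el in self.elements:
            if el not in VALID_ELEMENTS:
                raise SystemError_(f"invalid element symbol {el!r}")
        if not np.all(np.isfinite(self.positions)):
            raise SystemError_("non-finite coordinates")
        if energy is not None and not np.isfinite(energy):
            raise SystemError_("non-finite energy")
        self.energy = None if energy is None else float(energy)
        self.meta: dict = dict(meta or {})

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def atoms(self) -> list[Atom]:
        return [Atom(e, p) for e, p in zip(self.elements, self.positions)]

    def copy(self) -> "Conformer":
        return Conformer(self.elements, self.positions, self.energy, dict(self.meta))

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        e = "None" if self.energy is None else f"{self.energy:.6f} eV"
        return f"<Conformer {len(self)} atoms, E={e}>"


class Ensemble:
    """All conformers of one molecular system (shared element composition)."""

    def __init__(self, system: SystemDescriptor | str, conformers: Iterable[Conformer]):
        self.system = (
            system if isinstance(system, SystemDescriptor)
            else SystemDescriptor.from_id(system)
        )
        self.conformers: list[Conformer] = list(conformers)
        if not self.conformers:
            raise SystemError_("empty ensemble")
        ref = sorted(self.conformers[0].elements)
        for i, c in enumerate(self.conformers):
            if sorted(c.elements) != ref:
                raise SystemError_(
                    f"conformer {i} element multiset differs from the ensemble"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    @property
    def system_id(self) -> str:
        return self.system.system_id
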