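"""Readers and writers for the conformer file formats.

Two plain-text dialects are supported:

* multi-frame extended XYZ, where the per-frame comment line carries
  whitespace-separated ``key=value`` tokens (``energy`` in eV and ``system``
  are required; ``label``, ``topology`` and ``charges`` are optional), and
* a single-structure quantum-chemistry geometry dialect with lines
  ``atom  x y z  element`` (Angstrom) and ``#`` comments; periodic lattice
  keywords are rejected.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import yaml

from .systems import Conformer, Ensemble, SystemDescriptor, VALID_ELEMENTS


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_comment_tokens(line: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for tok in line.split():
        if "=" in tok:
            key, val = tok.split("=", 1)
            out[key] = val
    return out


def read_extxyz(path: str | os.PathLike) -> list[Ensemble]:
    """Read a multi-frame extended-XYZ file into per-system ensembles.

    Frames are grouped by their ``system`` id in order of first appearance.
    """
    groups: dict[str, list[Conformer]] = {}
    with open(path, "r", encoding="ascii") as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: malformed atom count {lines[i]!r}")
        if natoms < 2:
            raise ParseError(f"line {i + 1}: frame must contain at least 2 atoms")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 >= len(lines):
            raise ParseError(f"line {i + 1}: truncated frame")
        tokens = _parse_comment_tokens(lines[i + 1])
        if "energy" not in tokens:
            raise ParseError(f"line {i + 2}: missing energy key in comment line")
        if "system" not in tokens:
            raise ParseError(f"line {i + 2}: missing system key in comment line")
        try:
            energy = float(tokens["energy"])
        except ValueError:
            raise ParseError(f"line {i + 2}: unparseable energy {tokens['energy']!r}")
        elements: list[str] = []
        coords = np.empty((natoms, 3), dtype=float)
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(f"line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'El x y z'")
            if parts[0] not in VALID_ELEMENTS:
                raise ParseError(f"line {ln + 1}: unknown element {parts[0]!r}")
            elements.append(parts[0])
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(f"line {ln + 1}: unparseable coordinates")
        meta = {
            "source": str(path),
            "frame": frame,
            "system": tokens["system"],
        }
        for extra in ("label", "topology", "charges"):
            if extra in tokens:
                meta[extra] = tokens[extra]
        if "charges" in tokens:
            meta["charges"] = [float(q) for q in tokens["charges"].split(",")]
        groups.setdefault(tokens["system"], []).append(
            Conformer(elements, coords, energy, meta)
        )
        i += 2 + natoms
        frame += 1
    if not groups:
        raise ParseError("line 1: empty file")
    return [Ensemble(sys_id, confs) for sys_id, confs in groups.items()]


def _comment_line(conf: Conformer, system_id: str) -> str:
    tokens = [f"energy={conf.energy:.10f}", f"system={system_id}"]
    if conf.meta.get("label"):
        tokens.append(f"label={conf.meta['label']}")
    if conf.meta.get("topology"):
        tokens.append(f"topology={conf.meta['topology']}")
    if conf.meta.get("charges") is not None:
        q = ",".join(f"{float(x):.4f}" for x in conf.meta["charges"])
        tokens.append(f"charges={q}")
    return " ".join(tokens)


def write_extxyz(ensembles: Sequence[Ensemble] | Ensemble, path: str | os.PathLike) -> None:
    """Write ensembles as multi-frame extended XYZ (bit-stable for fixed input)."""
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("no ensembles to write")
    out: list[str] = []
    for ens in ensembles:
        for conf in ens:
            if conf.energy is None:
                raise ValueError(
                    f"conformer in {ens.system_id} has no energy; cannot serialize"
                )
            out.append(str(len(conf)))
            out.append(_comment_line(conf, ens.system_id))
            for el, (x, y, z) in zip(conf.elements, conf.positions):
                out.append(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("\n".join(out) + "\n")


def read_qc_geometry(path: str | os.PathLike) -> Conformer:
    """Read a single-structure geometry file (``atom x y z element`` lines).

    The returned conformer has no energy.  Lattice keywords are rejected:
    periodic systems are out of scope.
    """
    elements: list[str] = []
    coords: list[list[float]] = []
    with open(path, "r", encoding="ascii") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            key = parts[0].lower()
            if key.startswith("lattice"):
                raise ParseError(f"line {ln}: periodic input unsupported")
            if key != "atom":
                raise ParseError(f"line {ln}: unknown keyword {parts[0]!r}")
            if len(parts) != 5:
                raise ParseError(f"line {ln}: expected 'atom x y z element'")
            if parts[4] not in VALID_ELEMENTS:
                raise ParseError(f"line {ln}: unknown element {parts[4]!r}")
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError(f"line {ln}: unparseable coordinates")
            elements.append(parts[4])
    if not elements:
        raise ParseError("line 1: empty geometry file")
    return Conformer(elements, np.asarray(coords), energy=None, meta={"source": str(path)})


def read_manifest(path: str | os.PathLike) -> dict[str, SystemDescriptor]:
    """Read a YAML manifest mapping system id -> descriptor fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError("manifest must be a mapping of system id to fields")
    out: dict[str, SystemDescriptor] = {}
    for sys_id, fields in raw.items():
        if sys_id in ("seed", "generator"):  # run-level metadata keys
            continue
        out[sys_id] = SystemDescriptor(**fields)
    return out


def write_manifest(
    systems: Iterable[SystemDescriptor],
    path: str | os.PathLike,
    extra: dict | None = None,
) -> None:
    doc: dict = {}
    if extra:
        doc.update(extra)
    for d in systems:
        doc[d.system_id] = {
            "side_chain": d.side_chain,
            "protomer": d.protomer,
            "backbone": d.backbone,
            "complexation": d.complexation,
        }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
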