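"""Pipeline orchestration: configuration, staging, and report assembly.

``run_pipeline`` executes the full analysis chain on a suite directory
(read -> classify -> hierarchies -> binding -> trends -> coordination ->
toxicity) and writes a report bundle.  Every output declares the
configuration hash it was produced under; fixed inputs and seed give
byte-identical trend output.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .classify import classify_conformer, quadrant
from .coordination import cation_o_histogram, count_modes
from .energetics import (
    BindingRecord,
    EV_TO_KJ_PER_MOL,
    binding_energy,
    build_hierarchy,
    build_trend_table,
    contraction_report,
    rank_concordance,
    affinity_ranking,
    ion_ordering,
)
from .geometry import backbone_torsions, topology_of
from .io import read_extxyz, read_manifest
from .systems import CATIONS, Ensemble
from .toxicity import toxicity_correlation


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Missing or unreadable input data (exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 4)."""

    def __init__(self, stage: str, system: str | None, cause: Exception):
        self.stage = stage
        self.system = system
        super().__init__(f"stage {stage!r} failed"
                         + (f" on system {system}" if system else "")
                         + f": {cause}")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str
    output_dir: str
    seed: int = 0
    ions: list[str] = Field(default_factory=lambda: list(CATIONS))
    hbond_max_d_ha: float = 2.5
    hbond_max_d_da: float = 3.5
    hbond_min_angle: float = 120.0
    dedup_threshold_a: float = 0.3
    coordination_cutoffs: dict[str, float] = Field(default_factory=dict)
    histogram_bin_width_a: float = 0.05
    histogram_range_a: tuple[float, float] = (1.8, 3.6)
    histogram_bandwidth_a: float = 0.08
    toxicity_exclusions: list[str] = Field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.validated(raw)

    @classmethod
    def validated(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls(**raw)
        except (ValidationError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        doc = self.model_dump()
        doc.pop("output_dir", None)
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_suite(input_dir: str | Path) -> dict[str, Ensemble]:
    """Read a suite directory (``<system_id>/ensemble.extxyz`` + manifest)."""
    root = Path(input_dir)
    if not root.is_dir():
        raise DataError(f"input directory {root} does not exist")
    manifest_path = root / "manifest.yaml"
    ensembles: dict[str, Ensemble] = {}
    if manifest_path.exists():
        manifest = read_manifest(manifest_path)
        for sys_id in manifest:
            f = root / sys_id / "ensemble.extxyz"
            if not f.exists():
                raise DataError(f"manifest lists {sys_id} but {f} is missing")
            for ens in read_extxyz(f):
                ensembles[ens.system_id] = ens
    else:
        files = sorted(root.glob("**/*.extxyz"))
        if not files:
            raise DataError(f"no extended-XYZ files under {root}")
        for f in files:
            for ens in read_extxyz(f):
                ensembles[ens.system_id] = ens
    return ensembles


def classify_suite(ensembles: dict[str, Ensemble],
                   cutoffs: dict[str, float] | None = None) -> pd.DataFrame:
    """Classification report: one row per conformer."""
    rows = []
    for sys_id in sorted(ensembles):
        ens = ensembles[sys_id]
        d = ens.system
        for k, conf in enumerate(ens):
            topo = topology_of(conf)
            bc = classify_conformer(conf, topo, d.backbone, d.complexation, cutoffs)
            tors = backbone_torsions(conf, topo)
            row = {
                "system": sys_id,
                "conformer": k,
                "label": bc.label,
                "phi": np.nan if tors.phi is None else round(tors.phi, 2),
                "psi": np.nan if tors.psi is None else round(tors.psi, 2),
                "energy_ev": conf.energy,
                "evidence": "; ".join(f"{k2}={v}" for k2, v in bc.evidence),
            }
            if tors.phi is not None and tors.psi is not None:
                q = quadrant(tors.phi, tors.psi)
                row["quadrant"] = q.index + ("*" if q.boundary else "")
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis chain and write the report bundle.

    Returns a mapping of report names to file paths.  Raises ``StageError``
    naming the stage and offending system on failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    bundle: dict[str, Path] = {}

    def write_df(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(f"# config_hash={chash} version={__version__}\n")
            df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6f")
        bundle[name] = path

    def write_json(name: str, doc: dict) -> None:
        path = out / f"{name}.json"
        doc = {"config_hash": chash, "version": __version__, **doc}
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        bundle[name] = path

    # stage: read
    try:
        ensembles = load_suite(config.input_dir)
    except DataError:
        raise
    except Exception as exc:
        raise StageError("read", None, exc)

    # stage: classify
    try:
        cls = classify_suite(ensembles, config.coordination_cutoffs or None)
        write_df("classification", cls)
    except Exception as exc:
        raise StageError("classify", None, exc)

    # stage: hierarchy
    hierarchies = {}
    for sys_id, ens in sorted(ensembles.items()):
        try:
            hierarchies[sys_id] = build_hierarchy(ens, config.dedup_threshold_a)
        except Exception as exc:
            raise StageError("hierarchy", sys_id, exc)
    hrows = [
        {"system": sys_id, "rank": e.rank, "rel_ev": e.rel_ev, "rel_kj_mol": e.rel_kj_mol,
         "energy_ev": e.conformer.energy, "label": e.conformer.meta.get("label", "")}
        for sys_id, h in sorted(hierarchies.items()) for e in h.entries
    ]
    write_df("hierarchies", pd.DataFrame(hrows))

    # stage: contraction
    try:
        bare = {s: h for s, h in hierarchies.items() if h.system.complexation == "none"}
        withion = {s: h for s, h in hierarchies.items() if h.system.complexation != "none"}
        if withion:
            contraction = contraction_report(bare, withion)
            write_df("contraction", contraction)
    except Exception as exc:
        raise StageError("contraction", None, exc)

    # stage: binding
    records: list[BindingRecord] = []
    for sys_id, h in sorted(withion.items()):
        d = h.system
        bare_id = f"{d.ligand_name}_{d.backbone}_none"
        if bare_id not in hierarchies:
            raise StageError("binding", sys_id, KeyError(f"no bare reference {bare_id}"))
        e_lig = hierarchies[bare_id].global_minimum.energy
        e_cpx = h.global_minimum.energy
        records.append(BindingRecord(
            d, d.complexation, binding_energy(e_cpx, e_lig, 0.0),
            h.global_minimum.meta.get("label"),
        ))
    trends_doc: dict = {}
    if records:
        for backbone in ("free", "capped"):
            try:
                table = build_trend_table(records, backbone=backbone)
            except Exception:
                continue
            write_df(f"binding_matrix_{backbone}_ev",
                     table.matrix.reset_index(names="ligand"))
            kj = (table.matrix * EV_TO_KJ_PER_MOL).reset_index(names="ligand")
            write_df(f"binding_matrix_{backbone}_kjmol", kj)
            ions_present = [i for i in config.ions if i in table.matrix.columns]
            rankings = {}
            for ion in ions_present:
                order, tie = affinity_ranking(table, ion)
                rankings[ion] = {"ligands_strongest_first": order, "ties": tie}
            orderings = {}
            for lig in table.ligands():
                order, tie = ion_ordering(table, lig)
                orderings[lig] = {"ions_strongest_first": order, "ties": tie}
            tau = {}
            for i, a in enumerate(ions_present):
                for b in ions_present[i + 1:]:
                    cc = rank_concordance(table.matrix[a].to_dict(), table.matrix[b].to_dict())
                    tau[f"{a}-{b}"] = cc
            trends_doc[backbone] = {
                "affinity_rankings": rankings,
                "ion_orderings": orderings,
                "ion_pair_concordance": tau,
                "mean_e_bind_ev": {i: float(table.matrix[i].mean()) for i in ions_present},
            }
    write_json("trends", trends_doc)

    # stage: coordination
    coord_doc = {}
    for ion in config.ions:
        mins = [h.global_minimum for s, h in sorted(withion.items())
                if h.system.complexation == ion]
        if not mins:
            continue
        try:
            hist = cation_o_histogram(mins, config.histogram_bin_width_a,
                                      config.histogram_range_a)
            modes = count_modes(hist, config.histogram_bandwidth_a)
        except Exception as exc:
            raise StageError("coordination", ion, exc)
        write_df(f"hist_{ion}", pd.DataFrame({
            "bin_left_a": hist.bin_edges_a[:-1],
            "bin_right_a": hist.bin_edges_a[1:],
            "count": hist.counts,
        }))
        coord_doc[ion] = {
            "n_distances": int(hist.counts.sum()),
            "median_a": hist.median_a,
            "modes": modes,
        }
    write_json("coordination", coord_doc)

    # stage: toxicity
    tox_doc = {}
    for backbone, doc in trends_doc.items():
        means = doc["mean_e_bind_ev"]
        if len([i for i in means if i not in config.toxicity_exclusions]) >= 3:
            try:
                tox_doc[backbone] = toxicity_correlation(
                    means, exclusions=tuple(config.toxicity_exclusions))
            except Exception as exc:
                raise StageError("toxicity", backbone, exc)
    write_json("toxicity", tox_doc)

    # run manifest
    write_json("run_manifest", {
        "config": config.model_dump(),
        "n_systems": len(ensembles),
        "n_conformers": int(sum(len(e) for e in ensembles.values())),
    })
    return bundle


def validate_external_dataset(data_dir: str | Path) -> dict:
    """Opt-in validation against the deposited first-principles database.

    Reads every extended-XYZ ensemble under ``data_dir`` and reports the
    dataset-scale counts (total conformers, per-complexation totals, per-system
    counts, and the zwitterionic vs neutral preference of free amino acid +
    Ca complexes).  Requires the externally downloaded conformer database;
    not exercised by the bundled synthetic suite.
    """
    ensembles = load_suite(data_dir)
    total = sum(len(e) for e in ensembles.values())
    per_system = {s: len(e) for s, e in sorted(ensembles.items())}
    ca_free = sum(len(e) for e in ensembles.values()
                  if e.system.complexation == "Ca" and e.system.backbone == "free")
    ca_capped = sum(len(e) for e in ensembles.values()
                    if e.system.complexation == "Ca" and e.system.backbone == "capped")
    salt_bridge_pref = 0
    n_free_ca = 0
    for s, ens in sorted(ensembles.items()):
        d = ens.system
        if d.backbone != "free" or d.complexation != "Ca" or d.protomer != "default":
            continue
        n_free_ca += 1
        h = build_hierarchy(ens)
        conf = h.global_minimum
        bc = classify_conformer(conf, topology_of(conf), d.backbone, d.complexation)
        if bc.label == "salt_bridge":
            salt_bridge_pref += 1
    return {
        "total_conformers": total,
        "amino_acid_Ca_conformers": ca_free,
        "dipeptide_Ca_conformers": ca_capped,
        "per_system_counts": per_system,
        "free_Ca_systems": n_free_ca,
        "salt_bridge_preferred": salt_bridge_pref,
    }
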