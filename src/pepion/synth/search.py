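"""Torsional basin hopping on the toy potential.

Global minimization by random torsion perturbation followed by local
minimization, with Metropolis acceptance on the minimized energies.  Distinct
accepted minima are collected into an ensemble, deduplicated by circular
torsion distance.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from ..systems import Conformer, Ensemble, SystemDescriptor
from .builder import BuildError, build_peptide, place_ion
from .templates import ResidueTemplate, ToyEnergyParams, default_toy_params
from .toyenergy import toy_energy
from ..geometry import wrap_angle


def _torsion_names(template: ResidueTemplate) -> list[str]:
    if template.backbone == "capped":
        return ["phi", "psi"] + list(template.chi_names)
    return ["psic", "am"] + (["ho"] if template.form == "neutral" else []) + list(template.chi_names)


def _torsion_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.abs([wrap_angle(x) for x in (a - b)])
    return float(np.max(d))


def basin_hop_search(
    template: ResidueTemplate,
    params: ToyEnergyParams | None = None,
    n_steps: int = 50,
    step_deg: float = 60.0,
    seed: int = 0,
    ion_site: str | None = None,
    ion: str = "Ca",
    temperature_ev: float = 0.2,
    dedup_deg: float = 20.0,
    frozen: dict[str, float] | None = None,
) -> Ensemble:
    """Search the template's torsion space for toy-potential minima.

    Returns an ensemble of the distinct local minima found (energies set),
    sorted by energy.  ``ion_site`` optionally attaches a cation at each
    evaluated geometry; ``frozen`` pins named torsions, restricting the
    search to the remaining ones.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    p = params or default_toy_params()
    rng = np.random.default_rng(seed)
    frozen = dict(frozen or {})
    names = [n for n in _torsion_names(template) if n not in frozen]
    if not names:
        raise ValueError("no free torsions to search")

    def realize(x: np.ndarray) -> Conformer:
        tp = {n: wrap_angle(v) for n, v in zip(names, x)}
        tp.update(frozen)
        conf = build_peptide(template, params=tp, check_clash=False)
        if ion_site is not None:
            conf = place_ion(conf, ion_site, p.contact_distance(ion), ion)
        return conf

    def energy(x: np.ndarray) -> float:
        try:
            return toy_energy(realize(x), p)
        except (BuildError, ValueError):
            return 1e3

    def local_min(x0: np.ndarray) -> tuple[np.ndarray, float]:
        res = minimize(energy, x0, method="Nelder-Mead",
                       options={"xatol": 0.5, "fatol": 1e-5, "maxiter": 400})
        return res.x, float(res.fun)

    x0 = np.array([template.default_params.get(n, 180.0) for n in names], dtype=float)
    x_cur, e_cur = local_min(x0)
    minima: list[tuple[np.ndarray, float]] = [(x_cur, e_cur)]

    for _ in range(n_steps - 1):
        trial = x_cur + rng.uniform(-step_deg, step_deg, size=len(names))
        x_new, e_new = local_min(trial)
        if e_new <= e_cur or rng.random() < np.exp(-(e_new - e_cur) / temperature_ev):
            x_cur, e_cur = x_new, e_new
        if all(_torsion_distance(x_new, xm) > dedup_deg for xm, _ in minima):
            minima.append((x_new, e_new))

    minima.sort(key=lambda me: me[1])
    confs = []
    for k, (x, e) in enumerate(minima):
        conf = realize(x)
        conf.energy = e
        conf.meta["minimum_index"] = k
        confs.append(conf)
    ligand = template.name
    side_chain, protomer = (ligand[:-1], "protonated") if ligand.endswith("H") else (ligand, "default")
    system = SystemDescriptor(
        side_chain, protomer, template.backbone,
        "none" if ion_site is None else ion,
    )
    return Ensemble(system, confs)
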