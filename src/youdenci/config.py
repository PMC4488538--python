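"""YAML/JSON scenario configuration for the simulation driver.

Schema (YAML shown; JSON is equivalent)::

    seed: 1
    n_sims: 500
    B: 500
    alpha: 0.05
    methods: [NP, NPAC, BAC]
    cells:
      - non_diseased: {family: normal, mean: 0, variance: 1}
        diseased: {family: normal, variance: 1, target_j: 0.4, free: normal_mean}
        sizes: [[20, 20], [20, 40]]

A diseased entry either gives the family's full parameters or a
``target_j`` plus ``free`` (``normal_mean`` or ``gamma_rate``) with the
remaining parameter fixed; the free one is then solved so the scenario's
true Youden Index hits the target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .bootstrap import BootstrapSettings
from .scenarios import (
    DistributionSpec,
    ScenarioSpec,
    make_scenario,
    solve_diseased_parameter,
)

__all__ = ["SimulationConfig", "load_simulation_config", "dist_from_mapping"]

logger = logging.getLogger(__name__)

_PARAM_KEYS = {
    "normal": ("mean", "variance"),
    "gamma": ("shape", "rate"),
    "student_t": ("df",),
}


def _fail(path: str, msg: str):
    raise ValueError(f"config field {path!r}: {msg}")


def dist_from_mapping(mapping: dict, where: str) -> DistributionSpec:
    if not isinstance(mapping, dict) or "family" not in mapping:
        _fail(where, "expected a mapping with a 'family' key")
    family = mapping["family"]
    if family not in _PARAM_KEYS:
        _fail(f"{where}.family", f"unknown family {family!r}")
    try:
        params = tuple(float(mapping[k]) for k in _PARAM_KEYS[family])
    except KeyError as e:
        _fail(where, f"missing parameter {e.args[0]!r} for family {family!r}")
    try:
        return DistributionSpec(family, params)
    except ValueError as e:
        _fail(where, str(e))


def _diseased_spec(dx: DistributionSpec, mapping: dict, where: str) -> DistributionSpec:
    if "target_j" not in mapping:
        return dist_from_mapping(mapping, where)
    free = mapping.get("free")
    if free not in ("normal_mean", "gamma_rate"):
        _fail(f"{where}.free", "must be 'normal_mean' or 'gamma_rate' with target_j")
    target = float(mapping["target_j"])
    if free == "normal_mean":
        template = DistributionSpec.normal(0.0, float(mapping.get("variance", 1.0)))
    else:
        template = DistributionSpec.gamma(float(mapping["shape"]), 1.0)
    solved = solve_diseased_parameter(dx, template, free, target)
    logger.info("%s: solved %s = %.6f for target J = %g", where, free, solved, target)
    if free == "normal_mean":
        return DistributionSpec.normal(solved, template.params[1])
    return DistributionSpec.gamma(template.params[0], solved)


@dataclass(frozen=True)
class SimulationConfig:
    cells: list[ScenarioSpec]
    n_sims: int
    settings: BootstrapSettings
    methods: tuple[str, ...]


def load_simulation_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        _fail("<root>", "expected a mapping")
    try:
        settings = BootstrapSettings(
            B=int(raw.get("B", 500)),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
        )
    except ValueError as e:
        _fail("B/seed/alpha", str(e))
    n_sims = int(raw.get("n_sims", 5000))
    if n_sims < 1:
        _fail("n_sims", "must be >= 1")
    methods = tuple(raw.get("methods", ("NP", "NPAC", "BAC")))
    cells: list[ScenarioSpec] = []
    for i, cell in enumerate(raw.get("cells", [])):
        where = f"cells[{i}]"
        if "non_diseased" not in cell or "diseased" not in cell:
            _fail(where, "needs 'non_diseased' and 'diseased' entries")
        dx = dist_from_mapping(cell["non_diseased"], f"{where}.non_diseased")
        dy = _diseased_spec(dx, cell["diseased"], f"{where}.diseased")
        sizes = cell.get("sizes")
        if sizes is None:
            sizes = [[cell["m"], cell["n"]]] if "m" in cell else None
        if not sizes:
            _fail(where, "needs 'sizes' ([[m, n], ...]) or 'm' and 'n'")
        for m, n in sizes:
            cells.append(make_scenario(dx, dy, int(m), int(n)))
    if not cells:
        _fail("cells", "at least one cell is required")
    return SimulationConfig(cells, n_sims, settings, methods)
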