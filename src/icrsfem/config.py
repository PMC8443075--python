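"""Run configuration from YAML / TOML / JSON files.

A config file can override any of the geometry, tunnel, material, ring and
solver parameters, e.g.::

    geometry: {cct: 450}
    tunnel: {center_radial_position: 3.0}
    ring: {thickness_ends: [150, 300], base_ends: [600, 800], arc_length: 160}
    materials: {posterior_nu_rc: -0.34}
    solver: {n_steps: 12, iop_mmhg: 15}
"""

from __future__ import annotations

import json
from pathlib import Path

from .geometry import CorneaGeometry, TunnelSpec
from .implantation import RingDesign
from .materials import table1
from .mesh import MeshDensity

__all__ = ["load_config", "RunConfig"]


def _read(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    if path.suffix == ".toml":
        import tomllib
        return tomllib.loads(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format {path.suffix!r}")


class RunConfig:
    """Materialized configuration objects for one simulation run."""

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        self.geometry = CorneaGeometry(**raw.get("geometry", {}))
        self.tunnel = TunnelSpec(**raw.get("tunnel", {}))
        self.density = MeshDensity(**raw.get("density", {}))
        ring = dict(raw.get("ring", {}))
        for key in ("thickness_ends", "base_ends"):
            if key in ring:
                ring[key] = tuple(ring[key])
        self.ring = RingDesign(**ring)
        mat = raw.get("materials", {})
        self.materials = table1(posterior_nu_rc=mat.get("posterior_nu_rc", 0.34))
        solver = raw.get("solver", {})
        self.n_steps = int(solver.get("n_steps", 12))
        self.iop_mmhg = float(solver.get("iop_mmhg", 15.0))


def load_config(path=None) -> RunConfig:
    if path is None:
        return RunConfig()
    return RunConfig(_read(Path(path)))
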