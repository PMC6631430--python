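"""Validated pipeline configuration (JSON-backed)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .coating import SlitGeometry
from .electrolyte import ElectrolyteSpec
from .scenario import SyntheticScenario

__all__ = ["GeometryConfig", "ElectrolyteConfig", "ScenarioConfig",
           "StructureConfig", "ShieldingConfig", "PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    width: float = 20.0
    graft_lattice_a: float = 2.5
    bond_length: float = 0.15
    bead_radius: float = 0.156
    bond_angle_deg: float = 109.5

    def build(self) -> SlitGeometry:
        return SlitGeometry(**self.model_dump())


class ElectrolyteConfig(_Strict):
    bulk_concentration: float = 3.4e-2
    valences: tuple[int, int] = (1, -1)
    surface_charge: float = 3.28e-2
    dielectric_constant: float = 78.0
    temperature: float = 300.0

    def build(self) -> ElectrolyteSpec:
        return ElectrolyteSpec(**self.model_dump())


class ScenarioConfig(_Strict):
    degree: int = 14
    Eext: float = 1.6e-2
    a_bead: float = 0.019
    noise_sd: float = 0.0
    n_grid: int = 2001
    density_model: str = "parabolic_brush"
    layer_height: float | None = None
    n_chains_per_wall: int = 9

    def build(self, geometry: SlitGeometry, electrolyte: ElectrolyteSpec,
              seed: int) -> SyntheticScenario:
        kw = self.model_dump()
        kw.pop("n_chains_per_wall")
        return SyntheticScenario(geometry=geometry, electrolyte=electrolyte,
                                 seed=seed, **kw)


class StructureConfig(_Strict):
    rdf_r_max: float = 1.0
    rdf_bin_width: float = 0.005
    near_far_split: float = 0.3
    reference_z: float = 1.0
    slab_half_width: float = 0.15
    far_r_max: float = 2.0
    far_bin_width: float = 0.1


class ShieldingConfig(_Strict):
    a_near_over_a0: float = 0.18
    depth: float = 0.8
    decay: float = 0.3
    r_s_tol: float = 0.05


class PipelineConfig(_Strict):
    """Top-level configuration; unknown keys are rejected on load."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    electrolyte: ElectrolyteConfig = Field(default_factory=ElectrolyteConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    shielding: ShieldingConfig = Field(default_factory=ShieldingConfig)
    seed: int = 0
    output_dir: str = "."

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a JSON config; defaults when no path is given."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))
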