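"""Run configuration: model constants, unit options and sweep grids.

Defaults are the physiologic reference values used throughout the
package: mean aortic inlet pressure 93.33 mmHg, blood density 1.06 g/cm3
and viscosity 0.04 g/cm/s, tissue density 1.04 g/mL, regional CBF
0.8 / 0.2 / 0.5 mL/min/g (gray / white / other), perforator source
distance 3 mm, centerline spacing 0.5 mm, truncation sweep 0 to 1.0 mm
in 0.05 mm steps.  Configs load from flat TOML files; explicit keyword
overrides win over file values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .flow import DEFAULT_INLET_PRESSURE_MMHG
from .tissue import DEFAULT_CBF, DEFAULT_TISSUE_DENSITY

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    network_path: str | None = None
    mesh_path: str | None = None
    out_dir: str = "perfterra_run"
    boundary_model: str = "tessellation"
    inlet_pressure_mmhg: float = DEFAULT_INLET_PRESSURE_MMHG
    blood_viscosity: float = 0.04  # g/cm/s
    blood_density: float = 1.06  # g/cm^3
    tissue_density: float = DEFAULT_TISSUE_DENSITY  # g/mL
    cbf: dict = field(default_factory=lambda: dict(DEFAULT_CBF))  # mL/min/g
    uniform_cbf: float | None = None  # set to e.g. 0.5 to override the table
    d_max: float = 3.0  # mm
    spacing: float | None = 0.5  # mm, None = no resampling
    source_speed: float = 1.0
    sweep_r_max: float = 1.0  # mm
    sweep_step: float = 0.05  # mm
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        flat = {}
        for key, value in doc.items():
            if isinstance(value, dict) and key != "cbf":
                flat.update(value)  # sections mirror module names; flatten
            else:
                flat[key] = value
        flat.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def cbf_table(self):
        from .tissue import TissueClassTable

        if self.uniform_cbf is not None:
            return TissueClassTable.uniform(self.uniform_cbf, self.tissue_density)
        return TissueClassTable(dict(self.cbf), self.tissue_density)

    def constants(self):
        from .flow import FluidConstants

        return FluidConstants(self.blood_density, self.blood_viscosity)

    def digest(self) -> str:
        """Provenance hash of the full configuration."""
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]
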