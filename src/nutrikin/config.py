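"""Run configuration: schema-validated TOML/JSON loading.

An empty file is a valid configuration: every field defaults to the
package's standard parameter set (K_T = 1 μM, TRD_max = 0.4 pgN μm⁻²
d⁻¹, KQ = 10, KT_con = 0.1, N:C bounds 0.05–0.18 gN gC⁻¹,
G_max = 0.693 d⁻¹, and the seawater constants).  Unknown keys are
rejected.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError
from .geometry import CarbonModel, Environment, resolve_carbon_model
from .kinetics import OrganismConfig
from .quota import QuotaParams
from .transport import TransporterParams, empirical_tmax_curve


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnvironmentBlock(_Block):
    D: float = 1.5e-9           # m^2 s^-1
    eta: float = 1.0846e-3      # Pa s
    rho_org: float = 1.0634     # kg L^-1
    rho_w: float = 1.033        # kg L^-1
    g: float = 9.8              # m s^-2
    molar_mass_N: float = 14.0  # g mol^-1

    @model_validator(mode="after")
    def _positive(self) -> "EnvironmentBlock":
        for k, v in self.model_dump().items():
            if v <= 0:
                raise ValueError(f"environment.{k} must be positive")
        return self

    def to_domain(self) -> Environment:
        return Environment(**self.model_dump())


class StoichiometryBlock(_Block):
    NC_max: float = 0.18   # gN gC^-1
    NC_min: float = 0.05   # gN gC^-1
    KQ: float = 10.0
    G_max: float = 0.693   # d^-1

    @model_validator(mode="after")
    def _valid(self) -> "StoichiometryBlock":
        if not (0 < self.NC_min < self.NC_max):
            raise ValueError("stoichiometry requires 0 < NC_min < NC_max")
        if self.KQ <= 0 or self.G_max <= 0:
            raise ValueError("KQ and G_max must be positive")
        return self

    def to_domain(self) -> QuotaParams:
        return QuotaParams(**self.model_dump())


class TransporterBlock(_Block):
    K_T: float = 1.0        # μM
    TRD_max: float = 0.4    # pgN μm^-2 d^-1
    KT_con: float = 0.1

    @model_validator(mode="after")
    def _positive(self) -> "TransporterBlock":
        for k, v in self.model_dump().items():
            if v <= 0:
                raise ValueError(f"transporter.{k} must be positive")
        return self

    def to_domain(self) -> TransporterParams:
        return TransporterParams(**self.model_dump())


class OrganismBlock(_Block):
    ESD: float = 10.0  # μm
    model: str = "C150"
    carbon_density: float | None = None  # overrides preset: gC (L cell)^-1
    carbon_a: float | None = None        # overrides preset: C = a·V^b
    carbon_b: float | None = None
    motion: Literal["none", "swim", "sink"] = "none"
    tmax_mode: Literal["stress", "flat", "empirical"] = "stress"
    tmax_table: str | None = None  # CSV path (columns NC, Tmax_specific)

    @model_validator(mode="after")
    def _valid(self) -> "OrganismBlock":
        if self.ESD <= 0:
            raise ValueError("organism.ESD must be positive")
        if (self.carbon_a is None) != (self.carbon_b is None):
            raise ValueError("carbon_a and carbon_b must be given together")
        if self.tmax_mode == "empirical" and self.tmax_table is None:
            raise ValueError("tmax_mode=empirical requires tmax_table")
        return self

    def carbon_model(self) -> CarbonModel:
        if self.carbon_density is not None:
            return CarbonModel.fixed(self.carbon_density)
        if self.carbon_a is not None:
            return CarbonModel.allometric(self.carbon_a, self.carbon_b)
        return resolve_carbon_model(self.model)


class ScanBlock(_Block):
    esd_min: float = 2.0    # μm
    esd_max: float = 80.0   # μm
    n_esd: int = 25
    n_g: int = 200          # growth-sweep resolution

    @model_validator(mode="after")
    def _valid(self) -> "ScanBlock":
        if not (0 < self.esd_min < self.esd_max):
            raise ValueError("scan requires 0 < esd_min < esd_max")
        if self.n_esd < 2 or self.n_g < 2:
            raise ValueError("scan grid sizes must be >= 2")
        return self


class RunConfig(_Block):
    organism: OrganismBlock = OrganismBlock()
    environment: EnvironmentBlock = EnvironmentBlock()
    stoichiometry: StoichiometryBlock = StoichiometryBlock()
    transporter: TransporterBlock = TransporterBlock()
    scan: ScanBlock = ScanBlock()
    seed: int = 0

    def environment_domain(self) -> Environment:
        return self.environment.to_domain()

    def organism_config(self, base_dir: Path | None = None) -> OrganismConfig:
        """Resolve the organism block into a domain OrganismConfig."""
        tmax_curve = None
        if self.organism.tmax_mode == "empirical":
            import numpy as np

            path = Path(self.organism.tmax_table)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            arr = np.loadtxt(path, delimiter=",", skiprows=1)
            tmax_curve = empirical_tmax_curve(arr)
        # preserve preset name in provenance when no override is given
        model: CarbonModel | str
        if self.organism.carbon_density is None and self.organism.carbon_a is None:
            model = self.organism.model
        else:
            model = self.organism.carbon_model()
        return OrganismConfig(
            ESD=self.organism.ESD,
            carbon_model=model,
            motion=self.organism.motion,
            quota=self.stoichiometry.to_domain(),
            transporter=self.transporter.to_domain(),
            tmax_mode=self.organism.tmax_mode,
            tmax_curve=tmax_curve,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration.

    Schema violations raise :class:`ConfigError` listing the offending
    keys.  An empty file yields the full default configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data: dict
    if not text.strip():
        data = {}
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        try:
            data = tomllib.loads(text)
        except tomllib.TOMLDecodeError:
            try:
                data = json.loads(text)
            except json.JSONDecodeError as exc:
                raise ConfigError(
                    f"{path} parses as neither TOML nor JSON: {exc}"
                ) from exc
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        keys = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: offending keys: {keys}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as JSON (round-trips through load_config)."""
    Path(path).write_text(json.dumps(config.model_dump(), indent=2) + "\n")
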