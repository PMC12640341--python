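"""Run-configuration files: a small validated YAML schema.

An empty file (or no file) yields the reference defaults: 1-μm cell radius,
90-min doubling time, F_2D = 1.2, isotropic growth (f_z = 1/3), γ = 0.5,
RK4 step 0.5 min over 0–3000 min from a single cell.

The rate constant may be given either as ``t_double_min`` or directly as
``k_per_min``; if both are present the doubling time wins and a warning is
logged (the two are redundant via k = ln2/t_double).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .capgeom import PackingModel
from .errors import ConfigError
from .kinetics import build_rates, rate_from_doubling_time
from .simulate import PROFILE_SNAPSHOT_TIMES, SimulationConfig

__all__ = ["RunConfigFile", "load_config", "dump_config"]

log = logging.getLogger(__name__)


class RunConfigFile(BaseModel):
    """Declarative mirror of :class:`~capcolony.simulate.SimulationConfig`."""

    model_config = ConfigDict(extra="forbid")

    r_c_um: float = 1.0
    f_2d: float = 1.2
    f_3d: Optional[float] = None          # default: f_2d ** 1.5
    t_double_min: Optional[float] = None  # default 90 when k_per_min absent
    k_per_min: Optional[float] = None
    f_z: float = 1.0 / 3.0
    gamma: float = 0.5
    t0_min: float = 0.0
    t_end_min: float = 3000.0
    dt_min: float = 0.5
    n0: float = 1.0
    output_times_min: Optional[List[float]] = None
    profile_times_min: List[float] = list(PROFILE_SNAPSHOT_TIMES)

    @field_validator("gamma")
    @classmethod
    def _gamma_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {v}")
        return v

    @field_validator("f_z")
    @classmethod
    def _fz_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"f_z must lie in [0, 1], got {v}")
        return v

    def rate_constant(self) -> float:
        """Resolve k (min⁻¹) from the redundant pair (t_double, k)."""
        if self.t_double_min is not None and self.k_per_min is not None:
            log.warning(
                "both t_double_min and k_per_min given; using t_double_min "
                "(k = ln2/t_double = %.7g min^-1, ignoring k = %.7g)",
                rate_from_doubling_time(self.t_double_min), self.k_per_min,
            )
            return rate_from_doubling_time(self.t_double_min)
        if self.t_double_min is not None:
            return rate_from_doubling_time(self.t_double_min)
        if self.k_per_min is not None:
            if self.k_per_min <= 0:
                raise ConfigError(f"k_per_min must be positive, got {self.k_per_min}")
            return self.k_per_min
        return rate_from_doubling_time(90.0)

    def to_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            rates=build_rates(k=self.rate_constant(), f_z=self.f_z, gamma=self.gamma),
            packing=PackingModel(r_c=self.r_c_um, f_2d=self.f_2d, f_3d=self.f_3d),
            t0=self.t0_min,
            t_end=self.t_end_min,
            dt=self.dt_min,
            output_times=self.output_times_min,
            n0=self.n0,
        )


def load_config(path: Optional[Union[str, Path]] = None) -> SimulationConfig:
    """Parse and validate a YAML run configuration; ``None`` gives defaults.

    Raises :class:`~capcolony.errors.ConfigError` naming the offending keys
    on schema violations (unknown keys are rejected).
    """
    return load_config_file(path).to_simulation_config()


def load_config_file(path: Optional[Union[str, Path]] = None) -> RunConfigFile:
    """Like :func:`load_config` but returns the declarative file model."""
    if path is None:
        return RunConfigFile()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfigFile(**raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(cfg: RunConfigFile, path: Union[str, Path]) -> None:
    """Write a config model back to YAML (round-trips through load)."""
    data = cfg.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
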