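"""Structured run configuration.

A :class:`RunConfig` gathers every knob of a simulation or analysis run into
one validated record that round-trips losslessly through YAML.  Unknown keys
are rejected with an error naming them, so a typo in a config file fails
loudly instead of silently using a default.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

logger = logging.getLogger(__name__)

__all__ = ["PulseConfig", "FieldConfig", "SimulationConfig", "AnalysisConfig",
           "RunConfig", "load_config", "write_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class PulseConfig(_StrictModel):
    family: Literal["rectangular", "gaussian", "chirp", "wurst", "hs"]
    tp_ns: float
    dt_ns: float = 0.5
    delta_f_MHz: Optional[float] = None
    t_rise_ns: float = 0.0
    fwhm_ns: Optional[float] = None
    n: float = 6.0
    beta: float = 8.0
    h_lead: float = 1.0
    h_trail: float = 1.0

    @model_validator(mode="after")
    def _check_sweep(self) -> "PulseConfig":
        swept = self.family in ("chirp", "wurst", "hs")
        if swept and self.delta_f_MHz is None:
            raise ValueError(f"{self.family} pulses require delta_f_MHz")
        return self

    def to_params(self):
        from . import waveforms as wf

        tp = self.tp_ns * 1e-9
        if self.family == "rectangular":
            return wf.RectangularParams(tp)
        if self.family == "gaussian":
            fwhm = None if self.fwhm_ns is None else self.fwhm_ns * 1e-9
            return wf.GaussianParams(tp, fwhm)
        df = self.delta_f_MHz * 1e6
        if self.family == "chirp":
            return wf.ChirpParams(tp, df, self.t_rise_ns * 1e-9)
        if self.family == "wurst":
            return wf.WurstParams(tp, df, self.n)
        return wf.HSParams(tp, df, self.beta, self.h_lead, self.h_trail)


class FieldConfig(_StrictModel):
    nu1_max_MHz: float = 30.0
    resonator_fwhm_MHz: Optional[float] = None
    carrier_offset_MHz: float = 0.0

    def to_field(self):
        from .fixtures import resonator_profile
        from .spin_dynamics import SpinField

        resonator = None
        if self.resonator_fwhm_MHz is not None:
            resonator = resonator_profile(fwhm=self.resonator_fwhm_MHz * 1e6)
        return SpinField(self.nu1_max_MHz * 1e6, resonator,
                         self.carrier_offset_MHz * 1e6)


class SimulationConfig(_StrictModel):
    distance_mean_nm: float = 5.1
    distance_fwhm_nm: float = 0.2
    spin_concentration_uM: float = 160.0
    dimensionality: float = 3.5
    sigma0: float = 0.004
    t_max_us: float = 8.0
    dt_us: float = 0.008
    lam: Optional[float] = None  # override the profile-derived modulation depth


class AnalysisConfig(_StrictModel):
    tau_trunc_us: float = 7.0
    exclude_first: int = 10
    fit_start_fraction: float = 0.3
    dimensionality: float = 3.5


class RunConfig(_StrictModel):
    pulse: PulseConfig
    field: FieldConfig = FieldConfig()
    simulation: SimulationConfig = SimulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0
    output: Optional[str] = None


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML config; every applied default is logged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    config = RunConfig.model_validate(raw)
    defaults = RunConfig.model_fields
    for name in defaults:
        if name not in raw:
            logger.info("config default applied: %s=%s", name, getattr(config, name))
    return config


def write_config(config: RunConfig, path: Path | str) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
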