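"""Synthesis of shaped microwave pump pulses.

Five pulse families are supported: rectangular and Gaussian (monochromatic)
and chirp, WURST and hyperbolic-secant (frequency-swept).  A pulse is sampled
on a uniform time grid centred on the pulse midpoint and carries an amplitude
envelope A(t) ∈ [0, 1] (relative to the maximum available B1), an
instantaneous frequency offset ω(t) from the sweep centre, and the
accumulated phase ρ(t) = ∫ 2π ω dt.  The quadrature components an AWG plays
are I = A cos ρ and Q = A sin ρ.

Frequency-swept families:

* chirp — constant amplitude, linear sweep at rate Δf/tp; optional
  quarter-sine smoothing of the rising/falling edges over ``t_rise``.
* WURST — linear sweep with envelope A(t) = 1 − |sin(π t / tp)|ⁿ.
* HS — hyperbolic secant: A(t) = sech(β 2^(h−1) (t/tp)^h) with a
  tanh-shaped sweep ω(t) = (Δf/2) tanh(β t/tp)/tanh(β/2).  The truncation
  parameter β is dimensionless (time measured in units of tp): the common
  notation "β = 8/tp" means β = 8 here.  Asymmetric pulses (HS{1,6}) use a
  different order h on each half; the sweep function is shared by both halves
  so frequency and amplitude stay continuous at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "Waveform",
    "ChirpParams",
    "GaussianParams",
    "WurstParams",
    "HSParams",
    "RectangularParams",
    "synth_rectangular",
    "synth_gaussian",
    "synth_chirp",
    "synth_wurst",
    "synth_hs",
    "quadrature_components",
    "synthesize",
]

DEFAULT_DT = 0.5e-9  # s; "time resolution in the nanosecond region"


def _validate_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class RectangularParams:
    tp: float  # s

    def __post_init__(self) -> None:
        _validate_positive(tp=self.tp)


@dataclass(frozen=True)
class GaussianParams:
    tp: float  # s
    fwhm: Optional[float] = None  # s; default = Xepr convention tp/(2 sqrt(2 ln 2))

    def __post_init__(self) -> None:
        _validate_positive(tp=self.tp)
        if self.fwhm is None:
            object.__setattr__(self, "fwhm", self.tp / (2 * np.sqrt(2 * np.log(2))))
        if not 0 < self.fwhm <= self.tp:
            raise ValueError(f"fwhm must lie in (0, tp], got {self.fwhm}")


@dataclass(frozen=True)
class ChirpParams:
    tp: float  # s
    delta_f: float  # Hz, fend - fstart
    t_rise: float = 0.0  # s, quarter-sine edge smoothing; 0 disables

    def __post_init__(self) -> None:
        _validate_positive(tp=self.tp, delta_f=self.delta_f)
        if not 0 <= self.t_rise <= self.tp / 2:
            raise ValueError(f"t_rise must lie in [0, tp/2], got {self.t_rise}")


@dataclass(frozen=True)
class WurstParams:
    tp: float  # s
    delta_f: float  # Hz
    n: float = 6.0  # steepness exponent

    def __post_init__(self) -> None:
        _validate_positive(tp=self.tp, delta_f=self.delta_f)
        if self.n < 1:
            raise ValueError(f"WURST exponent n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class HSParams:
    tp: float  # s
    delta_f: float  # Hz
    beta: float = 8.0  # dimensionless truncation parameter
    h_lead: float = 1.0  # order of the first (leading) half
    h_trail: float = 1.0  # order of the second (trailing) half

    def __post_init__(self) -> None:
        _validate_positive(tp=self.tp, delta_f=self.delta_f, beta=self.beta)
        if self.h_lead < 1 or self.h_trail < 1:
            raise ValueError("HS order parameters must be >= 1")

    @property
    def symmetric(self) -> bool:
        return self.h_lead == self.h_trail


Params = Union[RectangularParams, GaussianParams, ChirpParams, WurstParams, HSParams]


@dataclass(frozen=True)
class Waveform:
    """A sampled pulse.

    time_grid : s, uniform, centred so t = 0 is the pulse midpoint.
    amplitude : envelope in [0, 1] relative to the B1 maximum; 0 off-pulse.
    frequency : instantaneous frequency offset from the sweep centre, Hz.
    phase     : accumulated phase ρ(t) in rad (trapezoidal integral of 2πω).
    """

    time_grid: np.ndarray
    amplitude: np.ndarray
    frequency: np.ndarray
    phase: np.ndarray
    family: str
    params: Params

    def __post_init__(self) -> None:
        n = len(self.time_grid)
        if not (len(self.amplitude) == len(self.frequency) == len(self.phase) == n):
            raise ValueError("waveform arrays must have equal length")
        if np.any(self.amplitude < -1e-12) or np.any(self.amplitude > 1 + 1e-12):
            raise ValueError("amplitude must lie in [0, 1]")

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    @property
    def tp(self) -> float:
        return float(self.params.tp)

    @property
    def swept(self) -> bool:
        return bool(np.ptp(self.frequency) > 0)


def _time_grid(tp: float, dt: float) -> np.ndarray:
    """Uniform sample-centred grid covering [-tp/2, tp/2].

    n = ceil(tp/dt) samples at spacing tp/n (≤ dt), so each sample represents
    an equal slice of the pulse and the summed slice durations equal tp
    exactly — a piecewise-constant propagator then reproduces the pulse area
    without truncation error.
    """
    _validate_positive(tp=tp, dt=dt)
    n = max(int(np.ceil(tp / dt - 1e-9)), 1)
    spacing = tp / n
    return (np.arange(n) - (n - 1) / 2) * spacing


def _integrate_phase(t: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """ρ(t) = ∫₀ᵗ 2πω dt′ by trapezoids, referenced so ρ = 0 at the midpoint t = 0."""
    cum = np.zeros_like(freq)
    if len(t) > 1:
        cum[1:] = np.cumsum(0.5 * (freq[1:] + freq[:-1]) * np.diff(t))
        cum -= np.interp(0.0, t, cum)
    return 2 * np.pi * cum


def synth_rectangular(tp: float, dt: float = DEFAULT_DT) -> Waveform:
    """Constant-amplitude, constant-phase pulse."""
    params = RectangularParams(tp)
    t = _time_grid(tp, dt)
    ones = np.ones_like(t)
    zeros = np.zeros_like(t)
    return Waveform(t, ones, zeros, zeros, "rectangular", params)


def synth_gaussian(tp: float, dt: float = DEFAULT_DT, fwhm: Optional[float] = None) -> Waveform:
    """Gaussian envelope A(t) = exp(−4 ln 2 · t²/FWHM²), hard-truncated at ±tp/2."""
    params = GaussianParams(tp, fwhm)
    t = _time_grid(tp, dt)
    amp = np.exp(-4 * np.log(2) * t**2 / params.fwhm**2)
    zeros = np.zeros_like(t)
    return Waveform(t, amp, zeros, zeros, "gaussian", params)


def _linear_sweep(t: np.ndarray, tp: float, delta_f: float) -> np.ndarray:
    return delta_f * t / tp  # -Δf/2 at -tp/2 ... +Δf/2 at +tp/2


def synth_chirp(params: ChirpParams, dt: float = DEFAULT_DT) -> Waveform:
    """Linear frequency sweep at constant amplitude with quarter-sine edges."""
    t = _time_grid(params.tp, dt)
    freq = _linear_sweep(t, params.tp, params.delta_f)
    amp = np.ones_like(t)
    if params.t_rise > 0:
        edge = params.tp / 2 - np.abs(t)  # distance from the nearer pulse edge
        ramp = edge < params.t_rise
        amp[ramp] = np.sin(np.pi * edge[ramp] / (2 * params.t_rise))
    return Waveform(t, amp, freq, _integrate_phase(t, freq), "chirp", params)


def synth_wurst(params: WurstParams, dt: float = DEFAULT_DT) -> Waveform:
    """WURST envelope over a linear sweep."""
    t = _time_grid(params.tp, dt)
    amp = 1 - np.abs(np.sin(np.pi * t / params.tp)) ** params.n
    freq = _linear_sweep(t, params.tp, params.delta_f)
    return Waveform(t, amp, freq, _integrate_phase(t, freq), "wurst", params)


def synth_hs(params: HSParams, dt: float = DEFAULT_DT) -> Waveform:
    """Hyperbolic-secant pulse, possibly asymmetric (different h per half).

    Each half uses its own order h in the sech envelope; the tanh frequency
    sweep is common to both halves, so both A and ω are continuous at t = 0
    with A(0) = 1 and ω(0) = 0.
    """
    t = _time_grid(params.tp, dt)
    x = t / params.tp  # in [-1/2, 1/2]
    h = np.where(x < 0, params.h_lead, params.h_trail)
    arg = params.beta * 2.0 ** (h - 1) * np.abs(x) ** h
    amp = 1.0 / np.cosh(arg)
    freq = (params.delta_f / 2) * np.tanh(params.beta * x) / np.tanh(params.beta / 2)
    return Waveform(t, amp, freq, _integrate_phase(t, freq), "hs", params)


def synthesize(params: Params, dt: float = DEFAULT_DT) -> Waveform:
    """Dispatch on the parameter record type."""
    if isinstance(params, RectangularParams):
        return synth_rectangular(params.tp, dt)
    if isinstance(params, GaussianParams):
        return synth_gaussian(params.tp, dt, params.fwhm)
    if isinstance(params, ChirpParams):
        return synth_chirp(params, dt)
    if isinstance(params, WurstParams):
        return synth_wurst(params, dt)
    if isinstance(params, HSParams):
        return synth_hs(params, dt)
    raise TypeError(f"unknown parameter record {type(params).__name__}")


def quadrature_components(w: Waveform) -> tuple[np.ndarray, np.ndarray]:
    """AWG quadratures I = A cos ρ, Q = A sin ρ (so I² + Q² = A²)."""
    return w.amplitude * np.cos(w.phase), w.amplitude * np.sin(w.phase)
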