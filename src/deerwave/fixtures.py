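"""Synthetic inputs: nitroxide spectrum, resonator profile, distance
distributions, and complete reproducible DEER datasets.

Nothing in this module is measured data.  The spectrum is a parametric
stand-in for a Q-band nitroxide absorption line: a three-line ¹⁴N hyperfine
pattern with asymmetric (split-normal) Gaussian broadening, calibrated so
that a 16 ns rectangular π pump at the spectrum maximum reaches a modulation
depth near 0.3 and 100 ns broadband pumps reach 0.5–0.65 — the ranges a
Q-band nitroxide setup at ν1 = 30 MHz realises.  The resonator is a
Lorentzian-magnitude transfer function with 200 MHz FWHM (power profile).

The two dataset regimes mirror the study conditions the sensitivity layer is
meant to discriminate: a doubly labelled ligand at 80 µM ("high_c", strong
intermolecular background) and at 30 µM ("low_c", nearly flat background).
Spin concentration is twice the molecular concentration (two labels per
molecule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import waveforms as wf
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .deer_model import (
    DeerTrace,
    DistanceDistribution,
    background_decay_constant,
    modulation_depth,
    simulate_trace,
)
from .spin_dynamics import SpinField, inversion_profile

__all__ = [
    "SpectrumModel",
    "ResonatorProfile",
    "SpectrumLine",
    "DEFAULT_SPECTRUM_LINES",
    "nitroxide_spectrum",
    "resonator_profile",
    "model_distribution",
    "default_pulse_set",
    "synthetic_dataset",
    "LIGAND_CONC",
    "LABELS_PER_MOLECULE",
    "DEFAULT_SIGMA0",
]

#: Ligand concentrations (mol/L) of the two study regimes.
LIGAND_CONC = {"high_c": 80e-6, "low_c": 30e-6}
#: Doubly labelled ligand: two nitroxides per molecule.
LABELS_PER_MOLECULE = 2
#: Default absolute noise std on the normalised trace.
DEFAULT_SIGMA0 = 0.004


@dataclass(frozen=True)
class SpectrumModel:
    """Normalised absorption spectrum on an offset grid relative to its maximum."""

    offsets: np.ndarray  # Hz
    intensity: np.ndarray  # 1/Hz, integral 1

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        total = np.trapezoid(self.intensity, self.offsets)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"intensity must integrate to 1, got {total}")


@dataclass(frozen=True)
class ResonatorProfile:
    """Lorentzian-magnitude transfer function on the ν1 (amplitude) scale.

    ``fwhm`` refers to the *power* profile: the amplitude value at
    ±fwhm/2 is sqrt(1/2), so that its square — the power — is halved.
    """

    center: float = 34.00e9  # Hz
    fwhm: float = 200e6  # Hz

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    def value_at(self, offset: np.ndarray | float) -> np.ndarray | float:
        """Relative ν1 scale at ``offset`` Hz from the resonator centre."""
        x = 2.0 * np.asarray(offset, dtype=float) / self.fwhm
        out = 1.0 / np.sqrt(1.0 + x * x)
        return float(out) if np.isscalar(offset) else out


@dataclass(frozen=True)
class SpectrumLine:
    """One hyperfine line: centre (Hz) and split-normal widths (Hz) and weight.

    ``sigma_low``/``sigma_high`` are the Gaussian standard deviations on the
    low- and high-frequency side of the line centre; unequal values give the
    asymmetric broadening of a powder pattern.
    """

    center: float
    sigma_low: float
    sigma_high: float
    weight: float = 1.0


#: Calibrated default ¹⁴N pattern: 45 MHz splitting, broad outer wings,
#: narrow inner flanks, slightly de-weighted centre line.
DEFAULT_SPECTRUM_LINES: tuple[SpectrumLine, ...] = (
    SpectrumLine(-45e6, sigma_low=25e6, sigma_high=10e6, weight=1.0),
    SpectrumLine(0.0, sigma_low=14e6, sigma_high=14e6, weight=0.95),
    SpectrumLine(45e6, sigma_low=10e6, sigma_high=30e6, weight=1.0),
)


def _split_normal(x: np.ndarray, line: SpectrumLine) -> np.ndarray:
    sigma = np.where(x < line.center, line.sigma_low, line.sigma_high)
    amp = 2.0 / (np.sqrt(2 * np.pi) * (line.sigma_low + line.sigma_high))
    return amp * np.exp(-0.5 * ((x - line.center) / sigma) ** 2)


def nitroxide_spectrum(grid: np.ndarray | None = None,
                       lines: Sequence[SpectrumLine] = DEFAULT_SPECTRUM_LINES) -> SpectrumModel:
    """Synthetic nitroxide absorption spectrum, normalised to unit integral.

    The grid must span at least ±150 MHz so the hyperfine wings are covered.
    The default model has a single global maximum at offset 0.
    """
    if grid is None:
        grid = np.arange(-300, 300.25, 0.25) * 1e6
    grid = np.asarray(grid, dtype=float)
    if grid[0] > -150e6 or grid[-1] < 150e6:
        raise ValueError("spectrum grid must span at least ±150 MHz")
    s = sum(line.weight * _split_normal(grid, line) for line in lines)
    s = s / np.trapezoid(s, grid)
    return SpectrumModel(grid, s)


def resonator_profile(center: float = 34.00e9, fwhm: float = 200e6) -> ResonatorProfile:
    """Resonator transfer profile (default: 34.00 GHz centre, 200 MHz FWHM)."""
    return ResonatorProfile(center, fwhm)


def model_distribution(mean: float = 5.1, fwhm: float = 0.2,
                       n_points: int = 81) -> DistanceDistribution:
    """Gaussian distance distribution (defaults: 5.1 nm mean, 0.2 nm FWHM)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    r = np.linspace(mean - 5 * sigma, mean + 5 * sigma, n_points)
    p = np.exp(-0.5 * ((r - mean) / sigma) ** 2)
    p = p / np.trapezoid(p, r)
    return DistanceDistribution(r, p)


def default_pulse_set() -> dict[str, wf.Params]:
    """The best-performing pump pulse of each family in the study conditions."""
    return {
        "rectangular": wf.RectangularParams(tp=16e-9),
        "chirp_short": wf.ChirpParams(tp=36e-9, delta_f=120e6, t_rise=0.0),
        "wurst": wf.WurstParams(tp=100e-9, delta_f=160e6, n=6),
        "hs11": wf.HSParams(tp=100e-9, delta_f=110e6, beta=8.0),
        "hs16": wf.HSParams(tp=100e-9, delta_f=110e6, beta=10.0, h_lead=1.0, h_trail=6.0),
    }


from functools import lru_cache


@lru_cache(maxsize=64)
def _pulse_lambda(params: wf.Params, nu1_max: float) -> float:
    """Modulation depth of a pulse at ν1, seed-independent hence memoised."""
    wave = wf.synthesize(params)
    profile = inversion_profile(wave, field=SpinField(nu1_max=nu1_max))
    return modulation_depth(profile, nitroxide_spectrum())


def synthetic_dataset(regime: str, pulse_set: Optional[dict[str, wf.Params]] = None,
                      seed: int = 0, out_dir: Optional[Path | str] = None,
                      sigma0: float = DEFAULT_SIGMA0,
                      nu1_max: float = 30e6, d: float = 3.5,
                      constants: PhysicalConstants = DEFAULT_CONSTANTS,
                      ) -> tuple[dict[str, DeerTrace], dict]:
    """Simulate one full DEER dataset for every pulse in ``pulse_set``.

    For each pulse: synthesize the waveform, compute its inversion profile at
    ``nu1_max``, derive the modulation depth λ and pump efficiency f from the
    synthetic spectrum, set the background constant k from the regime's spin
    concentration, and simulate an 8 µs / 8 ns trace with noise σ0.  Returns
    the traces and a manifest recording every parameter; when ``out_dir`` is
    given, traces are written as delimited text next to ``manifest.json``.
    """
    if regime not in LIGAND_CONC:
        raise ValueError(f"regime must be one of {sorted(LIGAND_CONC)}, got {regime!r}")
    if pulse_set is None:
        pulse_set = default_pulse_set()
    spin_conc = LABELS_PER_MOLECULE * LIGAND_CONC[regime]
    spectrum = nitroxide_spectrum()
    dist = model_distribution()
    field = SpinField(nu1_max=nu1_max)
    rng = np.random.default_rng(seed)

    traces: dict[str, DeerTrace] = {}
    manifest: dict = {
        "regime": regime,
        "ligand_concentration_M": LIGAND_CONC[regime],
        "labels_per_molecule": LABELS_PER_MOLECULE,
        "spin_concentration_M": spin_conc,
        "nu1_max_Hz": nu1_max,
        "background_dimensionality": d,
        "sigma0": sigma0,
        "seed": seed,
        "distance_mean_nm": 5.1,
        "distance_fwhm_nm": 0.2,
        "pulses": {},
    }
    for name, params in pulse_set.items():
        wave = wf.synthesize(params)
        profile = inversion_profile(wave, field=field)
        lam = modulation_depth(profile, spectrum)
        f = lam  # same spectrum-weighted flip probability governs the background
        k = background_decay_constant(spin_conc, f, constants)
        trace_seed = int(rng.integers(0, 2**31 - 1))
        trace = simulate_trace(dist, lam, k, d, sigma0, seed=trace_seed,
                               constants=constants)
        traces[name] = trace
        manifest["pulses"][name] = {
            "family": wave.family,
            "params": {key: float(val) for key, val in vars(params).items()
                       if isinstance(val, (int, float))},
            "lambda": lam,
            "f": f,
            "k_per_us": k,
            "trace_seed": trace_seed,
        }
    if out_dir is not None:
        from .io import write_trace

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, trace in traces.items():
            path = out / f"{name}.csv"
            write_trace(trace, path)
            manifest["pulses"][name]["file"] = path.name
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return traces, manifest
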