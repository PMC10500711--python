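# deerwave

Broadband pump-pulse synthesis and sensitivity simulation for four-pulse
DEER (double electron–electron resonance, also called PELDOR) — the pulsed
EPR experiment that measures nanometre distances between spin labels on
biomolecules.

Arbitrary waveform generators allow DEER pump pulses to be
frequency-swept (chirp, WURST, hyperbolic-secant), which inverts a much
larger slice of the nitroxide spectrum than a rectangular or Gaussian pulse
and therefore raises the modulation depth λ of the dipolar signal.  But the
same broader inversion accelerates the intermolecular background decay, and
dividing the background out of a long trace amplifies the noise at its end.
`deerwave` exists to quantify that trade-off: for a given pulse, spin
concentration and distance range, is the broadband pulse actually worth it?

The package is aimed at pulsed-EPR practitioners and method developers who
want to explore pulse parameters at the desk before spending spectrometer
time, and at anyone who needs a clean, tested reference implementation of
the underlying models.

## What it computes

* **Waveforms** — sampled A(t), ω(t), ρ(t) = ∫2πω dt′ and AWG quadratures
  I = A cos ρ, Q = A sin ρ for rectangular, Gaussian, chirp (quarter-sine
  smoothed), WURST (A = 1 − |sin πt/tp|ⁿ) and HS pulses
  (A = sech(β 2^(h−1)(t/tp)^h), ω = (Δf/2)·tanh(βt/tp)/tanh(β/2)),
  including asymmetric HS{1,6}.
* **Spin dynamics** — a norm-preserving piecewise-rotation Bloch propagator;
  inversion profiles Mz(ν); adiabaticity Q(t) = 2πν_eff/|dθ/dt| and the
  linear-sweep closed form Q_min = 2πν1²tp/Δf; spin-flip-time maps and the
  effective pulse length they imply.
* **DEER model** — powder-averaged dipolar kernel
  K(t, r) = ∫ cos(2πν⊥(1 − 3cos²θ)t) sinθ dθ with ν⊥ = D/r³
  (D ≈ 52 MHz·nm³); form factor F(t) = 1 − λ(1 − ∫P(r)K(t,r)dr);
  stretched-exponential background B(t) = exp(−(k|t|)^(d/3)) with
  k = (2πNaµ0g²µe²/9√3ħ)·f·c; the quarter-period minimum-distance rule
  tp < Tdd/4 and the three-oscillation truncation rule τ = 3r³max/52 µs.
* **Sensitivity analysis** — background fitting (with oscillation-leakage
  suppression), spline-based noise estimation, the modulation-to-noise
  ratio MNR = λ/n, MNR-versus-truncation curves, η2P = V(0) − V(t_min)
  parameter scans, and a closed-form MNR-gain model versus concentration
  and distance range.
* **Fixtures** — a synthetic Q-band nitroxide spectrum, resonator transfer
  profile, model distance distributions and fully reproducible synthetic
  DEER datasets for the 80 µM and 30 µM study regimes.

## Worked example

Simulate the 80 µM dataset and analyze each trace blind (the analyzer never
sees the generating parameters):

```python
from deerwave.fixtures import synthetic_dataset
from deerwave.sensitivity import mnr

traces, manifest = synthetic_dataset("high_c", seed=42)
for name, trace in traces.items():
    res = mnr(trace, tau_trunc=7.0)
    print(name, round(res.lambda_hat, 3), round(res.k_hat, 4), round(res.mnr))
```

Output (see `examples/03_simulate_and_analyze.py` for the annotated run):

```
pulse         lam true  lam_hat   k true   k_hat    noise    MNR
rectangular      0.327    0.342   0.0524  0.0509   0.0045     77
chirp_short      0.578    0.607   0.0926  0.0886   0.0051    120
wurst            0.645    0.677   0.1033  0.0977   0.0053    129
hs11             0.569    0.597   0.0911  0.0871   0.0050    119
hs16             0.507    0.531   0.0812  0.0783   0.0050    107
```

Broadband pumps roughly double the modulation depth of the rectangular
reference — and with it the MNR at this trace length — while the recovered
λ̂ and k̂ track the generating values.  `examples/04_truncation_tradeoff.py`
shows the flip side: at 80 µM the WURST curve falls to 0.73 of its 2 µs
value by 7 µs while the rectangular reference only falls to 0.90, and
`examples/05_analytic_gain.py` maps where the broadband advantage
disappears entirely (gain < 1 beyond ~6 nm at 80 µM ligand).

Each `examples/*.py` script is self-contained and prints what its numbers
mean; run them with `python examples/01_synthesize_pulses.py` etc.

There is also a thin CLI:

```sh
deerwave synth --family hs --tp 100 --df 110 --beta 10 --h 1,6 -o wave.csv
deerwave fixtures --regime high_c --seed 7 -o datadir/
deerwave analyze --trace datadir/hs11.csv --tau 7
deerwave gain --c 80e-6 --rmax-grid 3:8:0.5 -o gain.csv
```

Every command writes a manifest recording its inputs, parameters and seed.

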