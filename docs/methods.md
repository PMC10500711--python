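# Methods

This note documents the models behind `deerwave`, the conventions and
defaults it fixes where several reasonable choices exist, and what the
synthetic study conditions do and do not show about real measurements.

## Pulse model

A pulse is a sampled record of envelope A(t) ∈ [0, 1], instantaneous
frequency offset ω(t) from the sweep centre, and accumulated phase
ρ(t) = ∫₀ᵗ 2πω dt′ with t = 0 at the pulse midpoint and ρ(0) = 0.  The
time grid uses n = ⌈tp/dt⌉ samples at spacing tp/n ≤ dt (default dt
0.5 ns), so the samples tile the pulse exactly; a piecewise-constant
propagator then reproduces the pulse area without truncation error, and a
rectangular π pulse inverts to machine precision.

Conventions that the literature leaves ambiguous, fixed here:

* **HS truncation parameter.**  The common notation "β = 8/tp" is read as
  dimensionless β = 8 with t measured in units of tp, making the sech
  argument β·2^(h−1)(t/tp)^h dimensionless.
* **Asymmetric HS stitching.**  HS{1,6} uses h = 1 on the leading half and
  h = 6 on the trailing half of the *envelope* only; the tanh frequency
  sweep is shared by both halves.  This keeps A and ω continuous at t = 0
  and preserves the steep leading flank.  Whether the original asymmetric
  pulses also modified the sweep is not documented; this is a package
  convention.
* **Quarter-sine smoothing** applies to the chirp amplitude only, never to
  the frequency sweep.
* **Gaussian truncation** is hard at ±tp/2 without renormalisation, and the
  default FWHM is tp/(2√(2 ln 2)), the Xepr convention.

## Bloch propagation

Magnetisation starts at (0, 0, +1) and is rotated per sample about the
effective field 2π(ν1A cos ρ, ν1A sin ρ, Δ) by axis–angle (Rodrigues)
rotation — exact for a constant field, unconditionally norm-preserving, and
fast enough that no ODE solver is warranted (a full ±300 MHz profile takes
~20 ms).  Relaxation is neglected: pulse lengths ≤ 100 ns are orders of
magnitude below nitroxide T1/T2 at 50 K.  Halving dt moves on-band profile
points by < 1e-3; the steep flanks of HS profiles move by ~1.3e-3.

The propagator was cross-checked two ways: against the closed-form
rectangular-pulse (Rabi) inversion formula on a 50×20 offset × length grid
(agreement to 1e-14), and against a high-accuracy `scipy.solve_ivp`
integration of the same dynamics in both the carrier and the
frequency-modulated frame for swept pulses (agreement to 3 decimals).

Two findings from this simulation are worth flagging because naive
adiabatic-passage reasoning suggests otherwise:

* A 100 ns / 120 MHz chirp at ν1 = 30 MHz (Q_min = 4.7) does **not** invert
  completely: its sweep starts only 2ν1 from the band centre, so the
  initial effective field is tilted ~27° and the 10 ns quarter-sine ramp is
  itself only marginally adiabatic.  Mean Mz over the central 60 % of the
  band converges to ≈ −0.77; the same Q with doubled sweep margin
  (Δf = 240 MHz, tp = 200 ns) reaches −0.998.  Related: at fixed 10 ns
  smoothing the on-band efficiency *decreases* slightly above ν1 ≈ 20 MHz,
  the known edge-distortion effect of under-smoothed chirps.
* Spin-flip times (first zero crossing of Mz) lag the frequency-sweep
  schedule by up to ~1/(2ν1), because even an instantaneous resonance
  passage needs a finite nutation to push Mz through zero.  The effective
  flip window of the HS{1,1} pump (100 ns, 110 MHz, β = 8, ν1 = 30 MHz) is
  therefore [37, 93] ns — 55 ns wide, matching the ~60 ns effective length
  that sets the 2.3 nm distance floor, but positioned later in the pulse
  than the sweep schedule alone would suggest.  The window is reported as
  the full range of flip times over offsets that end more than
  half-inverted; percentile variants are configurable.

## DEER signal model

V(t) = F(t)·B(t) with

* F(t) = 1 − λ(1 − ∫P(r)K(t, r)dr), K the powder-averaged dipolar kernel
  evaluated by 1000-node Gauss–Legendre quadrature (error < 1e-6 over 8 µs;
  the distribution-averaged kernel is memoised since it is independent of
  λ, k and noise);
* B(t) = exp(−(k|t|)^(d/3)), k = (2πNaµ0g²µe²/9√3ħ)·f·c.

Units and constants: distances in nm, times in µs, concentrations in mol/L
of *pumped spins* — the doubly labelled ligand of the study system
contributes two spins per molecule, so "80 µM ligand" means c = 160 µM.
The dipolar constant D = µ0g²µe²/4πh = 52.23 MHz·nm³ is derived from
CODATA values with g = 2.0059 and used for every distance ↔ frequency
conversion, except inside the truncation rule τ = 3r³max/52 µs, where the
conventional printed 52 MHz·nm³ is kept verbatim so the familiar "≈ 7 µs
for 5.1 nm" lands exactly.  The decay-constant prefactor evaluates to
1.0 µs⁻¹ per (mM × unit inversion efficiency).

Noise is additive, Gaussian and homoscedastic on V (the assumption behind
the two-point η2P metric), with a seeded generator for reproducibility.
λ is the spectrum-weighted pump flip probability
∫S(ν)·(1 − Mz(ν))/2 dν; the background's inversion efficiency f is the
same spectrum average, so f = λ in the simulation pipeline.

## Sensitivity analysis

MNR = λ̂/n̂.  The pipeline fits s·B(t) to the trace tail (fit window from
0.3 of the trace length, d fixed at 3.5), divides, and estimates the noise
as the residual σ of a GCV-chosen cubic smoothing spline over the window
that drops the first 10 points and ends at the truncation time (7 µs
default).  λ̂ is one minus the spline mean over the last 20 % of that
window.  Two refinements beyond the plain recipe proved necessary:

* **Oscillation-leakage suppression in the background fit.**  For the
  narrow 5.1 nm distribution the dipolar oscillation never decays within
  8 µs, and a plain tail fit overestimates k by an absolute ~0.03 µs⁻¹ —
  a +70 % error at low concentration, which fabricates an MNR decline
  where none exists.  By default the fit therefore compares the data and
  the model after an identical moving average over the trace's dominant
  oscillation period (estimated from the FFT of the detrended trace): the
  oscillation cancels to first order while the matched smoothing of the
  model keeps the comparison unbiased.  Residual k̂ error is ≤ ~12 % on
  the narrow system and < 1 % once oscillations decay inside the window.
* **One λ̂ per curve.**  Truncating a trace changes its noise, not its
  modulation depth, so MNR-versus-τ curves estimate λ̂ once at the longest
  τ and re-evaluate only the noise; reading the plateau per-window makes
  the curves artificially non-monotone on oscillating form factors.

The η2P parameter scan simulates noiseless 8-point short traces per grid
cell and scales them by an echo-amplitude model: the spectral intensity at
the observer position (moving the observer out on the spectrum costs echo)
times one minus the pump inversion efficiency over a 25 MHz observer band
(a stand-in for pulse-overlap losses).  Genuine "2+1" echo-crossing
artefacts are deliberately out of scope; since those artefacts are the main
experimental penalty for *small* offsets, the in-model η2P optimum for
steep-flanked HS pulses sits at the smallest scanned offset rather than at
the 80–100 MHz found on a spectrometer.  The sweep-width optimum and its
overshoot penalty are reproduced.

The analytic gain model compares two pulses by
gain = (λs/λr)·n_r(τ)/n_s(τ) with n(τ) = σ0·RMS(1/B) over the noise
window, k from the decay-constant formula with f = λ/0.65, and
τ = τ(rmax) from the truncation rule.  It reproduces the full pipeline's
MNR ratios to within ~25 % — it is a back-of-envelope model, useful for
mapping regimes, not for precise prediction.

## Synthetic study conditions

The fixtures emulate a Q-band (34 GHz) nitroxide setup: ν1 = 30 MHz at the
maximum of a 200 MHz-FWHM Lorentzian-magnitude resonator profile, a 5.1 nm
Gaussian distance distribution of 0.2 nm FWHM, trace grid 8 µs / 8 ns,
σ0 = 0.004 (chosen so MNR lands at the tens-to-hundred scale of real
measurements), and ligand concentrations of 80 µM ("high_c") and 30 µM
("low_c").

The spectrum is a parametric stand-in, not a spin-Hamiltonian simulation:
three ¹⁴N hyperfine lines at −45/0/+45 MHz with split-normal (asymmetric
Gaussian) broadening — outer wings of 25–30 MHz σ, inner flanks of
10 MHz, centre line σ 14 MHz at weight 0.95.  These parameters were chosen
once so that a 16 ns rectangular π pump at the maximum reaches λ ≈ 0.33,
broadband pumps reach λ ≈ 0.51–0.65, and 65 % of the intensity lies within
±55 MHz of the maximum — the ranges a real nitroxide sample shows.
Symmetric lines cannot satisfy those constraints simultaneously; the
asymmetric wings are also what powder patterns actually look like.

What passing tests on these fixtures show: the estimator pipeline is
self-consistent, and the *mechanism* of the concentration/distance
trade-off — declining MNR curves with crossover ordering at 80 µM, flat
curves at 30 µM, gain < 1 beyond ~6 nm — operates as in the laboratory.
What they do not show: absolute experimental MNR values, which depend on
echo intensity, resonator detail, instrument noise spectra and acquisition
overheads that this package does not model.  Parameter-recovery accuracy is
validated on a calibration distribution (4.0 nm, 0.6 nm FWHM) whose
oscillations decay before the background-fit window; on the narrow 5.1 nm
system an irreducible oscillation-leakage bias of order 10 % in k̂ remains
even after suppression.

## Degenerate inputs and numerical edges

Empty offset grids, non-positive pulse lengths, fit windows shorter than
20 points, non-monotone trace time axes and NaNs are rejected with
descriptive errors.  A background fit that fails to converge falls back to
k = 0 and is flagged; a trace with no local minimum yields a flagged η2P
carrying V(0) − min(V).  The GCV spline falls back to a fixed smoothing
parameter with a warning if cross-validation fails.  Seeds derived from
user seeds stay below 2³¹.

## Known limitations

* Single-spin propagation only: no coupled two-spin evolution, orientation
  selection, exchange coupling, multi-spin effects or excluded-volume
  backgrounds.
* No "2+1"/pulse-overlap artefact model (see above) and no resonator
  bandwidth compensation of waveforms.
* The spectrum fixture is a surrogate; quantitative λ values transfer to a
  real spectrometer only to the extent that the real spectrum resembles it.
* Background fitting assumes the stretched-exponential family with known
  dimensionality d.
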