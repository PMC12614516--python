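# Methods

## The measurement problem

Shear-wave speed in soft media is set by shear stiffness, and its
frequency dependence (dispersion) by viscoelastic loss. A short-path
time-of-flight (TOF) device excites a single-cycle shear burst at one
frequency at a time (40–180 Hz in 20 Hz steps), records the transmit
(Tx) and receive (Rx) channels at 100 kHz, picks the wavefront arrival
on each channel, and converts the arrival-time difference over a known
path length D into a phase speed. Repeating across frequencies yields a
dispersion curve c_s(f), which is inverted for material parameters.
Oscillatory rheometry provides the reference measurement, but only at
0.1–1 Hz — two decades below the TOF band — which is exactly why the
cross-band machinery in `crossband` exists.

## Constitutive model

The Kelvin–Voigt fractional-derivative (KVFD) model is a spring E₀ in
parallel with a fractional dashpot η·(d/dt)^α. In the frequency domain,

    E*(f) = E₀ + η (j·2πf)^α
          = [E₀ + η(2πf)^α cos(πα/2)] + j·[η(2πf)^α sin(πα/2)],

with storage/loss moduli E′, E″ and loss angle δ = arctan(E″/E′).
Parameters, units, defaults:

| parameter | meaning | units | domain / default |
|---|---|---|---|
| E₀ | relaxed (zero-frequency) Young's modulus | Pa | > 0 |
| η | fractional viscosity | Pa·s^α | ≥ 0 |
| α | fractional order | — | open (0, 1); 0 and 1 only as explicit limits |
| ρ | density | kg/m³ | 1000 (water-like PVA cryogel; never reported with the measurements, so the water-like value is adopted and exposed in every API) |
| ν | Poisson's ratio | — | 0.5 (incompressible); E* = 2(1+ν)G* |

For a plane shear wave the complex wavenumber is
k = ω·sqrt(2(1+ν)ρ/E*) (the familiar `3ρ` at ν = 0.5), giving phase
velocity c_s = ω/Re(k) and attenuation α_att = −Im(k). The package
implements the loss-aware closed form

    c_s(f) = sqrt( 2(E′² + E″²) / (2(1+ν)ρ (|E*| + E′)) )

and verifies, in the test suite, that it agrees with the complex-
arithmetic route to 1e-10 relative over a grid α ∈ {0.1…0.9},
η ∈ {1…10⁴}, f ∈ {0.1…1000 Hz}. The attenuation closed form uses
|E*| − E′ = E″²/(|E*| + E′) to avoid cancellation at small loss; the
naive difference loses ~8 digits in the weak-loss regime. The loss
angle also controls the phase-velocity "inflation factor"
F = 1/cos(δ/2) ≥ 1 — the ratio of lossy to lossless phase speed — used
to bound the bias of lossless forward modeling.

## Signal pipeline

Stages, in order: ensemble averaging of repeated shots → zero-phase
band-pass (10–190 Hz) → 5-sample running median (impulse suppression) →
db4 level-4 wavelet shrinkage (soft universal threshold, noise σ from
the MAD of the finest detail band, periodized orthogonal transform so
output energy never exceeds input energy) → Savitzky–Golay smoothing
(201 samples ≈ 2 ms, order 3). The order is configurable for ablation.

The band-pass deserves a note. At 100 kHz sampling, a 10–190 Hz band is
extremely narrow relative to Nyquist: a windowed-sinc (Hamming) design
needs a transition width of about 3.3·fs/N, so rejecting DC below a
10 Hz band edge requires N ≈ 2·10⁴ taps — a short FIR physically cannot
realize this band. The default is an 18001-tap symmetric kernel applied
by edge-padded FFT convolution: a centered symmetric FIR is exactly
zero-phase (no forward–backward pass needed, which is the IIR route to
the same property), and the measured response is −54 dB at DC, 0 dB at
100 Hz, −95 dB at 1 kHz.

The energy-ratio figure 10·log₁₀(Σref²/Σtest²) is provided under its
own name (`snr_energy_ratio`) because it is an accounting convention,
not a signal-to-noise ratio; a conventional estimator (post-onset power
over pre-onset baseline power, `snr_onset`) sits beside it.

## Arrival picking

Per channel: analytic envelope A = |x + jH{x}|, instantaneous power
P = A², cumulative energy C(t) = ∫P dτ, and the knee of C — the first
index where dC/dt exceeds mean + k·std of dC/dt (k = 1 by default;
statistics over the full record by default, with a leading-baseline
window as the alternative). The first difference is aligned so that an
ideal power step at sample k crosses the threshold exactly at k.
Crossings in the first/last 1% of the record are rejected as edge
artifacts. The threshold is scale-covariant, so picks are invariant to
channel gain. TOF = (onset_Rx − onset_Tx)/fs; velocity = D/TOF.

Two systematic effects are worth knowing:

- The Hilbert envelope is non-causal, so a single-channel pick on a
  suddenly switched-on tone lands a few samples early. The effect is
  identical on both channels and cancels exactly in the TOF difference
  (shift-equivariance is asserted in the suite).
- The knee marks the arrival of wave *energy*, which travels at the
  group velocity. Under normal dispersion (c_s rising with f) the group
  front outruns the phase front, so knee velocities sit *above* c_s(f₀)
  in strongly lossy media: with the hard-phantom TOF parameters the
  overshoot is +5–11% across 40–180 Hz on clean synthetics. Detector
  validation against phase velocity is therefore performed in a
  weak-loss medium (E₀ = 5 kPa, η = 15 Pa·s^α, α = 0.5, δ(180 Hz) =
  3.8°), where group and phase arrival agree to ~3%; the lossy-medium
  overshoot is asserted separately as a known positive bias. Real
  measurements inherit the same effect, which a dispersion-only
  inversion partially absorbs into η and α.

Geometric QC (`farfield_check`) reports D ≥ 2λ (inclusive) and
boundary clearance > λ; it reports and never gates. At 40 Hz and
1.38 m/s, λ = 3.45 cm, so 2λ exceeds the ~4.9 cm path — the flag is
raised for the measured geometry at the low band edge.

## Dispersion inversion

`fit_kvfd` minimizes Σ wᵢ²(c_model(fᵢ) − c̄ᵢ)² over the mean velocities,
with wᵢ = 1/SEᵢ by default (inverse-variance weighting; unit weights
optional, and automatically substituted when any SE is undefined).
Bounds: E₀ ∈ (0, 10⁷] Pa, η ∈ (0, 10⁶] Pa·s^α, α ∈ (0, 1). Trust-region
reflective least squares is started from a deterministic grid
α₀ ∈ {0.1, …, 0.9}, with E₀ initialized from the low-frequency speed
(2(1+ν)ρc²(f_min)) and η₀ from the velocity rise across the band; the
best final cost wins and ties break toward the smallest η. Tolerances:
ftol 1e-12, xtol 1e-10, ≤ 2000 evaluations per start. No randomness.
Reported RMSE and R² are always the unweighted curve-level values on
mean velocities. The constrained mode freezes E₀ (used for the refit
against the rheometer value); the constrained optimum can never beat
the unconstrained one in the weighted objective, and the suite asserts
this.

E₀ is a zero-frequency extrapolation from a curve measured at
40–180 Hz, and identifiability sets a floor on its precision: with the
measured replicate structure (8 frequencies, 3 replicates, ~1% per-
replicate noise) the median E₀ error over seeded synthetic curves is
≈2.4% even though the fitted curves match the data to a fraction of the
noise level. Fitted curves are reliable; individual parameters trade
off, which is precisely why cross-modality comparison is done in the
velocity domain rather than parameter-by-parameter.

## Cross-band comparison

Each modality is fitted in its native band; each fit is then projected
onto the other band's frequency grid and scored against the measured
speeds there: RMSE, MAPE (denominator = measured), and signed mean bias
(predicted − measured). Relative parameter errors use the rheometer
value as denominator. The attenuation-related bias check tabulates δ(f)
in degrees, F, percent inflation (F − 1)·100, and the short-path
product α_att(f)·D per frequency. Note that with the hard-phantom
TOF-band parameters α_att·D is 0.84 at 40 Hz but reaches ≈8.8 at
180 Hz — the "short path ⇒ negligible decay" argument only holds at the
lower band edge for that parameter set. ν-sensitivity is closed-form:
at fixed G, perturbing ν by d around ν₀ changes reported E by
100·d/(1+ν₀) percent (perturbations are taken downward, since ν ≤ 0.5).

The low-band rheometer sweep underlying the reverse projection is not
distributed with the measurements; `make_rheometer_sweep` generates a
synthetic emulation from a KVFD parameter set (G* = E*/(2(1+ν)), with
optional multiplicative scatter). Tests using it check direction and
magnitude class of the reverse projection, not its exact error value.

## Synthetic data

`make_burst` produces pre-silence → n full sine cycles → silence.
`propagate_trace` multiplies the Tx spectrum by exp(−i·k(ω)·D) on the
positive-frequency half (rFFT, Hermitian symmetry, FFT length = next
power of two ≥ 4× the record to keep circular wrap-around negligible,
DC bin passed unchanged), so synthetic Rx traces carry physically
consistent dispersion and attenuation. An optional single-pole
resonator (default Q = 10 at the excitation frequency) emulates the
ring-down of a resonant receiver. `add_noise` adds seeded white
Gaussian noise, Poisson-timed impulses, and a power-line sinusoid; all
generators are pure functions of (spec, seed).

What the synthetics do *not* emulate: 3-D wave spreading, boundary
reflections and guided modes, transducer electromechanics, amplitude
calibration (arbitrary units — the detector is amplitude-invariant by
design), and drift/EMI structure beyond the three noise components.
Passing synthetic tests therefore validates the estimator chain under
the stated wave physics, not the hardware.

## Problem sizes and determinism

Synthetic records are 0.25 s at 100 kHz (25 000 samples); noisy-
recovery statistics use 50 seeded curves; noise-robustness uses 100
seeded trials. Every stochastic step takes an explicit integer seed and
is reproducible bit-for-bit. The fit is deterministic (no RNG).

## Known limitations

- ρ is assumed, not measured; velocities scale as 1/sqrt(ρ), so a 2%
  density error shifts moduli by 2%.
- The knee picks energy arrival; in strongly lossy media the reported
  speeds carry a positive group-velocity bias relative to c_s(f).
- E₀ from a 40–180 Hz band is extrapolation-limited (see above).
- The dispersion-only inversion never uses measured amplitude decay;
  the bias-check table quantifies, but does not correct, loss-related
  inflation.
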