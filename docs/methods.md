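# Model and methods

## The stack model

The transmission path from artery to transducer is lumped into a single
mass m₀ (tissue + microstructure, joined by contact) with a spring/damper
pair on each side: (k₀, c₀) toward the artery, (k_s, c_s) toward the sensor
substrate. The static pre-load displacement caused by the contact pressure
is excluded: its entire effect is absorbed into the nominal parameter
values. The transducer electronics are not modelled; the sensor output is
the substrate-to-mass relative displacement.

Two configurations:

- **Wall displacement as the true pulse (1DOF).** y(t) base-excites the
  mass:
  m₀ẍ + (c₀+c_s)ẋ + (k₀+k_s)x = k₀y + c₀ẏ.
- **Pulsatile pressure as the true pulse (2DOF).** The arterial wall is a
  grounded spring k_A loaded by F(t) = πa·Δp(t) (πa is a single effective-
  area scale factor, default 1; its absolute units are irrelevant because
  all outputs are reported as ratios). The wall coordinate x₁ is massless
  and couples to the mass coordinate x₂ through (k₀, c₀):
  (k_A+k₀)x₁ − k₀x₂ + c₀(ẋ₁−ẋ₂) = F,
  −k₀x₁ − c₀ẋ₁ + m₀ẍ₂ + (k₀+k_s)x₂ + (c₀+c_s)ẋ₂ = 0.

Substrate motion z_b(t) enters the mass equation as k_s z_b + c_s ż_b.

All quantities are dimensionless: k_A = 1 sets the stiffness scale and the
fundamental pulse amplitude sets the displacement scale. Nominal ratios:
k₀ = k_A/6, frequency ratio r₀ = ω₀/ω_C = 2, damping factors
ζ₀ = ζ_s = 1.5, k_s = 6k₀, heart rate 1 Hz. ζ_s is normalized by the
joined mass m₀ — the only mass in the model — since the microstructure
shares its mass with the stack; this is configurable through the ratio
interface if a different convention is wanted.

## Inputs

- **True pulse**: a ten-harmonic series with amplitude envelope
  (1, 0.55, 0.32, 0.18, 0.10, 0.055, 0.03, 0.018, 0.01, 0.006) relative to
  the fundamental and phases −0.4(k−1) rad — a monotonically decaying
  envelope typical of carotid waveforms. Fully configurable.
- **Substrate motion**: two tones, (2.0, 0.10 Hz, 0) and
  (0.8, 0.23 Hz, 0.8 rad) in units of the fundamental pulse amplitude —
  larger than the pulse and concentrated at low frequency, reflecting that
  the actual MA exceeds what the measured baseline suggests.
- **Grid**: dt = 1 ms, t ∈ [0, 12] s; the first 2 s are discarded from all
  metrics as a startup window, leaving 10 analyzed cycles at 1 Hz. These
  sizes keep every forward run at a few seconds on one core while resolving
  the 10 Hz top harmonic with 100 samples per period.

The model is fully deterministic; no random numbers are used anywhere. A
`noise` hook is reserved in the scenario schema but off by default.

## Signals: real convention

The physics is written per harmonic with complex gains; time series are
real, s(t) = Re[s₀e^{j(ωt+φ)}] = s₀cos(ωt+φ). Complex algebra is confined
to the frequency-response layer; derivatives of inputs are always analytic
(cos → −ω sin), never finite differences. A guard rejects any synthesized
frequency at or above the grid Nyquist frequency.

## Baseline drift and the TVSP coupling law

Because z_b is a finite sum of sinusoids, the drift equations are solved
exactly per component via the closed-form harmonic gains (a time-domain ODE
route is retained behind `method="ode"` for cross-validation; the two agree
to <1e−6 relative L2 after the startup window). This removes transient
ambiguity from the drift series that drives the parameter modulation.

The modulation law is linear: m(t) = κ_m·m₀·drift(t)/x_ref and likewise
for c, k, where drift = x_b (1DOF) or x₂b − x₁b (2DOF, the relative
displacement that strains the stack). Only proportionality is physically
established; the linear law with κ_m = κ_c = κ_k = 0.05 (5% peak
modulation, x_ref defaulting to max |drift| over the analysis window) is
this package's canonical choice, selected as a small-perturbation regime —
the regime in which the distortion phenomenology (harmonic-riding sidebands,
sub-percent heart-rate shifts, few-percent amplitude shifts) is cleanly
exhibited. All three κ and x_ref are configurable. A hard floor clamps each
modulated parameter at 5% of nominal (logged when hit) so the equations of
motion stay well-posed under aggressive couplings.

Derived instantaneous ratios: r(t) = √((k₀+k)/(m₀+m))/ω_C,
ζ(t) = (c₀+c)/(2√((k₀+k)(m₀+m))), and a total ratio r_total that adds the
sensor spring (and in the 2DOF case the arterial spring). How k_A enters
r_total is a genuine modelling choice: the default `series` variant uses
the stiffness seen from the mass, k_s + (k₀+k)k_A/((k₀+k)+k_A); a
`parallel` variant (k₀+k+k_s+k_A) is available behind a switch. Both
satisfy r_total > r pointwise.

## Time-varying integration

The modulated equations are integrated with adaptive RK45 (rtol 1e−8,
atol 1e−10, dense output on the grid); the modulation series are
interpolated with cubic splines, legitimate because the modulation varies
at ≲0.23 Hz, far below the pulse harmonics. The 2DOF system is reduced to
three states (x₁, x₂, ẋ₂); the massless wall equation yields ẋ₁
algebraically — valid because c₀ > 0. Initial conditions are the MA-free
closed-form steady state at t₀, and the first 2 s are discarded, so with
zero coupling the integrator reproduces the closed-form response to better
than 1e−4 relative L2 (tested), and under coupling the startup transient
(slowest pole ≈ −9.1 s⁻¹, decayed to ~1e−8 by 2 s) cannot leak into the
metrics.

## Equivalent forces and the round trip

With the nominal parameters frozen, the distortion can be represented as
forces: F_C = k₀y + c₀ẏ from the wall, F_b = k_s z_b + c_s ż_b from the
substrate, and F_T — the nominal operator applied to the modulated solution
— whose excess F_TVSP = F_T − F_C (1DOF; in 2DOF, F1TVSP = F1T − F on the
wall and F2TVSP = F2T on the mass) stands in for the parameter modulation.
The accelerations needed come from the integrator state and the evaluated
ODE right-hand side, exact at solver accuracy. The representation is
verified by round trip: integrating the *nominal* system under the full
force set must reproduce x_M + x_b (1DOF) or (x₁M+x₁b−x₁C, x₂M+x₂b−x₂C)
(2DOF). In the 2DOF round trip z_b is kept as a base input at the
substrate rather than converted to a mass force, because the sensor output
is a relative displacement and the substrate coordinate must remain
explicit. Canonical residuals are ~1e−10, with 1e−3 as the reported
pass/fail threshold.

## Waveform analytics

- **Foot detection**: upstroke peaks of the first derivative (refractory
  spacing 0.6/f₀ between upstrokes, height ≥ 25% of the maximum slope),
  then a backward walk of up to 0.95/f₀ from each upstroke to the nearest
  local minimum — the foot. On the canonical filtered waveform the foot
  precedes the upstroke by ~0.77 s, so the backward search must span most
  of a period; onsets are refined by parabolic interpolation, giving
  sub-millisecond timing on the 1 ms grid. No cycle-start convention is
  canonical in this problem; the foot convention is the standard one in
  pulse-waveform work and is deterministic.
- **Per-cycle metrics**: HR_i = 60/(t_{i+1}−t_i); amplitude = foot-to-peak;
  each cycle resampled to 200 points and normalized to unit time and unit
  amplitude for waveform (APW) comparison.
- **Spectra**: rectangular window over an integer number of fundamental
  periods, so pulse harmonics land on exact DFT bins and "distortion riding
  on each harmonic" is measurable as the fraction of non-DC energy within
  ±0.3 Hz of the harmonics (±Δf scales with f_C). The DC bin is excluded
  from energy fractions: a mean offset is not distortion. Per-bin energies
  are Parseval-consistent with the windowed signal energy.
- **Instantaneous envelope**: analytic signal via Hilbert transform with
  even mirror padding; instantaneous frequency from a 5-sample
  Savitzky–Golay derivative of the unwrapped phase (raw differencing
  amplifies noise); the outer 5% of samples are flagged edge-unreliable.
- **Spline baseline (CSE)**: natural cubic spline through the detected
  feet, constant beyond the end feet — the standard spline-through-onsets
  estimator. On TVSP-distorted signals it differs from the true measured
  drift by construction (both drift and TVSP shift the feet), which the
  tests assert rather than correct.

## Sensor-stiffness sweep

`stiffness_sweep` reruns a scenario across k_s/k₀ values and reports the
MA-free measured amplitude, the normalized-APW L2 deviation from the true
pulse, the TVSP distortion (absolute RMS and as a ratio to the clean
signal) and the baseline attenuation. A soft sensor (k_s = 2k₀) reads a
larger signal whose shape tracks the true pulse more closely, but suffers
larger baseline drift and larger absolute TVSP distortion. Note the
*ratio* of distortion to signal can fall even as absolute distortion
rises, because the signal grows faster; both are reported.

## Known limitations

- The TVSP coupling law (linearity, sign, absence of saturation) is a
  modelling assumption; only proportionality to drift is physically
  grounded.
- The synthetic pulse and substrate motion are stationary harmonic series:
  no beat-to-beat variability, no stochastic or impulsive motion, no
  sensor/transducer noise. Passing tests demonstrate the mechanism and its
  magnitudes under these conditions, not performance on clinical
  recordings.
- The 2DOF wall is massless; arterial inertia is neglected.
- Parameter estimation (inverting measured signals for stack parameters or
  MA) is out of scope.
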