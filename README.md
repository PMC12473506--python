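# pulsema

Forward modelling of motion-artifact (MA) distortion in arterial pulse
signals measured by tactile sensors.

A tactile sensor pressed on an artery reads the pulse through a transmission
path — overlying tissue, the tissue–sensor contact, and the sensor's
deformable microstructure — lumped here as a mass-spring-damper stack: a
joined mass m₀ with a spring/damper pair (k₀, c₀) toward the artery and
(k_s, c_s) toward the sensor substrate. Motion of the substrate z_b(t)
(holding fingers, body motion) does two things simultaneously:

1. **Baseline drift.** z_b drives the mass through (k_s, c_s); the sensor
   reads the substrate-to-mass distance, so the visible drift x_b − z_b is
   strongly attenuated (≈ −k₀/(k₀+k_s) at low frequency) and *opposite in
   sign* to the actual motion — a measured pulse signal badly understates
   the MA present in its measurement.
2. **Time-varying system parameters (TVSP).** The drift strains the tissue
   and contact, modulating m, c, k in proportion to it. The modulated stack
   filters the true pulse differently from the nominal one, producing a
   distortion x_TVSP = x_M − x_C that is small and abrupt, and — unlike the
   drift — concentrated in sidebands around every pulse harmonic, where no
   low-pass or wavelet baseline filter can remove it.

Two configurations are modelled: wall displacement y(t) as the true pulse
(base-excited 1DOF system) and pulsatile pressure Δp(t) as the true pulse
(2DOF system with the arterial wall as a spring k_A). The package provides
closed-form frequency responses, time-domain integration of the modulated
equations of motion, an equivalent-force decomposition with round-trip
verification, and the waveform analytics (cycle/foot detection, per-cycle
heart rate and amplitude, normalized waveforms, spectra, spline baseline
estimation) used to quantify the distortion.

## Worked example

```python
import pulsema as pm

scenario = pm.preset("canonical_1dof")   # nominal ratios, two-tone MA, 5% coupling
result = pm.run_scenario(scenario)
for key in ("baseline_attenuation", "drift_trend_correlation",
            "hr_max_rel_dev_pct", "amp_max_rel_change_pct",
            "tvsp_rms_ratio"):
    print(f"{key:28s} {result.metrics[key]: .4f}")
print("round-trip residual", result.roundtrip["residual_rel_l2"])
```

prints

```
baseline_attenuation          0.1447
drift_trend_correlation      -0.9963
hr_max_rel_dev_pct            0.0560
amp_max_rel_change_pct        3.7414
tvsp_rms_ratio                0.0228
round-trip residual 7.103370331454673e-11
```

Read: the drift visible in the measured signal peaks at only 14% of the
actual substrate motion and is almost perfectly anti-correlated with it;
the TVSP distortion perturbs per-cycle heart rate by at most 0.056% and
foot-to-peak amplitude by at most 3.7%; its RMS is 2.3% of the clean
signal; and replaying the equivalent-force decomposition through the
nominal system reproduces the distorted displacement to a relative L2
residual of 7·10⁻¹¹.

The same pipeline runs from the shell:

```
pulsema presets list
pulsema run scenario.yaml --out results_dir
pulsema sweep scenario.yaml --values 6,2
```

where `scenario.yaml` can be as small as `{preset: canonical_1dof}` with
optional overrides for the `pulse`, `stack`, `ma`, `coupling`, `grid` and
solver blocks. Outputs are CSV time series (9 significant digits), a
per-cycle table, metrics JSON, a round-trip report and a run manifest.

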