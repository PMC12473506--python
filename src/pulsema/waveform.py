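"""Cycle segmentation, per-cycle metrics, spectra, and baseline estimation.

The analytics mirror how measured arterial pulse waveforms (APW) are
processed in practice: cycles are delimited at the *foot* — the local
minimum immediately preceding the steepest systolic upstroke — heart rate
and foot-to-peak amplitude are read per cycle, each cycle is normalized to
unit time and unit amplitude for waveform comparison, and spectra are taken
over an integer number of fundamental periods with a rectangular window so
that the pulse harmonics fall on exact DFT bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .dynamics import MeasuredSignals
from .errors import DetectionError, DomainError

__all__ = [
    "CycleMetrics",
    "SpectrumReport",
    "detect_cycles",
    "hr_and_amplitude",
    "spectrum",
    "cse_baseline",
    "ma_metrics",
]

#: Number of samples each normalized cycle waveform is resampled to.
APW_SAMPLES = 200


@dataclass
class CycleMetrics:
    """Per-cycle measurements of a pulse series."""

    onset_times: np.ndarray          # s, strictly increasing
    onset_values: np.ndarray         # series value at each onset (foot)
    hr_bpm: np.ndarray               # 60 / cycle period, one fewer than onsets
    amplitude: np.ndarray            # foot-to-peak, per complete cycle
    apw_normalized: np.ndarray       # (n_cycles, APW_SAMPLES) in [0,1]^2


@dataclass
class SpectrumReport:
    """One-sided magnitude spectrum over an integer-cycle window."""

    frequency_hz: np.ndarray
    magnitude: np.ndarray            # one-sided amplitude spectrum
    energy: np.ndarray               # per-bin signal energy (Parseval-consistent)
    harmonic_band_energy_fraction: float
    low_freq_peak: tuple[float, float]  # (frequency_hz, magnitude), below f_C/2


def detect_cycles(series: np.ndarray, dt: float, f0_hint: float,
                  t0: float = 0.0) -> np.ndarray:
    """Detect cycle onsets (feet) of a pulse series.

    Feet are the local minima preceding the steepest upstroke of each cycle,
    with a refractory window of 0.6/f0_hint between upstrokes; onset times
    are refined by parabolic interpolation through the minimum and its
    neighbours.  Returns absolute onset times (``t0`` + offset).
    """
    x = np.asarray(series, dtype=float)
    if f0_hint <= 0:
        raise DomainError("f0_hint must be positive")
    if x.size * dt < 3.0 / f0_hint:
        raise DomainError("series must span at least 3 expected cycles")
    slope = np.gradient(x, dt)
    refractory = max(1, int(round(0.6 / f0_hint / dt)))
    lookback = max(2, int(round(0.95 / f0_hint / dt)))
    upstrokes, _ = find_peaks(slope, distance=refractory,
                              height=0.25 * slope.max())
    onsets = []
    for u in upstrokes:
        # walk back from the upstroke to the nearest local minimum (the foot)
        i = None
        for j in range(u - 1, max(0, u - lookback), -1):
            if x[j] <= x[j - 1] and x[j] <= x[j + 1]:
                i = j
                break
        if i is None or i == 0 or i == x.size - 1:
            continue
        # parabola through (i-1, i, i+1)
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        onsets.append(t0 + (i + delta) * dt)
    if len(onsets) < 2:
        raise DetectionError("fewer than 2 cycle onsets detected")
    return np.array(onsets)


def _value_at(series: np.ndarray, dt: float, t0: float, times: np.ndarray) -> np.ndarray:
    idx = (np.asarray(times) - t0) / dt
    return np.interp(idx, np.arange(series.size), series)


def hr_and_amplitude(series: np.ndarray, dt: float, onsets: np.ndarray,
                     t0: float = 0.0) -> CycleMetrics:
    """Per-cycle heart rate, foot-to-peak amplitude, and normalized APW."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        raise DomainError("need at least 2 onsets")
    if np.any(np.diff(onsets) <= 0):
        raise DomainError("onsets must be strictly increasing")
    x = np.asarray(series, dtype=float)
    periods = np.diff(onsets)
    hr = 60.0 / periods
    onset_values = _value_at(x, dt, t0, onsets)
    n_cycles = onsets.size - 1
    amplitude = np.empty(n_cycles)
    apw = np.empty((n_cycles, APW_SAMPLES))
    u = np.linspace(0.0, 1.0, APW_SAMPLES)
    for i in range(n_cycles):
        a, b = onsets[i], onsets[i + 1]
        tt = a + u * (b - a)
        cyc = _value_at(x, dt, t0, tt)
        peak = cyc.max()
        foot = onset_values[i]
        amplitude[i] = peak - foot
        span = cyc.max() - cyc.min()
        apw[i] = (cyc - cyc.min()) / span if span > 0 else 0.0
    return CycleMetrics(onset_times=onsets, onset_values=onset_values,
                        hr_bpm=hr, amplitude=amplitude, apw_normalized=apw)


def spectrum(series: np.ndarray, dt: float, f_C: float,
             n_harmonics: int = 10, delta_f: float | None = None) -> SpectrumReport:
    """Magnitude spectrum over an integer number of fundamental periods.

    The window is trimmed internally to a whole number of periods of
    ``f_C`` so the harmonics land on exact DFT bins (rectangular window).
    ``harmonic_band_energy_fraction`` is the share of total (non-DC) signal
    energy lying within +-delta_f of the harmonics k*f_C, k = 1..n_harmonics;
    ``low_freq_peak`` is the largest spectral line strictly below f_C/2.
    """
    x = np.asarray(series, dtype=float)
    n_per = int(round(1.0 / (f_C * dt)))
    n_cycles = x.size // n_per
    if n_cycles < 2:
        raise DomainError("window must span at least 2 fundamental periods")
    if delta_f is None:
        delta_f = 0.3 * f_C
    n = n_cycles * n_per
    x = x[:n]
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=dt)
    mag = np.abs(X) / n
    mag[1:] *= 2.0
    if n % 2 == 0:
        mag[-1] /= 2.0  # Nyquist bin is not doubled
    # per-bin energy such that energy.sum() == sum(x**2) (Parseval)
    energy = np.abs(X) ** 2 / n
    energy[1:] *= 2.0
    if n % 2 == 0:
        energy[-1] /= 2.0

    total = energy[1:].sum()  # exclude DC: the mean is not distortion
    in_band = np.zeros(freqs.size, dtype=bool)
    for k in range(1, n_harmonics + 1):
        in_band |= np.abs(freqs - k * f_C) <= delta_f + 1e-12
    frac = float(energy[1:][in_band[1:]].sum() / total) if total > 0 else 0.0

    low = (freqs > 0) & (freqs < 0.5 * f_C)
    if np.any(low):
        i = np.flatnonzero(low)[np.argmax(mag[low])]
        low_peak = (float(freqs[i]), float(mag[i]))
    else:
        low_peak = (math.nan, 0.0)
    return SpectrumReport(frequency_hz=freqs, magnitude=mag, energy=energy,
                          harmonic_band_energy_fraction=frac,
                          low_freq_peak=low_peak)


def cse_baseline(series: np.ndarray, dt: float, onsets: np.ndarray,
                 t0: float = 0.0) -> np.ndarray:
    """Cubic-spline baseline estimate anchored at cycle onsets.

    A natural cubic spline through (onset_i, series(onset_i)) evaluated on
    the full grid, held constant beyond the first/last onset.  This is the
    standard spline-through-feet drift estimator; on TVSP-distorted signals
    it systematically differs from the true measured drift because both
    drift and TVSP shift the feet.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 4:
        raise DomainError("cubic-spline baseline needs at least 4 onsets")
    values = _value_at(np.asarray(series, dtype=float), dt, t0, onsets)
    spline = CubicSpline(onsets, values, bc_type="natural")
    t = t0 + dt * np.arange(len(series))
    out = spline(np.clip(t, onsets[0], onsets[-1]))
    return out


def ma_metrics(
    measured: MeasuredSignals,
    metrics_free: CycleMetrics,
    metrics_meas: CycleMetrics,
    true_hr_bpm: float,
    transient: float = 2.0,
) -> dict:
    """Summary metrics of motion-artifact-induced distortion.

    ``metrics_free``/``metrics_meas`` are the per-cycle metrics of the
    MA-free and distorted signals of the same run.  Heart-rate deviation is
    taken against the true rate; amplitudes are compared cycle by cycle over
    the overlap.  Returns a plain dict ready for JSON export.
    """
    s = measured.series
    grid = measured.grid
    mask = grid.mask_after(grid.t0 + transient)
    z_b = s["z_b"][mask]
    if measured.mode == "1dof":
        drift_meas = (s["x_b"] - s["z_b"])[mask]
        x_C, x_TVSP = s["x_C"][mask], s["x_TVSP"][mask]
    else:
        drift_meas = (s["x2b"] - s["z_b"])[mask]
        x_C, x_TVSP = s["x2C"][mask], s["x2TVSP"][mask]

    max_zb = float(np.max(np.abs(z_b))) if z_b.size else 0.0
    if max_zb > 0:
        attenuation = float(np.max(np.abs(drift_meas)) / max_zb)
        corr = float(np.corrcoef(drift_meas, z_b)[0, 1])
        corr_defined = True
    else:
        attenuation, corr, corr_defined = 0.0, 0.0, False

    hr_dev = np.abs(metrics_meas.hr_bpm - true_hr_bpm) / true_hr_bpm
    n = min(metrics_free.amplitude.size, metrics_meas.amplitude.size)
    if n < metrics_free.amplitude.size or n < metrics_meas.amplitude.size:
        import logging
        logging.getLogger(__name__).warning(
            "cycle-count mismatch (%d vs %d); aligned on overlap",
            metrics_free.amplitude.size, metrics_meas.amplitude.size)
    amp_change = np.abs(metrics_meas.amplitude[:n] - metrics_free.amplitude[:n]) \
        / metrics_free.amplitude[:n]

    rms_c = float(np.sqrt(np.mean(x_C**2)))
    tvsp_ratio = float(np.sqrt(np.mean(x_TVSP**2)) / rms_c) if rms_c > 0 else 0.0
    return {
        "baseline_attenuation": attenuation,
        "drift_trend_correlation": corr,
        "drift_trend_correlation_defined": corr_defined,
        "hr_max_rel_dev_pct": float(100.0 * hr_dev.max()) if hr_dev.size else 0.0,
        "amp_max_rel_change_pct": float(100.0 * amp_change.max()) if n else 0.0,
        "tvsp_rms_ratio": tvsp_ratio,
    }
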