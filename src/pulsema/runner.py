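"""Configuration-driven orchestration of complete simulation scenarios.

A :class:`Scenario` bundles everything one forward run needs — pulse,
stack ratios, substrate motion, coupling law, grid and analysis options —
and :func:`run_scenario` executes the full pipeline: closed-form drift,
parameter modulation, time-varying integration, signal composition,
equivalent forces with round-trip verification, and waveform analytics.
Scenarios are plain data and can be read from YAML/JSON config files;
presets encode the canonical study conditions.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .dynamics import (
    MeasuredSignals,
    TvspCoupling,
    TvspSeries,
    compose_measured,
    simulate_baseline,
    simulate_tvsp,
    tvsp_from_drift,
)
from .errors import ConfigurationError
from .forces import ForceSet, force_tvsp, roundtrip_check
from .signals import (
    HarmonicPulse,
    MotionArtifactSignal,
    StackParams,
    TimeGrid,
    build_params,
    canonical_ma,
    canonical_pulse,
)
from .waveform import (
    CycleMetrics,
    cse_baseline,
    detect_cycles,
    hr_and_amplitude,
    ma_metrics,
    spectrum,
)

__all__ = ["Scenario", "ScenarioResult", "run_scenario", "stiffness_sweep",
           "load_scenario", "PRESETS", "preset"]

ModeName = Literal["wall_displacement_1dof", "pulsatile_pressure_2dof"]


@dataclass(frozen=True)
class StackRatios:
    """Dimensionless stack specification (resolved to StackParams at run time)."""

    kA: float = 1.0
    k0_over_kA: float = 1.0 / 6.0
    r0: float = 2.0
    zeta0: float = 1.5
    ks_over_k0: float = 6.0
    zeta_s: float = 1.5


@dataclass(frozen=True)
class Scenario:
    name: str
    mode: ModeName
    pulse: HarmonicPulse
    stack: StackRatios
    ma: MotionArtifactSignal
    coupling: TvspCoupling
    grid: TimeGrid = TimeGrid()
    transient: float = 2.0
    n_harmonics_analysis: int = 10
    delta_f: float | None = None
    r_total_variant: Literal["series", "parallel"] = "series"
    solver_opts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("wall_displacement_1dof", "pulsatile_pressure_2dof"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        want = ("wall_displacement" if self.mode == "wall_displacement_1dof"
                else "pulsatile_pressure")
        if self.pulse.mode != want:
            raise ConfigurationError(
                f"scenario mode {self.mode} requires a {want} pulse, got "
                f"{self.pulse.mode}")
        if self.transient < 0 or self.transient >= self.grid.t_end - self.grid.t0:
            raise ConfigurationError("transient must lie inside the grid span")

    @property
    def dof_mode(self) -> Literal["1dof", "2dof"]:
        return "1dof" if self.mode == "wall_displacement_1dof" else "2dof"

    def build_stack(self) -> StackParams:
        return build_params(
            kA=self.stack.kA, k0_over_kA=self.stack.k0_over_kA,
            r0=self.stack.r0, zeta0=self.stack.zeta0,
            ks_over_k0=self.stack.ks_over_k0, zeta_s=self.stack.zeta_s,
            heart_rate_hz=self.pulse.fundamental_hz,
            two_dof=(self.dof_mode == "2dof"),
        )


@dataclass
class ScenarioResult:
    scenario: Scenario
    params: StackParams
    measured: MeasuredSignals
    tvsp: TvspSeries
    forces: ForceSet
    roundtrip: dict
    metrics: dict
    metrics_free: CycleMetrics
    metrics_meas: CycleMetrics
    cse: np.ndarray
    spectra: dict = field(default_factory=dict)


def preset(name: str) -> Scenario:
    """Return a fresh copy of a named preset scenario."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _canonical_1dof() -> Scenario:
    return Scenario(
        name="canonical_1dof",
        mode="wall_displacement_1dof",
        pulse=canonical_pulse("wall_displacement"),
        stack=StackRatios(),
        ma=canonical_ma(),
        coupling=TvspCoupling(),
    )


def _canonical_2dof() -> Scenario:
    return Scenario(
        name="canonical_2dof",
        mode="pulsatile_pressure_2dof",
        pulse=canonical_pulse("pulsatile_pressure"),
        stack=StackRatios(),
        ma=canonical_ma(),
        coupling=TvspCoupling(),
    )


PRESETS = {
    "canonical_1dof": _canonical_1dof,
    "canonical_2dof": _canonical_2dof,
}


def run_scenario(scenario: Scenario, outdir: str | Path | None = None) -> ScenarioResult:
    """Execute the full pipeline for one scenario.

    Stages: closed-form drift -> parameter modulation -> time-varying
    integration -> signal composition -> equivalent forces -> round-trip
    verification -> cycle/spectral analytics.  If ``outdir`` is given, all
    series, spectra and metrics are written there (CSV/JSON plus a manifest);
    on error partial outputs are removed.
    """
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = _run(scenario)
        if outdir is not None:
            _write_outputs(result, outdir)
        return result
    except Exception:
        if outdir is not None:
            shutil.rmtree(outdir, ignore_errors=True)
        raise


def _run(scenario: Scenario) -> ScenarioResult:
    params = scenario.build_stack()
    grid = scenario.grid
    mode = scenario.dof_mode
    window = grid.mask_after(grid.t0 + scenario.transient)

    baseline = simulate_baseline(params, scenario.ma, grid, mode)
    tvsp = tvsp_from_drift(scenario.coupling, baseline["drift"], params, grid,
                           window=window,
                           r_total_variant=scenario.r_total_variant)
    solution = simulate_tvsp(params, scenario.pulse, tvsp, grid,
                             solver_opts=scenario.solver_opts)
    measured = compose_measured(params, scenario.pulse, scenario.ma, grid,
                                baseline, solution)
    forces = force_tvsp(measured, params)
    rt = roundtrip_check(forces, measured, params, transient=scenario.transient,
                         solver_opts=scenario.solver_opts)

    f_C = scenario.pulse.fundamental_hz
    dt = grid.dt
    i0 = int(np.argmax(window))
    t_start = grid.t[i0]
    free_name = "x_C" if mode == "1dof" else "x2C"
    free_series = measured[free_name][window]
    meas_name = "x_M" if mode == "1dof" else "x2M"
    meas_series = measured[meas_name][window]

    onsets_free = detect_cycles(free_series, dt, f_C, t0=t_start)
    onsets_meas = detect_cycles(meas_series, dt, f_C, t0=t_start)
    metrics_free = hr_and_amplitude(free_series, dt, onsets_free, t0=t_start)
    metrics_meas = hr_and_amplitude(meas_series, dt, onsets_meas, t0=t_start)
    metrics = ma_metrics(measured, metrics_free, metrics_meas,
                         true_hr_bpm=60.0 * f_C, transient=scenario.transient)

    tactile = measured["x_tactile"][window]
    onsets_tac = detect_cycles(tactile, dt, f_C, t0=t_start)
    cse = cse_baseline(tactile, dt, onsets_tac, t0=t_start)

    delta_f = scenario.delta_f if scenario.delta_f is not None else 0.3 * f_C
    tvsp_name = "x_TVSP" if mode == "1dof" else "x2TVSP"
    spec_tvsp = spectrum(measured[tvsp_name][window], dt, f_C,
                         n_harmonics=scenario.n_harmonics_analysis,
                         delta_f=delta_f)
    drift_meas = (measured["x_b"] if mode == "1dof" else measured["x2b"]) \
        - measured["z_b"]
    spec_drift = spectrum(drift_meas[window], dt, f_C,
                          n_harmonics=scenario.n_harmonics_analysis,
                          delta_f=delta_f)
    metrics.update({
        "tvsp_harmonic_band_energy_fraction":
            spec_tvsp.harmonic_band_energy_fraction,
        "drift_low_freq_peak_hz": spec_drift.low_freq_peak[0],
        "roundtrip_residual_rel_l2": rt["residual_rel_l2"],
    })

    spec_free = spectrum(free_series, dt, f_C,
                         n_harmonics=scenario.n_harmonics_analysis,
                         delta_f=delta_f)
    return ScenarioResult(
        scenario=scenario, params=params, measured=measured, tvsp=tvsp,
        forces=forces, roundtrip=rt, metrics=metrics,
        metrics_free=metrics_free, metrics_meas=metrics_meas, cse=cse,
        spectra={tvsp_name: spec_tvsp, "measured_drift": spec_drift,
                 free_name: spec_free},
    )


def stiffness_sweep(base: Scenario, ks_over_k0_values: list[float]) -> pd.DataFrame:
    """Rerun a scenario across sensor stiffness ratios and compare outcomes.

    For each value reports the MA-free measured pulse amplitude, the L2
    deviation of the measured normalized APW from the true pulse APW, the
    TVSP distortion ratio and the baseline attenuation.  Softer sensors
    (smaller ks/k0) read a larger signal whose shape tracks the true pulse
    more closely, at the price of more TVSP distortion.
    """
    if len(ks_over_k0_values) < 2:
        raise ConfigurationError("sweep needs at least 2 stiffness values")
    rows = []
    for v in ks_over_k0_values:
        sc = replace(base, name=f"{base.name}_ks{v:g}",
                     stack=replace(base.stack, ks_over_k0=float(v)))
        res = run_scenario(sc)
        grid, dt = sc.grid, sc.grid.dt
        window = grid.mask_after(grid.t0 + sc.transient)
        t_start = grid.t[int(np.argmax(window))]
        f_C = sc.pulse.fundamental_hz
        free_name = "x_C" if sc.dof_mode == "1dof" else "x2C"
        free = res.measured[free_name][window]
        onsets = detect_cycles(free, dt, f_C, t0=t_start)
        m_free = hr_and_amplitude(free, dt, onsets, t0=t_start)
        # true pulse waveform on the same window, same onset convention
        from .signals import eval_pulse
        true = eval_pulse(sc.pulse, grid)[window]
        onsets_true = detect_cycles(true, dt, f_C, t0=t_start)
        m_true = hr_and_amplitude(true, dt, onsets_true, t0=t_start)
        n = min(m_free.apw_normalized.shape[0], m_true.apw_normalized.shape[0])
        apw_dev = float(np.mean(np.linalg.norm(
            m_free.apw_normalized[:n] - m_true.apw_normalized[:n], axis=1)
            / np.linalg.norm(m_true.apw_normalized[:n], axis=1)))
        tvsp_name = "x_TVSP" if sc.dof_mode == "1dof" else "x2TVSP"
        tvsp_rms = float(np.sqrt(np.mean(res.measured[tvsp_name][window] ** 2)))
        rows.append({
            "ks_over_k0": float(v),
            "pulse_amplitude_free": float(np.mean(m_free.amplitude)),
            "apw_l2_deviation": apw_dev,
            "tvsp_rms": tvsp_rms,
            "tvsp_rms_ratio": res.metrics["tvsp_rms_ratio"],
            "baseline_attenuation": res.metrics["baseline_attenuation"],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration I/O

def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(cfg)


def scenario_from_dict(cfg: dict) -> Scenario:
    if "preset" in cfg:
        base = preset(cfg["preset"])
        overrides = {k: v for k, v in cfg.items() if k != "preset"}
        return _apply_overrides(base, overrides)
    return _apply_overrides(None, cfg)


def _apply_overrides(base: Scenario | None, cfg: dict) -> Scenario:
    def get(block: str) -> dict:
        return dict(cfg.get(block) or {})

    mode = cfg.get("mode", base.mode if base else "wall_displacement_1dof")
    pulse_cfg = get("pulse")
    if pulse_cfg or base is None:
        pulse_mode = ("wall_displacement" if mode == "wall_displacement_1dof"
                      else "pulsatile_pressure")
        if "harmonics" in pulse_cfg:
            harmonics = tuple((float(a), float(p)) for a, p in pulse_cfg["harmonics"])
            pulse = HarmonicPulse(
                fundamental_hz=float(pulse_cfg.get("fundamental_hz", 1.0)),
                harmonics=harmonics, mode=pulse_mode,
                force_scale=float(pulse_cfg.get("force_scale", 1.0)))
        else:
            pulse = canonical_pulse(
                pulse_mode,
                fundamental_hz=float(pulse_cfg.get("fundamental_hz", 1.0)),
                amplitude=float(pulse_cfg.get("amplitude", 1.0)))
    else:
        pulse = base.pulse

    stack = replace(base.stack if base else StackRatios(), **get("stack"))
    ma_cfg = get("ma")
    if "components" in ma_cfg:
        ma = MotionArtifactSignal(components=tuple(
            (float(b), float(f), float(p)) for b, f, p in ma_cfg["components"]))
    elif base is not None and not ma_cfg:
        ma = base.ma
    else:
        ma = canonical_ma(amplitude=float(ma_cfg.get("amplitude", 1.0)))
    coupling = replace(base.coupling if base else TvspCoupling(), **get("coupling"))
    grid = replace(base.grid if base else TimeGrid(), **get("grid"))

    if "solver" in cfg and "solver_opts" not in cfg:
        cfg = {**cfg, "solver_opts": cfg["solver"]}
    extra = {}
    for key in ("transient", "n_harmonics_analysis", "delta_f",
                "r_total_variant", "solver_opts"):
        if key in cfg:
            extra[key] = cfg[key]
        elif base is not None:
            extra[key] = getattr(base, key)
    return Scenario(
        name=cfg.get("name", base.name if base else "scenario"),
        mode=mode, pulse=pulse, stack=stack, ma=ma, coupling=coupling,
        grid=grid, **extra,
    )


# ---------------------------------------------------------------------------
# output writing

def _series_frame(result: ScenarioResult) -> pd.DataFrame:
    data = {"t": result.measured.grid.t}
    data.update(result.measured.series)
    tvsp = result.tvsp
    data.update({"tvsp_m": tvsp.m, "tvsp_c": tvsp.c, "tvsp_k": tvsp.k,
                 "r": tvsp.r, "zeta": tvsp.zeta, "r_total": tvsp.r_total})
    data.update(result.forces.series)
    if result.measured.mode == "1dof":
        data["x_b_minus_z_b"] = result.measured["x_b"] - result.measured["z_b"]
    else:
        data["x2b_minus_z_b"] = result.measured["x2b"] - result.measured["z_b"]
        data["x2b_minus_x1b"] = result.measured["x2b"] - result.measured["x1b"]
    return pd.DataFrame(data)


def _write_outputs(result: ScenarioResult, outdir: Path) -> None:
    fmt = "%.9g"
    df = _series_frame(result)
    df.to_csv(outdir / "series.csv", index=False, float_format=fmt)

    cyc = pd.DataFrame({
        "cycle_index": np.arange(result.metrics_meas.hr_bpm.size),
        "onset_s": result.metrics_meas.onset_times[:-1],
        "hr_bpm": result.metrics_meas.hr_bpm,
        "amplitude": result.metrics_meas.amplitude,
    })
    cyc.to_csv(outdir / "cycles.csv", index=False, float_format=fmt)

    if result.spectra:
        cols = {"frequency_hz": next(iter(result.spectra.values())).frequency_hz}
        cols.update({name: rep.magnitude for name, rep in result.spectra.items()})
        pd.DataFrame(cols).to_csv(outdir / "spectra.csv", index=False,
                                  float_format=fmt)

    (outdir / "metrics.json").write_text(
        json.dumps(result.metrics, indent=2, sort_keys=True))
    (outdir / "roundtrip.json").write_text(
        json.dumps(result.roundtrip, indent=2, sort_keys=True))

    manifest = {
        "package_version": _pkg_version,
        "scenario": _scenario_dict(result.scenario),
        "solver_defaults": {"rtol": 1e-8, "atol": 1e-10, "method": "RK45"},
    }
    (outdir / "manifest.txt").write_text(
        yaml.safe_dump(manifest, sort_keys=True))


def _scenario_dict(sc: Scenario) -> dict:
    d = asdict(sc)
    d["pulse"]["harmonics"] = [list(h) for h in sc.pulse.harmonics]
    d["ma"]["components"] = [list(c) for c in sc.ma.components]
    return d
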