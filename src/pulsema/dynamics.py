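"""Baseline drift, time-varying system parameters (TVSP) and their dynamics.

Substrate motion z_b(t) does two things at once: it drives a slow drift of
the stack mass (baseline drift), and — because the drift strains the tissue
and the contact — it modulates the stack's lumped mass, damping and
stiffness.  The modulated system filters the true pulse differently from the
nominal one, producing a distortion x_TVSP = x_M - x_C that is broadband and
locked to the pulse harmonics, unlike the low-frequency drift itself.

Drift is obtained in closed form (the inputs are finite sums of sinusoids,
so the steady-state harmonic solution is exact); the modulated equations of
motion are integrated numerically with an adaptive Runge-Kutta scheme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert, savgol_filter

from .errors import ConfigurationError, DomainError
from .lti import (
    gain_baseline_1dof,
    gains_2dof_baseline,
    harmonic_series,
    measured_free,
)
from .signals import (
    HarmonicPulse,
    MotionArtifactSignal,
    StackParams,
    TimeGrid,
    eval_ma,
    eval_pulse,
    pulse_force,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TvspCoupling",
    "TvspSeries",
    "MeasuredSignals",
    "Envelope",
    "simulate_baseline",
    "tvsp_from_drift",
    "simulate_tvsp",
    "compose_measured",
    "instantaneous_envelope",
]

#: Hard floor on the modulated parameters, as a fraction of nominal.
CLAMP_FLOOR = 0.05

#: Default solver settings for the time-varying integration.
DEFAULT_SOLVER_OPTS = {"rtol": 1e-8, "atol": 1e-10, "method": "RK45"}

Mode = Literal["1dof", "2dof"]


@dataclass(frozen=True)
class TvspCoupling:
    """Linear law mapping drift displacement to parameter modulation.

    Each lumped parameter is modulated in proportion to the drift,
    ``m(t) = kappa_m * m0 * drift(t) / x_ref`` (and likewise for c, k), so a
    ``kappa`` of 0.05 means a 5% peak modulation when the drift reaches the
    reference displacement ``x_ref``.  With ``x_ref = None`` the reference is
    taken as max |drift| over the analysis window, making kappa the actual
    peak fractional modulation of the run.
    """

    kappa_m: float = 0.05
    kappa_c: float = 0.05
    kappa_k: float = 0.05
    x_ref: float | None = None

    def __post_init__(self) -> None:
        for name in ("kappa_m", "kappa_c", "kappa_k"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.x_ref is not None and self.x_ref <= 0:
            raise DomainError("x_ref must be positive when given")

    @property
    def is_zero(self) -> bool:
        return self.kappa_m == self.kappa_c == self.kappa_k == 0.0


@dataclass
class TvspSeries:
    """Time series of the parameter modulations and derived ratios.

    ``m``, ``c``, ``k`` are the additive modulations (so the instantaneous
    parameters are ``m0 + m(t)`` etc.).  ``r`` and ``zeta`` are the
    instantaneous frequency ratio and damping factor of the stack alone;
    ``r_total`` additionally accounts for the sensor spring (and, in the
    2DOF configuration, the arterial spring).
    """

    grid: TimeGrid
    m: np.ndarray
    c: np.ndarray
    k: np.ndarray
    r: np.ndarray
    zeta: np.ndarray
    r_total: np.ndarray
    x_ref: float
    clamped: bool = False


@dataclass
class MeasuredSignals:
    """All aligned series of one forward run, plus derivative channels.

    ``series`` maps signal names (x_C, x_b, x_M, x_TVSP, x_tactile,
    x_tactile_MA, z_b in the 1DOF configuration; x1C/x2C, x1b/x2b, x1M/x2M,
    x1TVSP/x2TVSP, x_tactile, x_wall, x_tactile_MA, x_wall_MA, z_b in 2DOF)
    to arrays on ``grid``.  ``derivatives`` holds solver-grade first/second
    derivatives and the analytic input derivatives needed by the
    equivalent-force operations.
    """

    mode: Mode
    grid: TimeGrid
    series: dict[str, np.ndarray]
    derivatives: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


@dataclass
class Envelope:
    """Instantaneous amplitude/phase/frequency from the analytic signal."""

    amplitude: np.ndarray
    phase: np.ndarray
    omega: np.ndarray
    edge_unreliable: np.ndarray  # boolean mask; True near the grid edges


def _ma_terms(ma: MotionArtifactSignal) -> list[tuple[float, complex]]:
    return [(2.0 * math.pi * f, b * np.exp(1j * phi)) for b, f, phi in ma.components]


def simulate_baseline(
    params: StackParams,
    ma: MotionArtifactSignal,
    grid: TimeGrid,
    mode: Mode,
    method: Literal["closed_form", "ode"] = "closed_form",
) -> dict[str, np.ndarray]:
    """Drift displacement(s) caused by substrate motion on the nominal stack.

    Returns ``{"x_b": ..., "drift": ...}`` (1DOF, drift == x_b) or
    ``{"x1b": ..., "x2b": ..., "drift": ...}`` (2DOF, drift == x2b - x1b,
    the relative displacement that strains the stack).  The default route is
    the exact steady-state harmonic solution; ``method="ode"`` integrates
    the same equations in time for cross-validation.
    """
    if mode == "2dof" and params.kA is None:
        raise ConfigurationError("2dof baseline requires kA")
    if mode not in ("1dof", "2dof"):
        raise ConfigurationError(f"unknown mode {mode!r}")

    if method == "ode":
        return _simulate_baseline_ode(params, ma, grid, mode)

    terms = _ma_terms(ma)
    if mode == "1dof":
        xb_terms = [(w, gain_baseline_1dof(params, w) * c) for w, c in terms]
        x_b = harmonic_series(grid, xb_terms)
        return {"x_b": x_b, "drift": x_b,
                "x_b_dot": harmonic_series(grid, xb_terms, deriv=1)}
    x1_terms, x2_terms = [], []
    for w, c in terms:
        g1, g2 = gains_2dof_baseline(params, w)
        x1_terms.append((w, g1 * c))
        x2_terms.append((w, g2 * c))
    x1b = harmonic_series(grid, x1_terms)
    x2b = harmonic_series(grid, x2_terms)
    return {
        "x1b": x1b, "x2b": x2b, "drift": x2b - x1b,
        "x1b_dot": harmonic_series(grid, x1_terms, deriv=1),
        "x2b_dot": harmonic_series(grid, x2_terms, deriv=1),
    }


def _simulate_baseline_ode(
    params: StackParams, ma: MotionArtifactSignal, grid: TimeGrid, mode: Mode,
) -> dict[str, np.ndarray]:
    """Time-domain route for the drift equations (cross-validation only)."""
    p = params
    zb = lambda t: sum(b * math.cos(2 * math.pi * f * t + phi)
                       for b, f, phi in ma.components)
    zb_dot = lambda t: sum(-b * 2 * math.pi * f * math.sin(2 * math.pi * f * t + phi)
                           for b, f, phi in ma.components)
    closed = simulate_baseline(p, ma, grid, mode, method="closed_form")
    if mode == "1dof":
        def rhs(t, y):
            x, v = y
            f = p.ks * zb(t) + p.cs * zb_dot(t)
            return [v, (f - (p.c0 + p.cs) * v - (p.k0 + p.ks) * x) / p.m0]
        y0 = [closed["x_b"][0], closed["x_b_dot"][0]]
        sol = solve_ivp(rhs, (grid.t0, grid.t_end), y0, t_eval=grid.t,
                        **DEFAULT_SOLVER_OPTS)
        if not sol.success:
            raise RuntimeError(f"baseline ODE failed: {sol.message}")
        x_b = sol.y[0]
        return {"x_b": x_b, "drift": x_b, "x_b_dot": sol.y[1]}

    kA = p.kA
    def rhs(t, y):
        x1, x2, v2 = y
        # Massless wall coordinate: c0 x1' = c0 x2' - (kA+k0) x1 + k0 x2
        v1 = v2 + (-(kA + p.k0) * x1 + p.k0 * x2) / p.c0
        f = p.ks * zb(t) + p.cs * zb_dot(t)
        a2 = (f + p.k0 * x1 + p.c0 * v1
              - (p.k0 + p.ks) * x2 - (p.c0 + p.cs) * v2) / p.m0
        return [v1, v2, a2]
    y0 = [closed["x1b"][0], closed["x2b"][0], closed["x2b_dot"][0]]
    sol = solve_ivp(rhs, (grid.t0, grid.t_end), y0, t_eval=grid.t,
                    **DEFAULT_SOLVER_OPTS)
    if not sol.success:
        raise RuntimeError(f"baseline ODE failed: {sol.message}")
    x1b, x2b = sol.y[0], sol.y[1]
    return {"x1b": x1b, "x2b": x2b, "drift": x2b - x1b,
            "x2b_dot": sol.y[2]}


RTotalVariant = Literal["series", "parallel"]


def tvsp_from_drift(
    coupling: TvspCoupling,
    drift: np.ndarray,
    params: StackParams,
    grid: TimeGrid,
    window: np.ndarray | None = None,
    r_total_variant: RTotalVariant = "series",
) -> TvspSeries:
    """Map a drift series to the time-varying parameter modulations.

    ``window`` (boolean mask) restricts the default ``x_ref`` normalization
    to the analysis window.  ``r_total_variant`` selects how the arterial
    spring enters the total frequency ratio in the 2DOF configuration:
    ``series`` puts kA in series with the stack spring as seen from the mass,
    ``parallel`` simply adds it.
    """
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (grid.n,):
        raise DomainError("drift must live on the working grid")
    x_ref = coupling.x_ref
    if x_ref is None:
        sel = drift if window is None else drift[window]
        x_ref = float(np.max(np.abs(sel))) if sel.size else 0.0
    if x_ref == 0.0:
        if coupling.is_zero:
            x_ref = 1.0  # irrelevant: all modulations are zero
        else:
            raise DomainError(
                "x_ref is zero (no drift) but coupling is nonzero; supply "
                "x_ref explicitly or use zero coupling"
            )
    u = drift / x_ref
    m = coupling.kappa_m * params.m0 * u
    c = coupling.kappa_c * params.c0 * u
    k = coupling.kappa_k * params.k0 * u

    clamped = False
    for mod, nominal in ((m, params.m0), (c, params.c0), (k, params.k0)):
        floor = (CLAMP_FLOOR - 1.0) * nominal  # nominal + mod >= CLAMP_FLOOR*nominal
        if np.any(mod < floor):
            np.clip(mod, floor, None, out=mod)
            clamped = True
    if clamped:
        logger.warning(
            "TVSP modulation clamped at %.0f%% of nominal parameters",
            100 * CLAMP_FLOOR,
        )

    m_t, c_t, k_t = params.m0 + m, params.c0 + c, params.k0 + k
    r = np.sqrt(k_t / m_t) / params.omega_C
    zeta = c_t / (2.0 * np.sqrt(k_t * m_t))
    if params.kA is None:
        k_eff = k_t + params.ks
    elif r_total_variant == "series":
        k_eff = params.ks + k_t * params.kA / (k_t + params.kA)
    elif r_total_variant == "parallel":
        k_eff = k_t + params.ks + params.kA
    else:
        raise ConfigurationError(f"unknown r_total variant {r_total_variant!r}")
    r_total = np.sqrt(k_eff / m_t) / params.omega_C
    return TvspSeries(grid=grid, m=m, c=c, k=k, r=r, zeta=zeta,
                      r_total=r_total, x_ref=x_ref, clamped=clamped)


def _tvsp_interpolants(tvsp: TvspSeries):
    t = tvsp.grid.t
    return (CubicSpline(t, tvsp.m), CubicSpline(t, tvsp.c), CubicSpline(t, tvsp.k))


def simulate_tvsp(
    params: StackParams,
    pulse: HarmonicPulse,
    tvsp: TvspSeries,
    grid: TimeGrid,
    solver_opts: dict | None = None,
) -> dict[str, np.ndarray]:
    """Integrate the modulated equations of motion driven by the true pulse.

    1DOF (wall displacement y as base excitation):
        (m0+m) x'' + (c0+c+cs) x' + (k0+k+ks) x = (k0+k) y + (c0+c) y'

    2DOF (pressure force F on the arterial wall):
        (kA+k0+k) x1 - (k0+k) x2 + (c0+c)(x1' - x2') = F
        -(k0+k) x1 - (c0+c) x1' + (m0+m) x2'' + (k0+k+ks) x2
            + (c0+c+cs) x2' = 0
    where x1' is eliminated algebraically from the massless wall equation.

    Initial conditions are the MA-free closed-form steady state at t0, so
    with zero coupling the solution reproduces the closed-form response at
    solver accuracy.  Returns the displacement series along with solver-grade
    velocity and acceleration channels (suffix ``_dot``, ``_ddot``).
    """
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    if opts.get("rtol", 1) <= 0 or opts.get("atol", 1) <= 0:
        raise DomainError("solver tolerances must be positive")
    if tvsp.grid != grid:
        raise DomainError("tvsp series must live on the working grid")

    m_of, c_of, k_of = _tvsp_interpolants(tvsp)
    p = params

    if pulse.mode == "wall_displacement":
        if p.kA is not None:
            raise ConfigurationError("wall_displacement pulse with 2DOF params")
        free = measured_free(p, pulse, grid)
        free_dot = measured_free(p, pulse, grid, deriv=1)
        y = lambda t: _eval_harmonics(pulse, t, 0)
        y_dot = lambda t: _eval_harmonics(pulse, t, 1)

        def rhs(t, state):
            x, v = state
            mt, ct, kt = m_of(t), c_of(t), k_of(t)
            f = (p.k0 + kt) * y(t) + (p.c0 + ct) * y_dot(t)
            a = (f - (p.c0 + ct + p.cs) * v - (p.k0 + kt + p.ks) * x) / (p.m0 + mt)
            return [v, a]

        y0 = [free["x_C"][0], free_dot["x_C"][0]]
        sol = solve_ivp(rhs, (grid.t0, grid.t_end), y0, t_eval=grid.t, **opts)
        if not sol.success:
            raise RuntimeError(f"TVSP integration failed: {sol.message}")
        x_M, v_M = sol.y
        a_M = np.array([rhs(t, (x, v))[1] for t, x, v in zip(grid.t, x_M, v_M)])
        return {"x_M": x_M, "x_M_dot": v_M, "x_M_ddot": a_M}

    # pulsatile pressure, 2DOF
    if p.kA is None:
        raise ConfigurationError("pulsatile_pressure pulse requires kA")
    free = measured_free(p, pulse, grid)
    free_dot = measured_free(p, pulse, grid, deriv=1)
    F = lambda t: pulse.force_scale * _eval_harmonics(pulse, t, 0)
    kA = p.kA

    def wall_velocity(t, x1, x2, v2, ct, kt):
        # from the massless wall equation: (c0+c)(x1'-x2') = F - (kA+k0+k) x1 + (k0+k) x2
        return v2 + (F(t) - (kA + p.k0 + kt) * x1 + (p.k0 + kt) * x2) / (p.c0 + ct)

    def rhs(t, state):
        x1, x2, v2 = state
        mt, ct, kt = m_of(t), c_of(t), k_of(t)
        v1 = wall_velocity(t, x1, x2, v2, ct, kt)
        a2 = ((p.k0 + kt) * x1 + (p.c0 + ct) * v1
              - (p.k0 + kt + p.ks) * x2 - (p.c0 + ct + p.cs) * v2) / (p.m0 + mt)
        return [v1, v2, a2]

    y0 = [free["x1C"][0], free["x2C"][0], free_dot["x2C"][0]]
    sol = solve_ivp(rhs, (grid.t0, grid.t_end), y0, t_eval=grid.t, **opts)
    if not sol.success:
        raise RuntimeError(f"TVSP integration failed: {sol.message}")
    x1M, x2M, v2M = sol.y
    v1M = np.empty_like(x1M)
    a2M = np.empty_like(x1M)
    for i, t in enumerate(grid.t):
        _, _, a2 = rhs(t, (x1M[i], x2M[i], v2M[i]))
        v1M[i] = wall_velocity(t, x1M[i], x2M[i], v2M[i], c_of(t), k_of(t))
        a2M[i] = a2
    return {"x1M": x1M, "x2M": x2M, "x1M_dot": v1M, "x2M_dot": v2M,
            "x2M_ddot": a2M}


def _eval_harmonics(pulse: HarmonicPulse, t: float, deriv: int) -> float:
    out = 0.0
    for k, (a, phi) in enumerate(pulse.harmonics, start=1):
        w = k * pulse.omega_fundamental
        out += a * w**deriv * math.cos(w * t + phi + deriv * math.pi / 2.0)
    return out


def compose_measured(
    params: StackParams,
    pulse: HarmonicPulse,
    ma: MotionArtifactSignal,
    grid: TimeGrid,
    baseline: dict[str, np.ndarray],
    tvsp_solution: dict[str, np.ndarray],
) -> MeasuredSignals:
    """Assemble the measured-signal decomposition from the component runs.

    The identities are applied constructively:
    1DOF — x_TVSP = x_M - x_C; x_tactile = x_M + x_b - z_b;
           x_tactile_MA = x_TVSP + x_b - z_b.
    2DOF — per-coordinate analogues, with x_tactile = x2M + x2b - z_b
           (the sensor reads mass-to-substrate distance) and
           x_wall = x1M + x1b.
    """
    z_b = eval_ma(ma, grid)
    zb_dot = eval_ma(ma, grid, deriv=1)
    free = measured_free(params, pulse, grid)
    free_dot = measured_free(params, pulse, grid, deriv=1)

    if pulse.mode == "wall_displacement":
        x_C, x_b, x_M = free["x_C"], baseline["x_b"], tvsp_solution["x_M"]
        x_TVSP = x_M - x_C
        series = {
            "z_b": z_b, "x_C": x_C, "x_b": x_b, "x_M": x_M,
            "x_TVSP": x_TVSP,
            "x_tactile": x_M + x_b - z_b,
            "x_tactile_MA": x_TVSP + x_b - z_b,
        }
        derivs = {
            "y": eval_pulse(pulse, grid), "y_dot": eval_pulse(pulse, grid, deriv=1),
            "z_b_dot": zb_dot,
            "x_C_dot": free_dot["x_C"],
            "x_b_dot": baseline.get("x_b_dot"),
            "x_M_dot": tvsp_solution["x_M_dot"],
            "x_M_ddot": tvsp_solution["x_M_ddot"],
        }
        return MeasuredSignals(mode="1dof", grid=grid, series=series,
                               derivatives=derivs)

    x1C, x2C = free["x1C"], free["x2C"]
    x1b, x2b = baseline["x1b"], baseline["x2b"]
    x1M, x2M = tvsp_solution["x1M"], tvsp_solution["x2M"]
    x1TVSP, x2TVSP = x1M - x1C, x2M - x2C
    series = {
        "z_b": z_b, "x1C": x1C, "x2C": x2C, "x1b": x1b, "x2b": x2b,
        "x1M": x1M, "x2M": x2M, "x1TVSP": x1TVSP, "x2TVSP": x2TVSP,
        "x_tactile": x2M + x2b - z_b,
        "x_wall": x1M + x1b,
        "x_tactile_MA": x2TVSP + x2b - z_b,
        "x_wall_MA": x1TVSP + x1b,
    }
    derivs = {
        "F": pulse_force(pulse, grid),
        "F_dot": pulse_force(pulse, grid, deriv=1),
        "z_b_dot": zb_dot,
        "x1C_dot": free_dot["x1C"], "x2C_dot": free_dot["x2C"],
        "x1b_dot": baseline.get("x1b_dot"), "x2b_dot": baseline.get("x2b_dot"),
        "x1M_dot": tvsp_solution["x1M_dot"], "x2M_dot": tvsp_solution["x2M_dot"],
        "x2M_ddot": tvsp_solution["x2M_ddot"],
    }
    return MeasuredSignals(mode="2dof", grid=grid, series=series,
                           derivatives=derivs)


def instantaneous_envelope(series: np.ndarray, dt: float) -> Envelope:
    """Instantaneous amplitude, phase and frequency via the analytic signal.

    The series is detrended (mean removed), mirror-padded to suppress
    Hilbert-transform edge wrap-around, and the unwrapped phase is smoothed
    with a short Savitzky-Golay window before differentiating; raw
    differentiation of unwrapped phase amplifies noise.  The first and last
    5% of samples are flagged edge-unreliable.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 16:
        raise DomainError("series too short for envelope analysis (< 16 samples)")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise DomainError("constant series has no defined instantaneous phase")
    padded = np.concatenate([x[1:n][::-1], x, x[0:n - 1][::-1]])
    analytic = hilbert(padded)[n - 1: 2 * n - 1]
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    phase_s = savgol_filter(phase, window_length=5, polyorder=2)
    omega = savgol_filter(phase, window_length=5, polyorder=2, deriv=1, delta=dt)
    edge = np.zeros(n, dtype=bool)
    k = max(1, int(round(0.05 * n)))
    edge[:k] = True
    edge[-k:] = True
    return Envelope(amplitude=amp, phase=phase_s, omega=omega, edge_unreliable=edge)
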