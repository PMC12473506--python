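"""Equivalent-force decomposition of motion-artifact distortion.

Instead of modulating the stack parameters, the influence of motion
artifacts can be represented as extra forces acting on the *nominal*
(time-invariant) system: the true pulse contributes F_C (or F in the 2DOF
configuration), the substrate motion contributes through the sensor
spring/damper, and the parameter modulation is replaced by an equivalent
force F_TVSP on the mass (plus a wall force in the 2DOF case).  By
construction, driving the nominal system with the full force set reproduces
the displacements of the modulated system — verified here by round-trip
integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .dynamics import DEFAULT_SOLVER_OPTS, MeasuredSignals, Mode
from .errors import ConfigurationError, DomainError
from .signals import StackParams, TimeGrid

__all__ = [
    "ForceSet",
    "force_from_wall",
    "force_from_substrate",
    "force_tvsp",
    "roundtrip_check",
]


@dataclass
class ForceSet:
    """Equivalent-force series of one run, on the working grid.

    1DOF: F_C (wall), F_b (substrate), F_T (total at the mass), and
    F_TVSP = F_T - F_C.  2DOF: F (pressure force), F_b, F1T/F2T (wall/mass
    totals) and F1TVSP = F1T - F, F2TVSP = F2T.
    """

    mode: Mode
    grid: TimeGrid
    series: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


def _check_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DomainError("series are not on a common grid")


def force_from_wall(y: np.ndarray, y_dot: np.ndarray, params: StackParams) -> np.ndarray:
    """Equivalent force of the arterial-wall motion: F_C = k0 y + c0 y'."""
    _check_grid(y, y_dot)
    return params.k0 * y + params.c0 * y_dot


def force_from_substrate(z_b: np.ndarray, z_b_dot: np.ndarray,
                         params: StackParams) -> np.ndarray:
    """Equivalent force of the substrate motion: F_b = ks z_b + cs z_b'.

    This force represents the *actual* motion-artifact loading of the stack,
    which is much larger than the drift visible in the measured signal.
    """
    _check_grid(z_b, z_b_dot)
    return params.ks * z_b + params.cs * z_b_dot


def force_tvsp(measured: MeasuredSignals, params: StackParams) -> ForceSet:
    """Equivalent forces reproducing the TVSP-distorted displacements.

    Applies the nominal system operator to the modulated solution:
    1DOF — F_T = m0 x_M'' + (c0+cs) x_M' + (k0+ks) x_M, F_TVSP = F_T - F_C.
    2DOF — F1T = (kA+k0) x1M + c0 x1M' - k0 x2M - c0 x2M' (wall) and
    F2T = -k0 x1M - c0 x1M' + m0 x2M'' + (k0+ks) x2M + (c0+cs) x2M' (mass);
    F1TVSP = F1T - F, F2TVSP = F2T.  Derivatives come from the integrator
    state and the evaluated right-hand side, never finite differences.
    """
    p = params
    s, d = measured.series, measured.derivatives
    if measured.mode == "1dof":
        needed = ("x_M_dot", "x_M_ddot", "y", "y_dot", "z_b_dot")
        if any(d.get(k) is None for k in needed):
            raise DomainError(
                "missing derivative channels; rerun the simulation with "
                "state export (compose_measured provides them)"
            )
        F_C = force_from_wall(d["y"], d["y_dot"], p)
        F_b = force_from_substrate(s["z_b"], d["z_b_dot"], p)
        F_T = (p.m0 * d["x_M_ddot"] + (p.c0 + p.cs) * d["x_M_dot"]
               + (p.k0 + p.ks) * s["x_M"])
        return ForceSet(mode="1dof", grid=measured.grid, series={
            "F_C": F_C, "F_b": F_b, "F_T": F_T, "F_TVSP": F_T - F_C,
        })

    if p.kA is None:
        raise ConfigurationError("2dof force decomposition requires kA")
    needed = ("x1M_dot", "x2M_dot", "x2M_ddot", "F", "z_b_dot")
    if any(d.get(k) is None for k in needed):
        raise DomainError(
            "missing derivative channels; rerun the simulation with state "
            "export (compose_measured provides them)"
        )
    F = d["F"]
    F_b = force_from_substrate(s["z_b"], d["z_b_dot"], p)
    F1T = ((p.kA + p.k0) * s["x1M"] + p.c0 * d["x1M_dot"]
           - p.k0 * s["x2M"] - p.c0 * d["x2M_dot"])
    F2T = (-p.k0 * s["x1M"] - p.c0 * d["x1M_dot"] + p.m0 * d["x2M_ddot"]
           + (p.k0 + p.ks) * s["x2M"] + (p.c0 + p.cs) * d["x2M_dot"])
    return ForceSet(mode="2dof", grid=measured.grid, series={
        "F": F, "F_b": F_b, "F1T": F1T, "F2T": F2T,
        "F1TVSP": F1T - F, "F2TVSP": F2T,
    })


def roundtrip_check(
    forces: ForceSet,
    measured: MeasuredSignals,
    params: StackParams,
    transient: float = 2.0,
    threshold: float = 1e-3,
    solver_opts: dict | None = None,
) -> dict:
    """Verify the equivalent-force representation by forward integration.

    1DOF: the nominal system driven by F_C + F_b + F_TVSP must reproduce the
    total mass displacement x_M + x_b.  2DOF: the nominal system driven by
    F1TVSP on the wall and F2TVSP on the mass, with z_b kept as a base input
    at the substrate (the sensor reads a relative displacement, so substrate
    motion cannot be replaced by a mass force), must reproduce
    (x1M + x1b - x1C, x2M + x2b - x2C).

    Returns ``{"mode", "residual_rel_l2", "threshold", "pass"}``; a residual
    above threshold is reported, not raised.
    """
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    p = params
    grid = measured.grid
    t = grid.t
    mask = grid.mask_after(grid.t0 + transient)
    s, d = measured.series, measured.derivatives

    if forces.mode == "1dof":
        f_total = CubicSpline(
            t, forces["F_C"] + forces["F_b"] + forces["F_TVSP"])

        def rhs(tt, state):
            x, v = state
            a = (f_total(tt) - (p.c0 + p.cs) * v - (p.k0 + p.ks) * x) / p.m0
            return [v, a]

        target = s["x_M"] + s["x_b"]
        y0 = [target[0], d["x_M_dot"][0] + d["x_b_dot"][0]]
        sol = solve_ivp(rhs, (grid.t0, grid.t_end), y0, t_eval=t, **opts)
        if not sol.success:
            raise RuntimeError(f"round-trip integration failed: {sol.message}")
        resid = _rel_l2(sol.y[0][mask] - target[mask], target[mask])
    else:
        f1 = CubicSpline(t, forces["F1TVSP"])
        f2 = CubicSpline(t, forces["F2TVSP"])
        fb = CubicSpline(t, forces["F_b"])  # ks z_b + cs z_b': substrate input
        kA = p.kA

        def wall_velocity(tt, x1, x2, v2):
            return v2 + (f1(tt) - (kA + p.k0) * x1 + p.k0 * x2) / p.c0

        def rhs(tt, state):
            x1, x2, v2 = state
            v1 = wall_velocity(tt, x1, x2, v2)
            a2 = (f2(tt) + fb(tt) + p.k0 * x1 + p.c0 * v1
                  - (p.k0 + p.ks) * x2 - (p.c0 + p.cs) * v2) / p.m0
            return [v1, v2, a2]

        target1 = s["x1M"] + s["x1b"] - s["x1C"]
        target2 = s["x2M"] + s["x2b"] - s["x2C"]
        v2_0 = d["x2M_dot"][0] + d["x2b_dot"][0] - d["x2C_dot"][0]
        y0 = [target1[0], target2[0], v2_0]
        sol = solve_ivp(rhs, (grid.t0, grid.t_end), y0, t_eval=t, **opts)
        if not sol.success:
            raise RuntimeError(f"round-trip integration failed: {sol.message}")
        r1 = _rel_l2(sol.y[0][mask] - target1[mask], target1[mask])
        r2 = _rel_l2(sol.y[1][mask] - target2[mask], target2[mask])
        resid = max(r1, r2)

    return {
        "mode": forces.mode,
        "residual_rel_l2": float(resid),
        "threshold": threshold,
        "pass": bool(resid < threshold),
    }


def _rel_l2(err: np.ndarray, ref: np.ndarray) -> float:
    denom = float(np.linalg.norm(ref))
    if denom == 0.0:
        return float(np.linalg.norm(err))
    return float(np.linalg.norm(err)) / denom
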