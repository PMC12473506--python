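"""Closed-form frequency responses of the nominal (time-invariant) stack.

Two configurations are covered.  In the wall-displacement configuration the
stack is a base-excited single-mass system: the arterial wall motion y(t)
drives the mass through (k0, c0) while the sensor substrate holds the other
side through (ks, cs).  In the pulsatile-pressure configuration the arterial
wall is itself a spring kA driven by the pressure force, giving a coupled
two-degree-of-freedom system whose massless wall coordinate is constrained
through c0.

All gains are evaluated per harmonic as complex ratios; real time series are
recovered by applying each gain to the corresponding complex harmonic
amplitude and taking the real part.  omega = 0 is handled as an explicit
real (static) limit to avoid 0*j artifacts.
"""

from __future__ import annotations

import cmath

import numpy as np

from .errors import ConfigurationError, DomainError
from .signals import HarmonicPulse, StackParams, TimeGrid

__all__ = [
    "gain_pulse_1dof",
    "gain_baseline_1dof",
    "gains_2dof_force",
    "gains_2dof_baseline",
    "measured_free",
    "harmonic_series",
]


def _denom_1dof(p: StackParams, omega: float) -> complex:
    return -p.m0 * omega**2 + 1j * omega * (p.c0 + p.cs) + p.k0 + p.ks


def gain_pulse_1dof(params: StackParams, omega: float) -> complex:
    """Transmissibility from wall displacement y to mass displacement x.

    G0(omega) = (k0 + j omega c0) / (k0 + ks - m0 omega^2 + j omega (c0+cs)).
    The static limit is k0/(k0+ks).
    """
    if omega < 0:
        raise DomainError("omega must be non-negative")
    if omega == 0.0:
        return complex(params.k0 / (params.k0 + params.ks))
    return (params.k0 + 1j * omega * params.c0) / _denom_1dof(params, omega)


def gain_baseline_1dof(params: StackParams, omega: float) -> complex:
    """Gain from substrate motion z_b to mass displacement x_b.

    The sensor reads the substrate-to-mass distance, so the gain from z_b to
    the *measured* drift x_b - z_b is this minus one; at low frequency that
    difference is a small negative number — the measured drift is much
    smaller than the substrate motion and moves opposite to it.
    """
    if omega < 0:
        raise DomainError("omega must be non-negative")
    if omega == 0.0:
        return complex(params.ks / (params.k0 + params.ks))
    return (params.ks + 1j * omega * params.cs) / _denom_1dof(params, omega)


def _solve_2dof(params: StackParams, omega: float,
                f_wall: complex, f_mass: complex) -> tuple[complex, complex]:
    """Solve the coupled harmonic equations for (x1, x2) at one frequency.

    Wall:  (kA + k0 + j w c0) x1 - (k0 + j w c0) x2 = f_wall
    Mass:  -(k0 + j w c0) x1 + (k0 + ks - m0 w^2 + j w (c0 + cs)) x2 = f_mass
    """
    if params.kA is None:
        raise ConfigurationError("two-degree-of-freedom response requires kA")
    if omega == 0.0:
        a11 = params.kA + params.k0
        a12 = -params.k0
        a22 = params.k0 + params.ks
    else:
        coup = params.k0 + 1j * omega * params.c0
        a11 = params.kA + coup
        a12 = -coup
        a22 = -params.m0 * omega**2 + params.k0 + params.ks \
            + 1j * omega * (params.c0 + params.cs)
    det = a11 * a22 - a12 * a12
    x1 = (a22 * f_wall - a12 * f_mass) / det
    x2 = (a11 * f_mass - a12 * f_wall) / det
    return x1, x2


def gains_2dof_force(params: StackParams, omega: float) -> tuple[complex, complex]:
    """Gains from the pressure force F on the wall to (x1, x2).

    x1 is the arterial-wall displacement, x2 the mass (sensor) displacement.
    Derived by solving the coupled harmonic equations directly; the static
    limit reproduces the equilibrium of the spring network.
    """
    if omega < 0:
        raise DomainError("omega must be non-negative")
    return _solve_2dof(params, omega, f_wall=1.0 + 0j, f_mass=0.0 + 0j)


def gains_2dof_baseline(params: StackParams, omega: float) -> tuple[complex, complex]:
    """Gains from substrate motion z_b to (x1b, x2b).

    The substrate drives the mass equation through ks + j omega cs.
    """
    if omega < 0:
        raise DomainError("omega must be non-negative")
    if omega == 0.0:
        drive: complex = params.ks
    else:
        drive = params.ks + 1j * omega * params.cs
    return _solve_2dof(params, omega, f_wall=0.0 + 0j, f_mass=drive)


def harmonic_series(
    grid: TimeGrid,
    terms: list[tuple[float, complex]],
    deriv: int = 0,
) -> np.ndarray:
    """Real series sum_i Re[C_i (j w_i)^deriv e^{j w_i t}] on the grid.

    ``terms`` pairs each angular frequency with its complex amplitude; this
    is the common backend for applying complex gains harmonic by harmonic.
    """
    t = grid.t
    out = np.zeros_like(t)
    for w, c in terms:
        out += ((1j * w) ** deriv * c * np.exp(1j * w * t)).real
    return out


def _pulse_response_terms(
    params: StackParams, pulse: HarmonicPulse,
) -> dict[str, list[tuple[float, complex]]]:
    """Complex harmonic amplitudes of the MA-free measured signals."""
    amps = pulse.complex_amplitudes()
    w0 = pulse.omega_fundamental
    if pulse.mode == "wall_displacement":
        terms = {"x_C": []}
        for k, c in enumerate(amps, start=1):
            w = k * w0
            terms["x_C"].append((w, gain_pulse_1dof(params, w) * c))
        return terms
    terms = {"x1C": [], "x2C": []}
    for k, c in enumerate(amps, start=1):
        w = k * w0
        g1, g2 = gains_2dof_force(params, w)
        f = pulse.force_scale * c
        terms["x1C"].append((w, g1 * f))
        terms["x2C"].append((w, g2 * f))
    return terms


def measured_free(
    params: StackParams, pulse: HarmonicPulse, grid: TimeGrid, deriv: int = 0,
) -> dict[str, np.ndarray]:
    """MA-free measured signal(s) by per-harmonic complex-gain superposition.

    Returns ``{"x_C": ...}`` in wall-displacement mode and
    ``{"x1C": ..., "x2C": ...}`` in pulsatile-pressure mode.  ``deriv``
    selects a closed-form time derivative of each signal.
    """
    if pulse.mode == "pulsatile_pressure" and params.kA is None:
        raise ConfigurationError(
            "pulsatile_pressure pulse requires two-degree-of-freedom "
            "parameters (kA set)"
        )
    if pulse.mode == "wall_displacement" and params.kA is not None:
        raise ConfigurationError(
            "wall_displacement pulse is a 1DOF configuration; params carry kA"
        )
    terms = _pulse_response_terms(params, pulse)
    return {name: harmonic_series(grid, tl, deriv=deriv) for name, tl in terms.items()}


def frequency_response_table(
    params: StackParams,
    omegas: np.ndarray,
    which: str,
) -> np.ndarray:
    """Magnitude/phase table for Bode-style export.

    ``which`` is one of ``pulse_1dof``, ``baseline_1dof``, ``force_2dof_wall``,
    ``force_2dof_mass``, ``baseline_2dof_wall``, ``baseline_2dof_mass``.
    Returns an array of shape (n, 3): omega, magnitude, phase.
    """
    rows = []
    for w in np.asarray(omegas, dtype=float):
        if which == "pulse_1dof":
            g = gain_pulse_1dof(params, w)
        elif which == "baseline_1dof":
            g = gain_baseline_1dof(params, w)
        elif which in ("force_2dof_wall", "force_2dof_mass"):
            g1, g2 = gains_2dof_force(params, w)
            g = g1 if which.endswith("wall") else g2
        elif which in ("baseline_2dof_wall", "baseline_2dof_mass"):
            g1, g2 = gains_2dof_baseline(params, w)
            g = g1 if which.endswith("wall") else g2
        else:
            raise ConfigurationError(f"unknown response {which!r}")
        rows.append((w, abs(g), cmath.phase(g)))
    return np.array(rows)
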