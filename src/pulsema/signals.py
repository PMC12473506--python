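"""Stack parameters and synthetic input signals.

The measurement chain from artery to transducer — overlying tissue, the
tissue–sensor contact, and the deformable sensor microstructure — is lumped
into a mass-spring-damper stack.  Tissue–sensor contact joins the tissue and
microstructure masses into a single mass ``m0`` with a spring/damper pair on
each side: ``(k0, c0)`` toward the artery and ``(ks, cs)`` toward the sensor
substrate.  In the pulsatile-pressure configuration the arterial wall adds a
grounded spring ``kA``, turning the stack into a two-degree-of-freedom
system.

All quantities are kept dimensionless: ``kA = 1`` sets the stiffness scale
and the fundamental pulse amplitude sets the displacement scale, so the
physically meaningful inputs are ratios (frequency ratio ``r0``, damping
factors ``zeta0``/``zeta_s``, stiffness ratios) plus the heart rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DomainError

__all__ = [
    "HarmonicPulse",
    "MotionArtifactSignal",
    "StackParams",
    "TimeGrid",
    "build_params",
    "canonical_ma",
    "canonical_pulse",
    "eval_ma",
    "eval_pulse",
]

#: Harmonic amplitude envelope of the canonical pulse, relative to the
#: fundamental.  A monotonically decaying envelope typical of carotid
#: arterial pulse waveforms.
CANONICAL_HARMONIC_ENVELOPE = (
    1.0, 0.55, 0.32, 0.18, 0.10, 0.055, 0.03, 0.018, 0.01, 0.006,
)

#: Per-harmonic phase slope of the canonical pulse (rad per harmonic index).
CANONICAL_PHASE_SLOPE = -0.4


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid, seconds."""

    t0: float = 0.0
    t_end: float = 12.0
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError(f"dt must be positive, got {self.dt}")
        if self.t_end <= self.t0:
            raise DomainError("t_end must exceed t0")

    @property
    def n(self) -> int:
        return int(round((self.t_end - self.t0) / self.dt)) + 1

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.dt

    def mask_after(self, t_cut: float) -> np.ndarray:
        """Boolean mask of samples at or after absolute time ``t_cut``."""
        return self.t >= t_cut


@dataclass(frozen=True)
class HarmonicPulse:
    """True pulse signal as a finite harmonic series.

    ``harmonics[k-1] = (amplitude, phase)`` describes the k-th harmonic at
    frequency ``k * fundamental_hz``.  In ``wall_displacement`` mode the
    series is the arterial wall displacement y(t); in ``pulsatile_pressure``
    mode it is the pulsatile pressure, which acts on the arterial wall as a
    force F(t) = force_scale * dp(t) through the effective lumen area.
    """

    fundamental_hz: float
    harmonics: tuple[tuple[float, float], ...]
    mode: Literal["wall_displacement", "pulsatile_pressure"] = "wall_displacement"
    force_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fundamental_hz <= 0:
            raise DomainError("fundamental_hz must be positive")
        if len(self.harmonics) == 0:
            raise DomainError("pulse needs at least one harmonic")
        if any(a < 0 for a, _ in self.harmonics):
            raise DomainError("harmonic amplitudes must be non-negative")
        if self.mode == "pulsatile_pressure" and self.force_scale <= 0:
            raise DomainError("force_scale must be positive in pressure mode")
        if self.mode not in ("wall_displacement", "pulsatile_pressure"):
            raise DomainError(f"unknown pulse mode {self.mode!r}")

    @property
    def omega_fundamental(self) -> float:
        return 2.0 * math.pi * self.fundamental_hz

    @property
    def max_frequency_hz(self) -> float:
        return self.fundamental_hz * len(self.harmonics)

    def complex_amplitudes(self) -> np.ndarray:
        """Complex amplitude ``A_k exp(j phi_k)`` per harmonic."""
        amps = np.array([a for a, _ in self.harmonics])
        phases = np.array([p for _, p in self.harmonics])
        return amps * np.exp(1j * phases)


@dataclass(frozen=True)
class MotionArtifactSignal:
    """Sensor-substrate displacement z_b(t): a sum of low-frequency tones.

    ``components`` is a sequence of (amplitude, frequency_hz, phase) triples;
    an empty sequence is the motion-artifact-free case.
    """

    components: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if any(f <= 0 for _, f, _ in self.components):
            raise DomainError("MA component frequencies must be positive")

    @property
    def max_frequency_hz(self) -> float:
        return max((f for _, f, _ in self.components), default=0.0)


@dataclass(frozen=True)
class StackParams:
    """Lumped parameters of the tissue-contact-sensor stack.

    ``kA`` is present only in the two-degree-of-freedom (pulsatile-pressure)
    configuration.  ``omega_C`` is the heart-rate angular frequency used to
    form the dimensionless frequency ratio.
    """

    m0: float
    k0: float
    c0: float
    ks: float
    cs: float
    omega_C: float
    kA: float | None = None

    def __post_init__(self) -> None:
        for name in ("m0", "k0", "c0", "ks", "cs", "omega_C"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise DomainError(f"{name} must be positive and finite, got {v}")
        if self.kA is not None and not (self.kA > 0 and math.isfinite(self.kA)):
            raise DomainError(f"kA must be positive and finite, got {self.kA}")

    @property
    def omega0(self) -> float:
        """Natural angular frequency of the stack alone, sqrt(k0/m0)."""
        return math.sqrt(self.k0 / self.m0)

    @property
    def r0(self) -> float:
        """Frequency ratio omega0 / omega_C."""
        return self.omega0 / self.omega_C

    @property
    def zeta0(self) -> float:
        """Stack damping factor c0 / (2 sqrt(k0 m0))."""
        return self.c0 / (2.0 * math.sqrt(self.k0 * self.m0))

    @property
    def zeta_s(self) -> float:
        """Sensor damping factor cs / (2 sqrt(ks m0)).

        Normalized by the joined mass m0: the sensor microstructure shares
        its mass with the stack, so m0 is the only mass in the model.
        """
        return self.cs / (2.0 * math.sqrt(self.ks * self.m0))

    @property
    def is_2dof(self) -> bool:
        return self.kA is not None


def build_params(
    kA: float,
    k0_over_kA: float,
    r0: float,
    zeta0: float,
    ks_over_k0: float,
    zeta_s: float,
    heart_rate_hz: float,
    *,
    two_dof: bool = True,
) -> StackParams:
    """Construct :class:`StackParams` from dimensionless design ratios.

    Parameters are specified the way the stack is characterized physically:
    the arterial stiffness scale ``kA``, the stack-to-artery stiffness ratio,
    the frequency ratio ``r0 = omega0/omega_C``, damping factors, the
    sensor-to-stack stiffness ratio and the heart rate.  With ``two_dof``
    false the arterial spring is dropped (wall-displacement configuration)
    but ``kA`` still sets the stiffness scale for ``k0``.
    """
    args = {
        "kA": kA, "k0_over_kA": k0_over_kA, "r0": r0, "zeta0": zeta0,
        "ks_over_k0": ks_over_k0, "zeta_s": zeta_s, "heart_rate_hz": heart_rate_hz,
    }
    for name, v in args.items():
        if not (v > 0 and math.isfinite(v)):
            raise DomainError(f"{name} must be positive and finite, got {v}")
    omega_C = 2.0 * math.pi * heart_rate_hz
    k0 = k0_over_kA * kA
    omega0 = r0 * omega_C
    m0 = k0 / omega0**2
    c0 = 2.0 * zeta0 * math.sqrt(k0 * m0)
    ks = ks_over_k0 * k0
    cs = 2.0 * zeta_s * math.sqrt(ks * m0)
    return StackParams(
        m0=m0, k0=k0, c0=c0, ks=ks, cs=cs, omega_C=omega_C,
        kA=kA if two_dof else None,
    )


def nominal_params(heart_rate_hz: float = 1.0, *, two_dof: bool = False,
                   ks_over_k0: float = 6.0) -> StackParams:
    """Nominal stack: k0 = kA/6, r0 = 2, zeta0 = zeta_s = 1.5, ks = 6 k0."""
    return build_params(
        kA=1.0, k0_over_kA=1.0 / 6.0, r0=2.0, zeta0=1.5,
        ks_over_k0=ks_over_k0, zeta_s=1.5, heart_rate_hz=heart_rate_hz,
        two_dof=two_dof,
    )


def canonical_pulse(
    mode: Literal["wall_displacement", "pulsatile_pressure"] = "wall_displacement",
    fundamental_hz: float = 1.0,
    amplitude: float = 1.0,
) -> HarmonicPulse:
    """The default ten-harmonic pulse (heart rate 60 bpm, unit fundamental)."""
    harmonics = tuple(
        (amplitude * a, CANONICAL_PHASE_SLOPE * k)
        for k, a in enumerate(CANONICAL_HARMONIC_ENVELOPE)
    )
    return HarmonicPulse(fundamental_hz=fundamental_hz, harmonics=harmonics,
                         mode=mode, force_scale=1.0)


def canonical_ma(amplitude: float = 1.0) -> MotionArtifactSignal:
    """Default two-tone substrate motion, larger than the pulse and
    concentrated at low frequency."""
    return MotionArtifactSignal(components=(
        (2.0 * amplitude, 0.10, 0.0),
        (0.8 * amplitude, 0.23, 0.8),
    ))


def _check_nyquist(max_f: float, grid: TimeGrid, what: str) -> None:
    if max_f >= grid.nyquist_hz:
        raise DomainError(
            f"highest {what} frequency {max_f:g} Hz is not below the grid "
            f"Nyquist frequency {grid.nyquist_hz:g} Hz"
        )


def eval_pulse(pulse: HarmonicPulse, grid: TimeGrid, deriv: int = 0) -> np.ndarray:
    """Evaluate the pulse series (or a closed-form time derivative) on a grid.

    s(t) = sum_k A_k cos(2 pi k f_C t + phi_k); derivatives are applied per
    harmonic analytically, never by finite differences.
    """
    _check_nyquist(pulse.max_frequency_hz, grid, "pulse harmonic")
    t = grid.t
    out = np.zeros_like(t)
    for k, (a, phi) in enumerate(pulse.harmonics, start=1):
        w = k * pulse.omega_fundamental
        # d^n/dt^n cos(wt+phi) = w^n cos(wt + phi + n*pi/2)
        out += a * w**deriv * np.cos(w * t + phi + deriv * math.pi / 2.0)
    return out


def pulse_force(pulse: HarmonicPulse, grid: TimeGrid, deriv: int = 0) -> np.ndarray:
    """Force on the arterial wall, F(t) = force_scale * dp(t) (pressure mode)."""
    if pulse.mode != "pulsatile_pressure":
        raise DomainError("pulse_force requires a pulsatile_pressure pulse")
    return pulse.force_scale * eval_pulse(pulse, grid, deriv=deriv)


def eval_ma(ma: MotionArtifactSignal, grid: TimeGrid, deriv: int = 0) -> np.ndarray:
    """Evaluate substrate displacement z_b(t) (or a derivative) on a grid."""
    _check_nyquist(ma.max_frequency_hz, grid, "motion-artifact")
    t = grid.t
    out = np.zeros_like(t)
    for b, f, phi in ma.components:
        w = 2.0 * math.pi * f
        out += b * w**deriv * np.cos(w * t + phi + deriv * math.pi / 2.0)
    return out
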