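"""Behavioral model of the voltage-controlled coil current source.

The driver is an operational-amplifier current source: the control voltage
(after an input divider) appears across a shunt resistor in series with the
coil, so the static transfer is

    I_coil = divider * U_control / R_shunt

exactly linear within compliance.  Compliance is bounded by the supply minus
the amplifier's dropout voltage (default 4 V) and a continuous current limit
(default +-3 A, an OPA548-class output stage).  The closed loop is abstracted
as a canonical second-order system in (damping ratio zeta, natural frequency
omega_n) with an added slew-rate ceiling di/dt <= (supply - dropout)/L; the
hardware's compensation trimmer maps onto zeta.  Defaults reproduce a ~15%
step overshoot settling (2% band) in 400 us.

Double-wrapped (sham) operation: the anti-serial wiring carries the same
current and dissipates the same power but generates zero field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .coil_field import Polarity

__all__ = [
    "DriverModel",
    "StaticOperatingPoint",
    "StepResponse",
    "static_current",
    "min_supply_voltage",
    "power_dissipation",
    "steady_state_power_budget",
    "step_response",
    "frequency_response",
    "sham_blanking",
    "natural_frequency_for_settling",
    "overshoot_fraction",
]

DEFAULT_ZETA = 0.517
DEFAULT_SETTLING = 400e-6  # s, 2% band


def overshoot_fraction(zeta: float) -> float:
    """Closed-form peak overshoot of a second-order step: exp(-pi z / sqrt(1-z^2))."""
    if zeta >= 1.0:
        return 0.0
    return float(np.exp(-np.pi * zeta / np.sqrt(1.0 - zeta * zeta)))


def _unit_step(zeta: float, tau: np.ndarray) -> np.ndarray:
    """Unit step response of the canonical second-order system at omega_n = 1."""
    tau = np.asarray(tau, dtype=float)
    if zeta < 1.0:
        wd = np.sqrt(1.0 - zeta * zeta)
        return 1.0 - np.exp(-zeta * tau) * (np.cos(wd * tau)
                                            + zeta / wd * np.sin(wd * tau))
    if zeta == 1.0:
        return 1.0 - np.exp(-tau) * (1.0 + tau)
    wd = np.sqrt(zeta * zeta - 1.0)
    s1, s2 = -zeta + wd, -zeta - wd
    return 1.0 + (s2 * np.exp(s1 * tau) - s1 * np.exp(s2 * tau)) / (s1 - s2)


@lru_cache(maxsize=64)
def _normalized_settling_time(zeta: float, band: float = 0.02) -> float:
    """Last time (in units of 1/omega_n) the unit step leaves the +-band."""
    tau = np.linspace(0.0, 60.0, 600001)
    y = _unit_step(zeta, tau)
    outside = np.abs(y - 1.0) > band
    if not outside.any():
        return 0.0
    return float(tau[np.nonzero(outside)[0][-1] + 1])


def natural_frequency_for_settling(zeta: float = DEFAULT_ZETA,
                                   t_settle: float = DEFAULT_SETTLING,
                                   band: float = 0.02) -> float:
    """omega_n (rad/s) giving the requested 2%-band settling time at this zeta."""
    return _normalized_settling_time(zeta, band) / t_settle


@dataclass(frozen=True)
class DriverModel:
    """Driver parameters.  Resistances in ohm, inductance in henry, voltages
    in volt, currents in ampere."""

    R_shunt: float = 1.0
    control_divider: float = 1.0
    supply: float = 15.0
    dropout: float = 4.0
    current_limit: float = 3.0
    coil_R: float = 10.1  # exemplary x-axis pair
    coil_L: float = 1.05e-3
    damping_ratio: float = DEFAULT_ZETA
    natural_frequency: float = field(
        default_factory=lambda: natural_frequency_for_settling())

    def __post_init__(self):
        if self.R_shunt <= 0 or self.coil_R <= 0 or self.coil_L <= 0:
            raise ValueError("resistances and inductance must be positive")
        if not (0 < self.control_divider <= 1):
            raise ValueError("control divider must be in (0, 1]")
        if self.damping_ratio <= 0:
            raise ValueError("damping ratio must be positive")
        if self.supply <= self.dropout:
            raise ValueError("supply must exceed the dropout voltage")

    @property
    def compliance_voltage(self) -> float:
        return self.supply - self.dropout

    @property
    def compliance_current(self) -> float:
        """Largest steady current the output voltage can sustain in the coil."""
        return self.compliance_voltage / self.coil_R

    @property
    def slew_limit(self) -> float:
        """Maximum |di/dt| (A/s): compliance voltage across the inductance."""
        return self.compliance_voltage / self.coil_L


@dataclass
class StaticOperatingPoint:
    current: float  # A
    demanded: float  # A, before clipping
    current_limited: bool
    voltage_limited: bool

    @property
    def saturated(self) -> bool:
        return self.current_limited or self.voltage_limited


def static_current(model: DriverModel, U_control: float) -> StaticOperatingPoint:
    """Static transfer I = divider * U / R_shunt, clipped to the current limit
    and to voltage compliance; clipping is flagged, not raised."""
    demanded = model.control_divider * U_control / model.R_shunt
    i = demanded
    current_limited = abs(i) > model.current_limit
    if current_limited:
        i = np.sign(i) * model.current_limit
    # the amplifier must drive coil_R * I (plus shunt) within compliance
    voltage_limited = abs(i) * model.coil_R > model.compliance_voltage
    if voltage_limited:
        i = np.sign(i) * model.compliance_current
    return StaticOperatingPoint(current=float(i), demanded=float(demanded),
                                current_limited=bool(current_limited),
                                voltage_limited=bool(voltage_limited))


def min_supply_voltage(I_max: float, coil_R: float, dropout: float = 4.0) -> float:
    """Lowest supply magnitude driving I_max through coil_R: I*R + dropout."""
    if I_max < 0 or coil_R <= 0 or dropout < 0:
        raise ValueError("inputs must be non-negative (coil_R positive)")
    return I_max * coil_R + dropout


def power_dissipation(supply: float, coil_voltage: float, current: float) -> float:
    """Amplifier heat at steady state: (supply - |U_coil|) * |I|."""
    if abs(coil_voltage) > supply:
        raise ValueError("coil voltage cannot exceed the supply")
    return (supply - abs(coil_voltage)) * abs(current)


def steady_state_power_budget(model: DriverModel, current: float) -> dict:
    """Supply power split into coil dissipation and amplifier dissipation."""
    u_coil = current * model.coil_R
    p_supply = model.supply * abs(current)
    p_coil = current ** 2 * model.coil_R
    p_amp = power_dissipation(model.supply, u_coil, current)
    return {"supply": p_supply, "coil": p_coil, "amplifier": p_amp}


@dataclass
class StepResponse:
    time: np.ndarray  # s
    current: np.ndarray  # A
    overshoot_percent: float
    settling_time: float  # s, 2% band
    slew_limited: bool


def step_response(model: DriverModel, I_target: float, duration: float,
                  dt: float) -> StepResponse:
    """Closed-loop current step from 0 to I_target.

    Canonical second-order dynamics at (zeta, omega_n); the derivative state
    is clamped to the physical slew ceiling (supply - dropout)/L.  When the
    clamp never engages the trace follows the analytic solution; otherwise the
    ODE is integrated (RK4) with the clamp applied.
    """
    wn = model.natural_frequency
    if dt > 0.05 / wn:
        raise ValueError(f"dt must resolve the loop: dt <= {0.05 / wn:.3g} s")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    zeta = model.damping_ratio
    analytic = I_target * _unit_step(zeta, wn * t)
    slew_max = model.slew_limit
    max_slope = float(np.max(np.abs(np.diff(analytic)))) / dt if len(t) > 1 else 0.0
    if max_slope <= slew_max:
        current = analytic
        slew_limited = False
    else:
        current = _integrate_clamped(zeta, wn, I_target, t, dt, slew_max)
        slew_limited = True
    overshoot = max(0.0, float(np.max(current) / I_target) - 1.0) if I_target > 0 \
        else max(0.0, float(np.min(current) / I_target) - 1.0)
    band = 0.02 * abs(I_target)
    outside = np.abs(current - I_target) > band
    settle = float(t[np.nonzero(outside)[0][-1] + 1]) if outside.any() else 0.0
    return StepResponse(time=t, current=current,
                        overshoot_percent=100.0 * overshoot,
                        settling_time=settle, slew_limited=slew_limited)


def _integrate_clamped(zeta: float, wn: float, target: float, t: np.ndarray,
                       dt: float, slew_max: float) -> np.ndarray:
    """RK4 of i'' = wn^2 (target - i) - 2 zeta wn i' with |i'| <= slew_max."""

    def deriv(state):
        i, v = state
        a = wn * wn * (target - i) - 2.0 * zeta * wn * v
        # at the clamp, acceleration pushing further out is suppressed
        if v >= slew_max and a > 0:
            a = 0.0
        elif v <= -slew_max and a < 0:
            a = 0.0
        return np.array([v, a])

    out = np.empty_like(t)
    state = np.array([0.0, 0.0])
    out[0] = 0.0
    for k in range(1, len(t)):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        state[1] = np.clip(state[1], -slew_max, slew_max)
        out[k] = state[0]
    return out


def frequency_response(model: DriverModel, frequencies) -> dict:
    """Second-order closed-loop transfer sampled at ``frequencies`` (Hz).

    Returns linear gain, gain in dB, and phase in degrees (negative lag).
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    w = 2.0 * np.pi * f
    wn, zeta = model.natural_frequency, model.damping_ratio
    h = wn ** 2 / (wn ** 2 - w ** 2 + 2j * zeta * wn * w)
    gain = np.abs(h)
    phase = np.unwrap(np.angle(h))
    return {
        "frequency": f,
        "gain": gain,
        "gain_db": 20.0 * np.log10(gain),
        "phase_deg": np.rad2deg(phase),
    }


def sham_blanking(model: DriverModel, polarity: Polarity | str,
                  U_control: float) -> dict:
    """Double-wrapped sham operation.

    The coil current (and hence resistive heating) is identical in both
    wirings; the generated-field scale factor is 1 for serial and exactly 0
    for anti-serial wiring.
    """
    polarity = Polarity(polarity)
    op = static_current(model, U_control)
    scale = 1.0 if polarity == Polarity.SERIAL else 0.0
    return {"current": op.current, "field_scale": scale,
            "operating_point": op}
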