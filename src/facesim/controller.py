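"""PID-with-wind control law for FACE gas release valves.

The control law maps the setpoint error, its running integral and first
difference, and the current wind speed to a dimensionless command::

    raw = kp*(stpt - pv) + ki*Int(stpt - pv) + kd*Der(stpt - pv) + kw*ws

The wind term is a feedforward unique to open-air fumigation: wind is the
dominant loss process in a chamberless plot, so the valve must open with the
wind before any tracking error develops. The command is mapped linearly onto
the physical valve range [0, 10] (0 = fully closed, 10 = fully open).

Discretization: the integral is a rectangle-rule running sum of error*dt and
the derivative a first difference, zero on a fresh state. The integral
accumulator is clamped (anti-windup) so that a long valve saturation cannot
build up an arbitrarily large memory; without the clamp a controller that is
on for an entire season would take minutes to unwind after a disturbance.

Errors are in the species' native unit (ppm for CO2, ppb for O3), which is
why the packaged coefficient sets differ by species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .species import GasSpecies

VALVE_MIN = 0.0
VALVE_MAX = 10.0


@dataclass(frozen=True)
class ControllerCoefficients:
    """The four gains of the control law, all non-negative.

    kp : proportional gain (valve command per unit error)
    ki : integral gain (per unit error*second)
    kd : derivative gain (per unit error/second)
    kw : wind feedforward gain (per m/s)
    """

    kp: float
    ki: float
    kd: float
    kw: float

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd", "kw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Gains used operationally for CO2 seasons (error in ppm).
CO2_COEFFICIENTS = ControllerCoefficients(kp=0.0008, ki=0.000015, kd=0.016, kw=0.15)
#: Gains used operationally for O3 seasons (error in ppb).
O3_COEFFICIENTS = ControllerCoefficients(kp=0.0016, ki=0.00008, kd=0.016, kw=0.5)

DEFAULT_COEFFICIENTS: dict[GasSpecies, ControllerCoefficients] = {
    GasSpecies.CO2: CO2_COEFFICIENTS,
    GasSpecies.O3: O3_COEFFICIENTS,
}


@dataclass(frozen=True)
class ControllerState:
    """Integral and derivative memory of the loop.

    A fresh state has zero integral and no previous error; the first step
    therefore has a zero derivative term.
    """

    integral_accum: float = 0.0  # concentration * seconds
    prev_error: float | None = None


@dataclass(frozen=True)
class ValveCommand:
    """Raw control-law output and its clamped valve setting in [0, 10]."""

    raw_command: float
    valve_setting: float


def command_to_valve(raw_command: float, scale: float) -> float:
    """Map a raw command linearly onto the valve range and clamp to [0, 10]."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return min(max(scale * raw_command, VALVE_MIN), VALVE_MAX)


def integral_limit_for(scale: float, ki: float) -> float:
    """Command-equivalent anti-windup bound: the accumulator never holds more
    than would drive the valve fully open through the integral term alone."""
    if ki <= 0:
        return math.inf
    return (VALVE_MAX / scale) / ki


def pid_step(
    coeffs: ControllerCoefficients,
    state: ControllerState,
    setpoint: float,
    measured: float,
    wind_speed: float,
    dt: float,
    *,
    scale: float = 10.0,
    integral_limit: float | None = None,
) -> tuple[ValveCommand, ControllerState]:
    """Advance the control loop by one step of length ``dt`` seconds.

    ``setpoint`` and ``measured`` must share the species' native unit.
    Returns the valve command and the updated controller state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    error = setpoint - measured
    integral = state.integral_accum + error * dt
    if integral_limit is not None:
        integral = min(max(integral, -integral_limit), integral_limit)
    if state.prev_error is None:
        derivative = 0.0
    else:
        derivative = (error - state.prev_error) / dt
    raw = (
        coeffs.kp * error
        + coeffs.ki * integral
        + coeffs.kd * derivative
        + coeffs.kw * wind_speed
    )
    command = ValveCommand(raw_command=raw, valve_setting=command_to_valve(raw, scale))
    return command, ControllerState(integral_accum=integral, prev_error=error)
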