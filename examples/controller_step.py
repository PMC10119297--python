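"""One step of the valve control law, by hand.

The controller turns the setpoint error, its integral and derivative, and
the current wind speed into a valve command. Below: CO2 gains, a fresh
controller, plot at 450 ppm against a 550 ppm setpoint, wind 2 m/s.
"""

from facesim import CO2_COEFFICIENTS, ControllerState, pid_step

cmd, state = pid_step(
    CO2_COEFFICIENTS, ControllerState(),
    setpoint=550.0, measured=450.0, wind_speed=2.0, dt=4.0,
)
print(f"raw command     : {cmd.raw_command:.3f}")
print(f"valve setting   : {cmd.valve_setting:.2f}  (0 = closed, 10 = open)")
print(f"integral memory : {state.integral_accum:.0f} ppm*s")

# Composition: 0.0008*100 (proportional) + 0.000015*400 (integral after one
# 4-s step) + 0 (derivative, fresh state) + 0.15*2 (wind feedforward) = 0.386.
# The wind term dominates: in open air, wind is the main gas-loss process.
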