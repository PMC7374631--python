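"""Shared physical constants and canonical sampling rates."""

#: Gravitational acceleration, m/s^2.
GRAVITY = 9.81

#: Canonical force-plate sampling rate, Hz.
FORCE_RATE = 1000.0

#: Canonical motion-capture (joint angle) sampling rate, Hz.
KINEMATIC_RATE = 200.0

#: Sides and joints, in canonical order.
SIDES = ("left", "right")
JOINTS = ("hip", "knee", "ankle")

#: Force-plate channels, in canonical column order.
FORCE_CHANNELS = ("Fz", "Fy", "cop_y")
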