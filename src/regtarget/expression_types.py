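"""Direction labels shared across modules.

Kept in a tiny leaf module so that integration and simulation code can use
the labels without importing the clustering machinery.
"""

DOWN_UPON_KD = "down_upon_kd"
"""Transcript goes down when the factor is knocked down — activated by the factor."""

UP_UPON_KD = "up_upon_kd"
"""Transcript goes up when the factor is knocked down — repressed by the factor."""
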