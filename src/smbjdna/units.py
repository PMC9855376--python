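"""Physical constants and unit conversions."""

from scipy.constants import physical_constants

#: Conductance quantum G0 = 2 e^2 / h, in siemens (~77.48 uS).
CONDUCTANCE_QUANTUM_S: float = physical_constants["conductance quantum"][0]
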