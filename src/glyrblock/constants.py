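"""Physical constants for electrodiffusion arithmetic.

The Woodhull factor exp(-delta*F*V/RT) is the only place these enter; the
thermal voltage RT/F at the default recording temperature (295.15 K, i.e.
22 C room temperature) is 25.43 mV.
"""

from __future__ import annotations

from dataclasses import dataclass

FARADAY = 96485.33212  # C mol^-1
GAS_CONSTANT = 8.31446262  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 295.15  # K


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature."""

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = DEFAULT_TEMPERATURE

    @property
    def rt_f_mV(self) -> float:
        """Thermal voltage RT/F in millivolts."""
        return 1000.0 * self.R * self.T / self.F


def rt_f_mV(T: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal voltage RT/F in mV at temperature ``T`` (K)."""
    if not (T > 0):
        raise ValueError(f"temperature must be positive, got {T}")
    return 1000.0 * GAS_CONSTANT * T / FARADAY
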