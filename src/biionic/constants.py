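"""Physical constants for electro-diffusion calculations.

All potentials in this package are in mV, concentrations in mM, times in ms.
The default temperature is 298.1 K, the value used for the whole-cell
recordings this package emulates (25 degC water bath).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Faraday constant, C/mol (CODATA exact).
FARADAY = 96485.33212

#: Molar gas constant, J/(mol K) (CODATA exact).
GAS_CONSTANT = 8.314462618


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of F, R and the recording temperature.

    Parameters
    ----------
    F : float
        Faraday constant in C/mol.
    R : float
        Gas constant in J/(mol K).
    T : float
        Absolute temperature in K. Must be positive.
    """

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = 298.1

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")

    @property
    def rt_over_f_mV(self) -> float:
        """RT/F expressed in mV (~25.69 mV at 298.1 K)."""
        return 1000.0 * self.R * self.T / self.F

    @property
    def f_over_rt_per_mV(self) -> float:
        """F/RT expressed per mV; multiplies a potential in mV to give the
        dimensionless GHK exponent argument."""
        return 1.0 / self.rt_over_f_mV


#: Default constants at the standard recording temperature.
DEFAULT_CONSTANTS = PhysicalConstants()
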