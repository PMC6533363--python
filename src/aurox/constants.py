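"""Physical constants for equilibrium calculations.

The defaults deliberately use the rounded values common in low-temperature
geochemistry hand calculations (T = 298 K, 2.303 for ln 10, Faraday constant
96.49 kJ V^-1 eq^-1) so that derived constants agree with published
hand-derived chains to the printed precision.  All of them are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ThermoConstants:
    """Constants bundle used by every conversion in :mod:`aurox.thermo`.

    Attributes
    ----------
    R : float
        Gas constant, J mol^-1 K^-1.
    F : float
        Faraday constant, kJ V^-1 eq^-1 (96.49 kJ per volt gram equivalent).
    T : float
        Temperature, K.  298 K is the reference Earth-surface temperature.
    ln10 : float
        The "2.303" factor converting natural to decadic logarithms.
    """

    R: float = 8.314
    F: float = 96.49
    T: float = 298.0
    ln10: float = 2.303

    @property
    def rt_log10(self) -> float:
        """2.303*R*T in J mol^-1 (5705.85 J at the defaults)."""
        return self.ln10 * self.R * self.T

    @property
    def eh_factor(self) -> float:
        """pe = eh_factor * Eh; equals F/(2.303*R*T) in V^-1 (16.91 at defaults)."""
        return self.F * 1000.0 / self.rt_log10


#: Module-wide default constants (25 degC, rounded-constant convention).
DEFAULT = ThermoConstants()
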