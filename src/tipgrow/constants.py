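"""Thermodynamic constants used throughout the model."""

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant, temperature, Faraday constant and the thermal voltage.

    ``Vref = R*T/F`` is the thermal voltage that scales all
    Goldman-Hodgkin-Katz exponents.  It is derived, not free: supplying an
    inconsistent value raises ``ValueError``.
    """

    R: float = 8.314462618       # J mol^-1 K^-1
    T: float = 298.15            # K
    F: float = 96485.33212       # C mol^-1
    Vref: float = field(default=0.0)  # V, filled in __post_init__

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0 or self.F <= 0:
            raise ValueError("R, T and F must be strictly positive")
        vref = self.R * self.T / self.F
        if self.Vref == 0.0:
            object.__setattr__(self, "Vref", vref)
        elif abs(self.Vref - vref) > 1e-12 * vref:
            raise ValueError(
                f"Vref={self.Vref} inconsistent with R*T/F={vref}"
            )

    @property
    def RT(self) -> float:
        """R*T in J mol^-1 (multiply by mol m^-3 to get Pa)."""
        return self.R * self.T


DEFAULT_CONSTANTS = PhysicalConstants()
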