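"""Thermodynamic context: temperature and inverse temperature in kcal/mol units."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_MOL_K = 0.0019872041


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and the derived inverse temperature beta = 1/(kB*T).

    All energies in the package are kcal/mol, so ``beta`` carries units of
    (kcal/mol)^-1.  ``beta`` may be supplied explicitly, in which case it must
    agree with the temperature to 1e-12 relative.
    """

    temperature: float
    kB: float = KB_KCAL_MOL_K
    beta: float = field(default=0.0)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        derived = 1.0 / (self.kB * self.temperature)
        if self.beta == 0.0:
            object.__setattr__(self, "beta", derived)
        elif abs(self.beta - derived) > 1e-12 * abs(derived):
            raise ValueError(
                f"beta={self.beta} inconsistent with 1/(kB*T)={derived} beyond 1e-12 relative"
            )

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return 1.0 / self.beta
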