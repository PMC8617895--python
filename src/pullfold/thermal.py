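"""Thermal energy scale shared by every model in the package.

All mechanical quantities use the single-molecule unit system: forces in pN,
lengths in nm, energies in pN·nm (1 pN·nm ≈ 0.25 kBT at room temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in pN·nm/K.
BOLTZMANN_PN_NM_PER_K = 0.0138065


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and derived thermal energy scale.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Defaults to room temperature (298 K),
        the condition of the barnase pulling experiments.
    """

    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kBT(self) -> float:
        """Thermal energy kB·T in pN·nm."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kBT in 1/(pN·nm)."""
        return 1.0 / self.kBT


ROOM_TEMPERATURE = ThermalContext()
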