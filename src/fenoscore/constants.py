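"""Physical constants and unit conversions used throughout the package.

All values are CODATA 2018 and are frozen here rather than taken from
``scipy.constants`` at run time so that computed hyperfine couplings and
Larmor frequencies are stable across library upgrades.  Nuclear g-factors
follow the usual sign convention (positive for 1H, 2H, 14N).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 constants needed for dipolar couplings and Zeeman terms.

    ``mu0_over_4pi`` is the vacuum permeability divided by 4*pi, in SI
    (T^2 m^3 / J).  ``g_e`` is the free-electron g-factor (positive
    magnitude convention).
    """

    mu0_over_4pi: float = 1.00000000055e-7  # T^2 m^3 J^-1
    g_e: float = 2.00231930436256
    beta_e: float = 9.2740100783e-24        # Bohr magneton, J/T
    beta_n: float = 5.0507837461e-27        # nuclear magneton, J/T
    h: float = 6.62607015e-34               # Planck constant, J s
    c_cm: float = 2.99792458e10             # speed of light, cm/s
    nuclear_g_factors: dict = field(default_factory=lambda: dict(_NUCLEAR_G))

    # ---- derived conversion helpers -------------------------------------

    @property
    def mhz_per_cm1(self) -> float:
        """1 cm^-1 expressed in MHz (c in cm/s / 1e6)."""
        return self.c_cm / 1e6  # 29979.2458 MHz

    @property
    def electron_mhz_per_mt(self) -> float:
        """Electron Zeeman frequency per mT for g = 1, in MHz/mT."""
        return self.beta_e / self.h * 1e-3 / 1e6  # = 0.0139962 GHz/mT for g=1

    def nuclear_g(self, isotope: str) -> float:
        try:
            return self.nuclear_g_factors[isotope]
        except KeyError:
            raise KeyError(
                f"unknown isotope {isotope!r}; known: "
                f"{sorted(self.nuclear_g_factors)}"
            ) from None

    def nuclear_spin(self, isotope: str) -> float:
        return _NUCLEAR_SPIN[isotope]


_NUCLEAR_G = {
    "1H": 5.5856946893,
    "2H": 0.8574382338,
    "14N": 0.4037610,
}

_NUCLEAR_SPIN = {
    "1H": 0.5,
    "2H": 1.0,
    "14N": 1.0,
}

CONSTANTS = PhysicalConstants()
"""Module-level default constants instance."""
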