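"""Physical constants and unit conversions shared across the package.

Canonical internal units: area in Å²/molecule, surface pressure in mN/m,
surface potential in mV, temperature in K.  Molar energies are kJ/mol and
molar entropies J/(mol·K), matching the conventions of the monolayer
literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CONSTANTS",
    "Constants",
    "per_molecule_to_molar",
    "round_half_up",
]


@dataclass(frozen=True)
class Constants:
    """Immutable bundle of the physical constants the analyses need.

    Attributes
    ----------
    N_A : Avogadro constant, 1/mol (2019 SI exact value).
    eps0 : vacuum permittivity, F/m.
    debye : one debye in C·m.
    dgamma_dT : temperature coefficient of the surface tension of pure
        water, mN m⁻¹ K⁻¹, valid between roughly 10 and 35 °C.
    """

    N_A: float = 6.02214076e23
    eps0: float = 8.8541878128e-12
    debye: float = 3.33564e-30
    dgamma_dT: float = -0.153


CONSTANTS = Constants()

# 1 Å²·mN/m = 1e-20 m² · 1e-3 N/m = 1e-23 J per molecule
_A2_MNM_TO_KJ_PER_MOL = 1e-23 * CONSTANTS.N_A / 1000.0


def per_molecule_to_molar(value: float) -> float:
    """Convert a per-molecule energy in Å²·mN/m to kJ/mol.

    The conversion is the linear map ``value × 1e−23 J × N_A / 1000``;
    it preserves sign and is used for every ∫A dπ style integral.
    """
    return value * _A2_MNM_TO_KJ_PER_MOL


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    ``round()`` uses banker's rounding, which disagrees with how the
    monolayer literature prints e.g. π_t = 36.585 → 36.59.
    """
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)
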