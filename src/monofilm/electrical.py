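"""Electrical characterisation of a monolayer from ΔV–A records.

The Helmholtz relation ΔV = μ_⊥/(A·ε·ε₀) links the surface potential to
the vertical dipole-moment component of the film molecules.  Because the
film permittivity ε is unknown, compression-induced changes are expressed
through the *apparent* dipole moment μ_a = μ_⊥/ε = ε₀·ΔV·A, reported here
in debye (the SI value in C·m is kept alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .isotherms import Isotherm, PotentialIsotherm
from .units import CONSTANTS

__all__ = [
    "DipoleCurve",
    "apparent_dipole",
    "detect_critical_area",
    "detect_depolarization_onset",
]


@dataclass
class DipoleCurve:
    """Apparent dipole moment sampled on the area grid of the ΔV record."""

    area: np.ndarray  # Å²/molecule
    mu_a: np.ndarray  # debye
    mu_a_si: np.ndarray  # C·m


def apparent_dipole(pot: PotentialIsotherm) -> DipoleCurve:
    """μ_a = ε₀·ΔV·A per sample; zero wherever ΔV is zero."""
    volts = pot.potential * 1e-3
    area_m2 = pot.area * 1e-20
    mu_si = CONSTANTS.eps0 * volts * area_m2
    return DipoleCurve(area=pot.area.copy(), mu_a=mu_si / CONSTANTS.debye, mu_a_si=mu_si)


def detect_critical_area(
    pot: PotentialIsotherm, threshold: float = 15.0, k: int = 5
) -> Optional[float]:
    """Critical area: onset of the surface-potential change on compression.

    Largest area at which |ΔV| first exceeds ``threshold`` (default 15 mV,
    the typical Kelvin-probe reproducibility) and stays above it for ``k``
    consecutive samples.  Sign-symmetric in ΔV.
    """
    pot = pot.canonical()
    above = np.abs(pot.potential) > threshold
    n = len(above)
    for i in range(n - k + 1):
        if bool(np.all(above[i : i + k])):
            return float(pot.area[i])
    return None


def detect_depolarization_onset(
    iso: Isotherm, dipole: DipoleCurve, k: int = 5, tol: float = 0.0
) -> Optional[float]:
    """Area below which μ_a falls while π still rises on compression.

    A sustained drop of the apparent dipole moment during a continuing
    pressure rise signals depolarisation of the film — the signature of
    molecules stacking into a second layer whose dipoles partly compensate
    those underneath.  Returns the largest such area (the onset), scanning
    in canonical compression order and requiring both trends to persist
    over ``k`` consecutive samples, or ``None``.
    """
    iso = iso.canonical()
    pi_on_grid = np.interp(dipole.area, iso.area[::-1], iso.pressure[::-1])
    order = np.argsort(dipole.area)[::-1]  # compression order: area decreasing
    area = dipole.area[order]
    mu = dipole.mu_a[order]
    pi = pi_on_grid[order]
    dmu = np.diff(mu)
    dpi = np.diff(pi)
    falling = (dmu < -tol) & (dpi > tol)
    for i in range(len(falling) - k + 1):
        if bool(np.all(falling[i : i + k])):
            return float(area[i])
    return None
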