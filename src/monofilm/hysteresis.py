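"""Thermodynamics of compression–expansion hysteresis.

The free energy of one branch is ΔG = N_A·∫ A dπ between two fixed
pressures (default window 1.2 → 39.8 mN/m), converted to kJ/mol.  The
hysteresis free energy is the (signed) difference between the compression
and expansion branch integrals: the energy the film takes up on
compression and fails to return on expansion.  Because the expansion
branch of a lossy film lies at smaller areas than the compression branch,
the literal difference is positive; by the convention adopted here the
retained energy is reported as a negative ΔG^hys (energy "lost" by the
film into ordered aggregates), which matches how these quantities are
tabulated in the monolayer literature.

ΔS^hys follows from the temperature dependence of ΔG^hys (least-squares
slope, negated), and ΔH^hys from the Gibbs relation ΔH = ΔG + T·ΔS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .isotherms import COMPRESSION, EXPANSION, Isotherm
from .units import per_molecule_to_molar

__all__ = [
    "HysteresisCycle",
    "HysteresisThermo",
    "DEFAULT_PI1",
    "DEFAULT_PI2",
    "branch_free_energy",
    "hysteresis_free_energy",
    "hysteresis_entropy",
    "hysteresis_enthalpy",
    "analyze_cycle",
]

log = logging.getLogger(__name__)

#: Default integration window (mN/m) spanning the pre-lift to post-plateau
#: pressure range of chain-oxidised sterol films.
DEFAULT_PI1 = 1.2
DEFAULT_PI2 = 39.8


@dataclass
class HysteresisCycle:
    """One compression–expansion cycle recorded in a single run."""

    compression: Isotherm
    expansion: Isotherm
    cycle_index: int = 1
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if self.compression.direction != COMPRESSION:
            raise ValueError("compression branch must have direction=compression")
        if self.expansion.direction != EXPANSION:
            raise ValueError("expansion branch must have direction=expansion")
        if self.compression.temperature != self.expansion.temperature:
            raise ValueError("both branches must share the temperature")


@dataclass
class HysteresisThermo:
    """ΔG/ΔS/ΔH of hysteresis with the integration window that produced them."""

    dG_comp: float  # kJ/mol
    dG_exp: float  # kJ/mol
    dG_hys: float  # kJ/mol
    pi1: float
    pi2: float
    temperature: float
    dS_hys: Optional[float] = None  # J/(mol K)
    dH_hys: Optional[float] = None  # kJ/mol


def _monotone_window(branch: Isotherm, pi_lo: float, pi_hi: float):
    """π-increasing (area, π) samples covering [pi_lo, pi_hi].

    Real cycle records overshoot near the barrier turnaround; points that
    break monotonicity of π are dropped (longest increasing envelope) and
    the clipping is logged.
    """
    iso = branch.canonical()
    # orient so that π increases along the record
    area, pi = iso.area, iso.pressure
    if pi[0] > pi[-1]:
        area, pi = area[::-1], pi[::-1]
    keep = np.ones(len(pi), dtype=bool)
    running = -np.inf
    for i, p in enumerate(pi):
        if p <= running:
            keep[i] = False
        else:
            running = p
    if not np.all(keep):
        log.info("clipped %d non-monotone sample(s) from %s branch", int((~keep).sum()), branch.direction)
    area, pi = area[keep], pi[keep]
    if pi[0] > pi_lo or pi[-1] < pi_hi:
        raise ValueError(
            f"branch covers π ∈ [{pi[0]:.3g}, {pi[-1]:.3g}] mN/m, "
            f"which does not span the window [{pi_lo:.3g}, {pi_hi:.3g}]"
        )
    return area, pi


def branch_free_energy(
    branch: Isotherm, pi1: float = DEFAULT_PI1, pi2: float = DEFAULT_PI2
) -> float:
    """ΔG = N_A·∫_{π1}^{π2} A dπ for one branch, in kJ/mol.

    Trapezoidal integration on the recorded samples with the endpoint
    areas interpolated linearly at π1 and π2.  Swapping the bounds negates
    the result.
    """
    sign = 1.0
    if pi1 > pi2:
        pi1, pi2, sign = pi2, pi1, -1.0
    area, pi = _monotone_window(branch, pi1, pi2)
    a1 = np.interp(pi1, pi, area)
    a2 = np.interp(pi2, pi, area)
    inside = (pi > pi1) & (pi < pi2)
    pis = np.concatenate(([pi1], pi[inside], [pi2]))
    areas = np.concatenate(([a1], area[inside], [a2]))
    integral = np.trapezoid(areas, pis)  # Å²·mN/m per molecule
    return sign * per_molecule_to_molar(float(integral))


def hysteresis_free_energy(
    cycle: HysteresisCycle, pi1: float = DEFAULT_PI1, pi2: float = DEFAULT_PI2
) -> float:
    """ΔG^hys of one cycle, in kJ/mol (≤ 0 by the adopted convention).

    The magnitude is |ΔG^comp − ΔG^exp| over the window; the sign is
    negative, marking energy retained by the film (see module docstring).
    Identical branches give exactly zero.
    """
    g_comp = branch_free_energy(cycle.compression, pi1, pi2)
    g_exp = branch_free_energy(cycle.expansion, pi1, pi2)
    return -abs(g_comp - g_exp)


def hysteresis_entropy(series: Sequence[tuple[float, float]]) -> float:
    """ΔS^hys = −d(ΔG^hys)/dT from a (T, ΔG^hys) series, in J/(mol·K).

    Ordinary least squares over ≥ 2 distinct temperatures; with exactly
    two points this reduces to the two-point slope.
    """
    pts = np.asarray(series, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (temperature, dG_hys) points")
    T, g = pts[:, 0], pts[:, 1]
    if np.ptp(T) == 0:
        raise ValueError("need at least 2 distinct temperatures")
    slope = np.polyfit(T, g, 1)[0]  # kJ/(mol K)
    return float(-slope * 1000.0)


def hysteresis_enthalpy(dG_hys: float, dS_hys: float, T: float) -> float:
    """Gibbs relation ΔH^hys = ΔG^hys + T·ΔS^hys (entropy in J/(mol·K))."""
    if not T > 0:
        raise ValueError("temperature must be positive")
    return dG_hys + T * dS_hys / 1000.0


def analyze_cycle(
    cycle: HysteresisCycle,
    pi1: float = DEFAULT_PI1,
    pi2: float = DEFAULT_PI2,
    dS_hys: Optional[float] = None,
) -> HysteresisThermo:
    """Full thermodynamic summary of one cycle.

    ΔS^hys cannot be derived from a single-temperature cycle; when it is
    supplied, ΔH^hys is completed through the Gibbs relation.
    """
    g_comp = branch_free_energy(cycle.compression, pi1, pi2)
    g_exp = branch_free_energy(cycle.expansion, pi1, pi2)
    g_hys = -abs(g_comp - g_exp)
    res = HysteresisThermo(
        dG_comp=g_comp,
        dG_exp=g_exp,
        dG_hys=g_hys,
        pi1=pi1,
        pi2=pi2,
        temperature=cycle.temperature,
        dS_hys=dS_hys,
    )
    if dS_hys is not None:
        res.dH_hys = hysteresis_enthalpy(g_hys, dS_hys, cycle.temperature)
    return res
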