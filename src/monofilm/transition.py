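"""Thermodynamics of the pseudo-plateau (monolayer→bilayer-like) transition.

From a family of compression isotherms recorded at several temperatures,
the plateau midpoint pressure π_t = (π_b + π_e)/2 is extracted per
temperature and fitted linearly against T.  The transition enthalpy then
follows from the Clausius–Clapeyron relation adapted to a film on water:

    ΔH_t = N_A · T · ΔA_t · (dπ_t/dT − dγ/dT),    ΔA_t = A_e − A_b,

where dγ/dT = −0.153 mN m⁻¹ K⁻¹ is the temperature coefficient of the
surface tension of pure water (10–35 °C).  The transition entropy is
ΔS_t = ΔH_t/T, computed from the *unrounded* enthalpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import PlateauFeature, detect_plateau
from .isotherms import Isotherm
from .units import CONSTANTS, per_molecule_to_molar

__all__ = [
    "TransitionSeries",
    "TransitionEntry",
    "TransitionThermo",
    "plateau_midpressure",
    "fit_pit_slope",
    "clausius_clapeyron_enthalpy",
    "transition_entropy",
    "analyze_transition",
]


@dataclass
class TransitionSeries:
    """Per-temperature plateau features, ordered by strictly increasing T."""

    entries: list[tuple[float, PlateauFeature]]
    label: str = ""

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.entries]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])

    @property
    def pi_t(self) -> np.ndarray:
        return np.array([p.pi_t for _, p in self.entries])


@dataclass
class TransitionEntry:
    """Per-temperature transition result together with its inputs."""

    temperature: float
    plateau: PlateauFeature
    dH_t: float  # kJ/mol
    dS_t: float  # J/(mol K)


@dataclass
class TransitionThermo:
    """Fitted π_t(T) slope and per-temperature transition thermodynamics."""

    dpi_dT: float  # mN/(m K), least-squares fit
    slope_used: float  # slope actually fed into Clausius–Clapeyron
    dgamma_dT: float
    entries: list[TransitionEntry] = field(default_factory=list)


def plateau_midpressure(pi_b: float, pi_e: float) -> float:
    """π_t = (π_b + π_e)/2."""
    if pi_b > pi_e:
        raise ValueError("plateau midpoint requires pi_b <= pi_e")
    return (pi_b + pi_e) / 2.0


def fit_pit_slope(series: TransitionSeries) -> float:
    """Ordinary least-squares slope of π_t versus T, in mN/(m·K)."""
    T = series.temperatures
    if len(T) < 2:
        raise ValueError("need at least 2 temperatures to fit a slope")
    if np.ptp(T) == 0:
        raise ValueError("zero temperature spread")
    return float(np.polyfit(T, series.pi_t, 1)[0])


def clausius_clapeyron_enthalpy(
    T: float,
    A_b: float,
    A_e: float,
    dpi_dT: float,
    dgamma_dT: float = CONSTANTS.dgamma_dT,
) -> float:
    """ΔH_t = N_A·T·(A_e − A_b)·(dπ_t/dT − dγ/dT), in kJ/mol.

    The sign emerges from the inputs: ΔH_t > 0 exactly when ΔA_t and the
    driving term (dπ_t/dT − dγ/dT) have opposite signs.
    """
    if not T > 0:
        raise ValueError("temperature must be positive")
    if A_b == A_e:
        raise ValueError("plateau must have A_b != A_e")
    return per_molecule_to_molar(T * (A_e - A_b) * (dpi_dT - dgamma_dT))


def transition_entropy(dH_t: float, T: float) -> float:
    """ΔS_t = ΔH_t/T in J/(mol·K); feed the unrounded enthalpy."""
    if not T > 0:
        raise ValueError("temperature must be positive")
    return 1000.0 * dH_t / T


def analyze_transition(
    family: Sequence[Isotherm],
    dgamma_dT: float = CONSTANTS.dgamma_dT,
    slope: Optional[float] = None,
    label: str = "",
    **plateau_kwargs,
) -> TransitionThermo:
    """Full plateau-transition pipeline over a multi-temperature family.

    Composes plateau detection → π_t extraction → least-squares π_t(T)
    slope → per-temperature ΔH_t/ΔS_t.  ``slope`` overrides the fitted
    value in the Clausius–Clapeyron step (useful when an externally
    tabulated slope should be replayed; the small difference between a
    fitted and a rounded slope can shift ΔH_t appreciably when dπ_t/dT is
    close to dγ/dT).  Extra keyword arguments reach ``detect_plateau``.
    """
    missing = []
    entries: list[tuple[float, PlateauFeature]] = []
    for i, iso in enumerate(family):
        feat = detect_plateau(iso, **plateau_kwargs)
        if feat is None:
            missing.append(iso.label or f"isotherm #{i} (T={iso.temperature} K)")
        else:
            entries.append((iso.temperature, feat))
    if missing:
        raise ValueError("no plateau detected in: " + ", ".join(missing))
    entries.sort(key=lambda e: e[0])
    series = TransitionSeries(entries=entries, label=label)
    fitted = fit_pit_slope(series)
    used = fitted if slope is None else slope
    result = TransitionThermo(dpi_dT=fitted, slope_used=used, dgamma_dT=dgamma_dT)
    for T, feat in entries:
        dH = clausius_clapeyron_enthalpy(T, feat.A_b, feat.A_e, used, dgamma_dT)
        result.entries.append(
            TransitionEntry(temperature=T, plateau=feat, dH_t=dH, dS_t=transition_entropy(dH, T))
        )
    return result
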