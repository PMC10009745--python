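"""Published reference values for chain-oxidised sterol monolayers.

Literature Langmuir-trough results for 25-hydroxycholesterol (``25-OH``)
and 27-hydroxycholesterol (``27-OH``) films on water, used as worked
examples and as replay inputs for the thermodynamic pipeline:

* ``PLATEAU_ROWS`` — per-temperature pseudo-plateau characteristics read
  from compression isotherms: the areas (Å²/molecule) and pressures
  (mN/m) at the beginning (``A_b``, ``pi_b``) and end (``A_e``, ``pi_e``)
  of the plateau.
* ``PRINTED_SLOPES`` — the published dπ_t/dT values (mN m⁻¹ K⁻¹).
* ``HYSTERESIS_ROWS`` — per-cycle hysteresis thermodynamics at 20 °C:
  ΔG^hys (kJ/mol), ΔS^hys (J/(mol·K)) and ΔH^hys (kJ/mol) for three
  consecutive compression–expansion cycles.

These numbers are experimental inputs, not outputs of this package; the
pipeline recomputes the derived columns (π_t, slope, ΔH_t, ΔS_t, ΔH^hys)
from them.
"""

from __future__ import annotations

from .features import PlateauFeature
from .transition import TransitionSeries

__all__ = [
    "PLATEAU_ROWS",
    "PRINTED_SLOPES",
    "HYSTERESIS_ROWS",
    "plateau_series",
]

# columns: T [K], A_b, A_e [Å²/molecule], pi_b, pi_e [mN/m]
PLATEAU_ROWS: dict[str, list[tuple[float, float, float, float, float]]] = {
    "25-OH": [
        (283.0, 33.85, 25.34, 36.42, 36.75),
        (288.0, 33.99, 26.06, 34.91, 35.61),
        (293.0, 34.76, 30.14, 31.53, 31.53),
        (298.0, 35.41, 31.88, 30.61, 30.96),
        (303.0, 37.14, 33.96, 26.37, 26.59),
        (308.0, 37.36, 35.29, 25.36, 25.62),
    ],
    "27-OH": [
        (283.0, 37.94, 22.23, 20.24, 21.32),
        (293.0, 38.01, 25.41, 19.06, 19.58),
        (303.0, 39.11, 25.33, 17.34, 18.04),
        (308.0, 39.75, 26.94, 16.85, 17.36),
    ],
}

# published dπ_t/dT [mN/(m K)]
PRINTED_SLOPES: dict[str, float] = {"25-OH": -0.472, "27-OH": -0.150}

# columns: cycle index, ΔG^hys [kJ/mol], ΔS^hys [J/(mol K)], ΔH^hys [kJ/mol]
HYSTERESIS_ROWS: dict[str, list[tuple[int, float, float, float]]] = {
    "27-OH": [
        (1, -1.83, -2.76, -2.64),
        (2, -1.96, -3.12, -2.87),
        (3, -2.00, -3.51, -3.03),
    ],
    "25-OH": [
        (1, -2.85, -3.70, -3.94),
        (2, -0.45, -0.74, -0.67),
        (3, -0.42, -0.70, -0.63),
    ],
}


def plateau_series(compound: str) -> TransitionSeries:
    """Build a :class:`TransitionSeries` from the published plateau rows.

    The plateau's edge pressures cross only slightly (π_e − π_b of a few
    tenths of mN/m), so the derived π_t values reproduce the published
    midpoints exactly.
    """
    rows = PLATEAU_ROWS[compound]
    entries = [
        (T, PlateauFeature.from_bounds(A_b=A_b, A_e=A_e, pi_b=pi_b, pi_e=pi_e))
        for T, A_b, A_e, pi_b, pi_e in rows
    ]
    return TransitionSeries(entries=entries, label=compound)
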