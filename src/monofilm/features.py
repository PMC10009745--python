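"""Feature extraction from π–A isotherms.

Implements the standard descriptors used to characterise a Langmuir film:

* the surface compressional modulus C_s⁻¹ = −A·(dπ/dA) and the phase-state
  classification derived from its magnitude,
* the lift-off area (onset of the surface-pressure rise on compression),
* the collapse point (discontinuity of the first derivative of π–A),
* the pseudo-plateau of a first-order-like transition, with its boundary
  points (A_b, π_b), (A_e, π_e) and midpoint pressure π_t = (π_b + π_e)/2.

Derivatives are taken on a Savitzky–Golay smoothed curve; a window of 3
degenerates to plain central differences, which is what exact synthetic
tests should use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .isotherms import COMPRESSION, Isotherm

__all__ = [
    "PlateauFeature",
    "ModulusCurve",
    "compression_modulus",
    "classify_state",
    "detect_liftoff",
    "detect_collapse",
    "detect_plateau",
]

log = logging.getLogger(__name__)

#: Phase labels keyed by the C_s⁻¹ ranges of the classical compressibility
#: scheme; the unnamed gaps (50–100 and 250–500 mN/m) are ``intermediate``.
LOW_DENSITY_LIQUID = "low-density-liquid"
LIQUID_EXPANDED = "liquid-expanded"
LIQUID_CONDENSED = "liquid-condensed"
SOLID = "solid"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class PlateauFeature:
    """Boundary points and midpoint pressure of a detected pseudo-plateau.

    ``A_b``/``π_b`` mark the beginning (larger area), ``A_e``/``π_e`` the
    end of the plateau; ``pi_t`` is exactly the arithmetic mean of the two
    boundary pressures.
    """

    A_b: float
    A_e: float
    pi_b: float
    pi_e: float
    pi_t: float

    def __post_init__(self) -> None:
        if not self.A_e < self.A_b:
            raise ValueError(f"plateau requires A_e < A_b, got {self.A_e} >= {self.A_b}")
        if self.pi_b > self.pi_e:
            raise ValueError(f"plateau requires pi_b <= pi_e, got {self.pi_b} > {self.pi_e}")
        if self.pi_t != (self.pi_b + self.pi_e) / 2.0:
            raise ValueError("pi_t must equal (pi_b + pi_e)/2 exactly")

    @classmethod
    def from_bounds(cls, A_b: float, A_e: float, pi_b: float, pi_e: float) -> "PlateauFeature":
        return cls(A_b, A_e, pi_b, pi_e, (pi_b + pi_e) / 2.0)


@dataclass
class ModulusCurve:
    """C_s⁻¹ sampled on the (canonical) area grid of the source isotherm."""

    area: np.ndarray
    modulus: np.ndarray


def _canonical_compression(iso: Isotherm) -> Isotherm:
    iso = iso.canonical()
    if iso.direction != COMPRESSION:
        raise ValueError("operation requires a compression branch")
    return iso


def _smoothed_slope(area: np.ndarray, pressure: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """dπ/dA on the sample grid, after optional Savitzky–Golay smoothing.

    The grid is assumed near-uniform for the smoothing step (true of
    trough exports); the gradient itself uses the actual abscissae.
    """
    if window > 3 and len(pressure) >= window:
        pressure = savgol_filter(pressure, window, min(polyorder, window - 1))
    return np.gradient(pressure, area)


def compression_modulus(iso: Isotherm, window: int = 7, polyorder: int = 2) -> ModulusCurve:
    """Surface compressional modulus C_s⁻¹ = −A·(dπ/dA) along the branch.

    Interior points use (smoothed) central differences; the endpoints fall
    back to one-sided differences via ``np.gradient``.
    """
    iso = iso.canonical()
    if len(iso) < 5:
        raise ValueError("compression_modulus needs at least 5 points")
    d = np.diff(iso.area)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("area must be strictly monotone after canonicalization")
    slope = _smoothed_slope(iso.area, iso.pressure, window, polyorder)
    return ModulusCurve(area=iso.area.copy(), modulus=-iso.area * slope)


def classify_state(modulus: float) -> str:
    """Phase label from the magnitude of C_s⁻¹ (mN/m).

    Below 25: low-density liquid; 25–50: liquid-expanded; 100–250:
    liquid-condensed; above 500: solid.  The scheme leaves the ranges
    50–100 and 250–500 unnamed; they are reported as ``intermediate``.
    """
    if modulus < 0:
        raise ValueError("modulus must be non-negative")
    if modulus < 25:
        return LOW_DENSITY_LIQUID
    if modulus <= 50:
        return LIQUID_EXPANDED
    if modulus < 100:
        return INTERMEDIATE
    if modulus <= 250:
        return LIQUID_CONDENSED
    if modulus <= 500:
        return INTERMEDIATE
    return SOLID


def detect_liftoff(iso: Isotherm, threshold: float = 0.5, k: int = 5) -> Optional[float]:
    """Lift-off area: onset of the surface-pressure rise on compression.

    Returns the largest area at which π first exceeds ``threshold`` and
    stays above it for ``k`` consecutive samples (guarding against
    single-point noise), or ``None`` if the pressure never lifts.
    """
    iso = _canonical_compression(iso)
    above = iso.pressure > threshold
    n = len(above)
    for i in range(n - k + 1):
        if bool(np.all(above[i : i + k])):
            return float(iso.area[i])
    return None


def _windowed_slopes(area: np.ndarray, pressure: np.ndarray, w: int):
    """Left/right local linear-fit slopes around every interior sample.

    ``left[i]`` fits samples [i−w, i], ``right[i]`` fits [i, i+w]; the
    slope jump ``right − left`` peaks exactly at a piecewise-linear kink.
    """
    n = len(area)
    left = np.full(n, np.nan)
    right = np.full(n, np.nan)
    for i in range(n):
        if i >= w:
            a, p = area[i - w : i + 1], pressure[i - w : i + 1]
            left[i] = np.polyfit(a, p, 1)[0]
        if i + w < n:
            a, p = area[i : i + w + 1], pressure[i : i + w + 1]
            right[i] = np.polyfit(a, p, 1)[0]
    return left, right


def detect_collapse(
    iso: Isotherm,
    w: int = 8,
    jump_fraction: float = 0.5,
    min_pressure: float = 1.0,
) -> Optional[tuple[float, float]]:
    """Collapse point (π_c, A_c) from the slope discontinuity of π–A.

    Collapse is a film-failure kink: on compression, |dπ/dA| drops
    abruptly once 3D aggregates relieve the pressure.  Local slopes are
    fitted on ``w``-sample windows on each side of every point; a kink
    qualifies when the softening jump exceeds ``jump_fraction`` of the
    median slope magnitude.  Among qualifying kinks the one at the highest
    pressure is reported, which separates collapse from the (lower-lying)
    plateau edges.  Returns ``None`` for a smooth branch.
    """
    iso = _canonical_compression(iso)
    if len(iso) < 9:
        raise ValueError("detect_collapse needs at least 9 points")
    left, right = _windowed_slopes(iso.area, iso.pressure, w)
    # canonical compression: area decreasing, dπ/dA < 0 in the rising film.
    # "left" windows are at larger area (earlier), "right" at smaller.
    jump = right - left  # softening: slope moves toward 0 => jump > 0
    # reference the steep end of the slope distribution: the shallow
    # post-collapse (or plateau) segment must not drag the scale down
    mags = np.abs(np.concatenate([left[~np.isnan(left)], right[~np.isnan(right)]]))
    scale = float(np.percentile(mags, 90))
    if not np.isfinite(scale) or scale == 0:
        return None
    ok = (jump > jump_fraction * scale) & (iso.pressure > min_pressure)
    if not np.any(ok):
        return None
    idx = np.nonzero(ok)[0]
    # restrict to the highest-pressure cluster of qualifying points, then
    # take the sharpest kink within it
    top = idx[iso.pressure[idx] > iso.pressure[idx].max() - 2.0]
    best = top[np.argmax(jump[top])]
    return float(iso.pressure[best]), float(iso.area[best])


def _snap_to_intersection(area, pressure, plateau_coef, idx, side, m, lo, hi):
    """Snap a plateau-boundary index to the sample nearest the crossing of
    the plateau line and the flanking steep line (fitted on up to ``m``
    samples just outside the boundary).  Falls back to ``idx`` when the
    flank is too short or the lines are near-parallel."""
    if side < 0:
        j0, j1 = max(lo, idx - m), idx - 1
    else:
        j0, j1 = idx + 1, min(hi, idx + m)
    if j1 - j0 < 2:
        return idx
    flank = np.polyfit(area[j0 : j1 + 1], pressure[j0 : j1 + 1], 1)
    denom = flank[0] - plateau_coef[0]
    if abs(denom) < 1e-12:
        return idx
    x_cross = (plateau_coef[1] - flank[1]) / denom
    window_idx = np.arange(max(lo, idx - m), min(hi, idx + m) + 1)
    snapped = int(window_idx[np.argmin(np.abs(area[window_idx] - x_cross))])
    return snapped


def detect_plateau(
    iso: Isotherm,
    slope_fraction: float = 0.15,
    window: int = 7,
    polyorder: int = 2,
    liftoff_threshold: float = 0.5,
) -> Optional[PlateauFeature]:
    """Detect the pseudo-plateau of a monolayer→bilayer-like transition.

    Looks for the longest contiguous run of samples (within the lifted
    part of the branch) whose slope magnitude falls below
    ``slope_fraction`` × the median slope magnitude, flanked by steep
    regions on both sides.  The boundary samples themselves are reported
    as (A_b, π_b) and (A_e, π_e); π_t is their mean.  There is no
    universally agreed numeric criterion for "plateau"; 0.15 is this
    package's operational default and is fully configurable.
    """
    iso = _canonical_compression(iso)
    if len(iso) < 9:
        return None
    slope = _smoothed_slope(iso.area, iso.pressure, window, polyorder)
    lifted = np.nonzero(iso.pressure > liftoff_threshold)[0]
    if len(lifted) < 5:
        return None
    lo, hi = lifted[0], lifted[-1]
    mag = np.abs(slope[lo : hi + 1])
    # First pass: a coarse threshold against the steep end of the slope
    # distribution picks out candidate flat runs without assuming how much
    # of the branch the plateau occupies.
    steep_scale = float(np.percentile(mag, 90))
    if steep_scale == 0:
        return None
    flat = mag < slope_fraction * steep_scale
    # longest run of flat samples strictly inside the lifted region
    best_run: Optional[tuple[int, int]] = None
    i = 0
    while i < len(flat):
        if flat[i]:
            j = i
            while j + 1 < len(flat) and flat[j + 1]:
                j += 1
            if i > 0 and j < len(flat) - 1:  # flanked by steep regions
                if best_run is None or j - i > best_run[1] - best_run[0]:
                    best_run = (i, j)
            i = j + 1
        else:
            i += 1
    if best_run is None or best_run[1] - best_run[0] < 2:
        return None
    # Second pass: the reference slope is the median of the rise *before*
    # the run (the condensed ascent), and the run is regrown around its
    # centre against the refined threshold.
    pre = mag[: best_run[0]]
    pre_steep = pre[pre >= slope_fraction * steep_scale]
    med = float(np.median(pre_steep)) if len(pre_steep) >= 3 else steep_scale
    thr_fine = slope_fraction * med
    centre = (best_run[0] + best_run[1]) // 2
    b_rel, e_rel = centre, centre
    # an isolated noise spike in the smoothed slope must not end the run:
    # stop only on two consecutive above-threshold samples
    while b_rel - 1 > 0:
        if mag[b_rel - 1] >= thr_fine and (b_rel - 2 <= 0 or mag[b_rel - 2] >= thr_fine):
            break
        b_rel -= 1
    while e_rel + 1 < len(mag) - 1:
        if mag[e_rel + 1] >= thr_fine and (
            e_rel + 2 >= len(mag) - 1 or mag[e_rel + 2] >= thr_fine
        ):
            break
        e_rel += 1
    if e_rel - b_rel < 2:
        return None
    b, e = b_rel + lo, e_rel + lo
    # The smoothed slope mixes neighbouring segments over roughly half a
    # window around each edge, which pulls the detected run inside the
    # true plateau.  Walk each boundary back out while the sample still
    # lies on the plateau line (fitted to the run interior), i.e. until it
    # deviates beyond the fit's own noise level.
    pad = max(window // 2, 1)
    ib, ie = b + pad, e - pad
    if ie - ib < 2:
        ib, ie = b, e
    coef = np.polyfit(iso.area[ib : ie + 1], iso.pressure[ib : ie + 1], 1)
    resid = iso.pressure[ib : ie + 1] - np.polyval(coef, iso.area[ib : ie + 1])
    tol = max(4.0 * float(np.std(resid)), 1e-6)
    steps = 2 * max(window, 3)
    b0, e0 = b, e
    while b > lo and b0 - b < steps:
        nxt = abs(iso.pressure[b - 1] - np.polyval(coef, iso.area[b - 1])) >= tol
        nxt2 = b < 2 or abs(iso.pressure[b - 2] - np.polyval(coef, iso.area[b - 2])) >= tol
        if nxt and nxt2:  # two consecutive off-line samples end the plateau
            break
        b -= 1
    while e < hi and e - e0 < steps:
        nxt = abs(iso.pressure[e + 1] - np.polyval(coef, iso.area[e + 1])) >= tol
        nxt2 = e + 2 > hi or abs(iso.pressure[e + 2] - np.polyval(coef, iso.area[e + 2])) >= tol
        if nxt and nxt2:
            break
        e += 1
    # Snap each boundary to the sample nearest the intersection of the
    # plateau line with a line fitted to the flanking steep segment; the
    # intersection localises the edge well below the grid spacing even
    # under noise, while the reported boundary stays a point of the record.
    m = max(window, 5)
    b = _snap_to_intersection(iso.area, iso.pressure, coef, b, -1, m, lo, hi)
    e = _snap_to_intersection(iso.area, iso.pressure, coef, e, +1, m, lo, hi)
    if e - b < 2:
        return None
    pi_pair = (float(iso.pressure[b]), float(iso.pressure[e]))
    return PlateauFeature.from_bounds(
        A_b=float(iso.area[b]),
        A_e=float(iso.area[e]),
        pi_b=min(pi_pair),
        pi_e=max(pi_pair),
    )
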