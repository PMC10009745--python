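"""Synthetic data with planted ground truth for every analysis stage.

The generators emulate the phenomenology of condensed-type sterol
monolayers on water without any equation-of-state physics:

* :func:`gen_isotherm` — piecewise π–A compression branch: zero pressure
  above the lift-off area, a steep condensed rise, an optional near-flat
  pseudo-plateau whose midpoint pressure follows a planted linear
  temperature law π_t(T) = π_p0 + (dπ_t/dT)·(T − T0), a post-plateau rise
  with a lesser slope, and a slope break at collapse; optional additive
  Gaussian noise under a fixed seed.
* :func:`gen_family` — one isotherm per temperature sharing the planted
  plateau law (the raw material for Clausius–Clapeyron recovery tests).
* :func:`gen_cycle` — compression branch plus an expansion branch shifted
  to smaller areas, with the enclosed ∫(A_comp − A_exp)dπ over the
  integration window returned as analytic ground truth.
* :func:`gen_snapshot` — two leaflets of rod-like bipolar pseudo-sterols
  flanking a geometric water slab, placed on a jittered lattice at a
  planted tilt, with an exact number of hydrogen-bonded cross-leaflet
  pairs (O···O = 2.8 Å, angle 160°) and every other hydroxyl pair kept
  at least 3.5 Å apart.

Everything is deterministic under a fixed seed, and every planted value
is recoverable by the corresponding analysis operator — that closed loop
is the module's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .hysteresis import DEFAULT_PI1, DEFAULT_PI2, HysteresisCycle
from .isotherms import COMPRESSION, EXPANSION, Isotherm
from .mdgeom import LeafletSnapshot
from .units import per_molecule_to_molar

__all__ = [
    "PlateauSpec",
    "IsothermSpec",
    "SnapshotSpec",
    "gen_isotherm",
    "isotherm_ground_truth",
    "gen_family",
    "gen_cycle",
    "gen_snapshot",
]


@dataclass(frozen=True)
class PlateauSpec:
    """Planted pseudo-plateau: midpoint law and geometry.

    ``pi_p0`` is the midpoint pressure at the reference temperature
    ``T0``; the midpoint moves linearly with ``dpi_dT``.  ``width`` is the
    plateau extent in area and ``residual_rise`` the small positive
    π_e − π_b a real plateau shows (a few tenths of mN/m).
    """

    pi_p0: float = 20.0
    dpi_dT: float = -0.15
    width: float = 15.0
    residual_rise: float = 0.6
    T0: float = 293.15


@dataclass(frozen=True)
class IsothermSpec:
    """Planted piecewise isotherm; defaults sketch a bipolar-sterol film.

    Slopes are magnitudes in mN/m per Å² (the generated π increases as A
    decreases).  The defaults give a lift-off near 44 Å²/molecule, a
    plateau around 20 mN/m and collapse at 40 mN/m — the scale of a
    27-hydroxycholesterol-like film.
    """

    a_lift: float = 44.0
    condensed_slope: float = 3.3
    plateau: Optional[PlateauSpec] = PlateauSpec()
    post_plateau_slope: float = 2.5
    collapse_pi: float = 40.0
    post_collapse_slope: float = 0.3
    a_min: float = 12.0
    a_margin: float = 5.0
    grid_step: float = 0.05
    noise_sigma: float = 0.0
    temperature: float = 293.15
    seed: int = 0


def _piecewise(spec: IsothermSpec):
    """Breakpoints of the noiseless branch; raises on inconsistent specs."""
    gt: dict = {"a_lift": spec.a_lift}
    if spec.plateau is not None:
        p = spec.plateau
        pi_t = p.pi_p0 + p.dpi_dT * (spec.temperature - p.T0)
        pi_b = pi_t - p.residual_rise / 2.0
        pi_e = pi_t + p.residual_rise / 2.0
        if pi_e >= spec.collapse_pi:
            raise ValueError("inconsistent spec: plateau at or above collapse pressure")
        if pi_b <= 0:
            raise ValueError("inconsistent spec: plateau pressure not positive")
        a_b = spec.a_lift - pi_b / spec.condensed_slope
        a_e = a_b - p.width
        a_c = a_e - (spec.collapse_pi - pi_e) / spec.post_plateau_slope
        gt.update(A_b=a_b, A_e=a_e, pi_b=pi_b, pi_e=pi_e, pi_t=pi_t)
    else:
        a_c = spec.a_lift - spec.collapse_pi / spec.condensed_slope
    if a_c <= spec.a_min:
        raise ValueError("inconsistent spec: collapse below the smallest sampled area")
    gt.update(pi_c=spec.collapse_pi, A_c=a_c)
    return gt


def _pressure_at(area: np.ndarray, spec: IsothermSpec, gt: dict) -> np.ndarray:
    pi = np.zeros_like(area)
    rise = area < spec.a_lift
    pi[rise] = spec.condensed_slope * (spec.a_lift - area[rise])
    if spec.plateau is not None:
        p = spec.plateau
        a_b, a_e, pi_b, pi_e = gt["A_b"], gt["A_e"], gt["pi_b"], gt["pi_e"]
        on = (area <= a_b) & (area >= a_e)
        pi[on] = pi_b + (pi_e - pi_b) * (a_b - area[on]) / p.width
        post = area < a_e
        pi[post] = pi_e + spec.post_plateau_slope * (a_e - area[post])
    collapsed = pi > spec.collapse_pi
    a_c = gt["A_c"]
    pi[collapsed] = spec.collapse_pi + spec.post_collapse_slope * (a_c - area[collapsed])
    return pi


def gen_isotherm(spec: IsothermSpec) -> Isotherm:
    """Generate one compression branch from a planted piecewise law."""
    gt = _piecewise(spec)
    a_max = spec.a_lift + spec.a_margin
    area = np.arange(a_max, spec.a_min, -spec.grid_step)
    pi = _pressure_at(area, spec, gt)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pi = pi + rng.normal(0.0, spec.noise_sigma, size=pi.shape)
    return Isotherm(
        area=area,
        pressure=pi,
        temperature=spec.temperature,
        direction=COMPRESSION,
        label=f"synthetic T={spec.temperature:g}K seed={spec.seed}",
    )


def isotherm_ground_truth(spec: IsothermSpec) -> dict:
    """Planted feature values of :func:`gen_isotherm` for the same spec."""
    return _piecewise(spec)


def gen_family(spec: IsothermSpec, temperatures: Sequence[float]) -> list[Isotherm]:
    """One isotherm per temperature under the planted plateau law.

    Per-temperature noise streams are derived from ``spec.seed`` through a
    :class:`numpy.random.SeedSequence` spawn, so families with different
    base seeds are independent while each family is reproducible.
    """
    if spec.plateau is None:
        raise ValueError("gen_family requires a plateau in the spec")
    children = np.random.SeedSequence(spec.seed).spawn(len(temperatures))
    out = []
    for T, child in zip(temperatures, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(gen_isotherm(replace(spec, temperature=T, seed=sub_seed)))
    return out


def gen_cycle(
    spec: IsothermSpec,
    offset: Union[float, Callable[[np.ndarray], np.ndarray]] = 5.0,
    pi1: float = DEFAULT_PI1,
    pi2: float = DEFAULT_PI2,
    cycle_index: int = 1,
) -> tuple[HysteresisCycle, float]:
    """Compression branch plus an area-shifted expansion branch.

    ``offset`` is the rigid shift toward smaller areas (Å²), or a callable
    of π returning the shift per sample.  Returns the cycle together with
    the analytic |∫(A_comp − A_exp) dπ| over [pi1, pi2] in kJ/mol — the
    closed-form magnitude that ``hysteresis_free_energy`` must recover
    (with a negative sign under its convention).
    """
    comp = gen_isotherm(spec)
    pi_clean = _pressure_at(comp.area, spec, _piecewise(spec))
    if callable(offset):
        shift = np.asarray(offset(pi_clean), dtype=float)
    else:
        shift = np.full_like(comp.area, float(offset))
    if np.any(shift < 0):
        raise ValueError("offset must be non-negative")
    exp_area = comp.area - shift
    if np.any(exp_area <= 0):
        raise ValueError("offset makes expansion areas non-positive")
    expansion = Isotherm(
        area=exp_area[::-1],
        pressure=comp.pressure[::-1],
        temperature=spec.temperature,
        direction=EXPANSION,
        label=comp.label + " expansion",
    )
    # analytic enclosed area over the window, on the noiseless curve
    order = np.argsort(pi_clean)
    pi_s = pi_clean[order]
    shift_s = shift[order]
    keep = np.ones(len(pi_s), bool)
    keep[1:] = np.diff(pi_s) > 0
    pi_s, shift_s = pi_s[keep], shift_s[keep]
    grid = np.concatenate(([pi1], pi_s[(pi_s > pi1) & (pi_s < pi2)], [pi2]))
    sh = np.interp(grid, pi_s, shift_s)
    truth = per_molecule_to_molar(float(np.trapezoid(sh, grid)))
    cycle = HysteresisCycle(
        compression=comp, expansion=expansion, cycle_index=cycle_index,
        temperature=spec.temperature,
    )
    return cycle, truth


# ---------------------------------------------------------------------------
# snapshots


@dataclass(frozen=True)
class SnapshotSpec:
    """Planted two-leaflet slab of rod-like bipolar pseudo-sterols.

    Each molecule is a rod: waterward hydroxyl (O + H), ``n_beads``
    backbone beads, outward hydroxyl (O + H).  ``head_fraction`` of the
    molecules (exactly, after rounding) present the head (C(3)-OH-like)
    hydroxyl to the water slab; the rest are flipped.  ``n_bonded_pairs``
    cross-leaflet hydrogen bonds are planted with exact geometry
    (O···O = 2.8 Å, D–H···A angle 160°).
    """

    n_per_leaflet: int = 128
    lattice_spacing: float = 6.05
    planted_tilt: float = 0.0
    n_bonded_pairs: int = 0
    head_fraction: float = 0.55
    water_halfwidth: float = 2.0
    contact_gap: float = 0.2
    n_beads: int = 6
    bead_spacing: float = 1.5
    oh_length: float = 0.97
    jitter: float = 0.03
    box_z: float = 60.0
    seed: int = 0


def _hbond_hydrogen_position(d_pos: np.ndarray, a_pos: np.ndarray, r_oh: float, angle_deg: float) -> np.ndarray:
    """Place H on the D–A axis plane so that |D−H| = r_oh and the
    D–H···A angle equals ``angle_deg``."""
    da = a_pos - d_pos
    r_da = np.linalg.norm(da)
    u = da / r_da
    # perpendicular unit vector
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = trial - (trial @ u) * u
    v /= np.linalg.norm(v)
    theta = np.radians(angle_deg)
    # law of cosines: r_da² = r_oh² + r_ha² − 2 r_oh r_ha cosθ
    r_ha = r_oh * np.cos(theta) + np.sqrt(r_da**2 - (r_oh * np.sin(theta)) ** 2)
    cos_at_d = (r_oh**2 + r_da**2 - r_ha**2) / (2 * r_oh * r_da)
    sin_at_d = np.sqrt(max(0.0, 1.0 - cos_at_d**2))
    return d_pos + r_oh * (cos_at_d * u + sin_at_d * v)


def gen_snapshot(spec: SnapshotSpec) -> LeafletSnapshot:
    """Construct the snapshot; see :class:`SnapshotSpec` for the knobs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_leaflet
    if spec.n_bonded_pairs > n:
        raise ValueError("cannot plant more bonded pairs than molecules per leaflet")
    if spec.lattice_spacing < 3.6:
        raise ValueError("overcrowded box: lattice spacing under the 3.5 Å separation floor")
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    lx, ly = nx * spec.lattice_spacing, ny * spec.lattice_spacing
    box = np.array([lx, ly, spec.box_z])
    n_total = 2 * n
    n_head = int(round(spec.head_fraction * n_total))
    head_flags = np.zeros(n_total, bool)
    head_flags[rng.permutation(n_total)[:n_head]] = True

    rod_len = spec.bead_spacing * (spec.n_beads + 1)
    n_atoms_mol = 2 * 2 + spec.n_beads  # O,H + beads + O,H
    coords = np.zeros((n_total * n_atoms_mol, 3))
    mol_id = np.repeat(np.arange(n_total), n_atoms_mol)
    leaflet = np.full(n_total * n_atoms_mol, "", dtype=object)
    is_donor = np.zeros(n_total * n_atoms_mol, bool)
    is_acceptor = np.zeros(n_total * n_atoms_mol, bool)
    is_polar_h = np.zeros(n_total * n_atoms_mol, bool)
    parent = np.full(n_total * n_atoms_mol, -1, int)
    anchor = np.full(n_total * n_atoms_mol, "", dtype=object)

    z_contact_low = -(spec.water_halfwidth + spec.contact_gap)
    z_contact_high = spec.water_halfwidth + spec.contact_gap
    theta = np.radians(spec.planted_tilt)
    # collective tilt: one azimuth per leaflet, as in a tilted condensed
    # phase; per-molecule azimuths would let neighbouring rods collide
    leaflet_phi = rng.uniform(0, 2 * np.pi, size=2)

    for m in range(n_total):
        in_lower = m < n
        site = m if in_lower else m - n
        gx, gy = site % nx, site // nx
        base_xy = np.array(
            [(gx + 0.5) * spec.lattice_spacing, (gy + 0.5) * spec.lattice_spacing]
        )
        phi = leaflet_phi[0 if in_lower else 1]
        tilt_dir = np.array([np.cos(phi) * np.sin(theta), np.sin(phi) * np.sin(theta), np.cos(theta)])
        axis = -tilt_dir if in_lower else tilt_dir  # away from the water
        z0 = z_contact_low if in_lower else z_contact_high
        o_water = np.array([base_xy[0], base_xy[1], z0])
        # atoms along the axis: waterward O, H (lateral), beads, outward O, H
        i0 = m * n_atoms_mol
        coords[i0] = o_water
        coords[i0 + 1] = o_water + np.array([spec.oh_length, 0.0, 0.0])
        for b in range(spec.n_beads):
            coords[i0 + 2 + b] = o_water + axis * spec.bead_spacing * (b + 1)
        o_out = o_water + axis * rod_len
        coords[i0 + 2 + spec.n_beads] = o_out
        coords[i0 + 3 + spec.n_beads] = o_out + np.array([spec.oh_length, 0.0, 0.0])
        leaflet[i0 : i0 + n_atoms_mol] = "lower" if in_lower else "upper"
        for oi, hi in ((i0, i0 + 1), (i0 + 2 + spec.n_beads, i0 + 3 + spec.n_beads)):
            is_donor[oi] = is_acceptor[oi] = True
            is_polar_h[hi] = True
            parent[hi] = oi
        head_waterward = head_flags[m]
        anchor[i0] = "head" if head_waterward else "chain"
        anchor[i0 + 2 + spec.n_beads] = "chain" if head_waterward else "head"

    if spec.jitter > 0:
        coords += rng.normal(0.0, spec.jitter, size=coords.shape)

    # plant cross-leaflet bonds: donor = lower molecule k's waterward O,
    # acceptor = upper molecule k's waterward O, translated to exact geometry
    for k in range(spec.n_bonded_pairs):
        d_mol, a_mol = k, k + n
        d_o = d_mol * n_atoms_mol
        a_o = a_mol * n_atoms_mol
        target = coords[d_o] + np.array([0.0, 0.0, 2.8])
        shift = target - coords[a_o]
        coords[a_o : a_o + n_atoms_mol] += shift
        coords[d_o + 1] = _hbond_hydrogen_position(coords[d_o], coords[a_o], spec.oh_length, 160.0)
        # keep both hydroxyl hydrogens of the pair lateral so neither forms
        # a second qualifying geometry
        coords[a_o + 1] = coords[a_o] + np.array([spec.oh_length, 0.0, 0.0])

    return LeafletSnapshot(
        coords=coords,
        box=box,
        periodic=(True, True, False),
        mol_id=mol_id,
        leaflet=leaflet,
        is_donor=is_donor,
        is_acceptor=is_acceptor,
        is_polar_h=is_polar_h,
        parent_donor=parent,
        anchor=anchor,
        water_slab=(-spec.water_halfwidth, spec.water_halfwidth),
    )
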