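"""Geometric analysis of monolayer/bilayer leaflet snapshots.

Operates post hoc on molecular coordinate snapshots (Å) annotated with a
topology that assigns every atom to a molecule and a hydrogen-bond role.
Provided operators:

* hydrogen-bond census under the geometric criterion: donor–acceptor
  heavy-atom distance strictly below 3.0 Å and donor–hydrogen–acceptor
  angle (vertex at the hydrogen) of at least 135°, with minimum-image
  distances in the periodic directions;
* persistence filtering of bonds across frames (identity = donor heavy
  atom / acceptor heavy atom, so rotating hydroxyl hydrogens do not break
  a bond's identity);
* molecular tilt angles relative to an interface normal;
* area per lipid, anchoring classification of bipolar amphiphiles,
  density profiles and radial distribution functions.

Coordinates are read from PDB files (one frame per MODEL record) through
biotite; the topology travels as a JSON sidecar keyed by atom serial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "LeafletSnapshot",
    "HBond",
    "detect_hbonds",
    "persistent_hbonds",
    "tilt_angle",
    "area_per_lipid",
    "anchoring_fractions",
    "density_profile",
    "rdf",
    "read_snapshots",
    "write_snapshots",
]

HBOND_DISTANCE_MAX = 3.0  # Å, strict upper bound on donor–acceptor distance
HBOND_ANGLE_MIN = 135.0  # degrees, inclusive lower bound at the hydrogen


@dataclass
class LeafletSnapshot:
    """Annotated coordinate snapshot of a two-leaflet slab.

    Attributes
    ----------
    coords : (N, 3) float array, Å.
    box : (3,) box edge lengths, Å.
    periodic : per-axis periodicity flags; slab geometry is periodic in
        x, y only by default.
    mol_id : (N,) molecule index per atom.
    leaflet : (N,) leaflet tag per atom ("lower"/"upper" or similar).
    is_donor, is_acceptor : (N,) boolean role flags on heavy atoms; a
        hydroxyl oxygen is typically both.
    is_polar_h : (N,) boolean flag on polar hydrogens.
    parent_donor : (N,) atom index of the parent donor for each polar
        hydrogen, −1 elsewhere.
    anchor : (N,) anchor tag per atom ("" for none; conventionally
        "head" on the C(3)-OH oxygen and "chain" on the side-chain
        hydroxyl oxygen).
    water_slab : optional (z_lo, z_hi) interval standing in for the
        aqueous layer.
    """

    coords: np.ndarray
    box: np.ndarray
    mol_id: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, False)
    leaflet: Optional[np.ndarray] = None
    is_donor: Optional[np.ndarray] = None
    is_acceptor: Optional[np.ndarray] = None
    is_polar_h: Optional[np.ndarray] = None
    parent_donor: Optional[np.ndarray] = None
    anchor: Optional[np.ndarray] = None
    water_slab: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.mol_id = np.asarray(self.mol_id, dtype=int)
        n = len(self.coords)
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be a finite (N, 3) array")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.mol_id.shape != (n,):
            raise ValueError("mol_id must have one entry per atom")
        if self.is_polar_h is not None:
            if self.parent_donor is None:
                raise ValueError("polar hydrogens require parent_donor annotations")
            hs = np.nonzero(self.is_polar_h)[0]
            parents = self.parent_donor[hs]
            if np.any(parents < 0) or (
                self.is_donor is not None and not np.all(self.is_donor[parents])
            ):
                raise ValueError("every polar hydrogen needs exactly one parent donor-heavy atom")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def min_image(self, delta: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention along the periodic axes."""
        delta = np.array(delta, dtype=float, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.box[ax]
                delta[..., ax] -= L * np.round(delta[..., ax] / L)
        return delta


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond with its geometric descriptors."""

    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor–acceptor heavy-atom distance, Å (minimum image)
    angle: float  # donor–hydrogen–acceptor angle, degrees

    @property
    def identity(self) -> tuple[int, int]:
        return (self.donor, self.acceptor)


def detect_hbonds(
    snap: LeafletSnapshot,
    distance_max: float = HBOND_DISTANCE_MAX,
    angle_min: float = HBOND_ANGLE_MIN,
    include_intramolecular: bool = False,
) -> list[HBond]:
    """All hydrogen bonds satisfying the geometric criterion.

    The distance bound is strict (< ``distance_max``) and the angle bound
    inclusive (≥ ``angle_min``), with the angle measured at the hydrogen.
    Intramolecular pairs are excluded by default, since interfacial
    bonding between amphiphiles is what the census is after.
    """
    if snap.is_polar_h is None or snap.is_acceptor is None or snap.parent_donor is None:
        raise ValueError("snapshot lacks hydrogen-bond role annotations")
    hs = np.nonzero(snap.is_polar_h)[0]
    accs = np.nonzero(snap.is_acceptor)[0]
    bonds: list[HBond] = []
    if len(hs) == 0 or len(accs) == 0:
        return bonds
    a_pos = snap.coords[accs]  # (M, 3)
    for h in hs:
        d = int(snap.parent_donor[h])
        dvec = snap.min_image(a_pos - snap.coords[d])  # donor→acceptor
        dist = np.linalg.norm(dvec, axis=1)
        cand = dist < distance_max
        cand &= accs != d
        if not include_intramolecular:
            cand &= snap.mol_id[accs] != snap.mol_id[d]
        if not np.any(cand):
            continue
        hd = snap.min_image(snap.coords[d] - snap.coords[h])  # H→D
        ha = snap.min_image(a_pos[cand] - snap.coords[h])  # H→A
        cosang = (ha @ hd) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(hd))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for a_idx, dist_da, angle in zip(accs[cand], dist[cand], ang):
            if angle >= angle_min:
                bonds.append(
                    HBond(donor=d, hydrogen=int(h), acceptor=int(a_idx),
                          distance=float(dist_da), angle=float(angle))
                )
    return bonds


def persistent_hbonds(
    frames: Sequence[Iterable[HBond]], fraction: float = 0.8
) -> list[tuple[int, int]]:
    """Bond identities present in at least ``fraction`` of the frames.

    Identity is the (donor heavy atom, acceptor heavy atom) pair; the
    threshold is inclusive, so a bond seen in 8 of 10 frames passes a 0.8
    cut.  Raising the fraction can only shrink the result.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    counts: dict[tuple[int, int], int] = {}
    for frame in frames:
        for ident in {b.identity for b in frame}:
            counts[ident] = counts.get(ident, 0) + 1
    n = len(frames)
    # inclusive threshold; the small epsilon guards float representation
    # of fractions like 0.8 * 10
    need = fraction * n - 1e-9
    return sorted(ident for ident, c in counts.items() if c >= need)


def tilt_angle(coords: np.ndarray, normal: Sequence[float] = (0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, folded into [0°, 90°]) between a molecule's
    longitudinal axis and the interface normal.

    The longitudinal axis is the dominant principal axis of the
    (unweighted) second-moment tensor of the atom coordinates — a
    parameter-free, rotation-equivariant choice.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 atoms")
    centered = coords - coords.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate molecule: all atoms coincident")
    moment = centered.T @ centered
    w, v = np.linalg.eigh(moment)
    axis = v[:, -1]
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    cosang = abs(float(axis @ n))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def area_per_lipid(box_xy: Sequence[float], n_leaflet: int) -> float:
    """Mean in-plane area per molecule: Lx·Ly / n_leaflet (Å²)."""
    if n_leaflet <= 0:
        raise ValueError("n_leaflet must be positive")
    lx, ly = box_xy
    return float(lx) * float(ly) / n_leaflet


def anchoring_fractions(
    snap: LeafletSnapshot, water_slab: Optional[tuple[float, float]] = None
) -> dict[str, float]:
    """Fraction of molecules anchored in the water by each hydroxyl.

    A bipolar sterol can contact the aqueous layer with either its head
    (C(3)-OH) or its chain hydroxyl.  Per molecule, the anchor atom whose
    z lies closer to the water-slab midplane is taken as the anchoring
    group; an exact tie counts as head-anchored.  Returns fractions that
    sum to 1 over the tags present.
    """
    if snap.anchor is None:
        raise ValueError("snapshot lacks anchor annotations")
    slab = water_slab or snap.water_slab
    if slab is None:
        raise ValueError("no water slab interval given")
    mid = 0.5 * (slab[0] + slab[1])
    anchored = np.nonzero(snap.anchor != "")[0]
    per_mol: dict[int, dict[str, float]] = {}
    for i in anchored:
        per_mol.setdefault(int(snap.mol_id[i]), {})[str(snap.anchor[i])] = abs(
            snap.coords[i, 2] - mid
        )
    all_mols = set(int(m) for m in np.unique(snap.mol_id))
    missing = sorted(all_mols - set(per_mol))
    if missing:
        raise ValueError(f"molecules without anchor annotations: {missing}")
    counts: dict[str, int] = {}
    for dists in per_mol.values():
        best = min(dists.items(), key=lambda kv: (kv[1], kv[0] != "head"))
        counts[best[0]] = counts.get(best[0], 0) + 1
    total = sum(counts.values())
    fracs = {tag: c / total for tag, c in counts.items()}
    for tag in ("head", "chain"):
        fracs.setdefault(tag, 0.0)
    return fracs


def density_profile(
    coords: np.ndarray,
    box_length: float,
    axis: int = 2,
    bin_width: float = 1.0,
    weights: Optional[np.ndarray] = None,
):
    """Binned density along one box axis.

    Coordinates are folded into [0, L) first, so the histogram conserves
    the total weight exactly (Σ bins = N for count weighting).  Returns
    ``(edges, profile)`` with the profile in weight per bin.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = np.mod(np.asarray(coords, dtype=float)[:, axis], box_length)
    nbins = max(1, int(np.ceil(box_length / bin_width)))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    hist, _ = np.histogram(x, bins=edges, weights=weights)
    return edges, hist


def rdf(
    frames: Sequence[np.ndarray],
    box: Sequence[float],
    r_max: float,
    bin_width: float = 0.1,
    coords_b: Optional[Sequence[np.ndarray]] = None,
    periodic: tuple[bool, bool, bool] = (True, True, True),
):
    """Radial distribution function g(r) under minimum image.

    ``frames`` holds one (N, 3) selection per frame; a distinct second
    selection per frame may be supplied through ``coords_b``.  The
    histogram of pair distances is normalised against the ideal-gas
    expectation at the mean density of the B selection in the box, so a
    uniform configuration gives g ≈ 1.  ``r_max`` must not exceed half
    the smallest periodic box edge.
    """
    box = np.asarray(box, dtype=float)
    per_edges = box[np.asarray(periodic)]
    if len(per_edges) and r_max > per_edges.min() / 2 + 1e-9:
        raise ValueError("r_max exceeds half the smallest periodic box edge")
    if len(frames) == 0:
        raise ValueError("no frames given")
    nbins = int(np.ceil(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    hist = np.zeros(nbins)
    volume = float(np.prod(box))
    norm = 0.0
    for fi, a in enumerate(frames):
        a = np.asarray(a, dtype=float)
        b = a if coords_b is None else np.asarray(coords_b[fi], dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("empty selection")
        delta = b[None, :, :] - a[:, None, :]
        for ax in range(3):
            if periodic[ax]:
                L = box[ax]
                delta[..., ax] -= L * np.round(delta[..., ax] / L)
        dist = np.linalg.norm(delta, axis=-1)
        if coords_b is None:
            iu = np.triu_indices(len(a), k=1)
            dist = dist[iu]
            npairs = len(a) * (len(a) - 1) / 2
            rho = (len(b) - 1) / volume  # density of partners per particle
            norm += len(a) * rho / 2.0
        else:
            dist = dist.ravel()
            norm += len(a) * len(b) / volume
        h, _ = np.histogram(dist, bins=edges)
        hist += h
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (norm * shell)
    return edges, g


# ---------------------------------------------------------------------------
# PDB + JSON topology I/O


def _topology_payload(snap: LeafletSnapshot) -> dict:
    atoms = {}
    for i in range(snap.n_atoms):
        roles = []
        if snap.is_donor is not None and snap.is_donor[i]:
            roles.append("donor")
        if snap.is_acceptor is not None and snap.is_acceptor[i]:
            roles.append("acceptor")
        if snap.is_polar_h is not None and snap.is_polar_h[i]:
            roles.append("polar-h")
        entry: dict = {"mol": int(snap.mol_id[i]), "roles": roles}
        if snap.leaflet is not None:
            entry["leaflet"] = str(snap.leaflet[i])
        if snap.is_polar_h is not None and snap.is_polar_h[i]:
            entry["parent"] = int(snap.parent_donor[i])
        if snap.anchor is not None and snap.anchor[i]:
            entry["anchor"] = str(snap.anchor[i])
        atoms[str(i)] = entry
    payload = {
        "box": [float(x) for x in snap.box],
        "periodic": [bool(p) for p in snap.periodic],
        "atoms": atoms,
    }
    if snap.water_slab is not None:
        payload["water_slab"] = [float(snap.water_slab[0]), float(snap.water_slab[1])]
    return payload


def write_snapshots(frames: Sequence[LeafletSnapshot], pdb_path, topology_path) -> None:
    """Write frames as a multi-MODEL PDB plus a JSON topology sidecar.

    All frames must share the topology of the first; atom order defines
    the serial ↔ index mapping (0-based in the JSON).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    first = frames[0]
    n = first.n_atoms
    stack = struc.AtomArrayStack(len(frames), n)
    stack.coord = np.stack([f.coords for f in frames])
    stack.chain_id = np.full(n, "A")
    stack.res_id = first.mol_id + 1
    stack.res_name = np.full(n, "STE")
    is_h = first.is_polar_h if first.is_polar_h is not None else np.zeros(n, bool)
    stack.element = np.where(is_h, "H", "C")
    names = []
    seen: dict[int, int] = {}
    for i in range(n):
        k = seen.get(int(first.mol_id[i]), 0)
        seen[int(first.mol_id[i])] = k + 1
        names.append(f"{'H' if is_h[i] else 'C'}{k + 1}")
    stack.atom_name = np.array(names)
    stack.hetero = np.full(n, True)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    with open(topology_path, "w", encoding="utf-8") as fh:
        json.dump(_topology_payload(first), fh, indent=1)


def read_snapshots(pdb_path, topology_path) -> list[LeafletSnapshot]:
    """Read a (multi-MODEL) PDB plus JSON topology into snapshots."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    stack = pdb.get_structure()  # AtomArrayStack
    with open(topology_path, "r", encoding="utf-8") as fh:
        topo = json.load(fh)
    n = stack.array_length()
    mol_id = np.zeros(n, int)
    leaflet = np.full(n, "", dtype=object)
    is_donor = np.zeros(n, bool)
    is_acceptor = np.zeros(n, bool)
    is_polar_h = np.zeros(n, bool)
    parent = np.full(n, -1, int)
    anchor = np.full(n, "", dtype=object)
    for key, entry in topo["atoms"].items():
        i = int(key)
        mol_id[i] = entry["mol"]
        leaflet[i] = entry.get("leaflet", "")
        roles = entry.get("roles", [])
        is_donor[i] = "donor" in roles
        is_acceptor[i] = "acceptor" in roles
        is_polar_h[i] = "polar-h" in roles
        if is_polar_h[i]:
            parent[i] = entry["parent"]
        anchor[i] = entry.get("anchor", "")
    slab = topo.get("water_slab")
    return [
        LeafletSnapshot(
            coords=np.asarray(stack.coord[f], dtype=float),
            box=np.asarray(topo["box"], dtype=float),
            periodic=tuple(bool(p) for p in topo.get("periodic", (True, True, False))),
            mol_id=mol_id,
            leaflet=leaflet,
            is_donor=is_donor,
            is_acceptor=is_acceptor,
            is_polar_h=is_polar_h,
            parent_donor=parent,
            anchor=anchor,
            water_slab=tuple(slab) if slab else None,
        )
        for f in range(stack.stack_depth())
    ]
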