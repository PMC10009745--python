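"""Geometric operators on leaflet snapshots: hydrogen bonds, persistence,
tilt, area per lipid, anchoring, profiles and RDFs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monofilm.mdgeom import (
    HBond,
    LeafletSnapshot,
    anchoring_fractions,
    area_per_lipid,
    density_profile,
    detect_hbonds,
    persistent_hbonds,
    rdf,
    read_snapshots,
    tilt_angle,
    write_snapshots,
)
from monofilm.synthetic import SnapshotSpec, gen_snapshot


def make_snapshot(coords, mol_id, donors, hydrogens, parents, acceptors,
                  box=(20.0, 20.0, 20.0), periodic=(True, True, False)):
    n = len(coords)
    is_donor = np.zeros(n, bool)
    is_donor[list(donors)] = True
    is_acc = np.zeros(n, bool)
    is_acc[list(acceptors)] = True
    is_h = np.zeros(n, bool)
    is_h[list(hydrogens)] = True
    parent = np.full(n, -1, int)
    for h, d in parents.items():
        parent[h] = d
    return LeafletSnapshot(
        coords=np.asarray(coords, float), box=np.asarray(box, float),
        periodic=periodic, mol_id=np.asarray(mol_id, int),
        is_donor=is_donor, is_acceptor=is_acc, is_polar_h=is_h, parent_donor=parent,
    )


def brute_force_hbonds(snap, distance_max=3.0, angle_min=135.0):
    """All-pairs, all-periodic-images oracle, pure Python."""
    shifts = []
    ranges = [(-1, 0, 1) if p else (0,) for p in snap.periodic]
    for sx in ranges[0]:
        for sy in ranges[1]:
            for sz in ranges[2]:
                shifts.append(np.array([sx, sy, sz]) * snap.box)
    found = set()
    hs = np.nonzero(snap.is_polar_h)[0]
    accs = np.nonzero(snap.is_acceptor)[0]
    for h in hs:
        d = int(snap.parent_donor[h])
        for a in accs:
            if a == d or snap.mol_id[a] == snap.mol_id[d]:
                continue
            for s in shifts:
                a_pos = snap.coords[a] + s
                dist = np.linalg.norm(a_pos - snap.coords[d])
                if dist >= distance_max:
                    continue
                v1 = snap.coords[d] - snap.coords[h]
                v2 = a_pos - snap.coords[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang >= angle_min:
                    found.add((d, int(h), int(a)))
    return found


class TestHBondCriteria:
    def _pair(self, d_to_a, oh=0.97):
        # donor O at origin with H on the D→A axis (angle 180°)
        u = np.asarray(d_to_a) / np.linalg.norm(d_to_a)
        coords = [np.zeros(3), oh * u, np.asarray(d_to_a, float)]
        return make_snapshot(coords, [0, 0, 1], donors=[0], hydrogens=[1],
                             parents={1: 0}, acceptors=[2])

    def test_collinear_bond_detected(self):
        snap = self._pair([2.8, 0.0, 0.0])
        bonds = detect_hbonds(snap)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8)
        assert bonds[0].angle == pytest.approx(180.0)

    def test_distance_boundary_strict(self):
        assert detect_hbonds(self._pair([3.0, 0.0, 0.0])) == []
        assert len(detect_hbonds(self._pair([2.999999, 0.0, 0.0]))) == 1

    def test_angle_boundary_inclusive(self):
        # place H so the D–H···A angle is exactly 135°
        d = np.zeros(3)
        a = np.array([2.9, 0.0, 0.0])
        from monofilm.synthetic import _hbond_hydrogen_position

        h = _hbond_hydrogen_position(d, a, 0.97, 135.0)
        snap = make_snapshot([d, h, a], [0, 0, 1], donors=[0], hydrogens=[1],
                             parents={1: 0}, acceptors=[2])
        bonds = detect_hbonds(snap)
        assert len(bonds) == 1
        assert bonds[0].angle == pytest.approx(135.0, abs=1e-9)
        h_off = _hbond_hydrogen_position(d, a, 0.97, 134.9)
        snap2 = make_snapshot([d, h_off, a], [0, 0, 1], donors=[0], hydrogens=[1],
                              parents={1: 0}, acceptors=[2])
        assert detect_hbonds(snap2) == []

    def test_periodic_image_pair(self):
        # donor near x = 0, acceptor near x = L: image distance 2.8 Å
        box = 15.0
        snap = make_snapshot(
            [[0.5, 7.0, 7.0], [0.5 - 0.97, 7.0, 7.0], [box - 2.3, 7.0, 7.0]],
            [0, 0, 1], donors=[0], hydrogens=[1], parents={1: 0}, acceptors=[2],
            box=(box, box, box),
        )
        bonds = detect_hbonds(snap)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8)
        assert {(b.donor, b.hydrogen, b.acceptor) for b in bonds} == brute_force_hbonds(snap)

    def test_intramolecular_excluded_by_default(self):
        snap = make_snapshot(
            [[0, 0, 0], [0.97, 0, 0], [2.8, 0, 0]],
            [0, 0, 0], donors=[0], hydrogens=[1], parents={1: 0}, acceptors=[2],
        )
        assert detect_hbonds(snap) == []
        assert len(detect_hbonds(snap, include_intramolecular=True)) == 1

    def test_matches_brute_force_on_random_snapshots(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n_oh = 30
            box = np.array([11.0, 11.0, 11.0])
            o_pos = rng.uniform(0, 1, (n_oh, 3)) * box
            direc = rng.normal(size=(n_oh, 3))
            direc /= np.linalg.norm(direc, axis=1, keepdims=True)
            coords = np.empty((2 * n_oh, 3))
            coords[0::2] = o_pos
            coords[1::2] = o_pos + 0.97 * direc
            snap = make_snapshot(
                coords, np.repeat(np.arange(n_oh), 2),
                donors=list(range(0, 2 * n_oh, 2)),
                hydrogens=list(range(1, 2 * n_oh, 2)),
                parents={h: h - 1 for h in range(1, 2 * n_oh, 2)},
                acceptors=list(range(0, 2 * n_oh, 2)),
                box=box, periodic=(True, True, seed % 2 == 0),
            )
            got = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(snap)}
            assert got == brute_force_hbonds(snap), seed


class TestPersistence:
    def _frames(self, present_in):
        bond = HBond(donor=0, hydrogen=1, acceptor=4, distance=2.8, angle=170.0)
        return [[bond] if i in present_in else [] for i in range(10)]

    def test_eight_of_ten_kept(self):
        assert persistent_hbonds(self._frames(range(8)), 0.8) == [(0, 4)]

    def test_seven_of_ten_dropped(self):
        assert persistent_hbonds(self._frames(range(7)), 0.8) == []

    def test_full_presence_at_fraction_one(self):
        assert persistent_hbonds(self._frames(range(10)), 1.0) == [(0, 4)]

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 1.0), st.floats(0.1, 1.0))
    def test_monotone_in_fraction(self, f1, f2):
        frames = self._frames({0, 2, 4, 6, 8})
        lo, hi = sorted((f1, f2))
        assert set(persistent_hbonds(frames, hi)) <= set(persistent_hbonds(frames, lo))

    def test_identity_ignores_hydrogen(self):
        b1 = HBond(0, 1, 4, 2.8, 170.0)
        b2 = HBond(0, 2, 4, 2.9, 150.0)  # other hydroxyl H, same O pair
        assert persistent_hbonds([[b1], [b2]], 1.0) == [(0, 4)]


class TestTilt:
    def test_rod_along_normal(self):
        rod = np.outer(np.arange(5.0), [0, 0, 1.0])
        assert tilt_angle(rod) == pytest.approx(0.0, abs=1e-9)

    def test_rod_perpendicular(self):
        rod = np.outer(np.arange(5.0), [1.0, 0, 0])
        assert tilt_angle(rod) == pytest.approx(90.0, abs=1e-9)

    def test_diagonal_rod(self):
        rod = np.outer(np.arange(5.0), np.array([1.0, 0, 1.0]) / np.sqrt(2))
        assert tilt_angle(rod) == pytest.approx(45.0, abs=1e-6)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="coincident"):
            tilt_angle(np.zeros((4, 3)))

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0, 2 * np.pi), st.floats(-50, 50), st.floats(-50, 50))
    def test_invariant_under_rotation_about_normal_and_translation(self, phi, tx, ty):
        rng = np.random.default_rng(5)
        mol = np.outer(np.arange(8.0), [0.3, 0.1, 1.0]) + rng.normal(0, 0.05, (8, 3))
        rot = np.array(
            [[np.cos(phi), -np.sin(phi), 0], [np.sin(phi), np.cos(phi), 0], [0, 0, 1]]
        )
        moved = mol @ rot.T + np.array([tx, ty, 0.0])
        assert tilt_angle(moved) == pytest.approx(tilt_angle(mol), abs=1e-6)


class TestAreaAnchoring:
    def test_area_per_lipid(self):
        assert area_per_lipid((64.0, 64.0), 128) == 32.0
        assert area_per_lipid((68.4, 68.4), 128) == pytest.approx(36.55, abs=0.01)
        assert area_per_lipid((128.0, 128.0), 128) == 128.0  # quadruples

    def test_zero_molecules(self):
        with pytest.raises(ValueError):
            area_per_lipid((64.0, 64.0), 0)

    def _anchored_snapshot(self, n_head, n_total, tie=False):
        coords, mol_id, anchor = [], [], []
        for m in range(n_total):
            head_near = m < n_head
            z_head = 1.0 if head_near or tie else 8.0
            z_chain = 8.0 if head_near else 1.0
            if tie:
                z_chain = z_head
            coords += [[m % 10, m // 10, z_head], [m % 10, m // 10, z_chain]]
            mol_id += [m, m]
            anchor += ["head", "chain"]
        snap = LeafletSnapshot(
            coords=np.array(coords, float), box=np.array([10.0, 10.0, 20.0]),
            mol_id=np.array(mol_id), anchor=np.array(anchor, dtype=object),
            water_slab=(0.0, 2.0),
        )
        return snap

    def test_planted_fractions(self):
        fr = anchoring_fractions(self._anchored_snapshot(55, 100))
        assert fr["head"] == 0.55
        assert fr["chain"] == 0.45

    def test_all_head(self):
        fr = anchoring_fractions(self._anchored_snapshot(10, 10))
        assert fr == {"head": 1.0, "chain": 0.0}

    def test_tie_breaks_to_head(self):
        fr = anchoring_fractions(self._anchored_snapshot(0, 10, tie=True))
        assert fr["head"] == 1.0

    def test_unannotated_molecules_listed(self):
        snap = self._anchored_snapshot(5, 10)
        snap.anchor[4:6] = ""  # strip molecule 2 of its anchors
        with pytest.raises(ValueError, match=r"\[2\]"):
            anchoring_fractions(snap)


class TestProfiles:
    def test_count_conservation_exact(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-5, 25, (5000, 3))
        _, hist = density_profile(coords, box_length=20.0, bin_width=0.7)
        assert hist.sum() == 5000

    def test_planar_configuration_single_bin(self):
        coords = np.tile([[1.0, 2.0, 7.3]], (50, 1))
        _, hist = density_profile(coords, box_length=20.0, bin_width=1.0)
        assert hist.max() == 50
        assert (hist > 0).sum() == 1

    def test_uniform_flat_within_poisson_bands(self):
        rng = np.random.default_rng(12)
        n, nbins = 100_000, 100
        coords = rng.uniform(0, 50.0, (n, 3))
        _, hist = density_profile(coords, box_length=50.0, bin_width=0.5)
        expected = n / nbins
        dev = np.abs(hist - expected) / np.sqrt(expected)
        # Poisson flatness: nearly all bins inside the 3σ band and the
        # χ² statistic consistent with a uniform profile (99 dof)
        assert (dev < 3.0).mean() >= 0.97
        assert np.sum((hist - expected) ** 2 / expected) < 150.0

    def test_mass_weighting(self):
        coords = np.array([[0, 0, 1.0], [0, 0, 1.2]])
        _, hist = density_profile(coords, 10.0, bin_width=2.0, weights=np.array([12.0, 16.0]))
        assert hist[0] == 28.0

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            density_profile(np.zeros((3, 3)), 10.0, bin_width=0.0)


class TestRDF:
    def test_uniform_gas_tends_to_one(self):
        rng = np.random.default_rng(8)
        box = np.array([20.0, 20.0, 20.0])
        frames = [rng.uniform(0, 1, (400, 3)) * box for _ in range(5)]
        edges, g = rdf(frames, box, r_max=9.0, bin_width=0.5)
        r_mid = 0.5 * (edges[:-1] + edges[1:])
        far = r_mid > 2.0
        assert np.all(np.abs(g[far] - 1.0) < 0.25)
        assert abs(g[far].mean() - 1.0) < 0.05

    def test_isolated_pair_peak(self):
        box = np.array([50.0, 50.0, 50.0])
        frames = [np.array([[10.0, 10.0, 10.0], [15.0, 10.0, 10.0]])]
        edges, g = rdf(frames, box, r_max=20.0, bin_width=1.0)
        assert np.argmax(g) == 5  # the 5–6 Å bin
        assert (g > 0).sum() == 1

    def test_r_max_too_large(self):
        with pytest.raises(ValueError, match="half"):
            rdf([np.zeros((4, 3))], [10.0, 10.0, 10.0], r_max=6.0)

    def test_empty_selection(self):
        with pytest.raises(ValueError, match="empty"):
            rdf([np.zeros((0, 3))], [10.0, 10.0, 10.0], r_max=4.0)


class TestSnapshotIO:
    def test_pdb_topology_round_trip(self, tmp_path):
        snap = gen_snapshot(SnapshotSpec(n_per_leaflet=16, n_bonded_pairs=3,
                                         planted_tilt=10.0, seed=4))
        write_snapshots([snap, snap], tmp_path / "s.pdb", tmp_path / "t.json")
        frames = read_snapshots(tmp_path / "s.pdb", tmp_path / "t.json")
        assert len(frames) == 2
        back = frames[0]
        # PDB stores 3 decimals; topology must survive exactly
        np.testing.assert_allclose(back.coords, snap.coords, atol=1e-3)
        np.testing.assert_array_equal(back.mol_id, snap.mol_id)
        np.testing.assert_array_equal(back.is_donor, snap.is_donor)
        np.testing.assert_array_equal(back.parent_donor, snap.parent_donor)
        assert back.water_slab == snap.water_slab
        # the bond census is preserved through the round trip
        assert len(detect_hbonds(back)) == len(detect_hbonds(snap)) == 3
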