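"""Superposition, RMSD/RMSF, hydrogen bonds, stacking, restraints."""

import math

import numpy as np
import pytest

from alignpocket.geometry import (
    GeometryError,
    HBond,
    HBondCriteria,
    RestraintSpec,
    Structure,
    Trajectory,
    detect_hbonds,
    distance_stats,
    hbond_occupancy,
    kabsch_superpose,
    parse_structure,
    parse_trajectory,
    restraint_energy,
    restraint_violation_fraction,
    ring_geometry,
    rmsd_series,
    rmsf,
    stacking_metrics,
)


def make_structure(atoms):
    """atoms: list of (name, resname, resid, element, xyz)."""
    return Structure(
        np.arange(1, len(atoms) + 1),
        np.array([a[0] for a in atoms], dtype=object),
        np.array([a[1] for a in atoms], dtype=object),
        np.array([a[2] for a in atoms], dtype=int),
        np.array(["A"] * len(atoms), dtype=object),
        np.array([a[3] for a in atoms], dtype=object),
        np.array([a[4] for a in atoms], dtype=float),
    )


def make_traj(topology, frames):
    return Trajectory(topology, np.asarray(frames, dtype=float))


def random_rotation(rng):
    """Uniform-ish proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


PDB_ONE_MODEL = """ATOM      1  N   DON A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H   DON A   1       1.000   0.000   0.000  1.00  0.00           H
ATOM      3  O   ACC A   2       2.900   0.000   0.000  1.00  0.00           O
END
"""


class TestParsing:
    def test_single_model(self):
        s = parse_structure(PDB_ONE_MODEL)
        assert s.n_atoms == 3
        assert list(s.names) == ["N", "H", "O"]
        assert s.coords[2, 0] == pytest.approx(2.9)

    def test_two_model_trajectory(self):
        text = (
            "MODEL        1\n" + PDB_ONE_MODEL.replace("END\n", "ENDMDL\n")
            + "MODEL        2\n" + PDB_ONE_MODEL.replace("END\n", "ENDMDL\nEND\n")
        )
        traj = parse_trajectory(text)
        assert traj.n_frames == 2
        assert traj.topology.n_atoms == 3

    def test_frame_mismatch_names_model(self):
        model2 = "\n".join(PDB_ONE_MODEL.splitlines()[:2])
        text = (
            "MODEL        1\n" + PDB_ONE_MODEL.replace("END\n", "ENDMDL\n")
            + "MODEL        2\n" + model2 + "\nENDMDL\nEND\n"
        )
        with pytest.raises(GeometryError, match="model 2"):
            parse_trajectory(text)

    def test_element_inferred_from_name_when_blank(self):
        text = PDB_ONE_MODEL.replace("           N", "").replace(
            "           H", ""
        ).replace("           O", "")
        s = parse_structure(text)
        assert list(s.elements) == ["N", "H", "O"]

    def test_empty_input_errors(self):
        with pytest.raises(GeometryError):
            parse_structure("END\n")


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert rot @ pts[0] + trans == pytest.approx(pts[0], abs=1e-9)

    def test_translation_removed(self, rng):
        pts = rng.normal(size=(8, 3))
        _, _, rmsd = kabsch_superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        """RMSD invariant (<= 1e-9 A) under rigid motion of either input."""
        a = rng.normal(size=(12, 3))
        b = a + 0.3 * rng.normal(size=(12, 3))
        _, _, base = kabsch_superpose(a, b)
        for _ in range(10):
            rot = random_rotation(rng)
            shift = rng.normal(size=3) * 10
            _, _, r1 = kabsch_superpose(a @ rot.T + shift, b)
            _, _, r2 = kabsch_superpose(a, b @ rot.T + shift)
            assert abs(r1 - base) <= 1e-9
            assert abs(r2 - base) <= 1e-9

    def test_symmetry_in_arguments(self, rng):
        a = rng.normal(size=(9, 3))
        b = a + 0.2 * rng.normal(size=(9, 3))
        _, _, ab = kabsch_superpose(a, b)
        _, _, ba = kabsch_superpose(b, a)
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_proper_rotation(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_displaced_point_matches_rotation_grid_oracle(self):
        """RMSD for a 4-point set with one displaced point agrees with an
        exhaustive rotation-grid search to 1e-3 A."""
        ref = np.array(
            [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]]
        )
        mobile = ref.copy()
        mobile[0] += np.array([0.0, 0.0, 1.0])  # 1 A displacement along z
        _, _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(_grid_oracle_rmsd(mobile, ref), abs=1e-3)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


def _grid_oracle_rmsd(mobile, ref, n=40):
    """Brute-force search over ZYZ Euler rotations (coarse grid + refinement)."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)

    def rmsd_at(a, b, c):
        ca, sa, cb, sb, cc, sc = (
            math.cos(a), math.sin(a), math.cos(b), math.sin(b), math.cos(c), math.sin(c),
        )
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        rot = rz1 @ ry @ rz2
        return np.sqrt(np.mean(np.sum((mob_c @ rot.T - ref_c) ** 2, axis=1)))

    grid = np.linspace(0, 2 * math.pi, n, endpoint=False)
    half = np.linspace(0, math.pi, n // 2)
    best, args = min(
        ((rmsd_at(a, b, c), (a, b, c)) for a in grid for b in half for c in grid),
        key=lambda t: t[0],
    )
    a0, b0, c0 = args
    span = 2 * math.pi / n
    for _ in range(4):  # local refinement
        fine_a = np.linspace(a0 - span, a0 + span, 9)
        fine_b = np.linspace(b0 - span, b0 + span, 9)
        fine_c = np.linspace(c0 - span, c0 + span, 9)
        best, (a0, b0, c0) = min(
            ((rmsd_at(a, b, c), (a, b, c)) for a in fine_a for b in fine_b for c in fine_c),
            key=lambda t: t[0],
        )
        span /= 4
    return best


class TestRmsdSeries:
    def _static_traj(self, rng, n_atoms=5, n_frames=4):
        atoms = [
            ("CA", "GLY", i + 1, "C", rng.normal(size=3) * 5) for i in range(n_atoms)
        ]
        topo = make_structure(atoms)
        return make_traj(topo, [topo.coords] * n_frames)

    def test_static_trajectory_all_zero(self, rng):
        series = rmsd_series(self._static_traj(rng))
        assert series == pytest.approx(np.zeros(4), abs=1e-12)

    def test_reference_frame_is_zero(self, rng):
        traj = self._static_traj(rng)
        frames = traj.frames.copy()
        frames[2] += 1.0  # rigid shift: still 0 after superposition
        frames[3, 0, 2] += 2.0
        traj = make_traj(traj.topology, frames)
        series = rmsd_series(traj, reference_frame=1)
        assert series[1] == pytest.approx(0.0, abs=1e-12)
        assert series[2] == pytest.approx(0.0, abs=1e-9)
        assert series[3] > 0

    def test_sinusoidal_displacement_matches_closed_form(self):
        """Hexagon + centre atom; centre oscillates along z with amplitude h:
        optimal rotation stays the identity by symmetry and
        RMSD(t) = |h(t)| * sqrt(6)/7."""
        hexagon = 2.0 * np.array(
            [
                [math.cos(a), math.sin(a), 0.0]
                for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)
            ]
        )
        base = np.vstack([hexagon, [0.0, 0.0, 0.0]])
        atoms = [("CA", "GLY", i + 1, "C", base[i]) for i in range(7)]
        topo = make_structure(atoms)
        n_frames = 20
        amplitudes = 0.8 * np.sin(2 * math.pi * np.arange(n_frames) / n_frames)
        frames = []
        for h in amplitudes:
            f = base.copy()
            f[6, 2] = h
            frames.append(f)
        series = rmsd_series(make_traj(topo, frames))
        expected = np.abs(amplitudes) * math.sqrt(6) / 7
        assert series == pytest.approx(expected, abs=1e-9)

    def test_empty_selection_errors(self, rng):
        with pytest.raises(GeometryError):
            rmsd_series(self._static_traj(rng), selection="ZZ")


class TestRmsf:
    def test_static_trajectory_zero(self, rng):
        atoms = [("CA", "GLY", i + 1, "C", rng.normal(size=3) * 5) for i in range(6)]
        topo = make_structure(atoms)
        traj = make_traj(topo, [topo.coords] * 5)
        assert rmsf(traj) == pytest.approx(np.zeros(6), abs=1e-12)

    def test_rigid_translation_zero(self, rng):
        atoms = [("CA", "GLY", i + 1, "C", rng.normal(size=3) * 5) for i in range(6)]
        topo = make_structure(atoms)
        frames = [topo.coords + np.array([t, 2 * t, -t]) for t in range(5)]
        assert rmsf(make_traj(topo, frames)) == pytest.approx(np.zeros(6), abs=1e-9)

    def test_single_jittered_atom_recovers_sigma_sqrt3(self, rng):
        """One atom jittered with per-axis variance sigma^2 among many fixed
        anchors -> RMSF ~ sigma * sqrt(3)."""
        sigma = 0.1
        n_anchor, n_frames = 40, 500
        anchors = rng.normal(size=(n_anchor, 3)) * 10
        atoms = [("CA", "GLY", i + 1, "C", anchors[i]) for i in range(n_anchor)]
        atoms.append(("CA", "GLY", n_anchor + 1, "C", np.zeros(3)))
        topo = make_structure(atoms)
        frames = np.repeat(topo.coords[None, :, :], n_frames, axis=0)
        frames[:, n_anchor, :] += rng.normal(scale=sigma, size=(n_frames, 3))
        values = rmsf(make_traj(topo, frames))
        assert values[n_anchor] == pytest.approx(sigma * math.sqrt(3), rel=0.10)
        assert values[:n_anchor].max() < 0.05  # anchors barely move

    def test_single_frame_errors(self, rng):
        atoms = [("CA", "GLY", i + 1, "C", rng.normal(size=3)) for i in range(4)]
        topo = make_structure(atoms)
        with pytest.raises(GeometryError):
            rmsf(make_traj(topo, [topo.coords]))


def _hbond_system(o_xyz):
    return make_structure(
        [
            ("N", "DON", 1, "N", [0.0, 0.0, 0.0]),
            ("H", "DON", 1, "H", [1.0, 0.0, 0.0]),
            ("O", "ACC", 2, "O", o_xyz),
        ]
    )


class TestHydrogenBonds:
    def test_collinear_within_cutoffs_detected(self):
        bonds = detect_hbonds(_hbond_system([2.9, 0.0, 0.0]))
        assert bonds == [HBond(donor=0, hydrogen=1, acceptor=2)]

    def test_distance_fail_rejected(self):
        assert detect_hbonds(_hbond_system([3.2, 0.0, 0.0])) == []

    def test_angle_fail_rejected(self):
        # acceptor 2.8 A from N but 35 deg short of linearity: angle fail
        o = _acceptor_at_angle_deviation(2.8, 35.0)
        assert detect_hbonds(_hbond_system(o)) == []

    def test_angle_within_cutoff_detected(self):
        o = _acceptor_at_angle_deviation(2.8, 20.0)
        assert len(detect_hbonds(_hbond_system(o))) == 1

    def test_no_hydrogens_warns(self):
        s = make_structure(
            [
                ("N", "DON", 1, "N", [0.0, 0.0, 0.0]),
                ("O", "ACC", 2, "O", [2.9, 0.0, 0.0]),
            ]
        )
        with pytest.warns(UserWarning):
            assert detect_hbonds(s) == []

    def test_brute_force_oracle_on_random_systems(self, rng):
        """Detection equals an independent all-pairs oracle on <=50 atoms."""
        criteria = HBondCriteria()
        for _ in range(30):
            structure = _random_no_system(rng, n_heavy=int(rng.integers(4, 14)))
            got = {
                (b.donor, b.hydrogen, b.acceptor)
                for b in detect_hbonds(structure, criteria=criteria)
            }
            assert got == _oracle_hbonds(structure, criteria)

    def test_occupancy_monotone_in_cutoffs(self, rng):
        frames, topo = _occupancy_frames()
        loose = hbond_occupancy(
            make_traj(topo, frames), "1:N", "2:O", HBondCriteria(3.5, 40.0)
        )
        tight = hbond_occupancy(
            make_traj(topo, frames), "1:N", "2:O", HBondCriteria(3.0, 30.0)
        )
        tighter = hbond_occupancy(
            make_traj(topo, frames), "1:N", "2:O", HBondCriteria(2.95, 10.0)
        )
        assert 0.0 <= tighter <= tight <= loose <= 100.0

    def test_occupancy_never_formed(self):
        topo = _hbond_system([6.0, 0.0, 0.0])
        traj = make_traj(topo, [topo.coords] * 5)
        assert hbond_occupancy(traj, "1:N", "2:O") == 0.0

    def test_unresolvable_selection_errors(self):
        topo = _hbond_system([2.9, 0.0, 0.0])
        traj = make_traj(topo, [topo.coords])
        with pytest.raises(GeometryError):
            hbond_occupancy(traj, "9:N", "2:O")


def _acceptor_at_angle_deviation(distance_from_n, deviation_deg):
    """Acceptor at given N-distance whose D-H...A angle deviates as stated."""
    # Solve placement in the xy-plane: H at (1,0), D at origin.
    target = math.radians(180.0 - deviation_deg)
    # point at distance d from H along direction making angle target with H->D
    # H->D direction is (-1, 0); rotate by (pi - target) to get H->A direction
    direction = np.array([math.cos(math.pi - target), math.sin(math.pi - target), 0.0])
    for r in np.linspace(0.5, 5.0, 2000):
        a = np.array([1.0, 0.0, 0.0]) + r * direction
        if abs(np.linalg.norm(a) - distance_from_n) < 2e-3:
            return a
    raise AssertionError("no placement found")


def _random_no_system(rng, n_heavy):
    atoms = []
    resid = 1
    for _ in range(n_heavy):
        element = "N" if rng.random() < 0.5 else "O"
        xyz = rng.uniform(-4, 4, size=3)
        atoms.append((element, "RES", resid, element, xyz))
        if rng.random() < 0.6:  # attach a hydrogen ~1 A away
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(("H", "RES", resid, "H", xyz + direction))
        resid += 1
    return make_structure(atoms)


def _oracle_hbonds(structure, criteria):
    """Triple-loop reference implementation (independent of the package)."""
    xyz = structure.coords
    elements = [e.upper() for e in structure.elements]
    heavy = [i for i, e in enumerate(elements) if e in {"N", "O"}]
    found = set()
    for h, eh in enumerate(elements):
        if eh != "H":
            continue
        candidates = [
            (np.linalg.norm(xyz[d] - xyz[h]), d) for d in heavy
        ]
        if not candidates:
            continue
        dh, donor = min(candidates)
        if dh > criteria.covalent_dh_A:
            continue
        for acceptor in heavy:
            if acceptor == donor:
                continue
            if np.linalg.norm(xyz[acceptor] - xyz[donor]) > criteria.distance_cutoff_A:
                continue
            v1 = xyz[donor] - xyz[h]
            v2 = xyz[acceptor] - xyz[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if 180.0 - angle <= criteria.angle_cutoff_deg:
                found.add((donor, h, acceptor))
    return found


def _occupancy_frames():
    topo = _hbond_system([2.9, 0.0, 0.0])
    frames = []
    for distance in (2.8, 2.9, 3.05, 3.2, 3.4):
        f = topo.coords.copy()
        f[2, 0] = distance
        frames.append(f)
    return frames, topo


def _hexagon(radius=1.4):
    return radius * np.array(
        [
            [math.cos(a), math.sin(a), 0.0]
            for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)
        ]
    )


class TestRings:
    def test_hexagon_in_xy_plane(self):
        centroid, normal = ring_geometry(_hexagon() + np.array([1.0, 2.0, 3.0]))
        assert centroid == pytest.approx([1.0, 2.0, 3.0], abs=1e-12)
        assert normal == pytest.approx([0.0, 0.0, 1.0], abs=1e-12)

    def test_rotated_hexagon_normal_canonicalised(self):
        rot_x90 = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        _, normal = ring_geometry(_hexagon() @ rot_x90.T)
        # plane normal is +-y; canonical form has positive y
        assert normal == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)

    def test_noisy_ring_normal_within_one_degree(self, rng):
        pts = _hexagon() + rng.normal(scale=0.02, size=(6, 3))
        _, normal = ring_geometry(pts)
        angle = math.degrees(math.acos(abs(float(normal[2]))))
        assert angle < 1.0

    def test_collinear_errors(self):
        with pytest.raises(GeometryError):
            ring_geometry(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))


class TestStacking:
    def _ring_traj(self, distance, angle_deg, n_frames=4):
        atoms = []
        for i, xyz in enumerate(_hexagon()):
            atoms.append((f"C{i + 1}", "RGA", 1, "C", xyz))
        theta = math.radians(angle_deg)
        rot = np.array(
            [[1, 0, 0], [0, math.cos(theta), -math.sin(theta)],
             [0, math.sin(theta), math.cos(theta)]]
        )
        for i, xyz in enumerate(_hexagon()):
            atoms.append((f"C{i + 1}", "RGB", 2, "C", rot @ xyz + [0, 0, distance]))
        topo = make_structure(atoms)
        return make_traj(topo, [topo.coords] * n_frames)

    RING_A = [f"1:C{i + 1}" for i in range(6)]
    RING_B = [f"2:C{i + 1}" for i in range(6)]

    def test_parallel_close_rings_stacked(self):
        rep = stacking_metrics(self._ring_traj(3.5, 0.0), self.RING_A, self.RING_B)
        assert rep.verdict == "stacked"
        assert rep.mean_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert rep.mean_distance_A == pytest.approx(3.5, abs=1e-9)
        assert rep.stacked_fraction == 1.0

    def test_distant_tilted_rings_not_stacked(self):
        """The 5.79 A / 52 deg geometry is classified as incompatible with
        pi-stacking."""
        rep = stacking_metrics(self._ring_traj(5.79, 52.0), self.RING_A, self.RING_B)
        assert rep.verdict == "not_stacked"
        assert rep.stacked_fraction == 0.0
        assert rep.mean_angle_deg == pytest.approx(52.0, abs=1e-6)

    def test_half_stacked_fraction(self):
        stacked = self._ring_traj(3.5, 0.0, n_frames=2)
        apart = self._ring_traj(8.0, 0.0, n_frames=2)
        traj = make_traj(
            stacked.topology, np.vstack([stacked.frames, apart.frames])
        )
        rep = stacking_metrics(traj, self.RING_A, self.RING_B)
        assert rep.stacked_fraction == 0.5
        assert rep.verdict == "stacked"  # >= 0.5 rule

    def test_ring_exchange_symmetry(self):
        traj = self._ring_traj(4.2, 30.0)
        ab = stacking_metrics(traj, self.RING_A, self.RING_B)
        ba = stacking_metrics(traj, self.RING_B, self.RING_A)
        assert ab.mean_angle_deg == pytest.approx(ba.mean_angle_deg, abs=1e-9)
        assert ab.mean_distance_A == pytest.approx(ba.mean_distance_A, abs=1e-9)

    def test_global_rotation_invariance(self, rng):
        traj = self._ring_traj(4.2, 37.0)
        rot = random_rotation(rng)
        rotated = make_traj(traj.topology, traj.frames @ rot.T)
        a = stacking_metrics(traj, self.RING_A, self.RING_B)
        b = stacking_metrics(rotated, self.RING_A, self.RING_B)
        assert a.mean_angle_deg == pytest.approx(b.mean_angle_deg, abs=1e-6)
        assert a.mean_distance_A == pytest.approx(b.mean_distance_A, abs=1e-9)

    def test_angle_reported_acute(self):
        rep = stacking_metrics(self._ring_traj(4.0, 130.0), self.RING_A, self.RING_B)
        assert rep.mean_angle_deg == pytest.approx(50.0, abs=1e-6)


class TestDistanceStats:
    def _pair_traj(self, distances):
        topo = make_structure(
            [("P", "PRA", 1, "P", [0.0, 0.0, 0.0]), ("P", "PRB", 2, "P", [1.0, 0.0, 0.0])]
        )
        frames = []
        for d in distances:
            f = topo.coords.copy()
            f[1, 0] = d
            frames.append(f)
        return make_traj(topo, frames)

    def test_static_pair(self):
        mean, sd, series = distance_stats(self._pair_traj([4.3] * 5), "1:P", "2:P")
        assert mean == pytest.approx(4.3)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_two_frames(self):
        mean, sd, _ = distance_stats(self._pair_traj([3.0, 5.0]), "1:P", "2:P")
        assert mean == pytest.approx(4.0)
        assert sd == pytest.approx(1.0)

    def test_gaussian_recovery(self, rng):
        sample = rng.normal(7.7, 0.5, size=2000)
        mean, sd, _ = distance_stats(self._pair_traj(sample), "1:P", "2:P")
        assert mean == pytest.approx(sample.mean(), abs=1e-9)
        assert sd == pytest.approx(sample.std(), abs=1e-9)

    def test_unresolvable_atom_errors(self):
        with pytest.raises(GeometryError):
            distance_stats(self._pair_traj([4.0]), "1:P", "3:Q")


class TestRestraints:
    SPEC = RestraintSpec(r_i_nm=0.45, k=1000.0)

    def test_radii(self):
        assert self.SPEC.r0_nm == pytest.approx(0.15)
        assert self.SPEC.r1_nm == pytest.approx(0.75)
        assert self.SPEC.r2_nm == pytest.approx(1.75)

    def test_flat_bottom_is_zero(self):
        for r in np.linspace(self.SPEC.r0_nm, self.SPEC.r1_nm, 7):
            assert restraint_energy(r, self.SPEC) == 0.0

    def test_quadratic_region_value(self):
        r = self.SPEC.r1_nm + 0.5
        assert restraint_energy(r, self.SPEC) == pytest.approx(0.5 * 1000 * 0.25)

    def test_below_r0_quadratic(self):
        r = self.SPEC.r0_nm - 0.1
        assert restraint_energy(r, self.SPEC) == pytest.approx(0.5 * 1000 * 0.01)

    def test_linear_region_slope_and_continuity(self):
        k, r1, r2 = self.SPEC.k, self.SPEC.r1_nm, self.SPEC.r2_nm
        just_below = restraint_energy(r2 - 1e-9, self.SPEC)
        just_above = restraint_energy(r2 + 1e-9, self.SPEC)
        assert just_above == pytest.approx(just_below, rel=1e-6)
        slope = (
            restraint_energy(r2 + 1.0, self.SPEC) - restraint_energy(r2 + 0.5, self.SPEC)
        ) / 0.5
        assert slope == pytest.approx(k * (r2 - r1), rel=1e-12)

    @pytest.mark.parametrize("knot", ["r0_nm", "r1_nm", "r2_nm"])
    def test_c1_at_knots(self, knot):
        """Finite-difference derivative continuous at each knot (<=1e-6 rel)."""
        r = getattr(self.SPEC, knot)
        h = 1e-5
        e = lambda x: restraint_energy(x, self.SPEC)  # noqa: E731
        # second-order one-sided stencils are exact on polynomial pieces
        left = (3 * e(r) - 4 * e(r - h) + e(r - 2 * h)) / (2 * h)
        right = (-3 * e(r) + 4 * e(r + h) - e(r + 2 * h)) / (2 * h)
        scale = max(1.0, abs(left), abs(right))
        assert abs(right - left) / scale <= 1e-6

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            RestraintSpec(r_i_nm=0.1)  # r0 would be negative
        with pytest.raises(ValueError):
            RestraintSpec(r_i_nm=0.45, k=-1.0)

    def _restraint_traj(self, distances_nm):
        topo = make_structure(
            [("C1", "RSA", 1, "C", [0.0, 0.0, 0.0]), ("C1", "RSB", 2, "C", [1.0, 0.0, 0.0])]
        )
        frames = []
        for d in distances_nm:
            f = topo.coords.copy()
            f[1, 0] = d * 10.0  # nm -> A
            frames.append(f)
        return make_traj(topo, frames)

    def test_violation_fraction_zero_inside(self):
        traj = self._restraint_traj([0.45] * 10)
        assert restraint_violation_fraction(traj, "1:C1", "2:C1", self.SPEC) == 0.0

    def test_violation_fraction_planted_18pct(self):
        distances = [0.45] * 41 + [0.95] * 9  # 9/50 = 18% outside [r0, r1]
        traj = self._restraint_traj(distances)
        assert restraint_violation_fraction(traj, "1:C1", "2:C1", self.SPEC) == 18.0

    def test_violation_fraction_all_outside(self):
        traj = self._restraint_traj([1.9] * 4)
        assert restraint_violation_fraction(traj, "1:C1", "2:C1", self.SPEC) == 100.0
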