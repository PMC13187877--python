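"""Trajectory metrics: superposition, RMSD/RMSF, salt bridges, hydrogen bonds."""

import math

import numpy as np
import pytest

from tests.conftest import toy_atom
from vibromap import nma
from vibromap.structure_io import ProteinStructure, ResidueKey
from vibromap.synthetic import simulate_harmonic_trajectory
from vibromap.trajectory import (
    Trajectory,
    count_hbonds,
    detect_salt_bridges,
    kabsch_superpose,
    read_frame_table,
    read_multimodel_pdb,
    rmsd_series,
    rmsf_per_residue,
)


def rotation(theta: float, axis: int = 2) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    r = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    r[i, i] = r[j, j] = c
    r[i, j], r[j, i] = -s, s
    return r


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd < 1e-12

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(10, 3))
        mob = ref @ rotation(0.7).T + np.array([3.0, -1.0, 2.0])
        # superposing the moved copy back onto the reference is exact
        _, _, rmsd = kabsch_superpose(mob, ref)
        assert rmsd < 1e-8

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(6, 3))
        mob = ref.copy()
        mob[:, 0] *= -1  # reflection: must NOT be undone by a proper rotation
        rot, _, rmsd = kabsch_superpose(mob, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_matches_rotation_grid_search(self):
        """Four points, one perturbed: the Kabsch RMSD equals the minimum over
        a fine grid of rotations (independent brute-force oracle)."""
        ref = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        mob = ref.copy()
        mob[2] += np.array([0.0, 0.25, 0.0])
        _, _, rmsd = kabsch_superpose(mob, ref)

        def rmsd_at(a, b, c):
            r = rotation(a, 0) @ rotation(b, 1) @ rotation(c, 2)
            m = mob - mob.mean(axis=0)
            f = m @ r.T + ref.mean(axis=0)
            # optimal translation for a fixed rotation is the centroid match
            return math.sqrt(np.mean(np.sum((f - ref) ** 2, axis=1)))

        grid = np.linspace(-0.12, 0.12, 25)
        best = min(rmsd_at(a, b, c) for a in grid for b in grid for c in grid)
        assert rmsd == pytest.approx(best, abs=2e-4)
        assert rmsd <= best + 1e-12

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 0.1)


@pytest.fixture(scope="module")
def helix_traj(helix20_modes):
    s, _, modes = helix20_modes
    return s, simulate_harmonic_trajectory(modes, 300.0, 400, seed=3, structure=s)


class TestRmsdSeries:
    def test_identical_frames_give_zero(self, helix20_modes):
        s, _, _ = helix20_modes
        frames = np.repeat(s.coords[None], 20, axis=0)
        traj = Trajectory(frames, np.arange(20.0), s)
        out = rmsd_series(traj)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_equilibration_window_bookkeeping(self, helix_traj):
        s, traj = helix_traj
        full = rmsd_series(traj, equilibration_frames=0)
        skipped = rmsd_series(traj, equilibration_frames=10)
        assert len(skipped.values) == len(full.values)  # series keeps all frames
        assert skipped.mean == pytest.approx(float(np.mean(full.values[10:])))

    def test_amplitude_scales_as_sqrt_temperature(self, helix20_modes):
        s, _, modes = helix20_modes
        lo = simulate_harmonic_trajectory(modes, 300.0, 4000, seed=8, structure=s)
        hi = simulate_harmonic_trajectory(modes, 1200.0, 4000, seed=9, structure=s)
        r_lo = rmsd_series(lo)
        r_hi = rmsd_series(hi)
        assert r_hi.mean / r_lo.mean == pytest.approx(2.0, rel=0.10)

    def test_bad_reference_frame(self, helix_traj):
        _, traj = helix_traj
        with pytest.raises(ValueError):
            rmsd_series(traj, reference_frame=10**6)


class TestRmsfProfile:
    def test_identical_frames_give_zero_profile(self, helix20_modes):
        s, _, _ = helix20_modes
        frames = np.repeat(s.coords[None], 12, axis=0)
        out = rmsf_per_residue(Trajectory(frames, np.arange(12.0), s))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_matches_harmonic_covariance(self, helix20_modes):
        """RMSF profile vs the closed-form harmonic prediction (5% at 20k
        frames; rigid modes are unexcited so superposition is benign)."""
        from vibromap.synthetic import harmonic_position_variance

        s, _, modes = helix20_modes
        traj = simulate_harmonic_trajectory(modes, 300.0, 20000, seed=42, structure=s)
        profile = rmsf_per_residue(traj)
        predicted = np.sqrt(harmonic_position_variance(modes, 300.0))
        np.testing.assert_allclose(profile.values, predicted, rtol=0.05)

    def test_invariant_under_per_frame_rigid_motion(self, helix_traj):
        s, traj = helix_traj
        base = rmsf_per_residue(traj)
        frames = traj.frames.copy()
        frames[::2] = frames[::2] @ rotation(0.8).T + np.array([4.0, 1.0, -2.0])
        moved = rmsf_per_residue(Trajectory(frames, traj.times, s))
        np.testing.assert_allclose(moved.values, base.values, atol=1e-3)

    def test_needs_enough_frames(self, helix20_modes):
        s, _, _ = helix20_modes
        frames = np.repeat(s.coords[None], 5, axis=0)
        with pytest.raises(ValueError, match="10 frames"):
            rmsf_per_residue(Trajectory(frames, np.arange(5.0), s))


class TestSaltBridges:
    def test_pair_inside_cutoff(self, asp_lys_structure):
        pairs = detect_salt_bridges(asp_lys_structure, cutoff=4.0)
        assert pairs == [(ResidueKey("A", 1), ResidueKey("A", 2))]

    def test_pair_outside_cutoff(self, asp_lys_structure):
        assert detect_salt_bridges(asp_lys_structure, cutoff=2.5) == []

    def test_two_acids_one_base_deduplicated(self):
        atoms = [
            toy_atom(1, "OD1", "O", "ASP", 1, "A", (0, 0, 0)),
            toy_atom(2, "OD2", "O", "ASP", 1, "A", (1.0, 0, 0)),
            toy_atom(3, "OE1", "O", "GLU", 2, "A", (0, 3.0, 0)),
            toy_atom(4, "NZ", "N", "LYS", 3, "A", (0, 1.5, 0)),
        ]
        s = ProteinStructure(atoms)
        pairs = detect_salt_bridges(s, cutoff=4.0)
        # hand enumeration: ASP1-LYS3 (1.5 and 1.8 Å) once, GLU2-LYS3 (1.5 Å)
        assert pairs == [
            (ResidueKey("A", 1), ResidueKey("A", 3)),
            (ResidueKey("A", 2), ResidueKey("A", 3)),
        ]


def hbond_toy(angle_deg: float, da_dist: float = 2.9) -> ProteinStructure:
    """Donor N-H ... O acceptor with a prescribed donor-H-acceptor angle."""
    n_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([1.0, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)
    direction = np.array([math.cos(theta), math.sin(theta), 0.0])
    o_pos = h_pos + (da_dist - 1.0) * direction if angle_deg == 180.0 else None
    # place O at the requested N-H...O angle, da_dist from N
    if o_pos is None:
        # rotate around H: angle at H between H->N and H->O is angle_deg
        hn = (n_pos - h_pos) / np.linalg.norm(n_pos - h_pos)
        perp = np.array([0.0, 1.0, 0.0])
        ho = math.cos(math.radians(angle_deg)) * hn + math.sin(math.radians(angle_deg)) * perp
        o_pos = h_pos + 1.9 * ho
    atoms = [
        toy_atom(1, "N", "N", "GLY", 1, "A", n_pos),
        toy_atom(2, "H", "H", "GLY", 1, "A", h_pos),
        toy_atom(3, "O", "O", "GLY", 2, "A", o_pos),
    ]
    return ProteinStructure(atoms)


def synthetic_hbond_helix(n: int) -> ProteinStructure:
    """Cα trace with synthetic backbone N/H/O placed so that exactly the
    i -> i+4 hydrogen bonds satisfy the geometric criterion."""
    from vibromap.synthetic import SyntheticSpec, make_structure

    ca = make_structure(SyntheticSpec(n, "ideal_helix")).coords
    atoms = []
    serial = 1
    n_pos = ca + np.array([0.6, 0.0, 0.0])
    o_pos = np.empty_like(ca)
    for i in range(n):
        if i + 4 < n:
            v = n_pos[i + 4] - ca[i]
            o_pos[i] = n_pos[i + 4] - 2.9 * v / np.linalg.norm(v)
        else:
            o_pos[i] = ca[i] + np.array([0.0, 0.0, 0.2])
    for i in range(n):
        atoms.append(toy_atom(serial, "N", "N", "GLY", i + 1, "A", n_pos[i])); serial += 1
        if i >= 4:
            h = n_pos[i] + (o_pos[i - 4] - n_pos[i]) / np.linalg.norm(o_pos[i - 4] - n_pos[i]) * 1.0
            atoms.append(toy_atom(serial, "H", "H", "GLY", i + 1, "A", h)); serial += 1
        atoms.append(toy_atom(serial, "O", "O", "GLY", i + 1, "A", o_pos[i])); serial += 1
    return ProteinStructure(atoms)


class TestHydrogenBonds:
    def test_linear_geometry_counted(self):
        count, pairs = count_hbonds(hbond_toy(180.0))
        assert count == 1
        assert pairs == [(ResidueKey("A", 1), ResidueKey("A", 2))]

    def test_bent_geometry_rejected(self):
        count, _ = count_hbonds(hbond_toy(90.0))
        assert count == 0

    def test_distance_gate(self):
        count, _ = count_hbonds(hbond_toy(180.0, da_dist=3.9))
        assert count == 0

    def test_helix_counts_n_minus_four(self):
        n = 12
        s = synthetic_hbond_helix(n)
        count, pairs = count_hbonds(s)
        assert count == n - 4
        offsets = sorted(donor.residue_seq - acceptor.residue_seq for donor, acceptor in pairs)
        assert offsets == [4] * (n - 4)  # every bond is donor i -> acceptor i-4

    def test_region_restriction(self):
        s = synthetic_hbond_helix(12)
        count, _ = count_hbonds(s, region=(ResidueKey("A", 1), ResidueKey("A", 6)))
        # donors 5,6 reach acceptors 1,2 inside the region
        assert count == 2


class TestTrajectoryIO:
    def test_multimodel_pdb_round_trip(self, tmp_path, helix20_modes):
        from vibromap.structure_io import write_pdb

        s, _, modes = helix20_modes
        traj = simulate_harmonic_trajectory(modes, 300.0, 4, seed=2, structure=s)
        # write frames as a multi-model PDB by hand
        blocks = []
        for f in range(traj.n_frames):
            frame_struct = s.with_coords(traj.frames[f])
            p = tmp_path / "frame.pdb"
            write_pdb(frame_struct, p)
            body = "\n".join(
                line for line in p.read_text().splitlines()
                if line.startswith(("ATOM", "HETATM", "TER"))
            )
            blocks.append(f"MODEL     {f+1:>4d}\n{body}\nENDMDL")
        mm = tmp_path / "traj.pdb"
        mm.write_text("\n".join(blocks) + "\nEND\n")
        back = read_multimodel_pdb(mm)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.frames, traj.frames, atol=5e-4)

    def test_frame_table_round_trip(self, tmp_path, helix20_modes):
        s, _, modes = helix20_modes
        traj = simulate_harmonic_trajectory(modes, 300.0, 3, seed=2, structure=s)
        p = tmp_path / "frames.txt"
        np.savetxt(p, traj.frames.reshape(-1, 3))
        back = read_frame_table(p, s)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.frames, traj.frames, rtol=1e-12)
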