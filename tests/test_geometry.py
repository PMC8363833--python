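"""Superposition, RMSD/RMSF, interdomain geometry, ECDF curves, bond
occupancy and B-factor annotation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from hdxflex.geometry import (
    DomainDefinition,
    GeometrySeries,
    Structure,
    Trajectory,
    bond_occupancy,
    center_of_mass,
    interdomain_angle,
    interdomain_distance,
    kabsch_superpose,
    pair_atoms,
    probability_curve,
    read_pdb,
    rmsd_series,
    rmsf_per_residue,
    superpose_structures,
    write_bfactor,
    write_pdb,
)
from hdxflex.synthetic import TrajSimConfig, simulate_trajectory


def _structure(coords, names=None, resids=None, chains=None, resnames=None,
               masses=None):
    n = len(coords)
    names = np.array(names if names is not None else ["CA"] * n)
    resids = np.array(resids if resids is not None else np.arange(1, n + 1))
    chains = np.array(chains if chains is not None else ["A"] * n)
    resnames = np.array(resnames if resnames is not None else ["ALA"] * n)
    masses = np.array(masses if masses is not None else [12.011] * n)
    return Structure(
        names, np.array(["C"] * n), masses, resids, resnames, chains,
        np.asarray(coords, dtype=float),
    )


def _grid_search_rmsd(mobile, reference, iters=5, n=16):
    """Independent oracle: nested grid search over Euler angles (the
    translation optimum is the centroid match, known in closed form)."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    center = np.zeros(3)
    width = np.pi
    best = np.inf
    for _ in range(iters):
        grid = [np.linspace(c - width, c + width, n) for c in center]
        for x in grid[0]:
            for y in grid[1]:
                for z in grid[2]:
                    R = Rotation.from_euler("xyz", [x, y, z]).as_matrix()
                    r = np.sqrt(((a @ R.T - b) ** 2).sum() / len(a))
                    if r < best:
                        best = r
                        center = np.array([x, y, z])
        width /= n / 2.5
    return best


class TestKabsch:
    def test_self_superposition(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = pts @ R.T + np.array([5.0, -2.0, 7.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-9

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(4, 3)) * 3
        reference = rng.normal(size=(4, 3)) * 3
        _, _, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(_grid_search_rmsd(mobile, reference), abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], abs=1e-9
        )

    def test_joint_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        R = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        r1 = kabsch_superpose(a, b)[2]
        r2 = kabsch_superpose(a @ R.T + t, b @ R.T + t)[2]
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestPairAtoms:
    def test_identical_structures_all_paired(self):
        s = _structure(np.random.default_rng(0).normal(size=(6, 3)))
        ia, ib = pair_atoms(s, s, "identical")
        assert len(ia) == 6
        assert np.array_equal(ia, ib)

    def test_deleted_residue_unpaired(self):
        a = _structure(np.zeros((5, 3)))
        keep = np.array([True, True, False, True, True])
        b = a.subset(keep)
        ia, ib = pair_atoms(a, b, "identical")
        assert len(ia) == 4
        assert 2 not in ia

    def test_aligned_mode_handles_gap(self):
        # homologous sequences, one residue deleted in b: ungapped columns pair
        seq_a = "AKLMNQRSTV"
        seq_b = "AKLMQRSTV"  # N (position 5) deleted
        coords_a = np.arange(30, dtype=float).reshape(10, 3)
        coords_b = np.delete(coords_a, 4, axis=0)
        a = _structure(
            coords_a,
            resnames=[{"A": "ALA", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
                       "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL"}[c]
                      for c in seq_a],
        )
        b = _structure(
            coords_b,
            resids=np.delete(np.arange(1, 11), 4),
            resnames=[{"A": "ALA", "K": "LYS", "L": "LEU", "M": "MET",
                       "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL"}[c]
                      for c in seq_b],
        )
        ia, ib = pair_atoms(a, b, "aligned")
        assert len(ia) == 9  # everything except the deleted ASN
        assert 4 not in ia

    def test_no_pairs_error(self):
        a = _structure(np.zeros((3, 3)), chains=["A"] * 3)
        b = _structure(np.zeros((3, 3)), chains=["B"] * 3, resids=[50, 51, 52])
        with pytest.raises(ValueError, match="paired"):
            pair_atoms(a, b, "identical")


class TestRMSDSeries:
    def test_identical_frames_zero(self):
        ref = _structure(np.random.default_rng(0).normal(size=(10, 3)))
        traj = Trajectory(ref, np.repeat(ref.coords[None], 5, axis=0))
        series = rmsd_series(traj, ref, atom_names=None)
        assert np.allclose(series.values, 0.0, atol=1e-6)

    def test_translated_frames_zero(self):
        ref = _structure(np.random.default_rng(1).normal(size=(10, 3)))
        frames = np.stack([ref.coords + [i, 0, 0] for i in range(4)])
        series = rmsd_series(Trajectory(ref, frames), ref, atom_names=None)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_jittered_frames_match_sigma_sqrt3(self):
        # E[RMSD] ~ sigma*sqrt(3) for iid per-coordinate jitter, large N
        rng = np.random.default_rng(2)
        n_atoms, sigma = 600, 0.5
        ref = _structure(rng.normal(scale=10, size=(n_atoms, 3)))
        frames = ref.coords[None] + rng.normal(0, sigma, size=(20, n_atoms, 3))
        series = rmsd_series(Trajectory(ref, frames), ref, atom_names=None)
        assert series.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestRMSF:
    def test_static_trajectory_zero(self):
        ref = _structure(np.random.default_rng(0).normal(size=(8, 3)))
        traj = Trajectory(ref, np.repeat(ref.coords[None], 4, axis=0))
        assert np.allclose(rmsf_per_residue(traj)["rmsf"], 0.0, atol=1e-12)

    def test_oscillating_residue(self):
        # one atom oscillates +/- d along x; the anchor set is large and
        # extended, so the superposition barely drifts
        rng = np.random.default_rng(3)
        base = rng.normal(scale=50, size=(300, 3))
        d = 0.5
        frames = np.repeat(base[None], 10, axis=0).copy()
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        traj = Trajectory(_structure(base), frames)
        out = rmsf_per_residue(traj)
        assert out.loc[out["resid"] == 1, "rmsf"].iloc[0] == pytest.approx(d, rel=0.02)
        assert out["rmsf"].iloc[1:].max() < 0.02

    def test_per_residue_jitter_recovery(self):
        rng = np.random.default_rng(4)
        n_atoms, n_frames = 200, 500
        sig = np.linspace(0.2, 1.0, n_atoms)
        base = rng.normal(scale=50, size=(n_atoms, 3))
        frames = base[None] + rng.normal(size=(n_frames, n_atoms, 3)) * sig[None, :, None]
        out = rmsf_per_residue(Trajectory(_structure(base), frames))
        expected = sig * np.sqrt(3)
        # 3 standard errors of an RMS estimate ~ 3*expected/sqrt(2*n_frames)
        tol = 3 * expected / np.sqrt(2 * n_frames) + 0.02
        assert np.all(np.abs(out["rmsf"].to_numpy() - expected) < tol)

    def test_single_frame_error(self):
        ref = _structure(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_per_residue(Trajectory(ref, ref.coords[None]))


class TestCenterOfMass:
    def test_equal_masses(self):
        s = _structure([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(center_of_mass(s), [1, 0, 0])

    def test_mass_weighting(self):
        s = _structure([[0, 0, 0], [4, 0, 0]], masses=[1.0, 3.0])
        assert np.allclose(center_of_mass(s), [3, 0, 0])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(7, 3))
        v = np.array([1.0, -2.0, 0.5])
        s1 = _structure(coords)
        s2 = _structure(coords + v)
        assert np.allclose(center_of_mass(s2), center_of_mass(s1) + v)

    def test_empty_selection(self):
        s = _structure(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="empty selection"):
            center_of_mass(s, resid_range=(50, 60))


class TestInterdomain:
    DOM = DomainDefinition(ntd=(1, 2), linker=(3, 3), ctd=(4, 5))

    def test_distance_from_coms(self):
        s = _structure(
            [[0, 0, 0], [0, 0, 0], [0, 0, 15], [0, 0, 30], [0, 0, 30]],
            resids=[1, 2, 3, 4, 5],
        )
        assert interdomain_distance(s, self.DOM) == pytest.approx(30.0)

    def test_distance_symmetric_in_domains(self):
        s = _structure(
            [[0, 0, 0], [0, 0, 0], [0, 0, 15], [0, 0, 30], [0, 0, 30]],
            resids=[1, 2, 3, 4, 5],
        )
        swapped = DomainDefinition(ntd=(1, 2), linker=(3, 3), ctd=(4, 5))
        assert interdomain_distance(s, swapped) == interdomain_distance(s, self.DOM)

    def test_collinear_angle(self):
        s = _structure(
            [[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 0, 0]],
            resids=[1, 2, 3, 4, 5],
        )
        assert interdomain_angle(s, self.DOM) == pytest.approx(180.0)

    def test_orthogonal_angle(self):
        s = _structure(
            [[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 0]],
            resids=[1, 2, 3, 4, 5],
        )
        assert interdomain_angle(s, self.DOM) == pytest.approx(90.0)

    def test_angle_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=5, size=(5, 3))
        s = _structure(coords, resids=[1, 2, 3, 4, 5])
        R = Rotation.from_euler("xyz", [0.5, 1.2, -0.3]).as_matrix()
        s2 = _structure(coords @ R.T + [3, 4, 5], resids=[1, 2, 3, 4, 5])
        assert interdomain_angle(s, self.DOM) == pytest.approx(
            interdomain_angle(s2, self.DOM), abs=1e-9
        )

    def test_missing_domain_residues_listed(self):
        s = _structure(np.zeros((3, 3)), resids=[1, 2, 3])
        with pytest.raises(ValueError, match=r"\[4, 5\]"):
            interdomain_distance(s, self.DOM)

    def test_coincident_linker_com_error(self):
        s = _structure(
            [[1, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0], [2, 0, 0]],
            resids=[1, 2, 3, 4, 5],
        )
        with pytest.raises(ValueError, match="coincides"):
            interdomain_angle(s, self.DOM)


class TestProbabilityCurve:
    def test_constant_series_step(self):
        curve = probability_curve(np.full(20, 4.2))
        assert set(curve["value"]) == {4.2}
        assert curve["probability"].iloc[-1] == 1.0

    def test_median_at_half(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 1001)
        curve = probability_curve(vals)
        med_prob = curve.loc[
            (curve["value"] - np.median(vals)).abs().idxmin(), "probability"
        ]
        assert med_prob == pytest.approx(0.5, abs=0.05)

    def test_monotone_and_bounded(self):
        curve = probability_curve(np.random.default_rng(1).normal(size=50))
        p = curve["probability"].to_numpy()
        assert np.all(np.diff(p) >= 0)
        assert 0.0 <= p[0] and p[-1] == 1.0

    def test_matches_normal_cdf_within_ks_bound(self):
        rng = np.random.default_rng(2)
        n = 1000
        vals = rng.normal(30, 1, n)
        curve = probability_curve(vals)
        diffs = np.abs(
            curve["probability"].to_numpy() - norm.cdf(curve["value"], 30, 1)
        )
        assert diffs.max() < 1.63 / np.sqrt(n)  # KS critical value, alpha=0.01

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="10 frames"):
            probability_curve(np.arange(5, dtype=float))


class TestBondOccupancy:
    def _two_atom_traj(self, distances):
        s = _structure(
            [[0, 0, 0], [1, 0, 0]], names=["NZ", "OD1"],
            resids=[10, 20], resnames=["LYS", "ASP"],
        )
        frames = np.zeros((len(distances), 2, 3))
        frames[:, 1, 0] = distances
        return Trajectory(s, frames)

    def test_four_of_ten(self):
        d = [2.5, 2.5, 2.5, 2.5, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0]
        traj = self._two_atom_traj(d)
        occ, series = bond_occupancy(
            traj, 10, 20, kind="hbond", atoms_i=["NZ"], atoms_j=["OD1"]
        )
        assert occ == pytest.approx(0.4)
        assert np.allclose(series.values, d)

    def test_zero_cutoff(self):
        traj = self._two_atom_traj([2.0, 2.5])
        occ, _ = bond_occupancy(
            traj, 10, 20, kind="hbond", atoms_i=["NZ"], atoms_j=["OD1"], cutoff=0.0
        )
        assert occ == 0.0

    def test_saltbridge_default_atom_sets(self):
        traj = self._two_atom_traj([3.0, 3.5])
        occ, _ = bond_occupancy(traj, 20, 10, kind="saltbridge")
        assert occ == pytest.approx(0.5)  # 3.0 <= 3.2 < 3.5

    def test_unknown_residue(self):
        traj = self._two_atom_traj([2.0])
        with pytest.raises(ValueError, match="99"):
            bond_occupancy(traj, 99, 20, kind="hbond", atoms_i=["NZ"], atoms_j=["OD1"])


class TestPDBAndBFactor:
    def test_multi_model_round_trip(self, tmp_path):
        traj = simulate_trajectory(TrajSimConfig(n_frames=3, n_residues=165, seed=0))
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        back = read_pdb(path)
        assert back.n_frames == 3
        assert back.topology.n_atoms == traj.topology.n_atoms
        # PDB stores 3 decimals
        assert np.allclose(back.frames, traj.frames, atol=1.5e-3)

    def test_bfactor_round_trip_and_formatting(self, tmp_path):
        s = _structure(np.random.default_rng(0).normal(scale=5, size=(5, 3)))
        path = tmp_path / "bf.pdb"
        write_bfactor(s, {1: 12.345, 3: -7.5}, path, sentinel=0.0)
        text = path.read_text()
        assert "12.35" in text  # %6.2f formatting contract
        back = read_pdb(path).frame(0)
        assert back.bfactors[0] == pytest.approx(12.35, abs=0.01)
        assert back.bfactors[2] == pytest.approx(-7.5, abs=0.01)
        assert back.bfactors[1] == 0.0  # sentinel

    def test_bfactor_out_of_range(self, tmp_path):
        s = _structure(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="printable"):
            write_bfactor(s, {1: 5000.0}, tmp_path / "x.pdb")
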