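import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from capi.structure_io import AtomRecord, StructureModel, TrajectoryEnsemble
from capi.trajectory_descriptors import (
    DegenerateFitError, SelectionError,
    superpose, rmsf, distance_series, running_stats, twisted_accordion,
)
from capi.synthetic_data import make_trajectory, make_ring_cation


def _chain(n=30, seed=0, start_res=160):
    rng = np.random.default_rng(seed)
    atoms = [AtomRecord(i + 1, "CA", "GLY", "A", start_res + i, "C", rng.uniform(-10, 10, 3))
             for i in range(n)]
    return StructureModel(atoms)


def _quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion absolute orientation."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    M = mob.T @ ref
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    N = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(N)[-1]
    e0 = np.sum(mob**2) + np.sum(ref**2)
    return np.sqrt(max(e0 - 2 * lam, 0.0) / mobile.shape[0])


class TestSuperpose:
    def test_identity_for_identical_sets(self):
        coords = _chain().coordinates()
        R, t, rmsd = superpose(coords, coords)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)
        assert rmsd < 1e-12

    def test_exact_rigid_motion_recovered(self):
        ref = _chain().coordinates()
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([3.0, -7.0, 1.5])
        R, t, rmsd = superpose(mobile, ref)
        assert rmsd <= 1e-10
        assert np.allclose(mobile @ R.T + t, ref, atol=1e-9)
        assert abs(np.linalg.det(R) - 1.0) < 1e-10

    def test_noisy_rmsd_matches_quaternion_oracle(self):
        rng = np.random.default_rng(5)
        ref = _chain().coordinates()
        rot = Rotation.random(rng=rng).as_matrix()
        mobile = ref @ rot.T + rng.uniform(-5, 5, 3) + rng.normal(0, 0.1, ref.shape)
        _, _, rmsd = superpose(mobile, ref)
        assert abs(rmsd - _quaternion_superpose_rmsd(mobile, ref)) < 1e-8

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateFitError):
            superpose(line, line + 1.0)


class TestRMSF:
    def test_static_trajectory_gives_zero(self):
        base = _chain()
        traj = make_trajectory(base, 0.0, 10, seed=0)
        assert np.all(rmsf(traj).rmsf < 1e-12)

    def test_rigid_rotations_only_give_zero(self):
        base = _chain()
        rng = np.random.default_rng(2)
        coords = base.coordinates()
        frames = np.stack([coords @ Rotation.random(rng=rng).as_matrix().T
                           + rng.uniform(-3, 3, 3) for _ in range(20)])
        traj = TrajectoryEnsemble(base, frames, np.arange(20.0))
        assert np.all(rmsf(traj).rmsf <= 1e-8)

    def test_rigid_motion_invariance_of_profile(self):
        base = _chain()
        traj = make_trajectory(base, 0.3, 200, seed=1)
        rng = np.random.default_rng(3)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = TrajectoryEnsemble(base, traj.frames @ rot.T + np.array([5.0, -3.0, 8.0]),
                                   traj.times)
        assert np.max(np.abs(rmsf(traj).rmsf - rmsf(moved).rmsf)) < 1e-8

    def test_planted_amplitude_order_recovered(self):
        base = _chain(n=40, seed=4)
        planted = np.linspace(0.1, 0.8, 40)
        traj = make_trajectory(base, planted, 2000, seed=5)
        rho = spearmanr(planted, rmsf(traj).rmsf).statistic
        assert rho > 0.95

    def test_single_frame_rejected(self):
        base = _chain()
        traj = TrajectoryEnsemble(base, base.coordinates()[None], np.array([0.0]))
        with pytest.raises(ValueError):
            rmsf(traj)


class TestDistanceSeries:
    def test_constant_pair(self):
        atoms = [AtomRecord(1, "CA", "GLY", "A", 1, "C", np.zeros(3)),
                 AtomRecord(2, "CA", "GLY", "A", 2, "C", np.array([5.0, 0, 0])),
                 AtomRecord(3, "CA", "GLY", "A", 3, "C", np.array([0, 9.0, 0]))]
        base = StructureModel(atoms)
        traj = make_trajectory(base, 0.0, 10, seed=0)
        ds = distance_series(traj, "A:1:CA", "A:2:CA", window=5)
        assert np.allclose(ds.values, 5.0, atol=1e-12)

    def test_moving_point(self):
        atoms = [AtomRecord(1, "CA", "GLY", "A", 1, "C", np.zeros(3)),
                 AtomRecord(2, "CA", "GLY", "A", 2, "C", np.array([3.0, 0, 0]))]
        base = StructureModel(atoms)
        frames = np.zeros((3, 2, 3))
        frames[:, 1, 0] = [3.0, 4.0, 5.0]
        traj = TrajectoryEnsemble(base, frames, np.arange(3.0))
        ds = distance_series(traj, "A:1:CA", "A:2:CA", window=1)
        assert np.allclose(ds.values, [3.0, 4.0, 5.0])

    def test_ring_centroid_distance_matches_planted(self):
        model, _ = make_ring_cation(70.0, 25.0, 5.5)
        traj = TrajectoryEnsemble(model, model.coordinates()[None].repeat(4, axis=0),
                                  np.arange(4.0))
        ds = distance_series(traj, "A:94:ring", "A:86:CZ", window=1)
        assert np.allclose(ds.values, 5.5, atol=1e-6)

    def test_symmetry_in_endpoints(self):
        base = _chain()
        traj = make_trajectory(base, 0.2, 50, seed=6)
        d1 = distance_series(traj, "A:160:CA", "A:170:CA", window=10).values
        d2 = distance_series(traj, "A:170:CA", "A:160:CA", window=10).values
        assert np.array_equal(d1, d2)


class TestRunningStats:
    def test_constant_series(self):
        m, s = running_stats(np.full(50, 3.7), 10)
        assert np.allclose(m, 3.7) and np.allclose(s, 0.0)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=40)
        m, s = running_stats(x, 1)
        assert np.allclose(m, x) and np.allclose(s, 0.0)

    def test_ramp_center_matches_direct_sum(self):
        x = np.arange(1.0, 201.0)
        m, _ = running_stats(x, 100)
        i = 100
        oracle = x[i - 49: i + 51].mean()  # brute-force average of 100 surrounding values
        assert abs(m[i] - oracle) < 1e-12

    @pytest.mark.parametrize("n,window", [(7, 3), (50, 10), (237, 50), (500, 100), (16, 16)])
    def test_brute_force_equivalence_all_indices(self, n, window):
        x = np.random.default_rng(n).normal(size=n)
        m, s = running_stats(x, window)
        for i in range(n):
            lo = max(i - (window - 1) // 2, 0)
            hi = min(i + window // 2, n - 1) + 1
            w = x[lo:hi]
            assert abs(m[i] - w.mean()) < 1e-10
            assert abs(s[i] - w.std()) < 1e-10

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            running_stats(np.arange(5.0), 6)


class TestTwistedAccordion:
    def test_two_state_switch_detected(self):
        base = _chain(n=30, seed=0, start_res=160)  # covers residues 168 and 178
        i = 168 - 160
        j = 178 - 160
        traj = make_trajectory(base, 0.1, 400, seed=3, pair_switch=(i, j, 12.0, 8.0, 150))
        ds = twisted_accordion(traj, window=100)
        cross = int(np.argmax(ds.smoothed_mean < 10.0))
        assert abs(cross - 151) <= 50  # within half the smoothing window

    def test_static_fixture_constant(self):
        base = _chain(n=30, seed=0, start_res=160)
        i, j = 168 - 160, 178 - 160
        traj = make_trajectory(base, 0.0, 20, seed=0, pair_switch=(i, j, 9.0, 9.0, 10))
        ds = twisted_accordion(traj, window=10)
        assert np.allclose(ds.values, 9.0, atol=1e-12)

    def test_missing_residue_raises_selection_error(self):
        base = _chain(n=5, seed=0, start_res=160)  # no residue 178
        traj = make_trajectory(base, 0.0, 5, seed=0)
        with pytest.raises(SelectionError):
            twisted_accordion(traj)
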