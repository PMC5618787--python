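import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gsecens.ensemble_analysis import (apply_transform,
                                       density_map, gromos_cluster,
                                       hbond_occupancy, histogram,
                                       pairwise_rmsd_matrix, pca, porcupine,
                                       rmsf, superpose)
from gsecens.order_params import GeometryError
from gsecens.structure_io import Structure, Trajectory
from gsecens.synthetic_data import default_config, simulate_two_state_trajectory


def _toy_structure(n):
    return Structure(np.arange(1, n + 1), np.array(["CA"] * n, dtype=object),
                     np.array(["C"] * n, dtype=object), np.arange(1, n + 1),
                     np.array(["GLY"] * n, dtype=object),
                     np.array(["A"] * n, dtype=object), np.zeros((n, 3)))


def _traj(coords):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(_toy_structure(coords.shape[1]), coords)


def superpose_rmsd_oracle(mobile, reference):
    """Independent minimal-RMSD via scipy's vector alignment."""
    mc, rc = mobile.mean(0), reference.mean(0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    fitted = rot.apply(mobile - mc) + rc
    return float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))


class TestSuperpose:
    def test_identity(self, rng):
        X = rng.normal(size=(8, 3))
        rot, trans, r = superpose(X, X)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)

    def test_recovers_known_rigid_motion(self, rng):
        X = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = X @ R.T + np.array([1.0, -2.0, 0.5])
        rot, trans, r = superpose(moved, X)
        assert r == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(apply_transform(moved, rot, trans), X, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_closed_form_rmsd_for_symmetric_displacement(self):
        # radial +/-0.1 nm x-displacements on 2 of 4 atoms leave the optimal
        # transform at identity: RMSD = sqrt((0.1^2 + 0.1^2) / 4)
        ref = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        mob = ref.copy()
        mob[0, 0] += 0.1
        mob[1, 0] -= 0.1
        _, _, r = superpose(mob, ref)
        assert r == pytest.approx(np.sqrt(0.005), abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            X = rng.normal(size=(rng.integers(4, 12), 3))
            Y = X + 0.3 * rng.normal(size=X.shape)
            _, _, r = superpose(Y, X)
            assert r == pytest.approx(superpose_rmsd_oracle(Y, X), abs=1e-9)

    def test_symmetry(self, rng):
        X, Y = rng.normal(size=(2, 9, 3))
        assert superpose(X, Y)[2] == pytest.approx(superpose(Y, X)[2], abs=1e-9)

    def test_collinear_fit_set_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0, 0])
        with pytest.raises(GeometryError):
            superpose(line, line)


class TestRmsf:
    def test_static_trajectory_zero(self):
        base = np.random.default_rng(0).normal(size=(6, 3))
        t = _traj(np.repeat(base[None], 4, axis=0))
        np.testing.assert_allclose(rmsf(t), 0.0, atol=1e-12)

    def test_two_frame_closed_form(self):
        # one atom alternating +/-a about its mean; anchor atoms far away
        # dominate the fit, so the moving atom's RMSF equals a
        a = 0.05
        base = np.array([[5.0, 0, 0], [-5.0, 0, 0], [0, 5.0, 0], [0, -5.0, 0],
                         [0, 0, 0.0]])
        f1, f2 = base.copy(), base.copy()
        f1[4, 2] += a
        f2[4, 2] -= a
        vals = rmsf(_traj([f1, f2]), fit_indices=np.arange(4))
        assert vals[4] == pytest.approx(a, abs=1e-9)

    def test_normalized_max_is_one(self, benchmark_sim):
        _, traj, _, _ = benchmark_sim
        sub = Trajectory(traj.topology, traj.coords[:50])
        vals = rmsf(sub, normalize=True)
        assert vals.max() == pytest.approx(1.0)
        assert np.all(vals > 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(_traj(np.zeros((1, 5, 3))))


class TestHistogram:
    def test_constant_column_single_bin(self):
        dens, edges = histogram(np.full(100, 2.5), bins=10, range=(0, 5))
        assert np.count_nonzero(dens) == 1
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_uniform_samples(self, rng):
        x = rng.uniform(0, 1, size=10_000)
        dens, edges = histogram(x, bins=10, range=(0, 1))
        # each bin holds 0.1 of the mass within binomial sampling error
        np.testing.assert_allclose(dens * 0.1, 0.1, atol=4 * np.sqrt(0.1 * 0.9 / 10_000))

    def test_2d_product_structure(self, rng):
        x = rng.normal(size=20_000)
        y = rng.normal(size=20_000)
        dens, xe, ye = histogram(x, y, bins=8, range=((-3, 3), (-3, 3)))
        dx, dy = np.diff(xe)[0], np.diff(ye)[0]
        assert np.sum(dens) * dx * dy == pytest.approx(1.0, abs=1e-9)
        marg_x = dens.sum(axis=1) * dy
        marg_y = dens.sum(axis=0) * dx
        np.testing.assert_allclose(dens, np.outer(marg_x, marg_y), atol=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram(np.array([]))


def _two_mode_trajectory(n_frames=5000, ratio=2.0, seed=101):
    """Static anchor scaffold plus two independent 1-D Gaussian modes with
    amplitude std ratio `ratio` (variance ratio ratio^2)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(12, 3)) * 2.0
    coords = np.repeat(base[None], n_frames, axis=0)
    a = rng.normal(0.0, 0.1 * ratio, size=n_frames)
    b = rng.normal(0.0, 0.1, size=n_frames)
    coords[:, 10, 0] += a
    coords[:, 11, 1] += b
    return _traj(coords), np.arange(10)


class TestPca:
    def test_single_moving_coordinate(self):
        coords = np.repeat(np.random.default_rng(1).normal(size=(1, 6, 3)), 40, axis=0)
        coords[:, 5, 0] += np.linspace(-1, 1, 40)
        res = pca(_traj(coords), fit_indices=np.arange(5))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)
        base, vecs = porcupine(res, 0, scale=1.0)
        moving = np.linalg.norm(vecs, axis=1)
        assert np.argmax(moving) == 5
        assert moving[:5].max() < 1e-6

    def test_two_mode_variance_split(self):
        traj, fit_idx = _two_mode_trajectory()
        res = pca(traj, fit_indices=fit_idx)
        assert res.variance_fraction[0] == pytest.approx(0.8, abs=0.03)
        assert res.variance_fraction[1] == pytest.approx(0.2, abs=0.03)

    def test_eigenvector_orthonormality_and_variance_conservation(self, benchmark_sim):
        _, traj, _, _ = benchmark_sim
        sub = Trajectory(traj.topology, traj.coords[:80])
        res = pca(sub, n_components=10)
        G = res.eigenvectors @ res.eigenvectors.T
        np.testing.assert_allclose(G, np.eye(res.n_kept), atol=1e-8)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)  # descending
        assert np.all(res.eigenvalues >= 0)

    def test_porcupine_scale_and_bounds(self):
        traj, fit_idx = _two_mode_trajectory(n_frames=50)
        res = pca(traj, fit_indices=fit_idx, n_components=3)
        _, vecs = porcupine(res, 0, scale=0.0)
        np.testing.assert_allclose(vecs, 0.0)
        with pytest.raises(IndexError):
            porcupine(res, 99)

    def test_mode_direction_recovered(self):
        traj, fit_idx = _two_mode_trajectory(n_frames=3000)
        res = pca(traj, fit_indices=fit_idx, n_components=2)
        _, vecs = porcupine(res, 0)
        v = vecs[10] / np.linalg.norm(vecs[10])
        assert abs(v @ np.array([1.0, 0, 0])) >= 0.99


def gromos_reference(rmsd, cutoff):
    """Straightforward list-based reimplementation of the clustering rule."""
    n = rmsd.shape[0]
    remaining = list(range(n))
    member = [-1] * n
    cid = 0
    while remaining:
        best, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining if rmsd[i][j] <= cutoff or i == j)
            if count > best_count:
                best, best_count = i, count
        cluster = [j for j in remaining if rmsd[best][j] <= cutoff or j == best]
        for j in cluster:
            member[j] = cid
        remaining = [j for j in remaining if j not in cluster]
        cid += 1
    return member


class TestGromosCluster:
    def test_identical_frames_single_cluster(self):
        coords = np.repeat(np.random.default_rng(2).normal(size=(1, 5, 3)), 7, axis=0)
        res = gromos_cluster(coords, cutoff=0.01)
        assert res.n_clusters == 1
        assert res.sizes == [7]
        assert res.membership[res.centroids[0]] == 0

    def test_two_state_noise_free_recovers_labels(self):
        cfg = default_config(noise_sigma_nm=0.0, n_frames=30, seed=6)
        traj, gt = simulate_two_state_trajectory(cfg)
        res = gromos_cluster(traj.coords, cutoff=0.2)
        assert res.n_clusters == 2
        # cluster ids must be a relabeling of the hidden states
        for cid in (0, 1):
            states = set(gt.labels[res.membership == cid])
            assert len(states) == 1

    def test_large_cutoff_single_cluster(self, rng):
        coords = rng.normal(size=(6, 8, 3))
        res = gromos_cluster(coords, cutoff=1e3)
        assert res.n_clusters == 1

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(12):
            F = int(rng.integers(4, 16))
            coords = rng.normal(size=(F, 6, 3)) * 0.3
            M = pairwise_rmsd_matrix(coords)
            cutoff = float(rng.uniform(0.1, 0.6))
            res = gromos_cluster(coords, cutoff=cutoff, rmsd_matrix=M)
            ref = gromos_reference(M, cutoff)
            assert list(res.membership) == ref
            assert sorted(res.sizes, reverse=True) == res.sizes


def hbond_geometry(d_da, angle_deg):
    """Donor at origin, acceptor on +x at d_da, hydrogen placed 0.1 nm
    from the donor in the xz-plane so the D-H-A angle equals angle_deg."""
    D = np.zeros(3)
    A = np.array([d_da, 0.0, 0.0])
    ang = np.radians(angle_deg)
    r_dh = 0.1
    best, best_err = None, np.inf
    for t in np.linspace(0, np.pi, 20001):
        H = np.array([r_dh * np.cos(t), 0.0, r_dh * np.sin(t)])
        v1, v2 = D - H, A - H
        got = np.arccos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
        if abs(got - ang) < best_err:
            best, best_err = H, abs(got - ang)
    return D, best, A


class TestHbonds:
    _geometry = staticmethod(hbond_geometry)

    def test_criteria_accept_and_reject(self):
        D, H, A = self._geometry(0.28, 165.0)
        coords = np.stack([D, H, A])[None]
        occ = hbond_occupancy(_traj(coords), [(0, 1, 2)])
        assert occ[0] == 1.0
        D, H, A = self._geometry(0.35, 165.0)
        occ = hbond_occupancy(_traj(np.stack([D, H, A])[None]), [(0, 1, 2)])
        assert occ[0] == 0.0
        D, H, A = self._geometry(0.28, 120.0)  # angle below 150 degrees
        occ = hbond_occupancy(_traj(np.stack([D, H, A])[None]), [(0, 1, 2)])
        assert occ[0] == 0.0

    def test_half_satisfied_occupancy(self):
        Dg, Hg, Ag = self._geometry(0.28, 170.0)
        good = np.stack([Dg, Hg, Ag])
        bad = good.copy()
        bad[2, 0] += 0.2  # push acceptor out of range
        frames = np.stack([good, bad] * 5)
        occ = hbond_occupancy(_traj(frames), [(0, 1, 2)])
        assert occ[0] == 0.5

    def test_window_and_reorder_invariance(self, rng):
        Dg, Hg, Ag = self._geometry(0.28, 170.0)
        good = np.stack([Dg, Hg, Ag])
        bad = good.copy()
        bad[2, 0] += 0.5
        frames = np.stack([good] * 3 + [bad] * 7)
        t = _traj(frames)
        assert hbond_occupancy(t, [(0, 1, 2)], window=(0, 3))[0] == 1.0
        perm = rng.permutation(10)
        t2 = _traj(frames[perm])
        assert hbond_occupancy(t2, [(0, 1, 2)])[0] == hbond_occupancy(t, [(0, 1, 2)])[0]
        with pytest.raises(ValueError):
            hbond_occupancy(t, [(0, 1, 2)], window=(5, 5))

    def test_distance_only_mode_warns(self):
        Dg, Hg, Ag = self._geometry(0.28, 120.0)
        t = _traj(np.stack([Dg, Hg, Ag])[None])
        with pytest.warns(UserWarning, match="distance-only"):
            occ = hbond_occupancy(t, [(0, None, 2)])
        assert occ[0] == 1.0


class TestDensityMap:
    def test_single_atom_peak_location(self):
        dm = density_map(np.array([[1.0, 2.0, 3.0]]), resolution=0.8, voxel=0.1)
        peak = np.unravel_index(np.argmax(dm.grid), dm.grid.shape)
        pos = dm.origin + np.array(peak) * dm.voxel
        assert np.linalg.norm(pos - [1.0, 2.0, 3.0]) <= dm.voxel * np.sqrt(3) / 2 + 1e-9

    def test_mass_conservation(self, rng):
        coords = rng.normal(size=(40, 3))
        w = rng.uniform(1.0, 3.0, size=40)
        dm = density_map(coords, weights=w, resolution=0.8, voxel=0.1)
        assert dm.integral() == pytest.approx(w.sum(), rel=0.01)

    def test_mirror_symmetry(self):
        coords = np.array([[-0.55, 0.0, 0.0], [0.55, 0.0, 0.0]])
        dm = density_map(coords, resolution=0.8, voxel=0.1)
        np.testing.assert_allclose(dm.grid, dm.grid[::-1], atol=1e-9)

    def test_invalid_resolution_voxel(self):
        with pytest.raises(ValueError):
            density_map(np.zeros((1, 3)), resolution=0.05, voxel=0.1)
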