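import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tetherloc import densfit as df
from tetherloc import synthetic_data as sd
from tetherloc.densfit import DensityMap
from tetherloc.structio import Residue, RigidTransform, StructureModel


@pytest.fixture(scope="module")
def probe():
    return sd.make_domain(30, seed=4)


@pytest.fixture(scope="module")
def probe_map(probe):
    return sd.simulate_density(probe, resolution=14.0, voxel=2.0, pad=12.0)


def random_map(shape=(16, 16, 16), voxel=2.0, seed=0):
    r = np.random.default_rng(seed)
    return DensityMap(r.normal(size=shape), voxel)


class TestIO:
    def test_ccp4_round_trip_bit_exact(self, tmp_path, probe_map):
        m = DensityMap(probe_map.grid.astype(np.float32).astype(np.float64),
                       probe_map.voxel, np.array([1.5, -2.0, 3.25]))
        p = tmp_path / "m.ccp4"
        m.write_ccp4(p)
        back = df.read_ccp4(p)
        np.testing.assert_array_equal(back.grid, m.grid)
        assert back.voxel == pytest.approx(m.voxel)
        np.testing.assert_array_equal(back.origin, m.origin)


class TestFilters:
    def test_lowpass_strength_scales_with_resolution(self, probe_map):
        """Coarser target resolution attenuates more; the map's variance
        decreases monotonically with the filter scale."""
        variances = [
            df.lowpass(probe_map, resolution=r).grid.var() for r in (5.0, 10.0, 20.0)
        ]
        assert variances[0] > variances[1] > variances[2]

    def test_lowpass_smooths_white_noise(self):
        m = random_map(seed=3)
        out = df.lowpass(m, resolution=8.0)
        assert out.grid.var() < m.grid.var()
        assert out.grid.mean() == pytest.approx(m.grid.mean(), abs=1e-12)

    def test_lowpass_impulse_matches_closed_form(self):
        n, voxel, res = 32, 2.0, 12.0
        grid = np.zeros((n, n, n))
        grid[n // 2, n // 2, n // 2] = 1.0
        out = df.lowpass(DensityMap(grid, voxel), res)
        # analytic: transfer exp(-ln2 f² res²) ⇒ real-space Gaussian kernel
        a = math.log(2.0) * res**2
        idx = np.arange(n) - n // 2
        r2 = (idx[:, None, None] ** 2 + idx[None, :, None] ** 2
              + idx[None, None, :] ** 2) * voxel**2
        kernel = (math.pi / a) ** 1.5 * np.exp(-(math.pi**2) * r2 / a) * voxel**3
        assert np.abs(out.grid - kernel).max() < 0.01 * kernel.max()

    def test_lowpass_nyquist_guard(self, probe_map):
        with pytest.raises(ValueError):
            df.lowpass(probe_map, resolution=1.0)

    def test_laplacian_of_constant_is_zero(self):
        m = DensityMap(np.full((8, 8, 8), 3.7), 1.5)
        np.testing.assert_array_equal(df.laplacian(m).grid, 0.0)

    def test_laplacian_impulse_stencil(self):
        grid = np.zeros((9, 9, 9))
        grid[4, 4, 4] = 1.0
        out = df.laplacian(DensityMap(grid, 2.0)).grid
        assert out[4, 4, 4] == pytest.approx(-6 / 4.0)
        assert out[3, 4, 4] == pytest.approx(1 / 4.0)
        assert out[4, 4, 5] == pytest.approx(1 / 4.0)

    def test_laplacian_of_quadratic_ramp(self):
        n, voxel = 12, 1.5
        x = np.arange(n) * voxel
        grid = np.broadcast_to((x**2)[:, None, None], (n, n, n)).copy()
        out = df.laplacian(DensityMap(grid, voxel)).grid
        np.testing.assert_allclose(out[1:-1, 1:-1, 1:-1], 2.0, atol=1e-9)


class TestMirror:
    def test_involution(self, probe_map):
        np.testing.assert_array_equal(df.mirror(df.mirror(probe_map)).grid,
                                      probe_map.grid)

    def test_centrosymmetric_map_is_self_mirror(self):
        g = np.zeros((9, 9, 9))
        g[4, 4, 4] = 2.0
        g[2, 4, 4] = g[6, 4, 4] = 1.0
        m = DensityMap(g, 2.0)
        np.testing.assert_array_equal(df.mirror(m).grid, m.grid)

    def test_chiral_map_differs_from_mirror(self, probe_map):
        assert np.abs(df.mirror(probe_map).grid - probe_map.grid).max() > 0


class TestRotationGrid:
    @pytest.mark.parametrize("step", [30.0, 45.0])
    def test_covers_random_rotations_within_step(self, step):
        grid = df.rotation_grid(step)
        rng = np.random.default_rng(1)
        for _ in range(15):
            R = Rotation.random(rng=rng).as_matrix()
            angles = [df._rotation_angle_deg(R, G) for G in grid]
            assert min(angles) <= step

    def test_identity_on_grid(self):
        grid = df.rotation_grid(30.0)
        np.testing.assert_array_equal(grid[0], np.eye(3))


class TestExhaustiveFit:
    def test_self_fit_recovers_identity(self, probe, probe_map):
        res = df.exhaustive_fit(probe_map, probe, angular_step=20.0,
                                lowpass_to=14.0, laplacian_filter=False)
        best = res[0]
        assert best.ccc >= 0.99
        assert best.transform.angle_to(RigidTransform.identity()) <= 20.0
        centroid = probe.ca_array().mean(axis=0)
        assert np.linalg.norm(best.transform.apply(centroid) - centroid) <= probe_map.voxel

    def test_recovers_constructed_rotation(self, probe):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        c = probe.ca_array().mean(axis=0)
        rt = RigidTransform(R, c - R @ c)
        dmap = sd.simulate_density(probe.transformed(rt), resolution=14.0,
                                   voxel=2.0, pad=12.0)
        res = df.exhaustive_fit(dmap, probe, angular_step=20.0, lowpass_to=14.0)
        assert res[0].transform.angle_to(rt) <= 20.0

    def test_spectral_scores_equal_direct_space(self, probe, probe_map, rng):
        for lap in (False, True):
            R = Rotation.random(rng=rng).as_matrix()
            ccc, dens = df.correlation_scores(probe_map, probe, R,
                                              lowpass_to=14.0, laplacian_filter=lap)
            for _ in range(3):
                shift = tuple(int(rng.integers(0, s)) for s in probe_map.shape)
                oracle = df.direct_space_ccc(probe_map, dens, shift,
                                             laplacian_filter=lap)
                assert abs(ccc[shift] - oracle) < 1e-6

    def test_score_invariant_under_affine_rescaling(self, probe, probe_map):
        scaled = DensityMap(3.0 * probe_map.grid + 5.0, probe_map.voxel,
                            probe_map.origin)
        a = df.exhaustive_fit(probe_map, probe, angular_step=40.0, lowpass_to=14.0,
                              refine=False, n_results=1)
        b = df.exhaustive_fit(scaled, probe, angular_step=40.0, lowpass_to=14.0,
                              refine=False, n_results=1)
        assert a[0].ccc == pytest.approx(b[0].ccc, abs=1e-9)

    def test_degenerate_inputs_rejected(self, probe, probe_map):
        with pytest.raises(ValueError):
            df.exhaustive_fit(DensityMap(np.zeros((8, 8, 8)), 2.0), probe)
        empty = StructureModel("e", {"A": [Residue("A", 1, "ALA", None)]})
        with pytest.raises(ValueError):
            df.exhaustive_fit(probe_map, empty)


class TestHandedness:
    def test_sign_flips_with_particle_hand(self):
        sol = sd.make_solenoid(n_residues=120)
        dmap = sd.simulate_density(sol, resolution=22.0, voxel=4.0, pad=10.0)
        particles = sd.simulate_particles(dmap, n=6, snr=1.0, seed=3)
        res = df.handedness_test(particles, dmap, angular_step=60.0)
        assert res["mean_delta_ccc"] > 0
        flipped = sd.simulate_particles(df.mirror(dmap), n=6, snr=1.0, seed=4)
        res_m = df.handedness_test(flipped, dmap, angular_step=60.0)
        assert res_m["mean_delta_ccc"] < 0

    def test_too_few_particles_rejected(self, probe_map):
        with pytest.raises(ValueError):
            df.handedness_test([probe_map], probe_map)


class TestFSC:
    def test_self_correlation_is_one_everywhere(self, probe_map):
        curve = df.fsc(probe_map, probe_map)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-9)
        assert np.all(np.diff(curve.frequencies) > 0)

    def test_independent_noise_decorrelates(self):
        a = random_map(seed=1)
        b = random_map(seed=2)
        curve = df.fsc(a, b)
        assert np.abs(curve.values[2:]).max() < 0.2

    def test_half_map_resolution_near_filter_scale(self):
        sol = sd.make_solenoid(n_residues=100)
        clean = sd.simulate_density(sol, resolution=25.0, voxel=3.0, pad=15.0)
        r = np.random.default_rng(5)
        noise = clean.grid.std() * 0.6
        a = DensityMap(clean.grid + r.normal(scale=noise, size=clean.shape),
                       3.0, clean.origin)
        b = DensityMap(clean.grid + r.normal(scale=noise, size=clean.shape),
                       3.0, clean.origin)
        res = df.resolution_at(df.fsc(a, b), 0.5)
        assert res == pytest.approx(25.0, rel=0.15)

    def test_grid_mismatch_rejected(self, probe_map):
        with pytest.raises(ValueError):
            df.fsc(probe_map, random_map(shape=(8, 8, 8)))


class TestContour:
    def test_extreme_targets(self, probe_map):
        t_all = df.contour_by_volume(probe_map, probe_map.total_volume())
        assert t_all == pytest.approx(probe_map.grid.min())
        t_one = df.contour_by_volume(probe_map, probe_map.voxel**3)
        assert t_one == pytest.approx(probe_map.grid.max())

    def test_half_volume_matches_sort_oracle(self):
        m = random_map(seed=7)
        target = m.total_volume() / 2
        t = df.contour_by_volume(m, target)
        enclosed = (m.grid >= t).sum() * m.voxel**3
        assert 0 <= target - enclosed <= m.voxel**3
        oracle = np.sort(m.grid, axis=None)[::-1][int(target // m.voxel**3) - 1]
        assert t == pytest.approx(oracle)

    def test_monotone_in_target(self):
        m = random_map(seed=8)
        t1 = df.contour_by_volume(m, 100.0)
        t2 = df.contour_by_volume(m, 1000.0)
        assert t2 <= t1

    def test_invalid_targets(self, probe_map):
        with pytest.raises(ValueError):
            df.contour_by_volume(probe_map, -1.0)
        with pytest.raises(ValueError):
            df.contour_by_volume(probe_map, probe_map.total_volume() * 2)


class TestResidualSegment:
    def test_fully_explained_map_leaves_nothing(self, probe, probe_map):
        thr = df.contour_by_volume(probe_map, df.model_volume(probe))
        seg, info = df.residual_segment(probe_map, probe, thr, resolution=14.0,
                                        mask_radius=25.0)
        assert info["total_masked_voxels"] == 0

    def test_disjoint_blob_recovered(self, probe):
        blob = sd.make_domain(10, seed=2, chain_id="Z")
        for r in blob.residues():
            r.ca = r.ca + np.array([60.0, 0.0, 0.0])
        both = probe.copy()
        both.chains["Z"] = blob.chains["Z"]
        dmap = sd.simulate_density(both, resolution=14.0, voxel=2.0, pad=12.0)
        thr = df.contour_by_volume(dmap, df.model_volume(both))
        seg, info = df.residual_segment(dmap, probe, thr, resolution=14.0)
        above = dmap.grid >= thr
        blob_pts = blob.ca_array()
        idx = np.argwhere(above)
        coords = dmap.origin + dmap.voxel * idx
        near_blob = (np.linalg.norm(
            coords[:, None, :] - blob_pts[None, :, :], axis=2
        ).min(axis=1) < 8.0)
        truth_mask = np.zeros(dmap.shape, dtype=bool)
        truth_mask[tuple(idx[near_blob].T)] = True
        overlap = (seg.grid.astype(bool) & truth_mask).sum() / truth_mask.sum()
        assert overlap >= 0.9
        assert info["largest_volume"] <= above.sum() * dmap.voxel**3
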