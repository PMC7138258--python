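import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cepaq.grid import GridSpec
from cepaq.phantom import (A_MAX_MM, ETA_MAX, BloodOpticsModel, DatasetSpec,
                           TissueVolume, VesselPath, assign_optics,
                           background_offset, blood_mu_a, build_manifest,
                           iter_items, random_walk_vessel, rasterize_vessels,
                           realize_item, standard_datasets)


# --------------------------------------------------------------------------
# random walk
# --------------------------------------------------------------------------

class TestRandomWalkVessel:
    def test_eta_zero_degenerate_path(self):
        path = random_walk_vessel(0, 10, (1.0, 2.0, 3.0))
        frozen = VesselPath(points=np.tile([1.0, 2.0, 3.0], (11, 1)),
                            eta=0.0, radius_mm=3.0)
        assert np.allclose(frozen.points, frozen.points[0])
        # sampled eta is almost surely nonzero, but forcing it collapses
        # the walk: all increments scale with eta
        increments = np.diff(path.points, axis=0)
        assert np.all(np.abs(increments) <= path.eta * A_MAX_MM + 1e-12)

    def test_step_bound(self):
        for seed in range(5):
            path = random_walk_vessel(seed, 50, (0, 0, 0))
            steps = np.abs(np.diff(path.points, axis=0))
            assert steps.max() <= ETA_MAX * A_MAX_MM  # 0.04 mm

    def test_point_count(self):
        path = random_walk_vessel(3, 17, (0, 0, 0))
        assert path.points.shape == (18, 3)

    def test_determinism(self):
        a = random_walk_vessel(42, 30, (5, 5, 0))
        b = random_walk_vessel(42, 30, (5, 5, 0))
        assert np.array_equal(a.points, b.points)
        assert a.eta == b.eta

    def test_n_steps_validation(self):
        with pytest.raises(ValueError):
            random_walk_vessel(0, 0, (0, 0, 0))

    def test_centerline_extrusion(self):
        path = random_walk_vessel(1, 4, (1, 1, 0.3))
        line = path.centerline(step_mm=0.6)
        assert np.allclose(line - path.points,
                           np.outer(np.arange(5) * 0.6, [0, 0, 1]))


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def _brute_force_mask(paths, grid):
    """Exhaustive distance-to-segment oracle over all voxel centers."""
    cx, cz, cy = grid.voxel_centers_mm()
    mask = np.zeros(grid.dims, dtype=bool)
    for path in paths:
        pts = path.centerline(grid.spacing_mm)
        for i in range(grid.nx):
            for j in range(grid.nz):
                for k in range(grid.ny):
                    p = np.array([cx[i], cz[j], cy[k]])
                    for a, b in zip(pts[:-1], pts[1:]):
                        d = b - a
                        dd = d @ d
                        t = 0.0 if dd == 0 else np.clip((p - a) @ d / dd, 0, 1)
                        if np.linalg.norm(p - a - t * d) <= path.radius_mm:
                            mask[i, j, k] = True
                            break
    return mask


class TestRasterizeVessels:
    def test_matches_point_in_cylinder_oracle(self):
        grid = GridSpec(dims=(16, 12, 10))
        path = VesselPath(points=np.tile([4.8, 3.6, 0.3], (10, 1)),
                          eta=0.0, radius_mm=3.0)
        labels = rasterize_vessels([path], grid)
        assert np.array_equal(labels > 0, _brute_force_mask([path], grid))

    def test_oracle_with_wander(self):
        grid = GridSpec(dims=(12, 10, 8))
        paths = [random_walk_vessel(s, 7, (3.3, 2.7, 0.3), radius_mm=1.4)
                 for s in (1, 2)]
        labels = rasterize_vessels(paths, grid)
        assert np.array_equal(labels > 0, _brute_force_mask(paths, grid))

    def test_tiny_radius_marks_path_voxels_only(self):
        grid = GridSpec(dims=(8, 8, 4))
        # centerline through voxel centers, radius below half the spacing
        path = VesselPath(points=np.tile([2.1, 2.1, 0.3], (4, 1)),
                          eta=0.0, radius_mm=0.25)
        labels = rasterize_vessels([path], grid)
        expected = np.zeros(grid.dims, dtype=bool)
        expected[3, 3, :] = True
        assert np.array_equal(labels > 0, expected)

    def test_empty_path_list(self):
        grid = GridSpec(dims=(4, 4, 4))
        assert not rasterize_vessels([], grid).any()

    def test_outside_grid_warns(self):
        grid = GridSpec(dims=(4, 4, 4))
        path = VesselPath(points=np.tile([100.0, 100.0, 0.0], (3, 1)),
                          eta=0.0, radius_mm=0.5)
        with pytest.warns(UserWarning, match="outside"):
            labels = rasterize_vessels([path], grid)
        assert not labels.any()

    def test_overlapping_vessels_merge(self):
        grid = GridSpec(dims=(8, 8, 4))
        p1 = VesselPath(points=np.tile([2.4, 2.4, 0.3], (4, 1)), eta=0.0,
                        radius_mm=1.2)
        p2 = VesselPath(points=np.tile([2.7, 2.4, 0.3], (4, 1)), eta=0.0,
                        radius_mm=1.2)
        labels = rasterize_vessels([p1, p2], grid)
        assert set(np.unique(labels)) <= {0, 1, 2}
        assert (labels == 2).any()


# --------------------------------------------------------------------------
# optics assignment
# --------------------------------------------------------------------------

class TestAssignOptics:
    def test_dsbase_values_before_blur(self):
        grid = GridSpec(dims=(8, 8, 4))
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[3:5, 3:5, :] = 1
        vol = assign_optics(labels, grid, vessel_mu_a=4.7,
                            background_mu_a=0.1, blur_sigma_mm=0.0)
        assert np.all(vol.mu_a[labels > 0] == 4.7)
        assert np.all(vol.mu_a[labels == 0] == 0.1)
        assert vol.mu_s_prime == 1.5
        assert vol.gamma == 1.0

    def test_blur_zero_is_piecewise_constant(self):
        grid = GridSpec(dims=(6, 6, 3))
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[2, 2, 1] = 1
        vol = assign_optics(labels, grid, 5.0, 0.1, blur_sigma_mm=0.0)
        assert set(np.unique(vol.mu_a)) == {0.1, 5.0}

    def test_blur_preserves_mean(self):
        grid = GridSpec(dims=(10, 10, 6))
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[4:6, 4:6, 2:4] = 1
        sharp = assign_optics(labels, grid, 4.7, 0.1, blur_sigma_mm=0.0)
        blurred = assign_optics(labels, grid, 4.7, 0.1, blur_sigma_mm=0.6)
        assert blurred.mu_a.mean() == pytest.approx(sharp.mu_a.mean(),
                                                    rel=1e-10)

    def test_per_vessel_values(self):
        grid = GridSpec(dims=(6, 6, 2))
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[1, 1, :] = 1
        labels[4, 4, :] = 2
        vol = assign_optics(labels, grid, {1: 2.0, 2: 9.0}, 0.1,
                            blur_sigma_mm=0.0)
        assert vol.mu_a[1, 1, 0] == 2.0
        assert vol.mu_a[4, 4, 1] == 9.0


# --------------------------------------------------------------------------
# blood optics
# --------------------------------------------------------------------------

class TestBloodMuA:
    def test_zero_bvf(self):
        assert blood_mu_a(800, 0.5, bvf=0.0) == 0.0

    def test_affine_in_so2(self):
        m = BloodOpticsModel()
        for lam in (750, 800, 850):
            mid = blood_mu_a(lam, 0.5, m)
            assert mid == pytest.approx(
                (blood_mu_a(lam, 0.0, m) + blood_mu_a(lam, 1.0, m)) / 2,
                rel=1e-12)

    def test_near_isosbestic_at_800(self):
        # derived from the shipped extinction table: Hb/HbO2 differ by
        # ~6.6% at 800 nm (the isosbestic point sits slightly below 800)
        m = BloodOpticsModel()
        lo, hi = blood_mu_a(800, 0.0, m), blood_mu_a(800, 1.0, m)
        assert abs(lo - hi) / hi < 0.08

    def test_wavelength_out_of_range(self):
        with pytest.raises(ValueError, match="outside table"):
            blood_mu_a(500, 0.5)

    def test_so2_out_of_range(self):
        with pytest.raises(ValueError):
            blood_mu_a(800, 1.5)

    @given(c=st.floats(1.0, 300.0), bvf=st.floats(0.001, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_concentration_and_bvf(self, c, bvf):
        base = BloodOpticsModel()
        m = BloodOpticsModel(c_hb=c)
        assert blood_mu_a(800, 0.3, m, bvf=bvf) <= blood_mu_a(
            800, 0.3, BloodOpticsModel(c_hb=c + 10), bvf=bvf)
        assert blood_mu_a(800, 0.3, base, bvf=bvf) <= blood_mu_a(
            800, 0.3, base, bvf=min(1.0, bvf * 1.5)) + 1e-15

    def test_whole_blood_magnitude(self):
        # 150 g/L fully oxygenated blood at 800 nm is a few cm^-1
        mua = blood_mu_a(800, 1.0)
        assert 2.0 < mua < 8.0

    def test_background_offset_calibration(self):
        m = BloodOpticsModel()
        off = background_offset(m)
        bg = blood_mu_a(800, 0.5, m, bvf=m.bvf_background) + off
        assert bg == pytest.approx(0.1, abs=1e-12)


# --------------------------------------------------------------------------
# dataset designs and manifests
# --------------------------------------------------------------------------

class TestDatasetSpecs:
    def test_standard_designs_table(self):
        ds = standard_datasets()
        assert ds["DSbase"].vessel_radius_mm == (3.0, 3.0)
        assert ds["DSbase"].vessel_mu_a == (4.7, 4.7)
        assert ds["DSbase"].vessel_count == (1, 1)
        assert ds["DSbase"].background_mu_a == (0.1, 0.1)
        assert ds["DSmulti"].n_train == 400
        assert ds["DSradius"].vessel_radius_mm == (0.5, 6.0)
        assert ds["DSabsorb"].vessel_mu_a == (1.0, 12.0)
        assert ds["DSvessel"].vessel_count == (1, 7)
        assert ds["DSbackground"].background_mu_a == (1e-4, 0.2)
        assert ds["DSoxy"].wavelengths == (750.0, 800.0, 850.0)
        assert ds["DSoxy"].n_train == 240 and ds["DSoxy"].n_test == 11

    def test_default_split_sizes(self):
        spec = standard_datasets()["DSbase"]
        assert (spec.n_train, spec.n_val, spec.n_test) == (150, 25, 25)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside design bounds"):
            DatasetSpec(name="bad", vessel_mu_a=(0.5, 20.0))
        with pytest.raises(ValueError, match="outside design bounds"):
            DatasetSpec(name="bad", vessel_radius_mm=(0.1, 3.0))

    def test_manifest_determinism(self):
        spec = standard_datasets()["DSbase"].scaled(n_train=3, n_val=1,
                                                    n_test=1)
        assert build_manifest(spec, 5) == build_manifest(spec, 5)
        assert build_manifest(spec, 5) != build_manifest(spec, 6)

    def test_empty_manifest(self):
        spec = standard_datasets()["DSbase"].scaled(n_train=0, n_val=0,
                                                    n_test=0)
        assert build_manifest(spec, 1) == []

    def test_dsbase_manifest_fixed_parameters(self):
        spec = standard_datasets()["DSbase"].scaled(n_train=5, n_val=2,
                                                    n_test=2)
        for rec in build_manifest(spec, 3):
            assert rec["n_vessels"] == 1
            assert rec["vessels"][0]["radius_mm"] == 3.0
            assert rec["vessels"][0]["mu_a"] == 4.7
            assert rec["background_mu_a"] == 0.1

    def test_sampled_parameters_within_bounds(self):
        spec = standard_datasets()["DSmulti"].scaled(n_train=25, n_val=0,
                                                     n_test=5)
        radii, mus = [], []
        for rec in build_manifest(spec, 11):
            assert 1 <= rec["n_vessels"] <= 7
            assert 1e-4 <= rec["background_mu_a"] <= 0.2
            for v in rec["vessels"]:
                assert 0.5 <= v["radius_mm"] <= 6.0
                assert 1.0 <= v["mu_a"] <= 12.0
                radii.append(v["radius_mm"])
                mus.append(v["mu_a"])
        # empirical spread covers a good part of the design range
        assert min(radii) < 1.5 and max(radii) > 5.0
        assert min(mus) < 3.0 and max(mus) > 10.0

    def test_dsoxy_test_so2_levels(self):
        spec = standard_datasets()["DSoxy"].scaled(n_train=2)
        recs = [r for r in build_manifest(spec, 2) if r["split"] == "test"]
        assert [r["so2"] for r in recs] == pytest.approx(
            np.arange(11) * 0.1)

    def test_dsoxy_training_so2_uniform(self):
        spec = standard_datasets()["DSoxy"].scaled(n_train=40)
        so2 = [r["so2"] for r in build_manifest(spec, 4)
               if r["split"] == "train"]
        assert all(0.0 <= s <= 1.0 for s in so2)
        assert max(so2) - min(so2) > 0.5


class TestRealizeItem:
    def test_monospectral_volume(self):
        grid = GridSpec(dims=(16, 12, 8))
        spec = DatasetSpec(name="DSbase", grid=grid).scaled(
            n_train=1, n_val=0, n_test=0)
        rec, vol = next(iter_items(spec, 9))
        assert isinstance(vol, TissueVolume)
        assert vol.mu_a.shape == grid.dims
        assert (vol.labels > 0).any()
        assert vol.mu_a.max() <= 4.7 + 1e-9
        assert vol.mu_a.min() >= 0.1 - 1e-9

    def test_multispectral_volume(self):
        grid = GridSpec(dims=(16, 12, 8))
        spec = DatasetSpec(
            name="DSoxy", vessel_radius_mm=(2.3, 4.0),
            wavelengths=(750.0, 800.0, 850.0),
            test_so2_levels=(0.0, 0.5, 1.0), grid=grid).scaled(
                n_train=1, n_val=0, n_test=1)
        items = list(iter_items(spec, 9))
        rec, vol = items[-1]
        assert rec["split"] == "test" and vol.so2 == 0.0
        assert set(vol.mu_a_by_wavelength) == {750.0, 800.0, 850.0}
        # vessel absorption follows the blood model at each wavelength
        m = BloodOpticsModel()
        core = vol.labels > 0
        for lam in (750.0, 800.0, 850.0):
            expected = blood_mu_a(lam, vol.so2, m)
            # blurring moves boundary voxels; check the vessel core max
            assert vol.mu_a_by_wavelength[lam][core].max() == pytest.approx(
                expected, rel=0.05)

    def test_byte_identical_items(self):
        grid = GridSpec(dims=(12, 10, 6))
        spec = DatasetSpec(name="DSbase", grid=grid).scaled(
            n_train=2, n_val=0, n_test=0)
        a = [(r, v) for r, v in iter_items(spec, 33)]
        b = [(r, v) for r, v in iter_items(spec, 33)]
        for (ra, va), (rb, vb) in zip(a, b):
            assert ra == rb
            assert np.array_equal(va.mu_a, vb.mu_a)
            assert np.array_equal(va.labels, vb.labels)
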