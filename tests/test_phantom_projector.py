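"""Phantom construction and polychromatic forward projection."""

import math

import numpy as np
import pytest

from tomomar import (
    PhantomConfig,
    TomoGeometry,
    VoxelPhantom,
    build_phantom,
    material_pathlengths,
    polychromatic_project,
)
from tomomar.materials import WATER
from tomomar.spectra import delta_spectrum


def water_slab(n_slices=8, extent=41, vox=3.5):
    """Homogeneous water slab spanning the full lateral extent."""
    fr = np.zeros((3, n_slices, extent, extent))
    fr[1] = 1.0
    return VoxelPhantom(fractions=fr, voxel_size_mm=vox)


@pytest.fixture(scope="module")
def slab_geometry():
    # odd detector => a pixel exactly on the central axis
    return TomoGeometry(detector_shape=(65, 65), pixel_pitch_mm=4.464, n_views=5)


class TestBuildPhantom:
    def test_default_has_all_three_materials(self, tiny_phantom):
        for ch in range(3):
            assert tiny_phantom.fractions[ch].sum() > 0

    def test_titanium_volume_matches_analytic_cylinder(self, tiny_phantom, tiny_phantom_config):
        cfg = tiny_phantom_config
        analytic = math.pi * cfg.implant_radius_mm**2 * cfg.bone_length_mm
        shell = 2 * math.pi * cfg.implant_radius_mm * cfg.bone_length_mm * cfg.voxel_size_mm
        assert abs(tiny_phantom.material_volume_mm3(0) - analytic) < shell

    def test_zero_inner_radii_gives_pure_water_cylinder(self):
        cfg = PhantomConfig(
            grid_shape=(16, 16, 16),
            voxel_size_mm=4.0,
            implant_radius_mm=0,
            bone_inner_radius_mm=0,
            bone_outer_radius_mm=0,
            case_radius_mm=20.0,
            fracture_gap_mm=0,
        )
        ph = build_phantom(cfg)
        assert ph.fractions[0].sum() == 0
        assert ph.fractions[2].sum() == 0
        # interior voxels well inside the case are pure water
        assert ph.fractions[1][8, 8, 8] == 1.0

    def test_all_zero_config_gives_empty_phantom(self):
        cfg = PhantomConfig(
            grid_shape=(8, 8, 8),
            voxel_size_mm=4.0,
            implant_radius_mm=0,
            bone_inner_radius_mm=0,
            bone_outer_radius_mm=0,
            case_radius_mm=0.0,
            fracture_gap_mm=0,
        )
        assert build_phantom(cfg).fractions.sum() == 0

    def test_non_nested_radii_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            PhantomConfig(implant_radius_mm=30.0, bone_inner_radius_mm=14.0)

    def test_fracture_gap_interrupts_bone_not_nail(self, tiny_phantom_config):
        ph = build_phantom(tiny_phantom_config)
        nz, ny, nx = ph.grid_shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * ph.voxel_size_mm
        gap = np.abs(x - tiny_phantom_config.fracture_center_mm) < (
            tiny_phantom_config.fracture_gap_mm / 2.0 - ph.voxel_size_mm
        )
        if gap.any():
            assert ph.fractions[2][:, :, gap].sum() == 0
            assert ph.fractions[0][:, :, gap].sum() > 0

    def test_deterministic(self, tiny_phantom_config):
        a = build_phantom(tiny_phantom_config)
        b = build_phantom(tiny_phantom_config)
        np.testing.assert_array_equal(a.fractions, b.fractions)


class TestMaterialPathlengths:
    def test_central_ray_through_slab_is_analytic(self, slab_geometry):
        ph = water_slab()
        paths = material_pathlengths(ph, slab_geometry)
        iv = slab_geometry.n_views // 2  # 0 degree view
        k = paths.maps["water"][iv, 32, 32]  # exactly central pixel
        # K = 0.1 cm/mm * thickness(mm) * rho; the 0-deg central ray is axial
        assert k == pytest.approx(0.1 * 8 * 3.5 * WATER.density, rel=1e-12)
        assert paths.maps["titanium_alloy"][iv].max() == 0
        assert paths.maps["foam_cortical_shell"][iv].max() == 0

    def test_oblique_view_scales_as_secant(self, slab_geometry):
        ph = water_slab()
        paths = material_pathlengths(ph, slab_geometry)
        iv = 0
        src = slab_geometry.source_position(slab_geometry.view_angles_deg[iv])
        # central detector pixel (index 32,32) sits at u=v=0
        dz = slab_geometry.detector_z_mm - src[2]
        sec = math.sqrt(src[0] ** 2 + src[1] ** 2 + dz**2) / abs(dz)
        k = paths.maps["water"][iv, 32, 32]
        assert k == pytest.approx(0.1 * 8 * 3.5 * sec, rel=1e-9)

    def test_empty_phantom_gives_zero_maps(self, slab_geometry):
        fr = np.zeros((3, 4, 8, 8))
        ph = VoxelPhantom(fractions=fr, voxel_size_mm=3.5)
        paths = material_pathlengths(ph, slab_geometry)
        for arr in paths.maps.values():
            assert arr.max() == 0

    def test_symmetric_phantom_mirror_symmetry(self, tiny_phantom_config, slab_geometry):
        # fracture off => phantom symmetric under y -> -y
        cfg = PhantomConfig(
            grid_shape=(32, 32, 32), voxel_size_mm=4.5, fracture_gap_mm=0
        )
        ph = build_phantom(cfg)
        paths = material_pathlengths(ph, slab_geometry)
        kw = paths.maps["water"]
        n = slab_geometry.n_views
        # projection at +theta equals the v-mirrored projection at -theta
        np.testing.assert_allclose(kw[0], kw[n - 1][::-1, :], atol=1e-9)

    def test_truncation_warning(self, slab_geometry):
        big = PhantomConfig(grid_shape=(8, 96, 96), voxel_size_mm=6.0, case_radius_mm=250.0)
        ph = build_phantom(big)
        with pytest.warns(UserWarning, match="field of view"):
            paths = material_pathlengths(ph, slab_geometry)
        assert paths.truncated


class TestPolychromaticProject:
    def test_zero_pathlengths_give_unit_intensity(self, slab_geometry, attn, spec70):
        fr = np.zeros((3, 4, 8, 8))
        ph = VoxelPhantom(fractions=fr, voxel_size_mm=3.5)
        paths = material_pathlengths(ph, slab_geometry)
        stack = polychromatic_project(paths, spec70, attn)
        np.testing.assert_allclose(stack.data, 1.0, rtol=1e-12)

    def test_delta_spectrum_matches_monochromatic_closed_form(self, slab_geometry, attn):
        ph = water_slab()
        paths = material_pathlengths(ph, slab_geometry)
        e = 60.0
        stack = polychromatic_project(paths, delta_spectrum(e), attn)
        mu = float(attn.mu_rho("water", e))
        np.testing.assert_allclose(
            stack.data, np.exp(-mu * paths.maps["water"]), rtol=1e-12
        )

    def test_quadrature_matches_independent_fine_grid_oracle(self, attn, spec70):
        # 10 cm of water: reference quadrature evaluated directly on the bins
        k_water = 10.0 * WATER.density  # g/cm^2
        mu = attn.mu_rho("water", spec70.energies)
        oracle = float(np.dot(spec70.weights, np.exp(-mu * k_water)) / spec70.weights.sum())

        geo = TomoGeometry(detector_shape=(9, 9), pixel_pitch_mm=4.0, n_views=3)
        fr = np.zeros((3, 25, 9, 9))
        fr[1] = 1.0
        ph = VoxelPhantom(fractions=fr, voxel_size_mm=4.0)
        paths = material_pathlengths(ph, geo)
        stack = polychromatic_project(paths, spec70, attn)
        iv, c = 1, 4  # central view, central pixel: exactly 100 mm of water
        assert paths.maps["water"][iv, c, c] == pytest.approx(k_water, rel=1e-12)
        assert stack.data[iv, c, c] == pytest.approx(oracle, rel=1e-6)

    def test_beam_hardening_concavity_vs_monochromatic_linearity(self, attn, spec70):
        thick = np.linspace(10, 200, 12)  # mm of water
        kw = 0.1 * thick * WATER.density
        mu70 = attn.mu_rho("water", spec70.energies)
        poly = np.array(
            [float(np.dot(spec70.weights, np.exp(-mu70 * k))) for k in kw]
        )
        neg_log = -np.log(poly)
        # strict concavity: second differences negative
        d2 = np.diff(neg_log, 2)
        assert np.all(d2 < 0)
        # any delta spectrum is exactly linear
        mono = kw * float(attn.mu_rho("water", 140.0))
        r = np.corrcoef(thick, mono)[0, 1]
        assert r**2 > 0.999999

    def test_poisson_noise_variance_matches_mean(self, slab_geometry, attn, spec70):
        ph = water_slab(n_slices=2)
        paths = material_pathlengths(ph, slab_geometry)
        i0 = 1000.0
        rng = np.random.default_rng(7)
        draws = np.array(
            [
                polychromatic_project(paths, spec70, attn, noise_photons=i0, rng=rng).data[2, 32, 32]
                for _ in range(10000)
            ]
        )
        counts = draws * i0
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_negative_pathlength_rejected(self, slab_geometry, attn, spec70):
        ph = water_slab(n_slices=2)
        paths = material_pathlengths(ph, slab_geometry)
        paths.maps["water"][0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            polychromatic_project(paths, spec70, attn)
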