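"""Sphere-ROI quantification: lattice oracles, backgrounds, ratios."""

import numpy as np
import pytest

from kinetoquant.detect import Spot, detect_kinetochores
from kinetoquant.io import ImageStack
from kinetoquant.quant import (
    EmptyShellError,
    QuantParams,
    corrected_intensity,
    integrate_sphere,
    local_background,
    measure_cell,
    measure_kinetochore,
    sphere_voxels,
)


def brute_force_sphere(center, radius, voxel_size, shape):
    """Independent oracle: full-grid centre-in-sphere lattice enumeration."""
    idx = np.argwhere(np.ones(shape, dtype=bool))
    centres = (idx + 0.5) * np.asarray(voxel_size)
    d2 = np.sum((centres - np.asarray(center)) ** 2, axis=1)
    return idx[d2 <= radius**2]


def make_stack(crest, sac=None, voxel_size=(0.1, 0.1, 0.1)):
    sac = crest if sac is None else sac
    return ImageStack(np.stack([crest, sac]), voxel_size, ("CREST", "SAC"))


class TestSphereVoxels:
    def test_isotropic_lattice_count(self):
        """0.45 um sphere on 0.1 um isotropic voxels holds 57 voxels.

        Oracle: integer lattice points with i^2+j^2+k^2 <= (0.225/0.1)^2 =
        5.0625, i.e. <= 5: 21 (k=0) + 2x13 (k=+-1) + 2x5 (k=+-2) = 57.
        """
        shape = (21, 21, 21)
        center = (10.5 * 0.1, 10.5 * 0.1, 10.5 * 0.1)  # a voxel centre
        idx, edge = sphere_voxels(center, 0.45, (0.1, 0.1, 0.1), shape)
        assert len(idx) == 57
        assert not edge
        oracle = brute_force_sphere(center, 0.225, (0.1, 0.1, 0.1), shape)
        assert set(map(tuple, idx)) == set(map(tuple, oracle))

    def test_anisotropic_lattice_count(self):
        """With 0.3 um z-spacing only the central plane fits: 21 voxels."""
        shape = (7, 21, 21)
        center = (3.5 * 0.3, 10.5 * 0.1, 10.5 * 0.1)
        idx, edge = sphere_voxels(center, 0.45, (0.3, 0.1, 0.1), shape)
        assert len(idx) == 21
        assert not edge
        assert np.all(idx[:, 0] == 3)  # single z-plane disk

    def test_tiny_sphere_single_voxel(self):
        idx, _ = sphere_voxels((0.55, 0.55, 0.55), 0.05, (0.1, 0.1, 0.1), (11, 11, 11))
        assert len(idx) == 1
        assert tuple(idx[0]) == (5, 5, 5)

    def test_edge_flag(self):
        idx, edge = sphere_voxels((0.05, 0.05, 0.05), 0.45, (0.1, 0.1, 0.1), (11, 11, 11))
        assert edge
        assert len(idx) < 57  # truncated set

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_random_centers(self, seed):
        """Exact agreement with brute-force enumeration at random centres."""
        rng = np.random.default_rng(seed)
        voxel = (0.3, 0.1, 0.1)
        shape = (12, 30, 30)
        extent = np.array(shape) * np.array(voxel)
        for _ in range(25):
            center = rng.uniform(0.3, extent - 0.3)
            idx, _ = sphere_voxels(center, 0.45, voxel, shape)
            oracle = brute_force_sphere(center, 0.225, voxel, shape)
            assert set(map(tuple, idx)) == set(map(tuple, oracle))


class TestIntegrateSphere:
    def test_uniform_image(self):
        img = np.full((21, 21, 21), 10, dtype=np.uint16)
        stack = make_stack(img)
        center = (10.5 * 0.1,) * 3
        raw, n, edge = integrate_sphere(stack, "CREST", center)
        assert (raw, n) == (570.0, 57)

    def test_zero_channel(self):
        stack = make_stack(np.zeros((21, 21, 21), dtype=np.uint16))
        raw, _, _ = integrate_sphere(stack, "SAC", (1.05, 1.05, 1.05))
        assert raw == 0.0

    def test_single_hot_voxel(self):
        img = np.zeros((21, 21, 21), dtype=np.uint16)
        img[10, 10, 10] = 1234
        stack = make_stack(img)
        raw, _, _ = integrate_sphere(stack, "CREST", (1.05, 1.05, 1.05))
        assert raw == 1234.0

    def test_matches_bruteforce_masked_sum(self, small_cell):
        """Integration equals a full-grid masked sum exactly (integers)."""
        stack, truth = small_cell
        img = stack.channel("CREST")
        rng = np.random.default_rng(5)
        extent = np.array(stack.extent_um)
        for _ in range(20):
            center = rng.uniform(0.4, extent - 0.4)
            raw, n, _ = integrate_sphere(stack, "CREST", center)
            oracle_idx = brute_force_sphere(center, 0.225, stack.voxel_size_um, img.shape)
            assert raw == float(img[tuple(oracle_idx.T)].sum(dtype=np.float64))
            assert n == len(oracle_idx)


class TestLocalBackground:
    def test_constant_background(self):
        stack = make_stack(np.full((21, 21, 21), 7, dtype=np.uint16))
        bg = local_background(stack, "CREST", (1.05, 1.05, 1.05))
        assert bg == 7.0

    def test_median_robust_to_bright_voxel(self):
        img = np.full((21, 21, 21), 7, dtype=np.uint16)
        img[10, 10, 13] = 60000  # inside the shell (0.3 um off-centre)
        stack = make_stack(img)
        assert local_background(stack, "CREST", (1.05, 1.05, 1.05)) == 7.0

    def test_empty_shell_after_exclusion_errors(self):
        """A shell fully covered by neighbouring spheres is an error."""
        stack = make_stack(np.full((21, 21, 21), 7, dtype=np.uint16))
        center = (1.05, 1.05, 1.05)
        # exclusion spheres on a dense lattice cover every shell voxel
        grid = np.arange(0.05, 2.1, 0.2)
        exclusions = [(z, y, x) for z in grid for y in grid for x in grid]
        with pytest.raises(EmptyShellError, match="shell_width"):
            local_background(stack, "CREST", center, exclusion_centers_um=exclusions)

    def test_sister_sphere_excluded(self):
        """A bright sister inside the shell is masked out of the estimate."""
        img = np.full((21, 21, 21), 7, dtype=np.uint16)
        sister = (1.05, 1.05, 1.40)
        sidx, _ = sphere_voxels(sister, 0.45, (0.1, 0.1, 0.1), img.shape)
        img[tuple(sidx.T)] = 50000
        stack = make_stack(img)
        bg = local_background(stack, "CREST", (1.05, 1.05, 1.05), exclusion_centers_um=[sister])
        assert bg == 7.0


class TestCorrectedIntensity:
    def test_arithmetic(self):
        assert corrected_intensity(570.0, 57, 5.0) == (285.0, False)

    def test_clamp_policy(self):
        corrected, clamped = corrected_intensity(100.0, 57, 5.0)
        assert corrected == 0.0 and clamped

    def test_zero_background_identity(self):
        assert corrected_intensity(123.0, 57, 0.0) == (123.0, False)


class TestMeasureKinetochore:
    def test_identical_channels_ratio_one(self, small_cell):
        """SAC channel identical to CREST gives ratio exactly 1."""
        stack, truth = small_cell
        crest = stack.channel("CREST")
        twin = make_stack(crest, crest, voxel_size=stack.voxel_size_um)
        spot = Spot(0, tuple(truth.positions_um[0]), 1.0)
        m = measure_kinetochore(twin, spot)
        assert m.ratio == pytest.approx(1.0)

    def test_crest_nonpositive_flag(self):
        """Zero corrected CREST yields no ratio and the flag."""
        img = np.full((21, 21, 21), 9, dtype=np.uint16)
        stack = make_stack(np.zeros_like(img) + 9, img)
        m = measure_kinetochore(stack, Spot(0, (1.05, 1.05, 1.05), 1.0))
        assert m.crest_nonpositive
        assert np.isnan(m.ratio)

    def test_ratio_recovery_noise_free(self, noisefree_cell):
        """Measured ratio within 5% of the true amplitude ratio, per spot."""
        stack, truth = noisefree_cell
        spots = detect_kinetochores(stack)
        ms = measure_cell(stack, spots)
        assert len(ms) > 0
        for m in ms:
            pos = np.array([s.position_um for s in spots if s.kt_id == m.kt_id][0])
            t = np.linalg.norm(truth.positions_um - pos, axis=1).argmin()
            true_ratio = truth.amp_sac[t] / truth.amp_crest[t]
            assert m.ratio == pytest.approx(true_ratio, rel=0.05)

    def test_scale_invariance_of_ratio(self, small_cell):
        """Multiplying both channels by c leaves every ratio unchanged."""
        stack, truth = small_cell
        spot = Spot(0, tuple(truth.positions_um[0]), 1.0)
        m1 = measure_kinetochore(stack, spot)
        scaled = ImageStack(
            stack.intensities.astype(np.float64) * 3.0,
            stack.voxel_size_um,
            stack.channel_names,
        )
        m2 = measure_kinetochore(scaled, spot)
        assert m2.ratio == pytest.approx(m1.ratio, rel=1e-12)

    def test_additive_background_invariance(self, small_cell):
        """Adding a constant to a channel leaves corrected values unchanged."""
        stack, truth = small_cell
        spot = Spot(0, tuple(truth.positions_um[0]), 1.0)
        m1 = measure_kinetochore(stack, spot)
        shifted = ImageStack(
            stack.intensities.astype(np.float64) + 100.0,
            stack.voxel_size_um,
            stack.channel_names,
        )
        m2 = measure_kinetochore(shifted, spot)
        assert m2.corrected_sac == pytest.approx(m1.corrected_sac, abs=1e-9)
        assert m2.corrected_crest == pytest.approx(m1.corrected_crest, abs=1e-9)
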