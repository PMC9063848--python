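"""Raw-map construction, contour matching, FSC and resolution criteria."""

import numpy as np
import pytest

from mapqc import fixtures, halfmap
from mapqc.core_io import ValidationError, VoxelGrid


class TestAverageHalfMaps:
    def test_identical_inputs_idempotent(self, random_grid):
        avg = halfmap.average_half_maps(random_grid, random_grid)
        assert np.array_equal(avg.data, random_grid.data)

    def test_symmetric_noise_cancels_exactly(self, random_grid, rng):
        noise = rng.normal(size=random_grid.shape)
        h1 = random_grid.with_data(random_grid.data + noise)
        h2 = random_grid.with_data(random_grid.data - noise)
        avg = halfmap.average_half_maps(h1, h2)
        # cancellation is exact up to the rounding of the two additions
        assert np.allclose(avg.data, random_grid.data, rtol=1e-12, atol=1e-12)

    def test_shape_mismatch_names_field(self, random_grid):
        other = VoxelGrid(np.zeros((8, 8, 8)))
        with pytest.raises(ValidationError, match="shape"):
            halfmap.average_half_maps(random_grid, other)

    def test_voxel_size_mismatch_names_field(self, random_grid):
        other = VoxelGrid(np.zeros(random_grid.shape), voxel_size=(2.0, 2.0, 2.0))
        with pytest.raises(ValidationError, match="voxel_size"):
            halfmap.average_half_maps(random_grid, other)


class TestScaleToReference:
    def test_fixed_point(self, random_grid):
        out = halfmap.scale_to_reference(random_grid, random_grid)
        assert np.array_equal(out.data, random_grid.data)

    def test_affine_input_recovers_reference(self, random_grid):
        warped = random_grid.with_data(2.0 * random_grid.data + 5.0)
        out = halfmap.scale_to_reference(warped, random_grid)
        assert np.allclose(out.data, random_grid.data, atol=1e-9)

    def test_moments_match_reference(self, rng):
        a = VoxelGrid(rng.normal(3.0, 2.0, size=(12, 12, 12)))
        ref = VoxelGrid(rng.normal(-1.0, 0.5, size=(12, 12, 12)))
        out = halfmap.scale_to_reference(a, ref)
        assert out.data.mean() == pytest.approx(ref.data.mean(), rel=1e-6, abs=1e-9)
        assert out.data.std() == pytest.approx(ref.data.std(), rel=1e-6)

    def test_zero_variance_rejected(self, random_grid):
        flat = random_grid.with_data(np.full(random_grid.shape, 1.0))
        with pytest.raises(ValidationError):
            halfmap.scale_to_reference(flat, random_grid)


class TestMatchContourByVolume:
    def test_identity_recovers_attained_level(self, random_grid):
        level = float(np.sort(random_grid.data.ravel())[-100])
        match = halfmap.match_contour_by_volume(random_grid, random_grid, level)
        assert match.level == level
        assert match.achieved_count == match.target_count

    def test_constant_shift_preserves_count(self, random_grid):
        shifted = random_grid.with_data(random_grid.data + 10.0)
        level = float(np.sort(random_grid.data.ravel())[-50])
        match = halfmap.match_contour_by_volume(shifted, random_grid, level)
        assert match.achieved_count == match.target_count
        assert match.level == pytest.approx(level + 10.0)

    def test_minimal_count_error_vs_exhaustive_scan(self, rng):
        grid = VoxelGrid(rng.normal(size=(10, 10, 10)))
        ref = VoxelGrid(rng.normal(size=(10, 10, 10)))
        ref_level = 0.7
        match = halfmap.match_contour_by_volume(grid, ref, ref_level)
        target = np.count_nonzero(ref.data >= ref_level)
        best = min(
            abs(int(np.count_nonzero(grid.data >= v)) - target)
            for v in np.unique(grid.data)
        )
        assert abs(match.achieved_count - target) == best

    def test_unreachable_target_warns(self, random_grid):
        match = halfmap.match_contour_by_volume(
            random_grid, random_grid, random_grid.data.max() + 1.0
        )
        assert match.warning is not None
        assert match.level > random_grid.data.max()


class TestFsc:
    def test_self_correlation_is_one(self, rng):
        g = VoxelGrid(rng.normal(size=(64, 64, 64)))
        curve = halfmap.fsc(g, g)
        assert np.abs(curve.fsc - 1.0).max() < 1e-6

    def test_sign_flip_is_minus_one(self, rng):
        g = VoxelGrid(rng.normal(size=(64, 64, 64)))
        curve = halfmap.fsc(g, g.with_data(-g.data))
        assert np.abs(curve.fsc + 1.0).max() < 1e-6

    def test_symmetric_in_arguments(self, rng):
        a = VoxelGrid(rng.normal(size=(16, 16, 16)))
        b = VoxelGrid(rng.normal(size=(16, 16, 16)))
        assert np.allclose(halfmap.fsc(a, b).fsc, halfmap.fsc(b, a).fsc)

    def test_invariant_under_common_translation(self, rng):
        a = VoxelGrid(rng.normal(size=(16, 16, 16)))
        b = VoxelGrid(rng.normal(size=(16, 16, 16)))
        shift = (2, -3, 5)
        a2 = a.with_data(np.roll(a.data, shift, axis=(0, 1, 2)))
        b2 = b.with_data(np.roll(b.data, shift, axis=(0, 1, 2)))
        assert np.allclose(halfmap.fsc(a, b).fsc, halfmap.fsc(a2, b2).fsc, atol=1e-10)

    def test_white_noise_null_distribution(self):
        rng = np.random.default_rng(99)
        a = VoxelGrid(rng.normal(size=(64, 64, 64)))
        b = VoxelGrid(rng.normal(size=(64, 64, 64)))
        curve = halfmap.fsc(a, b)
        bound = 4.0 / np.sqrt(curve.n_voxels_per_shell[1:])
        ok = np.abs(curve.fsc[1:]) <= bound
        assert ok.mean() >= 0.95

    def test_geometry_mismatch_rejected(self, rng):
        a = VoxelGrid(rng.normal(size=(16, 16, 16)))
        b = VoxelGrid(rng.normal(size=(16, 16, 16)), origin=(50.0, 0.0, 0.0))
        with pytest.raises(ValidationError, match="origin"):
            halfmap.fsc(a, b)


class TestCriterionCurves:
    def test_half_bit_large_n_limit(self):
        curves = halfmap.criterion_curves(np.array([10**12]))
        assert curves["half_bit"][0] == pytest.approx(0.2071 / 1.2071, abs=1e-4)

    def test_three_sigma_large_n_limit(self):
        curves = halfmap.criterion_curves(np.array([10**12]))
        assert curves["three_sigma"][0] == pytest.approx(0.0, abs=1e-4)

    def test_half_bit_at_single_voxel(self):
        curves = halfmap.criterion_curves(np.array([1]))
        expected = (0.2071 + 1.9102) / (1.2071 + 0.9102)
        assert curves["half_bit"][0] == pytest.approx(expected, rel=1e-6)


class TestResolutionAtThreshold:
    def _curve(self, fsc_values, freqs=None):
        n = len(fsc_values)
        freqs = np.arange(n) / (2 * (n - 1)) if freqs is None else freqs
        return halfmap.FSCCurve(
            frequencies=np.asarray(freqs, dtype=float),
            fsc=np.asarray(fsc_values, dtype=float),
            n_voxels_per_shell=np.full(n, 100),
        )

    def test_never_crossing_returns_none(self):
        curve = self._curve(np.ones(10))
        assert halfmap.resolution_at_threshold(curve, 0.5) is None

    def test_step_crossing_interpolates_midpoint(self):
        fsc_values = [1.0, 1.0, 1.0, 0.0, 0.0]
        curve = self._curve(fsc_values)
        res = halfmap.resolution_at_threshold(curve, 0.5)
        f_mid = (curve.frequencies[2] + curve.frequencies[3]) / 2
        assert res == pytest.approx(1.0 / f_mid)

    def test_oscillation_flagged_on_recrossing(self, rng):
        fsc_values = np.array([1.0, 0.9, 0.05, 0.4, 0.05, 0.02])
        curve = self._curve(fsc_values)
        threshold = np.full(6, 0.143)
        res, osc = halfmap._first_crossing(curve, threshold)
        assert res is not None and osc


class TestRawMapPathway:
    def test_recovers_recommended_level_exactly(self, clean_signal):
        grid, _ = clean_signal
        level = float(np.sort(grid.data.ravel())[-500])
        raw = halfmap.make_raw_map(grid, grid, grid, recommended_level=level)
        assert raw.matched_level == level
        assert raw.grid.data.mean() == pytest.approx(grid.data.mean(), abs=1e-12)
        assert raw.grid.data.std() == pytest.approx(grid.data.std(), rel=1e-12)

    def test_designed_crossover_recovered_within_one_shell(self, clean_signal):
        grid, _ = clean_signal
        h1, h2 = fixtures.make_half_maps(grid, crossover_resolution=8.0, seed=13)
        curve = halfmap.fsc(h1, h2)
        res = curve.crossings["fsc_0.143"]
        shell_width = curve.frequencies[1]
        assert abs(1.0 / res - 1.0 / 8.0) <= shell_width


class TestAuthorFsc:
    def test_two_column_text(self, tmp_path):
        p = tmp_path / "fsc.txt"
        p.write_text("# freq fsc\n0.01 0.99\n0.02, 0.95\n\n0.03 0.80\n")
        freqs, vals = halfmap.read_author_fsc(p)
        assert freqs.tolist() == [0.01, 0.02, 0.03]
        assert vals.tolist() == [0.99, 0.95, 0.80]

    def test_xml_points(self, tmp_path):
        p = tmp_path / "fsc.xml"
        p.write_text('<fsc><point x="0.01" y="0.98"/><point x="0.02" y="0.90"/></fsc>')
        freqs, vals = halfmap.read_author_fsc(p)
        assert len(freqs) == 2 and vals[1] == 0.90

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "fsc.txt"
        p.write_text("# nothing\n")
        with pytest.raises(ValidationError):
            halfmap.read_author_fsc(p)
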