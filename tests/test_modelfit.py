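"""Interpolation, inclusion metrics, simulated maps, map-model FSC, Q-score."""

import math

import numpy as np
import pytest

from mapqc import fixtures, modelfit
from mapqc.core_io import Atom, AtomicModel, Chain, Residue, ValidationError, VoxelGrid


def single_atom_model(coords, element="C", b=0.0, name="CA"):
    atom = Atom(element, name, coords, b_factor=b)
    return AtomicModel(chains=[Chain("A", [Residue("ALA", 1, "", "amino-acid", [atom])])])


class TestInterpolateAt:
    def test_voxel_center_returns_voxel_value(self, random_grid):
        # voxel (k,j,i) = (3,4,5) → physical (x,y,z) = (5,4,3) at 1 Å/voxel
        val = modelfit.interpolate_at(random_grid, np.array([[5.0, 4.0, 3.0]]))
        assert val[0] == pytest.approx(random_grid.data[3, 4, 5])

    def test_midpoint_is_arithmetic_mean(self):
        data = np.zeros((3, 3, 4))
        data[:, :, 1] = 2.0
        data[:, :, 2] = 6.0
        g = VoxelGrid(data)
        val = modelfit.interpolate_at(g, np.array([[1.5, 1.0, 1.0]]))
        assert val[0] == pytest.approx(4.0)

    def test_outside_box_returns_sentinel(self, random_grid):
        vals = modelfit.interpolate_at(
            random_grid, np.array([[-1.0, 0.0, 0.0], [0.0, 100.0, 0.0]])
        )
        assert np.all(vals == modelfit.OUTSIDE)
        assert np.all(vals < random_grid.data.min())

    def test_matches_nested_loop_oracle(self, rng):
        data = rng.normal(size=(8, 8, 8))
        g = VoxelGrid(data, voxel_size=(1.3, 1.3, 1.3), origin=(-2.0, 1.0, 0.5))
        points = rng.uniform(1.5, 6.0, size=(100, 3)) * 1.3 + np.array([-2.0, 1.0, 0.5])
        got = modelfit.interpolate_at(g, points)
        for p, v in zip(points, got):
            fz = (p[2] - 0.5) / 1.3
            fy = (p[1] - 1.0) / 1.3
            fx = (p[0] + 2.0) / 1.3
            k, j, i = int(fz), int(fy), int(fx)
            tz, ty, tx = fz - k, fy - j, fx - i
            expected = 0.0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        w = ((tz if dz else 1 - tz) * (ty if dy else 1 - ty)
                             * (tx if dx else 1 - tx))
                        expected += w * data[k + dz, j + dy, i + dx]
            assert v == pytest.approx(expected, abs=1e-10)


class TestAtomInclusion:
    def test_level_at_minimum_includes_everything(self, clean_signal):
        grid, model = clean_signal
        sweep = modelfit.atom_inclusion_sweep(grid, model)
        assert sweep.fraction_all[0] == 1.0
        assert sweep.fraction_backbone[0] == 1.0

    def test_model_outside_density_scores_zero(self, clean_signal):
        grid, model = clean_signal
        level = float(np.sort(grid.data.ravel())[-1000])
        shifted = model.translated((200.0, 200.0, 200.0))
        inc = modelfit.residue_inclusion(grid, shifted, level)
        assert inc.average == 0.0
        assert all(r.score == 0.0 for r in inc.per_residue)

    def test_hand_counted_fraction(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, :5] = 1.0  # 5 bright voxels along x at z=4, y=4
        g = VoxelGrid(data)
        chain = Chain("A")
        for i in range(10):  # 10 atoms at voxel centers x = 0..9... clipped to box
            chain.residues.append(
                Residue("ALA", i + 1, "", "amino-acid",
                        [Atom("C", "CA", (float(i % 8), 4.0, 4.0))])
            )
        model = AtomicModel(chains=[chain])
        inc = modelfit.residue_inclusion(g, model, 0.5)
        # atoms at x=0..4 plus the repeated x=0,1 from i=8,9 → 7 of 10 inside
        assert inc.average == pytest.approx(7 / 10)

    def test_fraction_nonincreasing_in_level(self, clean_signal):
        grid, model = clean_signal
        sweep = modelfit.atom_inclusion_sweep(grid, model)
        assert np.all(np.diff(sweep.fraction_all) <= 1e-12)
        assert np.all(np.diff(sweep.fraction_backbone) <= 1e-12)

    def test_residue_scores_reaggregate_to_atom_fraction(self, clean_signal):
        grid, model = clean_signal
        level = float(np.sort(grid.data.ravel())[-2000])
        inc = modelfit.residue_inclusion(grid, model, level)
        weighted = sum(r.score * r.n_atoms for r in inc.per_residue)
        n_atoms = sum(r.n_atoms for r in inc.per_residue)
        assert inc.average == pytest.approx(weighted / n_atoms)

    def test_long_chain_chunked_in_batches_of_200(self):
        g = VoxelGrid(np.ones((8, 8, 8)))
        chain = Chain("A")
        for i in range(250):
            chain.residues.append(
                Residue("ALA", i + 1, "", "amino-acid", [Atom("C", "CA", (4.0, 4.0, 4.0))])
            )
        inc = modelfit.residue_inclusion(g, AtomicModel(chains=[chain]), 0.5)
        assert inc.chunks == [("A", 0, 200), ("A", 200, 250)]

    def test_colour_endpoints(self):
        assert modelfit.inclusion_colour(0.0) == (1.0, 0.0, 0.0)  # red
        assert modelfit.inclusion_colour(1.0) == (0.0, 1.0, 1.0)  # cyan


class TestSimulateMap:
    def _like(self, n=32, voxel=0.5):
        return VoxelGrid(np.zeros((n, n, n)), voxel_size=(voxel,) * 3)

    def test_single_carbon_integral_proportional_to_z(self):
        like = self._like()
        model = single_atom_model((8.0, 8.0, 8.0))  # at a voxel center
        sim = modelfit.simulate_map(model, like, resolution=3.0)
        peak = np.unravel_index(np.argmax(sim.grid.data), sim.grid.shape)
        assert peak == (16, 16, 16)
        integral = sim.grid.data.sum() * like.voxel_volume
        assert integral == pytest.approx(6.0, rel=0.01)  # Z(C) × occupancy

    def test_two_distant_atoms_equal_peaks(self):
        like = self._like(n=48)
        a1 = Atom("C", "CA", (6.0, 6.0, 6.0))
        a2 = Atom("C", "CA", (18.0, 18.0, 18.0))
        model = AtomicModel(chains=[Chain("A", [
            Residue("ALA", 1, "", "amino-acid", [a1]),
            Residue("ALA", 2, "", "amino-acid", [a2]),
        ])])
        sim = modelfit.simulate_map(model, like, resolution=3.0)
        assert sim.grid.data[12, 12, 12] == pytest.approx(sim.grid.data[36, 36, 36], rel=1e-6)

    def test_b_factor_broadens_and_conserves_mass(self):
        like = self._like()
        sharp = modelfit.simulate_map(single_atom_model((8.0, 8.0, 8.0), b=0.0), like, 3.0)
        broad = modelfit.simulate_map(single_atom_model((8.0, 8.0, 8.0), b=40.0), like, 3.0)
        assert broad.grid.data[16, 16, 16] < sharp.grid.data[16, 16, 16]
        assert broad.grid.data.sum() == pytest.approx(sharp.grid.data.sum(), rel=0.01)

    def test_whole_voxel_translation_equivariance(self):
        like = self._like(n=40)
        sim1 = modelfit.simulate_map(single_atom_model((8.0, 8.0, 8.0)), like, 3.0)
        sim2 = modelfit.simulate_map(single_atom_model((9.0, 10.0, 11.0)), like, 3.0)
        rolled = np.roll(sim1.grid.data, (6, 4, 2), axis=(0, 1, 2))  # (z,y,x) voxels
        assert np.allclose(rolled, sim2.grid.data, atol=1e-12)

    def test_sub_nyquist_resolution_rejected(self):
        like = self._like(voxel=2.0)
        with pytest.raises(ValidationError):
            modelfit.simulate_map(single_atom_model((8.0, 8.0, 8.0)), like, resolution=3.0)


class TestMapModelFsc:
    def test_self_consistency_is_unity(self, clean_signal):
        grid, model = clean_signal
        sim = modelfit.simulate_map(model, grid, 6.0)
        curve, res = modelfit.map_model_fsc(sim.grid, model, 6.0)
        assert np.abs(curve.fsc - 1.0).max() < 1e-6
        assert res is None

    def test_designed_crossover_near_six_angstrom(self, clean_signal):
        grid, model = clean_signal
        degraded = fixtures.make_degraded_map(grid, crossover_resolution=6.0, seed=21)
        curve, res = modelfit.map_model_fsc(degraded, model, 6.0)
        shell_width = curve.frequencies[1]
        assert res is not None
        assert abs(1.0 / res - 1.0 / 6.0) <= shell_width

    def test_displaced_model_decorrelates(self, clean_signal):
        grid, model = clean_signal
        moved = model.translated((20.0, 0.0, 0.0))
        curve, res = modelfit.map_model_fsc(grid, moved, 6.0)
        upper = curve.fsc[len(curve.fsc) // 2:]
        assert np.abs(upper).mean() < 0.2
        assert res is not None and res > 15.0  # crossing at very low frequency


class TestQScore:
    def test_perfect_gaussian_scores_one(self):
        n, vox, sigma = 48, 0.2, 0.6
        center = (n - 1) / 2 * vox
        c = vox * np.arange(n)
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij", sparse=True)
        r2 = (zz - center) ** 2 + (yy - center) ** 2 + (xx - center) ** 2
        g = VoxelGrid(np.exp(-r2 / (2 * sigma**2)), voxel_size=(vox,) * 3)
        q = modelfit.q_score(g, single_atom_model((center, center, center)), sigma=sigma)
        assert q.overall == pytest.approx(1.0, abs=1e-3)

    def test_pure_noise_scores_near_zero(self):
        rng = np.random.default_rng(42)
        g = VoxelGrid(rng.normal(size=(64, 64, 64)))
        chain = Chain("A")
        for i, p in enumerate(rng.uniform(8, 56, size=(200, 3))):
            chain.residues.append(
                Residue("ALA", i + 1, "", "amino-acid", [Atom("C", "CA", tuple(p))])
            )
        q = modelfit.q_score(g, AtomicModel(chains=[chain]))
        assert abs(q.overall) <= 0.1

    def test_invariant_under_affine_map_rescaling(self, clean_signal):
        grid, model = clean_signal
        q1 = modelfit.q_score(grid, model)
        q2 = modelfit.q_score(grid.with_data(7.3 * grid.data + 2.9), model)
        assert q2.overall == pytest.approx(q1.overall, abs=1e-6)

    def test_misplaced_atom_scores_lower(self, clean_signal):
        grid, model = clean_signal
        good = modelfit.q_score(grid, model)
        # rotate one residue's CB stub out of its density by moving it 4 Å
        bad_model = model.translated((0.0, 0.0, 0.0))
        target = bad_model.chains[0].residues[10]
        for atom in target.atoms:
            if atom.name == "CB":
                x, y, z = atom.coords
                atom.coords = (x + 4.0, y + 4.0, z)
        bad = modelfit.q_score(grid, bad_model)
        good_res = next(r for r in good.per_residue if r.seq_num == 11)
        bad_res = next(r for r in bad.per_residue if r.seq_num == 11)
        assert bad_res.score < good_res.score

    def test_atom_far_outside_map_is_unreliable(self, clean_signal):
        grid, _ = clean_signal
        q = modelfit.q_score(grid, single_atom_model((500.0, 500.0, 500.0)))
        assert q.n_unreliable == 1
        assert math.isnan(q.overall)

    def test_aggregates_are_means_of_atoms(self, clean_signal):
        grid, model = clean_signal
        q = modelfit.q_score(grid, model)
        finite = [v for v in q.per_atom if math.isfinite(v)]
        assert q.overall == pytest.approx(np.mean(finite))
        assert q.per_chain["A"] == pytest.approx(np.mean(finite))
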