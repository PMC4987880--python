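import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.transform import Rotation

from pharmscreen import fixtures, shape as sh
from pharmscreen.core import Atom, Molecule, QueryDocument, Sphere
from pharmscreen.shape import (ShapeConstraints, ShapeGrid,
                               check_constraints_filter,
                               check_constraints_strict, grow_shrink,
                               inertia_canonicalize, rasterize_spheres,
                               search_shape, shape_tanimoto, voxelize_sev)

from conftest import embed


def grid_from_indices(indices, resolution=0.5, dims=(20, 20, 20)):
    occ = np.zeros(dims, dtype=bool)
    for idx in indices:
        occ[idx] = True
    return ShapeGrid(origin=np.zeros(3), resolution=resolution, occupancy=occ)


class TestVoxelize:
    def test_single_atom_volume_close_to_analytic(self):
        carbon = Molecule(name="c", atoms=[Atom("C", (0.3, -0.2, 0.11))])
        analytic = 4.0 / 3.0 * np.pi * 1.7 ** 3
        v05 = voxelize_sev(carbon, resolution=0.5).volume
        v02 = voxelize_sev(carbon, resolution=0.2).volume
        assert abs(v05 - analytic) / analytic <= 0.15
        assert abs(v02 - analytic) / analytic <= 0.05
        # convergence: finer grid is at least as accurate
        assert abs(v02 - analytic) <= abs(v05 - analytic) + 1e-9

    def test_far_apart_atoms_two_components(self):
        mol = Molecule(name="2c", atoms=[Atom("C", (0, 0, 0)),
                                         Atom("C", (100.0, 0, 0))])
        grid = voxelize_sev(mol)
        _, n = ndimage.label(grid.occupancy)
        assert n == 2

    def test_integer_voxel_translation_equivariance(self, template):
        g1 = voxelize_sev(template)
        shift = np.array([1.0, -2.5, 3.5])  # whole voxels at 0.5 A
        g2 = voxelize_sev(template.with_coords(template.coords + shift))
        off = tuple(int(round(s / 0.5)) for s in shift)
        shifted = {(i + off[0], j + off[1], k + off[2])
                   for (i, j, k) in g1.global_indices()}
        assert shifted == g2.global_indices()


class TestGrowShrink:
    def test_zero_delta_identity(self, template):
        g = voxelize_sev(template)
        assert grow_shrink(g, 0.0).global_indices() == g.global_indices()

    def test_single_voxel_eroded_to_empty(self):
        g = grid_from_indices([(5, 5, 5)])
        assert grow_shrink(g, -0.5).is_empty()

    def test_closing_covers_original(self, template):
        g = voxelize_sev(template)
        closed = grow_shrink(grow_shrink(g, 1.0), -1.0)
        assert g.global_indices() <= closed.global_indices()

    def test_erosion_shrinks_dilation_grows(self, template):
        g = voxelize_sev(template)
        assert grow_shrink(g, -0.5).count < g.count < grow_shrink(g, 0.5).count


class TestTanimoto:
    def test_identical_grids(self, template):
        g = voxelize_sev(template)
        assert shape_tanimoto(g, g) == 1.0

    def test_disjoint_grids(self):
        a = grid_from_indices([(0, 0, 0), (1, 0, 0)])
        b = grid_from_indices([(10, 10, 10)])
        assert shape_tanimoto(a, b) == 0.0

    def test_subset_ratio(self):
        big = [(i, j, k) for i in range(5) for j in range(5) for k in range(4)]
        small = big[:50]
        assert shape_tanimoto(grid_from_indices(small),
                              grid_from_indices(big)) == 0.5

    def test_symmetry_and_bounds(self, template):
        g1 = voxelize_sev(template)
        lig = fixtures.fixture_ligands(2, seed=6)[1]
        g2 = voxelize_sev(lig)
        t = shape_tanimoto(g1, g2)
        assert t == shape_tanimoto(g2, g1)
        assert 0.0 <= t <= 1.0

    def test_both_empty_defined_zero(self):
        empty = grid_from_indices([])
        assert shape_tanimoto(empty, empty) == 0.0


class TestInertiaCanonicalize:
    def test_already_canonical_near_identity(self, template):
        canon = template.transformed(inertia_canonicalize(template))
        tfm2 = inertia_canonicalize(canon)
        assert np.abs(tfm2.rotation - np.eye(3)).max() <= 1e-6
        assert np.abs(tfm2.translation).max() <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_rotated_copy_canonicalizes_identically(self, template, seed):
        rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        moved = template.with_coords(template.coords @ rot.T + [2.0, -3.0, 5.0])
        c0 = template.transformed(inertia_canonicalize(template)).coords
        c1 = moved.transformed(inertia_canonicalize(moved)).coords
        assert np.abs(c0 - c1).max() <= 1e-3

    def test_mirror_image_differs(self, template):
        mirror = template.with_coords(template.coords * np.array([-1, 1, 1]))
        c0 = template.transformed(inertia_canonicalize(template)).coords
        c1 = mirror.transformed(inertia_canonicalize(mirror)).coords
        assert np.abs(c0 - c1).max() > 1e-2

    def test_too_few_heavy_atoms_error(self):
        mol = Molecule(name="co", atoms=[Atom("C", (0, 0, 0)),
                                         Atom("O", (1.2, 0, 0))])
        with pytest.raises(ValueError, match="3 heavy atoms"):
            inertia_canonicalize(mol)


class TestConstraints:
    def test_inclusive_voxel_inside_passes(self, template):
        g = voxelize_sev(template)
        idx = next(iter(g.occupied))
        inc = ShapeGrid(g.origin, g.resolution,
                        np.zeros_like(g.occupancy))
        inc.occupancy[idx] = True
        cons = ShapeConstraints(inclusive=inc)
        assert check_constraints_strict(g, cons)

    def test_inclusive_voxel_outside_fails(self, template):
        g = voxelize_sev(template)
        inc = ShapeGrid(g.origin, g.resolution, np.zeros_like(g.occupancy))
        inc.occupancy[0, 0, 0] = True  # padded corner, guaranteed empty
        assert not check_constraints_strict(g, ShapeConstraints(inclusive=inc))

    def test_exclusive_overlap_fails(self, template):
        g = voxelize_sev(template)
        idx = next(iter(g.occupied))
        exc = ShapeGrid(g.origin, g.resolution, np.zeros_like(g.occupancy))
        exc.occupancy[idx] = True
        assert not check_constraints_strict(g, ShapeConstraints(exclusive=exc))

    def test_filter_no_constraints_true(self, template):
        assert check_constraints_filter(template, ShapeConstraints())

    def test_filter_heavy_atom_in_exclusive_fails(self, template):
        pos = template.heavy_coords[0]
        exc = rasterize_spheres([Sphere(tuple(pos), 1.0)])
        assert not check_constraints_filter(
            template, ShapeConstraints(exclusive=exc))

    def test_filter_inclusive_missed_fails(self, template):
        far = template.heavy_coords.mean(axis=0) + 50.0
        inc = rasterize_spheres([Sphere(tuple(far), 1.0)])
        assert not check_constraints_filter(
            template, ShapeConstraints(inclusive=inc))

    @pytest.mark.parametrize("seed", range(5))
    def test_strict_pass_implies_filter_pass(self, seed):
        rng = np.random.default_rng(seed)
        ligs = fixtures.fixture_ligands(4, seed=5)
        mol = ligs[seed % len(ligs)]
        g = voxelize_sev(mol)
        # erosion below the smallest vdW radius keeps atom-center voxels
        inc = grow_shrink(g, -float(rng.uniform(0.25, 1.0)))
        exc = rasterize_spheres(
            [Sphere(tuple(mol.heavy_coords.mean(0) + rng.uniform(3, 12, 3)),
                    float(rng.uniform(0.5, 2.0)))])
        cons = ShapeConstraints(inclusive=inc, exclusive=exc)
        if check_constraints_strict(g, cons):
            assert check_constraints_filter(mol, cons)


class TestSearchShape:
    def test_self_retrieval_top_ranked(self, template):
        from test_pharma_search import tiny_library

        others = fixtures.fixture_ligands(3, seed=9)
        lib = tiny_library([template] + others)
        hits = search_shape(ShapeConstraints(), lib,
                            query_shape=voxelize_sev(template.transformed(
                                inertia_canonicalize(template))))
        assert hits[0].molecule_id == "m000000"
        assert hits[0].shape_similarity >= 0.95

    def test_exclusive_everywhere_no_hits(self, template):
        from test_pharma_search import tiny_library

        lib = tiny_library([template])
        exc = rasterize_spheres([Sphere((0.0, 0.0, 0.0), 30.0)])
        hits = search_shape(ShapeConstraints(exclusive=exc), lib,
                            query_shape=voxelize_sev(template))
        assert hits == []

    def test_requires_reference(self, template):
        from test_pharma_search import tiny_library

        with pytest.raises(ValueError, match="inclusive"):
            search_shape(ShapeConstraints(), tiny_library([template]))
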