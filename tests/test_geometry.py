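"""Mesh/voxel geometry: volumes, centroids, rasterization, margins."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from heartatlas import (
    BinaryMask,
    GridSpec,
    MeshError,
    boolean_volumes,
    center_of_mass,
    inner_margin,
    make_primitive,
    mesh_volume,
    outer_shell,
    point_mesh_distance,
    voxelize,
)
from conftest import rotated


def unit_cube_at_origin():
    cube = make_primitive("box", extents=[10.0, 10.0, 10.0])
    cube.apply_translation([5.0, 5.0, 5.0])
    return cube


class TestMeshVolume:
    def test_unit_cube_is_one_cc(self):
        assert mesh_volume(unit_cube_at_origin()) == pytest.approx(1.0)

    def test_icosphere_within_half_percent_from_below(self):
        mesh = make_primitive("sphere", radius=50.0, subdivisions=4)
        analytic = 4.0 / 3.0 * np.pi * 50.0**3 / 1000.0  # 523.6 cm^3
        vol = mesh_volume(mesh)
        assert vol < analytic  # inscribed tessellation
        assert vol == pytest.approx(analytic, rel=0.005)

    def test_flipped_orientation_repaired_with_warning(self):
        mesh = make_primitive("sphere", radius=10.0, subdivisions=2)
        flipped = mesh.copy()
        flipped.invert()
        with pytest.warns(UserWarning, match="orientation repaired"):
            vol = mesh_volume(flipped)
        assert vol == pytest.approx(mesh_volume(mesh))

    def test_non_watertight_rejected_with_boundary_edges(self):
        mesh = make_primitive("sphere", radius=10.0, subdivisions=2)
        holed = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[:-1], process=False
        )
        with pytest.raises(MeshError, match="boundary"):
            mesh_volume(holed)

    def test_rigid_invariance(self):
        mesh = make_primitive("cone", base_radius=12.3, height=29.1)
        moved = rotated(mesh, 0.7, [1, 0.3, 0.2], [11.0, -7.0, 3.0])
        assert mesh_volume(moved) == pytest.approx(mesh_volume(mesh), rel=1e-6)


class TestCenterOfMass:
    def test_cube_centroid(self):
        np.testing.assert_allclose(
            center_of_mass(unit_cube_at_origin()), [5.0, 5.0, 5.0], atol=1e-9
        )

    def test_translated_sphere_centroid(self):
        mesh = make_primitive("sphere", radius=12.0, subdivisions=3)
        mesh.apply_translation([0.0, 0.0, 30.0])
        np.testing.assert_allclose(center_of_mass(mesh), [0, 0, 30], atol=1e-6)

    def test_l_shape_matches_voxel_counting_centroid(self):
        # L-prism: CCW footprint extruded 10 mm, wound outward by hand
        foot = np.array(
            [(0, 0), (20, 0), (20, 10), (10, 10), (10, 20), (0, 20)], float
        )
        bottom = np.c_[foot, np.zeros(6)]
        top = np.c_[foot, np.full(6, 10.0)]
        verts = np.vstack([bottom, top])
        faces = []
        for k in range(1, 5):  # star-shaped fan from vertex 0
            faces.append([6, 6 + k, 6 + k + 1])      # top, +z
            faces.append([0, k + 1, k])              # bottom, -z
        for i in range(6):                           # outward side quads
            j = (i + 1) % 6
            faces.extend([[i, j, 6 + j], [i, 6 + j, 6 + i]])
        lshape = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        assert lshape.is_watertight
        grid = GridSpec.covering(lshape.bounds, 0.5, pad=1.0)
        mask = voxelize(lshape, grid)
        np.testing.assert_allclose(
            center_of_mass(lshape), mask.centroid(), atol=0.25
        )

    def test_solid_not_vertex_average(self):
        # a cone's vertex average differs from its solid centroid (h/4)
        cone = make_primitive("cone", base_radius=20.0, height=40.0)
        com = center_of_mass(cone)
        assert com[2] == pytest.approx(10.0, abs=0.3)

    def test_rigid_invariance(self):
        mesh = make_primitive("ellipsoid", semi_axes=[10, 14, 8])
        rot = trimesh.transformations.rotation_matrix(0.9, [0.2, 1, 0.5])
        shift = np.array([4.0, -2.0, 9.0])
        moved = mesh.copy()
        moved.apply_transform(rot)
        moved.apply_translation(shift)
        expected = rot[:3, :3] @ center_of_mass(mesh) + shift
        np.testing.assert_allclose(center_of_mass(moved), expected, atol=1e-6)


class TestVoxelize:
    def test_aligned_cube_exact_count(self):
        grid = GridSpec((0.5, 0.5, 0.5), (1, 1, 1), (12, 12, 12))
        assert voxelize(unit_cube_at_origin(), grid).count == 1000

    def test_sphere_within_one_percent_of_analytic(self):
        mesh = make_primitive("sphere", radius=20.0, subdivisions=4)
        grid = GridSpec.covering(mesh.bounds, 1.0, pad=2.0)
        analytic = 4.0 / 3.0 * np.pi * 20.0**3 / 1000.0
        assert voxelize(mesh, grid).volume_cc == pytest.approx(analytic, rel=0.01)

    @pytest.mark.parametrize(
        "kind,params",
        [
            ("sphere", {"radius": 20.0, "subdivisions": 4}),
            ("cone", {"base_radius": 12.3, "height": 29.1}),
            ("box", {"extents": [17.3, 23.1, 11.7]}),
        ],
    )
    def test_convergence_to_mesh_volume(self, kind, params):
        """Voxel volumes converge to the mesh's own (divergence-theorem)
        volume with strictly decreasing error at 2 -> 1 -> 0.5 mm."""
        mesh = rotated(make_primitive(kind, **params), 0.3, [1, 0.7, 0.4],
                       [0.0, 0.0, 0.0])
        ref = mesh_volume(mesh)
        errs = []
        for spacing in (2.0, 1.0, 0.5):
            grid = GridSpec.covering(mesh.bounds, spacing, pad=2 * spacing)
            errs.append(abs(voxelize(mesh, grid).volume_cc - ref) / ref)
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 0.01

    def test_mesh_exceeding_grid_names_axis(self):
        mesh = make_primitive("sphere", radius=20.0, subdivisions=2)
        grid = GridSpec((-19.0, -30.0, -30.0), (1, 1, 1), (60, 60, 60))
        with pytest.raises(MeshError, match="along x"):
            voxelize(mesh, grid)

    def test_clip_keeps_in_grid_part(self):
        mesh = unit_cube_at_origin()  # [0,10]^3
        grid = GridSpec((0.5, 0.5, 0.5), (1, 1, 1), (5, 12, 12))
        mask = voxelize(mesh, grid, clip=True)
        assert mask.count == 5 * 10 * 10

    def test_interior_placement_converges(self):
        mesh = make_primitive("sphere", radius=15.0, subdivisions=4)
        mesh.apply_translation([17.0, 17.0, 17.0])  # fully inside corner
        ref = mesh_volume(mesh)
        for spacing in (2.0, 1.0, 0.5):
            grid = GridSpec((spacing / 2,) * 3, (spacing,) * 3,
                            tuple([int(34 / spacing)] * 3))
            vol = voxelize(mesh, grid).volume_cc
            # within a ~2-voxel-layer worth of the surface area
            bound = 2 * spacing * 4 * np.pi * 15.0**2 / 1000.0
            assert abs(vol - ref) < bound


class TestBooleanVolumes:
    def grid(self):
        return GridSpec((0.5, 0.5, 0.5), (1, 1, 1), (16, 12, 12))

    def test_identity(self):
        m = voxelize(unit_cube_at_origin(), self.grid())
        vols = boolean_volumes(m, m)
        assert vols["volIntersection"] == vols["volUnion"] == vols["volA"]

    def test_disjoint(self):
        g = GridSpec((0.5, 0.5, 0.5), (1, 1, 1), (26, 12, 12))
        a = voxelize(unit_cube_at_origin(), g)
        shifted = unit_cube_at_origin()
        shifted.apply_translation([12.0, 0.0, 0.0])
        b = voxelize(shifted, g)
        vols = boolean_volumes(a, b)
        assert vols["volIntersection"] == 0.0
        assert vols["volUnion"] == pytest.approx(vols["volA"] + vols["volB"])

    def test_half_overlap_cubes_analytic(self):
        a = voxelize(unit_cube_at_origin(), self.grid())
        shifted = unit_cube_at_origin()
        shifted.apply_translation([5.0, 0.0, 0.0])
        b = voxelize(shifted, self.grid())
        vols = boolean_volumes(a, b)
        assert vols["volIntersection"] == pytest.approx(0.5)
        assert vols["volUnion"] == pytest.approx(1.5)

    def test_inclusion_exclusion_exact_random_pairs(self, rng):
        g = GridSpec((0, 0, 0), (1, 1, 1), (30, 30, 30))
        for _ in range(20):
            a = BinaryMask(g, rng.random((30, 30, 30)) < 0.3)
            b = BinaryMask(g, rng.random((30, 30, 30)) < 0.3)
            v = boolean_volumes(a, b)
            assert v["volUnion"] == pytest.approx(
                v["volA"] + v["volB"] - v["volIntersection"], abs=1e-12
            )

    def test_mismatched_grids_rejected(self):
        a = BinaryMask(GridSpec((0, 0, 0), (1, 1, 1), (5, 5, 5)),
                       np.ones((5, 5, 5), bool))
        b = BinaryMask(GridSpec((0, 0, 0), (2, 2, 2), (5, 5, 5)),
                       np.ones((5, 5, 5), bool))
        with pytest.raises(ValueError, match="different grids"):
            boolean_volumes(a, b)


@pytest.fixture(scope="module")
def sphere_mask():
    mesh = make_primitive("sphere", radius=50.0, subdivisions=4)
    grid = GridSpec.covering(mesh.bounds, 1.0, pad=2.0)
    return voxelize(mesh, grid)


class TestMargins:
    def test_erosion_matches_analytic_ratio(self, sphere_mask):
        eroded = inner_margin(sphere_mask, 20.0)
        ratio = eroded.volume_cc / sphere_mask.volume_cc
        assert ratio == pytest.approx((30.0 / 50.0) ** 3, rel=0.05)

    def test_zero_margin_identity(self, sphere_mask):
        out = inner_margin(sphere_mask, 0.0)
        assert np.array_equal(out.values, sphere_mask.values)

    def test_margin_larger_than_structure_warns_empty(self, sphere_mask):
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("error")
            with pytest.raises(UserWarning, match="erased"):
                inner_margin(sphere_mask, 60.0)
        with w.catch_warnings():
            w.simplefilter("ignore")
            assert inner_margin(sphere_mask, 60.0).count == 0

    def test_anti_extensive_and_monotone(self, sphere_mask):
        prev = sphere_mask
        for margin in (5.0, 10.0, 20.0):
            cur = inner_margin(sphere_mask, margin)
            assert not np.any(cur.values & ~sphere_mask.values)
            assert not np.any(cur.values & ~prev.values)
            prev = cur

    def test_shell_volume_analytic(self, sphere_mask):
        shell = outer_shell(sphere_mask, 10.0)
        expected = (1 - 0.8**3) * sphere_mask.volume_cc
        assert shell.volume_cc == pytest.approx(expected, rel=0.05)

    def test_shell_and_core_partition_exactly(self, sphere_mask):
        shell = outer_shell(sphere_mask, 10.0)
        core = inner_margin(sphere_mask, 10.0)
        assert not np.any(shell.values & core.values)
        assert np.array_equal(shell.values | core.values, sphere_mask.values)

    def test_thick_shell_is_whole_mask(self, sphere_mask):
        shell = outer_shell(sphere_mask, 60.0)
        assert np.array_equal(shell.values, sphere_mask.values)


class TestPrimitives:
    def test_cone_volume_analytic(self):
        cone = make_primitive("cone", base_radius=12.0, height=30.0)
        assert mesh_volume(cone) == pytest.approx(
            np.pi * 144 * 30 / 3 / 1000.0, rel=0.01
        )

    def test_box_volume_exact(self):
        box = make_primitive("box", extents=[10.0, 10.0, 1000.0])
        assert mesh_volume(box) == pytest.approx(100.0)

    def test_ellipsoid_volume_analytic(self):
        ell = make_primitive("ellipsoid", semi_axes=[10.0, 15.0, 20.0])
        assert mesh_volume(ell) == pytest.approx(
            4 / 3 * np.pi * 10 * 15 * 20 / 1000.0, rel=0.01
        )

    @pytest.mark.parametrize(
        "kind,params",
        [
            ("sphere", {"radius": -1.0}),
            ("cone", {"base_radius": 10.0, "height": 0.0}),
            ("box", {"extents": [1.0, -2.0, 3.0]}),
        ],
    )
    def test_nonpositive_dimension_rejected(self, kind, params):
        with pytest.raises(ValueError, match="positive"):
            make_primitive(kind, **params)

    def test_all_primitives_watertight(self):
        for kind, params in [
            ("sphere", {"radius": 5.0}),
            ("ellipsoid", {"semi_axes": [3, 4, 5]}),
            ("cone", {"base_radius": 5.0, "height": 9.0}),
            ("box", {"extents": [2, 3, 4]}),
        ]:
            assert make_primitive(kind, **params).is_watertight


class TestMarginProperties:
    """Hypothesis checks of the erosion lattice properties."""

    _cache = {}

    @classmethod
    def mask(cls):
        if "m" not in cls._cache:
            mesh = make_primitive("sphere", radius=40.0, subdivisions=3)
            grid = GridSpec.covering(mesh.bounds, 2.0, pad=4.0)
            cls._cache["m"] = voxelize(mesh, grid)
        return cls._cache["m"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=45.0),
        st.floats(min_value=0.0, max_value=45.0),
    )
    def test_inner_margin_anti_extensive_and_monotone(self, m1, m2):
        base = self.mask()
        small, large = sorted([m1, m2])
        a = inner_margin(base, small)
        b = inner_margin(base, large)
        # anti-extensive: output within input; monotone: larger margin
        # erodes at least as much
        assert not np.any(a.values & ~base.values)
        assert not np.any(b.values & ~a.values)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=45.0))
    def test_shell_core_partition(self, thickness):
        base = self.mask()
        shell = outer_shell(base, thickness)
        core = inner_margin(base, thickness)
        assert not np.any(shell.values & core.values)
        assert np.array_equal(shell.values | core.values, base.values)


class TestPointMeshDistance:
    def test_box_exact_cases(self):
        box = make_primitive("box", extents=[2.0, 2.0, 2.0])
        d = point_mesh_distance(
            np.array([[5.0, 0, 0], [0, 0, 0], [1.5, 1.5, 1.5]]), box
        )
        np.testing.assert_allclose(d, [4.0, 1.0, np.sqrt(3) * 0.5], atol=1e-9)

    def test_matches_dense_surface_sampling(self, rng):
        cone = make_primitive("cone", base_radius=12.0, height=30.0)
        pts = rng.uniform(-40, 40, (5, 3))
        exact = point_mesh_distance(pts, cone)
        samples = cone.sample(200000)
        for p, d in zip(pts, exact):
            brute = np.linalg.norm(samples - p, axis=1).min()
            assert d <= brute + 1e-6
            assert d == pytest.approx(brute, abs=0.2)
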