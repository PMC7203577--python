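import numpy as np
import pytest

from amylv import geometry
from amylv.template import LVTemplateSpec, coarse_template_spec, generate_template

from conftest import random_rotation


class TestLongAxisAlignment:
    def test_equal_distances_move_nothing(self, coarse_mesh):
        series = [coarse_mesh, coarse_mesh.copy(), coarse_mesh.copy()]
        out = geometry.align_long_axis(series, [1.5, 1.5, 1.5])
        for m in out:
            np.testing.assert_allclose(m.points, coarse_mesh.points)

    def test_shift_arithmetic(self, coarse_mesh):
        series = [coarse_mesh.copy() for _ in range(3)]
        out = geometry.align_long_axis(series, [2.0, 1.0, 3.0])
        for m, shift in zip(out, [1.0, 0.0, 2.0]):
            np.testing.assert_allclose(
                m.points[:, 2] - coarse_mesh.points[:, 2], shift
            )

    def test_minimum_frame_invariant_under_permutation(self, coarse_mesh):
        rng = np.random.default_rng(7)
        d = rng.uniform(0.0, 3.0, size=6)
        series = [coarse_mesh.copy() for _ in range(6)]
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(6)
            out = geometry.align_long_axis([series[i] for i in perm], d[perm])
            k = int(np.argmin(d[perm]))
            np.testing.assert_allclose(out[k].points, coarse_mesh.points)

    def test_mismatched_frame_count_rejected(self, coarse_mesh):
        with pytest.raises(ValueError, match="one annulus distance per frame"):
            geometry.align_long_axis([coarse_mesh], [1.0, 2.0])


class TestCircumferentialAlignment:
    def test_identity_when_already_aligned(self, coarse_mesh):
        v1 = coarse_mesh.insertion_angle("v1")
        out = geometry.align_circumferential(coarse_mesh, v1)
        np.testing.assert_allclose(out.points, coarse_mesh.points, atol=1e-12)

    def test_rotation_brings_v1_to_reference(self, coarse_mesh):
        out = geometry.align_circumferential(coarse_mesh, 90.0)
        # re-extracted from the rotated marker node itself
        assert out.insertion_angle("v1") == pytest.approx(90.0, abs=1e-9)
        np.testing.assert_array_equal(out.hexes, coarse_mesh.hexes)

    def test_idempotent(self, coarse_mesh):
        once = geometry.align_circumferential(coarse_mesh, 45.0)
        twice = geometry.align_circumferential(once, 45.0)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-12)


class TestFiberRule:
    def test_linear_helix_angle_across_the_wall(self, coarse_mesh):
        c, r, l = geometry.local_directions(coarse_mesh)
        s = coarse_mesh.node_s[coarse_mesh.hexes].mean(axis=1)
        ang = np.degrees(
            np.arctan2(
                np.einsum("ei,ei->e", coarse_mesh.fiber, l),
                np.einsum("ei,ei->e", coarse_mesh.fiber, c),
            )
        )
        lateral = coarse_mesh.elem_ring >= 0
        np.testing.assert_allclose(
            ang[lateral], -60.0 + 120.0 * s[lateral], atol=1e-8
        )

    def test_unit_and_orthogonal(self, coarse_mesh):
        f, s = coarse_mesh.fiber, coarse_mesh.sheet
        np.testing.assert_allclose(np.linalg.norm(f, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(s, axis=1), 1.0, atol=1e-12)
        assert np.abs(np.einsum("ei,ei->e", f, s)).max() < 1e-6

    @pytest.mark.parametrize("s, expected", [(0.0, -60.0), (0.25, -30.0),
                                             (0.5, 0.0), (1.0, 60.0)])
    def test_interpolation_endpoints(self, s, expected):
        # the rule itself: alpha(s) = -60 + 120 s (0 = epi, 1 = endo)
        assert -60.0 + 120.0 * s == pytest.approx(expected)


class TestDeformationGradient:
    def test_identity(self, coarse_mesh):
        F = geometry.deformation_gradient(coarse_mesh, coarse_mesh.points)
        np.testing.assert_allclose(F, np.broadcast_to(np.eye(3), F.shape), atol=1e-12)

    def test_uniform_dilation(self, coarse_mesh):
        F = geometry.deformation_gradient(coarse_mesh, 1.2 * coarse_mesh.points)
        np.testing.assert_allclose(F, 1.2 * np.broadcast_to(np.eye(3), F.shape),
                                   atol=1e-12)

    def test_exact_recovery_of_affine_motion(self, coarse_mesh):
        rng = np.random.default_rng(3)
        for _ in range(5):
            A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(A) <= 0.2:
                continue
            x = coarse_mesh.points @ A.T + rng.standard_normal(3)
            F = geometry.deformation_gradient(coarse_mesh, x)
            np.testing.assert_allclose(F, np.broadcast_to(A, F.shape), atol=1e-10)

    def test_mismatched_meshes_rejected(self, coarse_mesh):
        with pytest.raises(ValueError, match="co-registered"):
            geometry.deformation_gradient(coarse_mesh, coarse_mesh.points[:-1])


class TestStrainComponents:
    def test_reference_state_strain_free(self):
        e_cc, e_ll = geometry.strain_components(
            np.eye(3), np.array([1.0, 0, 0]), np.array([0, 0, 1.0])
        )
        assert e_cc == 0.0 and e_ll == 0.0

    def test_closed_form_uniaxial(self):
        F = np.diag([1.1, 1.0, 1.0])
        e_cc, _ = geometry.strain_components(
            F, np.array([1.0, 0, 0]), np.array([0, 0, 1.0])
        )
        assert e_cc == pytest.approx((1.1**2 - 1) / 2, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        c = np.array([1.0, 0, 0])
        l = np.array([0, 0, 1.0])
        base = geometry.strain_components(F, c, l)
        for _ in range(10):
            R = random_rotation(rng)
            rotated = geometry.strain_components(R @ F, c, l)
            np.testing.assert_allclose(rotated, base, atol=1e-12)

    def test_rigid_motions_are_strain_free(self, coarse_mesh):
        rng = np.random.default_rng(5)
        c, _, l = geometry.local_directions(coarse_mesh)
        for _ in range(3):
            R = random_rotation(rng)
            x = coarse_mesh.points @ R.T + rng.standard_normal(3)
            F = geometry.deformation_gradient(coarse_mesh, x)
            e_cc, e_ll = geometry.strain_components(F, c, l)
            assert np.abs(e_cc).max() < 1e-10
            assert np.abs(e_ll).max() < 1e-10


class TestRegionalStrains:
    def test_uniform_motion_gives_uniform_regional_means(self, coarse_mesh):
        field = geometry.regional_strains([1.05 * coarse_mesh.points], coarse_mesh)
        expected = (1.05**2 - 1) / 2
        np.testing.assert_allclose(field.E_cc, expected, atol=1e-12)
        np.testing.assert_allclose(field.E_ll, expected, atol=1e-12)
        assert field.E_cc.shape == (3, 20, 1)

    def test_regions_partition_each_layer(self, coarse_mesh):
        rings = geometry.select_layer_rings(coarse_mesh, 3)
        assert len(set(rings)) == 3
        for ring in rings:
            elems = np.flatnonzero(coarse_mesh.elem_ring == ring)
            regs = geometry._region_of_elements(coarse_mesh, elems, 20)
            counts = np.bincount(regs, minlength=20)
            assert counts.sum() == len(elems)
            assert np.all(counts > 0)

    def test_regional_mean_matches_bruteforce_average(self, coarse_mesh):
        rng = np.random.default_rng(9)
        # smooth random nodal motion
        x = coarse_mesh.points * (1.0 + 0.05 * np.sin(coarse_mesh.points[:, 2]))[:, None]
        x = x + 0.02 * np.cos(coarse_mesh.points[:, :1] * 2.0)
        field = geometry.regional_strains([x], coarse_mesh)
        c, _, l = geometry.local_directions(coarse_mesh)
        rings = geometry.select_layer_rings(coarse_mesh, 3)
        for k, ring in enumerate(rings):
            elems = np.flatnonzero(coarse_mesh.elem_ring == ring)
            regs = geometry._region_of_elements(coarse_mesh, elems, 20)
            for r in range(20):
                members = elems[regs == r]
                vals = [
                    geometry.strain_components(
                        geometry.deformation_gradient(coarse_mesh, x, int(e)),
                        c[e], l[e],
                    )[0]
                    for e in members
                ]
                assert field.E_cc[k, r, 0] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_empty_region_rejected(self):
        # 16 circumferential elements cannot tile 20 regions
        spec = coarse_template_spec(n_circ=16, n_long=4)
        mesh = generate_template(spec)
        with pytest.raises(ValueError, match="region"):
            geometry.regional_strains([mesh.points * 1.01], mesh)


class TestVolumes:
    def test_hemispherical_cavity_closed_form(self, hemisphere_mesh):
        exact = 2.0 / 3.0 * np.pi * 27.0
        assert geometry.chamber_volume(hemisphere_mesh) == pytest.approx(exact, rel=0.01)

    def test_hemispherical_wall_closed_form(self, hemisphere_mesh):
        exact = 2.0 / 3.0 * np.pi * (64.0 - 27.0)
        assert geometry.wall_volume(hemisphere_mesh) == pytest.approx(exact, rel=0.01)

    def test_half_prolate_spheroid_closed_form(self):
        # semi-axes a = b = 2, c = 4: half-spheroid volume (2/3) pi a b c
        spec = LVTemplateSpec(
            endo_base_radius=2.0, epi_base_radius=2.8, apex_to_base_length=4.8,
            truncation_fraction=0.0, n_circ=40, n_long=60, n_trans=2,
        )
        mesh = generate_template(spec)
        exact = 2.0 / 3.0 * np.pi * 2.0 * 2.0 * 4.0
        assert geometry.chamber_volume(mesh) == pytest.approx(exact, rel=0.01)

    def test_wall_plus_chamber_equals_capped_epi_volume(self, hemisphere_mesh):
        total = geometry.epi_capped_volume(hemisphere_mesh)
        parts = geometry.wall_volume(hemisphere_mesh) + geometry.chamber_volume(
            hemisphere_mesh
        )
        assert parts == pytest.approx(total, abs=1e-9)

    def test_refinement_convergence_of_wall_volume(self):
        def vol(nc):
            spec = LVTemplateSpec(n_circ=nc, n_long=24, n_trans=2)
            return geometry.wall_volume(generate_template(spec))

        assert abs(vol(80) - vol(40)) / vol(80) < 0.005

    def test_rigid_invariance_and_cubic_scaling(self, coarse_mesh):
        rng = np.random.default_rng(2)
        v0 = geometry.wall_volume(coarse_mesh)
        R = random_rotation(rng)
        moved = coarse_mesh.with_points(coarse_mesh.points @ R.T + [1.0, -2.0, 0.5])
        assert geometry.wall_volume(moved) == pytest.approx(v0, rel=1e-12)
        scaled = coarse_mesh.with_points(2.0 * coarse_mesh.points)
        assert geometry.wall_volume(scaled) == pytest.approx(8.0 * v0, rel=1e-12)
        # chamber volume is defined by the capped endo surface; same laws
        c0 = geometry.chamber_volume(coarse_mesh)
        assert geometry.chamber_volume(scaled) == pytest.approx(8.0 * c0, rel=1e-12)

    def test_inverted_element_rejected(self, coarse_mesh):
        bad = coarse_mesh.points.copy()
        e0 = coarse_mesh.hexes[0]
        centroid = bad[e0].mean(axis=0)
        bad[e0] = 2 * centroid - bad[e0]  # point reflection inverts the cell
        with pytest.raises(ValueError, match="inverted"):
            geometry.wall_volume(coarse_mesh.with_points(bad))


class TestWallThickness:
    def test_scaling_homogeneity(self, hemisphere_mesh):
        t0 = geometry.median_wall_thickness(hemisphere_mesh)
        t2 = geometry.median_wall_thickness(
            hemisphere_mesh.with_points(2.0 * hemisphere_mesh.points)
        )
        assert t2 == pytest.approx(2.0 * t0, rel=1e-9)
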