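"""Neomandible assembly, ICP best-fit, U-distance and heat-map distances."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from osteoguide import (
    ContractError,
    DegenerateGeometryError,
    TriMesh,
    assemble_neomandible,
    heatmap,
    icp_bestfit,
    lateral_axis_of_plan,
    mate_planes,
    reconstruct,
    u_distance,
)
from osteoguide.mesh_core import Plane, RigidTransform
from osteoguide.reconstruction import _closest_on_triangles, closest_on_mesh

from conftest import random_rotation


@pytest.fixture(scope="module")
def planned_assembly(planned_segments, planned_pairs, plan):
    return assemble_neomandible([s.mesh for s in planned_segments],
                                planned_pairs, plan)


class TestMatePlanes:
    def test_self_mate_is_half_turn_about_vestibular(self, rng):
        n = rng.normal(size=3)
        plane = Plane(rng.normal(size=3), n)
        v = np.cross(plane.normal, rng.normal(size=3))
        t = mate_planes(plane, v, plane, v)
        # 180 deg rotation: trace = -1; centroid fixed
        assert np.trace(t.rotation) == pytest.approx(-1.0, abs=1e-9)
        assert np.allclose(t.apply(plane.point), plane.point, atol=1e-9)
        v_unit = v / np.linalg.norm(v)
        assert np.allclose(t.rotation @ v_unit, v_unit, atol=1e-9)

    def test_postconditions_on_random_pairs(self, rng):
        for _ in range(50):
            moving = Plane(rng.normal(scale=10, size=3), rng.normal(size=3))
            fixed = Plane(rng.normal(scale=10, size=3), rng.normal(size=3))
            mv = np.cross(moving.normal, rng.normal(size=3))
            fv = np.cross(fixed.normal, rng.normal(size=3))
            t = mate_planes(moving, mv, fixed, fv)
            assert np.allclose(t.apply(moving.point), fixed.point, atol=1e-9)
            assert (t.rotation @ moving.normal) @ fixed.normal == pytest.approx(-1.0, abs=1e-9)

    def test_roll_undefined_when_vest_parallel_to_normal(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        with pytest.raises(DegenerateGeometryError):
            mate_planes(plane, [0, 0, 2.0], plane, [1, 0, 0])


class TestAssembleNeomandible:
    def test_zero_noise_reproduces_planned_poses(self, planned_assembly, plan):
        for t, sp in zip(planned_assembly.transforms, plan):
            assert np.allclose(t.rotation, sp.pose.rotation, atol=1e-9)
            assert np.allclose(t.translation, sp.pose.translation, atol=1e-9)

    def test_zero_noise_fused_matches_planned_neomandible(
            self, planned_segments, planned_pairs, plan, planned_assembly):
        expected = None
        for sm, sp in zip(planned_segments, plan):
            placed = TriMesh(sp.pose.apply(sm.mesh.vertices), sm.mesh.faces)
            expected = placed if expected is None else expected.concatenate(placed)
        dev = np.linalg.norm(planned_assembly.fused.vertices - expected.vertices, axis=1)
        assert dev.max() < 1e-6

    def test_contact_residual_zero_by_construction(self, params, plan, rng):
        from osteoguide import PerturbationModel, GuideGeometry, perturb_plan, build_segments
        executed = perturb_plan(plan, PerturbationModel(shift_sd=0.6, tilt_sd=3.0),
                                GuideGeometry(), seed=5)
        segs = build_segments(params, executed)
        asm = assemble_neomandible([s.mesh for s in segs], executed, plan)
        assert asm.contact_residuals.max() < 1e-6

    def test_middle_segment_lengthening_translates_distal_arm(
            self, params, plan, planned_segments, planned_assembly):
        """+2 mm on the middle segment shifts the distal arm by the planned
        middle-segment axis direction; dU follows in closed form."""
        from osteoguide import build_segments
        d = 2.0
        pairs = [(sp.proximal_plane, sp.distal_plane) for sp in plan]
        sp1 = plan[1]
        pairs[1] = (sp1.proximal_plane,
                    Plane(sp1.distal_plane.point - d * sp1.axis_u, sp1.distal_plane.normal))
        segs = build_segments(params, pairs)
        asm = assemble_neomandible([s.mesh for s in segs], pairs, plan)
        # closed-form prediction: distal arm translated by -d * (R_2 u) in the
        # neomandible frame, proximal arm unchanged
        shift = -d * (plan[1].pose.rotation @ plan[1].axis_u)
        t2 = asm.transforms[2]
        expected_t2 = RigidTransform(plan[2].pose.rotation,
                                     plan[2].pose.translation + shift)
        assert np.allclose(t2.rotation, expected_t2.rotation, atol=1e-9)
        assert np.allclose(t2.translation, expected_t2.translation, atol=1e-9)
        # rigid-chain prediction of the whole fused construct, built from the
        # planned poses alone: seg1 and seg2 keep their planned poses (their
        # proximal joints are untouched), seg3 rides the 2 mm translation
        predicted = np.vstack([
            plan[0].pose.apply(segs[0].mesh.vertices),
            plan[1].pose.apply(segs[1].mesh.vertices),
            plan[2].pose.apply(segs[2].mesh.vertices) + shift,
        ])
        assert np.linalg.norm(asm.fused.vertices - predicted, axis=1).max() < 1e-9
        axis = lateral_axis_of_plan(plan)
        expected_u = u_distance(TriMesh(predicted, asm.fused.faces), axis)
        got_u = u_distance(asm.fused, axis)
        assert got_u == pytest.approx(expected_u, abs=1e-6)
        assert got_u != pytest.approx(u_distance(planned_assembly.fused, axis), abs=0.1)


class TestICP:
    def test_identity_for_equal_meshes(self, planned_segments):
        mesh = planned_segments[0].mesh
        res = icp_bestfit(mesh, mesh, seed=0)
        assert res.rms < 1e-9
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-6)

    def test_recovers_small_rigid_motions(self, planned_segments, rng):
        mesh = planned_segments[1].mesh
        for _ in range(10):
            angle = rng.uniform(0, 5)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            r = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
            t = rng.uniform(-3, 3, size=3)
            target = TriMesh(mesh.vertices @ r.T + t, mesh.faces)
            res = icp_bestfit(mesh, target, seed=3)
            aligned = res.transform.apply(mesh.vertices)
            rms = np.sqrt(np.mean(np.sum((aligned - target.vertices) ** 2, axis=1)))
            assert rms < 1e-6

    def test_rms_monotone_nonincreasing(self, planned_assembly, params, plan):
        from osteoguide import PerturbationModel, GuideGeometry, perturb_plan, build_segments
        executed = perturb_plan(plan, PerturbationModel(shift_sd=0.5, tilt_sd=2.0),
                                GuideGeometry(), seed=9)
        segs = build_segments(params, executed)
        asm = assemble_neomandible([s.mesh for s in segs], executed, plan)
        res = icp_bestfit(asm.fused, planned_assembly.fused, seed=1)
        diffs = np.diff(res.rms_history)
        assert (diffs <= 1e-12).all()

    def test_empty_source_unconstructible(self):
        # the empty-mesh contract is enforced at TriMesh construction
        with pytest.raises(ContractError):
            TriMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))


class TestUDistance:
    def test_extreme_vertex_pair(self):
        verts = np.array([[-40.0, 0, 0], [40.0, 0, 0], [0, 5, 0], [0, -5, 3]])
        mesh = TriMesh(verts, [[0, 1, 2], [0, 1, 3]])
        assert u_distance(mesh, [1, 0, 0]) == pytest.approx(80.0)

    def test_isometry_invariance(self, planned_assembly, rng):
        axis = np.array([1.0, 0, 0])
        base = u_distance(planned_assembly.fused, axis)
        t = RigidTransform(random_rotation(rng), rng.normal(scale=20, size=3))
        moved = TriMesh(t.apply(planned_assembly.fused.vertices),
                        planned_assembly.fused.faces)
        assert u_distance(moved, t.rotation @ axis) == pytest.approx(base, abs=1e-9)


class TestHeatmap:
    def test_identical_meshes_zero(self, planned_segments):
        mesh = planned_segments[0].mesh
        heat, summary = heatmap(mesh, mesh)
        assert summary["max"] < 1e-9
        assert (heat.scalar >= 0).all()

    def test_flat_patch_normal_translation(self):
        # regular grid in z=0, translated 1 mm along its normal
        g = np.linspace(0, 10, 6)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        for i in range(5):
            for j in range(5):
                a = i * 6 + j
                faces += [[a, a + 1, a + 7], [a, a + 7, a + 6]]
        planned = TriMesh(verts, faces)
        executed = TriMesh(verts + [0, 0, 1.0], faces)
        heat, summary = heatmap(executed, planned)
        assert np.allclose(heat.scalar, 1.0, atol=1e-9)
        assert summary["mean"] == pytest.approx(1.0, abs=1e-9)

    def test_signed_variant_flips_inside(self):
        g = np.linspace(0, 10, 4)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        for i in range(3):
            for j in range(3):
                a = i * 4 + j
                faces += [[a, a + 1, a + 5], [a, a + 5, a + 4]]
        planned = TriMesh(verts, faces)
        above = TriMesh(verts + [0, 0, 1.0], faces)
        below = TriMesh(verts - [0, 0, 1.0], faces)
        h_above, _ = heatmap(above, planned, signed=True)
        h_below, _ = heatmap(below, planned, signed=True)
        assert (h_above.scalar * h_below.scalar <= 1e-12).all()
        assert np.allclose(np.abs(h_above.scalar), 1.0, atol=1e-9)

    def test_candidate_pruning_matches_all_pairs_brute_force(self, planned_segments, rng):
        target = planned_segments[2].mesh
        queries = target.vertices[rng.choice(target.n_vertices, 60, replace=False)]
        queries = queries + rng.normal(scale=3.0, size=queries.shape)
        dist, _ = closest_on_mesh(queries, target)
        tri = target.vertices[target.faces]
        brute = np.empty(len(queries))
        for i, q in enumerate(queries):
            pts = _closest_on_triangles(np.broadcast_to(q, (len(tri), 3)).copy(), tri)
            brute[i] = np.linalg.norm(pts - q, axis=1).min()
        assert np.abs(dist - brute).max() < 1e-12

    def test_point_triangle_distance_matches_constrained_optimiser(self, rng):
        for _ in range(20):
            tri = rng.normal(scale=5, size=(1, 3, 3))
            q = rng.normal(scale=5, size=(1, 3))
            ours = np.linalg.norm(_closest_on_triangles(q, tri)[0] - q[0])

            a, b, c = tri[0]
            def cost(uv):
                u, v = uv
                u, v = max(u, 0), max(v, 0)
                if u + v > 1:
                    s = u + v
                    u, v = u / s, v / s
                p = a + u * (b - a) + v * (c - a)
                return np.linalg.norm(p - q[0])
            best = min(minimize(cost, x0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14}).fun
                       for x0 in [(0.3, 0.3), (0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
            assert ours == pytest.approx(best, abs=1e-6)

    def test_empty_planned_rejected(self, planned_segments):
        with pytest.raises(ContractError):
            heatmap(planned_segments[0].mesh,
                    TriMesh(np.eye(3), np.empty((0, 3), dtype=int)))


class TestReconstructEndToEnd:
    def test_zero_noise_identity(self, planned_assembly, plan):
        axis = lateral_axis_of_plan(plan)
        rr = reconstruct(planned_assembly, planned_assembly, axis, seed=2)
        assert abs(rr.delta_u) < 1e-6
        assert rr.heat_summary["max"] < 1e-6
        assert rr.u_planned > 0
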