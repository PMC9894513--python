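import json

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from palatosym import (
    DeviationResult,
    IcpConfig,
    Plane,
    RegistrationError,
    RigidTransform,
    SurfaceDistanceQuery,
    SymmetryConfig,
    colorize_deviation,
    icp_best_fit,
    landmark_prealign,
    matching_percentage,
    mirror_mesh,
    perturb_rigid,
    signed_deviation,
    symmetry_pipeline,
)
from palatosym.synthetic_palate import PalateParams, generate_palate

from conftest import random_rigid

MIDLINE = Plane([0, 0, 0], [1, 0, 0])


# ---------------------------------------------------------------------------
# Brute-force closest-point oracle (independent algorithm: candidate set =
# plane projection, all edge projections, all vertices; exhaustive over all
# triangles)
# ---------------------------------------------------------------------------

def _oracle_closest_on_tri(p, tri):
    a, b, c = tri
    candidates = [a, b, c]
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    if nn > 0:
        q = p - np.dot(p - a, n) / nn * n  # projection onto the plane
        # barycentric membership
        m = np.c_[b - a, c - a]
        st, *_ = np.linalg.lstsq(m, q - a, rcond=None)
        if st[0] >= -1e-12 and st[1] >= -1e-12 and st.sum() <= 1 + 1e-12:
            candidates.append(q)
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        t = np.clip(np.dot(p - e0, d) / np.dot(d, d), 0.0, 1.0)
        candidates.append(e0 + t * d)
    candidates = np.array(candidates)
    return candidates[np.argmin(np.linalg.norm(candidates - p, axis=1))]


def oracle_surface_distance(points, mesh):
    tris = np.asarray(mesh.triangles, float)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for tri in tris:
            q = _oracle_closest_on_tri(p, tri)
            best = min(best, np.linalg.norm(p - q))
        out[i] = best
    return out


class TestSurfaceDistance:
    def test_matches_exhaustive_oracle(self, coarse_sphere):
        """KD-pruned query equals brute force over every triangle, every point."""
        rng = np.random.default_rng(11)
        pts = rng.uniform(-1.5, 1.5, (60, 3))
        q = SurfaceDistanceQuery(coarse_sphere)
        _, dist, _ = q.query(pts)
        np.testing.assert_allclose(dist, oracle_surface_distance(pts, coarse_sphere),
                                   atol=1e-12)

    def test_sign_inside_outside_sphere(self, coarse_sphere):
        q = SurfaceDistanceQuery(coarse_sphere)
        signed, _ = q.signed_distances(np.array([[0, 0, 0], [0, 0, 2.0]]))
        assert signed[0] < 0 < signed[1]


class TestMirror:
    def test_involution(self, palate_symmetric):
        mesh = palate_symmetric.mesh
        twice = mirror_mesh(mirror_mesh(mesh, MIDLINE), MIDLINE)
        assert np.abs(twice.vertices - mesh.vertices).max() < 1e-9
        np.testing.assert_array_equal(twice.faces, mesh.faces)

    def test_points_on_plane_fixed(self, tetra):
        plane = Plane([0, 0, 0], [0, 0, 1])
        mirrored = mirror_mesh(tetra, plane)
        on_plane = np.abs(tetra.vertices[:, 2]) < 1e-12
        np.testing.assert_allclose(mirrored.vertices[on_plane], tetra.vertices[on_plane],
                                   atol=1e-12)

    def test_symmetric_mesh_maps_to_itself(self, palate_symmetric):
        """Nearest-neighbour matching: the mirrored vertex set equals the
        original up to permutation for a symmetric-by-construction mesh."""
        mesh = palate_symmetric.mesh
        mirrored = mirror_mesh(mesh, MIDLINE)
        d, _ = cKDTree(mesh.vertices).query(mirrored.vertices)
        assert d.max() < 1e-9

    def test_winding_keeps_normals_outward(self, coarse_sphere):
        mirrored = mirror_mesh(coarse_sphere, MIDLINE)
        # outward normals: face normal . (centroid - origin) > 0 everywhere
        outward = np.einsum("ij,ij->i", mirrored.face_normals,
                            mirrored.triangles.mean(axis=1))
        assert np.all(outward > 0)


class TestPrealign:
    gingival = Plane([0, 0, 0], [0, 0, 1])

    def test_identity_for_same_mesh(self, palate_symmetric):
        mesh = palate_symmetric.mesh
        tf = landmark_prealign(mesh, mesh, MIDLINE, self.gingival)
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-9
        assert np.linalg.norm(tf.translation) < 1e-9

    def test_recovers_known_displacement(self, palate_symmetric):
        """Moving mesh displaced 10 deg + 3 mm, planes co-transformed: the
        pre-alignment is the exact inverse."""
        mesh = palate_symmetric.mesh
        moved, tf = perturb_rigid(mesh, 10.0, 3.0, seed=5)
        mpp_m = Plane(tf.apply(MIDLINE.point), tf.rotation @ MIDLINE.normal)
        ging_m = Plane(tf.apply(self.gingival.point), tf.rotation @ self.gingival.normal)
        rec = landmark_prealign(moved, mesh, mpp_m, ging_m,
                                mpp_fixed=MIDLINE, gingival_fixed=self.gingival)
        residual = rec.compose(tf)
        assert residual.rotation_angle_deg() < 1e-6
        moved_back = rec.apply(moved.vertices)
        assert np.abs(moved_back - mesh.vertices).max() < 1e-6

    def test_degenerate_frame(self, palate_symmetric):
        mesh = palate_symmetric.mesh
        tilted = Plane([0, 0, 0], [np.cos(np.deg2rad(2)), 0, np.sin(np.deg2rad(2))])
        with pytest.raises(RegistrationError):
            landmark_prealign(mesh, mesh, MIDLINE, tilted)


class TestICP:
    def test_identity_on_identical_meshes(self, palate_symmetric):
        mesh = palate_symmetric.mesh
        res = icp_best_fit(mesh, mesh)
        assert res.final_rms < 1e-9
        assert res.transform.rotation_angle_deg() < 1e-9
        assert np.linalg.norm(res.transform.translation) < 1e-9

    def test_recovers_perturbation(self, palate_symmetric):
        mesh = palate_symmetric.mesh
        moved, truth = perturb_rigid(mesh, 5.0, 2.0, seed=2)
        init = landmark_prealign(moved, mesh, MIDLINE, Plane([0, 0, 0], [0, 0, 1]))
        res = icp_best_fit(moved, mesh, init=init)
        residual = res.transform.compose(truth)
        assert residual.rotation_angle_deg() < 0.1
        displacement = np.abs(residual.apply(mesh.vertices) - mesh.vertices)
        assert displacement.max() < 0.01

    def test_rms_monotone_with_local_bump(self, palate_symmetric):
        """A 1 mm localized bump cannot be registered away: RMS stays > 0 but
        never increases across iterations."""
        mesh = palate_symmetric.mesh
        bumped = mesh.copy()
        v = np.asarray(bumped.vertices, float).copy()
        center = v.mean(0)
        w = np.exp(-np.linalg.norm(v - center, axis=1) ** 2 / (2 * 3.0**2))
        v[:, 2] += 1.0 * w
        bumped.vertices = v
        res = icp_best_fit(bumped, mesh)
        hist = np.array(res.rms_history)
        assert np.all(np.diff(hist) <= 1e-12)
        assert hist[-1] > 0
        assert hist[-1] <= hist[0]


class TestSignedDeviation:
    def test_zero_on_identical(self, palate_symmetric):
        mesh = palate_symmetric.mesh
        dev = signed_deviation(mesh, mesh)
        assert dev.mean_abs == 0.0 and dev.max_abs == 0.0
        assert dev.n_points == len(mesh.vertices)

    def test_parallel_patches_analytic(self):
        """Reference plane 0.2 mm above the test plane (normals up): every
        signed distance is exactly +0.2."""
        g = np.linspace(0, 10, 8)
        xx, yy = np.meshgrid(g, g)

        def patch(z):
            verts = np.c_[xx.ravel(), yy.ravel(), np.full(xx.size, z)]
            tri = []
            n = len(g)
            for i in range(n - 1):
                for j in range(n - 1):
                    a = i * n + j
                    tri += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
            return trimesh.Trimesh(verts, np.array(tri), process=False)

        ref, test = patch(0.2), patch(0.0)
        dev = signed_deviation(ref, test)
        np.testing.assert_allclose(dev.signed_distances, 0.2, atol=1e-12)
        assert dev.mean_abs == pytest.approx(0.2)
        assert dev.max_abs == pytest.approx(0.2)

    def test_matches_triangle_oracle(self, coarse_sphere):
        """Signed deviation magnitudes equal the exhaustive per-triangle
        closest-point oracle on a <=200-face test mesh."""
        rng = np.random.default_rng(3)
        ref = trimesh.creation.icosphere(subdivisions=2)
        ref.vertices = ref.vertices * (1.0 + rng.uniform(-0.05, 0.05, (len(ref.vertices), 1)))
        dev = signed_deviation(ref, coarse_sphere)
        oracle = oracle_surface_distance(np.asarray(ref.vertices), coarse_sphere)
        np.testing.assert_allclose(np.abs(dev.signed_distances), oracle, atol=1e-12)

    def test_empty_test_mesh_errors(self, palate_symmetric):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int),
                                process=False)
        with pytest.raises(ValueError):
            signed_deviation(palate_symmetric.mesh, empty)

    def test_max_ge_mean(self, palate_asymmetric):
        res = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks)
        assert res.deviation.max_abs >= res.deviation.mean_abs >= 0


class TestMatchingPercentage:
    def _dev(self, distances):
        d = np.asarray(distances, float)
        return DeviationResult(signed_distances=d, mean_abs=float(np.abs(d).mean()),
                               max_abs=float(np.abs(d).max()), n_points=len(d))

    def test_counting(self):
        dev = self._dev([0.1, 0.2, 0.6, 0.8])
        assert matching_percentage(dev, 0.5) == pytest.approx(50.0)
        assert dev.tolerance == 0.5

    def test_all_within(self):
        assert matching_percentage(self._dev([0.0, 0.0]), 0.1) == 100.0

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(0)
        dev = self._dev(rng.normal(0, 0.4, 500))
        assert matching_percentage(dev, 0.3) <= matching_percentage(dev, 0.5)

    def test_hundred_iff_max_within(self):
        dev = self._dev([0.1, -0.4, 0.2])
        assert matching_percentage(dev, dev.max_abs) == 100.0
        assert matching_percentage(dev, dev.max_abs - 1e-9) < 100.0

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            matching_percentage(self._dev([0.1]), 0.0)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    d=st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=50),
    tol_pair=st.tuples(st.floats(0.01, 2), st.floats(0.01, 2)),
)
def test_matching_percentage_monotone_property(d, tol_pair):
    """For any distance set, matching % is non-decreasing in the tolerance
    and hits 100 exactly when the max |d| is within it."""
    arr = np.asarray(d, float)
    dev = DeviationResult(signed_distances=arr, mean_abs=float(np.abs(arr).mean()),
                          max_abs=float(np.abs(arr).max()), n_points=len(arr))
    lo, hi = sorted(tol_pair)
    assert matching_percentage(dev, lo) <= matching_percentage(dev, hi)
    assert matching_percentage(dev, dev.max_abs + 1e-9) == 100.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_reflection_involution_property(seed):
    """Reflecting any point twice across any valid plane returns it."""
    rng = np.random.default_rng(seed)
    plane = Plane(rng.uniform(-10, 10, 3), rng.standard_normal(3) + 1e-3)
    pts = rng.uniform(-50, 50, (20, 3))
    np.testing.assert_allclose(plane.reflect(plane.reflect(pts)), pts, atol=1e-9)


class TestColorize:
    def test_zero_deviation_all_green(self, tetra):
        dev = DeviationResult(signed_distances=np.zeros(4), mean_abs=0, max_abs=0,
                              n_points=4, tolerance=0.5)
        colored = colorize_deviation(tetra, dev, scale_limit=2.0)
        np.testing.assert_array_equal(colored.visual.vertex_colors[:, :3],
                                      np.tile([0, 255, 0], (4, 1)))

    def test_endpoints_and_clamp(self, tetra):
        dev = DeviationResult(signed_distances=np.array([2.0, -2.0, 5.0, 0.0]),
                              mean_abs=2.25, max_abs=5.0, n_points=4, tolerance=0.5)
        c = colorize_deviation(tetra, dev, scale_limit=2.0).visual.vertex_colors
        np.testing.assert_array_equal(c[0, :3], [255, 0, 0])   # +limit: pure red
        np.testing.assert_array_equal(c[1, :3], [0, 0, 255])   # -limit: pure blue
        np.testing.assert_array_equal(c[2, :3], [255, 0, 0])   # beyond limit clamps
        np.testing.assert_array_equal(c[3, :3], [0, 255, 0])

    def test_scale_limit_must_exceed_tolerance(self, tetra):
        dev = DeviationResult(signed_distances=np.zeros(4), mean_abs=0, max_abs=0,
                              n_points=4, tolerance=0.5)
        with pytest.raises(ValueError):
            colorize_deviation(tetra, dev, scale_limit=0.5)

    def test_asymmetric_palate_color_pattern(self, palate_asymmetric):
        """Unilateral alveolar bend: red band on one flank, blue on the mirror
        flank, green vault."""
        res = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks)
        colors = res.colored_mesh.visual.vertex_colors[:, :3]
        v = np.asarray(res.colored_mesh.vertices)
        # within tolerance is exactly pure green; any red/blue component marks
        # the out-of-tolerance band on the positive/negative side
        red = colors[:, 0] > 0
        blue = colors[:, 2] > 0
        assert red.sum() > 10 and blue.sum() > 10
        # the two out-of-tolerance bands sit on opposite sides of the midline
        assert np.sign(v[red, 0].mean()) != np.sign(v[blue, 0].mean())
        # band is low on the palate; the vault dome stays green
        band = 5.0
        vault = v[:, 2] > band
        green = (colors[:, 1] == 255) & (colors[:, 0] == 0) & (colors[:, 2] == 0)
        assert green[vault].mean() > 0.99
        assert red[~vault].sum() > 0 and blue[~vault].sum() > 0


class TestPipeline:
    def test_symmetric_palate_scores_100(self, palate_symmetric):
        res = symmetry_pipeline(palate_symmetric.mesh, palate_symmetric.landmarks)
        assert res.deviation.matching_pct == 100.0

    def test_deterministic_report(self, palate_asymmetric):
        r1 = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks)
        r2 = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks)
        assert json.dumps(r1.report, sort_keys=True) == json.dumps(r2.report, sort_keys=True)

    def test_matching_decreases_with_amplitude(self):
        pcts = []
        for a in (0.0, 0.75, 1.5):
            model = generate_palate(PalateParams(mesh_resolution=40, asymmetry_amplitude=a))
            res = symmetry_pipeline(model.mesh, model.landmarks)
            pcts.append(res.deviation.matching_pct)
        assert pcts[0] > pcts[1] > pcts[2]

    def test_rigid_motion_invariance(self, palate_asymmetric):
        """Matching % is invariant (within 0.1 points) under a joint rigid
        motion of mesh and landmarks."""
        base = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks)
        rng = np.random.default_rng(9)
        R, t = random_rigid(rng)
        moved = palate_asymmetric.mesh.copy()
        moved.vertices = np.asarray(moved.vertices) @ R.T + t
        lm = palate_asymmetric.landmarks.transformed(R, t)
        res = symmetry_pipeline(moved, lm)
        assert abs(res.deviation.matching_pct - base.deviation.matching_pct) < 0.1

    def test_both_tolerances_exercised(self, palate_asymmetric):
        """0.5 mm default and the 0.3 mm display tolerance: tighter band can
        only lower the matching percentage."""
        r_05 = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks,
                                 SymmetryConfig(tolerance_mm=0.5))
        r_03 = symmetry_pipeline(palate_asymmetric.mesh, palate_asymmetric.landmarks,
                                 SymmetryConfig(tolerance_mm=0.3))
        assert r_03.deviation.matching_pct <= r_05.deviation.matching_pct

    def test_stage_error_tagging(self, palate_symmetric):
        from palatosym import PipelineStageError
        lm = palate_symmetric.landmarks
        no_apical = type(lm)(dict(lm.points), apical_dgj=None,
                             crossbite_side=lm.crossbite_side)
        with pytest.raises(PipelineStageError, match="fit_gingival_plane"):
            symmetry_pipeline(palate_symmetric.mesh, no_apical)


class TestRigidTransform:
    def test_rejects_reflection(self):
        F = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(F, np.zeros(3))

    def test_compose_inverse(self):
        rng = np.random.default_rng(1)
        _, tfa = perturb_rigid(trimesh.creation.icosphere(1), 20, 5, seed=1)
        inv = tfa.inverse()
        resid = inv.compose(tfa)
        assert resid.rotation_angle_deg() < 1e-10
        assert np.linalg.norm(resid.translation) < 1e-10
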