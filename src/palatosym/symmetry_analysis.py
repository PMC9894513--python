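"""Mirror-symmetry deviation analysis of the segmented palate.

The palate is mirrored across the median palatal plane, the mirrored copy is
registered back onto the original (plane-frame pre-alignment followed by
point-to-plane ICP), and asymmetry is quantified as the signed closest-point
distance from every original vertex to the registered mirrored surface.  The
matching percentage — the fraction of vertices whose absolute deviation lies
within a tolerance band (default 0.5 mm) — is the scalar symmetry index; a
perfectly symmetric surface scores 100 %.

Sign convention: positive means the reference vertex lies on the outward-
normal side of the test surface (rendered red), negative the opposite
(blue); within tolerance is green.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .mesh_io import LandmarkSet
from .palate_geometry import (
    DegenerateInputError,
    Plane,
    construct_mpp,
    fit_gingival_plane,
    segment_palate,
)

__all__ = [
    "RegistrationError",
    "PipelineStageError",
    "RigidTransform",
    "DeviationResult",
    "IcpConfig",
    "IcpResult",
    "SymmetryConfig",
    "SymmetryResult",
    "SurfaceDistanceQuery",
    "mirror_mesh",
    "landmark_prealign",
    "icp_best_fit",
    "signed_deviation",
    "matching_percentage",
    "colorize_deviation",
    "symmetry_pipeline",
]


class RegistrationError(RuntimeError):
    """Registration could not proceed (no correspondences, degenerate frame)."""


class PipelineStageError(RuntimeError):
    """Failure inside symmetry_pipeline, tagged with the stage that raised."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation det +1, never a reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Closest point on a triangulated surface
# ---------------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                          c: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (a,b,c) to each query p, vectorised.

    Standard barycentric-region case analysis; all inputs (m, 3).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)   # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)   # edge AC

    va = d3 * d6 - d5 * d4
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(den != 0, num / den, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))                                  # edge BC

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    interior = a + v[:, None] * ab + w[:, None] * ac                     # face
    out[~done] = interior[~done]
    return out


class SurfaceDistanceQuery:
    """Exact closest-point queries against a triangle mesh.

    Candidate triangles are pruned with two KD-trees (mesh vertices for an
    upper bound, triangle centroids for the candidate ball).  A triangle
    whose closest point beats the current bound must have a point within the
    bound of the query, hence a centroid within bound + max centroid-to-
    vertex radius — so the pruning is lossless and results equal a brute-
    force scan over every triangle.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise ValueError("empty test mesh")
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles, float)
        self.face_normals = np.asarray(mesh.face_normals, float)
        self.centroids = self.triangles.mean(axis=1)
        self._r_max = float(
            np.linalg.norm(self.triangles - self.centroids[:, None, :], axis=2).max()
        )
        self._vertex_tree = cKDTree(np.asarray(mesh.vertices, float))
        self._centroid_tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, distances, triangle_ids) for each query point.

        Ties between triangles (closest point on a shared edge/vertex) break
        deterministically to the lowest triangle index.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        ub, _ = self._vertex_tree.query(pts)
        radii = ub + self._r_max + 1e-9
        candidate_lists = self._centroid_tree.query_ball_point(pts, r=radii)
        lengths = np.fromiter((len(c) for c in candidate_lists), int, len(pts))
        tids = np.concatenate([np.sort(c) for c in candidate_lists]) if len(pts) else np.empty(0, int)
        pidx = np.repeat(np.arange(len(pts)), lengths)
        tri = self.triangles[tids]
        cand_closest = _closest_on_triangles(pts[pidx], tri[:, 0], tri[:, 1], tri[:, 2])
        d2 = np.einsum("ij,ij->i", pts[pidx] - cand_closest, pts[pidx] - cand_closest)
        # per-point argmin; lexsort keeps the lowest triangle id on ties
        order = np.lexsort((tids, d2, pidx))
        boundaries = np.searchsorted(pidx[order], np.arange(len(pts)))
        best = order[boundaries]
        closest = cand_closest[best]
        dist = np.sqrt(d2[best])
        tid = tids[best]
        return closest, dist, tid

    def signed_distances(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed distance of each point to the surface, plus triangle ids.

        Sign is taken against the face normal of the triangle carrying the
        closest point: positive = point lies on the outward-normal side.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        closest, dist, tid = self.query(pts)
        side = np.einsum("ij,ij->i", pts - closest, self.face_normals[tid])
        return np.where(side >= 0, dist, -dist), tid

    def boundary_distance(self, points: np.ndarray, sample_step: float = 0.25) -> np.ndarray:
        """Distance from each point to the test mesh's boundary edges.

        Boundary edges are sampled every ``sample_step`` mm; returns +inf for
        a watertight mesh.
        """
        edges = self.mesh.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = unique[counts == 1]
        if len(boundary) == 0:
            return np.full(len(np.atleast_2d(points)), np.inf)
        v = np.asarray(self.mesh.vertices, float)
        samples = []
        for e in boundary:
            p0, p1 = v[e[0]], v[e[1]]
            n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / sample_step)) + 1)
            t = np.linspace(0.0, 1.0, n)[:, None]
            samples.append(p0 + t * (p1 - p0))
        tree = cKDTree(np.vstack(samples))
        d, _ = tree.query(np.atleast_2d(np.asarray(points, float)))
        return d


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------

def mirror_mesh(mesh: trimesh.Trimesh, mpp: Plane) -> trimesh.Trimesh:
    """Reflect a mesh across the median palatal plane.

    Reflection flips orientation, so face winding is reversed afterwards to
    keep outward normals outward — the deviation sign convention depends on
    it.  Mirroring twice returns the original mesh.
    """
    verts = mpp.reflect(np.asarray(mesh.vertices, float))
    faces = np.asarray(mesh.faces, int)[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _plane_frame(mpp: Plane, gingival: Plane, min_angle_deg: float = 5.0) -> np.ndarray:
    """Right-handed orthonormal frame (columns) from the two reference planes."""
    e1 = mpp.normal
    g = gingival.normal
    cos = abs(float(np.dot(e1, g)))
    if cos > np.cos(np.deg2rad(min_angle_deg)):
        raise RegistrationError(
            "MPP and gingival normals are within 5 deg of parallel; frame degenerate"
        )
    e2 = g - np.dot(g, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def landmark_prealign(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    mpp: Plane,
    gingival: Plane,
    mpp_fixed: Plane | None = None,
    gingival_fixed: Plane | None = None,
) -> RigidTransform:
    """Preliminary registration from the MPP / gingival plane frames.

    Rotates the frame spanned by (MPP normal, gingival normal, their cross
    product) of the moving mesh onto the fixed mesh's frame and aligns the
    vertex centroids.  ``mpp``/``gingival`` describe the moving mesh; the
    fixed mesh's planes default to the same ones (the mirrored-vs-original
    case, where both models share the reference planes).  Always a proper
    rotation.
    """
    frame_m = _plane_frame(mpp, gingival)
    frame_f = _plane_frame(mpp_fixed or mpp, gingival_fixed or gingival)
    R = frame_f @ frame_m.T
    c_m = np.asarray(moving.vertices, float).mean(axis=0)
    c_f = np.asarray(fixed.vertices, float).mean(axis=0)
    return RigidTransform(R, c_f - R @ c_m)


@dataclass
class IcpConfig:
    """Point-to-plane ICP settings.

    ``rejection_multiplier`` scales the median nearest-neighbour spacing of
    the fixed mesh's vertices into the correspondence rejection distance.
    Correspondence is full-vertex and deterministic; random subsampling only
    happens when ``subsample`` is set, driven by ``seed``.
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-6
    rejection_multiplier: float = 10.0
    subsample: int | None = None
    seed: int = 0


@dataclass
class IcpResult:
    transform: RigidTransform
    rms_history: list[float]
    iterations: int
    converged: bool

    @property
    def final_rms(self) -> float:
        return self.rms_history[-1]


def _solve_point_to_plane(p: np.ndarray, q: np.ndarray, n: np.ndarray) -> RigidTransform:
    """One linearised point-to-plane step: argmin sum(((Rp + t - q) . n)^2)."""
    b = np.einsum("ij,ij->i", q - p, n)
    A = np.hstack([np.cross(p, n), n])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-15:
        R = np.eye(3)
    else:  # Rodrigues from the linearised rotation vector
        k = omega / angle
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, t)


def icp_best_fit(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    init: RigidTransform | None = None,
    config: IcpConfig | None = None,
) -> IcpResult:
    """Best-fit alignment: point-to-plane ICP of moving onto fixed.

    Returns the composed transform (init, then refinement).  The point-to-
    surface RMS is evaluated after every step; a step that increases it is
    reverted and iteration stops, so the recorded RMS history is monotone
    non-increasing.  Deterministic: full-vertex correspondences unless
    ``config.subsample`` requests seeded subsampling.
    """
    cfg = config or IcpConfig()
    init = init or RigidTransform.identity()
    query = SurfaceDistanceQuery(fixed)
    src = np.asarray(moving.vertices, float)
    if cfg.subsample is not None and cfg.subsample < len(src):
        rng = np.random.default_rng(cfg.seed)
        src = src[rng.choice(len(src), cfg.subsample, replace=False)]

    vtree = cKDTree(np.asarray(fixed.vertices, float))
    nn_d, _ = vtree.query(np.asarray(fixed.vertices, float), k=2)
    reject = cfg.rejection_multiplier * float(np.median(nn_d[:, 1]))

    total = init
    pts = total.apply(src)

    def surface_rms(p):
        _, d, _ = query.query(p)
        mask = d <= reject
        if not mask.any():
            raise RegistrationError("no correspondences within rejection distance")
        return float(np.sqrt(np.mean(d[mask] ** 2))), mask

    rms, mask = surface_rms(pts)
    history = [rms]
    converged = False
    iterations = 0
    for _ in range(cfg.max_iterations):
        closest, dist, tid = query.query(pts)
        mask = dist <= reject
        if not mask.any():
            raise RegistrationError("no correspondences within rejection distance")
        step = _solve_point_to_plane(pts[mask], closest[mask], query.face_normals[tid[mask]])
        cand_total = step.compose(total)
        cand_pts = cand_total.apply(src)
        cand_rms, _ = surface_rms(cand_pts)
        if cand_rms > history[-1]:
            break  # reverted: keep the monotone best-so-far transform
        total, pts = cand_total, cand_pts
        iterations += 1
        history.append(cand_rms)
        if abs(history[-2] - history[-1]) < cfg.convergence_tol:
            converged = True
            break
    return IcpResult(transform=total, rms_history=history,
                     iterations=iterations, converged=converged)


# ---------------------------------------------------------------------------
# Deviation analysis
# ---------------------------------------------------------------------------

@dataclass
class DeviationResult:
    """Per-vertex signed deviations (mm) of a reference model vs a test surface.

    ``n_points`` counts the distances entering the statistics — all reference
    vertices by default ("100 % of the surface points"); a border-exclusion
    band reduces it and reports ``n_excluded``.
    """

    signed_distances: np.ndarray
    mean_abs: float
    max_abs: float
    n_points: int
    matching_pct: float | None = None
    tolerance: float | None = None
    n_excluded: int = 0
    included: np.ndarray | None = None      # bool mask over reference vertices
    reverse_distances: np.ndarray | None = None  # test->reference, symmetric mode

    def all_distances(self) -> np.ndarray:
        """Distances entering matching %, both directions in symmetric mode."""
        incl = self.signed_distances if self.included is None \
            else self.signed_distances[self.included]
        if self.reverse_distances is not None:
            return np.concatenate([incl, self.reverse_distances])
        return incl


def signed_deviation(
    reference: trimesh.Trimesh,
    test: trimesh.Trimesh,
    border_exclude_mm: float = 0.0,
    symmetric: bool = False,
) -> DeviationResult:
    """Signed closest-point distance from every reference vertex to the test surface.

    The closest point is taken over whole triangles (point-to-surface, not
    point-to-point); the sign follows the test surface's outward normal at
    the carrying triangle.  ``border_exclude_mm`` drops reference vertices
    whose closest point lies within that distance of a boundary edge of the
    test surface; ``symmetric`` additionally measures test->reference and
    pools both directions into the summary statistics.
    """
    if len(test.faces) == 0:
        raise ValueError("empty test mesh")
    query = SurfaceDistanceQuery(test)
    ref_pts = np.asarray(reference.vertices, float)
    signed, tid = query.signed_distances(ref_pts)
    included = None
    n_excluded = 0
    if border_exclude_mm > 0:
        closest, _, _ = query.query(ref_pts)
        border_d = query.boundary_distance(closest)
        included = border_d > border_exclude_mm
        n_excluded = int((~included).sum())
    dist_pool = signed if included is None else signed[included]
    reverse = None
    if symmetric:
        rev_query = SurfaceDistanceQuery(reference)
        reverse, _ = rev_query.signed_distances(np.asarray(test.vertices, float))
        dist_pool = np.concatenate([dist_pool, reverse])
    if dist_pool.size == 0:
        raise ValueError("border exclusion removed every reference vertex")
    return DeviationResult(
        signed_distances=signed,
        mean_abs=float(np.mean(np.abs(dist_pool))),
        max_abs=float(np.max(np.abs(dist_pool))),
        n_points=int(dist_pool.size),
        n_excluded=n_excluded,
        included=included,
        reverse_distances=reverse,
    )


def matching_percentage(dev: DeviationResult, tolerance: float) -> float:
    """Percent of deviations within +/- tolerance; stored into the result."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    d = dev.all_distances()
    pct = 100.0 * float(np.count_nonzero(np.abs(d) <= tolerance)) / d.size
    dev.matching_pct = pct
    dev.tolerance = float(tolerance)
    return pct


def colorize_deviation(
    mesh: trimesh.Trimesh,
    dev: DeviationResult,
    scale_limit: float = 2.0,
    tolerance: float | None = None,
) -> trimesh.Trimesh:
    """RGB deviation map: green within tolerance, grading to red (+) / blue (-).

    Deviations beyond ``+/- scale_limit`` clamp to pure red / pure blue,
    matching the conventional surface-comparison colour bar.
    """
    tol = dev.tolerance if tolerance is None else float(tolerance)
    if tol is None:
        raise ValueError("no tolerance given and none stored in the deviation result")
    if scale_limit <= tol:
        raise ValueError("scale_limit must exceed the tolerance")
    d = np.asarray(dev.signed_distances, float)
    if len(d) != len(mesh.vertices):
        raise ValueError("deviation result was not computed on this mesh")
    colors = np.zeros((len(d), 4), dtype=np.uint8)
    colors[:, 3] = 255
    t = np.clip((np.abs(d) - tol) / (scale_limit - tol), 0.0, 1.0)
    green = np.abs(d) <= tol
    pos = (~green) & (d > 0)
    neg = (~green) & (d < 0)
    colors[green] = [0, 255, 0, 255]
    colors[pos, 0] = np.round(255 * t[pos]).astype(np.uint8)
    colors[pos, 1] = np.round(255 * (1 - t[pos])).astype(np.uint8)
    colors[neg, 2] = np.round(255 * t[neg]).astype(np.uint8)
    colors[neg, 1] = np.round(255 * (1 - t[neg])).astype(np.uint8)
    out = mesh.copy()
    out.visual.vertex_colors = colors
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class SymmetryConfig:
    """End-to-end settings of the symmetry analysis."""

    tolerance_mm: float = 0.5
    scale_limit_mm: float = 2.0
    border_exclude_mm: float = 0.0
    symmetric_distance: bool = False
    icp: IcpConfig = field(default_factory=IcpConfig)


@dataclass
class SymmetryResult:
    deviation: DeviationResult
    colored_mesh: trimesh.Trimesh
    transform: RigidTransform
    segmented: trimesh.Trimesh
    mpp: Plane
    gingival: Plane
    icp: IcpResult

    @property
    def report(self) -> dict:
        """JSON-ready summary of the run."""
        return {
            "matching_pct": self.deviation.matching_pct,
            "mean_abs_mm": self.deviation.mean_abs,
            "max_abs_mm": self.deviation.max_abs,
            "tolerance_mm": self.deviation.tolerance,
            "n_points": self.deviation.n_points,
            "n_excluded": self.deviation.n_excluded,
            "icp": {
                "iterations": self.icp.iterations,
                "final_rms_mm": self.icp.final_rms,
            },
        }


def symmetry_pipeline(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    config: SymmetryConfig | None = None,
) -> SymmetryResult:
    """Full mirror-symmetry workflow on one maxillary model.

    Stages: gingival-plane fit -> MPP construction -> palatal segmentation ->
    mirroring -> plane-frame pre-alignment -> point-to-plane ICP ->
    signed deviation -> matching percentage -> colour map.  Any stage failure
    is re-raised as :class:`PipelineStageError` tagged with the stage name.
    """
    cfg = config or SymmetryConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise PipelineStageError(name, exc) from exc

    if landmarks.apical_dgj is None or len(landmarks.apical_dgj) < 3:
        raise PipelineStageError(
            "fit_gingival_plane",
            DegenerateInputError("landmark set carries no apical DGJ points"),
        )
    # the raphe midpoint sits on the vault, orienting the gingival normal
    vault_ref = 0.5 * (landmarks["raphe_1"] + landmarks["raphe_2"])
    gingival = stage("fit_gingival_plane", fit_gingival_plane,
                     landmarks.apical_dgj, orient_toward=vault_ref)
    mpp = stage("construct_mpp", construct_mpp,
                landmarks["raphe_1"], landmarks["raphe_2"], gingival.normal)
    segmented = stage("segment_palate", segment_palate, mesh, gingival)
    mirrored = stage("mirror_mesh", mirror_mesh, segmented, mpp)
    pre = stage("landmark_prealign", landmark_prealign, mirrored, segmented, mpp, gingival)
    icp_res = stage("icp_best_fit", icp_best_fit, mirrored, segmented, pre, cfg.icp)
    registered = mirrored.copy()
    registered.vertices = icp_res.transform.apply(np.asarray(mirrored.vertices, float))
    dev = stage("signed_deviation", signed_deviation, segmented, registered,
                cfg.border_exclude_mm, cfg.symmetric_distance)
    stage("matching_percentage", matching_percentage, dev, cfg.tolerance_mm)
    colored = stage("colorize_deviation", colorize_deviation, segmented, dev,
                    cfg.scale_limit_mm, cfg.tolerance_mm)
    return SymmetryResult(
        deviation=dev,
        colored_mesh=colored,
        transform=icp_res.transform,
        segmented=segmented,
        mpp=mpp,
        gingival=gingival,
        icp=icp_res,
    )
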