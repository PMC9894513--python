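"""Reference planes, palatal segmentation and arch morphometrics.

The median palatal plane (MPP) is the sagittal mirror plane of the analysis:
it contains the two raphe landmarks and a vertical direction (by default the
gingival-plane normal, making the MPP perpendicular to the gingival plane).
The gingival plane is a total-least-squares fit through the most apical
dento-gingival-junction points and separates the palatal vault from the
dental/gingival part of the model.

Arch measurements follow the clinical definitions: ICW/IMW are Euclidean
distances between bilateral dento-gingival-junction midpoints of primary
canines / first molars; the emi-lateral widths eICW/eIMW are the orthogonal
distances of one such midpoint to the MPP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_io import LandmarkSet, LandmarkSchemaError, validate_mesh

__all__ = [
    "DegenerateInputError",
    "SegmentationError",
    "Plane",
    "ArchMeasurements",
    "construct_mpp",
    "fit_gingival_plane",
    "segment_palate",
    "landmark_width",
    "emi_width",
    "measure_arch",
]


class DegenerateInputError(ValueError):
    """Geometric input does not determine the requested object."""


class SegmentationError(ValueError):
    """Plane clipping produced an empty palate."""


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, float).reshape(3))
        n = np.asarray(self.normal, float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise DegenerateInputError("plane normal has zero length")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed orthogonal distance, positive on the normal side."""
        pts = np.atleast_2d(np.asarray(points, float))
        d = (pts - self.point) @ self.normal
        return d if np.asarray(points).ndim > 1 else d[0]

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Mirror points across the plane: v - 2((v-p)·n)n."""
        pts = np.atleast_2d(np.asarray(points, float))
        d = (pts - self.point) @ self.normal
        out = pts - 2.0 * d[:, None] * self.normal
        return out if np.asarray(points).ndim > 1 else out[0]

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        d = (pts - self.point) @ self.normal
        out = pts - d[:, None] * self.normal
        return out if np.asarray(points).ndim > 1 else out[0]

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


def construct_mpp(
    raphe_1: np.ndarray,
    raphe_2: np.ndarray,
    vertical_hint: np.ndarray,
    min_angle_deg: float = 1.0,
) -> Plane:
    """Median palatal plane through the two raphe points.

    Two points under-determine a plane; the plane returned contains the raphe
    axis and the direction ``vertical_hint`` (typically the gingival-plane
    normal, so the MPP is the sagittal plane through the raphe perpendicular
    to the gingival plane).  The plane's point is the raphe midpoint and its
    normal is ``normalize((raphe_2 - raphe_1) x vertical_hint)``.
    """
    r1 = np.asarray(raphe_1, float).reshape(3)
    r2 = np.asarray(raphe_2, float).reshape(3)
    axis = r2 - r1
    axis_len = np.linalg.norm(axis)
    if axis_len < 1e-12:
        raise DegenerateInputError("raphe points coincide; MPP undefined")
    hint = np.asarray(vertical_hint, float).reshape(3)
    hint_len = np.linalg.norm(hint)
    if hint_len < 1e-12:
        raise DegenerateInputError("vertical_hint has zero length")
    sin_angle = np.linalg.norm(np.cross(axis / axis_len, hint / hint_len))
    if sin_angle < np.sin(np.deg2rad(min_angle_deg)):
        raise DegenerateInputError(
            "vertical_hint is (nearly) parallel to the raphe axis; MPP undefined"
        )
    normal = np.cross(axis, hint)
    return Plane(point=0.5 * (r1 + r2), normal=normal)


def fit_gingival_plane(
    apical_dgj: np.ndarray,
    orient_toward: np.ndarray | None = None,
) -> Plane:
    """Total-least-squares plane through the apical DGJ points.

    Minimises the sum of squared orthogonal distances (the smallest-singular-
    vector of the centered point cloud).  With ``orient_toward`` given (the
    vault centroid), the normal is flipped so that point lies on the positive
    side — the convention every downstream segmentation step relies on.
    """
    pts = np.asarray(apical_dgj, float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegenerateInputError("need at least 3 apical DGJ points to fit a plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered cloud: normal = right singular vector of the
    # smallest singular value; collinear clouds have two ~zero values.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise DegenerateInputError("apical DGJ points are collinear; plane undefined")
    normal = vt[2]
    plane = Plane(point=centroid, normal=normal)
    if orient_toward is not None and plane.signed_distance(np.asarray(orient_toward, float)) < 0:
        plane = plane.flipped()
    return plane


def segment_palate(mesh: trimesh.Trimesh, gingival: Plane) -> trimesh.Trimesh:
    """Clip the model to the vault side of the gingival plane.

    Triangles crossing the plane are split exactly at the plane (new vertices
    on the plane), so the segmented area varies continuously with the plane
    position.  The output contains every part of the surface with
    non-negative signed distance to the oriented gingival plane.
    """
    out = mesh.slice_plane(plane_origin=gingival.point, plane_normal=gingival.normal)
    if out is None or len(out.faces) == 0:
        raise SegmentationError("no geometry on the vault side of the gingival plane")
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()
    report = validate_mesh(out)
    if not report.clean or len(out.faces) == 0:
        raise SegmentationError(f"segmented palate failed validation: {report}")
    return out


def landmark_width(p_left: np.ndarray, p_right: np.ndarray) -> float:
    """Euclidean distance (mm) between bilateral DGJ midpoints (ICW / IMW)."""
    return float(np.linalg.norm(np.asarray(p_left, float) - np.asarray(p_right, float)))


def emi_width(landmark: np.ndarray, mpp: Plane) -> float:
    """Unsigned orthogonal distance (mm) from a DGJ midpoint to the MPP."""
    return float(abs(mpp.signed_distance(np.asarray(landmark, float))))


@dataclass
class ArchMeasurements:
    """Linear arch measurements of one model (all mm, all > 0).

    ``ICW``/``IMW`` are the bilateral intercanine / intermolar widths;
    the ``e*`` fields are the emi-lateral widths measured to the MPP.
    ``*_cbs``/``*_ncbs`` aliases resolve left/right into crossbite /
    non-crossbite side and are only present when a crossbite side is known.
    """

    ICW: float
    IMW: float
    eICW_left: float
    eICW_right: float
    eIMW_left: float
    eIMW_right: float
    eICW_cbs: float | None = None
    eICW_ncbs: float | None = None
    eIMW_cbs: float | None = None
    eIMW_ncbs: float | None = None
    crossbite_side: str = "none"
    timepoint: str | None = None

    def to_row(self, subject_id: str | None = None) -> dict:
        """One flat CSV-ready record."""
        row: dict = {"subject_id": subject_id, "timepoint": self.timepoint}
        for k in ("ICW", "IMW", "eICW_left", "eICW_right", "eIMW_left", "eIMW_right",
                  "eICW_cbs", "eICW_ncbs", "eIMW_cbs", "eIMW_ncbs"):
            row[k] = getattr(self, k)
        return row


def measure_arch(
    landmarks: LandmarkSet,
    mpp: Plane,
    timepoint: str | None = None,
    project_onto: Plane | None = None,
) -> ArchMeasurements:
    """Assemble all arch widths from a landmark set and the MPP.

    With ``project_onto`` set (e.g. the gingival plane), landmarks are first
    projected onto that plane so widths become in-plane rather than full 3D
    distances; default is 3D Euclidean.
    """
    def get(name: str) -> np.ndarray:
        try:
            p = landmarks[name]
        except KeyError as exc:
            raise LandmarkSchemaError(f"missing landmark {name!r}") from exc
        return project_onto.project(p) if project_onto is not None else p

    cl, cr = get("canine_L"), get("canine_R")
    ml, mr = get("molar_L"), get("molar_R")
    m = ArchMeasurements(
        ICW=landmark_width(cl, cr),
        IMW=landmark_width(ml, mr),
        eICW_left=emi_width(cl, mpp),
        eICW_right=emi_width(cr, mpp),
        eIMW_left=emi_width(ml, mpp),
        eIMW_right=emi_width(mr, mpp),
        crossbite_side=landmarks.crossbite_side,
        timepoint=timepoint,
    )
    side = landmarks.crossbite_side
    if side in ("left", "right"):
        cbs, ncbs = ("left", "right") if side == "left" else ("right", "left")
        m.eICW_cbs = getattr(m, f"eICW_{cbs}")
        m.eICW_ncbs = getattr(m, f"eICW_{ncbs}")
        m.eIMW_cbs = getattr(m, f"eIMW_{cbs}")
        m.eIMW_ncbs = getattr(m, f"eIMW_{ncbs}")
    return m
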