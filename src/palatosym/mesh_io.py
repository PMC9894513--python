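"""Mesh and landmark file handling.

Meshes are maxillary dental models or segmented palatal vaults, represented
as :class:`trimesh.Trimesh` with coordinates in millimetres.  Units are fixed
to mm throughout the package; no unit metadata is trusted from files.
Landmarks are named anatomical points stored as plain JSON so they stay
diff-able and hand-editable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger("palatosym")

__all__ = [
    "MeshFormatError",
    "MeshValidationError",
    "LandmarkSchemaError",
    "LandmarkSet",
    "ValidationReport",
    "REQUIRED_LANDMARKS",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "validate_mesh",
]


class MeshFormatError(ValueError):
    """File could not be parsed as the declared mesh format."""


class MeshValidationError(ValueError):
    """Mesh violates a structural invariant (non-finite, empty, bad indices)."""


class LandmarkSchemaError(ValueError):
    """Landmark JSON is missing required names or has malformed coordinates."""


#: Landmark names required by every measurement entry point: the two raphe
#: points defining the median palatal plane and the dento-gingival-junction
#: midpoints of primary canines and first molars on each side.
REQUIRED_LANDMARKS = ("raphe_1", "raphe_2", "canine_L", "canine_R", "molar_L", "molar_R")

_CROSSBITE_SIDES = ("left", "right", "none")


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) on a maxillary model.

    Parameters
    ----------
    points
        Mapping from landmark name to a 3-vector.  Must contain all of
        :data:`REQUIRED_LANDMARKS`.
    apical_dgj
        Optional ``(n, 3)`` array of the most apical dento-gingival-junction
        points of all teeth; used to fit the gingival (segmentation) plane.
    crossbite_side
        Which side carries the posterior crossbite, or ``"none"``.
    """

    points: dict[str, np.ndarray]
    apical_dgj: np.ndarray | None = None
    crossbite_side: str = "none"

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.points]
        if missing:
            raise LandmarkSchemaError(f"missing required landmark(s): {missing}")
        for name, p in self.points.items():
            if not np.all(np.isfinite(p)):
                raise LandmarkSchemaError(f"non-finite coordinate in landmark {name!r}")
        if np.linalg.norm(self.points["raphe_1"] - self.points["raphe_2"]) <= 0:
            raise LandmarkSchemaError("raphe_1 and raphe_2 must be distinct points")
        if self.crossbite_side not in _CROSSBITE_SIDES:
            raise LandmarkSchemaError(
                f"crossbite_side must be one of {_CROSSBITE_SIDES}, got {self.crossbite_side!r}"
            )
        if self.apical_dgj is not None:
            self.apical_dgj = np.asarray(self.apical_dgj, dtype=float).reshape(-1, 3)
            if not np.all(np.isfinite(self.apical_dgj)):
                raise LandmarkSchemaError("non-finite coordinate in apical_dgj")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Return a copy with every point mapped through ``R p + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        pts = {k: R @ v + t for k, v in self.points.items()}
        ap = None if self.apical_dgj is None else self.apical_dgj @ R.T + t
        return LandmarkSet(pts, apical_dgj=ap, crossbite_side=self.crossbite_side)

    def to_dict(self) -> dict:
        d: dict = {k: [float(x) for x in v] for k, v in self.points.items()}
        if self.apical_dgj is not None:
            d["apical_dgj"] = [[float(x) for x in p] for p in self.apical_dgj]
        d["crossbite_side"] = self.crossbite_side
        return d


@dataclass
class ValidationReport:
    """Structural health counts for a mesh; ``clean`` iff all counts are zero."""

    n_vertices: int
    n_faces: int
    degenerate_faces: int
    unreferenced_vertices: int
    nonfinite_coordinates: int

    @property
    def clean(self) -> bool:
        return (
            self.degenerate_faces == 0
            and self.unreferenced_vertices == 0
            and self.nonfinite_coordinates == 0
        )


def _as_trimesh(obj, path: Path) -> trimesh.Trimesh:
    if isinstance(obj, trimesh.Scene):
        geoms = list(obj.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no geometry")
        obj = trimesh.util.concatenate(geoms)
    if not isinstance(obj, trimesh.Trimesh):
        raise MeshFormatError(f"{path}: not a triangle mesh ({type(obj).__name__})")
    return obj


def read_mesh(path, fmt: str = "auto") -> trimesh.Trimesh:
    """Read a triangle mesh (STL binary/ASCII, PLY, OBJ), validated, in mm.

    STL stores a triangle soup; vertices identical to within ~1e-9 mm are
    welded on read so per-vertex deviation fields are well defined.

    Raises
    ------
    MeshFormatError
        If the file is missing, unparsable, or contains no triangles.
    MeshValidationError
        If the parsed mesh has non-finite coordinates or fewer than
        4 vertices / 1 face.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"{path}: no such file")
    file_type = None if fmt == "auto" else fmt
    try:
        mesh = trimesh.load(str(path), file_type=file_type, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - loader errors vary by format
        raise MeshFormatError(f"{path}: cannot parse as mesh ({exc})") from exc
    mesh = _as_trimesh(mesh, path)
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise MeshFormatError(f"{path}: empty mesh")
    bad = np.nonzero(~np.isfinite(mesh.vertices).all(axis=1))[0]
    if bad.size:
        raise MeshValidationError(
            f"{path}: non-finite coordinates at vertex indices {bad[:10].tolist()}"
        )
    # STL is a soup of per-triangle vertices; weld exact/near duplicates.
    if (file_type or path.suffix.lstrip(".").lower()) in ("stl", "stl_ascii"):
        mesh.merge_vertices(merge_tex=True, merge_norm=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    if len(mesh.vertices) < 4 or len(mesh.faces) < 1:
        raise MeshValidationError(f"{path}: fewer than 4 vertices / 1 face after cleanup")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, fmt: str | None = None) -> Path:
    """Write a mesh as STL (binary) or PLY (ASCII, with vertex colors if set).

    PLY output carries per-vertex uchar red/green/blue properties whenever
    the mesh has vertex colors (deviation maps).  STL cannot store vertex
    attributes; writing a colored mesh to STL drops them with a logged
    warning.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    has_colors = (
        hasattr(mesh.visual, "vertex_colors")
        and mesh.visual.kind == "vertex"
    )
    if fmt in ("stl", "stl_ascii"):
        if has_colors:
            log.warning("%s: STL cannot store vertex attributes; colors dropped", path)
        data = trimesh.exchange.stl.export_stl(mesh) if fmt == "stl" else \
            trimesh.exchange.stl.export_stl_ascii(mesh).encode()
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif fmt == "ply":
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        path.write_bytes(data)
    else:
        raise MeshFormatError(f"unsupported output format {fmt!r} (use stl or ply)")
    return path


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file.

    Schema: an object mapping landmark names to ``[x, y, z]`` mm arrays,
    with optional ``"apical_dgj"`` (list of points) and ``"crossbite_side"``
    (``"left" | "right" | "none"``, default ``"none"``).
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LandmarkSchemaError(f"{path}: cannot read landmark JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise LandmarkSchemaError(f"{path}: top-level JSON must be an object")
    crossbite = raw.pop("crossbite_side", "none")
    apical = raw.pop("apical_dgj", None)
    points = {}
    for name, val in raw.items():
        try:
            p = np.asarray(val, dtype=float).reshape(3)
        except (TypeError, ValueError) as exc:
            raise LandmarkSchemaError(f"{path}: landmark {name!r} is not a numeric [x,y,z]") from exc
        points[name] = p
    missing = [n for n in REQUIRED_LANDMARKS if n not in points]
    if missing:
        raise LandmarkSchemaError(f"{path}: missing required landmark(s): {missing}")
    return LandmarkSet(points, apical_dgj=apical, crossbite_side=crossbite)


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(landmarks.to_dict(), indent=2))
    return path


def validate_mesh(mesh: trimesh.Trimesh, area_eps: float = 1e-12) -> ValidationReport:
    """Report structural defects without modifying the mesh.

    Degenerate faces are triangles whose area is below ``area_eps`` mm^2;
    unreferenced vertices appear in no face; non-finite coordinates are
    counted per vertex.
    """
    verts = np.asarray(mesh.vertices, float)
    faces = np.asarray(mesh.faces, int)
    nonfinite = int((~np.isfinite(verts).all(axis=1)).sum())
    finite_verts = np.where(np.isfinite(verts), verts, 0.0)
    tri = finite_verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    degenerate = int((areas <= area_eps).sum())
    referenced = np.zeros(len(verts), dtype=bool)
    referenced[faces.ravel()] = True
    unreferenced = int((~referenced).sum())
    return ValidationReport(
        n_vertices=len(verts),
        n_faces=len(faces),
        degenerate_faces=degenerate,
        unreferenced_vertices=unreferenced,
        nonfinite_coordinates=nonfinite,
    )
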