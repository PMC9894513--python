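"""Synthetic palates and cohorts for end-to-end testing without patient scans.

The mesh generator produces a smooth palatal-vault-like dome over a U-shaped
arch, with an optional unilateral inward bend of the alveolar band — the
asymmetry pattern seen in functional posterior crossbite, where the alveolar
process of the crossbite side bends to maintain occlusal contact.  Landmarks
(raphe points, canine/molar DGJ midpoints, apical DGJ points) are placed
analytically, so every arch measurement has an exact ground truth.

The cohort generator draws per-subject longitudinal measurements from
correlated normals parameterised by group/timepoint/side summary statistics;
its defaults encode a reference cohort of 25 treated and 14 untreated
children with functional posterior crossbite in early mixed dentition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .mesh_io import LandmarkSet
from .palate_geometry import Plane
from .symmetry_analysis import RigidTransform

__all__ = [
    "PalateParams",
    "PalateModel",
    "CohortParams",
    "REFERENCE_SUMMARY",
    "REFERENCE_DIFFS",
    "generate_palate",
    "generate_cohort",
    "perturb_rigid",
]


# ---------------------------------------------------------------------------
# Palate meshes
# ---------------------------------------------------------------------------

@dataclass
class PalateParams:
    """Geometry of the synthetic palate (all lengths mm).

    The surface is parameterised by u in [0, 1] (anterior -> posterior) and a
    cross-arch coordinate t: x = R(u) * t, z = H(u) * cos(pi t / 2), with
    arch half-width R(u) widening posteriorly and vault height H(u) peaking
    mid-palate.  |t| <= 1 is the vault (z >= 0); |t| > 1 continues into a
    sub-gingival skirt (z < 0) so the gingival plane z = 0 actually cuts.

    ``asymmetry_amplitude`` shifts the alveolar band (the lowest
    ``alveolar_band_height`` mm of the vault plus the skirt) laterally
    toward ``asymmetry_side``'s midline: the crossbite-side wall is
    displaced inward by the amplitude and the contralateral wall outward,
    with a quadratic fade to zero at the top of the band.  The vault dome
    and the raphe landmarks are untouched; original-vs-mirrored deviations
    at the band approach twice the amplitude (reflection doubles a lateral
    offset), scaled by the wall's normal direction.
    """

    arch_width: float = 30.0
    arch_depth: float = 35.0
    vault_height: float = 12.0
    alveolar_band_height: float = 5.0
    asymmetry_amplitude: float = 0.0
    asymmetry_side: str = "right"
    mesh_resolution: int = 80
    noise_sd: float = 0.0
    seed: int = 0
    skirt: float = 0.18          # extension of |t| past 1, in t units
    canine_u: float = 0.18       # parametric arch position of the canines
    molar_u: float = 0.80        # parametric arch position of the molars
    raphe_u: float = 0.25        # anterior raphe point (near the second ruga)

    def __post_init__(self) -> None:
        if self.asymmetry_amplitude < 0:
            raise ValueError("asymmetry_amplitude must be >= 0")
        if self.mesh_resolution < 10:
            raise ValueError("mesh_resolution must be >= 10")
        if min(self.arch_width, self.arch_depth, self.vault_height,
               self.alveolar_band_height) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.asymmetry_side not in ("left", "right"):
            raise ValueError("asymmetry_side must be 'left' or 'right'")


@dataclass
class PalateModel:
    """A generated palate: mesh + landmarks + exact ground truth."""

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    truth: dict


def _half_width(p: PalateParams, u: np.ndarray) -> np.ndarray:
    # arch widens posteriorly: ~72 % of full half-width at the incisors
    return 0.5 * p.arch_width * (0.72 + 0.28 * u)


def _height(p: PalateParams, u: np.ndarray) -> np.ndarray:
    # vault highest mid-palate, never flat
    return p.vault_height * (0.5 + 0.5 * np.sin(np.pi * u))


def _bend_weight(p: PalateParams, z: np.ndarray) -> np.ndarray:
    """Inward-bend magnitude profile: 1 at/below the gingival margin,
    fading quadratically to 0 at the top of the alveolar band."""
    w = np.clip(1.0 - z / p.alveolar_band_height, 0.0, 1.0)
    return w * w


def _surface_point(p: PalateParams, u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact parametric surface including the asymmetric bend."""
    u = np.asarray(u, float)
    t = np.asarray(t, float)
    x = _half_width(p, u) * t
    y = p.arch_depth * u
    z = _height(p, u) * np.cos(0.5 * np.pi * t)
    if p.asymmetry_amplitude > 0:
        # lateral shift of the alveolar band toward the crossbite side: the
        # crossbite-side wall moves inward by the amplitude, the contralateral
        # wall outward, emulating adaptive dentoalveolar bending under a
        # functional mandibular shift.  Mirroring doubles the offset.
        sign = 1.0 if p.asymmetry_side == "right" else -1.0
        x = x - sign * p.asymmetry_amplitude * _bend_weight(p, z)
    return np.stack([x, y, z], axis=-1)


def vault_area(params: PalateParams, n: int = 600) -> float:
    """Surface area (mm^2) of the vault (|t| <= 1) by dense quadrature.

    Integrates the first fundamental form of the exact parameterisation on
    an n x n grid — independent of any triangulation, so it serves as the
    reference value for segmentation-area checks.
    """
    u = np.linspace(0.0, 1.0, n)
    t = np.linspace(-1.0, 1.0, n)
    uu, tt = np.meshgrid(u, t, indexing="ij")
    h = 1e-5
    pu = (_surface_point(params, uu + h, tt) - _surface_point(params, uu - h, tt)) / (2 * h)
    pt = (_surface_point(params, uu, tt + h) - _surface_point(params, uu, tt - h)) / (2 * h)
    jac = np.linalg.norm(np.cross(pu, pt), axis=-1)
    return float(np.trapezoid(np.trapezoid(jac, t, axis=1), u))


def generate_palate(params: PalateParams | None = None) -> PalateModel:
    """Generate a palate mesh, analytically placed landmarks, and ground truth.

    The ground-truth record stores the exact arch widths implied by the
    landmark positions, the gingival plane (z = 0), the midline plane
    (x = 0), the bend amplitude/side, and the quadrature vault area.
    """
    p = params or PalateParams()
    n = p.mesh_resolution
    t_max = 1.0 + p.skirt
    u = np.linspace(0.0, 1.0, n)
    t = np.linspace(-t_max, t_max, n)
    uu, tt = np.meshgrid(u, t, indexing="ij")
    verts = _surface_point(p, uu, tt).reshape(-1, 3)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        verts = verts + rng.normal(0.0, p.noise_sd, verts.shape)
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    # mirror-symmetric triangulation: quads on the right half use the
    # reflected diagonal, so the triangulated surface (not just the vertex
    # set) is exactly symmetric when the geometry is
    t_mid = np.tile(0.5 * (t[:-1] + t[1:]), n - 1)
    left = t_mid <= 0.0
    faces = np.concatenate([
        np.stack([a[left], b[left], d[left]], 1),
        np.stack([a[left], d[left], c[left]], 1),
        np.stack([a[~left], b[~left], c[~left]], 1),
        np.stack([b[~left], d[~left], c[~left]], 1),
    ])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # orient outward (+z-ish at the dome apex)
    apex = _surface_point(p, np.array(0.5), np.array(0.0))
    fid = int(np.argmin(np.linalg.norm(mesh.triangles.mean(axis=1) - apex, axis=1)))
    if mesh.face_normals[fid][2] < 0:
        mesh.faces = mesh.faces[:, ::-1]

    # landmarks: raphe on the exact midline, DGJ midpoints at the gingival
    # margin (t = +/-1, z = 0), apical DGJ points along both margins
    raphe_u2 = p.raphe_u + 10.0 / p.arch_depth  # 1 cm distal to the first point
    raphe_1 = _surface_point(p, np.array(p.raphe_u), np.array(0.0))
    raphe_2 = _surface_point(p, np.array(raphe_u2), np.array(0.0))
    canine_L = _surface_point(p, np.array(p.canine_u), np.array(-1.0))
    canine_R = _surface_point(p, np.array(p.canine_u), np.array(1.0))
    molar_L = _surface_point(p, np.array(p.molar_u), np.array(-1.0))
    molar_R = _surface_point(p, np.array(p.molar_u), np.array(1.0))
    apical_u = np.linspace(0.08, 0.92, 8)
    apical = np.concatenate([
        _surface_point(p, apical_u, np.full_like(apical_u, -1.0)),
        _surface_point(p, apical_u, np.full_like(apical_u, 1.0)),
    ])
    crossbite = p.asymmetry_side if p.asymmetry_amplitude > 0 else "none"
    landmarks = LandmarkSet(
        {
            "raphe_1": raphe_1, "raphe_2": raphe_2,
            "canine_L": canine_L, "canine_R": canine_R,
            "molar_L": molar_L, "molar_R": molar_R,
        },
        apical_dgj=apical,
        crossbite_side=crossbite,
    )
    truth = {
        "ICW": float(np.linalg.norm(canine_L - canine_R)),
        "IMW": float(np.linalg.norm(molar_L - molar_R)),
        "eICW_left": float(abs(canine_L[0])),
        "eICW_right": float(abs(canine_R[0])),
        "eIMW_left": float(abs(molar_L[0])),
        "eIMW_right": float(abs(molar_R[0])),
        "gingival_plane": Plane([0.0, 0.0, 0.0], [0.0, 0.0, 1.0]),
        "midline_plane": Plane([0.0, 0.0, 0.0], [1.0, 0.0, 0.0]),
        "asymmetry_amplitude": p.asymmetry_amplitude,
        "asymmetry_side": p.asymmetry_side,
        "vault_area": vault_area(p, n=400),
    }
    return PalateModel(mesh=mesh, landmarks=landmarks, truth=truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Summary statistics (mean, SD) of the reference cohort, keyed by
#: (group, variable) -> timepoint -> side (bilateral variables use a flat
#: (mean, sd); sided variables map side -> (mean, sd) plus the SD of the
#: per-subject side gap).  These are the generator defaults and the inputs
#: of the worked-example arithmetic.
REFERENCE_SUMMARY: dict = {
    ("TG", "ICW"): {"T0": (24.2, 1.35), "T1": (26.4, 1.67)},
    ("CG", "ICW"): {"T0": (25.03, 1.40), "T1": (24.94, 1.51)},
    ("TG", "IMW"): {"T0": (28.63, 1.63), "T1": (31.2, 1.81)},
    ("CG", "IMW"): {"T0": (29.62, 2.03), "T1": (29.46, 2.16)},
    ("TG", "eICW"): {
        "T0": {"CBS": (11.67, 1.32), "nCBS": (12.53, 1.28), "gap_sd": 0.15},
        "T1": {"CBS": (12.98, 1.40), "nCBS": (13.42, 1.37), "gap_sd": 0.16},
    },
    ("CG", "eICW"): {
        "T0": {"CBS": (13.01, 1.21), "nCBS": (12.02, 1.24), "gap_sd": 0.10},
        "T1": {"CBS": (12.96, 1.35), "nCBS": (11.97, 1.39), "gap_sd": 0.10},
    },
    ("TG", "eIMW"): {
        "T0": {"CBS": (13.53, 1.19), "nCBS": (15.07, 1.22), "gap_sd": 0.21},
        "T1": {"CBS": (15.15, 1.27), "nCBS": (16.03, 1.28), "gap_sd": 0.19},
    },
    ("CG", "eIMW"): {
        "T0": {"CBS": (14.06, 1.41), "nCBS": (15.56, 1.46), "gap_sd": 0.15},
        "T1": {"CBS": (13.95, 1.51), "nCBS": (15.49, 1.50), "gap_sd": 0.14},
    },
    ("TG", "matching_pct"): {"T0": (81.12, 3.03), "T1": (92.32, 4.05)},
    ("CG", "matching_pct"): {"T0": (79.36, 2.95), "T1": (77.47, 3.14)},
}

#: Reported difference columns of the reference cohort: (mean, sd) of the
#: T1-T0 change for bilateral variables and matching %, and of the
#: per-subject side gap for emi-lateral variables by timepoint.  Two cells
#: are internally inconsistent with REFERENCE_SUMMARY (TG IMW change, CG
#: eICW T1 gap); consistency checking lives in cohort_stats.
REFERENCE_DIFFS: dict = {
    ("TG", "ICW", "T1-T0"): (2.2, 0.4),
    ("CG", "ICW", "T1-T0"): (0.09, 0.17),
    ("TG", "IMW", "T1-T0"): (2.9, 0.7),
    ("CG", "IMW", "T1-T0"): (0.16, 0.24),
    ("TG", "eICW", "T0"): (0.86, 0.15),
    ("TG", "eICW", "T1"): (0.44, 0.16),
    ("CG", "eICW", "T0"): (0.99, 0.10),
    ("CG", "eICW", "T1"): (0.98, 0.10),
    ("TG", "eIMW", "T0"): (1.54, 0.21),
    ("TG", "eIMW", "T1"): (0.88, 0.19),
    ("CG", "eIMW", "T0"): (1.50, 0.15),
    ("CG", "eIMW", "T1"): (1.54, 0.14),
    ("TG", "matching_pct", "T1-T0"): (11.2, 1.86),
    ("CG", "matching_pct", "T1-T0"): (-1.89, 0.27),
}


@dataclass
class CohortParams:
    """Longitudinal cohort simulation settings.

    ``summary`` follows the :data:`REFERENCE_SUMMARY` layout.  ``sd_scale``
    scales every SD; 0 yields the degenerate cohort where each subject
    carries the configured means exactly — the worked-example input.
    ``correlation`` is the within-subject T0-T1 correlation.
    """

    n_tg: int = 25
    n_cg: int = 14
    correlation: float = 0.9
    sd_scale: float = 1.0
    seed: int = 0
    summary: dict = field(default_factory=lambda: REFERENCE_SUMMARY)

    def __post_init__(self) -> None:
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must be in [0, 1)")
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be >= 0")


def _correlated_pair(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """(n, 2) standard normals with correlation rho between the columns."""
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    return z


def generate_cohort(params: CohortParams | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate a longitudinal TG/CG cohort table.

    Bilateral variables: per subject, (T0, T1) values are correlated normals
    with the configured per-timepoint means/SDs.  Sided variables: the nCBS
    value is drawn the same way and the CBS value is nCBS minus an
    independently drawn side gap with the configured gap mean
    (nCBS - CBS from the summary means) and gap SD, so side-difference
    statistics are controlled directly.  Deterministic under ``seed``.

    Returns the long-format cohort table (subject_id, group, timepoint,
    variable, side, value) and the ground-truth parameter record.
    """
    p = params or CohortParams()
    rng = np.random.default_rng(p.seed)
    rows: list[dict] = []
    for group, n in (("TG", p.n_tg), ("CG", p.n_cg)):
        subjects = [f"{group}{i + 1:03d}" for i in range(n)]
        for (g, variable), spec in p.summary.items():
            if g != group:
                continue
            sided = isinstance(spec["T0"], dict)
            if not sided:
                z = _correlated_pair(rng, n, p.correlation)
                for j, tp in enumerate(("T0", "T1")):
                    mean, sd = spec[tp]
                    vals = mean + p.sd_scale * sd * z[:, j]
                    rows += [
                        {"subject_id": s, "group": group, "timepoint": tp,
                         "variable": variable, "side": "bilateral", "value": v}
                        for s, v in zip(subjects, vals)
                    ]
            else:
                z_ncbs = _correlated_pair(rng, n, p.correlation)
                z_gap = _correlated_pair(rng, n, p.correlation)
                for j, tp in enumerate(("T0", "T1")):
                    m_cbs, _ = spec[tp]["CBS"]
                    m_ncbs, sd_ncbs = spec[tp]["nCBS"]
                    gap_sd = spec[tp]["gap_sd"]
                    ncbs = m_ncbs + p.sd_scale * sd_ncbs * z_ncbs[:, j]
                    gap = (m_ncbs - m_cbs) + p.sd_scale * gap_sd * z_gap[:, j]
                    cbs = ncbs - gap
                    for s, v_c, v_n in zip(subjects, cbs, ncbs):
                        rows.append({"subject_id": s, "group": group, "timepoint": tp,
                                     "variable": variable, "side": "CBS", "value": v_c})
                        rows.append({"subject_id": s, "group": group, "timepoint": tp,
                                     "variable": variable, "side": "nCBS", "value": v_n})
    table = pd.DataFrame(rows)
    truth = {
        "summary": p.summary,
        "n_tg": p.n_tg,
        "n_cg": p.n_cg,
        "correlation": p.correlation,
        "sd_scale": p.sd_scale,
        "seed": p.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Registration fixtures
# ---------------------------------------------------------------------------

def perturb_rigid(
    mesh: trimesh.Trimesh,
    rotation_deg: float,
    translation_mm: float,
    seed: int = 0,
) -> tuple[trimesh.Trimesh, RigidTransform]:
    """Apply a random rigid motion of exact stated magnitude; return its truth.

    The rotation (by ``rotation_deg`` about a random axis) pivots about the
    vertex centroid so the mesh does not fly off; the translation has length
    exactly ``translation_mm`` in a random direction.  Same seed, same
    transform.
    """
    rng = np.random.default_rng(seed)
    if rotation_deg == 0.0:
        R = np.eye(3)
    else:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rotation_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    if translation_mm == 0.0:
        d = np.zeros(3)
    else:
        d = rng.standard_normal(3)
        d = translation_mm * d / np.linalg.norm(d)
    c = np.asarray(mesh.vertices, float).mean(axis=0)
    transform = RigidTransform(R, c - R @ c + d)
    out = mesh.copy()
    out.vertices = transform.apply(np.asarray(mesh.vertices, float))
    return out, transform
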