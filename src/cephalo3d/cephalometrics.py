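"""Clinical 46-landmark schema and the 16 cephalometric characteristic measures.

The schema covers the classical 2D cephalometric points plus fusion and
facial-surgery landmarks: 16 bilaterally symmetric landmark pairs (suffixed
``L``/``R``) and 14 midline landmarks, partitioned into dental (12),
facial-surgery (9) and skeletal (25) groups.

The measures follow the extended McNamara analysis plus four traditional
items, in three families:

* five 3D point-to-point distances (mm): anterior facial height (ANS-Me) and
  the left/right effective mandibular (Co-Gn) and midfacial (Co-A) lengths;
* six vector components (mm), projected on the anterior axis of the Frankfort
  horizontal frame: Nasion perpendicular to A, Pogonion to Nasion
  perpendicular, left/right upper-incisor point-A verticals, and left/right
  lower-incisor offsets from the A-Pogonion line;
* five angles (degrees): SNA, SNB, SNA-SNB (signed), the mandibular plane
  angle (plane through Me and both Gonions vs. Frankfort horizontal) and the
  angle between Frankfort horizontal and the true horizontal plane.

The Frankfort horizontal plane is the best orthogonal (total) least-squares
fit through the visible Porions and Orbitales; at least three of the four
points are required. "True horizontal" defaults to the scanner axial plane,
normal (0, 0, 1) in world coordinates, and is the only measure input that is
not invariant to rigid motion of the landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .imaging_io import LandmarkSet

__all__ = [
    "LandmarkDef",
    "AnatomicalFrame",
    "MeasureResult",
    "CephalometricReport",
    "DegenerateGeometryError",
    "FrameError",
    "schema",
    "schema_id_list",
    "fit_plane_tls",
    "frankfort_frame",
    "three_point_angle",
    "plane_angle",
    "measure_all",
    "MEASURE_IDS",
]

SCHEMA_VERSION = "clinical-46/1"


class DegenerateGeometryError(ValueError):
    """Raised when points are too few or collinear to define the geometry."""


class FrameError(DegenerateGeometryError):
    """Raised when the Frankfort anatomical frame cannot be constructed."""


@dataclass(frozen=True)
class LandmarkDef:
    id: str
    name: str
    laterality: str  # "left" | "right" | "midline"
    group: str  # "dental" | "facial-surgery" | "skeletal"
    mirror_id: str | None


def _bilateral(base: str, name: str, group_l: str, group_r: str | None = None):
    gr = group_r or group_l
    return [
        LandmarkDef(base + "L", name + " Left", "left", group_l, base + "R"),
        LandmarkDef(base + "R", name + " Right", "right", gr, base + "L"),
    ]


def _mid(lid: str, name: str, group: str) -> LandmarkDef:
    return LandmarkDef(lid, name, "midline", group, None)


_SCHEMA: tuple[LandmarkDef, ...] = tuple(
    [
        # --- midline ---
        _mid("A", "Subspinale", "skeletal"),
        _mid("ANS", "Anterior Nasal Spine", "skeletal"),
        _mid("B", "Supramentale", "skeletal"),
        _mid("Ba", "Basion", "skeletal"),
        _mid("CLI", "Center of lower incisors", "dental"),
        _mid("CUI", "Center of upper incisors", "dental"),
        _mid("FI", "Foramen Incisivum", "facial-surgery"),
        _mid("Gn", "Gnathion", "skeletal"),
        _mid("Me", "Menton", "skeletal"),
        _mid("N", "Nasion", "skeletal"),
        _mid("PNS", "Posterior Nasal Spine", "skeletal"),
        _mid("Pog", "Pogonion", "skeletal"),
        _mid("S", "Sella Turcica", "skeletal"),
        _mid("SM", "Spina Mentalis", "skeletal"),
    ]
    # --- bilateral pairs ---
    + _bilateral("Co", "Condylion", "skeletal")
    + _bilateral("FInf", "Foramen Infraorbitale", "facial-surgery")
    + _bilateral("FMan", "Foramen Mandibulae", "facial-surgery")
    + _bilateral("FMen", "Foramen Mentale", "facial-surgery")
    + _bilateral("FPal", "Foramen Palatinum major", "facial-surgery")
    + _bilateral("Go", "Gonion", "skeletal")
    + _bilateral("J", "Jugale", "skeletal")
    + _bilateral("LIA", "Lower Incisor Apex", "dental")
    + _bilateral("LIE", "Lower Incisor Edge", "dental")
    + _bilateral("LMol", "Lower Molar", "dental")
    + _bilateral("Or", "Orbitale", "skeletal")
    + _bilateral("PcmU", "Crestal point between molars, upper", "dental")
    + _bilateral("Po", "Porion", "skeletal")
    + _bilateral("UIA", "Upper Incisor Apex", "dental")
    + _bilateral("UIE", "Upper Incisor Edge", "skeletal")
    + _bilateral("UMol", "Upper Molar", "skeletal")
)


def schema() -> tuple[LandmarkDef, ...]:
    """The fixed 46-entry clinical landmark table."""
    return _SCHEMA


def schema_id_list() -> list[str]:
    return [d.id for d in _SCHEMA]


# ---------------------------------------------------------------------------
# Geometry primitives


def fit_plane_tls(points: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 points.

    Returns ``(centroid, unit_normal)`` where the normal minimises the sum of
    squared orthogonal distances. Implemented as the smallest-eigenvalue
    eigenvector of the 3x3 scatter matrix of the centred points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateGeometryError(
            f"plane fit needs >= 3 points in 3D, got shape {pts.shape}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scatter = centered.T @ centered
    evals, evecs = np.linalg.eigh(scatter)
    # Collinear (or coincident) points: two near-zero eigenvalues.
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = evecs[:, 0]
    return centroid, normal / np.linalg.norm(normal)


def three_point_angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Angle at Q (degrees, in [0, 180]) between rays QP and QR."""
    u = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    v = np.asarray(r, dtype=float) - np.asarray(q, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("zero-length ray in three-point angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Unsigned angle between two planes (degrees, in [0, 90]) from their normals."""
    out = []
    for n in (n1, n2):
        n = np.asarray(n, dtype=float)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"plane normal must be unit length, |n| = {norm}")
        out.append(n / norm)
    c = np.clip(abs(np.dot(out[0], out[1])), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal anatomical reference frame anchored to Frankfort horizontal.

    ``superior`` is the FH-plane normal signed toward Nasion; ``anterior``
    lies in the FH plane pointing from the ear (Porions) toward the orbits;
    ``lateral = superior x anterior`` completes the triad.
    """

    fh_point: np.ndarray
    superior: np.ndarray
    anterior: np.ndarray
    lateral: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sup = np.asarray(self.superior, dtype=float)
        ant = np.asarray(self.anterior, dtype=float)
        if abs(np.linalg.norm(sup) - 1) > 1e-9 or abs(np.linalg.norm(ant) - 1) > 1e-9:
            raise ValueError("frame axes must be unit vectors")
        if abs(np.dot(sup, ant)) > 1e-9:
            raise ValueError("anterior axis must lie in the FH plane")
        object.__setattr__(self, "superior", sup)
        object.__setattr__(self, "anterior", ant)
        object.__setattr__(self, "lateral", np.cross(sup, ant))
        object.__setattr__(self, "fh_point", np.asarray(self.fh_point, dtype=float))


def frankfort_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical frame from the TLS Frankfort plane over visible Po/Or points.

    Requires at least three of {PoL, PoR, OrL, OrR} plus Nasion (which signs
    the superior axis). The anterior axis is the in-plane component of the
    vector from the Porion midpoint to the Orbitale midpoint.
    """
    po = [landmarks.get(i) for i in ("PoL", "PoR") if landmarks.is_present(i)]
    orb = [landmarks.get(i) for i in ("OrL", "OrR") if landmarks.is_present(i)]
    pts = po + orb
    if len(pts) < 3:
        raise FrameError(
            f"Frankfort fit needs >= 3 of PoL/PoR/OrL/OrR, found {len(pts)}"
        )
    nasion = landmarks.get("N")
    if nasion is None:
        raise FrameError("Nasion required to orient the Frankfort frame")
    if not po or not orb:
        raise FrameError("need at least one Porion and one Orbitale for anterior axis")
    centroid, normal = fit_plane_tls(pts)
    if np.dot(nasion - centroid, normal) < 0:
        normal = -normal
    ant_raw = np.mean(orb, axis=0) - np.mean(po, axis=0)
    ant_in_plane = ant_raw - np.dot(ant_raw, normal) * normal
    norm = np.linalg.norm(ant_in_plane)
    if norm < 1e-9:
        raise FrameError("degenerate anterior axis: orbit midpoint coincides with porion midpoint")
    return AnatomicalFrame(fh_point=centroid, superior=normal, anterior=ant_in_plane / norm)


# ---------------------------------------------------------------------------
# Measures


@dataclass
class MeasureResult:
    id: str
    value: float | None
    units: str  # "mm" | "degrees"
    type: str  # "point-to-point" | "vector-component" | "plane-angle"
    available: bool
    inputs_used: tuple[str, ...]


@dataclass
class CephalometricReport:
    measures: dict[str, MeasureResult]
    schema_version: str = SCHEMA_VERSION

    def value(self, mid: str) -> float | None:
        return self.measures[mid].value

    def to_dict(self) -> dict:
        return {
            mid: {
                "value": m.value,
                "units": m.units,
                "type": m.type,
                "available": m.available,
                "inputs": list(m.inputs_used),
            }
            for mid, m in self.measures.items()
        }


MEASURE_IDS: tuple[str, ...] = (
    "anterior_facial_height",
    "left_effective_mandibular_length",
    "right_effective_mandibular_length",
    "left_effective_midfacial_length",
    "right_effective_midfacial_length",
    "nasion_perpendicular_to_A",
    "pogonion_to_nasion_perpendicular",
    "left_upper_incisor_A_vertical",
    "right_upper_incisor_A_vertical",
    "left_lower_incisor_to_A_pog_line",
    "right_lower_incisor_to_A_pog_line",
    "SNA",
    "SNB",
    "SNA_minus_SNB",
    "mandibular_plane_angle",
    "frankfort_horizontal_angle",
)

_MEASURE_UNITS_TYPES = {
    "anterior_facial_height": ("mm", "point-to-point"),
    "left_effective_mandibular_length": ("mm", "point-to-point"),
    "right_effective_mandibular_length": ("mm", "point-to-point"),
    "left_effective_midfacial_length": ("mm", "point-to-point"),
    "right_effective_midfacial_length": ("mm", "point-to-point"),
    "nasion_perpendicular_to_A": ("mm", "vector-component"),
    "pogonion_to_nasion_perpendicular": ("mm", "vector-component"),
    "left_upper_incisor_A_vertical": ("mm", "vector-component"),
    "right_upper_incisor_A_vertical": ("mm", "vector-component"),
    "left_lower_incisor_to_A_pog_line": ("mm", "vector-component"),
    "right_lower_incisor_to_A_pog_line": ("mm", "vector-component"),
    "SNA": ("degrees", "plane-angle"),
    "SNB": ("degrees", "plane-angle"),
    "SNA_minus_SNB": ("degrees", "plane-angle"),
    "mandibular_plane_angle": ("degrees", "plane-angle"),
    "frankfort_horizontal_angle": ("degrees", "plane-angle"),
}


def _line_offset_signed(
    point: np.ndarray, a: np.ndarray, b: np.ndarray, sign_axis: np.ndarray
) -> float:
    """Signed perpendicular offset of ``point`` from the line through a and b.

    Magnitude is the 3D perpendicular distance; the sign is that of the
    offset vector's projection on ``sign_axis``.
    """
    d = b - a
    dn = np.linalg.norm(d)
    if dn < 1e-12:
        raise DegenerateGeometryError("A and Pog coincide; line undefined")
    u = d / dn
    off = (point - a) - np.dot(point - a, u) * u
    mag = float(np.linalg.norm(off))
    return float(np.sign(np.dot(off, sign_axis)) * mag) if mag > 0 else 0.0


def measure_all(
    landmarks: LandmarkSet, true_horizontal: np.ndarray = (0.0, 0.0, 1.0)
) -> CephalometricReport:
    """Compute the 16 characteristic measures, flagging unavailable ones.

    A measure is unavailable (value ``None``) when any required landmark is
    absent or the Frankfort frame cannot be built; unavailability is data,
    not an error.
    """
    th = np.asarray(true_horizontal, dtype=float)
    th = th / np.linalg.norm(th)

    frame: AnatomicalFrame | None
    try:
        frame = frankfort_frame(landmarks)
    except DegenerateGeometryError:
        frame = None

    results: dict[str, MeasureResult] = {}

    def add(mid: str, value: float | None, inputs: tuple[str, ...]) -> None:
        units, mtype = _MEASURE_UNITS_TYPES[mid]
        results[mid] = MeasureResult(
            id=mid,
            value=None if value is None else float(value),
            units=units,
            type=mtype,
            available=value is not None,
            inputs_used=inputs,
        )

    def pts(*ids: str) -> list[np.ndarray] | None:
        got = [landmarks.get(i) for i in ids]
        return None if any(g is None for g in got) else got  # type: ignore[return-value]

    # --- point-to-point distances ---
    for mid, (i, j) in {
        "anterior_facial_height": ("ANS", "Me"),
        "left_effective_mandibular_length": ("CoL", "Gn"),
        "right_effective_mandibular_length": ("CoR", "Gn"),
        "left_effective_midfacial_length": ("CoL", "A"),
        "right_effective_midfacial_length": ("CoR", "A"),
    }.items():
        p = pts(i, j)
        add(mid, None if p is None else np.linalg.norm(p[0] - p[1]), (i, j))

    # --- vector components on the Frankfort anterior axis ---
    frame_ids = ("PoL", "PoR", "OrL", "OrR", "N")

    def vec_component(mid: str, point_id: str, ref_id: str) -> None:
        p = pts(point_id, ref_id)
        if frame is None or p is None:
            add(mid, None, (point_id, ref_id) + frame_ids)
        else:
            add(mid, np.dot(p[0] - p[1], frame.anterior), (point_id, ref_id) + frame_ids)

    vec_component("nasion_perpendicular_to_A", "A", "N")
    vec_component("pogonion_to_nasion_perpendicular", "Pog", "N")
    vec_component("left_upper_incisor_A_vertical", "UIEL", "A")
    vec_component("right_upper_incisor_A_vertical", "UIER", "A")

    for mid, lie in {
        "left_lower_incisor_to_A_pog_line": "LIEL",
        "right_lower_incisor_to_A_pog_line": "LIER",
    }.items():
        p = pts(lie, "A", "Pog")
        if frame is None or p is None:
            add(mid, None, (lie, "A", "Pog") + frame_ids)
        else:
            add(
                mid,
                _line_offset_signed(p[0], p[1], p[2], frame.anterior),
                (lie, "A", "Pog") + frame_ids,
            )

    # --- angles ---
    p = pts("S", "N", "A")
    sna = None if p is None else three_point_angle(*p)
    add("SNA", sna, ("S", "N", "A"))
    p = pts("S", "N", "B")
    snb = None if p is None else three_point_angle(*p)
    add("SNB", snb, ("S", "N", "B"))
    add(
        "SNA_minus_SNB",
        None if (sna is None or snb is None) else sna - snb,
        ("S", "N", "A", "B"),
    )

    p = pts("Me", "GoL", "GoR")
    if frame is None or p is None:
        add("mandibular_plane_angle", None, ("Me", "GoL", "GoR") + frame_ids)
    else:
        try:
            _, mand_normal = fit_plane_tls(p)
            add(
                "mandibular_plane_angle",
                plane_angle(mand_normal, frame.superior),
                ("Me", "GoL", "GoR") + frame_ids,
            )
        except DegenerateGeometryError:
            add("mandibular_plane_angle", None, ("Me", "GoL", "GoR") + frame_ids)

    add(
        "frankfort_horizontal_angle",
        None if frame is None else plane_angle(frame.superior, th),
        frame_ids,
    )

    return CephalometricReport(measures=results)
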