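"""Seeded synthetic skull phantoms: volumes with ground-truth landmarks.

Each phantom case is a dark background with bright ellipsoidal shells (a
cranial vault and a mandibular body, standing in for bone) plus one bright
Gaussian blob centred on each landmark, then additive Gaussian intensity
noise. Landmarks vary across cases by per-landmark anatomical jitter and a
shared per-case rigid perturbation applied identically to image content and
coordinates. An optional cohort shift offsets the template for cohort "B",
emulating a between-population difference.

Blob amplitudes differ per landmark (evenly spaced in [1.0, 1.5], above the
shell intensity of 0.6) so a convolutional network can tell the channels
apart; photorealism is explicitly not a goal — the phantom exists so the
full pipeline is trainable and testable on one CPU with no external data.

Two built-in templates are provided: ``toy8`` (8 midline/mandibular
landmarks on a 48^3 grid at 1.6 mm) and ``full46`` (the complete clinical
schema on a 96^3 grid at 1.6 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cephalometrics import schema_id_list
from .imaging_io import LandmarkSet, Volume

__all__ = [
    "PhantomSpec",
    "PhantomError",
    "generate_case",
    "generate_landmarks",
    "generate_cohorts",
    "toy8_spec",
    "full46_spec",
    "TOY8_IDS",
]


class PhantomError(ValueError):
    pass


TOY8_IDS: tuple[str, ...] = ("N", "S", "A", "B", "Pog", "Me", "GoL", "GoR")

# toy8 canonical positions (world mm) inside a 76.8 mm cube, origin at 0:
# x lateral, y anterior, z superior, midsagittal plane at x = 38.4.
_TOY8_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "N": (38.4, 60.0, 46.0),
    "S": (38.4, 34.0, 48.0),
    "A": (38.4, 62.0, 34.0),
    "B": (38.4, 60.0, 24.0),
    "Pog": (38.4, 58.0, 16.0),
    "Me": (38.4, 52.0, 12.0),
    "GoL": (16.0, 30.0, 18.0),
    "GoR": (60.8, 30.0, 18.0),
}

# full46 canonical positions in a centred frame (x lateral with left = +x,
# y anterior, z superior), later shifted to the 96^3 grid centre. Rough
# skull-scale anatomy; bilateral ids mirror in x.
_FULL46_CENTERED: dict[str, tuple[float, float, float]] = {
    "S": (0, 0, 40), "N": (0, 45, 45), "A": (0, 52, 5), "B": (0, 50, -15),
    "Pog": (0, 49, -25), "Gn": (0, 47, -30), "Me": (0, 43, -33),
    "ANS": (0, 55, 10), "PNS": (0, 5, 8), "Ba": (0, -15, 5), "SM": (0, 40, -28),
    "FI": (0, 48, 2), "CUI": (0, 52, -8), "CLI": (0, 50, -12),
}
_FULL46_BILATERAL: dict[str, tuple[float, float, float]] = {
    "Co": (45, -20, 25), "Po": (50, -25, 20), "Or": (35, 40, 20),
    "J": (40, 25, 5), "Go": (42, -15, -25), "FMan": (38, -10, -10),
    "FMen": (22, 35, -25), "FInf": (25, 45, 25), "FPal": (12, 10, 5),
    "UMol": (25, 15, -5), "LMol": (25, 15, -12), "PcmU": (25, 20, -6),
    "UIA": (4, 50, 0), "UIE": (4, 52, -8), "LIA": (4, 48, -18), "LIE": (4, 50, -12),
}


def full46_template() -> dict[str, np.ndarray]:
    """Canonical world-mm positions for all 46 clinical landmarks."""
    center = np.full(3, 76.0)  # centre of the 96^3, 1.6 mm grid
    out: dict[str, np.ndarray] = {}
    for lid, pos in _FULL46_CENTERED.items():
        out[lid] = np.asarray(pos, dtype=float) + center
    for base, (x, y, z) in _FULL46_BILATERAL.items():
        out[base + "L"] = np.array([x, y, z], dtype=float) + center
        out[base + "R"] = np.array([-x, y, z], dtype=float) + center
    return out


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator; defaults are the toy8 conditions."""

    grid_size: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 1.6
    landmark_ids: tuple[str, ...] = TOY8_IDS
    template_positions: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: np.asarray(v, dtype=float) for k, v in _TOY8_TEMPLATE.items()}
    )
    jitter_sd: float = 2.0  # mm of per-landmark anatomical variation
    blob_radius: float = 4.0  # mm of the bright bone feature at each landmark
    shell_params: tuple[dict, ...] = (
        {"center": (38.4, 40.0, 44.0), "radii": (22.0, 24.0, 20.0),
         "thickness": 0.15, "intensity": 0.6},
        {"center": (38.4, 44.0, 18.0), "radii": (20.0, 16.0, 10.0),
         "thickness": 0.20, "intensity": 0.6},
    )
    noise_sd: float = 0.05
    cohort_shift: np.ndarray | Mapping[str, np.ndarray] = field(
        default_factory=lambda: np.zeros(3)
    )
    rigid_rotation_deg: float = 3.0  # per-case uniform rotation bound
    rigid_translation_mm: float = 2.0  # per-case uniform translation bound
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_size = tuple(int(g) for g in np.broadcast_to(self.grid_size, (3,)))
        self.landmark_ids = tuple(self.landmark_ids)
        self.template_positions = {
            k: np.asarray(v, dtype=float) for k, v in self.template_positions.items()
        }
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise PhantomError("jitter_sd and noise_sd must be >= 0")
        missing = [i for i in self.landmark_ids if i not in self.template_positions]
        if missing:
            raise PhantomError(f"template positions missing for {missing}")
        hi = (np.array(self.grid_size) - 1) * self.spacing
        margin = 4.0 * self.jitter_sd
        for lid in self.landmark_ids:
            p = self.template_positions[lid]
            if np.any(p - margin < 0) or np.any(p + margin > hi):
                raise PhantomError(
                    f"template position for {lid} not inside grid with 4*jitter_sd margin"
                )

    def shift_for(self, lid: str) -> np.ndarray:
        if isinstance(self.cohort_shift, Mapping):
            return np.asarray(self.cohort_shift.get(lid, np.zeros(3)), dtype=float)
        return np.asarray(self.cohort_shift, dtype=float)

    def blob_amplitudes(self) -> np.ndarray:
        n = len(self.landmark_ids)
        return np.linspace(1.0, 1.5, n) if n > 1 else np.array([1.25])


def toy8_spec(**overrides) -> PhantomSpec:
    """The 8-landmark toy benchmark: 48^3 at 1.6 mm (76.8 mm cube)."""
    return PhantomSpec(**overrides)


def full46_spec(**overrides) -> PhantomSpec:
    """Full clinical schema on a 96^3, 1.6 mm grid."""
    template = full46_template()
    center = 76.0
    defaults = dict(
        grid_size=(96, 96, 96),
        landmark_ids=tuple(schema_id_list()),
        template_positions=template,
        shell_params=(
            {"center": (center, center + 5, center + 20),
             "radii": (55.0, 60.0, 45.0), "thickness": 0.12, "intensity": 0.6},
            {"center": (center, center + 20, center - 22),
             "radii": (46.0, 40.0, 22.0), "thickness": 0.15, "intensity": 0.6},
        ),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


# ---------------------------------------------------------------------------


def _case_rngs(spec: PhantomSpec, case_index: int, cohort: str):
    code = {"A": 0, "B": 1}.get(cohort)
    if code is None:
        raise PhantomError(f"cohort must be 'A' or 'B', got {cohort!r}")
    ss = np.random.SeedSequence(entropy=(spec.seed, case_index, code))
    lm_ss, img_ss = ss.spawn(2)
    return np.random.default_rng(lm_ss), np.random.default_rng(img_ss)


def _rigid(spec: PhantomSpec, rng: np.random.Generator):
    from .training_inference import _rotation_matrix

    ang = np.radians(rng.uniform(-spec.rigid_rotation_deg, spec.rigid_rotation_deg, size=3))
    t = rng.uniform(-spec.rigid_translation_mm, spec.rigid_translation_mm, size=3)
    return _rotation_matrix(ang), t


def _sample_landmarks(
    spec: PhantomSpec, rng: np.random.Generator, cohort: str
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Jittered, cohort-shifted, rigidly perturbed landmark positions."""
    rot, t = _rigid(spec, rng)
    center = (np.array(spec.grid_size) - 1) * spec.spacing / 2.0
    hi = (np.array(spec.grid_size) - 1) * spec.spacing
    positions: dict[str, np.ndarray] = {}
    for lid in spec.landmark_ids:
        base = spec.template_positions[lid].copy()
        if cohort == "B":
            base = base + spec.shift_for(lid)
        for attempt in range(11):
            p = base + rng.normal(0.0, spec.jitter_sd, size=3)
            p = rot @ (p - center) + center + t
            if np.all(p >= 0) and np.all(p <= hi):
                positions[lid] = p
                break
        else:
            raise PhantomError(f"landmark {lid} escaped the grid after 10 jitter retries")
    return positions, rot, t


def generate_landmarks(
    spec: PhantomSpec, case_index: int, cohort: str = "A"
) -> LandmarkSet:
    """Landmarks of a case without rendering the image (fast path).

    Identical to the landmarks of :func:`generate_case` for the same
    (spec, case_index, cohort).
    """
    lm_rng, _ = _case_rngs(spec, case_index, cohort)
    positions, _, _ = _sample_landmarks(spec, lm_rng, cohort)
    return LandmarkSet(positions, spec.landmark_ids)


def generate_case(
    spec: PhantomSpec, case_index: int, cohort: str = "A"
) -> tuple[Volume, LandmarkSet]:
    """One deterministic phantom case: rendered volume plus ground truth.

    Image = dark background + bright ellipsoidal shells + a bright Gaussian
    blob at each landmark + Gaussian intensity noise, all transformed by the
    same per-case rigid perturbation as the landmarks.
    """
    lm_rng, img_rng = _case_rngs(spec, case_index, cohort)
    positions, rot, t = _sample_landmarks(spec, lm_rng, cohort)
    shape = spec.grid_size
    center = (np.array(shape) - 1) * spec.spacing / 2.0

    ax = [np.arange(n, dtype=np.float32) * spec.spacing for n in shape]
    xs = ax[0][:, None, None]
    ys = ax[1][None, :, None]
    zs = ax[2][None, None, :]

    img = np.zeros(shape, dtype=np.float32)

    # shells, rigidly transformed with the case: evaluate the ellipsoid in
    # the back-transformed frame u = R^T (x - c') with c' = R(c - centre) + centre + t
    for shell in spec.shell_params:
        c = np.asarray(shell["center"], dtype=float)
        radii = np.asarray(shell["radii"], dtype=float)
        cprime = rot @ (c - center) + center + t
        dx = xs - cprime[0]
        dy = ys - cprime[1]
        dz = zs - cprime[2]
        u0 = rot[0, 0] * dx + rot[1, 0] * dy + rot[2, 0] * dz
        u1 = rot[0, 1] * dx + rot[1, 1] * dy + rot[2, 1] * dz
        u2 = rot[0, 2] * dx + rot[1, 2] * dy + rot[2, 2] * dz
        q = np.sqrt((u0 / radii[0]) ** 2 + (u1 / radii[1]) ** 2 + (u2 / radii[2]) ** 2)
        half = shell["thickness"] / 2.0
        band = np.abs(q - 1.0) <= half
        img = np.where(band, np.maximum(img, np.float32(shell["intensity"])), img)

    # landmark blobs: Gaussian bump with sd = blob_radius / 2
    sd = spec.blob_radius / 2.0
    for amp, lid in zip(spec.blob_amplitudes(), spec.landmark_ids):
        p = positions[lid]
        d2 = (xs - p[0]) ** 2 + (ys - p[1]) ** 2 + (zs - p[2]) ** 2
        img = np.maximum(img, np.float32(amp) * np.exp(-d2 / (2.0 * sd * sd)).astype(np.float32))

    if spec.noise_sd > 0:
        img = img + img_rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    vol = Volume(img, spacing=np.full(3, spec.spacing), origin=np.zeros(3))
    return vol, LandmarkSet(positions, spec.landmark_ids)


@dataclass
class PhantomCase:
    case_id: str
    cohort: str
    volume: Volume | None
    landmarks: LandmarkSet


def generate_cohorts(
    spec: PhantomSpec,
    n_per_cohort: int,
    seed: int | None = None,
    render: bool = True,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Two cohorts of phantom cases plus a (case_id, cohort) metadata table.

    Cohort A uses the template; cohort B adds ``spec.cohort_shift``. With a
    zero shift the cohorts are exchangeable. ``render=False`` skips image
    synthesis (landmarks only). With ``out_dir`` set, volumes (NIfTI),
    landmark CSVs, and ``metadata.csv`` are written there.
    """
    from dataclasses import replace as _replace

    from .imaging_io import write_landmarks, write_volume

    if n_per_cohort < 1:
        raise PhantomError("n_per_cohort must be >= 1")
    if seed is not None:
        spec = _replace(spec, seed=seed)
    cases: list[PhantomCase] = []
    rows = []
    for cohort in ("A", "B"):
        for i in range(n_per_cohort):
            case_id = f"{cohort}{i:03d}"
            if render:
                vol, lms = generate_case(spec, i, cohort)
            else:
                vol, lms = None, generate_landmarks(spec, i, cohort)
            cases.append(PhantomCase(case_id, cohort, vol, lms))
            rows.append({"case_id": case_id, "cohort": cohort})
    meta = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for case in cases:
            if case.volume is not None:
                write_volume(case.volume, out / f"{case.case_id}.nii.gz")
            write_landmarks(case.landmarks, out / f"{case.case_id}.csv")
        meta.to_csv(out / "metadata.csv", index=False)
    return cases, meta
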