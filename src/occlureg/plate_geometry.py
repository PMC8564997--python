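"""Mounting-plate landmark geometry, naming, and rigid transforms.

A pair of articulator mounting plates carries nine hemispherical concaves
each (9 maxillary + 9 mandibular).  The concaves sit on the right, front and
left lateral faces of each plate and are named with FDI-style two-digit
tokens (1x/2x upper right/left, 4x/3x lower right/left); the central front
concaves are ``0`` (maxillary) and ``0'`` (mandibular).  Each maxillary
concave is vertically paired with its mandibular partner, giving the nine
reference pairs used for registration and evaluation.

All coordinates are Cartesian millimetres.  Frames are related exclusively
by :class:`RigidTransform` (proper rotation + translation); no scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .exceptions import (
    DegenerateFrameError,
    InvalidLabelError,
    InvalidLayoutError,
    InvalidTransformError,
)

__all__ = [
    "MAXILLARY_LABELS",
    "MANDIBULAR_LABELS",
    "ALL_LABELS",
    "CANONICAL_PAIRS",
    "jaw_of",
    "pair_of",
    "normalize_label",
    "RigidTransform",
    "LandmarkSet",
    "PlateLayout",
    "default_layout",
    "build_observation_frame",
    "apply_transform",
    "compose",
    "invert",
]

#: FDI-style concave labels, anterior-to-posterior within each face.
MAXILLARY_LABELS: tuple[str, ...] = ("11", "12", "13", "14", "0", "21", "22", "23", "24")
MANDIBULAR_LABELS: tuple[str, ...] = ("41", "42", "43", "44", "0'", "31", "32", "33", "34")
ALL_LABELS: tuple[str, ...] = MAXILLARY_LABELS + MANDIBULAR_LABELS

#: The nine maxillary–mandibular reference pairs.
CANONICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("11", "41"),
    ("12", "42"),
    ("13", "43"),
    ("14", "44"),
    ("0", "0'"),
    ("21", "31"),
    ("22", "32"),
    ("23", "33"),
    ("24", "34"),
)

_PAIR_MAP: dict[str, str] = {}
for _m, _n in CANONICAL_PAIRS:
    _PAIR_MAP[_m] = _n
    _PAIR_MAP[_n] = _m

MAXILLARY = "maxillary"
MANDIBULAR = "mandibular"


def normalize_label(label: str) -> str:
    """Canonicalize a concave label; ``0p`` (file form) maps to ``0'``."""
    token = str(label).strip()
    if token == "0p":
        token = "0'"
    if token not in _PAIR_MAP:
        raise InvalidLabelError(f"unknown concave label {label!r}; valid: {ALL_LABELS}")
    return token


def jaw_of(label: str) -> str:
    """Jaw of a concave label: ``0``/1x/2x are maxillary, ``0'``/4x/3x mandibular."""
    token = normalize_label(label)
    return MAXILLARY if token in MAXILLARY_LABELS else MANDIBULAR


def pair_of(label: str) -> str:
    """Opposing-jaw partner of a concave (an involution: pair_of∘pair_of = id)."""
    return _PAIR_MAP[normalize_label(label)]


def _as_point(value) -> np.ndarray:
    p = np.asarray(value, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise InvalidLayoutError(f"non-finite coordinate {value!r}")
    return p


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p ↦ R·p + t (rotation matrix + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    _ORTHO_TOL = 1e-10

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidTransformError("non-finite transform entries")
        if not np.allclose(R.T @ R, np.eye(3), atol=self._ORTHO_TOL):
            raise InvalidTransformError("rotation is not orthogonal within 1e-10")
        if abs(np.linalg.det(R) - 1.0) > self._ORTHO_TOL:
            raise InvalidTransformError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, rotation, translation, *, repair: bool = False) -> "RigidTransform":
        """Build a transform, optionally re-orthogonalizing a near-rotation.

        Inputs claiming to be rotations are validated, not silently repaired;
        set ``repair=True`` to project onto SO(3) via SVD first.
        """
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        if repair:
            U, _, Vt = np.linalg.svd(R)
            R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        return cls(R, translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) or (3,) array of points through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composite transform applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def invert(a: RigidTransform) -> RigidTransform:
    """Inverse rigid motion: compose(a, invert(a)) is the identity."""
    Rt = a.rotation.T
    return RigidTransform(Rt, -Rt @ a.translation)


@dataclass
class LandmarkSet:
    """Labelled concave center coordinates (mm) in a stated frame.

    ``frame_tag`` records provenance: "nominal", "standard", "fitted:maxillary",
    "aligned:group4", ...
    """

    points: dict[str, np.ndarray]
    frame_tag: str = "nominal"

    def __post_init__(self):
        self.points = {normalize_label(k): _as_point(v) for k, v in self.points.items()}

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self.points

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[normalize_label(label)]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.points)

    def jaw_view(self, jaw: str) -> "LandmarkSet":
        """Restriction to one jaw's labels."""
        if jaw not in (MAXILLARY, MANDIBULAR):
            raise ValueError(f"jaw must be {MAXILLARY!r} or {MANDIBULAR!r}, got {jaw!r}")
        return LandmarkSet(
            {k: v for k, v in self.points.items() if jaw_of(k) == jaw}, self.frame_tag
        )

    def to_array(self, ids: Iterable[str]) -> np.ndarray:
        """Stack the named points into an (N, 3) array, order preserved."""
        ids = [normalize_label(i) for i in ids]
        missing = [i for i in ids if i not in self.points]
        if missing:
            raise InvalidLabelError(f"landmarks missing from set: {missing}")
        return np.array([self.points[i] for i in ids], dtype=float)


@dataclass(frozen=True)
class PlateLayout:
    """Nominal centers and opening axes of all 18 concaves, articulator frame.

    ``jaw_separation`` is the vertical distance between the two plates'
    reference faces; individual concaves carry additional per-position height
    offsets, so the nine pair distances are not all equal.
    """

    centers: dict[str, np.ndarray]
    axes: dict[str, np.ndarray]
    concave_radius: float = 3.0
    jaw_separation: float = 90.0

    def __post_init__(self):
        centers = {normalize_label(k): _as_point(v) for k, v in self.centers.items()}
        if set(centers) != set(ALL_LABELS):
            raise InvalidLayoutError(
                f"layout must contain exactly the 18 concave IDs; got {sorted(centers)}"
            )
        axes = {normalize_label(k): _as_point(v) for k, v in self.axes.items()}
        if set(axes) != set(ALL_LABELS):
            raise InvalidLayoutError("layout axes must cover all 18 concave IDs")
        for k, a in axes.items():
            n = np.linalg.norm(a)
            if abs(n - 1.0) > 1e-12:
                raise InvalidLayoutError(f"axis of {k} is not a unit vector (norm {n})")
        if not self.concave_radius > 0:
            raise InvalidLayoutError("concave_radius must be > 0")
        for jaw_ids in (("12", "0", "22"), ("42", "0'", "32")):
            p = np.array([centers[i] for i in jaw_ids])
            if _triangle_area(p) < 1e-9:
                raise InvalidLayoutError(f"points {jaw_ids} are collinear")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "axes", axes)

    @property
    def concave_diameter(self) -> float:
        return 2.0 * self.concave_radius

    def nominal_landmarks(self) -> LandmarkSet:
        return LandmarkSet(dict(self.centers), "nominal")

    def with_radius(self, concave_radius: float) -> "PlateLayout":
        return replace(self, concave_radius=concave_radius)


def _triangle_area(p: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))


# Face membership: right lateral face (patient right = negative X), front, left.
_FACE_OF = {
    "12": "right", "13": "right", "14": "right",
    "42": "right", "43": "right", "44": "right",
    "11": "front", "0": "front", "21": "front",
    "41": "front", "0'": "front", "31": "front",
    "22": "left", "23": "left", "24": "left",
    "32": "left", "33": "left", "34": "left",
}
_FACE_AXIS = {"right": (-1.0, 0.0, 0.0), "front": (0.0, -1.0, 0.0), "left": (1.0, 0.0, 0.0)}
# Height offsets above the plate reference face, in units of height_stagger:
# lateral concaves rise posteriorly; the off-center front pair sits halfway up.
_HEIGHT_STEPS = {"1": 0.0, "2": 1.0, "3": 2.0}  # posterior index within a face
_FRONT_SIDE_STEP = 0.5


def default_layout(
    *,
    concave_radius: float = 3.0,
    jaw_separation: float = 90.0,
    face_width: float = 60.0,
    lateral_spacing: float = 20.0,
    front_spacing: float = 15.0,
    height_stagger: float = 2.0,
    explicit_centers: Mapping[str, Iterable[float]] | None = None,
) -> PlateLayout:
    """Parameterized default plate layout (all lengths mm).

    Nine 6-mm-diameter concaves per plate: three per lateral face
    (right {12,13,14}/{42,43,44}, front {11,0,21}/{41,0',31}, left
    {22,23,24}/{32,33,34}), opposing pair members vertically aligned.  The
    exact spacings of the physical plate are not published, so every length
    is overridable for sensitivity checks; ``explicit_centers`` replaces
    individual nominal centers outright.
    """
    if not concave_radius > 0:
        raise InvalidLayoutError("concave_radius must be > 0")
    for name, v in (
        ("jaw_separation", jaw_separation),
        ("face_width", face_width),
        ("lateral_spacing", lateral_spacing),
        ("front_spacing", front_spacing),
    ):
        if not v > 0:
            raise InvalidLayoutError(f"{name} must be > 0")
    if height_stagger < 0:
        raise InvalidLayoutError("height_stagger must be >= 0")

    half_w = face_width / 2.0
    z0 = jaw_separation / 2.0

    def height(label: str) -> float:
        face = _FACE_OF[label]
        if face == "front":
            return 0.0 if label in ("0", "0'") else _FRONT_SIDE_STEP * height_stagger
        # posterior position from the second digit: x2 → 0, x3 → 1, x4 → 2
        return _HEIGHT_STEPS[str(int(label[1]) - 1)] * height_stagger

    def xy(label: str) -> tuple[float, float]:
        face = _FACE_OF[label]
        if face == "front":
            if label in ("0", "0'"):
                return 0.0, 0.0
            sign = -1.0 if label in ("11", "41") else 1.0  # patient right at -X
            return sign * front_spacing, 0.0
        x = -half_w if face == "right" else half_w
        step = int(label[1]) - 2  # x2 most anterior on each lateral face
        y = lateral_spacing / 2.0 + step * lateral_spacing
        return x, y

    centers: dict[str, np.ndarray] = {}
    axes: dict[str, np.ndarray] = {}
    for label in ALL_LABELS:
        x, y = xy(label)
        h = z0 + height(label)
        z = h if jaw_of(label) == MAXILLARY else -h
        centers[label] = np.array([x, y, z])
        axes[label] = np.array(_FACE_AXIS[_FACE_OF[label]])

    if explicit_centers:
        seen: set[str] = set()
        for label, point in explicit_centers.items():
            token = normalize_label(label)
            if token in seen:
                raise InvalidLayoutError(f"duplicate explicit center for {label!r}")
            seen.add(token)
            centers[token] = _as_point(point)

    return PlateLayout(centers, axes, concave_radius, jaw_separation)


def build_observation_frame(landmarks: LandmarkSet) -> RigidTransform:
    """Transform into the observation coordinate system.

    The frame is anchored on the maxillary concaves 12, 0 and 22: point 0
    maps to the origin, the three points span the z = 0 plane, X runs along
    the 12→22 line (left to right), and the frame is right-handed with Z
    pointing from the mandibular toward the maxillary plate (resolved via 0'
    when present).
    """
    for required in ("12", "0", "22"):
        if required not in landmarks:
            raise DegenerateFrameError(f"observation frame requires landmark {required}")
    p12, p0, p22 = landmarks["12"], landmarks["0"], landmarks["22"]
    if _triangle_area(np.array([p12, p0, p22])) < 1e-9:
        raise DegenerateFrameError("points 12, 0, 22 are collinear (area < 1e-9 mm^2)")

    x = p22 - p12
    x = x / np.linalg.norm(x)
    z = np.cross(x, p12 - p0)
    z = z / np.linalg.norm(z)
    if "0'" in landmarks:
        # Z must point from the mandibular plate toward the maxillary one.
        if float(np.dot(z, p0 - landmarks["0'"])) < 0:
            z = -z
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return RigidTransform(R, -R @ p0)


def apply_transform(t: RigidTransform, landmarks: LandmarkSet, frame_tag: str | None = None) -> LandmarkSet:
    """Map every landmark through ``t``; pairwise distances are preserved."""
    mapped = {k: t.apply(v) for k, v in landmarks.points.items()}
    tag = frame_tag if frame_tag is not None else f"{landmarks.frame_tag}|transformed"
    return LandmarkSet(mapped, tag)
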