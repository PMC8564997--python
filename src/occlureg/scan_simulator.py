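"""Synthetic measurement stage: contact-probe standard data and optical scans.

Two measurement channels are emulated:

* a contact coordinate-measuring arm probing each concave center directly,
  with per-coordinate Gaussian noise of sd ``sigma_contact`` (default
  0.024 mm), repeated ``n_probe_repeats`` times (default 3) and averaged —
  the *standard data*;
* an optical model scanner sampling each concave's spherical surface with
  per-point Gaussian noise of sd ``sigma_scan`` (default 0.059 mm) in an
  arbitrary per-scan rigid pose — the raw material for the *fitting data*.

The device "accuracy" figures are read as 1-sigma isotropic noise; both are
configurable.  All randomness flows from one master seed through named
substreams keyed by (purpose, jaw, operator, repetition, concave), so a run
is fully reproducible from its configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .plate_geometry import (
    MANDIBULAR,
    MAXILLARY,
    LandmarkSet,
    PlateLayout,
    RigidTransform,
    default_layout,
    jaw_of,
)

__all__ = [
    "NoiseModel",
    "PointCloud",
    "SimulationConfig",
    "substream",
    "sample_concave_surface",
    "simulate_contact_standard",
    "simulate_scan_session",
]

# Named substream identifiers (first spawn_key entry).
_STREAM_STANDARD = 0
_STREAM_POSE = 1
_STREAM_SCAN = 2
_STREAM_SUBSAMPLE = 3

_JAW_INDEX = {MAXILLARY: 0, MANDIBULAR: 1}


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for a named purpose under one master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in keys)))


@dataclass(frozen=True)
class NoiseModel:
    """Device noise levels (mm, 1-sigma) and repeat-averaging counts."""

    sigma_contact: float = 0.024
    sigma_scan: float = 0.059
    n_probe_repeats: int = 3
    n_scan_repeats: int = 3

    def __post_init__(self):
        if self.sigma_contact < 0 or self.sigma_scan < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_probe_repeats < 1 or self.n_scan_repeats < 1:
            raise ValueError("repeat counts must be >= 1")


@dataclass
class PointCloud:
    """Surface samples (N, 3) of one concave, mm, with provenance tag."""

    points: np.ndarray
    source_id: str = ""
    frame_tag: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("a point cloud needs at least one 3D point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite point coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class SimulationConfig:
    """Full description of one simulated accuracy experiment.

    Defaults reproduce the study design: 15 repetitions by each of 2
    operators, 3-fold averaging of both measurement channels, 300 surface
    samples per concave over a 75-degree cap, and the device noise levels of
    the contact arm (0.024 mm) and scanner (0.059 mm).  The operator effect
    is a random subsample (default fraction 0.7) of each cloud before sphere
    fitting, mimicking manual selection of the concave region in software;
    ``operator_subsample_fraction`` may be one fraction for all operators or
    one per operator.
    """

    layout: PlateLayout = field(default_factory=default_layout)
    noise: NoiseModel = field(default_factory=NoiseModel)
    points_per_concave: int = 300
    cap_half_angle_deg: float = 75.0
    operator_subsample_fraction: float | Sequence[float] = 0.7
    n_repetitions: int = 15
    n_operators: int = 2
    seed: int = 0
    fixed_radius_fit: bool = False
    use_nominal_reference: bool = False

    def __post_init__(self):
        if self.points_per_concave < 4:
            raise ValueError("points_per_concave must be >= 4")
        if not 0 < self.cap_half_angle_deg <= 90:
            raise ValueError("cap_half_angle_deg must be in (0, 90]")
        for f in self.subsample_fractions():
            if not 0 < f <= 1:
                raise ValueError("operator_subsample_fraction must be in (0, 1]")
        if self.n_repetitions < 1 or self.n_operators < 1:
            raise ValueError("n_repetitions and n_operators must be >= 1")

    def subsample_fractions(self) -> tuple[float, ...]:
        """Per-operator subsample fractions, broadcasting a scalar."""
        f = self.operator_subsample_fraction
        if np.isscalar(f):
            return (float(f),) * self.n_operators
        fractions = tuple(float(x) for x in f)
        if len(fractions) != self.n_operators:
            raise ValueError("need one subsample fraction per operator")
        return fractions


def _cap_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def sample_concave_surface(
    center,
    radius: float,
    axis,
    n: int,
    sigma: float,
    rng: np.random.Generator,
    cap_half_angle_deg: float = 90.0,
    source_id: str = "",
    frame_tag: str = "",
) -> PointCloud:
    """Uniform samples on a spherical cap about ``axis`` plus isotropic noise.

    Noiseless samples lie exactly at distance ``radius`` from ``center``;
    each point is then displaced by an independent N(0, sigma^2 I) offset.
    """
    if n < 1:
        raise ValueError("need at least one sample point")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center, dtype=float).reshape(3)
    u, v, w = _cap_basis(axis)
    cos_min = np.cos(np.deg2rad(cap_half_angle_deg))
    # Uniform area measure on the cap: cos(theta) ~ U[cos_min, 1].
    cos_t = rng.uniform(cos_min, 1.0, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    dirs = (
        np.outer(sin_t * np.cos(phi), u)
        + np.outer(sin_t * np.sin(phi), v)
        + np.outer(cos_t, w)
    )
    pts = center + radius * dirs
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
    return PointCloud(pts, source_id=source_id, frame_tag=frame_tag)


def simulate_contact_standard(
    layout: PlateLayout, noise: NoiseModel, rng: np.random.Generator
) -> LandmarkSet:
    """Contact-probed *standard data*: repeat-averaged noisy center probes.

    Each nominal center receives ``n_probe_repeats`` independent isotropic
    Gaussian perturbations (sd ``sigma_contact`` per coordinate) whose mean
    is reported, so the per-coordinate variance of the output is
    sigma_contact^2 / n_probe_repeats.
    """
    points = {}
    for label, c in layout.centers.items():
        draws = c + rng.normal(0.0, noise.sigma_contact, size=(noise.n_probe_repeats, 3))
        points[label] = draws.mean(axis=0)
    return LandmarkSet(points, "standard")


def random_pose(rng: np.random.Generator, translation_range: float = 50.0) -> RigidTransform:
    """Rotation uniform over SO(3) (normalized Gaussian quaternion) and
    translation uniform in the ±``translation_range`` mm cube."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-translation_range, translation_range, size=3)
    return RigidTransform(R, t)


def simulate_scan_session(
    layout: PlateLayout,
    jaw: str,
    config: SimulationConfig,
    operator: int,
    repetition: int,
) -> tuple[dict[str, list[PointCloud]], RigidTransform]:
    """One optical scan session of one jaw's plate.

    The plate is scanned in a random rigid pose drawn deterministically from
    (seed, jaw, operator, repetition).  For each of the jaw's nine concaves,
    ``n_scan_repeats`` replicate clouds are emitted sharing that single pose
    (the scan repeats that feed the fitting-data averaging); the operator
    effect is an independent random subsample of each cloud's points.
    """
    if jaw not in _JAW_INDEX:
        raise ValueError(f"jaw must be {MAXILLARY!r} or {MANDIBULAR!r}")
    jaw_idx = _JAW_INDEX[jaw]
    pose = random_pose(substream(config.seed, _STREAM_POSE, jaw_idx, operator, repetition))
    fraction = config.subsample_fractions()[operator]

    labels = [lab for lab in layout.centers if jaw_of(lab) == jaw]
    clouds: dict[str, list[PointCloud]] = {}
    for ci, label in enumerate(labels):
        center = pose.apply(layout.centers[label])
        axis = pose.rotation @ layout.axes[label]
        rng_cloud = substream(config.seed, _STREAM_SCAN, jaw_idx, operator, repetition, ci)
        rng_sub = substream(config.seed, _STREAM_SUBSAMPLE, jaw_idx, operator, repetition, ci)
        replicates = []
        for rep in range(config.noise.n_scan_repeats):
            cloud = sample_concave_surface(
                center,
                layout.concave_radius,
                axis,
                config.points_per_concave,
                config.noise.sigma_scan,
                rng_cloud,
                config.cap_half_angle_deg,
                source_id=label,
                frame_tag=f"scan:{jaw}:op{operator}:rep{repetition}",
            )
            if fraction < 1.0:
                m = max(4, int(round(fraction * len(cloud))))
                idx = rng_sub.choice(len(cloud), size=m, replace=False)
                cloud = PointCloud(cloud.points[np.sort(idx)], cloud.source_id, cloud.frame_tag)
            replicates.append(cloud)
        clouds[label] = replicates
    return clouds, pose
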