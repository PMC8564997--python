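"""Plain-text interchange: landmark CSV, layout/transform JSON, XYZ clouds.

The mandibular central concave ``0'`` is written as ``0p`` in files to avoid
quoting headaches; readers accept both spellings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .plate_geometry import (
    LandmarkSet,
    PlateLayout,
    RigidTransform,
    default_layout,
    jaw_of,
    normalize_label,
)
from .scan_simulator import NoiseModel, PointCloud, SimulationConfig

__all__ = [
    "write_landmarks",
    "read_landmarks",
    "write_transform",
    "read_transform",
    "write_xyz",
    "read_xyz",
    "layout_from_json",
    "config_from_json",
]

_FILE_LABEL = {"0'": "0p"}


def _file_label(label: str) -> str:
    return _FILE_LABEL.get(label, label)


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    """Landmark CSV with header ``id,jaw,x_mm,y_mm,z_mm`` (UTF-8, mm)."""
    rows = [
        {
            "id": _file_label(label),
            "jaw": jaw_of(label),
            "x_mm": p[0],
            "y_mm": p[1],
            "z_mm": p[2],
        }
        for label, p in landmarks.points.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_landmarks(path, frame_tag: str | None = None) -> LandmarkSet:
    frame = pd.read_csv(path, dtype={"id": str})
    required = {"id", "jaw", "x_mm", "y_mm", "z_mm"}
    if not required <= set(frame.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    points = {}
    for _, row in frame.iterrows():
        label = normalize_label(row["id"])
        stated = str(row["jaw"]).strip().lower()
        if stated != jaw_of(label):
            raise ValueError(f"label {label} is {jaw_of(label)}, file says {stated!r}")
        points[label] = np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
    return LandmarkSet(points, frame_tag or str(path))


def write_transform(t: RigidTransform, path) -> Path:
    """Transform JSON: 9 row-major rotation entries + 3 translation entries (mm)."""
    path = Path(path)
    path.write_text(
        json.dumps(
            {"rotation": t.rotation.ravel().tolist(), "translation": t.translation.tolist()},
            indent=2,
        )
    )
    return path


def read_transform(path, repair: bool = False) -> RigidTransform:
    data = json.loads(Path(path).read_text())
    R = np.asarray(data["rotation"], dtype=float).reshape(3, 3)
    return RigidTransform.from_matrix(R, data["translation"], repair=repair)


def write_xyz(cloud: PointCloud, path) -> Path:
    """Whitespace-delimited XYZ file, one ``x y z`` triple (mm) per line."""
    path = Path(path)
    np.savetxt(path, cloud.points, fmt="%.9f")
    return path


def read_xyz(path, source_id: str = "", frame_tag: str = "") -> PointCloud:
    pts = np.loadtxt(path, ndmin=2)
    return PointCloud(pts, source_id=source_id, frame_tag=frame_tag or str(path))


def layout_from_json(spec: Mapping | str | Path) -> PlateLayout:
    """Build a layout from the JSON schema (``*_mm`` keys, optional
    ``explicit_centers`` rows shaped like landmark-CSV records)."""
    if not isinstance(spec, Mapping):
        spec = json.loads(Path(spec).read_text())
    explicit = None
    if "explicit_centers" in spec:
        explicit = {
            row["id"]: (row["x_mm"], row["y_mm"], row["z_mm"])
            for row in spec["explicit_centers"]
        }
    kwargs = {}
    for key, arg in (
        ("concave_radius_mm", "concave_radius"),
        ("jaw_separation_mm", "jaw_separation"),
        ("face_width_mm", "face_width"),
        ("lateral_spacing_mm", "lateral_spacing"),
        ("front_spacing_mm", "front_spacing"),
        ("height_stagger_mm", "height_stagger"),
    ):
        if key in spec:
            kwargs[arg] = float(spec[key])
    return default_layout(**kwargs, explicit_centers=explicit)


def config_from_json(spec: Mapping | str | Path) -> SimulationConfig:
    """Simulation config from JSON (noise levels, repetitions, seed, layout)."""
    if not isinstance(spec, Mapping):
        spec = json.loads(Path(spec).read_text())
    layout = layout_from_json(spec.get("layout", {}))
    noise_spec = spec.get("noise", {})
    noise = NoiseModel(
        sigma_contact=float(noise_spec.get("sigma_contact_mm", 0.024)),
        sigma_scan=float(noise_spec.get("sigma_scan_mm", 0.059)),
        n_probe_repeats=int(noise_spec.get("n_probe_repeats", 3)),
        n_scan_repeats=int(noise_spec.get("n_scan_repeats", 3)),
    )
    kwargs = {}
    for key in (
        "points_per_concave",
        "cap_half_angle_deg",
        "operator_subsample_fraction",
        "n_repetitions",
        "n_operators",
        "seed",
        "fixed_radius_fit",
        "use_nominal_reference",
    ):
        if key in spec:
            kwargs[key] = spec[key]
    return SimulationConfig(layout=layout, noise=noise, **kwargs)
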