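"""Equal-weight reference-point rigid alignment (RPS construction).

Each jaw's fitted landmark set is aligned onto the contact-measured standard
set using only a chosen subset of reference landmarks, with equal weights,
by the closed-form Kabsch solution: centroid subtraction, 3x3
cross-covariance, SVD and determinant sign correction.  The sign correction
makes a reflection impossible by construction; exact collinearity of the
reference landmarks leaves a continuum of optima and is reported as an
error rather than silently resolved.

No scaling term: plates and models are treated as one rigid body.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateConfigurationError, InsufficientLandmarksError
from .plate_geometry import (
    LandmarkSet,
    RigidTransform,
    apply_transform,
    normalize_label,
    pair_of,
)

__all__ = ["kabsch_align", "fiducial_registration_error", "construct_icp_relation"]

_COLLINEAR_TOL = 1e-9


def kabsch_align(source: LandmarkSet, target: LandmarkSet, ids: Sequence[str]) -> RigidTransform:
    """Rigid transform minimizing the equal-weight landmark SSD.

    Returns the global optimum of sum_i ||T(s_i) − t_i||^2 over proper rigid
    motions T.  Requires at least 3 correspondences whose source points are
    not collinear.
    """
    ids = [normalize_label(i) for i in ids]
    if len(set(ids)) < 3:
        raise InsufficientLandmarksError(f"rigid alignment needs >= 3 distinct landmarks, got {ids}")
    S = source.to_array(ids)
    T = target.to_array(ids)

    s_mean = S.mean(axis=0)
    t_mean = T.mean(axis=0)
    S0 = S - s_mean
    T0 = T - t_mean

    # Collinear source points: rank(S0) <= 1, i.e. second singular value ~ 0.
    sv = np.linalg.svd(S0, compute_uv=False)
    if sv[1] < _COLLINEAR_TOL:
        raise DegenerateConfigurationError(
            "reference landmarks are collinear; the optimal rotation is not unique"
        )

    H = S0.T @ T0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, t_mean - R @ s_mean)


def fiducial_registration_error(
    t: RigidTransform, source: LandmarkSet, target: LandmarkSet, ids: Sequence[str]
) -> float:
    """RMS residual (mm) at the alignment landmarks after applying ``t``.

    Zero iff the transformed source landmarks coincide with the target ones.
    Distinct from the error at held-out (target) points, which this package
    measures downstream through pair distances.
    """
    ids = [normalize_label(i) for i in ids]
    if len(set(ids)) < 3:
        raise InsufficientLandmarksError("FRE is defined over >= 3 landmarks here")
    S = source.to_array(ids)
    T = target.to_array(ids)
    r = t.apply(S) - T
    return float(np.sqrt(np.mean(np.sum(r**2, axis=1))))


def construct_icp_relation(
    fitted_max: LandmarkSet,
    fitted_mand: LandmarkSet,
    standard: LandmarkSet,
    group_pairs: Iterable[tuple[str, str] | str],
    group_label: str | int | None = None,
) -> tuple[LandmarkSet, LandmarkSet]:
    """3D construction of the intercuspal relation for one reference group.

    Aligns the maxillary fitted set onto the standard data using the group's
    maxillary member landmarks, and the mandibular fitted set using the
    mandibular members.  Because the standard set carries the articulator's
    jaw relation, both jaws land in one common frame, reconstructing the
    occlusal relation.  Returns the two aligned sets.
    """
    max_ids: list[str] = []
    mand_ids: list[str] = []
    for pair in group_pairs:
        if isinstance(pair, str):
            m = normalize_label(pair)
            n = pair_of(m)
        else:
            m, n = (normalize_label(pair[0]), normalize_label(pair[1]))
        if pair_of(m) != n:
            raise ValueError(f"({m}, {n}) is not a canonical maxillary–mandibular pair")
        max_ids.append(m)
        mand_ids.append(n)

    tag = f"aligned:{group_label}" if group_label is not None else "aligned"
    t_max = kabsch_align(fitted_max, standard, max_ids)
    t_mand = kabsch_align(fitted_mand, standard, mand_ids)
    return (
        apply_transform(t_max, fitted_max, tag),
        apply_transform(t_mand, fitted_mand, tag),
    )
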