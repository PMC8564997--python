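"""Best-fit sphere extraction from concave point clouds.

Two-stage metrology-style fit: an algebraic linear least-squares
initialization (exact on noiseless spherical data) followed by geometric
Levenberg–Marquardt refinement of the orthogonal-distance objective
sum_i (||p_i − c|| − r)^2.  The geometric fit is the reported one; a
fixed-radius variant holds r at the nominal design radius and optimizes the
center only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateFitError, SphereFitNumericalError
from .plate_geometry import LandmarkSet, jaw_of
from .scan_simulator import PointCloud, SimulationConfig

__all__ = ["SphereFit", "fit_sphere_algebraic", "fit_sphere_geometric", "fit_concave_centers"]

GRADIENT_TOL = 1e-10
MAX_ITERATIONS = 100


@dataclass(frozen=True)
class SphereFit:
    """Fitted sphere: center (mm), radius (mm), RMS of |distance − radius|."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not self.radius > 0:
            raise DegenerateFitError(f"fitted radius must be > 0, got {self.radius}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def _residual_rms(points: np.ndarray, center: np.ndarray, radius: float) -> float:
    d = np.linalg.norm(points - center, axis=1)
    return float(np.sqrt(np.mean((d - radius) ** 2)))


def fit_sphere_algebraic(cloud: PointCloud) -> SphereFit:
    """Linear least-squares sphere fit.

    Expanding ||p − c||^2 = r^2 gives the linear system
    2 c·p + (r^2 − ||c||^2) = ||p||^2 in the unknowns (c, r^2 − ||c||^2);
    exact on noiseless spherical data.  Fewer than 4 points or a coplanar
    cloud leaves the system rank-deficient.
    """
    pts = cloud.points
    n = pts.shape[0]
    if n < 4:
        raise DegenerateFitError(f"sphere fit needs >= 4 points, got {n}")
    A = np.column_stack([2.0 * pts, np.ones(n)])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("degenerate point configuration (coplanar or collinear)")
    center = sol[:3]
    r2 = sol[3] + float(center @ center)
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateFitError("algebraic fit produced a non-positive squared radius")
    radius = float(np.sqrt(r2))
    return SphereFit(center, radius, _residual_rms(pts, center, radius), n, converged=True)


def fit_sphere_geometric(
    cloud: PointCloud,
    init: SphereFit | None = None,
    fixed_radius: float | None = None,
) -> SphereFit:
    """Geometric (orthogonal-distance) refinement of a sphere fit.

    Levenberg–Marquardt on residuals ||p_i − c|| − r with analytic Jacobian;
    with ``fixed_radius`` the radius is held and only the center moves.  The
    result never has a larger objective than the initialization; the
    ``converged`` flag reflects the 1e-10 gradient tolerance within the
    100-iteration cap.
    """
    pts = cloud.points
    if init is None:
        init = fit_sphere_algebraic(cloud)
    if fixed_radius is not None and not fixed_radius > 0:
        raise ValueError("fixed_radius must be > 0")

    if fixed_radius is None:

        def resid(x):
            d = np.linalg.norm(pts - x[:3], axis=1)
            return d - x[3]

        def jac(x):
            diff = x[:3] - pts
            d = np.linalg.norm(diff, axis=1)
            J = np.empty((pts.shape[0], 4))
            J[:, :3] = diff / d[:, None]
            J[:, 3] = -1.0
            return J

        x0 = np.append(init.center, init.radius)
    else:
        r_fix = float(fixed_radius)

        def resid(x):
            return np.linalg.norm(pts - x, axis=1) - r_fix

        def jac(x):
            diff = x - pts
            return diff / np.linalg.norm(diff, axis=1)[:, None]

        x0 = np.array(init.center, dtype=float)

    if not np.all(np.isfinite(resid(x0))):
        raise SphereFitNumericalError("non-finite objective at the initial estimate")

    res = least_squares(
        resid,
        x0,
        jac=jac,
        method="lm",
        gtol=GRADIENT_TOL,
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=MAX_ITERATIONS * (x0.size + 1),
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.cost):
        raise SphereFitNumericalError("geometric refinement produced non-finite values")

    if fixed_radius is None:
        center, radius = res.x[:3], float(abs(res.x[3]))
    else:
        center, radius = res.x, r_fix

    # LM is monotone from its start, but guard against pathological exits.
    if np.sum(resid(res.x) ** 2) > np.sum(resid(x0) ** 2) + 1e-15:
        center = init.center
        radius = init.radius if fixed_radius is None else r_fix
        return SphereFit(center, radius, _residual_rms(pts, center, radius), pts.shape[0], False)

    converged = bool(res.status in (1, 2, 3, 4))
    return SphereFit(center, radius, _residual_rms(pts, center, radius), pts.shape[0], converged)


def fit_concave_centers(
    session_clouds: Mapping[str, Sequence[PointCloud]],
    config: SimulationConfig,
) -> LandmarkSet:
    """Fitting data for one jaw: repeat-averaged geometric sphere centers.

    For each concave, every replicate cloud is fitted independently
    (algebraic initialization, geometric refinement, optionally at the fixed
    nominal radius) and the fitted centers are averaged.
    """
    if not session_clouds:
        raise ValueError("no clouds supplied")
    jaws = {jaw_of(label) for label in session_clouds}
    if len(jaws) != 1:
        raise ValueError(f"session clouds must cover a single jaw, got {sorted(jaws)}")
    jaw = jaws.pop()
    if len(session_clouds) != 9:
        raise ValueError(f"expected the jaw's 9 concaves, got {len(session_clouds)}")

    fixed = config.layout.concave_radius if config.fixed_radius_fit else None
    points = {}
    for label, replicates in session_clouds.items():
        centers = []
        for cloud in replicates:
            try:
                fit = fit_sphere_geometric(cloud, fixed_radius=fixed)
            except (DegenerateFitError, SphereFitNumericalError) as exc:
                raise type(exc)(f"concave {label}: {exc}") from exc
            centers.append(fit.center)
        points[label] = np.mean(centers, axis=0)
    return LandmarkSet(points, f"fitted:{jaw}")
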