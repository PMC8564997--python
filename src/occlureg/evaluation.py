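"""The measurement core: group scheme, held-out pair distances, trueness and
precision RMSE over the repeated-measurement design.

Seven reference-point groups are compared.  For each (operator, repetition,
group) unit the two jaws are aligned to the standard data using only the
group's reference pairs, and the inter-jaw distance D_M of every *held-out*
pair is compared with its contact-measured reference distance D_R:

* trueness RMSE (one value per unit)      sqrt(mean_pairs (D_M − D_R)^2)
* precision RMSE (per repetition, within  sqrt(mean_pairs (D_M[p, r] −
  one operator and group)                       mean_r' D_M[p, r'])^2)

following the ISO 5725-1 reading of accuracy as trueness (closeness to a
reference value) plus precision (closeness of repeated measurements).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_geometry import (
    MANDIBULAR,
    MAXILLARY,
    CANONICAL_PAIRS,
    LandmarkSet,
    apply_transform,
    build_observation_frame,
    normalize_label,
    pair_of,
)
from .rps_registration import construct_icp_relation
from .scan_simulator import SimulationConfig, simulate_contact_standard, simulate_scan_session, substream, _STREAM_STANDARD
from .sphere_fitting import fit_concave_centers

__all__ = [
    "GroupScheme",
    "PairDistanceRecord",
    "AccuracyResult",
    "ExperimentReport",
    "group_scheme",
    "evaluation_pairs",
    "pair_distances",
    "trueness_rmse",
    "precision_rmse",
    "run_experiment",
]

Pair = tuple[str, str]

# The seven reference-point groups, by maxillary member; groups 1–3 use three
# pairs, groups 4–7 four, differing in anterior/posterior spread.
_GROUP_MAX_IDS: dict[int, tuple[str, ...]] = {
    1: ("14", "0", "24"),
    2: ("13", "0", "23"),
    3: ("12", "0", "22"),
    4: ("14", "12", "22", "24"),
    5: ("14", "11", "21", "24"),
    6: ("13", "11", "21", "23"),
    7: ("12", "11", "21", "22"),
}


def _as_pair(value) -> Pair:
    if isinstance(value, str):
        m = normalize_label(value)
        return (m, pair_of(m)) if m in dict(CANONICAL_PAIRS) else (pair_of(m), m)
    m, n = normalize_label(value[0]), normalize_label(value[1])
    if pair_of(m) != n:
        raise ValueError(f"({m}, {n}) is not a canonical pair")
    return (m, n)


@dataclass(frozen=True)
class GroupScheme:
    """Ordered map group index (1..7) → reference pairs."""

    groups: dict[int, tuple[Pair, ...]]

    def __post_init__(self):
        if sorted(self.groups) != list(range(1, 8)):
            raise ValueError("a group scheme needs exactly groups 1..7")
        canonical = set(CANONICAL_PAIRS)
        normed = {}
        for g, pairs in self.groups.items():
            pairs = tuple(_as_pair(p) for p in pairs)
            if len(set(pairs)) != len(pairs):
                raise ValueError(f"group {g} has duplicate pairs")
            if not set(pairs) <= canonical:
                raise ValueError(f"group {g} contains non-canonical pairs")
            expected = 3 if g <= 3 else 4
            if len(pairs) != expected:
                raise ValueError(f"group {g} must have {expected} pairs, got {len(pairs)}")
            normed[g] = pairs
        object.__setattr__(self, "groups", normed)

    def reference_pairs(self, group: int) -> tuple[Pair, ...]:
        if group not in self.groups:
            raise KeyError(f"unknown group index {group}")
        return self.groups[group]


def group_scheme() -> GroupScheme:
    """The canonical seven-group reference-pair scheme."""
    return GroupScheme({g: tuple(ids) for g, ids in _GROUP_MAX_IDS.items()})


def evaluation_pairs(scheme: GroupScheme, group: int) -> tuple[Pair, ...]:
    """Held-out pairs of a group: the nine canonical pairs minus its
    reference pairs, in canonical order."""
    refs = set(scheme.reference_pairs(group))
    return tuple(p for p in CANONICAL_PAIRS if p not in refs)


def pair_distances(
    max_set: LandmarkSet, mand_set: LandmarkSet, pairs: Iterable[Pair]
) -> list[tuple[Pair, float]]:
    """Euclidean inter-jaw distance (mm) per pair, order-stable."""
    out = []
    for pair in pairs:
        m, n = _as_pair(pair)
        out.append(((m, n), float(np.linalg.norm(max_set[m] - mand_set[n]))))
    return out


@dataclass(frozen=True)
class PairDistanceRecord:
    """One held-out pair measurement within one (operator, repetition, group)."""

    operator: int
    repetition: int
    group: int
    pair: Pair
    d_r: float
    d_m: float

    def __post_init__(self):
        if not (self.d_r > 0 and self.d_m > 0):
            raise ValueError("pair distances must be positive")

    @property
    def diff(self) -> float:
        """Signed distance deviation D_M − D_R (mm)."""
        return self.d_m - self.d_r


def trueness_rmse(records: Sequence[PairDistanceRecord]) -> float:
    """RMSE of D_M − D_R over the held-out pairs of one unit."""
    if len(records) == 0:
        raise ValueError("trueness RMSE needs at least one record")
    keys = {(r.operator, r.repetition, r.group) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span several (operator, repetition, group) units: {keys}")
    diffs = np.array([r.diff for r in records])
    return float(np.sqrt(np.mean(diffs**2)))


def precision_rmse(d_m: np.ndarray) -> np.ndarray:
    """Per-repetition precision RMSE from a (pairs × repetitions) D_M matrix.

    Column r maps to sqrt(mean_p (D_M[p, r] − mean_r' D_M[p, r'])^2): the RMS
    deviation of that repetition's distances from the per-pair repetition
    means (ISO 5725-1 repeatability flavour).
    """
    M = np.asarray(d_m, dtype=float)
    if M.ndim != 2:
        raise ValueError("need a (pairs × repetitions) matrix")
    if M.shape[1] < 2:
        raise ValueError("precision is undefined for a single repetition")
    dev = M - M.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(dev**2, axis=0))


@dataclass(frozen=True)
class AccuracyResult:
    """Per-group accuracy: mean ± sd of the per-unit RMSE values (mm).

    ``trueness_values`` has one entry per (operator, repetition);
    ``precision_values`` maps operator → per-repetition precision vector.
    """

    group: int
    trueness_mean: float
    trueness_sd: float
    precision_mean: float
    precision_sd: float
    trueness_values: np.ndarray
    precision_values: dict[int, np.ndarray]


@dataclass
class ExperimentReport:
    """Everything a simulated accuracy experiment produced."""

    config: SimulationConfig
    standard: LandmarkSet
    d_r: dict[Pair, float]
    records: list[PairDistanceRecord]
    accuracy: dict[int, AccuracyResult]
    scheme: GroupScheme
    stats: "object | None" = None  # filled by stats_report when requested

    def records_frame(self) -> pd.DataFrame:
        """Long-format records table (operator, repetition, group, pair, mm)."""
        rows = [
            {
                "operator": r.operator,
                "repetition": r.repetition,
                "group": r.group,
                "pair": f"{r.pair[0]}-{r.pair[1]}",
                "D_R_mm": r.d_r,
                "D_M_mm": r.d_m,
                "diff_mm": r.diff,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "trueness_mean": a.trueness_mean,
                "trueness_sd": a.trueness_sd,
                "precision_mean": a.precision_mean,
                "precision_sd": a.precision_sd,
            }
            for g, a in sorted(self.accuracy.items())
        ]
        return pd.DataFrame(rows)

    def n_units(self) -> int:
        """Number of alignment-evaluation units (group × repetition × operator)."""
        return len({(r.operator, r.repetition, r.group) for r in self.records})


def run_experiment(config: SimulationConfig, compute_stats: bool = True) -> ExperimentReport:
    """Execute the full simulated design.

    One contact-measured standard set (expressed in the observation frame);
    then, per (operator, repetition): one scan session and sphere fit per
    jaw, and per group an alignment onto the standard followed by held-out
    pair distance measurement.  Aggregates trueness per unit and precision
    per (operator, group) across repetitions.

    With ``compute_stats`` the ANOVA/Tukey/ICC layer is attached to the
    report; zero-noise configurations make those statistics degenerate
    (identical values everywhere), in which case they raise, so switch the
    flag off for exactness studies.
    """
    layout = config.layout
    scheme = group_scheme()

    standard = simulate_contact_standard(
        layout, config.noise, substream(config.seed, _STREAM_STANDARD)
    )
    obs = build_observation_frame(standard)
    standard = apply_transform(obs, standard, "standard")

    if config.use_nominal_reference:
        reference = apply_transform(
            build_observation_frame(layout.nominal_landmarks()),
            layout.nominal_landmarks(),
            "nominal",
        )
    else:
        reference = standard
    d_r = {
        pair: dist
        for pair, dist in pair_distances(
            reference.jaw_view(MAXILLARY), reference.jaw_view(MANDIBULAR), CANONICAL_PAIRS
        )
    }

    records: list[PairDistanceRecord] = []
    trueness: dict[int, list[float]] = {g: [] for g in scheme.groups}
    # d_m_by[(operator, group)][pair] → per-repetition distances
    d_m_by: dict[tuple[int, int], dict[Pair, list[float]]] = {}

    for operator in range(config.n_operators):
        for repetition in range(config.n_repetitions):
            fitted = {}
            for jaw in (MAXILLARY, MANDIBULAR):
                clouds, _ = simulate_scan_session(layout, jaw, config, operator, repetition)
                fitted[jaw] = fit_concave_centers(clouds, config)
            for g in sorted(scheme.groups):
                aligned_max, aligned_mand = construct_icp_relation(
                    fitted[MAXILLARY], fitted[MANDIBULAR], standard,
                    scheme.reference_pairs(g), group_label=g,
                )
                unit_records = []
                for pair, d_m in pair_distances(aligned_max, aligned_mand, evaluation_pairs(scheme, g)):
                    rec = PairDistanceRecord(operator, repetition, g, pair, d_r[pair], d_m)
                    unit_records.append(rec)
                    d_m_by.setdefault((operator, g), {}).setdefault(pair, []).append(d_m)
                records.extend(unit_records)
                trueness[g].append(trueness_rmse(unit_records))

    accuracy: dict[int, AccuracyResult] = {}
    for g in sorted(scheme.groups):
        t_vals = np.array(trueness[g])
        prec: dict[int, np.ndarray] = {}
        for operator in range(config.n_operators):
            per_pair = d_m_by[(operator, g)]
            M = np.array([per_pair[p] for p in evaluation_pairs(scheme, g)])
            if config.n_repetitions >= 2:
                prec[operator] = precision_rmse(M)
        p_all = (
            np.concatenate([prec[o] for o in sorted(prec)]) if prec else np.array([])
        )
        accuracy[g] = AccuracyResult(
            group=g,
            trueness_mean=float(t_vals.mean()),
            trueness_sd=float(t_vals.std(ddof=1)) if t_vals.size > 1 else 0.0,
            precision_mean=float(p_all.mean()) if p_all.size else float("nan"),
            precision_sd=float(p_all.std(ddof=1)) if p_all.size > 1 else 0.0,
            trueness_values=t_vals,
            precision_values=prec,
        )

    report = ExperimentReport(
        config=config,
        standard=standard,
        d_r=d_r,
        records=records,
        accuracy=accuracy,
        scheme=scheme,
    )
    if compute_stats:
        from .stats_report import experiment_statistics

        report.stats = experiment_statistics(report)
    return report
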