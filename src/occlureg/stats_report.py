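"""Statistical layer: one-way ANOVA with Tukey HSD across the seven groups,
and two-way single-measure ICC reliability with 95% confidence intervals.

The ICC forms follow the standard two-way mean-square decompositions
(rows = targets, columns = raters/measurements):

* consistency, single measurement          ICC(C,1) = (MSR − MSE) / (MSR + (k−1) MSE)
* absolute agreement, single measurement   ICC(A,1) = (MSR − MSE) /
        (MSR + (k−1) MSE + (k/n)(MSC − MSE))

The mixed- versus random-effects distinction changes the interpretation of
these forms, not their point-estimate formulas; confidence intervals use the
F-based derivations (exact for consistency, Satterthwaite-approximate for
absolute agreement).  Shapiro–Wilk / Levene pre-checks are not re-implemented
here: ``normality_hook`` lets callers plug in stock routines, and written
reports note their absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import UndefinedStatisticError
from .evaluation import ExperimentReport, evaluation_pairs

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "ICCResult",
    "one_way_anova",
    "tukey_hsd",
    "icc_single",
    "intra_inter_operator_report",
    "experiment_statistics",
    "write_report_tables",
    "TWO_WAY_MIXED_ABSOLUTE_SINGLE",
    "TWO_WAY_RANDOM_CONSISTENCY_SINGLE",
]

TWO_WAY_MIXED_ABSOLUTE_SINGLE = "two_way_mixed_absolute_single"
TWO_WAY_RANDOM_CONSISTENCY_SINGLE = "two_way_random_consistency_single"
_ABSOLUTE_MODELS = (TWO_WAY_MIXED_ABSOLUTE_SINGLE, "two_way_random_absolute_single")
_CONSISTENCY_MODELS = (TWO_WAY_RANDOM_CONSISTENCY_SINGLE, "two_way_mixed_consistency_single")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs comparisons: (i, j) → (mean difference, adjusted p)."""

    labels: tuple
    mean_diff: dict
    p_adjusted: dict

    def p(self, i, j) -> float:
        return self.p_adjusted[(i, j) if (i, j) in self.p_adjusted else (j, i)]

    def diff(self, i, j) -> float:
        if (i, j) in self.mean_diff:
            return self.mean_diff[(i, j)]
        return -self.mean_diff[(j, i)]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("ICC confidence bounds must bracket the estimate")


def _group_arrays(groups: Sequence) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for a in arrays:
        if a.size < 2:
            raise ValueError("every group needs at least two values")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite observations")
    return arrays


def _sums_of_squares(arrays: list[np.ndarray]) -> tuple[float, float, int, int]:
    all_x = np.concatenate(arrays)
    gm = all_x.mean()
    ssb = float(sum(a.size * (a.mean() - gm) ** 2 for a in arrays))
    ssw = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    df_b = len(arrays) - 1
    df_w = all_x.size - len(arrays)
    return ssb, ssw, df_b, df_w


def one_way_anova(groups: Sequence) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within."""
    arrays = _group_arrays(groups)
    ssb, ssw, df_b, df_w = _sums_of_squares(arrays)
    if df_w < 1:
        raise ValueError("within-group degrees of freedom must be >= 1")
    msw = ssw / df_w
    if msw == 0.0:
        if ssb == 0.0:
            raise UndefinedStatisticError("all observations identical; F is undefined")
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ssb / df_b) / msw
    return AnovaResult(float(F), df_b, df_w, float(sps.f.sf(F, df_b, df_w)))


def tukey_hsd(groups: Sequence, labels: Sequence | None = None) -> TukeyResult:
    """Tukey HSD all-pairs comparisons (Tukey–Kramer at unequal n).

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group mean square: q_ij = |m_i − m_j| /
    sqrt(MSW (1/n_i + 1/n_j) / 2), p = P(Q_{k, df_w} > q_ij).
    """
    arrays = _group_arrays(groups)
    k = len(arrays)
    labels = tuple(labels) if labels is not None else tuple(range(1, k + 1))
    if len(labels) != k:
        raise ValueError("need one label per group")
    _, ssw, _, df_w = _sums_of_squares(arrays)
    msw = ssw / df_w
    if msw == 0.0:
        raise UndefinedStatisticError("zero pooled within-group variance")
    mean_diff, p_adj = {}, {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            se = np.sqrt(msw * (1.0 / arrays[i].size + 1.0 / arrays[j].size) / 2.0)
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
            mean_diff[(labels[i], labels[j])] = diff
            p_adj[(labels[i], labels[j])] = p
    return TukeyResult(labels, mean_diff, p_adj)


def _two_way_mean_squares(M: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = M.shape
    gm = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * float(np.sum((row_means - gm) ** 2))
    ssc = n * float(np.sum((col_means - gm) ** 2))
    sst = float(np.sum((M - gm) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0), n, k


def icc_single(data, model: str, alpha: float = 0.05) -> ICCResult:
    """Two-way single-measurement ICC with a 95% confidence interval.

    ``data`` is a complete (targets × raters) matrix.  Models:
    consistency (two-way random or mixed) and absolute agreement (two-way
    mixed or random) — the forms used for inter- and intra-operator
    reliability respectively.
    """
    M = np.asarray(data, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 targets and >= 2 raters")
    if not np.all(np.isfinite(M)):
        raise ValueError("ICC requires a complete, finite matrix")
    msr, msc, mse, n, k = _two_way_mean_squares(M)
    if msr == 0.0 and msc == 0.0 and mse == 0.0:
        raise UndefinedStatisticError("constant matrix; ICC is undefined")

    if model in _CONSISTENCY_MODELS:
        denom = msr + (k - 1) * mse
        if denom == 0.0:
            raise UndefinedStatisticError("zero denominator in consistency ICC")
        icc = (msr - mse) / denom
        if mse == 0.0:
            lo, hi = icc, icc
        else:
            F = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = F / sps.f.ppf(1 - alpha / 2, df1, df2)
            fu = F * sps.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif model in _ABSOLUTE_MODELS:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom == 0.0:
            raise UndefinedStatisticError("zero denominator in absolute-agreement ICC")
        icc = (msr - mse) / denom
        if mse == 0.0 and msc == 0.0:
            lo, hi = icc, icc
        else:
            # Satterthwaite df for the (a·MSC + b·MSE) compound (McGraw–Wong).
            a = (k * icc) / (n * (1 - icc)) if icc != 1.0 else np.inf
            if not np.isfinite(a):
                lo, hi = icc, icc
            else:
                b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                )
                f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr
                )
    else:
        raise ValueError(f"unknown ICC model {model!r}")

    icc = float(min(icc, 1.0))
    lo = float(min(lo, icc))
    hi = float(min(max(hi, icc), 1.0))
    return ICCResult(icc, model, lo, hi)


def intra_inter_operator_report(
    report: ExperimentReport,
) -> tuple[dict[tuple[int, int], ICCResult], dict[int, ICCResult]]:
    """Reliability ICCs from an experiment's held-out distance records.

    Intra-operator (per group, per operator): D_M matrix with evaluation
    pairs as targets and repetitions as raters, absolute-agreement
    two-way mixed single-measurement form.  Inter-operator (per group):
    per-pair repetition-mean D_M with operators as raters, consistency
    two-way random single-measurement form.
    """
    cfg = report.config
    if cfg.n_operators < 2 or cfg.n_repetitions < 2:
        raise ValueError("reliability needs >= 2 operators and >= 2 repetitions")

    frame = report.records_frame()
    intra: dict[tuple[int, int], ICCResult] = {}
    inter: dict[int, ICCResult] = {}
    for g in sorted(report.scheme.groups):
        pair_labels = [f"{m}-{n}" for m, n in evaluation_pairs(report.scheme, g)]
        sub = frame[frame["group"] == g]
        wide = sub.pivot_table(
            index="pair", columns=["operator", "repetition"], values="D_M_mm"
        ).loc[pair_labels]
        op_means = []
        for operator in range(cfg.n_operators):
            M = wide[operator].to_numpy()
            intra[(g, operator)] = icc_single(M, TWO_WAY_MIXED_ABSOLUTE_SINGLE)
            op_means.append(M.mean(axis=1))
        inter[g] = icc_single(np.column_stack(op_means), TWO_WAY_RANDOM_CONSISTENCY_SINGLE)
    return intra, inter


@dataclass
class ExperimentStatistics:
    """ANOVA/Tukey over group RMSE values plus reliability ICC tables."""

    anova_trueness: AnovaResult
    tukey_trueness: TukeyResult
    anova_precision: AnovaResult
    tukey_precision: TukeyResult
    icc_intra: dict[tuple[int, int], ICCResult]
    icc_inter: dict[int, ICCResult]


def experiment_statistics(
    report: ExperimentReport,
    normality_hook: Callable[[dict[int, np.ndarray]], object] | None = None,
) -> ExperimentStatistics:
    """The paper-shaped statistical battery for one experiment report.

    ``normality_hook`` may run stock normality/variance pre-checks
    (e.g. ``scipy.stats.shapiro`` / ``levene``) on the per-group trueness
    vectors; its result is not consumed here.
    """
    groups = sorted(report.accuracy)
    t_samples = [report.accuracy[g].trueness_values for g in groups]
    p_samples = [
        np.concatenate([v for _, v in sorted(report.accuracy[g].precision_values.items())])
        for g in groups
    ]
    if normality_hook is not None:
        normality_hook({g: report.accuracy[g].trueness_values for g in groups})
    icc_intra, icc_inter = intra_inter_operator_report(report)
    return ExperimentStatistics(
        anova_trueness=one_way_anova(t_samples),
        tukey_trueness=tukey_hsd(t_samples, groups),
        anova_precision=one_way_anova(p_samples),
        tukey_precision=tukey_hsd(p_samples, groups),
        icc_intra=icc_intra,
        icc_inter=icc_inter,
    )


def _tukey_frame(res: TukeyResult) -> pd.DataFrame:
    k = len(res.labels)
    table = pd.DataFrame(index=list(res.labels), columns=list(res.labels), dtype=object)
    for i in res.labels:
        for j in res.labels:
            table.loc[i, j] = "N/A" if i == j else repr(res.p(i, j))
    table.index.name = "group"
    return table


def write_report_tables(report: ExperimentReport, out_dir) -> list[Path]:
    """Write the report's CSV tables and a provenance JSON.

    Emits ``records.csv``, ``summary.csv``, ``anova.csv``, ``tukey.csv``
    (trueness, 7×7 with N/A diagonal), ``tukey_precision.csv``,
    ``icc_intra.csv``, ``icc_inter.csv`` and ``report.json``; ordering is
    deterministic, so identical reports produce byte-identical files.
    Normality/variance pre-checks are not part of the battery; report.json
    records that.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats = report.stats if report.stats is not None else experiment_statistics(report)

    written = []

    def _write(name: str, frame: pd.DataFrame, index=False):
        path = out / name
        frame.to_csv(path, index=index, float_format="%.17g")
        written.append(path)

    _write("records.csv", report.records_frame())
    _write("summary.csv", report.summary_frame())

    anova = pd.DataFrame(
        [
            {"metric": "trueness", "F": stats.anova_trueness.F,
             "df_between": stats.anova_trueness.df_between,
             "df_within": stats.anova_trueness.df_within, "p": stats.anova_trueness.p},
            {"metric": "precision", "F": stats.anova_precision.F,
             "df_between": stats.anova_precision.df_between,
             "df_within": stats.anova_precision.df_within, "p": stats.anova_precision.p},
        ]
    )
    _write("anova.csv", anova)
    _write("tukey.csv", _tukey_frame(stats.tukey_trueness), index=True)
    _write("tukey_precision.csv", _tukey_frame(stats.tukey_precision), index=True)

    intra_rows = [
        {"group": g, "operator": op + 1, "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for (g, op), r in sorted(stats.icc_intra.items())
    ]
    _write("icc_intra.csv", pd.DataFrame(intra_rows))
    inter_rows = [
        {"group": g, "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for g, r in sorted(stats.icc_inter.items())
    ]
    _write("icc_inter.csv", pd.DataFrame(inter_rows))

    cfg = report.config
    provenance = {
        "seed": cfg.seed,
        "n_repetitions": cfg.n_repetitions,
        "n_operators": cfg.n_operators,
        "points_per_concave": cfg.points_per_concave,
        "cap_half_angle_deg": cfg.cap_half_angle_deg,
        "sigma_contact_mm": cfg.noise.sigma_contact,
        "sigma_scan_mm": cfg.noise.sigma_scan,
        "n_probe_repeats": cfg.noise.n_probe_repeats,
        "n_scan_repeats": cfg.noise.n_scan_repeats,
        "operator_subsample_fraction": list(cfg.subsample_fractions()),
        "n_units": report.n_units(),
        "normality_prechecks": "not run (delegate to stock routines if needed)",
        "summary": json.loads(report.summary_frame().to_json(orient="records")),
    }
    path = out / "report.json"
    path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    written.append(path)
    return written
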