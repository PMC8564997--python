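import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from occlureg import NoiseModel, SimulationConfig, icc_single, one_way_anova, run_experiment, tukey_hsd
from occlureg.exceptions import UndefinedStatisticError
from occlureg.stats_report import (
    TWO_WAY_MIXED_ABSOLUTE_SINGLE,
    TWO_WAY_RANDOM_CONSISTENCY_SINGLE,
    experiment_statistics,
    intra_inter_operator_report,
    write_report_tables,
)


class TestAnova:
    def test_hand_computed_example(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4, df = (1, 4)
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(1.5, 1, 4), abs=1e-12)

    def test_identical_groups_give_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [rng.normal(size=rng.integers(3, 10)) for _ in range(rng.integers(2, 6))]
            ref_F, ref_p = sps.f_oneway(*groups)
            mine = one_way_anova(groups)
            assert mine.F == pytest.approx(ref_F, abs=1e-9)
            assert mine.p == pytest.approx(ref_p, abs=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=6) for _ in range(3)]
        base = one_way_anova(groups)
        shifted = one_way_anova([g + 7.5 for g in groups])
        scaled = one_way_anova([g * 3.2 for g in groups])
        assert base.F == pytest.approx(shifted.F, rel=1e-12)
        assert base.F == pytest.approx(scaled.F, rel=1e-12)

    def test_constant_data_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


class TestTukey:
    def test_equal_means_give_p_one(self):
        res = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        for i in range(1, 4):
            for j in range(i + 1, 4):
                assert res.p(i, j) == pytest.approx(1.0, abs=1e-9)
                assert res.diff(i, j) == 0.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [
                rng.normal(rng.normal(), 1, size=rng.integers(5, 12))
                for _ in range(rng.integers(3, 6))
            ]
            ref = sps.tukey_hsd(*groups)
            mine = tukey_hsd(groups)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    assert mine.p(i + 1, j + 1) == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_adjusted_p_not_below_pairwise_t(self):
        # family-wise adjustment can only make a comparison harder
        rng = np.random.default_rng(3)
        for _ in range(50):
            groups = [rng.normal(size=8) for _ in range(4)]
            mine = tukey_hsd(groups)
            for i in range(4):
                for j in range(i + 1, 4):
                    _, p_t = sps.ttest_ind(groups[i], groups[j], equal_var=True)
                    assert mine.p(i + 1, j + 1) >= p_t - 1e-12

    def test_unequal_sizes_supported(self):
        res = tukey_hsd([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]])
        ref = sps.tukey_hsd([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        assert res.p(1, 2) == pytest.approx(ref.pvalue[0, 1], abs=1e-9)


class TestIccSingle:
    def test_identical_raters_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        M = np.column_stack([col, col, col])
        for model in (TWO_WAY_MIXED_ABSOLUTE_SINGLE, TWO_WAY_RANDOM_CONSISTENCY_SINGLE):
            res = icc_single(M, model)
            assert res.icc == pytest.approx(1.0)

    def test_additive_rater_shift(self):
        # consistency ignores a constant column offset; absolute agreement does not
        M = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        cons = icc_single(M, TWO_WAY_RANDOM_CONSISTENCY_SINGLE)
        absag = icc_single(M, TWO_WAY_MIXED_ABSOLUTE_SINGLE)
        assert cons.icc == pytest.approx(1.0)
        # hand mean squares: MSR = 8, MSC = 1.5, MSE = 0 → ICC(A,1) = 8/9
        assert absag.icc == pytest.approx(8.0 / 9.0, abs=1e-12)
        assert absag.icc < 1.0

    def test_column_shift_invariance_of_consistency_only(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1)) * 2
        shifted = M + np.array([0.0, 5.0, -3.0])
        cons0 = icc_single(M, TWO_WAY_RANDOM_CONSISTENCY_SINGLE)
        cons1 = icc_single(shifted, TWO_WAY_RANDOM_CONSISTENCY_SINGLE)
        assert cons0.icc == pytest.approx(cons1.icc, abs=1e-12)
        abs0 = icc_single(M, TWO_WAY_MIXED_ABSOLUTE_SINGLE)
        abs1 = icc_single(shifted, TWO_WAY_MIXED_ABSOLUTE_SINGLE)
        assert abs(abs0.icc - abs1.icc) > 1e-3

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(50):
            n, k = int(rng.integers(4, 10)), int(rng.integers(2, 5))
            M = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "scores": M.ravel(),
                }
            )
            ref = pg.intraclass_corr(
                df, targets="targets", raters="raters", ratings="scores"
            ).set_index("Type")
            for model, typ in (
                (TWO_WAY_MIXED_ABSOLUTE_SINGLE, "ICC(A,1)"),
                (TWO_WAY_RANDOM_CONSISTENCY_SINGLE, "ICC(C,1)"),
            ):
                mine = icc_single(M, model)
                assert mine.icc == pytest.approx(ref.loc[typ, "ICC"], abs=1e-6)
                lo, hi = ref.loc[typ, "CI95"]
                # the reference implementation prints CIs rounded to 2 decimals
                assert mine.ci_low == pytest.approx(lo, abs=0.0051)
                assert mine.ci_high == pytest.approx(hi, abs=0.0051)

    def test_constant_matrix_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_single(np.full((4, 3), 2.0), TWO_WAY_MIXED_ABSOLUTE_SINGLE)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            M = rng.normal(size=(5, 4)) + rng.normal(size=(5, 1))
            for model in (TWO_WAY_MIXED_ABSOLUTE_SINGLE, TWO_WAY_RANDOM_CONSISTENCY_SINGLE):
                res = icc_single(M, model)
                assert res.ci_low <= res.icc <= res.ci_high <= 1.0


class TestOperatorReliability:
    def test_zero_noise_reliability_saturates(self, zero_noise_report):
        # with zero noise every repetition reproduces the reference distances,
        # so all residual mean squares vanish and every ICC is exactly 1
        intra, inter = intra_inter_operator_report(zero_noise_report)
        for res in list(intra.values()) + list(inter.values()):
            assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_default_noise_iccs_in_unit_interval(self, small_report):
        intra, inter = intra_inter_operator_report(small_report)
        assert len(intra) == 7 * small_report.config.n_operators
        assert len(inter) == 7
        for res in list(intra.values()) + list(inter.values()):
            assert 0.0 < res.icc <= 1.0

    def test_wider_subsample_gap_lowers_inter_icc(self):
        # operators retaining very different point fractions agree less
        def mean_inter(fractions, seed):
            cfg = SimulationConfig(
                operator_subsample_fraction=fractions,
                points_per_concave=60,
                n_repetitions=3,
                seed=seed,
            )
            rep = run_experiment(cfg, compute_stats=False)
            _, inter = intra_inter_operator_report(rep)
            return np.mean([r.icc for r in inter.values()])

        # averaged over seeds, a large asymmetry cannot beat the symmetric setup
        seeds = range(400, 408)
        same = np.mean([mean_inter((0.9, 0.9), s) for s in seeds])
        gap = np.mean([mean_inter((0.9, 0.05), s) for s in seeds])
        assert gap <= same + 1e-6


class TestReportTables:
    def test_written_files_and_shapes(self, small_report, tmp_path):
        files = write_report_tables(small_report, tmp_path)
        names = {f.name for f in files}
        assert {
            "records.csv", "summary.csv", "anova.csv", "tukey.csv",
            "tukey_precision.csv", "icc_intra.csv", "icc_inter.csv", "report.json",
        } <= names
        tukey = pd.read_csv(tmp_path / "tukey.csv", index_col=0, keep_default_na=False)
        assert tukey.shape == (7, 7)
        assert all(tukey.iloc[i, i] == "N/A" for i in range(7))
        off_diag = tukey.values[~np.eye(7, dtype=bool)]
        assert len(off_diag) == 42  # 21 unordered pairs, mirrored
        intra = pd.read_csv(tmp_path / "icc_intra.csv")
        assert len(intra) == 7 * small_report.config.n_operators

    def test_summary_round_trip(self, small_report, tmp_path):
        write_report_tables(small_report, tmp_path)
        back = pd.read_csv(tmp_path / "summary.csv", float_precision="round_trip")
        for _, row in back.iterrows():
            acc = small_report.accuracy[int(row["group"])]
            assert row["trueness_mean"] == acc.trueness_mean
            assert row["precision_sd"] == acc.precision_sd

    def test_rerun_byte_identical(self, small_report, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1 = write_report_tables(small_report, d1)
        f2 = write_report_tables(small_report, d2)
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_experiment_statistics_symmetry(self, small_report):
        stats = small_report.stats or experiment_statistics(small_report)
        assert stats.tukey_trueness.p(1, 4) == stats.tukey_trueness.p(4, 1)
        assert stats.tukey_trueness.diff(1, 4) == -stats.tukey_trueness.diff(4, 1)
        assert 0 <= stats.anova_trueness.p <= 1
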