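"""Tests of the statistics layer against hand computations and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from corespec.exceptions import ConfigurationError, MissingDataError
from corespec.rois import ROI_NAMES
from corespec.stats import (
    StatReport,
    bh_fdr,
    clinical_correlation,
    kruskal_wallis,
    pairwise_posthoc,
    run_stats,
    shapiro_wilk_gate,
    summary_ttest,
)

from _oracles import kw_exact_null_distribution, kw_exact_p, kw_h_statistic, \
    spearman_rank_formula


class TestShapiroGate:
    def test_uniform_flagged_non_normal(self):
        flags = []
        for seed in range(40):
            x = np.random.default_rng(seed).uniform(size=500)
            flags.append(shapiro_wilk_gate(x)[0]["normal"])
        assert np.mean(flags) <= 0.05

    def test_gaussian_calibration(self):
        flags = []
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(500)
            flags.append(shapiro_wilk_gate(x)[0]["normal"])
        assert 0.90 <= np.mean(flags) <= 0.99

    def test_constant_sample_degenerate(self):
        out = shapiro_wilk_gate(np.ones(10))[0]
        assert out["degenerate"] and not out["normal"]

    def test_too_small(self):
        with pytest.raises(ConfigurationError):
            shapiro_wilk_gate(np.array([1.0, 2.0]))


class TestKruskalWallis:
    def test_hand_computed_fixture(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9], method="chi2")
        assert h == pytest.approx(7.2)
        # cross-check against the rank-sum oracle
        assert kw_h_statistic(
            [np.array([1., 2, 3]), np.array([4., 5, 6]), np.array([7., 8, 9])]
        ) == pytest.approx(7.2)

    def test_identical_groups_convention(self):
        h, p = kruskal_wallis([5, 5, 5], [5, 5], [5, 5, 5])
        assert (h, p) == (0.0, 1.0)

    def test_exact_matches_enumeration_oracle(self):
        null = kw_exact_null_distribution((3, 3, 3))
        rng = np.random.default_rng(0)
        for _ in range(5):
            groups = [rng.standard_normal(3) for _ in range(3)]
            h, p_exact = kruskal_wallis(*groups, method="exact")
            assert p_exact == pytest.approx(kw_exact_p(h, null))

    def test_chi2_close_to_exact_permutation(self):
        """Asymptotic p close to the enumerated permutation null.

        The comparison uses the mid-p convention (half weight on the
        observed atom), the standard way to compare a discrete permutation
        distribution against a continuous reference.
        """
        null = kw_exact_null_distribution((4, 4, 4))
        rng = np.random.default_rng(7)
        deviations = []
        for _ in range(100):
            groups = [rng.standard_normal(4) for _ in range(3)]
            h, p_chi2 = kruskal_wallis(*groups, method="chi2")
            deviations.append(abs(p_chi2 - kw_exact_p(h, null, mid_p=True)))
        assert np.mean(deviations) < 0.02

    def test_input_validation(self):
        with pytest.raises(ConfigurationError):
            kruskal_wallis([1.0, 2.0])
        with pytest.raises(ConfigurationError):
            kruskal_wallis([1.0], [2.0])


class TestPairwisePosthoc:
    def test_three_group_multiplier(self, rng):
        samples = {g: rng.standard_normal(10) for g in ("a", "b", "c")}
        out = pairwise_posthoc(samples)
        assert len(out) == 3
        for res in out.values():
            expected = min(1.0, res["p_raw"] * 3)
            assert res["p_adjusted"] == pytest.approx(expected)
            assert res["p_adjusted"] >= res["p_raw"]

    def test_clipping_at_one(self):
        samples = {"a": [1.0, 2.0, 3.0], "b": [1.5, 2.5, 3.5],
                   "c": [1.2, 2.2, 3.2]}
        out = pairwise_posthoc(samples)
        assert all(res["p_adjusted"] <= 1.0 for res in out.values())

    def test_single_group_rejected(self):
        with pytest.raises(ConfigurationError):
            pairwise_posthoc({"a": [1.0, 2.0]})


class TestBhFdr:
    def test_step_up_fixture(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.25])
        adjusted, reject = bh_fdr(p, q=0.05)
        assert list(reject) == [True, True, True, True, False]
        assert np.allclose(adjusted[:4], 0.05)
        assert adjusted[4] == pytest.approx(0.25)

    def test_all_ones(self):
        adjusted, reject = bh_fdr(np.ones(10))
        assert not reject.any()
        assert np.all(adjusted == 1.0)

    def test_single_p_identity(self):
        adjusted, reject = bh_fdr(np.array([0.04]))
        assert adjusted[0] == pytest.approx(0.04)
        assert reject[0]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, p_list):
        p = np.array(p_list)
        adjusted, _ = bh_fdr(p)
        assert np.all(adjusted + 1e-12 >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_fdr(np.array([0.5, 1.5]))

    def test_controls_empirical_fdr_on_mixture(self):
        """Mean false-discovery proportion <= q on 80/20 null mixtures."""
        rng = np.random.default_rng(11)
        m, reps = 200, 200
        fdps = []
        for _ in range(reps):
            null = rng.uniform(size=int(0.8 * m))
            alt = rng.beta(0.1, 1.0, size=m - len(null))
            p = np.concatenate([null, alt])
            is_null = np.arange(m) < len(null)
            _, reject = bh_fdr(p, q=0.05)
            r = reject.sum()
            fdps.append((reject & is_null).sum() / max(r, 1))
        assert np.mean(fdps) <= 0.07


class TestClinicalCorrelation:
    def test_exact_linear_pearson(self):
        x = np.random.default_rng(0).standard_normal(60)
        r, p, method = clinical_correlation(x, 2 * x + 1)
        assert method == "pearson"
        assert r == pytest.approx(1.0)

    def test_monotone_decreasing_spearman(self):
        x = np.random.default_rng(1).standard_normal(60)
        y = -np.exp(3 * x)  # heavy-tailed: fails the normality gate
        r, p, method = clinical_correlation(x, y)
        assert method == "spearman"
        assert r == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 0.5, 3.0])
        from scipy.stats import spearmanr

        assert spearmanr(x, y)[0] == pytest.approx(spearman_rank_formula(x, y))

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            clinical_correlation(np.ones(10), np.arange(10.0))


class TestSummaryTtest:
    # published group summaries: CI vs CNI WISC-IV indices, n = 24 each
    TABLE = {
        "FSIQ": (84.63, 4.79, 107.79, 8.03),
        "VCI": (82.96, 9.12, 104.96, 12.23),
        "PRI": (88.5, 10.44, 111.79, 7.37),
        "WMI": (88.29, 8.47, 100.79, 10.01),
    }

    @pytest.mark.parametrize("index", list(TABLE))
    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_wisc_indices_below_point_001(self, index, variant):
        m1, s1, m2, s2 = self.TABLE[index]
        t, df, p = summary_ttest(m1, s1, 24, m2, s2, 24, variant=variant)
        assert p < 0.001

    def test_pooled_fsiq_t_value(self):
        t, df, p = summary_ttest(84.63, 4.79, 24, 107.79, 8.03, 24,
                                 variant="pooled")
        # direct pooled-variance formula as in-test oracle
        sp2 = (23 * 4.79**2 + 23 * 8.03**2) / 46
        t_direct = (84.63 - 107.79) / np.sqrt(sp2 * (2 / 24))
        assert t == pytest.approx(t_direct)
        assert abs(t) == pytest.approx(12.1, abs=0.1)
        assert df == 46

    def test_resampling_cross_check(self, rng):
        """Summary-statistic t equals sample t on samples matching the summary."""
        from scipy.stats import ttest_ind

        def samples(mean, sd, n, seed):
            x = np.random.default_rng(seed).standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = samples(84.63, 4.79, 24, 0)
        b = samples(107.79, 8.03, 24, 1)
        t_samp, p_samp = ttest_ind(a, b)
        t_sum, df, p_sum = summary_ttest(84.63, 4.79, 24, 107.79, 8.03, 24,
                                         variant="pooled")
        assert t_samp == pytest.approx(t_sum)
        assert p_samp == pytest.approx(p_sum)

    def test_identical_summaries(self):
        t, df, p = summary_ttest(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            summary_ttest(1.0, 0.0, 10, 2.0, 1.0, 10)
        with pytest.raises(ConfigurationError):
            summary_ttest(1.0, 1.0, 1, 2.0, 1.0, 10)


def _synthetic_power_table(rng, n_per_group=10, bands=("delta", "alpha"),
                           shift_cell=None, shift=0.0):
    rows = []
    sid = 0
    for group in ("CI", "CNI", "HC"):
        for _ in range(n_per_group):
            sid += 1
            for roi in ROI_NAMES:
                for band in bands:
                    value = rng.normal(0.2, 0.02)
                    if shift_cell == (group, roi, band):
                        value += shift
                    rows.append({
                        "subject_id": f"S{sid:03d}", "group": group,
                        "roi": roi, "band": band, "value": value,
                    })
    return pd.DataFrame(rows)


def _synthetic_manifest(table, rng):
    subjects = table[["subject_id", "group"]].drop_duplicates()
    manifest = subjects.copy()
    n = len(manifest)
    manifest["onset_age"] = rng.normal(8, 1.5, n)
    manifest["course_months"] = rng.normal(6, 2, n)
    manifest["seizure_count"] = rng.normal(3, 1, n)
    return manifest


class TestRunStats:
    def test_planted_shift_detected_and_report_roundtrip(self, rng, tmp_path):
        table = _synthetic_power_table(
            rng, shift_cell=("CI", "PCC.L", "delta"), shift=0.1
        )
        manifest = _synthetic_manifest(table, rng)
        report = run_stats(table, manifest)
        assert "PCC.L" in report.rejection_set("CI-HC", "delta")
        assert "PCC.L" not in report.rejection_set("CI-HC", "alpha")
        # omnibus rows carry H; pairwise rows carry the Bonferroni p
        omnibus = report.tests[report.tests.contrast == "omnibus"]
        assert omnibus["H"].notna().all()
        pairwise = report.tests[report.tests.contrast != "omnibus"]
        assert (pairwise["p_bonf"] + 1e-12 >= pairwise["p_raw"]).all()

        report.save(tmp_path)
        loaded = StatReport.load(tmp_path)
        pd.testing.assert_frame_equal(loaded.tests, report.tests)
        pd.testing.assert_frame_equal(loaded.correlations, report.correlations)

    def test_missing_cells_rejected(self, rng):
        table = _synthetic_power_table(rng)
        incomplete = table.iloc[:-1]
        with pytest.raises(MissingDataError):
            run_stats(incomplete, _synthetic_manifest(table, rng))

    def test_correlation_block_structure(self, rng):
        table = _synthetic_power_table(rng, n_per_group=8, bands=("delta",))
        manifest = _synthetic_manifest(table, rng)
        report = run_stats(table, manifest)
        corr = report.correlations
        assert set(corr["group"]) == {"CI", "CNI"}
        assert set(corr["covariate"]) == {
            "onset_age", "course_months", "seizure_count"
        }
        assert set(corr["method"]) <= {"pearson", "spearman"}
        assert (corr["p_fdr"] + 1e-12 >= corr["p_raw"]).all()
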