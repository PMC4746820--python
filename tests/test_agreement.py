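"""Equivalence testing, error metrics, and Bland–Altman agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedaltrack import (
    CadenceProfile,
    DeviceErrorModel,
    RunConfig,
    StudyDesign,
    apply_device,
    bland_altman,
    build_report,
    differences,
    equivalence_paired_t,
    equivalence_random_intercept,
    equivalence_t,
    error_metrics,
    simulate_study,
)
from pedaltrack.aggregate import PairedSeries


def pairs_frame(d, subjects=None, criterion_level=55.0):
    """Pairs whose differences are exactly d (criterion − test)."""
    d = np.asarray(d, dtype=float)
    subjects = (
        np.asarray(subjects)
        if subjects is not None
        else np.array([f"S{i:03d}" for i in range(d.size)])
    )
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "time": np.arange(d.size),
            "criterion": criterion_level + d / 2,
            "test": criterion_level - d / 2,
        }
    )


class TestDifferences:
    @pytest.mark.parametrize(
        "c, t, expected", [(55.0, 56.0, -1.0), (60.0, 60.0, 0.0), (56.4, 56.3, 0.1)]
    )
    def test_sign_convention_criterion_minus_test(self, c, t, expected):
        p = PairedSeries("S01", "minute", [0], [c], [t])
        assert differences(p)["diff"].iloc[0] == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            differences([])

    def test_order_and_labels_preserved(self):
        df = pairs_frame([1.0, -2.0, 0.5])
        out = differences(df)
        np.testing.assert_allclose(out["diff"], [1.0, -2.0, 0.5])
        assert list(out["subject_id"]) == list(df["subject_id"])


class TestEquivalencePairedT:
    def test_ci_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.normal(-1.0, 0.3, 41)
        res = equivalence_paired_t(pairs_frame(d))
        lo, hi = stats.ttest_1samp(d, 0.0).confidence_interval(0.95)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)
        assert res.mean_difference == pytest.approx(d.mean())

    def test_ci_inside_margin_is_equivalent(self):
        rng = np.random.default_rng(1)
        d = rng.normal(-1.0, 0.3, 41)  # CI ≈ (−1.1, −0.9)
        res = equivalence_paired_t(pairs_frame(d))
        assert -1.5 < res.ci_low and res.ci_high < 1.5
        assert res.equivalent

    def test_wide_ci_not_equivalent(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-0.5, 5.0, 8)
        res = equivalence_paired_t(pairs_frame(d))
        assert not res.equivalent

    def test_all_zero_differences_equivalent_with_zero_se(self):
        res = equivalence_paired_t(pairs_frame(np.zeros(10)))
        assert res.mean_difference == 0.0
        assert res.se == 0.0
        assert res.equivalent

    def test_containment_is_strict(self):
        d = np.array([0.0, 2.0, 4.0])  # mean 2, CI endpoints well defined
        res = equivalence_t(d, margin=2.0, alpha=0.025)
        # margin exactly at an endpoint must fail containment
        strict = equivalence_t(d, margin=res.ci_high, alpha=0.025)
        assert not strict.equivalent

    def test_replicated_subjects_rejected(self):
        df = pairs_frame([1.0, 2.0], subjects=["S1", "S1"])
        with pytest.raises(ValueError, match="one pair per subject"):
            equivalence_paired_t(df)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            equivalence_paired_t(pairs_frame([1.0]))

    @pytest.mark.parametrize("scale", [1.5, 2.0, 10.0])
    def test_equivalence_monotone_in_margin(self, scale):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1.0, 20)
        base = equivalence_paired_t(pairs_frame(d), margin=1.5)
        wider = equivalence_paired_t(pairs_frame(d), margin=1.5 * scale)
        assert not base.equivalent or wider.equivalent


class TestEquivalenceRandomIntercept:
    def test_balanced_design_matches_subject_means_t(self):
        rng = np.random.default_rng(5)
        n, m = 12, 20
        d = (rng.normal(-1.0, 0.8, n)[:, None] + rng.normal(0, 1.5, (n, m))).ravel()
        df = pairs_frame(d, subjects=np.repeat([f"S{i}" for i in range(n)], m))
        res = equivalence_random_intercept(df)
        means = df.assign(d=df.criterion - df.test).groupby("subject_id")["d"].mean()
        assert res.mean_difference == pytest.approx(means.mean(), abs=1e-6)
        assert res.se == pytest.approx(means.std(ddof=1) / math.sqrt(n), abs=1e-6)
        oracle = equivalence_t(means.to_numpy())
        assert res.equivalent == oracle.equivalent

    def test_recovers_generating_mean_difference(self):
        rng = np.random.default_rng(42)
        n, m = 41, 20
        d = (rng.normal(-1.0, 0.5, n)[:, None] + rng.normal(0, 2.0, (n, m))).ravel()
        df = pairs_frame(d, subjects=np.repeat([f"S{i:02d}" for i in range(n)], m))
        res = equivalence_random_intercept(df)
        assert abs(res.mean_difference - (-1.0)) < 3 * res.se

    def test_unbalanced_fit_close_to_subject_means(self):
        rng = np.random.default_rng(8)
        sizes = rng.integers(5, 30, 15)
        rows = []
        for i, m in enumerate(sizes):
            rows.append(
                pairs_frame(
                    rng.normal(-1.0, 1.0) + rng.normal(0, 1.5, m),
                    subjects=np.repeat(f"S{i:02d}", m),
                )
            )
        df = pd.concat(rows, ignore_index=True)
        res = equivalence_random_intercept(df)
        means = df.assign(d=df.criterion - df.test).groupby("subject_id")["d"].mean()
        assert res.mean_difference == pytest.approx(means.mean(), abs=0.2)
        assert 0 < res.se < 1.0

    def test_identical_differences_degenerate(self):
        df = pairs_frame(np.full(20, -0.7), subjects=np.repeat(["A", "B"], 10))
        res = equivalence_random_intercept(df)
        assert res.mean_difference == pytest.approx(-0.7)
        assert res.se == 0.0

    def test_single_subject_directed_to_paired_t(self):
        df = pairs_frame([1.0, 2.0, 3.0], subjects=["S1"] * 3)
        with pytest.raises(ValueError, match="paired_t"):
            equivalence_random_intercept(df)


class TestErrorMetrics:
    def test_single_pair_mape(self):
        df = pd.DataFrame(
            {"subject_id": ["S1"], "time": [0], "criterion": [50.0], "test": [51.0]}
        )
        assert error_metrics(df).mape == pytest.approx(2.0)

    def test_perfect_agreement(self):
        df = pairs_frame(np.zeros(10))
        em = error_metrics(df)
        assert em.mape == 0.0
        assert em.pct_within_1 == 100.0
        assert math.isnan(em.pearson_r)  # zero variance: undefined, flagged

    def test_threshold_counting_is_strict(self):
        df = pd.DataFrame(
            {
                "subject_id": ["S1", "S2"],
                "time": [0, 1],
                "criterion": [50.0, 50.0],
                "test": [50.5, 54.0],
            }
        )
        em = error_metrics(df)
        assert em.pct_within_1 == 50.0
        assert em.pct_within_3 == 50.0
        assert em.pct_within_5 == 100.0

    def test_within_percentages_monotone(self):
        rng = np.random.default_rng(3)
        df = pairs_frame(rng.normal(0, 3, 200))
        em = error_metrics(df)
        assert em.pct_within_1 <= em.pct_within_3 <= em.pct_within_5

    def test_zero_criterion_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["S1"], "time": [0], "criterion": [0.0], "test": [1.0]}
        )
        with pytest.raises(ValueError):
            error_metrics(df)

    def test_mape_matches_brute_force_for_multiplicative_bias(self):
        rng = np.random.default_rng(6)
        c = rng.uniform(40, 70, 100)
        b = 0.018
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(100)],
                "time": np.arange(100),
                "criterion": c,
                "test": c * (1 + b),
            }
        )
        em = error_metrics(df)
        brute = np.mean(np.abs(c - c * (1 + b)) / c * 100)
        assert em.mape == pytest.approx(brute)
        assert em.mape == pytest.approx(100 * b)


class TestBlandAltman:
    def test_simple_mode_is_sample_sd(self):
        rng = np.random.default_rng(10)
        d = rng.normal(-1, 1.2, 40)
        df = pairs_frame(d)
        res = bland_altman(df, "simple")
        assert res.bias == pytest.approx(d.mean())
        assert res.sd_difference == pytest.approx(d.std(ddof=1))
        assert res.loa_low == pytest.approx(res.bias - 1.96 * res.sd_difference)
        assert res.loa_high == pytest.approx(res.bias + 1.96 * res.sd_difference)

    def test_single_subject_with_no_between_variance_reduces_to_simple(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0, 1, 30)
        two = pairs_frame(d, subjects=np.repeat(["A", "B"], 15))
        # force zero between-variance by centering each half
        d2 = np.concatenate([d[:15] - d[:15].mean(), d[15:] - d[15:].mean()])
        df = pairs_frame(d2, subjects=np.repeat(["A", "B"], 15))
        res = bland_altman(df, "linked_replicates")
        assert res.variance_between == 0.0
        assert res.sd_difference == pytest.approx(math.sqrt(res.variance_within))

    def test_linked_recovers_variance_components(self):
        rng = np.random.default_rng(13)
        n, m = 50, 20
        d = (rng.normal(-1.0, 1.0, n)[:, None] + rng.normal(0, 1.5, (n, m))).ravel()
        df = pairs_frame(d, subjects=np.repeat([f"S{i:02d}" for i in range(n)], m))
        res = bland_altman(df, "linked_replicates")
        assert res.sd_difference == pytest.approx(math.hypot(1.0, 1.5), rel=0.10)

    def test_linked_sd_at_least_within_sd(self):
        rng = np.random.default_rng(14)
        n, m = 20, 10
        d = (rng.normal(0, 2.0, n)[:, None] + rng.normal(0, 1.0, (n, m))).ravel()
        df = pairs_frame(d, subjects=np.repeat([f"S{i:02d}" for i in range(n)], m))
        res = bland_altman(df, "linked_replicates")
        assert res.variance_between > 0
        assert res.sd_difference >= math.sqrt(res.variance_within)

    def test_slope_recovers_constructed_proportional_bias(self):
        mean = np.linspace(40, 70, 50)
        d = 0.1 * mean - 5.0
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(50)],
                "time": np.arange(50),
                "criterion": mean + d / 2,
                "test": mean - d / 2,
            }
        )
        res = bland_altman(df, "simple")
        assert res.slope == pytest.approx(0.1, abs=1e-9)
        assert res.slope_p < 1e-12

    def test_linked_single_subject_rejected(self):
        df = pairs_frame([1.0, 2.0], subjects=["S1", "S1"])
        with pytest.raises(ValueError):
            bland_altman(df, "linked_replicates")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_frame([1.0, 2.0]), "fancy")


class TestBuildReport:
    def test_self_comparison_is_perfect(self, small_study):
        reports = build_report(small_study.criterion, small_study.criterion)
        for rep in reports.values():
            assert rep.equivalence.mean_difference == pytest.approx(0.0)
            assert rep.errors.mape == pytest.approx(0.0)
            assert rep.errors.pct_within_1 == 100.0
            assert rep.equivalence.equivalent
            assert rep.bland_altman.loa_high - rep.bland_altman.loa_low == pytest.approx(0.0)

    def test_multiplicative_bias_shows_up_as_mape(self):
        study = simulate_study(
            StudyDesign(n_subjects=6, seed=3),
            criterion_model=DeviceErrorModel(kind="perfect"),
            test_model=DeviceErrorModel(kind="compound", rate_scale=1.018),
            profile=CadenceProfile(within_sd=1.0),
        )
        reports = build_report(study.criterion, study.test)
        trial = reports["trial"]
        # pure multiplicative bias b (test = criterion·(1+b)): MAPE ≈ 100·b
        assert trial.errors.mape == pytest.approx(100 * 0.018, rel=0.12)
        assert trial.equivalence.mean_difference < 0

    def test_report_structure_and_counts(self, small_study):
        reports = build_report(small_study.criterion, small_study.test)
        assert set(reports) == {"minute", "trial"}
        assert reports["trial"].n_pairs == reports["trial"].n_subjects
        assert reports["minute"].n_pairs >= reports["minute"].n_subjects >= 1
        assert reports["minute"].bland_altman.mode == "linked_replicates"
        assert reports["trial"].bland_altman.mode == "simple"

    def test_disjoint_subjects_rejected(self, small_study):
        import dataclasses

        renamed = [
            dataclasses.replace(s, subject_id=s.subject_id + "_x")
            for s in small_study.test
        ]
        with pytest.raises(ValueError):
            build_report(small_study.criterion, renamed)

    def test_config_margin_controls_verdict(self, small_study):
        tight = RunConfig(margin=0.05)
        reports = build_report(small_study.criterion, small_study.test, tight)
        assert not reports["trial"].equivalence.equivalent
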