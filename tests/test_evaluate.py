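"""Evaluation statistics against independent oracles.

AUC is checked against exhaustive pair counting and the ROC trapezoid,
Youden thresholds against brute-force maximisation over every candidate
cut, the DeLong machinery against bootstrap/permutation references and R's
pROC, and the contingency statistics against published worked values.
"""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from motifscreen.evaluate import (
    auc,
    chisq_independence,
    delong_ci,
    delong_paired_test,
    kruskal_wallis,
    marker_threshold_classifier,
    proportion_ci,
    roc_curve_points,
    screening_metrics,
    trapezoidal_auc,
    youden_threshold,
)


def pair_count_auc(scores, labels):
    """Oracle: explicit count over all (case, control) pairs, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        # 3 of 4 (case, control) pairs won
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_all_tied(self):
        assert auc([0.3] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 51)
            y = np.zeros(n, dtype=int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            assert auc(scores, y) == pytest.approx(pair_count_auc(scores, y))

    def test_matches_roc_trapezoid(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(6, 40)
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            scores = rng.normal(size=n) + y
            curve = roc_curve_points(scores, y)
            assert trapezoidal_auc(curve) == pytest.approx(auc(scores, y), abs=1e-9)

    def test_roc_curve_monotone_with_endpoints(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        curve = roc_curve_points(rng.normal(size=40) + y, y)
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)
        assert (curve.sensitivity[0], curve.specificity[0]) == (1.0, 0.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (0.0, 1.0)


class TestDeLong:
    def test_point_estimate_equals_auc(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        s = rng.normal(size=60) + 0.8 * y
        assert delong_ci(s, y).auc == pytest.approx(auc(s, y))

    def test_perfect_separation_degenerates_to_point_ci(self):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        s = np.r_[np.zeros(10), np.ones(10)]
        est = delong_ci(s, y)
        assert est.variance == 0.0
        assert (est.ci_lower, est.ci_upper) == (1.0, 1.0)
        assert not est.degenerate  # AUC not interior

    def test_se_close_to_bootstrap(self):
        rng = np.random.default_rng(101)
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        s = np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 30)]
        est = delong_ci(s, y)
        boot = []
        for _ in range(10_000):
            i0 = rng.integers(0, 30, 30)
            i1 = 30 + rng.integers(0, 30, 30)
            boot.append(auc(s[np.r_[i0, i1]], y))
        boot_se = np.std(boot, ddof=1)
        assert np.sqrt(est.variance) == pytest.approx(boot_se, rel=0.15)

    def test_self_comparison_p_is_one(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        s = rng.normal(size=40) + y
        cmp = delong_paired_test(s, s, y)
        assert cmp.delta == 0.0 and cmp.p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        a = rng.normal(size=50) + y
        b = rng.normal(size=50) + 0.3 * y
        ab = delong_paired_test(a, b, y)
        ba = delong_paired_test(b, a, y)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_informative_vs_noise_rejects(self):
        rng = np.random.default_rng(7)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        a = y + rng.normal(0, 0.7, n)
        b = rng.normal(size=n)
        cmp = delong_paired_test(a, b, y)
        assert cmp.p < 0.01
        # permutation oracle agrees on rejection: permute which model label
        # attaches to each paired score vector via sign flips of the
        # per-sample contribution is nontrivial; use label-preserving
        # swap of (a, b) per sample
        swaps = 0
        reps = 500
        obs = abs(cmp.delta)
        for _ in range(reps):
            flip = rng.random(n) < 0.5
            a2 = np.where(flip, b, a)
            b2 = np.where(flip, a, b)
            if abs(auc(a2, y) - auc(b2, y)) >= obs:
                swaps += 1
        assert swaps / reps < 0.01

    def test_agrees_with_r_proc(self, tmp_path):
        """Cross-check DeLong p-value and CI against pROC on one fixture."""
        rng = np.random.default_rng(33)
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        a = rng.normal(size=80) + 0.9 * y
        b = rng.normal(size=80) + 0.3 * y
        est = delong_ci(a, y)
        cmp = delong_paired_test(a, b, y)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(pROC))
            y <- c({','.join(str(int(v)) for v in y)})
            a <- c({','.join(f'{v:.17g}' for v in a)})
            b <- c({','.join(f'{v:.17g}' for v in b)})
            ra <- roc(y, a, quiet=TRUE, direction="<")
            rb <- roc(y, b, quiet=TRUE, direction="<")
            ci <- ci.auc(ra, method="delong")
            tt <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(ci[1], ci[3], tt$p.value, sep="\\n")
            """
        )
        path = tmp_path / "delong.R"
        path.write_text(script)
        out = subprocess.run(
            ["Rscript", str(path)], capture_output=True, text=True, check=True
        ).stdout.split()
        r_lo, r_hi, r_p = map(float, out)
        assert est.ci_lower == pytest.approx(r_lo, abs=1e-6)
        assert est.ci_upper == pytest.approx(r_hi, abs=1e-6)
        assert cmp.p == pytest.approx(r_p, abs=1e-6)


class TestYouden:
    def test_separable_midpoint(self):
        t, j = youden_threshold([0.2, 0.3, 0.7, 0.8], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)
        assert j == pytest.approx(1.0)

    def test_all_identical_scores(self):
        t, j = youden_threshold([0.4] * 8, [0, 0, 0, 0, 1, 1, 1, 1])
        assert j == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(6, 60)
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            t, j = youden_threshold(scores, y)
            pos, neg = scores[y == 1], scores[y == 0]
            uniq = np.unique(scores)
            cands = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2, np.inf]
            best = max((pos >= c).mean() + (neg < c).mean() - 1 for c in cands)
            assert j == pytest.approx(best)
            assert (pos >= t).mean() + (neg < t).mean() - 1 == pytest.approx(best)

    def test_tie_breaks_toward_higher_sensitivity(self):
        # threshold below all scores (everything positive) and above all
        # (everything negative) both give J=0; higher sensitivity wins
        t, j = youden_threshold([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        pos = np.array([0.5, 0.5])
        assert (pos >= t).mean() == 1.0


class TestScreening:
    def test_printed_wald_ci_examples(self):
        lo, hi = proportion_ci(25, 26)
        assert round(100 * lo, 1) == 88.8
        assert hi == 1.0
        lo, hi = proportion_ci(10, 11)
        assert round(100 * lo, 1) == 73.9
        assert hi == 1.0

    def test_full_sensitivity_clips_upper(self):
        lo, hi = proportion_ci(12, 12)
        assert hi == 1.0

    def test_wilson_interval_is_interior(self):
        lo, hi = proportion_ci(25, 26, method="wilson")
        assert 0 < lo < 25 / 26 < hi < 1

    def test_threshold_above_max(self, cohort_default):
        meta = cohort_default["meta"]
        scores = np.linspace(0, 1, len(meta))
        report = screening_metrics(scores, meta, threshold=2.0)
        assert report.sensitivity.percent == 0.0
        assert report.specificity.percent == 100.0

    def test_confusion_sums_to_n(self, cohort_default):
        meta = cohort_default["meta"]
        rng = np.random.default_rng(0)
        report = screening_metrics(rng.random(len(meta)), meta, threshold=0.5)
        assert sum(report.confusion.values()) == len(meta)
        # subgroup sensitivities only over case subgroups
        assert set(report.subgroup_sensitivity) <= {
            "LGIN", "HGIN", "StageI", "StageII", "StageIII", "StageIV",
        }

    def test_marker_direction_flip_inverts_calls(self, cohort_default):
        meta = cohort_default["meta"]
        rng = np.random.default_rng(1)
        values = rng.lognormal(size=len(meta))
        hi_calls, _ = marker_threshold_classifier(values, meta, 1.0, "high_is_positive")
        lo_calls, _ = marker_threshold_classifier(values, meta, 1.0, "low_is_positive")
        # calls disagree except exactly on the threshold
        on_thr = values == 1.0
        assert np.array_equal(hi_calls[~on_thr], ~lo_calls[~on_thr])

    def test_marker_all_above_threshold(self, cohort_default):
        meta = cohort_default["meta"]
        values = np.full(len(meta), 5.0)
        _, report = marker_threshold_classifier(values, meta, 1.0)
        assert report.sensitivity.percent == 100.0
        assert report.specificity.percent == 0.0

    def test_marker_missing_values_excluded(self, cohort_default):
        meta = cohort_default["meta"]
        values = np.linspace(0.1, 2.0, len(meta))
        values[:5] = np.nan
        calls, report = marker_threshold_classifier(values, meta, 1.0)
        assert len(calls) == len(meta) - 5
        assert any("5 sample(s) excluded" in n for n in report.notes)

    def test_marker_auc_matches_binormal_closed_form(self):
        # log-scale shifted log-normal: AUC = Phi(delta / sqrt(2) / sigma)
        rng = np.random.default_rng(55)
        sigma, shift = 0.5, 1.5
        n = 200
        neg = rng.lognormal(0.0, sigma, n)
        pos = rng.lognormal(np.log(shift), sigma, n)
        values = np.r_[neg, pos]
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        expected = stats.norm.cdf(np.log(shift) / np.sqrt(2 * sigma**2))
        assert auc(values, y) == pytest.approx(expected, abs=0.04)


class TestContingency:
    def test_uniform_2x2(self):
        chi2, df, p = chisq_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0 and df == 1

    @pytest.mark.parametrize(
        "table, expected_chi2, expected_df",
        [
            # published baseline tables: category x (train, val, test)
            ([[149, 69, 97], [91, 34, 51]], 0.93, 2),  # sex
            ([[55, 34, 36], [160, 62, 98], [25, 7, 14]], 4.50, 4),  # smoking
            ([[63, 33, 41], [151, 63, 92], [26, 7, 15]], 2.13, 4),  # drinking
            (
                [[50, 15, 26], [62, 38, 47], [30, 8, 14], [15, 7, 7], [83, 35, 54]],
                7.26,
                8,
            ),  # group
            (
                [
                    [23, 8, 15],
                    [27, 7, 11],
                    [51, 35, 38],
                    [11, 3, 9],
                    [21, 6, 8],
                    [9, 2, 6],
                    [15, 7, 7],
                    [83, 35, 54],
                ],
                11.90,
                14,
            ),  # subgroup
        ],
    )
    def test_published_baseline_tables(self, table, expected_chi2, expected_df):
        chi2, df, p = chisq_independence(table)
        assert round(chi2, 2) == expected_chi2
        assert df == expected_df

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence([[0, 0], [5, 5]])

    def test_yates_only_2x2(self):
        with pytest.raises(ValueError):
            chisq_independence([[1, 2, 3], [4, 5, 6]], correction=True)


class TestKruskal:
    def test_identical_groups(self):
        h, p = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(0.0)

    def test_hand_computed_value(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert round(h, 3) == 3.857

    def test_all_constant(self):
        h, p = kruskal_wallis([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_p_matches_permutation_null(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=30)
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        h_obs, p_obs = kruskal_wallis(values, groups)
        count = 0
        reps = 10_000
        for _ in range(reps):
            h, _ = kruskal_wallis(values, rng.permutation(groups))
            count += h >= h_obs
        assert p_obs == pytest.approx(count / reps, abs=0.03)
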