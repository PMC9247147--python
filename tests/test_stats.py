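"""Nonparametric battery: against closed forms, scipy cross-checks, and
exhaustive permutation oracles at tiny n."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crpcoord import (DataError, DegenerateSignalError, compare_tasks,
                      effect_size_r, friedman, holm_adjust, kruskal_wallis,
                      ks_normality, median_ci, wilcoxon_signed_rank)


class TestKSNormality:
    def test_normal_data_rarely_rejected(self):
        passes = 0
        for s in range(100):
            x = np.random.default_rng(s).normal(size=200)
            passes += ks_normality(x) > 0.05
        assert passes >= 95

    def test_skewed_data_rejected(self):
        rejects = 0
        for s in range(100):
            x = np.exp(np.random.default_rng(s).normal(0, 1.5, size=200))
            rejects += ks_normality(x) < 0.05
        assert rejects >= 95

    def test_constant_sample_is_error(self):
        with pytest.raises(DataError):
            ks_normality(np.full(20, 1.0))

    def test_small_sample_is_error(self):
        with pytest.raises(DataError):
            ks_normality([1.0, 2.0, 3.0])


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        # identical within-row orderings: chi2 = n(k-1) for k = 3
        m = np.tile([1.0, 2.0, 3.0], (10, 1))
        chi2, df, p = friedman(m)
        assert chi2 == pytest.approx(20.0)
        assert df == 2

    def test_identical_conditions_give_zero(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        chi2, df, p = friedman(m)
        assert chi2 == 0.0
        assert p == 1.0

    def test_missing_cells_rejected(self):
        m = np.ones((5, 3))
        m[2, 1] = np.nan
        with pytest.raises(DataError):
            friedman(m)

    def test_chi2_approximation_close_to_exact_permutation_p(self):
        # 6 participants × 3 conditions; five rows ranked (3,2,1), one (1,3,2)
        m = np.array([[3, 2, 1]] * 5 + [[1, 3, 2]], dtype=float)
        chi2, df, p = friedman(m)
        assert chi2 == pytest.approx(7.0)
        # exact null: all (3!)^6 within-row rank assignments
        perms = list(itertools.permutations([1, 2, 3]))
        count = total = 0
        for combo in itertools.product(perms, repeat=6):
            cs = [sum(row[j] for row in combo) for j in range(3)]
            stat = 12.0 / (6 * 3 * 4) * sum(c * c for c in cs) - 3 * 6 * 4
            count += stat >= chi2 - 1e-9
            total += 1
        assert abs(p - count / total) < 0.01

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = sum(friedman(rng.normal(size=(14, 3)))[2] < 0.05
                         for _ in range(2000))
        assert 0.04 <= rejections / 2000 <= 0.06


class TestWilcoxon:
    def test_all_positive_distinct_differences_closed_form(self):
        # every difference positive, magnitudes distinct: W+ is maximal and
        # Z = [n(n+1)/4] / sqrt(n(n+1)(2n+1)/24) = 3.2958 at n = 14
        y = np.zeros(14)
        x = np.arange(1.0, 15.0)
        z, p = wilcoxon_signed_rank(x, y)
        assert z == pytest.approx(3.2958, abs=1e-3)
        assert round(abs(z), 1) == 3.3

    def test_sign_follows_first_argument(self):
        y = np.zeros(14)
        x = np.arange(1.0, 15.0)
        z_neg, _ = wilcoxon_signed_rank(y, x)
        assert z_neg == pytest.approx(-3.2958, abs=1e-3)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            wilcoxon_signed_rank(np.arange(10.0), np.arange(10.0))

    def test_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(0.5, 1.0, 12)
            y = rng.normal(0.0, 1.0, 12)
            z, p = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, method="approx", correction=False)
            assert abs(z) == pytest.approx(abs(ref.zstatistic), abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approximation_close_to_exact_at_n6(self):
        x = np.array([1.2, 1.5, 0.93, 0.31, 0.75, 0.21])
        y = np.zeros(6)
        z, p = wilcoxon_signed_rank(x, y)
        # exact two-sided p over all 2^6 sign assignments
        ranks = sps.rankdata(np.abs(x))
        mu = 6 * 7 / 4.0
        w_obs = ranks[x > 0].sum()
        dist = [sum(r for bit, r in zip(bits, ranks) if bit)
                for bits in itertools.product([0, 1], repeat=6)]
        p_exact = np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in dist])
        assert abs(p - p_exact) < 0.005


class TestEffectSize:
    @pytest.mark.parametrize("z, n, expected", [
        (-2.6, 14, 0.69), (-3.3, 14, 0.88), (0.0, 14, 0.0),
    ])
    def test_reference_values(self, z, n, expected):
        assert round(effect_size_r(z, n).r, 2) == expected

    @pytest.mark.parametrize("r, label", [
        (0.05, "small"), (0.2, "medium"), (0.4, "medium"), (0.7, "large"),
    ])
    def test_magnitude_classification(self, r, label):
        assert effect_size_r(r, 1).magnitude == label


class TestKruskalWallis:
    def test_identical_groups_have_zero_h(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == 0.0

    def test_maximal_separation_closed_form(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
        assert h == pytest.approx(27.0 / 7.0)  # 3.857…

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            kruskal_wallis([[1.0, 2.0], []])

    def test_chi2_approximation_close_to_exact_permutation_p(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0, 8.0])
        g2 = np.array([5.0, 6.0, 7.0, 9.0, 10.0])
        h, p = kruskal_wallis([g1, g2])
        pooled = np.concatenate([g1, g2])
        idx = range(10)
        hs = []
        for pick in itertools.combinations(idx, 5):
            a = pooled[list(pick)]
            b = pooled[[i for i in idx if i not in pick]]
            hs.append(kruskal_wallis([a, b])[0])
        p_exact = np.mean([v >= h - 1e-9 for v in hs])
        assert abs(p - p_exact) < 0.01


class TestMedianCI:
    def test_all_equal_sample_collapses(self):
        med, lo, hi = median_ci(np.full(20, 3.5), seed=0)
        assert med == lo == hi == 3.5

    def test_interval_brackets_median_and_narrows(self):
        x100 = np.arange(1.0, 101.0)
        med, lo, hi = median_ci(x100, seed=1)
        assert lo <= 50.5 <= hi
        x1000 = np.arange(1.0, 1001.0) / 10.0
        _, lo2, hi2 = median_ci(x1000, seed=1)
        assert (hi2 - lo2) < (hi - lo)

    def test_seed_determinism(self):
        x = np.random.default_rng(3).normal(size=30)
        assert median_ci(x, seed=42) == median_ci(x, seed=42)

    def test_small_sample_is_error(self):
        with pytest.raises(DataError):
            median_ci([1.0, 2.0, 3.0])


def test_holm_adjustment_monotone_and_bounded():
    adj = holm_adjust([0.01, 0.04, 0.03, 0.5])
    assert adj == pytest.approx([0.04, 0.09, 0.09, 0.5])
    assert all(a <= 1.0 for a in adj)


@pytest.fixture(scope="module")
def results():
    rng = np.random.default_rng(8)
    rows = []
    for p in range(14):
        dom = "right" if p % 2 else "left"
        for task, (mu_sd, mu_se) in (("UniSTS", (5.3, 0.3)), ("SU", (3.9, 0.35)),
                                     ("Hop", (5.5, 0.9))):
            for side in ("left", "right"):
                rows.append({
                    "participant_id": f"P{p:02d}", "task": task, "side": side,
                    "dominance": "dominant" if side == dom else "nondominant",
                    "sd_mrp": abs(rng.normal(mu_sd, 1.0)),
                    "sampen": abs(rng.normal(mu_se, 0.1)),
                })
    return pd.DataFrame(rows)


class TestCompareTasks:
    def test_report_structurally_complete(self, results):
        report = compare_tasks(results, seed=0, n_boot=500)
        assert len(report.omnibus) == 4            # 2 legs × 2 measures
        assert len(report.pairwise) == 12          # 2 legs × 2 measures × 3 pairs
        assert len(report.medians) == 12           # 2 legs × 2 measures × 3 tasks
        assert len(report.dominance) == 6          # 3 tasks × 2 measures
        for m in report.medians:
            assert m.ci_low <= m.median <= m.ci_high
        for c in report.pairwise:
            assert 0.0 <= c.p <= 1.0 and c.r >= 0.0

    def test_strong_contrast_detected(self, results):
        report = compare_tasks(results, seed=0, n_boot=500)
        hop_su = [c for c in report.pairwise if c.measure == "sampen"
                  and {c.task_a, c.task_b} == {"Hop", "SU"}]
        assert all(c.p < 0.01 and c.magnitude == "large" for c in hop_su)


class TestPowerDirection:
    def test_su_contrasts_dominate_matched_null_contrast(self):
        """With SU's lag spread (4°) below the other tasks' (6°), the SU
        sdMRP contrasts should be significant far more often, and with
        larger effect sizes, than the UniSTS-vs-Hop contrast (a true null)."""
        from crpcoord.pipeline import RunConfig, analyze_cohort
        from crpcoord.synthetic import generate_cohort
        su_sig = null_sig = 0
        su_r, null_r = [], []
        for s in range(10):
            df = analyze_cohort(generate_cohort(n_participants=14, seed=7000 + s),
                                RunConfig(seed=0))
            for leg in ("left", "right"):
                wide = df[df["side"] == leg].pivot_table(
                    index="participant_id", columns="task", values="sd_mrp")
                for other in ("UniSTS", "Hop"):
                    z, p = wilcoxon_signed_rank(wide[other].to_numpy(),
                                                wide["SU"].to_numpy())
                    su_sig += p < 0.05
                    su_r.append(effect_size_r(z, 14).r)
                z, p = wilcoxon_signed_rank(wide["UniSTS"].to_numpy(),
                                            wide["Hop"].to_numpy())
                null_sig += p < 0.05
                null_r.append(effect_size_r(z, 14).r)
        assert su_sig > 2 * null_sig
        assert np.median(su_r) > np.median(null_r)
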