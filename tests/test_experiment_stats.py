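"""Bayes factors, effect sizes, ANOVA and screening rules.

The JZS Bayes factor is checked two ways: against published values computed
from printed (t, n) summaries, and against an independent Monte-Carlo
integration over the Cauchy effect prior.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import dreammachine as dm
from dreammachine import experiment_stats as es


def mc_bf10(t, df, n_eff, r=math.sqrt(0.5), n_draws=200_000, seed=0):
    """Monte-Carlo oracle: average noncentral-t likelihood ratio over draws
    from the Cauchy(0, r) effect prior, antithetic over the prior's symmetry
    (each draw is paired with its negation)."""
    rng = np.random.default_rng(seed)
    delta = stats.cauchy.rvs(scale=r, size=n_draws, random_state=rng)
    log_den = stats.t.logpdf(t, df)
    w_pos = np.exp(stats.nct.logpdf(t, df, delta * np.sqrt(n_eff)) - log_den)
    w_neg = np.exp(stats.nct.logpdf(t, df, -delta * np.sqrt(n_eff)) - log_den)
    w = 0.5 * (w_pos + w_neg)
    return w.mean(), w.std(ddof=1) / np.sqrt(n_draws)


class TestJzsBF:
    @pytest.mark.parametrize(
        "t, df, n_eff, expected",
        [
            (3.705, 20, 21, 26.960),      # temporal session, presence
            (2.822, 20, 21, 4.830),       # temporal session, attention
            (1.685, 11, 12, 0.866),       # mood, paired
            (4.185, 11, 12, 28.09),       # intensity, paired
            (2.364, 25, 12 * 15 / 27, 2.545),   # patterns, independent
            (0.428, 25, 12 * 15 / 27, 0.385),   # muddle, independent
        ],
    )
    def test_matches_published_values(self, t, df, n_eff, expected):
        assert dm.jzs_bf10(t, df, n_eff) == pytest.approx(expected, rel=0.01)

    def test_null_t_favors_null_and_matches_monte_carlo(self):
        bf = dm.jzs_bf10(0.0, 11, 12)
        assert bf < 1.0
        mc, se = mc_bf10(0.0, 11, 12, n_draws=1_000_000)
        assert abs(bf - mc) <= 3 * se

    @pytest.mark.parametrize("t", [0.0, 2.0, 6.0])
    @pytest.mark.parametrize("n", [5, 12, 21, 50])
    def test_quadrature_agrees_with_monte_carlo_grid(self, t, n):
        bf = dm.jzs_bf10(t, n - 1, n)
        mc, se = mc_bf10(t, n - 1, n, seed=n * 7 + int(t), n_draws=1_000_000)
        assert abs(bf - mc) <= 3 * se

    def test_strictly_increasing_in_abs_t(self):
        ts = np.linspace(0, 6, 13)
        bfs = [dm.jzs_bf10(t, 11, 12) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    @settings(derandomize=True, max_examples=20)
    @given(t=st.floats(0.0, 8.0), n=st.integers(3, 60))
    def test_symmetric_in_t_sign(self, t, n):
        assert dm.jzs_bf10(t, n - 1, n) == pytest.approx(dm.jzs_bf10(-t, n - 1, n), rel=1e-9)

    def test_prior_scale_validation(self):
        with pytest.raises(ValueError):
            dm.BFConfig(prior_scale=0.0)


class TestCohensD:
    @pytest.mark.parametrize(
        "t, n, expected",
        [(3.705, 21, 0.808), (1.685, 12, 0.486), (0.0, 10, 0.0)],
    )
    def test_paired(self, t, n, expected):
        assert dm.cohens_d_paired(t, n) == pytest.approx(expected, abs=0.001)

    @pytest.mark.parametrize(
        "t, n1, n2, expected",
        [(2.364, 12, 15, 0.916), (1.335, 12, 15, 0.517), (0.0, 5, 5, 0.0)],
    )
    def test_independent(self, t, n1, n2, expected):
        assert dm.cohens_d_independent(t, n1, n2) == pytest.approx(expected, abs=0.001)


class TestTTests:
    def test_identical_paired_samples(self, rng):
        x = rng.uniform(0, 100, 10)
        res = dm.paired_ttest(x, x)
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.bf10 < 1.0

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            dm.paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_direct_formula_on_synthetic_ratings(self):
        spec = dm.SyntheticRatingsSpec(
            n_subjects=12, dimensions=("intensity",), delta={"intensity": 1.2}, seed=5
        )
        t = dm.generate_synthetic_ratings(spec)
        x = t[t.condition == spec.conditions[1]].sort_values("subject").rating.to_numpy()
        y = t[t.condition == spec.conditions[0]].sort_values("subject").rating.to_numpy()
        res = dm.paired_ttest(x, y)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.df == 11
        # paired identity: d = mean(diff)/sd(diff) = t / sqrt(n), exactly
        assert res.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_independent_uses_pooled_df(self, rng):
        x = rng.normal(50, 10, 12)
        y = rng.normal(55, 10, 15)
        res = dm.independent_ttest(x, y)
        assert res.df == 25
        assert res.design == "independent(12, 15)"

    def test_summary_matches_raw(self, rng):
        x = rng.normal(40, 8, 9)
        y = rng.normal(45, 8, 9)
        raw = dm.paired_ttest(x, y)
        summ = dm.summary_ttest(raw.t, 9, "paired")
        assert summ.bf10 == pytest.approx(raw.bf10, rel=1e-9)
        assert summ.cohens_d == pytest.approx(raw.cohens_d, rel=1e-9)


class TestBonferroniAndInterpretation:
    def test_bonferroni_cases(self):
        assert dm.bonferroni([0.01], 5)[0] == pytest.approx(0.05)
        assert dm.bonferroni([0.3], 5)[0] == 1.0
        assert dm.bonferroni([0.3], 5, cap=False)[0] == pytest.approx(1.5)

    def test_bonferroni_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            dm.bonferroni([1.2], 3)

    @pytest.mark.parametrize(
        "bf, verdict",
        [(28.09, "supports_H1"), (0.194, "supports_H0"), (1.0, "insensitive"),
         (3.0, "insensitive"), (1 / 3, "insensitive")],
    )
    def test_interpret_thresholds(self, bf, verdict):
        assert dm.interpret_bf(bf) == verdict


def brute_force_ss(y):
    """Mean-decomposition oracle by explicit loops (subjects x A x B)."""
    s, a, b = y.shape
    grand = y.mean()
    ss = {k: 0.0 for k in ["subj", "A", "B", "AB", "AS", "BS", "total"]}
    for i in range(s):
        for j in range(a):
            for k in range(b):
                ss["total"] += (y[i, j, k] - grand) ** 2
    for i in range(s):
        ss["subj"] += a * b * (y[i].mean() - grand) ** 2
    for j in range(a):
        ss["A"] += s * b * (y[:, j].mean() - grand) ** 2
    for k in range(b):
        ss["B"] += s * a * (y[:, :, k].mean() - grand) ** 2
    for j in range(a):
        for k in range(b):
            ss["AB"] += s * (y[:, j, k].mean() - y[:, j].mean() - y[:, :, k].mean() + grand) ** 2
    for i in range(s):
        for j in range(a):
            ss["AS"] += b * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
    for i in range(s):
        for k in range(b):
            ss["BS"] += a * (y[i, :, k].mean() - y[i].mean() - y[:, :, k].mean() + grand) ** 2
    return ss


@pytest.fixture(scope="module")
def timing_table():
    return dm.generate_synthetic_timing(
        dm.SyntheticTimingSpec(seed=3, bias=0.1, n_subjects=21)
    )


class TestRmAnova:

    def test_zero_noise_additive_target_effect(self):
        table = dm.generate_synthetic_timing(
            dm.SyntheticTimingSpec(weber=0.0, bias=0.1, n_subjects=6, n_trials=2)
        )
        res = dm.rm_anova_2way(table)
        assert res["video_type"].ss == pytest.approx(0.0, abs=1e-18)
        assert res["target_s"].p < 1e-12

    def test_sums_of_squares_match_brute_force_oracle(self, timing_table):
        res = dm.rm_anova_2way(timing_table)
        cells = timing_table.groupby(["subject", "target_s", "video_type"])["produced_s"].mean()
        y = cells.to_numpy().reshape(21, 3, 2)
        ss = brute_force_ss(y)
        assert res["target_s"].ss == pytest.approx(ss["A"], rel=1e-10)
        assert res["video_type"].ss == pytest.approx(ss["B"], rel=1e-10)
        assert res["target_s*video_type"].ss == pytest.approx(ss["AB"], rel=1e-10)
        assert res["target_s"].ss_error == pytest.approx(ss["AS"], rel=1e-10)
        assert res["video_type"].ss_error == pytest.approx(ss["BS"], rel=1e-10)
        assert res.ss_total == pytest.approx(ss["total"], rel=1e-10)

    def test_total_ss_conservation(self, timing_table):
        res = dm.rm_anova_2way(timing_table)
        parts = (
            res.ss_subjects
            + sum(e.ss for e in res.effects)
            + sum(e.ss_error for e in res.effects)
        )
        assert parts == pytest.approx(res.ss_total, rel=1e-10)

    def test_subject_relabelling_invariance(self, timing_table):
        res = dm.rm_anova_2way(timing_table)
        permuted = timing_table.copy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(21)
        permuted["subject"] = permuted["subject"].map({i: perm[i] for i in range(21)})
        res2 = dm.rm_anova_2way(permuted)
        for e, e2 in zip(res.effects, res2.effects):
            assert e2.F == pytest.approx(e.F, rel=1e-10)

    def test_agrees_with_pingouin(self, timing_table):
        pg = pytest.importorskip("pingouin")
        cells = timing_table.groupby(
            ["subject", "target_s", "video_type"], as_index=False
        )["produced_s"].mean()
        aov = pg.rm_anova(
            data=cells, dv="produced_s", within=["target_s", "video_type"],
            subject="subject", detailed=True,
        ).set_index("Source")
        res = dm.rm_anova_2way(timing_table)
        assert res["target_s"].F == pytest.approx(aov.loc["target_s", "F"], rel=1e-6)
        assert res["video_type"].F == pytest.approx(aov.loc["video_type", "F"], rel=1e-6)
        assert res["target_s*video_type"].F == pytest.approx(
            aov.loc["target_s * video_type", "F"], rel=1e-6
        )

    def test_missing_cell_rejected(self, timing_table):
        broken = timing_table[
            ~((timing_table.subject == 0) & (timing_table.target_s == 1.0)
              & (timing_table.video_type == "control"))
        ]
        with pytest.raises(ValueError, match="unbalanced"):
            dm.rm_anova_2way(broken)


class TestScreeningRules:
    def test_perfect_production_passes(self):
        ok, _ = dm.practice_criterion([1, 2, 4, 1, 2, 4], [1, 2, 4, 1, 2, 4])
        assert ok

    def test_anticorrelated_production_fails(self):
        ok, _ = dm.practice_criterion([1.0, 2.0, 4.0], [-1.0, -2.0, -4.0])
        assert not ok

    def test_zero_variance_fails_with_reason(self):
        ok, reason = dm.practice_criterion([1.0, 2.0, 4.0], [2.0, 2.0, 2.0])
        assert not ok and "variance" in reason

    def test_noisy_but_correlated_passes(self):
        spec = dm.SyntheticTimingSpec(weber=0.1, n_subjects=1, n_trials=7, seed=8)
        t = dm.generate_synthetic_timing(spec)
        t = t[t.block == 0]
        ok, _ = dm.practice_criterion(t["target_s"], t["produced_s"])
        assert ok

    @pytest.mark.parametrize(
        "means, keep",
        [((1.75, 2.41, 4.38), True), ((4.0, 2.0, 1.0), False), ((2.0, 2.0, 3.0), False)],
    )
    def test_inversion_exclusion(self, means, keep):
        assert dm.inversion_exclusion(means) is keep


class TestAscqCompare:
    def test_table_against_itself(self):
        table = dm.generate_synthetic_ratings(dm.SyntheticRatingsSpec(seed=1))
        a = table[table.condition == "control"]
        b = table[table.condition == "control"]
        report = dm.ascq_compare(a, b, "paired")
        assert (report["t"] == 0.0).all()
        assert not (report["interpretation"] == "supports_H1").any()

    def test_schema_seventeen_rows(self):
        table = dm.generate_synthetic_ratings(dm.SyntheticRatingsSpec(seed=1))
        a = table[table.condition == "control"]
        b = table[table.condition == "hallucination_machine"]
        report = dm.ascq_compare(a, b, "paired")
        assert len(report) == 17
        assert list(report.columns) == [
            "dimension", "bf10", "t", "df", "p", "p_bonferroni", "cohens_d",
            "interpretation",
        ]
        assert (report["p_bonferroni"] >= report["p"] - 1e-15).all()

    def test_null_false_positive_rate_after_correction(self):
        """Under delta = 0 everywhere, Bonferroni-adjusted discoveries are
        rare: about m * 0.05/m = 0.05 per whole table."""
        hits = total = 0
        for seed in range(30):
            table = dm.generate_synthetic_ratings(dm.SyntheticRatingsSpec(seed=seed))
            a = table[table.condition == "control"]
            b = table[table.condition == "hallucination_machine"]
            report = dm.ascq_compare(a, b, "paired")
            hits += int((report["p_bonferroni"] < 0.05).sum())
            total += len(report)
        assert hits / 30 < 0.3  # expectation 0.05 tables-with-hit equivalents

    def test_independent_design(self):
        a = dm.generate_synthetic_ratings(dm.SyntheticRatingsSpec(n_subjects=12, seed=2))
        b = dm.generate_synthetic_ratings(dm.SyntheticRatingsSpec(n_subjects=15, seed=3))
        report = dm.ascq_compare(
            a[a.condition == "control"], b[b.condition == "control"], "independent"
        )
        assert (report["df"] == 25).all()
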