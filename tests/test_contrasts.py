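"""Proportion splits, Kruskal–Wallis, Dunn post hoc and the contrast report."""

import numpy as np
import pytest
from scipy import stats

import folscan as fs
from folscan.cohort import DegenerateError, SizeHistogram, ValidationError
from folscan.contrasts import dunn_posthoc, kruskal_wallis, split_by_proportion

from conftest import cohort_from_matrix


def _kw_oracle(groups):
    """Textbook rank-sum formula with tie correction, independent of scipy."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([g.size for g in groups])[:-1]
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / r.size for r in np.split(ranks, splits)
    ) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts.astype(float) ** 3 - counts)
    h /= 1.0 - ties / (n**3 - n)
    p = stats.chi2.sf(h, len(groups) - 1)
    return h, p


class TestKruskalWallis:
    def test_hand_worked_example(self):
        """Three groups of consecutive integers: H = 7.2 by direct evaluation
        of the rank-sum formula (no ties)."""
        h, df, p = kruskal_wallis(
            [np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])]
        )
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_identical_groups_give_zero(self):
        g = np.array([3.0, 1.0, 2.0, 5.0])
        h, df, p = kruskal_wallis([g, g.copy()])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_observations_defined(self):
        h, df, p = kruskal_wallis([np.ones(4), np.ones(3)])
        assert (h, p) == (0.0, 1.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            groups = [
                rng.integers(0, 15, size=int(rng.integers(5, 30))).astype(float)
                for _ in range(k)
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, df, p = kruskal_wallis(groups)
            ho, po = _kw_oracle(groups)
            assert h == pytest.approx(ho, rel=1e-10, abs=1e-10)
            assert p == pytest.approx(po, rel=1e-10, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=20), rng.normal(1, 1, 25), rng.normal(0.5, 2, 15)]
        h1, _, p1 = kruskal_wallis(groups)
        h2, _, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([np.array([1.0]), np.array([2.0, 3.0])])


class TestDunn:
    def test_two_group_z_squared_equals_h(self, rng):
        a, b = rng.normal(size=12), rng.normal(1, 1, size=15)  # no ties a.s.
        h, _, _ = kruskal_wallis([a, b])
        tab = dunn_posthoc([a, b], correction="none")
        assert tab["z"].iloc[0] ** 2 == pytest.approx(h, abs=1e-10)

    def test_adjusted_p_monotone(self, rng):
        groups = [rng.normal(size=20), rng.normal(0.8, 1, 20), rng.normal(1.6, 1, 20)]
        for corr in ("bonferroni", "holm"):
            tab = dunn_posthoc(groups, correction=corr)
            assert (tab["p_adjusted"] >= tab["p_raw"] - 1e-15).all()

    def test_matches_rank_formula_oracle(self, rng):
        """Three-group fixture vs an explicit evaluation of the z formula."""
        groups = [
            rng.integers(0, 10, 12).astype(float),
            rng.integers(0, 10, 9).astype(float),
            rng.integers(0, 10, 15).astype(float),
        ]
        tab = dunn_posthoc(groups, correction="none")
        pooled = np.concatenate(groups)
        n = pooled.size
        ranks = stats.rankdata(pooled)
        rbar = [r.mean() for r in np.split(ranks, np.cumsum([12, 9, 15])[:-1])]
        _, counts = np.unique(pooled, return_counts=True)
        a = n * (n + 1) / 12 - np.sum(counts.astype(float) ** 3 - counts) / (12 * (n - 1))
        z01 = (rbar[0] - rbar[1]) / np.sqrt(a * (1 / 12 + 1 / 9))
        row = tab[(tab.group_i == 0) & (tab.group_j == 1)].iloc[0]
        assert row["z"] == pytest.approx(z01, rel=1e-10, abs=1e-10)
        assert row["p_raw"] == pytest.approx(2 * stats.norm.sf(abs(z01)), rel=1e-10)


class TestSplit:
    def test_three_patients_three_groups(self):
        X = np.zeros((3, 18), dtype=int)
        # proportions in [12,19]: 0.1, 0.5, 0.9
        X[0, 6], X[0, 0] = 1, 9
        X[1, 6], X[1, 0] = 5, 5
        X[2, 6], X[2, 0] = 9, 1
        cohort = cohort_from_matrix(X, [1, 2, 3])
        a = split_by_proportion(cohort, fs.Window(12, 19), k=3)
        assert list(a.labels) == [0, 1, 2]

    def test_balanced_sizes(self, step_cohort):
        cohort, _, _ = step_cohort  # n=300
        a = split_by_proportion(cohort, fs.Window(12, 19), k=3)
        assert a.group_sizes() == [100, 100, 100]
        a2 = split_by_proportion(cohort, fs.Window(12, 19), k=2)
        assert a2.group_sizes() == [150, 150]

    def test_degenerate_split(self):
        X = np.zeros((10, 18), dtype=int)
        X[:, 6] = 3  # everyone 100% inside [12,19]
        cohort = cohort_from_matrix(X, np.arange(10))
        with pytest.raises(DegenerateError, match="split impossible"):
            split_by_proportion(cohort, fs.Window(12, 19), k=2)

    def test_k_larger_than_n(self):
        X = np.zeros((2, 18), dtype=int)
        X[0, 6], X[1, 0] = 1, 1
        cohort = cohort_from_matrix(X, [0, 1])
        with pytest.raises(ValidationError):
            split_by_proportion(cohort, fs.Window(12, 19), k=3)


class TestContrastReport:
    def test_delta_matches_generator_expectation(self, step_curve):
        """Top-vs-bottom tertile delta in mature oocytes tracks the analytic
        expectation computed from the planted yield curve."""
        cfg = fs.preset(
            "hcg_like", n_patients=600, seed=77, yield_curve=fs.YieldCurve("step", 12, 19, 0.8, 0.1)
        )
        cohort, truth = fs.generate_cohort(cfg)
        w = fs.Window(12, 19)
        res = fs.contrast_report(cohort, w, k=3)
        labels = res.assignment.labels
        exp_mature = np.array(
            [truth.expected_mature(r.histogram, cfg.p_mature_given_oocyte) for r in cohort]
        )
        analytic = exp_mature[labels == 2].mean() - exp_mature[labels == 0].mean()
        observed = res.delta_top_bottom["mature"]
        # Monte-Carlo SD of the observed delta around its expectation
        y = cohort.outcome_vector("mature")
        mc_sd = np.sqrt(
            y[labels == 2].var() / (labels == 2).sum()
            + y[labels == 0].var() / (labels == 0).sum()
        )
        assert observed > 0
        assert abs(observed - analytic) < 3 * mc_sd

    def test_full_window_is_degenerate(self, step_cohort):
        cohort, _, _ = step_cohort
        with pytest.raises(DegenerateError):
            fs.contrast_report(cohort, fs.Window(8, 25), k=2)

    def test_report_structure(self, step_cohort):
        cohort, _, _ = step_cohort
        res = fs.contrast_report(cohort, fs.Window(12, 19), k=2, outcomes=("oocytes", "mature"))
        assert set(res.summaries) == {"oocytes", "mature"}
        for o, (h, df, p) in res.kw.items():
            assert h >= 0 and df == 1 and 0 <= p <= 1
        b, t, p = res.follicle_total_check
        assert 0 <= p <= 1 and b > 0 and t > 0

    def test_permutation_null_is_uniform(self, step_cohort, rng):
        """Shuffling outcomes breaks the association: deltas centre at 0 and
        KW p values look uniform (KS sanity check at alpha = 0.01)."""
        cohort, _, _ = step_cohort
        w = fs.Window(12, 19)
        assignment = split_by_proportion(cohort, w, k=2)
        y = cohort.outcome_vector("oocytes")
        deltas, ps = [], []
        for _ in range(200):
            yp = rng.permutation(y)
            g = [yp[assignment.labels == 0], yp[assignment.labels == 1]]
            deltas.append(g[1].mean() - g[0].mean())
            ps.append(kruskal_wallis(g)[2])
        assert abs(np.mean(deltas)) < 3 * np.std(deltas) / np.sqrt(len(deltas))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_kw_close_to_mann_whitney_for_two_groups(self, step_cohort):
        cohort, _, _ = step_cohort
        res = fs.contrast_report(cohort, fs.Window(12, 19), k=2, outcomes=("oocytes",))
        labels = res.assignment.labels
        y = cohort.outcome_vector("oocytes")
        mw = stats.mannwhitneyu(
            y[labels == 1], y[labels == 0], alternative="two-sided", use_continuity=False
        )
        assert abs(res.kw["oocytes"][2] - mw.pvalue) < 0.02
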