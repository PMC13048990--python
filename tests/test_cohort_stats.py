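"""Cohort statistics: CV decomposition, ANOVA/Tukey/letters, correlations,
growth rates."""

import numpy as np
import pandas as pd
import pytest

from coccosims import cohort_stats
from coccosims.cohort_stats import (
    CohortStatsError,
    anova_tukey,
    correlation_matrix,
    cv_decomposition,
    growth_rate,
    summarize_samples,
)


def _table(groups: dict[str, np.ndarray], element="na") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for v in vals:
            rows.append({"sample_id": g, f"ratio_{element}": v})
    return pd.DataFrame(rows)


class TestCvDecomposition:
    def test_identical_values_give_zero(self):
        t = _table({"a": [2.0, 2.0, 2.0]})
        t["precision_cv_na"] = 0.01
        dec = cv_decomposition(t, "Na", "a")
        assert dec["among_lith_cv"] == 0.0
        np.testing.assert_allclose(dec["within_lith_cvs"], 0.01)

    def test_six_sample_means_hand_calculation(self):
        """Six Sr/Ca culture means (x1000): hand CV is ~3.4%."""
        t = _table({"a": [84.2, 78.1, 81.1, 79.8, 76.4, 78.4]})
        dec = cv_decomposition(t, "Na", "a")
        assert dec["among_lith_cv"] == pytest.approx(0.034309, abs=5e-6)

    def test_among_cv_recovery_from_lognormal_groups(self):
        """True among-lith CV 0.3, n = 30 liths: the fraction of estimates
        within 20% of truth matches the sampling-distribution oracle.

        The oracle (direct simulation of SD/mean over lognormal samples,
        5000 reps) puts the coverage of the +/-20% band at 0.834 +/- 0.005;
        the implementation must reproduce that coverage within MC error.
        """
        sigma = np.sqrt(np.log(1 + 0.3**2))
        ok = 0
        seeds = 400
        for s in range(seeds):
            r = np.random.default_rng(80_000 + s)
            t = _table({"a": r.lognormal(0.0, sigma, 30)})
            cv = cv_decomposition(t, "Na", "a")["among_lith_cv"]
            ok += abs(cv - 0.3) / 0.3 <= 0.20
        oracle_coverage = 0.834
        mc_se = np.sqrt(oracle_coverage * (1 - oracle_coverage) / seeds)
        assert abs(ok / seeds - oracle_coverage) <= 4 * mc_se

    def test_flag_when_cv_exceeds_one(self):
        t = _table({"a": [0.001, 0.001, 5.0, 9.0]})
        assert cv_decomposition(t, "Na", "a")["among_exceeds_one"]

    def test_needs_two_liths(self):
        with pytest.raises(CohortStatsError):
            cv_decomposition(_table({"a": [1.0]}), "Na", "a")


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        res = anova_tukey(_table({"a": vals, "b": vals}), "Na")
        assert res.share_letter("a", "b")
        assert res.pairs["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_statsmodels_cross_check(self, rng):
        """Adjusted p-values match statsmodels' Tukey HSD."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        t = _table({
            "a": rng.lognormal(0.0, 0.3, 8),
            "b": rng.lognormal(0.4, 0.3, 10),
            "c": rng.lognormal(0.5, 0.3, 12),
        })
        res = anova_tukey(t, "Na")
        sm = pairwise_tukeyhsd(np.log(t["ratio_na"]), t["sample_id"])
        np.testing.assert_allclose(res.pairs["p_adj"].to_numpy(), sm.pvalues,
                                   atol=1e-9)

    def test_letters_respect_significance(self, rng):
        t = _table({
            "a": rng.lognormal(0.0, 0.2, 12),
            "b": rng.lognormal(2.0, 0.2, 12),
            "c": rng.lognormal(2.05, 0.2, 12),
        })
        res = anova_tukey(t, "Na")
        for _, row in res.pairs.iterrows():
            shares = res.share_letter(row["group1"], row["group2"])
            assert shares == (row["p_adj"] >= res.alpha)

    def test_row_order_invariance(self, rng):
        t = _table({
            "a": rng.lognormal(0.0, 0.3, 10),
            "b": rng.lognormal(0.8, 0.3, 10),
            "c": rng.lognormal(0.4, 0.3, 10),
        })
        res1 = anova_tukey(t, "Na")
        shuffled = t.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = anova_tukey(shuffled, "Na")
        assert res1.letters == res2.letters
        assert res1.anova_f == pytest.approx(res2.anova_f, rel=1e-12)

    def test_global_rescaling_invariance(self, rng):
        """Scaling all ratios by c shifts logs; F, p, letters are unchanged."""
        t = _table({
            "a": rng.lognormal(0.0, 0.3, 9),
            "b": rng.lognormal(0.6, 0.3, 11),
            "c": rng.lognormal(0.3, 0.3, 10),
        })
        t2 = t.copy()
        t2["ratio_na"] = t2["ratio_na"] * 37.5
        r1, r2 = anova_tukey(t, "Na"), anova_tukey(t2, "Na")
        assert r1.anova_f == pytest.approx(r2.anova_f, rel=1e-9)
        np.testing.assert_allclose(r1.pairs["p_adj"], r2.pairs["p_adj"], atol=1e-12)
        assert r1.letters == r2.letters

    def test_degenerate_zero_variance_warns(self):
        t = _table({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        res = anova_tukey(t, "Na")
        assert res.warning
        assert not res.share_letter("a", "b")

    def test_zero_ratios_are_excluded_and_counted(self):
        t = _table({"a": [1.0, 1.1, 0.0, 1.2], "b": [2.0, 2.1, 2.2]})
        res = anova_tukey(t, "Na")
        assert res.n_zero_excluded == 1
        assert res.n["a"] == 3


class TestCorrelations:
    def test_exact_linear_covariate_gives_r_one(self):
        t = _table({g: [np.exp(v)] * 3 for g, v in
                    zip("abcde", [0.1, 0.5, 1.0, 1.5, 2.2])})
        cov = pd.DataFrame({
            "sample_id": list("abcde"),
            "salinity": [2 * v + 1 for v in [0.1, 0.5, 1.0, 1.5, 2.2]],
        })
        res = correlation_matrix(t, ["Na"], cov)
        assert res.iloc[0]["r"] == pytest.approx(1.0, abs=1e-12)
        assert res.iloc[0]["significant"]

    def test_five_point_hand_fixture(self):
        """Pearson r computed from the explicit sum formula."""
        x = np.array([0.2, 1.1, 0.7, 1.9, 1.3])  # log-ratios
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])  # covariate
        t = _table({f"g{i}": [np.exp(x[i])] for i in range(5)})
        t = pd.concat([t, t], ignore_index=True)  # 2 liths per group, same value
        cov = pd.DataFrame({"sample_id": [f"g{i}" for i in range(5)], "ta": y})
        res = correlation_matrix(t, ["Na"], cov)
        # hand formula on the duplicated per-lith pairs
        xl = np.concatenate([x, x])
        yl = np.concatenate([y, y])
        n = len(xl)
        r_hand = (n * np.sum(xl * yl) - xl.sum() * yl.sum()) / np.sqrt(
            (n * np.sum(xl**2) - xl.sum() ** 2) * (n * np.sum(yl**2) - yl.sum() ** 2)
        )
        assert res.iloc[0]["r"] == pytest.approx(r_hand, abs=1e-12)

    def test_permutation_null_significance_rate(self):
        """Permuting group covariates: ~5% of tests come out significant."""
        rng = np.random.default_rng(99)
        groups = [f"g{i}" for i in range(12)]
        t = _table({g: rng.lognormal(0.0, 0.4, 5) for g in groups})
        cov_values = rng.normal(35.0, 2.0, 12)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            cov = pd.DataFrame({"sample_id": groups,
                                "salinity": rng.permutation(cov_values)})
            res = correlation_matrix(t, ["Na"], cov)
            hits += int(res.iloc[0]["significant"])
        rate = hits / n_perm
        mc_se = np.sqrt(0.05 * 0.95 / n_perm)
        assert abs(rate - 0.05) <= 3 * mc_se

    def test_too_few_pairs(self):
        t = _table({"a": [1.0, 2.0]})
        cov = pd.DataFrame({"sample_id": ["a"], "salinity": [30.0]})
        with pytest.raises(CohortStatsError):
            correlation_matrix(t.iloc[:2], ["Na"], cov)


class TestGrowthRate:
    def test_exact_exponential(self):
        t = np.arange(8, dtype=float)
        res = growth_rate(t, 40.0 * np.exp(0.45 * t))
        assert res.mu_per_day == pytest.approx(0.45, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_exponential_within_ci(self, rng):
        t = np.arange(10, dtype=float)
        dens = 40.0 * np.exp(0.45 * t) * rng.lognormal(0.0, 0.05, 10)
        res = growth_rate(t, dens)
        assert abs(res.mu_per_day - 0.45) < 3 * res.stderr

    def test_two_points_is_an_error(self):
        with pytest.raises(CohortStatsError):
            growth_rate([0.0, 1.0], [40.0, 60.0])
        with pytest.raises(CohortStatsError):
            growth_rate([0.0, 1.0, 2.0], [40.0, 0.0, 60.0])


def test_summarize_samples_layout(rng):
    t = _table({
        "C1": rng.lognormal(0.0, 0.3, 10),
        "C2": rng.lognormal(0.5, 0.3, 10),
    })
    t["precision_cv_na"] = 0.05
    out = summarize_samples(t, ["Na"])
    assert set(out["sample_id"]) == {"C1", "C2"}
    assert {"na_mean", "na_se", "na_letters", "n"} <= set(out.columns)
    row = out.set_index("sample_id").loc["C1"]
    vals = t.loc[t.sample_id == "C1", "ratio_na"]
    assert row["na_mean"] == pytest.approx(vals.mean())
    assert row["na_se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(10))
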