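"""Descriptive comparison tables, test dispatch, and the Breslow-Day
homogeneity test (enumeration oracle + simulation calibration)."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dcas.cohort_stats import test_association as assoc_test
from dcas import (
    VariableSpec,
    breslow_day,
    corpus_to_frame,
    default_variable_specs,
    describe,
)


def _study_like_frame():
    """Frame reproducing the printed case-column margins: 305 cases of whom
    259 male and 169 with a physical-health problem."""
    rows = []
    for i in range(305):
        rows.append(
            {
                "group": "DCAS",
                "sex": "Male" if i < 259 else "Female",
                "physical_health_flag": i < 169,
                "age": 70.0 + (i % 7),
            }
        )
    for i in range(400):
        rows.append(
            {
                "group": "non-DCAS",
                "sex": "Male" if i < 300 else "Female",
                "physical_health_flag": i < 150,
                "age": 66.0 + (i % 7),
            }
        )
    return pd.DataFrame(rows)


class TestDescribe:
    def test_case_percentages_match_study_margins(self):
        specs = [
            VariableSpec("sex", "categorical", "chi-square"),
            VariableSpec("physical_health_flag", "categorical", "chi-square"),
        ]
        table = describe(_study_like_frame(), "group", specs)
        male = table[(table.variable == "sex") & (table.level == "Male")].iloc[0]
        assert male["DCAS_n"] == 259
        assert male["DCAS_pct"] == pytest.approx(84.9, abs=0.05)
        phys = table[
            (table.variable == "physical_health_flag") & (table.level == "True")
        ].iloc[0]
        assert phys["DCAS_n"] == 169
        assert phys["DCAS_pct"] == pytest.approx(55.4, abs=0.05)

    def test_percentages_sum_to_100_within_group(self):
        table = describe(
            _study_like_frame(),
            "group",
            [VariableSpec("sex", "categorical", "chi-square")],
        )
        assert table["DCAS_pct"].sum() == pytest.approx(100.0, abs=0.2)

    def test_single_category_group_is_100_percent(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 5 + ["b"] * 6,
                "v": ["only"] * 5 + ["only"] * 3 + ["other"] * 3,
            }
        )
        table = describe(df, "group", [VariableSpec("v", "categorical", "fisher")])
        only = table[table.level == "only"].iloc[0]
        assert only["a_pct"] == pytest.approx(100.0)

    def test_continuous_rows_report_mean_sd(self):
        table = describe(
            _study_like_frame(), "group", [VariableSpec("age", "continuous", "t-test")]
        )
        row = table.iloc[0]
        assert row["DCAS_mean"] == pytest.approx(73.0, abs=0.2)
        assert row["p_value"] < 1e-6

    def test_generator_defaults_survive_description(self, corpus_50k):
        """A default-parameter corpus reproduces its configured case-column
        percentages within sampling error."""
        df = corpus_to_frame(corpus_50k)
        df["group"] = [n.true_label for n in corpus_50k]
        table = describe(
            df,
            "group",
            [
                VariableSpec("sex", "categorical", "chi-square"),
                VariableSpec("physical_health_flag", "categorical", "chi-square"),
                VariableSpec("crisis_flag", "categorical", "chi-square"),
            ],
        )
        male = table[(table.variable == "sex") & (table.level == "Male")].iloc[0]
        assert male["DCAS_pct"] == pytest.approx(84.9, abs=5.0)
        phys = table[
            (table.variable == "physical_health_flag") & (table.level == "True")
        ].iloc[0]
        assert phys["DCAS_pct"] == pytest.approx(55.4, abs=7.0)
        crisis = table[(table.variable == "crisis_flag") & (table.level == "True")].iloc[0]
        assert crisis["DCAS_pct"] == pytest.approx(45.6, abs=7.0)


class TestAssociationDispatch:
    def test_yates_chi_square_reproduces_printed_sex_p_value(self):
        # female/male counts per group at registry scale
        table = [[15_014, 50_623], [46, 259]]
        _, p = assoc_test(table, "chi-square")
        assert round(p, 3) == 0.002

    def test_uncorrected_variant_differs(self):
        table = [[15_014, 50_623], [46, 259]]
        _, p_corr = assoc_test(table, "chi-square", yates=True)
        _, p_raw = assoc_test(table, "chi-square", yates=False)
        assert p_raw < p_corr

    def test_identical_proportions_give_null_result(self):
        stat, p = assoc_test([[40, 60], [20, 30]], "chi-square")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fisher_matches_full_enumeration_on_3x2(self):
        obs = np.array([[3, 1], [1, 4], [2, 2]])
        _, p = assoc_test(obs, "fisher")
        # enumeration over all tables with the observed margins
        row_sums = obs.sum(axis=1)
        col1 = obs.sum(axis=0)[0]
        n = obs.sum()

        def log_prob(a):  # first-column cells
            return sum(
                math.lgamma(r + 1) - math.lgamma(x + 1) - math.lgamma(r - x + 1)
                for r, x in zip(row_sums, a)
            ) + math.lgamma(col1 + 1) + math.lgamma(n - col1 + 1) - math.lgamma(n + 1)

        p_obs = log_prob(obs[:, 0])
        total = 0.0
        for a0, a1 in itertools.product(range(row_sums[0] + 1), range(row_sums[1] + 1)):
            a2 = col1 - a0 - a1
            if 0 <= a2 <= row_sums[2]:
                lp = log_prob([a0, a1, a2])
                if lp <= p_obs + 1e-9:
                    total += math.exp(lp)
        assert p == pytest.approx(total, rel=1e-6)

    @pytest.mark.parametrize("test", ["chi-square", "fisher"])
    def test_group_swap_symmetry_tables(self, test):
        table = np.array([[12, 30], [7, 9]])
        _, p1 = assoc_test(table, test)
        _, p2 = assoc_test(table[:, ::-1], test)
        assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize("test", ["t-test", "mann-whitney"])
    def test_group_swap_symmetry_samples(self, test):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1.2, 35)
        _, p1 = assoc_test((a, b), test)
        _, p2 = assoc_test((b, a), test)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            assoc_test([[0, 0], [5, 10]], "chi-square")


class TestBreslowDay:
    def test_identical_strata_are_perfectly_homogeneous(self):
        stratum = np.array([[30, 70], [20, 80]])
        stat, p = breslow_day([stratum, stratum])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_copies_of_one_stratum_stay_homogeneous(self):
        stratum = np.array([[15, 35], [10, 40]])
        stat, _ = breslow_day([stratum] * 4)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_single_stratum_is_an_error(self):
        with pytest.raises(ValueError, match="2 strata"):
            breslow_day([np.array([[5, 5], [5, 5]])])

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="zero margin"):
            breslow_day([np.array([[0, 0], [5, 5]]), np.array([[5, 5], [5, 5]])])

    @staticmethod
    def _simulate_stratum(p_exposed, p_unexposed, n_per_arm, rng):
        a = rng.binomial(n_per_arm, p_exposed)
        c = rng.binomial(n_per_arm, p_unexposed)
        return np.array([[a, n_per_arm - a], [c, n_per_arm - c]])

    def test_detects_heterogeneous_odds_ratios(self):
        """Strata with odds ratios 1.0 vs 4.0 (n=500 per stratum) are
        rejected at alpha=0.05 in at least 80% of replicates."""
        rng = np.random.default_rng(1)
        p0 = 0.25
        p_or4 = (4 * p0 / (1 - p0)) / (1 + 4 * p0 / (1 - p0))
        rejections = 0
        for _ in range(200):
            s1 = self._simulate_stratum(p0, p0, 250, rng)
            s2 = self._simulate_stratum(p_or4, p0, 250, rng)
            _, p = breslow_day([s1, s2])
            rejections += p < 0.05
        assert rejections / 200 >= 0.8
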