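"""Indicator definitions on constructed F0 tables, plus rank synthesis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cqman import (
    DilutionDesign,
    DomainError,
    FormatError,
    ParameterError,
    bias_ratio,
    bias_slope,
    coefficient_of_variation,
    compute_indicators,
    normalize_f0,
    precision_within_group,
    rank_synthesis,
    relative_error,
    resolution_fold,
)

LEVELS_5 = (150000.0, 15000.0, 1500.0, 150.0, 15.0)


def perfect_table(genes=3, reps=3, levels=LEVELS_5, scale=1.0):
    """F0 exactly proportional to concentration (per gene scale factor)."""
    rows = []
    for g in range(genes):
        c = scale * (1.0 + g)
        for li, level in enumerate(levels):
            for r in range(reps):
                rows.append(
                    {
                        "gene": f"G{g}",
                        "well_id": f"G{g}L{li}R{r}",
                        "concentration": level,
                        "f0": c * level / levels[0],
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def design():
    return DilutionDesign.from_levels(LEVELS_5, 3)


class TestDesign:
    def test_expected_ratio_and_orientation(self):
        d = DilutionDesign.from_levels(LEVELS_5, 3)
        assert d.expected_extreme_ratio == pytest.approx(10000.0)
        d2 = DilutionDesign.from_levels((15000, 1500, 150, 15), 11, "low_over_high")
        assert d2.expected_extreme_ratio == pytest.approx(0.001)

    def test_uneven_spacing_rejected(self):
        with pytest.raises(ParameterError):
            DilutionDesign.from_levels((1000.0, 100.0, 50.0), 3)


class TestNormalization:
    def test_top_group_mean_is_exactly_one(self, design):
        rng = np.random.default_rng(0)
        table = perfect_table()
        table["f0"] *= rng.lognormal(0.0, 0.3, len(table))
        norm = normalize_f0(table, design)
        top = norm[norm["concentration"] == LEVELS_5[0]]
        for _, grp in top.groupby("gene"):
            assert grp["f0_norm"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_two_replicate_centering(self):
        table = pd.DataFrame(
            {
                "gene": ["g"] * 6,
                "well_id": list("abcdef"),
                "concentration": [1000.0, 1000.0, 100.0, 100.0, 10.0, 10.0],
                "f0": [1e-6, 3e-6, 2e-7, 2e-7, 2e-8, 2e-8],
            }
        )
        norm = normalize_f0(table, DilutionDesign.from_levels((1000, 100, 10), 2))
        np.testing.assert_allclose(norm["f0_norm"].iloc[:2], [0.5, 1.5])

    def test_nc_levels(self, design):
        norm = normalize_f0(perfect_table(), design)
        assert sorted(norm["nc"].unique(), reverse=True) == pytest.approx(
            [1.0, 0.1, 0.01, 0.001, 0.0001]
        )

    def test_gene_scale_invariance_of_all_indicators(self, design):
        rng = np.random.default_rng(5)
        table = perfect_table()
        table["f0"] *= rng.lognormal(0.0, 0.2, len(table))
        scaled = table.copy()
        scaled.loc[scaled["gene"] == "G1", "f0"] *= 123.0
        rep0 = compute_indicators(table, design)
        rep1 = compute_indicators(scaled, design)
        for field in (
            "bias_ratio_dev", "bias_slope_dev", "mean_relative_error",
            "mean_cv_pct", "mean_precision", "resolution_fold",
        ):
            assert getattr(rep1, field) == pytest.approx(getattr(rep0, field), rel=1e-9)

    def test_well_order_invariance(self, design):
        rng = np.random.default_rng(6)
        table = perfect_table()
        table["f0"] *= rng.lognormal(0.0, 0.2, len(table))
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r0, r1 = compute_indicators(table, design), compute_indicators(shuffled, design)
        assert r1.to_dict().keys() == r0.to_dict().keys()
        assert r1.mean_relative_error == pytest.approx(r0.mean_relative_error, rel=1e-12)
        assert r1.resolution_fold == pytest.approx(r0.resolution_fold, rel=1e-12)


class TestBias:
    def test_perfect_data_unbiased(self, design):
        norm = normalize_f0(perfect_table(), design)
        assert bias_ratio(norm, design) == pytest.approx(0.0, abs=1e-8)
        assert bias_slope(norm) == pytest.approx(0.0, abs=1e-12)

    def test_low_over_high_orientation(self):
        levels = (15000.0, 1500.0, 150.0, 15.0)
        d = DilutionDesign.from_levels(levels, 2, "low_over_high")
        norm = normalize_f0(perfect_table(genes=2, reps=2, levels=levels), d)
        assert bias_ratio(norm, d) == pytest.approx(0.0, abs=1e-10)

    def test_known_ratio_deviation(self, design):
        table = perfect_table(genes=1)
        # inflate the bottom group mean by 10000/12000 so ratio becomes 12000
        bottom = table["concentration"] == 15.0
        table.loc[bottom, "f0"] *= 10000.0 / 12000.0
        norm = normalize_f0(table, design)
        assert bias_ratio(norm, design) == pytest.approx(2000.0, rel=1e-9)

    def test_power_law_slope_deviation(self, design):
        table = perfect_table()
        norm = normalize_f0(table, design)
        norm["f0_norm"] = norm["nc"] ** 1.1
        assert bias_slope(norm) == pytest.approx(0.1, abs=1e-9)


class TestErrorDispersion:
    def test_relative_error_cases(self, design):
        norm = normalize_f0(perfect_table(), design)
        assert relative_error(norm) == pytest.approx(0.0, abs=1e-12)
        # one well 50% above its NC
        norm.loc[norm.index[0], "f0_norm"] = norm.loc[norm.index[0], "nc"] * 1.5
        assert relative_error(norm) == pytest.approx(0.5 / len(norm), rel=1e-9)

    def test_relative_error_uses_absolute_values(self, design):
        norm = normalize_f0(perfect_table(genes=1, reps=1, levels=(100.0, 10.0, 1.0)),
                            DilutionDesign.from_levels((100, 10, 1), 1))
        norm["f0_norm"] = norm["nc"] * np.array([1.2, 0.8, 1.0])
        assert relative_error(norm) == pytest.approx((0.2 + 0.2 + 0.0) / 3)

    def test_cv_hand_computed(self):
        d = DilutionDesign.from_levels((100.0, 10.0), 3)
        table = pd.DataFrame(
            {
                "gene": ["g"] * 6,
                "well_id": list("abcdef"),
                "concentration": [100.0] * 3 + [10.0] * 3,
                "f0": [2.0, 2.0, 2.0, 0.1, 0.2, 0.3],
            }
        )
        norm = normalize_f0(table, d)
        # top group {2,2,2}: CV 0%; bottom {1,2,3}/20: sample SD/mean = 50%
        assert coefficient_of_variation(norm) == pytest.approx(25.0, rel=1e-9)

    def test_precision_hand_computed(self):
        d = DilutionDesign.from_levels((100.0, 10.0), 3)
        table = pd.DataFrame(
            {
                "gene": ["g"] * 6,
                "well_id": list("abcdef"),
                "concentration": [100.0] * 3 + [10.0] * 3,
                "f0": [0.9, 1.0, 1.1, 1.0, 1.0, 1.0],
            }
        )
        norm = normalize_f0(table, d)
        norm["f0_norm"] = [0.9, 1.0, 1.1, 1.0, 1.0, 1.0]  # fix exact values
        assert precision_within_group(norm) == pytest.approx((0.01 + 0.0) / 2)


class TestResolution:
    def test_perfect_data_fold_one(self, design):
        norm = normalize_f0(perfect_table(), design)
        assert resolution_fold(norm) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_residual_scale(self, design):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1, 45)
        folds = []
        for s in (0.05, 0.1):
            table = perfect_table()
            table["f0"] *= 10 ** (s * noise)
            folds.append(resolution_fold(normalize_f0(table, design)))
        assert 1.0 < folds[0] < folds[1]

    def test_matches_statsmodels_prediction_interval(self, design):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        table = perfect_table(genes=1)
        table["f0"] *= 10 ** rng.normal(0.0, 0.1, len(table))
        norm = normalize_f0(table, design)

        x = np.log10(norm["f0_norm"].to_numpy())
        y = np.log10(norm["nc"].to_numpy())
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        halfs = []
        for _, lvl in norm.groupby("nc"):
            xl = float(np.log10(lvl["f0_norm"]).mean())
            pred = fit.get_prediction(np.array([[1.0, xl]]))
            lo, hi = pred.conf_int(obs=True, alpha=0.05)[0]
            halfs.append((hi - lo) / 2.0)
        expected = float(10.0 ** np.mean(halfs))
        assert resolution_fold(norm) == pytest.approx(expected, rel=1e-9)

    def test_too_few_levels_rejected(self):
        d = DilutionDesign.from_levels((100.0, 10.0), 3)
        norm = normalize_f0(perfect_table(genes=1, levels=(100.0, 10.0)), d)
        with pytest.raises(DomainError):
            resolution_fold(norm)


def _friedman_permutation_pvalue(table: pd.DataFrame) -> float:
    """Exact permutation null: permute method values within each indicator."""
    observed = rank_synthesis(table).statistic
    k = table.shape[0]
    stats_all = []
    cols = [table[c].to_numpy() for c in table.columns]
    perms = list(itertools.permutations(range(k)))
    for assignment in itertools.product(perms, repeat=len(cols)):
        perm = table.copy()
        for ci, (col, order) in enumerate(zip(table.columns, assignment)):
            perm[col] = cols[ci][list(order)]
        stats_all.append(rank_synthesis(perm).statistic)
    stats_all = np.asarray(stats_all)
    return float(np.mean(stats_all >= observed - 1e-12))


class TestRankSynthesis:
    def test_dominating_method_ranks(self):
        table = pd.DataFrame(
            {"i1": [0.1, 0.2], "i2": [1.0, 2.0], "i3": [5.0, 9.0]},
            index=["A", "B"],
        )
        rs = rank_synthesis(table)
        assert rs.mean_ranks["A"] == 1.0 and rs.mean_ranks["B"] == 2.0

    def test_complete_ties_statistic_zero(self):
        table = pd.DataFrame(np.ones((4, 3)), index=list("ABCD"), columns=list("xyz"))
        rs = rank_synthesis(table)
        assert rs.statistic == 0.0
        assert rs.pvalue == 1.0
        assert (rs.mean_ranks == 2.5).all()

    def test_identical_orderings_fixture(self):
        # 3 methods, 2 indicators, same ordering in both blocks
        table = pd.DataFrame(
            {"i1": [1.0, 2.0, 3.0], "i2": [0.1, 0.5, 0.9]}, index=list("ABC")
        )
        rs = rank_synthesis(table)
        assert rs.statistic == pytest.approx(4.0)
        assert rs.pvalue == pytest.approx(float(stats.chi2.sf(4.0, 2)))

    def test_matches_scipy_friedman_without_ties(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            rng.normal(size=(4, 6)), index=list("ABCD"),
            columns=[f"i{j}" for j in range(6)],
        )
        rs = rank_synthesis(table)
        # scipy blocks are rows of its arguments: pass one array per method
        ref = stats.friedmanchisquare(*[table.loc[m].to_numpy() for m in table.index])
        assert rs.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert rs.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_chi2_tail_close_to_exact_permutation(self):
        """In the rejection tail — where the test is used to call methods
        different — the chi-square p-value matches the exhaustive
        within-block permutation null to 0.02.  (Mid-range p-values of the
        chi-square approximation are known to run low at this block count;
        only tail agreement is asserted.)"""
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.normal(size=(3, 4)), index=list("ABC"),
            columns=[f"i{j}" for j in range(4)],
        )
        rs = rank_synthesis(table)
        assert rs.pvalue < 0.11  # fixture sits in the tail by construction
        p_exact = _friedman_permutation_pvalue(table)
        assert abs(rs.pvalue - p_exact) <= 0.02

    def test_higher_is_better_direction(self):
        table = pd.DataFrame({"acc": [0.9, 0.7], "err": [0.1, 0.3]}, index=["A", "B"])
        rs = rank_synthesis(table, directions={"acc": "higher"})
        assert rs.mean_ranks["A"] == 1.0

    def test_non_numeric_cells_rejected(self):
        table = pd.DataFrame({"i1": [1.0, "bad"], "i2": [2.0, 3.0]}, index=["A", "B"])
        with pytest.raises(FormatError):
            rank_synthesis(table)
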