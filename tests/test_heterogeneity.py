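"""Population statistics: summaries, correlations, ANOVA, matrix scope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ramanbca import (
    anova_between_lines,
    correlate_between,
    correlate_within,
    correlation_matrix,
    summarize_profiles,
)
from ramanbca.heterogeneity import OrganelleProfile, strength_label
from ramanbca.synthetic import build_population_spec, simulate_population


def make_profiles(data):
    """rows: (cell_line, cell_id, organelle, analyte, conc)"""
    return pd.DataFrame(
        data,
        columns=["cell_line", "cell_id", "organelle", "analyte",
                 "concentration_mgml"],
    )


class TestSummaries:
    def test_single_row_group(self):
        df = make_profiles([("A", "c1", "nucleolus", "protein", 80.0)])
        out = summarize_profiles(df)
        row = out.iloc[0]
        assert row["mean"] == row["min"] == row["max"] == 80.0
        assert row["sd"] == 0.0
        assert bool(row["single_obs"])

    def test_two_disjoint_cell_lines(self):
        df = make_profiles(
            [("A", f"a{i}", "ER", "protein", 50.0 + i) for i in range(3)]
            + [("B", f"b{i}", "ER", "protein", 90.0 + i) for i in range(3)])
        out = summarize_profiles(df)
        assert len(out) == 2
        means = dict(zip(out["cell_line"], out["mean"]))
        assert means == {"A": 51.0, "B": 91.0}

    def test_group_means_near_generator_truth(self):
        spec = build_population_spec(n_cells=500, cell_line="HeLa")
        df = simulate_population(spec, seed=21)
        out = summarize_profiles(df)
        from ramanbca.synthetic import DEFAULT_CONCENTRATIONS
        for _, row in out.iterrows():
            mu, sd = DEFAULT_CONCENTRATIONS[row["organelle"]][row["analyte"]]
            sem = sd / np.sqrt(row["n"])
            assert abs(row["mean"] - mu) < 2.5 * sem + 0.5  # truncation shifts slightly

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_profiles(make_profiles([]))


class TestCorrelateWithin:
    def test_perfect_positive(self):
        rows = []
        for i in range(10):
            rows.append(("A", f"c{i}", "nucleolus", "protein", 50.0 + 2 * i))
            rows.append(("A", f"c{i}", "nucleolus", "RNA", 25.0 + i))  # y = x/2
        res = correlate_within(make_profiles(rows), "nucleolus", ("protein", "RNA"))
        assert res.r == pytest.approx(1.0)
        assert res.strength == "strong"
        assert res.n == 10

    def test_perfect_negative(self):
        rows = []
        for i in range(10):
            rows.append(("A", f"c{i}", "ER", "protein", 50.0 + i))
            rows.append(("A", f"c{i}", "ER", "lipid", 60.0 - i))
        res = correlate_within(make_profiles(rows), "ER", ("protein", "lipid"))
        assert res.r == pytest.approx(-1.0)

    def test_simulated_level_recovered(self):
        spec = build_population_spec(
            n_cells=200, cell_line="HeLa",
            correlations={(("nucleolus", "protein"), ("nucleolus", "RNA")): 0.8})
        df = simulate_population(spec, seed=31)
        res = correlate_within(df, "nucleolus", ("protein", "RNA"))
        z, q = np.arctanh(0.8), 2.576 / np.sqrt(200 - 3)
        assert np.tanh(z - q) < res.r < np.tanh(z + q)
        assert res.ci95[0] < res.r < res.ci95[1]

    def test_zero_variance_rejected(self):
        rows = []
        for i in range(5):
            rows.append(("A", f"c{i}", "ER", "protein", 50.0))
            rows.append(("A", f"c{i}", "ER", "RNA", 10.0 + i))
        with pytest.raises(ValueError, match="variance"):
            correlate_within(make_profiles(rows), "ER", ("protein", "RNA"))


class TestCorrelateBetween:
    def test_identical_tables_r_one(self):
        rows = []
        for i in range(8):
            v = 40.0 + 3 * i
            rows.append(("A", f"c{i}", "nucleolus", "protein", v))
            rows.append(("A", f"c{i}", "ER", "protein", v))
        res = correlate_between(make_profiles(rows), "nucleolus", "protein",
                                "ER", "protein")
        assert res.r == pytest.approx(1.0)

    def test_independent_organelles_near_zero(self):
        spec = build_population_spec(n_cells=200, cell_line="HeLa")  # cov 0 across
        df = simulate_population(spec, seed=41)
        res = correlate_between(df, "nucleolus", "protein", "ER", "protein")
        assert abs(res.r) < 0.15

    def test_simulated_cross_level_recovered(self):
        spec = build_population_spec(
            n_cells=150, cell_line="WI-38",
            correlations={(("nucleolus", "protein"), ("ER", "protein")): 0.75})
        df = simulate_population(spec, seed=51)
        res = correlate_between(df, "nucleolus", "protein", "ER", "protein")
        z, q = np.arctanh(0.75), 2.576 / np.sqrt(150 - 3)
        assert np.tanh(z - q) < res.r < np.tanh(z + q)

    def test_missing_organelle_reported(self):
        rows = []
        for i in range(5):
            rows.append(("A", f"c{i}", "nucleolus", "protein", 50.0 + i))
        rows.append(("A", "c0", "ER", "protein", 40.0))
        with pytest.raises(ValueError, match="organelle"):
            correlate_between(make_profiles(rows), "nucleolus", "protein",
                              "ER", "protein")

    def test_duplicate_organelle_paired_by_order(self):
        # two mitochondria per cell: first vs second, acquisition order
        rows = []
        for i in range(6):
            v = 30.0 + i
            rows.append(("A", f"c{i}", "mitochondrion", "protein", v))
            rows.append(("A", f"c{i}", "mitochondrion", "protein", 2 * v))
        res = correlate_between(make_profiles(rows), "mitochondrion", "protein",
                                "mitochondrion", "protein")
        assert res.r == pytest.approx(1.0)
        assert res.n == 6


class TestAnova:
    def test_identical_groups(self):
        rows = [("A", f"a{i}", "ER", "protein", 70.0) for i in range(4)]
        rows += [("B", f"b{i}", "ER", "protein", 70.0) for i in range(4)]
        res = anova_between_lines(make_profiles(rows), "ER", "protein")
        assert res.F == 0.0
        assert res.p == 1.0
        assert not res.significant

    def test_f_equals_t_squared(self, rng):
        # closed-form equivalence for two groups
        a = rng.normal(70, 10, size=12)
        b = rng.normal(78, 10, size=15)
        rows = [("A", f"a{i}", "ER", "protein", v) for i, v in enumerate(a)]
        rows += [("B", f"b{i}", "ER", "protein", v) for i, v in enumerate(b)]
        res = anova_between_lines(make_profiles(rows), "ER", "protein")
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, abs=1e-9)
        assert res.p == pytest.approx(t.pvalue, abs=1e-9)

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        groups = {"A": rng.normal(70, 8, 10), "B": rng.normal(75, 8, 12),
                  "C": rng.normal(72, 8, 9)}
        rows = [(g, f"{g}{i}", "ER", "RNA", v)
                for g, vals in groups.items() for i, v in enumerate(vals)]
        df = make_profiles(rows)
        res = anova_between_lines(df, "ER", "RNA")
        fit = ols("concentration_mgml ~ C(cell_line)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        assert res.F == pytest.approx(table["F"].iloc[0], rel=1e-9)
        assert res.p == pytest.approx(table["PR(>F)"].iloc[0], rel=1e-9)

    def test_null_p_values_uniform(self):
        # Kolmogorov-Smirnov on 2000 null ANOVA p-values
        rng = np.random.default_rng(61)
        pvals = np.empty(2000)
        for i in range(2000):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            pvals[i] = stats.f_oneway(a, b).pvalue
        d = stats.kstest(pvals, "uniform").statistic
        # 1% critical value for n=2000 is ~1.63/sqrt(n)
        assert d < 1.63 / np.sqrt(2000)

    def test_single_group_rejected(self):
        rows = [("A", f"a{i}", "ER", "protein", 70.0 + i) for i in range(4)]
        with pytest.raises(ValueError, match="2 cell lines"):
            anova_between_lines(make_profiles(rows), "ER", "protein")


class TestCorrelationMatrix:
    def test_pair_counts_full_scope(self):
        spec = build_population_spec(n_cells=30, cell_line="HeLa")
        df = simulate_population(spec, seed=71)
        out = correlation_matrix(df)
        # 9 variables -> 36 unordered off-diagonal pairs + 9 diagonal
        assert len(out) == 45
        assert out["diagonal"].sum() == 9
        offdiag = out[~out["diagonal"]]
        assert len(offdiag) == 36
        assert offdiag["within_organelle"].sum() == 9
        assert (~offdiag["within_organelle"]).sum() == 27

    def test_two_analytes_one_organelle(self):
        rows = []
        for i in range(5):
            rows.append(("A", f"c{i}", "ER", "protein", 50.0 + i))
            rows.append(("A", f"c{i}", "ER", "RNA", 10.0 + 2 * i))
        out = correlation_matrix(make_profiles(rows))
        assert len(out) == 3  # 2 diagonal + 1 off-diagonal
        assert (out[out["diagonal"]]["r"] == 1.0).all()
        off = out[~out["diagonal"]].iloc[0]
        assert off["r"] == pytest.approx(1.0)

    def test_errors_collected_not_fatal(self):
        rows = []
        for i in range(5):
            rows.append(("A", f"c{i}", "ER", "protein", 50.0))  # zero variance
            rows.append(("A", f"c{i}", "ER", "RNA", 10.0 + i))
        out = correlation_matrix(make_profiles(rows))
        bad = out[(~out["diagonal"])].iloc[0]
        assert np.isnan(bad["r"])
        assert "variance" in bad["error"]


class TestProperties:
    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 10), b=st.floats(-50, 50),
        flip=st.booleans(),
    )
    def test_affine_invariance_of_r(self, seed, a, b, flip):
        rng = np.random.default_rng(seed)
        x = rng.normal(50, 10, 20)
        y = 0.5 * x + rng.normal(0, 5, 20)
        slope = -a if flip else a
        rows = []
        for i in range(20):
            rows.append(("A", f"c{i}", "ER", "protein", x[i]))
            rows.append(("A", f"c{i}", "ER", "RNA", y[i]))
        base = correlate_within(make_profiles(rows), "ER", ("protein", "RNA")).r
        rows2 = []
        for i in range(20):
            rows2.append(("A", f"c{i}", "ER", "protein", x[i]))
            rows2.append(("A", f"c{i}", "ER", "RNA", slope * y[i] + b))
        scaled = correlate_within(make_profiles(rows2), "ER", ("protein", "RNA")).r
        expected = -base if flip else base
        assert scaled == pytest.approx(expected, abs=1e-9)

    def test_strength_labels(self):
        assert strength_label(0.1) == "weak"
        assert strength_label(-0.35) == "moderate"
        assert strength_label(0.6) == "moderate-to-high"
        assert strength_label(-0.8) == "strong"

    def test_organelle_profile_validation(self):
        with pytest.raises(ValueError):
            OrganelleProfile("c1", "A", "golgi", {"protein": 80.0})
        with pytest.raises(ValueError):
            OrganelleProfile("c1", "A", "ER", {"protein": -1.0})
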