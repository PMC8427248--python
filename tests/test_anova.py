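import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import qtrial as qt
from qtrial.trial_core import TrialDataError
from tests.conftest import long_frame


def brute_force_rcbd_ss(y):
    """Sums of squared deviations computed by explicit loops (g x r)."""
    g, r = y.shape
    grand = y.sum() / y.size
    ss_g = sum(r * (y[i].mean() - grand) ** 2 for i in range(g))
    ss_b = sum(g * (y[:, k].mean() - grand) ** 2 for k in range(r))
    ss_tot = sum((y[i, k] - grand) ** 2 for i in range(g) for k in range(r))
    return ss_g, ss_b, ss_tot - ss_g - ss_b


def brute_force_combined_ss(y):
    """Direct-definition decomposition for the nested-blocks layout (g,e,r)."""
    g, e, r = y.shape
    grand = y.mean()
    ss_g = sum(e * r * (y[i].mean() - grand) ** 2 for i in range(g))
    ss_env = sum(g * r * (y[:, j].mean() - grand) ** 2 for j in range(e))
    ss_b = sum(g * (y[:, j, k].mean() - y[:, j].mean()) ** 2
               for j in range(e) for k in range(r))
    ss_ge = sum(r * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
                for i in range(g) for j in range(e))
    ss_tot = ((y - grand) ** 2).sum()
    return ss_g, ss_env, ss_b, ss_ge, ss_tot - ss_g - ss_env - ss_b - ss_ge


class TestRcbdAnova:
    def test_matches_brute_force_on_toy(self, toy_rcbd):
        a = qt.rcbd_anova(toy_rcbd, "y", "E1")
        y = toy_rcbd.trait_array("y", "E1")
        ss_g, ss_b, ss_e = brute_force_rcbd_ss(y)
        assert a.table.loc["genotype", "SS"] == pytest.approx(ss_g)
        assert a.table.loc["block", "SS"] == pytest.approx(ss_b)
        assert a.table.loc["error", "SS"] == pytest.approx(ss_e)
        assert a.table.loc["genotype", "df"] == 2
        assert a.table.loc["block", "df"] == 1
        assert a.table.loc["error", "df"] == 2
        assert a.table.loc["genotype", "F"] == pytest.approx(
            (ss_g / 2) / (ss_e / 2)
        )

    def test_all_equal_values_give_zero_ss_and_undefined_f(self):
        rows = [(g, "E1", b, "y", 3.0) for g in "ABC" for b in ("B1", "B2")]
        a = qt.rcbd_anova(qt.TrialTable(long_frame(rows)), "y", "E1")
        assert a.table.loc["genotype", "SS"] == 0
        assert np.isnan(a.table.loc["genotype", "F"])
        assert np.isnan(a.table.loc["genotype", "p"])  # undefined, not 1

    def test_unbalanced_refused_without_override(self, toy_rcbd):
        data = toy_rcbd.data.copy()
        data.loc[0, "value"] = np.nan
        t = qt.TrialTable(data)
        with pytest.raises(TrialDataError, match="unbalanced"):
            qt.rcbd_anova(t, "y", "E1")
        a = qt.rcbd_anova(t, "y", "E1", allow_unbalanced=True)
        assert a.table.loc["error", "df"] == 1  # one plot deleted


class TestCombinedAnova:
    def test_matches_brute_force_on_2x2x2(self, toy_combined):
        a = qt.combined_anova(toy_combined, "y")
        y = toy_combined.trait_array("y")
        ss = brute_force_combined_ss(y)
        for src, expected in zip(
            ["genotype", "environment", "block(environment)",
             "genotype x environment", "error"],
            [ss[0], ss[1], ss[2], ss[3], ss[4]],
        ):
            assert a.table.loc[src, "SS"] == pytest.approx(expected, abs=1e-10)
        assert a.table.loc["genotype", "df"] == 1
        assert a.table.loc["environment", "df"] == 1
        assert a.table.loc["block(environment)", "df"] == 2
        assert a.table.loc["genotype x environment", "df"] == 1
        assert a.table.loc["error", "df"] == 2

    def test_agrees_with_statsmodels_ols_decomposition(self, simulated_trial):
        """Independent cross-check: sequential OLS ANOVA reproduces the
        balanced decomposition source by source."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        a = qt.combined_anova(simulated_trial, "y")
        fit = smf.ols(
            "value ~ C(environment) + C(environment):C(block) "
            "+ C(genotype) + C(genotype):C(environment)",
            data=simulated_trial.data,
        ).fit()
        aov = sm.stats.anova_lm(fit, typ=1)
        pairs = {
            "environment": "C(environment)",
            "block(environment)": "C(environment):C(block)",
            "genotype": "C(genotype)",
            "genotype x environment": "C(genotype):C(environment)",
            "error": "Residual",
        }
        for ours, theirs in pairs.items():
            assert a.table.loc[ours, "SS"] == pytest.approx(
                aov.loc[theirs, "sum_sq"], rel=1e-8
            )
            assert a.table.loc[ours, "df"] == int(aov.loc[theirs, "df"])

    def test_single_environment_directed_to_rcbd(self):
        rows = [(g, "E1", b, "y", v) for (g, b), v in
                zip([(g, b) for g in "AB" for b in ("B1", "B2")], [1.0, 2, 3, 4])]
        with pytest.raises(TrialDataError, match="rcbd_anova"):
            qt.combined_anova(qt.TrialTable(long_frame(rows)), "y")

    def test_gxe_denominator_flag(self, simulated_trial):
        pooled = qt.combined_anova(simulated_trial, "y")
        mixed = qt.combined_anova(simulated_trial, "y", genotype_denominator="gxe")
        ms_g = pooled.table.loc["genotype", "MS"]
        ms_ge = pooled.table.loc["genotype x environment", "MS"]
        assert mixed.table.loc["genotype", "F"] == pytest.approx(ms_g / ms_ge)
        # other rows untouched
        assert mixed.table.loc["environment", "F"] == pytest.approx(
            pooled.table.loc["environment", "F"]
        )

    def test_null_gxe_f_averages_to_one(self):
        """With var_ge = 0 the expected G x E F ratio is ~1."""
        spec = qt.VarianceSpec(mu=0.0, var_g=2.0, var_resid=1.0)
        fs = [
            qt.combined_anova(
                qt.simulate_trial(qt.TrialDesign(g=8, e=3, r=3, seed=s), spec), "trait1"
            ).table.loc["genotype x environment", "F"]
            for s in range(300)
        ]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.06)

    def test_block_relabeling_leaves_genotype_ss_unchanged(self, simulated_trial):
        before = qt.combined_anova(simulated_trial, "y").table.loc["genotype", "SS"]
        data = simulated_trial.data.copy()
        swap = {"B01": "B02", "B02": "B03", "B03": "B01"}
        data.loc[data["environment"] == "E2", "block"] = data.loc[
            data["environment"] == "E2", "block"
        ].map(swap)
        after = qt.combined_anova(qt.TrialTable(data), "y").table.loc["genotype", "SS"]
        assert after == pytest.approx(before, rel=1e-12)


@given(seed=st.integers(0, 2**20), g=st.integers(2, 5), e=st.integers(2, 3),
       r=st.integers(2, 3))
def test_ss_and_df_additivity(seed, g, e, r):
    """SS of all sources sums to total SS and df to N-1 on any input."""
    spec = qt.VarianceSpec(mu=5.0, var_g=3.0, var_resid=1.0, var_e_env=2.0,
                           var_ge=1.0, var_block=0.5)
    t = qt.simulate_trial(qt.TrialDesign(g=g, e=e, r=r, seed=seed), spec)
    a = qt.combined_anova(t, "trait1")
    sources = a.table.drop(index="total")
    assert sources["SS"].sum() == pytest.approx(a.table.loc["total", "SS"], rel=1e-8)
    assert sources["df"].sum() == g * e * r - 1


class TestLsdCv:
    def test_lsd_matches_hand_computation(self, toy_rcbd):
        from scipy import stats

        a = qt.rcbd_anova(toy_rcbd, "y", "E1")
        lsd = qt.lsd_value(a, alpha=0.05)
        expected = stats.t.ppf(0.975, 2) * np.sqrt(2 * a.ms_error / 2)
        assert lsd == pytest.approx(expected)

    def test_lsd_normal_limit(self):
        """With MS_E = 2 and n = 4 the LSD tends to 1.96 as error df grow."""
        tab = pd.DataFrame(
            {"df": [100000, 1], "SS": [200000.0, 1.0], "MS": [2.0, 1.0],
             "F": np.nan, "p": np.nan},
            index=["error", "genotype"],
        )
        a = qt.AnovaTable(tab, "y", "single", 1.0, n_per_mean=4)
        assert qt.lsd_value(a, 0.05) == pytest.approx(1.96, abs=0.001)

    def test_lsd_strictly_increases_as_alpha_shrinks(self, toy_rcbd):
        a = qt.rcbd_anova(toy_rcbd, "y", "E1")
        lsds = [qt.lsd_value(a, alpha) for alpha in (0.5, 0.1, 0.05, 0.01)]
        assert all(x < y for x, y in zip(lsds, lsds[1:]))

    def test_lsd_invalid_alpha(self, toy_rcbd):
        a = qt.rcbd_anova(toy_rcbd, "y", "E1")
        for alpha in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                qt.lsd_value(a, alpha)

    def test_cv_arithmetic(self):
        tab = pd.DataFrame(
            {"df": [4], "SS": [16.0], "MS": [4.0], "F": np.nan, "p": np.nan},
            index=["error"],
        )
        a = qt.AnovaTable(tab, "y", "single", 20.0, n_per_mean=2)
        assert qt.cv_percent(a) == pytest.approx(10.0)
        tab0 = tab.assign(MS=0.0)
        assert qt.cv_percent(qt.AnovaTable(tab0, "y", "single", 20.0, 2)) == 0.0
        with pytest.raises(ValueError, match="nonzero"):
            qt.cv_percent(a, grand_mean=0.0)


class TestLetterGroups:
    def test_clear_separation(self):
        letters = qt.letter_groups({"A": 10.0, "B": 10.0, "C": 20.0}, lsd=1.0)
        assert letters["C"] == "a"
        assert letters["A"] == letters["B"] == "b"

    def test_all_within_lsd_share_one_letter(self):
        letters = qt.letter_groups({"A": 10.0, "B": 10.4, "C": 10.8}, lsd=1.0)
        assert set(letters.values()) == {"a"}

    def test_share_letter_iff_within_lsd(self):
        """The defining property of the display: a shared letter is exactly
        a mean difference within the LSD."""
        rng = np.random.default_rng(4)
        means = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 10, 12))}
        lsd = 1.7
        letters = qt.letter_groups(means, lsd)
        for a in means:
            for b in means:
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (abs(means[a] - means[b]) <= lsd)

    def test_reference_grain_yield_top_group(self, cowpea_means):
        """With the published grain-yield LSD of 0.12 t/ha the two top
        genotypes (1.99 and 1.95) share the leading letter."""
        from qtrial.datasets import cowpea_reference_lsd

        letters = qt.letter_groups(cowpea_means.means["GWT"],
                                   float(cowpea_reference_lsd()["GWT"]))
        assert "a" in letters["SARI-3-11-100"]
        assert "a" in letters["SARVX-09-004"]
        assert "a" not in letters["Songotra"]

    def test_nonpositive_lsd_rejected(self):
        with pytest.raises(ValueError):
            qt.letter_groups({"A": 1.0, "B": 2.0}, lsd=0.0)


def test_mean_separation_assembles_consistent_summary(simulated_trial):
    sep = qt.mean_separation(simulated_trial, "y")
    a = qt.combined_anova(simulated_trial, "y")
    assert sep.lsd == pytest.approx(qt.lsd_value(a))
    assert sep.cv == pytest.approx(qt.cv_percent(a))
    assert set(sep.letters) == set(simulated_trial.genotypes)
    assert sep.grand_mean == pytest.approx(float(a.grand_mean))
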