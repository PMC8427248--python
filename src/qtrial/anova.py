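"""RCBD analysis of variance, LSD mean separation, CV% and letter display.

Single-environment layout:  genotype (g-1), block (r-1), error (g-1)(r-1).
Combined (multi-environment) layout with blocks nested in environments
(blocks re-randomized each year):

    genotype            g-1
    environment         e-1
    block(environment)  e(r-1)
    genotype x env      (g-1)(e-1)
    error (pooled)      e(g-1)(r-1)

Sums of squares come from the standard balanced decomposition around
marginal means.  By default every F statistic uses the pooled error mean
square as denominator, matching the usual fixed-effects presentation of a
combined variety-trial ANOVA; ``genotype_denominator='gxe'`` switches the
genotype test to the G x E mean square (the conservative choice when
environments are regarded as random).

A mean square of zero makes F undefined; it is reported as NaN (and so is
its p-value), never as infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_core import TrialTable, TrialDataError, genotype_means

ANOVA_COLUMNS = ["df", "SS", "MS", "F", "p"]


@dataclass
class AnovaTable:
    """Sources-of-variation table for one trait.

    ``table`` is indexed by source with columns df, SS, MS, F, p; the total
    row carries only df and SS.  ``layout`` is ``'single'`` or ``'combined'``.
    """

    table: pd.DataFrame
    trait: str
    layout: str
    grand_mean: float
    n_per_mean: int  # plots averaged into one genotype mean

    @property
    def ms_error(self) -> float:
        return float(self.table.loc["error", "MS"])

    @property
    def df_error(self) -> int:
        return int(self.table.loc["error", "df"])

    @property
    def ms_genotype(self) -> float:
        return float(self.table.loc["genotype", "MS"])


def _finish(rows: dict, denom_ms: float, denom_df: int, f_sources: list[str]) -> pd.DataFrame:
    """Attach MS, F and p columns; undefined ratios become NaN."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["df", "SS"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df["MS"] = np.where(df["df"] > 0, df["SS"] / df["df"], np.nan)
    df["F"] = np.nan
    df["p"] = np.nan
    for src in f_sources:
        ms = df.loc[src, "MS"]
        if denom_ms > 0 and np.isfinite(ms):
            f = ms / denom_ms
            df.loc[src, "F"] = f
            df.loc[src, "p"] = stats.f.sf(f, df.loc[src, "df"], denom_df)
    total = pd.DataFrame(
        {"df": [int(df["df"].sum())], "SS": [df["SS"].sum()], "MS": np.nan,
         "F": np.nan, "p": np.nan},
        index=["total"],
    )
    out = pd.concat([df, total])
    out["df"] = out["df"].astype(int)
    return out


def _unbalanced_anova(table: TrialTable, trait: str, environment: str | None):
    """Plot-deletion ANOVA for unbalanced data via an OLS sequential fit.

    Missing plots are dropped and degrees of freedom reduced accordingly;
    the expected-mean-square identities of the balanced layout no longer
    hold exactly, so this path requires the explicit ``allow_unbalanced``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = table.data[(table.data["trait"] == trait) & table.data["value"].notna()].copy()
    if environment is not None:
        sub = sub[sub["environment"] == environment]
        formula = "value ~ C(block) + C(genotype)"
        rename = {"C(block)": "block", "C(genotype)": "genotype"}
    else:
        formula = (
            "value ~ C(environment) + C(environment):C(block) "
            "+ C(genotype) + C(genotype):C(environment)"
        )
        rename = {
            "C(environment)": "environment",
            "C(environment):C(block)": "block(environment)",
            "C(genotype)": "genotype",
            "C(genotype):C(environment)": "genotype x environment",
        }
    fit = smf.ols(formula, data=sub).fit()
    aov = sm.stats.anova_lm(fit, typ=1).rename(index=rename)
    rows = {src: (int(aov.loc[src, "df"]), float(aov.loc[src, "sum_sq"]))
            for src in rename.values()}
    rows["error"] = (int(aov.loc["Residual", "df"]), float(aov.loc["Residual", "sum_sq"]))
    return rows, float(sub["value"].mean())


def rcbd_anova(
    table: TrialTable,
    trait: str,
    environment: str,
    allow_unbalanced: bool = False,
) -> AnovaTable:
    """Single-environment RCBD ANOVA for one trait.

    F for genotype (and block) is tested against the error mean square;
    p-values come from the upper tail of the F distribution.
    """
    g, e, r = table.design_counts
    if r < 2:
        raise TrialDataError("RCBD ANOVA requires at least 2 blocks")
    try:
        y = table.trait_array(trait, environment=environment)  # (g, r)
    except TrialDataError:
        if not allow_unbalanced:
            raise
        rows, grand = _unbalanced_anova(table, trait, environment)
        edf, ess = rows["error"]
        tab = _finish(rows, ess / edf if edf > 0 else 0.0, edf, ["block", "genotype"])
        return AnovaTable(tab, trait, "single", grand, n_per_mean=r)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_b = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_e = ss_total - ss_g - ss_b
    rows = {
        "block": (r - 1, ss_b),
        "genotype": (g - 1, ss_g),
        "error": ((g - 1) * (r - 1), ss_e),
    }
    ms_e = ss_e / ((g - 1) * (r - 1))
    tab = _finish(rows, ms_e, (g - 1) * (r - 1), ["block", "genotype"])
    return AnovaTable(tab, trait, "single", float(grand), n_per_mean=r)


def combined_anova(
    table: TrialTable,
    trait: str,
    genotype_denominator: str = "pooled",
    allow_unbalanced: bool = False,
) -> AnovaTable:
    """Combined ANOVA over environments with blocks nested in environments."""
    g, e, r = table.design_counts
    if e < 2:
        raise TrialDataError(
            "combined ANOVA needs at least 2 environments; use rcbd_anova for one"
        )
    if r < 2:
        raise TrialDataError("combined ANOVA requires at least 2 blocks")
    if genotype_denominator not in ("pooled", "gxe"):
        raise ValueError(f"genotype_denominator must be 'pooled' or 'gxe'")

    try:
        y = table.trait_array(trait)  # (g, e, r)
    except TrialDataError:
        if not allow_unbalanced:
            raise
        rows, grand = _unbalanced_anova(table, trait, None)
        edf, ess = rows["error"]
        tab = _finish(
            rows, ess / edf if edf > 0 else 0.0, edf,
            ["environment", "block(environment)", "genotype", "genotype x environment"],
        )
        return AnovaTable(tab, trait, "combined", grand, n_per_mean=e * r)

    grand = y.mean()
    gm = y.mean(axis=(1, 2))          # genotype means
    em = y.mean(axis=(0, 2))          # environment means
    bm = y.mean(axis=0)               # (e, r) block-within-env means
    gem = y.mean(axis=2)              # (g, e) cell means

    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(e * r * ((gm - grand) ** 2).sum())
    ss_env = float(g * r * ((em - grand) ** 2).sum())
    ss_b = float(g * ((bm - em[:, None]) ** 2).sum())
    ss_ge = float(r * ((gem - gm[:, None] - em[None, :] + grand) ** 2).sum())
    ss_e = ss_total - ss_g - ss_env - ss_b - ss_ge

    df_e = e * (g - 1) * (r - 1)
    rows = {
        "environment": (e - 1, ss_env),
        "block(environment)": (e * (r - 1), ss_b),
        "genotype": (g - 1, ss_g),
        "genotype x environment": ((g - 1) * (e - 1), ss_ge),
        "error": (df_e, ss_e),
    }
    ms_e = ss_e / df_e
    tab = _finish(
        rows, ms_e, df_e,
        ["environment", "block(environment)", "genotype", "genotype x environment"],
    )
    if genotype_denominator == "gxe":
        ms_ge = tab.loc["genotype x environment", "MS"]
        df_ge = int(tab.loc["genotype x environment", "df"])
        if ms_ge > 0:
            f = tab.loc["genotype", "MS"] / ms_ge
            tab.loc["genotype", "F"] = f
            tab.loc["genotype", "p"] = stats.f.sf(f, g - 1, df_ge)
        else:
            tab.loc["genotype", ["F", "p"]] = np.nan
    return AnovaTable(tab, trait, "combined", float(grand), n_per_mean=e * r)


def lsd_value(anova: AnovaTable, alpha: float = 0.05, n_per_mean: int | None = None) -> float:
    """Least significant difference between two genotype means at level alpha.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n), with n the
    number of plots averaged into each mean (r, or e*r for the combined
    layout).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if anova.df_error < 1:
        raise ValueError("error degrees of freedom must be >= 1")
    n = anova.n_per_mean if n_per_mean is None else n_per_mean
    t = stats.t.ppf(1 - alpha / 2, anova.df_error)
    return float(t * np.sqrt(2.0 * anova.ms_error / n))


def cv_percent(anova: AnovaTable, grand_mean: float | None = None) -> float:
    """Experimental coefficient of variation, 100 * sqrt(MS_error) / mean."""
    mean = anova.grand_mean if grand_mean is None else grand_mean
    if mean == 0:
        raise ValueError("grand mean must be nonzero for CV%")
    return float(100.0 * np.sqrt(anova.ms_error) / abs(mean))


def letter_groups(means, lsd: float) -> dict[str, str]:
    """Compact letter display from all pairwise LSD comparisons.

    Genotypes whose means differ by at most ``lsd`` share at least one
    letter; letters are assigned to the maximal runs of the descending-sorted
    means whose range does not exceed ``lsd``.  Ties in the sort are broken
    by input order, making the display deterministic.
    """
    if lsd <= 0:
        raise ValueError(f"lsd must be positive, got {lsd}")
    if isinstance(means, pd.Series):
        items = list(means.items())
    else:
        items = list(dict(means).items())
    # stable sort descending on mean; ties keep input order
    order = sorted(range(len(items)), key=lambda i: -items[i][1])
    names = [items[i][0] for i in order]
    vals = np.array([items[i][1] for i in order])

    # maximal intervals [a, b] with vals[a] - vals[b] <= lsd; b is monotone in a,
    # and an interval is maximal exactly when its b exceeds the previous one
    intervals = []
    b = 0
    for a in range(len(vals)):
        b = max(b, a)
        while b + 1 < len(vals) and vals[a] - vals[b + 1] <= lsd:
            b += 1
        if not intervals or b > intervals[-1][1]:
            intervals.append((a, b))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for idx, (a, b) in enumerate(intervals):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for i in range(a, b + 1):
            letters[names[i]] += ch
    return {name: letters[name] for name, _ in items}


@dataclass
class MeanSeparation:
    """Genotype means with LSD separation summary for one trait."""

    means: pd.Series
    sds: pd.Series
    letters: dict[str, str]
    lsd: float
    cv: float
    alpha: float
    grand_mean: float
    trait: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "sd": self.sds,
             "letters": pd.Series(self.letters)}
        )


def mean_separation(
    table: TrialTable,
    trait: str,
    alpha: float = 0.05,
    sd_basis: str = "plots",
    genotype_denominator: str = "pooled",
) -> MeanSeparation:
    """Genotype means of one trait with LSD letters, LSD and CV%.

    Uses the combined ANOVA error term when the trial has several
    environments, the single-environment RCBD error otherwise.
    """
    g, e, r = table.design_counts
    if e >= 2:
        aov = combined_anova(table, trait, genotype_denominator=genotype_denominator)
    else:
        aov = rcbd_anova(table, trait, table.environments[0])
    col = genotype_means(table, trait, sd_basis=sd_basis)
    lsd = lsd_value(aov, alpha=alpha)
    cv = cv_percent(aov)
    letters = letter_groups(col["mean"], lsd) if lsd > 0 else {
        name: "a" for name in col.index
    }
    return MeanSeparation(
        means=col["mean"], sds=col["sd"], letters=letters, lsd=lsd, cv=cv,
        alpha=alpha, grand_mean=col.attrs["grand_mean"], trait=trait,
    )
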