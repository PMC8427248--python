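"""Variance components, heritability, variability coefficients and genetic
advance from RCBD mean squares.

Method-of-moments estimators from the genotype and error mean squares of a
balanced analysis:

    sigma_g^2 = (MS_G - MS_E) / r_eff        genotypic variance
    sigma_e^2 = MS_E                         environmental (error) variance
    sigma_p^2 = sigma_g^2 + sigma_e^2        phenotypic variance

where r_eff is the number of plots averaged into one genotype mean (r for a
single environment, e*r for a combined analysis — only the latter makes the
combined-analysis MS_G commensurate with per-mean variance).  From these:

    GCV = 100 * sigma_g / mu      genotypic coefficient of variation, %
    PCV = 100 * sigma_p / mu      phenotypic coefficient of variation, %
    h2  = 100 * sigma_g^2 / sigma_p^2          broad-sense heritability, %
    GA  = i * sigma_p * h2                     expected genetic advance
    GAM = 100 * GA / mu                        GA as percent of the mean

with i the standardized selection differential (2.06 at 5 % selection
intensity) and h2 used as a proportion inside GA.  A negative moment
estimate of sigma_g^2 is truncated to zero in reported summaries; the raw
value is preserved for diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import combined_anova, rcbd_anova
from .trial_core import TrialTable

#: standardized selection differential at 5 % selection intensity
DEFAULT_SELECTION_INTENSITY = 2.06


@dataclass(frozen=True)
class VarianceComponents:
    """Moment estimates of the variance decomposition for one trait."""

    var_g: float
    var_e: float
    var_p: float
    ms_g: float
    ms_e: float
    r_effective: int
    var_g_raw: float
    truncated: bool


def variance_components(ms_g: float, ms_e: float, r: int) -> VarianceComponents:
    """Estimate (sigma_g^2, sigma_e^2, sigma_p^2) from mean squares.

    ``r`` is the effective replication: the number of plots behind each
    genotype mean.
    """
    if r < 1:
        raise ValueError(f"replication r must be >= 1, got {r}")
    if ms_g < 0 or ms_e < 0:
        raise ValueError("mean squares must be nonnegative")
    raw = (ms_g - ms_e) / r
    truncated = raw < 0
    var_g = 0.0 if truncated else raw
    return VarianceComponents(
        var_g=var_g, var_e=ms_e, var_p=var_g + ms_e,
        ms_g=ms_g, ms_e=ms_e, r_effective=r,
        var_g_raw=raw, truncated=truncated,
    )


def components_from_values(var_g: float, var_e: float) -> VarianceComponents:
    """Wrap already-known component values (e.g. a published table)."""
    if var_g < 0 or var_e < 0:
        raise ValueError("variances must be nonnegative")
    return VarianceComponents(
        var_g=var_g, var_e=var_e, var_p=var_g + var_e,
        ms_g=np.nan, ms_e=var_e, r_effective=1,
        var_g_raw=var_g, truncated=False,
    )


def coefficients_of_variation(vc: VarianceComponents, mu: float) -> tuple[float, float]:
    """(GCV%, PCV%): component standard deviations scaled by the grand mean."""
    if mu <= 0:
        raise ValueError(f"grand mean must be positive, got {mu}")
    gcv = 100.0 * np.sqrt(vc.var_g) / mu
    pcv = 100.0 * np.sqrt(vc.var_p) / mu
    return float(gcv), float(pcv)


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability h2 = 100 * sigma_g^2 / sigma_p^2, percent."""
    if vc.var_p <= 0:
        raise ValueError("phenotypic variance is zero: degenerate trait")
    # var_g/var_p can overshoot 1 by an ulp when var_e is 0
    return float(min(100.0, max(0.0, 100.0 * vc.var_g / vc.var_p)))


def genetic_advance(
    vc: VarianceComponents,
    h2: float,
    mu: float,
    i: float = DEFAULT_SELECTION_INTENSITY,
) -> tuple[float, float]:
    """(GA, GAM%): expected response to truncation selection.

    ``h2`` is on the 0-100 percent scale as printed in summary tables; it is
    converted to a proportion internally.
    """
    if mu <= 0:
        raise ValueError(f"grand mean must be positive, got {mu}")
    if vc.var_p < 0:
        raise ValueError("phenotypic variance must be nonnegative")
    ga = i * np.sqrt(vc.var_p) * (h2 / 100.0)
    return float(ga), float(100.0 * ga / mu)


def classify(value: float, low: float, high: float) -> str:
    """Conventional low/moderate/high banding used in variability studies."""
    if value < low:
        return "low"
    if value < high:
        return "moderate"
    return "high"


def genetic_summary(
    table: TrialTable,
    i: float = DEFAULT_SELECTION_INTENSITY,
    r_policy: str = "combined",
    genotype_denominator: str = "pooled",
    annotate: bool = False,
) -> pd.DataFrame:
    """Per-trait genetic-parameter summary from a balanced trial.

    Runs the combined ANOVA per trait (single-environment RCBD when the
    trial has one environment), extracts MS_G and MS_E, and applies the
    moment estimators.  ``r_policy='combined'`` uses r_eff = e*r (plots per
    genotype mean in the combined analysis); ``'per_env'`` uses r.

    Returns a DataFrame indexed by trait with columns
    ``var_e, var_g, var_p, h2, gcv, pcv, ga, gam, mu`` (percent scales as
    conventionally printed), plus the truncation flag; with
    ``annotate=True``, conventional low/moderate/high bands are appended
    (10/20 cutoffs for GCV, PCV and GAM; 30/60 for h2).
    """
    if r_policy not in ("combined", "per_env"):
        raise ValueError("r_policy must be 'combined' or 'per_env'")
    g, e, r = table.design_counts
    r_eff = e * r if r_policy == "combined" else r
    rows = {}
    for trait in table.traits:
        if e >= 2:
            aov = combined_anova(table, trait, genotype_denominator=genotype_denominator)
        else:
            aov = rcbd_anova(table, trait, table.environments[0])
        vc = variance_components(aov.ms_genotype, aov.ms_error, r_eff)
        mu = aov.grand_mean
        h2 = broad_sense_heritability(vc)
        gcv, pcv = coefficients_of_variation(vc, mu)
        ga, gam = genetic_advance(vc, h2, mu, i=i)
        rows[trait] = {
            "var_e": vc.var_e, "var_g": vc.var_g, "var_p": vc.var_p,
            "h2": h2, "gcv": gcv, "pcv": pcv, "ga": ga, "gam": gam,
            "mu": mu, "var_g_raw": vc.var_g_raw, "truncated": vc.truncated,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[list(table.traits)]
    if annotate:
        out["gcv_band"] = [classify(v, 10, 20) for v in out["gcv"]]
        out["pcv_band"] = [classify(v, 10, 20) for v in out["pcv"]]
        out["h2_band"] = [classify(v, 30, 60) for v in out["h2"]]
        out["gam_band"] = [classify(v, 10, 20) for v in out["gam"]]
    return out


def summary_from_components(
    components: pd.DataFrame, i: float = DEFAULT_SELECTION_INTENSITY
) -> pd.DataFrame:
    """Recompute the full parameter chain from (var_g, var_e, mu) columns.

    Useful for checking the internal consistency of a published
    variance-component table: every derived column (var_p, h2, gcv, pcv,
    ga, gam) is recomputed from the three inputs alone.
    """
    rows = {}
    for trait, row in components.iterrows():
        vc = components_from_values(float(row["var_g"]), float(row["var_e"]))
        mu = float(row["mu"])
        h2 = broad_sense_heritability(vc)
        gcv, pcv = coefficients_of_variation(vc, mu)
        ga, gam = genetic_advance(vc, h2, mu, i=i)
        rows[trait] = {
            "var_e": vc.var_e, "var_g": vc.var_g, "var_p": vc.var_p,
            "h2": h2, "gcv": gcv, "pcv": pcv, "ga": ga, "gam": gam, "mu": mu,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[components.index]
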