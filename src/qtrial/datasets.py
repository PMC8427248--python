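"""Reference summary tables from a published three-year cowpea trial.

Seventeen cowpea genotypes (sixteen advanced breeding lines plus the check
variety Songotra) were evaluated over three years in an RCBD with three
blocks, for eight traits:

====== ===========================================  ======
trait  meaning                                       units
====== ===========================================  ======
DFF    days to 50 % flowering                        days
DNPM   days to 90 % pod maturity                     days
PHM    plant height at maturity                      cm
NPP    number of pods per plant                      count
PODWT  pod yield                                     t/ha
NSP    number of seeds per pod                       count
GWT    grain yield                                   t/ha
HSW    100-seed weight                               g
====== ===========================================  ======

The raw plot data were not deposited; what is reproduced here are the
published genotype-mean table (means and standard deviations, with the
grand-mean, LSD and CV footer rows) and the variance-component / genetic-
parameter summary.  These tables serve as fixtures for the multivariate
stages (which operate on genotype means), for internal-consistency checks
of the parameter chain, and as realistic variance scales for the synthetic
trial generator.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .trial_core import GenotypeMeanTable

TRAITS = ("DFF", "DNPM", "PHM", "NPP", "PODWT", "NSP", "GWT", "HSW")

# genotype: DFF DNPM PHM NPP PODWT NSP GWT HSW  (mean, sd) pairs interleaved
_MEANS_CSV = """\
genotype,DFF,DFF_sd,DNPM,DNPM_sd,PHM,PHM_sd,NPP,NPP_sd,PODWT,PODWT_sd,NSP,NSP_sd,GWT,GWT_sd,HSW,HSW_sd
IT07K-299-6,41.78,1.41,64.44,0.29,30.56,1.36,25.11,4.34,2.77,0.30,14.78,1.23,1.91,0.20,16.80,0.70
IT08K-125-107,41.22,0.86,63.56,1.18,37.00,7.80,14.33,6.44,1.68,0.80,11.78,1.77,1.16,0.50,18.47,0.90
IT10K-836-2,41.56,1.19,64.33,0.41,24.22,4.97,21.11,0.34,2.39,0.10,12.78,0.77,1.78,0.10,18.87,1.30
Songotra,42.11,1.57,64.67,0.07,30.00,0.80,19.42,1.35,2.43,0.01,13.67,0.12,1.68,0.01,16.64,0.90
SARI-2-2-1,39.56,0.81,62.56,2.18,30.11,0.92,15.78,4.99,2.44,0.11,13.33,0.22,1.52,0.20,16.74,0.80
SARI-2-3-4,40.89,0.52,65.56,0.82,21.44,7.75,12.00,8.77,1.96,0.50,13.11,0.44,1.40,0.30,16.37,1.20
SARI-3-11-100,43.11,2.75,67.22,2.48,40.89,11.69,25.20,4.43,2.87,0.40,15.22,1.67,1.99,0.30,21.27,3.70
SARI-3-11-45,40.56,0.19,66.56,1.82,32.33,3.14,21.24,0.47,2.61,0.20,13.89,0.34,1.77,0.10,18.25,0.70
SARI-3-11-80,39.44,0.92,65.56,0.82,31.78,2.58,22.42,1.65,2.42,0.12,13.44,0.10,1.71,0.02,18.82,1.30
SARI-3-11-90,42.00,1.63,67.00,2.26,26.33,2.86,20.51,0.26,2.55,0.10,14.00,0.45,1.75,0.10,17.55,0.01
SARI-5-5-5,37.11,3.25,59.78,4.96,28.44,0.75,24.60,3.83,2.65,0.20,13.78,0.23,1.80,0.10,16.86,0.70
SARI-6-2-6,43.33,2.97,68.33,3.60,29.00,0.20,24.33,3.56,2.81,0.40,14.00,0.45,1.88,0.20,18.18,0.70
SARI-6-2-9,37.56,2.81,63.33,1.41,23.33,5.86,16.27,4.50,2.13,0.30,12.00,1.55,1.51,0.20,16.33,1.20
SARVX-09-001,38.44,1.92,63.78,0.96,27.67,1.53,20.29,0.48,2.55,0.10,13.00,0.55,1.72,0.02,16.76,0.80
SARVX-09-002,39.33,1.03,64.78,0.04,27.22,1.97,23.11,2.34,2.37,0.10,13.56,0.01,1.71,0.02,16.60,0.90
SARVX-09-003,38.78,1.59,64.44,0.29,28.11,1.08,23.80,3.30,2.34,0.10,13.33,0.22,1.63,0.10,16.61,0.90
SARVX-09-004,39.44,0.92,64.67,0.07,27.89,1.31,23.58,2.81,2.71,0.30,14.67,1.12,1.95,0.30,16.81,0.70
"""

# published footer rows of the mean table
_GRAND_MEANS = {"DFF": 40.37, "DNPM": 64.74, "PHM": 29.20, "NPP": 20.77,
                "PODWT": 2.50, "NSP": 13.55, "GWT": 1.70, "HSW": 17.50}
_LSD_005 = {"DFF": 1.44, "DNPM": 1.04, "PHM": 2.04, "NPP": 2.64,
            "PODWT": 0.21, "NSP": 1.16, "GWT": 0.12, "HSW": 0.57}
_CV_PCT = {"DFF": 3.9, "DNPM": 1.7, "PHM": 3.4, "NPP": 13.7, "PODWT": 9,
           "NSP": 9.2, "GWT": 7.7, "HSW": 3.5}

# published variance components and derived genetic parameters per trait:
# var_e, var_g, var_p, h2 (%), GCV, PCV, GA, GAM (%); mu is the grand mean
_SUMMARY_CSV = """\
trait,var_e,var_g,var_p,h2,gcv,pcv,ga,gam
DFF,2.68,9.35,12.03,77.72,7.57,8.59,5.56,13.78
DNPM,1.32,11.35,12.67,89.58,5.20,5.50,6.58,10.16
PHM,16.68,60.92,77.60,78.51,26.73,30.17,14.27,48.86
NPP,9.59,45.01,54.60,82.44,32.30,35.58,12.57,60.51
PODWT,0.07,0.26,0.33,78.79,20.40,22.98,0.93,37.35
NSP,1.55,1.90,3.45,55.03,10.16,13.70,2.11,15.55
GWT,0.02,0.13,0.15,86.36,20.94,22.53,0.68,40.14
HSW,0.46,4.97,5.43,91.52,12.73,13.31,4.40,25.13
"""

#: design of the reference trial
DESIGN = {"g": 17, "e": 3, "r": 3}


def cowpea_reference_means() -> GenotypeMeanTable:
    """Published genotype-by-trait mean table (17 genotypes x 8 traits).

    SDs are the published per-genotype standard deviations (taken over the
    three year means, ``sd_basis='env_means'``); grand means are the
    published footer row.
    """
    df = pd.read_csv(io.StringIO(_MEANS_CSV), index_col="genotype")
    means = df[list(TRAITS)]
    sds = df[[f"{t}_sd" for t in TRAITS]]
    sds.columns = list(TRAITS)
    return GenotypeMeanTable(
        means=means,
        sds=sds,
        grand_means=pd.Series(_GRAND_MEANS)[list(TRAITS)],
        sd_basis="env_means",
    )


def cowpea_reference_summary() -> pd.DataFrame:
    """Published variance components and genetic parameters per trait.

    Columns: var_e, var_g, var_p, h2 (%), gcv, pcv, ga, gam (%), mu
    (grand mean, from the mean-table footer).
    """
    df = pd.read_csv(io.StringIO(_SUMMARY_CSV), index_col="trait")
    df["mu"] = pd.Series(_GRAND_MEANS)
    return df.loc[list(TRAITS)]


def cowpea_reference_lsd() -> pd.Series:
    """Published LSD (alpha = 0.05) footer row of the mean table."""
    return pd.Series(_LSD_005)[list(TRAITS)]


def cowpea_reference_cv() -> pd.Series:
    """Published CV% footer row of the mean table."""
    return pd.Series(_CV_PCT)[list(TRAITS)].astype(float)
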