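"""Plot-level trial data model, validation and CSV I/O.

A multi-environment variety trial laid out as a randomized complete block
design (RCBD) produces one observation per (genotype, environment, block,
trait).  :class:`TrialTable` is the canonical long-form container for those
observations; :class:`GenotypeMeanTable` holds the derived genotype-by-trait
mean table (the familiar "Table of means" of a variety-trial report).

Two CSV dialects are accepted on read:

* long — columns ``genotype, environment, block, trait, value``
* wide  — columns ``genotype, environment, block, <trait1>, <trait2>, ...``
  (one row per plot, the way field books are usually kept)

Wide input is melted to the long canonical form internally.  Label order is
preserved as encountered in the input so that output tables reproduce the
original row order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

KEY_COLUMNS = ("genotype", "environment", "block")
LONG_COLUMNS = KEY_COLUMNS + ("trait", "value")


class TrialDataError(ValueError):
    """Raised for structurally invalid trial data (duplicates, bad cells)."""


def _ordered_unique(values: Iterable) -> tuple:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return tuple(seen)


@dataclass
class TrialTable:
    """Long-form plot-level observations of a (possibly multi-year) RCBD.

    Parameters
    ----------
    data
        DataFrame with columns ``genotype, environment, block, trait, value``.
        Missing observations are carried as NaN values, never dropped.
    """

    data: pd.DataFrame
    genotypes: tuple = field(init=False)
    environments: tuple = field(init=False)
    blocks: tuple = field(init=False)
    traits: tuple = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise TrialDataError(f"missing required columns: {missing}")
        df = df.loc[:, list(LONG_COLUMNS)].copy()
        for c in KEY_COLUMNS + ("trait",):
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce").astype(float)

        dup = df.duplicated(subset=["genotype", "environment", "block", "trait"])
        if dup.any():
            first = df.loc[dup].iloc[0]
            raise TrialDataError(
                "duplicate plot key: genotype={genotype!r} environment={environment!r} "
                "block={block!r} trait={trait!r}".format(**first.to_dict())
            )
        if np.isinf(df["value"].to_numpy()).any():
            raise TrialDataError("non-finite trait value encountered")

        self.data = df.reset_index(drop=True)
        self.genotypes = _ordered_unique(df["genotype"])
        self.environments = _ordered_unique(df["environment"])
        self.blocks = _ordered_unique(df["block"])
        self.traits = _ordered_unique(df["trait"])

    # -- design bookkeeping -------------------------------------------------

    @property
    def design_counts(self) -> tuple[int, int, int]:
        """(g, e, r): genotypes, environments, blocks per environment."""
        return len(self.genotypes), len(self.environments), len(self.blocks)

    def n_missing(self, trait: str) -> int:
        sub = self.data[self.data["trait"] == trait]
        g, e, r = self.design_counts
        return g * e * r - int(sub["value"].notna().sum())

    def is_balanced(self, trait: str) -> bool:
        """True when every (genotype, environment, block) cell is observed."""
        return self.n_missing(trait) == 0

    # -- numeric views ------------------------------------------------------

    def trait_array(self, trait: str, environment: str | None = None) -> np.ndarray:
        """Balanced observation array, shape (g, e, r) (or (g, r) for one env).

        Cells are ordered by first-appearance label order.  Raises on missing
        cells: balanced expected-mean-square algebra requires a full layout.
        """
        if trait not in self.traits:
            raise TrialDataError(f"unknown trait {trait!r}")
        sub = self.data[self.data["trait"] == trait]
        if environment is not None:
            if environment not in self.environments:
                raise TrialDataError(f"unknown environment {environment!r}")
            sub = sub[sub["environment"] == environment]
            envs = (environment,)
        else:
            envs = self.environments
        g, r = len(self.genotypes), len(self.blocks)
        e = len(envs)
        gi = pd.Categorical(sub["genotype"], categories=self.genotypes).codes
        ei = pd.Categorical(sub["environment"], categories=envs).codes
        bi = pd.Categorical(sub["block"], categories=self.blocks).codes
        arr = np.full((g, e, r), np.nan)
        arr[gi, ei, bi] = sub["value"].to_numpy()
        if np.isnan(arr).any():
            raise TrialDataError(
                f"trait {trait!r} is unbalanced: "
                f"{int(np.isnan(arr).sum())} of {arr.size} cells missing"
            )
        return arr[:, 0, :] if environment is not None else arr

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, source) -> "TrialTable":
        """Read a long- or wide-dialect trial CSV (path, stream or string)."""
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
        df.columns = [c.strip().lower() for c in df.columns]
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise TrialDataError(f"header must name columns {missing}")
        if "trait" in df.columns and "value" in df.columns:
            long = df
        else:
            trait_cols = [c for c in df.columns if c not in KEY_COLUMNS]
            if not trait_cols:
                raise TrialDataError("no trait columns found")
            long = df.melt(
                id_vars=list(KEY_COLUMNS),
                value_vars=trait_cols,
                var_name="trait",
                value_name="value",
            )
        vals = pd.to_numeric(long["value"], errors="coerce")
        bad = vals.isna() & long["value"].notna() & (long["value"].astype(str).str.strip() != "")
        if bad.any():
            i = int(bad.idxmax())
            raise TrialDataError(
                f"non-numeric trait cell {long.loc[i, 'value']!r} at input row {i} "
                f"(genotype={long.loc[i, 'genotype']!r}, trait={long.loc[i, 'trait']!r})"
            )
        # float() is correctly rounded (to_numeric's fast parser is not),
        # keeping write/read round trips bit-exact
        precise = np.array(
            [float(x) if isinstance(x, str) and x.strip() != "" else np.nan
             for x in long["value"]],
            dtype=float,
        )
        long = long.assign(value=precise)
        return cls(long)

    def to_csv(self, target=None, wide: bool = False):
        """Write the table; long dialect by default.

        Values are written with :func:`repr` precision so a read/write round
        trip preserves every float bit-for-bit.
        """
        if wide:
            out = self.data.pivot_table(
                index=list(KEY_COLUMNS), columns="trait", values="value", sort=False
            ).reset_index()
            out = out[list(KEY_COLUMNS) + list(self.traits)]
        else:
            out = self.data
        return out.to_csv(target, index=False)


@dataclass
class GenotypeMeanTable:
    """Genotype-by-trait mean table with companion standard deviations.

    ``means``/``sds`` are genotype x trait DataFrames; ``grand_means`` is the
    per-trait mean over all plots.  ``sd_basis`` records whether the SDs were
    taken over all plots of a genotype or over its per-environment means
    (both conventions appear in published tables).
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    grand_means: pd.Series
    sd_basis: str = "plots"

    @property
    def genotypes(self) -> tuple:
        return tuple(self.means.index)

    @property
    def traits(self) -> tuple:
        return tuple(self.means.columns)


def genotype_means(
    table: TrialTable, trait: str, sd_basis: str = "plots"
) -> pd.DataFrame:
    """Per-genotype mean and SD of one trait, plus the grand mean.

    ``sd_basis='plots'`` takes the SD over every plot of the genotype
    (sample SD, ddof=1); ``sd_basis='env_means'`` first averages within each
    environment and takes the SD of those per-environment means.

    Returns a DataFrame indexed by genotype with columns ``mean`` and ``sd``
    and attribute-style access to ``.attrs['grand_mean']``.
    """
    if trait not in table.traits:
        raise TrialDataError(f"unknown trait {trait!r}")
    if sd_basis not in ("plots", "env_means"):
        raise TrialDataError(f"sd_basis must be 'plots' or 'env_means', got {sd_basis!r}")
    sub = table.data[(table.data["trait"] == trait) & table.data["value"].notna()]
    counts = sub.groupby("genotype", sort=False)["value"].count()
    empty = [g for g in table.genotypes if counts.get(g, 0) == 0]
    if empty:
        raise TrialDataError(f"genotype(s) with zero observations for {trait!r}: {empty}")

    grp = sub.groupby("genotype", sort=False)["value"]
    means = grp.mean().reindex(list(table.genotypes))
    if sd_basis == "plots":
        sds = grp.std(ddof=1).reindex(list(table.genotypes))
    else:
        env_means = (
            sub.groupby(["genotype", "environment"], sort=False)["value"]
            .mean()
            .reset_index()
        )
        sds = (
            env_means.groupby("genotype", sort=False)["value"]
            .std(ddof=1)
            .reindex(list(table.genotypes))
        )
    out = pd.DataFrame({"mean": means, "sd": sds})
    out.attrs["grand_mean"] = float(sub["value"].mean())
    out.attrs["trait"] = trait
    return out


def genotype_mean_table(table: TrialTable, sd_basis: str = "plots") -> GenotypeMeanTable:
    """Assemble the full genotype x trait mean table over all traits."""
    means, sds, grand = {}, {}, {}
    for t in table.traits:
        col = genotype_means(table, t, sd_basis=sd_basis)
        means[t] = col["mean"]
        sds[t] = col["sd"]
        grand[t] = col.attrs["grand_mean"]
    return GenotypeMeanTable(
        means=pd.DataFrame(means)[list(table.traits)],
        sds=pd.DataFrame(sds)[list(table.traits)],
        grand_means=pd.Series(grand)[list(table.traits)],
        sd_basis=sd_basis,
    )
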