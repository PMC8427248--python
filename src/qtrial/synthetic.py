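"""Synthetic RCBD multi-environment trial generator.

Simulates plot observations from the additive linear model that underlies
the balanced RCBD combined analysis,

    y_ijk = mu + G_i + E_j + GE_ij + B_k(j) + eps_ijk,

with every effect an independent zero-mean Gaussian at its specified
variance.  Because the true variance components are known, every downstream
stage (ANOVA, variance components, heritability, correlation, PCA,
clustering) can be tested by parameter recovery.

A single integer seed governs the whole draw; each effect gets its own
deterministic sub-stream spawned from that seed, so adding traits or effects
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial_core import TrialTable


@dataclass(frozen=True)
class TrialDesign:
    """Balanced RCBD layout: g genotypes x e environments x r blocks."""

    g: int
    e: int
    r: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 2:
            raise ValueError(f"need at least 2 genotypes, got g={self.g}")
        if self.e < 1:
            raise ValueError(f"need at least 1 environment, got e={self.e}")
        if self.r < 2:
            raise ValueError(f"need at least 2 blocks, got r={self.r}")


@dataclass(frozen=True)
class VarianceSpec:
    """True variance components of one trait, in squared trait units.

    ``var_g`` is the genotypic variance, ``var_resid`` the plot residual
    (error) variance; environment, genotype-by-environment and
    block-within-environment components default to zero.
    """

    mu: float
    var_g: float
    var_resid: float
    var_e_env: float = 0.0
    var_ge: float = 0.0
    var_block: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_g", "var_resid", "var_e_env", "var_ge", "var_block"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    @property
    def plot_variance(self) -> float:
        """Total variance of a single plot observation."""
        return self.var_g + self.var_e_env + self.var_ge + self.var_block + self.var_resid


@dataclass
class MultiTraitSpec:
    """Per-trait variance specs plus a genetic correlation among traits.

    ``genetic_correlation`` correlates the genotype effects across traits
    (unit diagonal, entries in [-1, 1], positive semi-definite); every other
    effect is drawn independently per trait.
    """

    specs: Mapping[str, VarianceSpec]
    genetic_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traits = tuple(self.specs)
        t = len(self.traits)
        if self.genetic_correlation is None:
            self.genetic_correlation = np.eye(t)
        R = np.asarray(self.genetic_correlation, dtype=float)
        if R.shape != (t, t):
            raise ValueError(f"correlation matrix must be {t}x{t}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.abs(R).max() > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.3e})"
            )
        self.genetic_correlation = R


def _labels(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _effect_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_values(
    design: TrialDesign, spec: VarianceSpec, rngs: Sequence[np.random.Generator],
    G: np.ndarray | None = None,
) -> np.ndarray:
    """Plot values with shape (g, e, r); genotype effects G may be supplied."""
    g, e, r = design.g, design.e, design.r
    rg, re_, rge, rb, reps = rngs
    if G is None:
        G = rg.normal(0.0, np.sqrt(spec.var_g), size=g)
    E = re_.normal(0.0, np.sqrt(spec.var_e_env), size=e)
    GE = rge.normal(0.0, np.sqrt(spec.var_ge), size=(g, e))
    B = rb.normal(0.0, np.sqrt(spec.var_block), size=(e, r))
    eps = reps.normal(0.0, np.sqrt(spec.var_resid), size=(g, e, r))
    return (
        spec.mu
        + G[:, None, None]
        + E[None, :, None]
        + GE[:, :, None]
        + B[None, :, :]
        + eps
    )


def _to_table(design: TrialDesign, values: Mapping[str, np.ndarray]) -> TrialTable:
    g, e, r = design.g, design.e, design.r
    gl, el, bl = _labels("G", g), _labels("E", e), _labels("B", r)
    gi, ei, bi = np.meshgrid(np.arange(g), np.arange(e), np.arange(r), indexing="ij")
    frames = []
    for trait, arr in values.items():
        frames.append(
            pd.DataFrame(
                {
                    "genotype": np.array(gl)[gi.ravel()],
                    "environment": np.array(el)[ei.ravel()],
                    "block": np.array(bl)[bi.ravel()],
                    "trait": trait,
                    "value": arr.ravel(),
                }
            )
        )
    return TrialTable(pd.concat(frames, ignore_index=True))


def simulate_trial(
    design: TrialDesign, spec: VarianceSpec, trait: str = "trait1"
) -> TrialTable:
    """Simulate one balanced single-trait trial; deterministic given the seed."""
    rngs = _effect_streams(design.seed, 5)
    return _to_table(design, {trait: _simulate_values(design, spec, rngs)})


def simulate_multitrait(design: TrialDesign, spec: MultiTraitSpec) -> TrialTable:
    """Simulate a multi-trait trial with correlated genotype effects.

    Genotype effects are drawn jointly from N(0, D^1/2 R D^1/2) where R is
    the genetic correlation and D the diagonal of per-trait genotypic
    variances; all other effects are independent across traits.
    """
    traits = spec.traits
    t = len(traits)
    root, *streams = np.random.SeedSequence(design.seed).spawn(1 + 5 * t)
    sd = np.sqrt([spec.specs[k].var_g for k in traits])
    cov = spec.genetic_correlation * np.outer(sd, sd)
    G = np.random.default_rng(root).multivariate_normal(
        np.zeros(t), cov, size=design.g, method="svd"
    )
    values = {}
    for j, trait in enumerate(traits):
        rngs = [np.random.default_rng(s) for s in streams[5 * j : 5 * j + 5]]
        values[trait] = _simulate_values(design, spec.specs[trait], rngs, G=G[:, j])
    return _to_table(design, values)


def cowpea_like_spec(genetic_correlation: np.ndarray | None = None) -> MultiTraitSpec:
    """Default eight-trait spec at the signal/noise scale of a three-year
    cowpea advanced-line trial (see :mod:`qtrial.datasets`).

    Genotypic and residual variances and grand means are taken from the
    reference variance-component table; by default the genotype effects are
    correlated with the empirical correlation of the reference genotype
    means, so simulated data reproduce realistic trait inter-relationships.
    """
    from .datasets import cowpea_reference_means, cowpea_reference_summary

    ref = cowpea_reference_summary()
    specs = {
        trait: VarianceSpec(
            mu=float(row["mu"]), var_g=float(row["var_g"]), var_resid=float(row["var_e"])
        )
        for trait, row in ref.iterrows()
    }
    if genetic_correlation is None:
        means = cowpea_reference_means().means
        genetic_correlation = np.corrcoef(means.to_numpy(), rowvar=False)
    return MultiTraitSpec(specs=specs, genetic_correlation=genetic_correlation)
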