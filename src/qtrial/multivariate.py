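"""Correlation, principal components and hierarchical clustering of
genotype-by-trait mean tables.

All three analyses operate on the genotype mean table (one row per
genotype, one column per trait):

* Pearson correlation among traits with two-tailed significance from the
  t distribution on n-2 degrees of freedom, no multiplicity correction;
* PCA on the trait correlation matrix (traits standardized over genotypes;
  eigenvalues therefore sum to the number of traits), with the conventional
  |loading| > 0.3 rule flagging the traits that matter on each component;
* agglomerative clustering with Euclidean distance and average linkage
  (UPGMA), by default on standardized trait means so that traits measured
  in large units cannot dominate the distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .trial_core import GenotypeMeanTable


def _as_means_frame(m) -> pd.DataFrame:
    if isinstance(m, GenotypeMeanTable):
        return m.means
    return pd.DataFrame(m)


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    """Trait correlation matrix with two-tailed p-values over n genotypes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self, alpha: float = 0.05) -> pd.DataFrame:
        """'*' where the off-diagonal correlation is significant at alpha."""
        flag = (self.p < alpha) & ~np.eye(len(self.r), dtype=bool)
        return self.r.round(2).astype(str).where(~flag, self.r.round(2).astype(str) + "*")


def correlation_matrix(m) -> CorrelationResult:
    """Pairwise Pearson correlation among traits with t-test p-values.

    p for each off-diagonal pair comes from t = r sqrt((n-2)/(1-r^2)) on
    n-2 df, two-tailed.  Diagonal r is exactly 1 with p left undefined.
    """
    X = _as_means_frame(m)
    n, t = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 genotypes, got {n}")
    if t < 2:
        raise ValueError(f"need at least 2 traits, got {t}")
    sd = X.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"trait(s) with zero variance: {constant}")
    r = np.corrcoef(X.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.isinf(tstat) | np.isnan(tstat)] = 0.0
    np.fill_diagonal(p, np.nan)
    cols = list(X.columns)
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """Correlation-matrix PCA of a genotype mean table.

    ``loadings`` columns are unit-norm eigenvectors (traits x components);
    ``scores`` are the standardized data projected onto them (genotypes x
    components), so score variances equal the eigenvalues.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variability_pct: np.ndarray
    cumulative_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(m) -> PcaResult:
    """Eigendecomposition of the trait correlation matrix.

    Traits are standardized to zero mean and unit variance (ddof=1) over
    genotypes, so each component's share of variance is eigenvalue divided
    by the number of traits.  Each eigenvector's sign is flipped so its
    largest-magnitude loading is positive (the sign of an eigenvector is
    arbitrary; published tables may differ by a global flip per component).
    """
    X = _as_means_frame(m)
    n, t = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 genotypes, got {n}")
    if t < 2:
        raise ValueError(f"need at least 2 traits, got {t}")
    sd = X.std(ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        raise ValueError(f"trait(s) constant across genotypes: {degenerate}")
    Z = (X - X.mean()) / sd
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    comps = [f"PC{j + 1}" for j in range(t)]
    loadings = pd.DataFrame(V, index=X.columns, columns=comps)
    scores = pd.DataFrame(Z.to_numpy() @ V, index=X.index, columns=comps)
    variability = 100.0 * w / w.sum()
    return PcaResult(
        eigenvalues=w,
        loadings=loadings,
        scores=scores,
        variability_pct=variability,
        cumulative_pct=np.cumsum(variability),
    )


def important_traits(p: PcaResult, threshold: float = 0.3) -> pd.DataFrame:
    """Boolean trait x component flags where |loading| strictly exceeds
    the threshold (0.3 by convention for 'large enough to matter')."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return p.loadings.abs() > threshold


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    """Average-linkage dendrogram over genotypes with a k-cluster cut.

    ``linkage`` is the SciPy merge matrix (heights in Euclidean distance
    units); ``assignments`` maps each genotype to a cluster id in 1..k.
    """

    linkage: np.ndarray
    assignments: pd.Series
    k: int
    labels: tuple
    standardized: bool

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Dendrogram as a rooted Newick string with branch lengths.

        Branch lengths are the gaps between successive merge heights, so
        leaf-to-root distance equals half the final merge height (ultrametric
        tree, as for any UPGMA dendrogram).
        """
        root = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            if node.is_leaf():
                name = str(self.labels[node.id]).replace(" ", "_")
                return f"{name}:{parent_height / 2:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            length = (parent_height - node.dist) / 2
            return f"({left},{right}):{length:.10g}"

        return walk(root, root.dist) + ";"


def hierarchical_cluster(m, k: int, standardize: bool = True) -> ClusterResult:
    """UPGMA clustering of genotypes on their trait means.

    Distances are Euclidean over (by default standardized) trait means;
    cluster-to-cluster distance is the average of all between-cluster
    pairwise distances.  The tree is cut into k groups; ids are renumbered
    1..k in order of first appearance down the genotype list.
    """
    X = _as_means_frame(m)
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}, got {k}")
    data = X.to_numpy(dtype=float)
    if standardize:
        sd = data.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [c for c, s in zip(X.columns, sd) if s == 0]
            raise ValueError(f"trait(s) constant across genotypes: {bad}")
        data = (data - data.mean(axis=0)) / sd
    Z = hierarchy.linkage(data, method="average", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber deterministically by first appearance
    remap: dict[int, int] = {}
    ids = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap) + 1
        ids.append(remap[c])
    return ClusterResult(
        linkage=Z,
        assignments=pd.Series(ids, index=X.index, name="cluster"),
        k=k,
        labels=tuple(X.index),
        standardized=standardize,
    )
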