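"""Hierarchical clustering of samples on z-scored methylation features.

Samples (patient x region tissue pieces) are clustered with Ward.D2
agglomeration on Euclidean distances over row-standardized (z-scored)
site or region methylation, with ordinary bootstrap clade support
(site rows resampled with replacement).  Used to ask whether a feature
set separates tumor (TC/TE) from non-tumor samples, and whether
shallow-change features pull near-tumor adjacent samples (P5/P10) onto
the tumor branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a sites x samples matrix.

    Each row is centered and scaled to unit variance (sample sd, ddof=1)
    over its non-missing cells; missing cells are imputed with the row
    mean, i.e. 0 after scaling.  Rows with fewer than 2 observed cells
    or zero variance are dropped with a warning.
    """
    vals = matrix.to_numpy(dtype=float)
    n_obs = np.isfinite(vals).sum(axis=1)
    mean = np.nanmean(np.where(n_obs[:, None] >= 1, vals, np.nan), axis=1)
    sd = np.full(len(vals), np.nan)
    ok = n_obs >= 2
    sd[ok] = np.nanstd(vals[ok], axis=1, ddof=1)
    keep = ok & (sd > 0)
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} constant or under-observed rows")
    z = (vals[keep] - mean[keep, None]) / sd[keep, None]
    z = np.where(np.isfinite(z), z, 0.0)
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix, Ward.D2 heights
    labels: list  # sample labels, observation order
    k_labels: np.ndarray | None = None
    bootstrap_support: dict | None = field(default=None, repr=False)

    def cut(self, k: int) -> np.ndarray:
        """Flat labels for a k-group cut."""
        return hierarchy.fcluster(self.linkage, k, criterion="maxclust")

    def clades(self) -> list[frozenset]:
        """Sample-label sets of every internal node."""
        return _clades(self.linkage, self.labels)


def _clades(Z: np.ndarray, labels: list) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        m = members[int(a)] | members[int(b)]
        members[n + k] = m
        out.append(m)
    return out


def ward_cluster(matrix: pd.DataFrame, k: int | None = None) -> ClusterResult:
    """Ward.D2 agglomerative clustering of the columns (samples).

    ``matrix`` is features x samples (typically z-scored).  scipy's
    'ward' linkage on Euclidean distances implements the Ward.D2
    criterion (squared-distance Lance-Williams update, heights on the
    distance scale); ties break deterministically by observation order.
    """
    X = matrix.to_numpy(dtype=float).T
    if not np.isfinite(X).all():
        raise ValueError("non-finite cells; z-score/impute first")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Z = hierarchy.linkage(X, method="ward")
    res = ClusterResult(linkage=Z, labels=list(matrix.columns))
    if k is not None:
        res.k_labels = res.cut(k)
    return res


def bootstrap_support(
    matrix: pd.DataFrame, B: int = 1000, seed: int = 0
) -> dict[frozenset, float]:
    """Ordinary bootstrap probability per clade of the full-data tree.

    Feature rows are resampled with replacement B times; support is the
    fraction of resamples in which a clade's exact sample set reappears.
    (This is the plain bootstrap probability, not a multiscale/AU
    corrected value.)
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    base = ward_cluster(matrix)
    targets = {c: 0 for c in base.clades()}
    rng = np.random.default_rng(seed)
    n_rows = matrix.shape[0]
    vals = matrix.to_numpy(dtype=float)
    for _ in range(B):
        rows = rng.integers(0, n_rows, size=n_rows)
        Z = hierarchy.linkage(vals[rows].T, method="ward")
        for c in _clades(Z, base.labels):
            if c in targets:
                targets[c] += 1
    return {c: v / B for c, v in targets.items()}


def to_newick(result: ClusterResult, support: dict[frozenset, float] | None = None) -> str:
    """Newick serialization of the dendrogram, heights as branch depths.

    Internal nodes optionally carry bootstrap supports as node labels.
    """
    tree = hierarchy.to_tree(result.linkage)
    labels = result.labels

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        tag = ""
        if support is not None:
            clade = frozenset(labels[i] for i in node.pre_order(lambda x: x.id))
            if clade in support:
                tag = f"{support[clade]:.3g}"
        return f"({left},{right}){tag}:{length:.6g}"

    root = walk(tree, tree.dist)
    return root + ";"
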