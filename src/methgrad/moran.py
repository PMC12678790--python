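"""Moran's I regularity scoring of pairwise-significance matrices.

A site's 7x7 significance matrix is treated as spatial data on the
matrix grid and scored with Moran's I,

    I = sum_{i != j} w_ij (x_i - xbar)(x_j - xbar) / (S^2 * sum_{i != j} w_ij),

with S^2 = (1/n) sum_i (x_i - xbar)^2 and w_ij an inverse-distance
spatial weight.  Higher I means the significant cells cluster on the
grid — an ordered, spatially regular difference pattern — while values
near the permutation expectation -1/(n-1) indicate scattered,
pattern-free significance.

Grid convention
---------------
The convention is pinned by reproducing the worked example (site
chr12:51820212, I = 0.1581) exactly and is used project-wide:

* observations are the 42 off-diagonal cells of the 7x7 grid at their
  integer (row, col) coordinates — the diagonal cells are excluded;
* each significant unordered pair contributes a single 1 placed in its
  upper-triangle cell (row < col); the mirror cell stays 0 (half-matrix
  encoding);
* w_ij = 1 / Euclidean distance between cell coordinates, then
  row-standardized (each row of w sums to one).

Under this convention the permutation expectation of I is -1/41.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sigmatrix import N_REGIONS, SignificanceMatrix


@dataclass
class GridWeights:
    """Spatial weights over matrix-grid cells."""

    coords: np.ndarray  # (n, 2) integer (row, col) per observation
    w: np.ndarray  # (n, n), zero diagonal

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class MoranResult:
    I: float
    x_bar: float
    S2: float
    null_values: np.ndarray | None = field(default=None, repr=False)


def inverse_distance_weights(
    rows: int = N_REGIONS,
    cols: int = N_REGIONS,
    metric: str = "euclidean",
    *,
    include_diagonal: bool = False,
    row_standardize: bool = True,
) -> GridWeights:
    """Inverse-distance weights over the cells of a rows x cols grid.

    Defaults give the project convention (off-diagonal cells only,
    Euclidean metric, row-standardized).  ``include_diagonal=True`` and
    the Manhattan metric are retained for convention experiments.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    cells = [(r, c) for r in range(rows) for c in range(cols) if include_diagonal or r != c]
    coords = np.array(cells, dtype=float)
    dr = np.abs(coords[:, None, 0] - coords[None, :, 0])
    dc = np.abs(coords[:, None, 1] - coords[None, :, 1])
    if metric == "euclidean":
        dist = np.hypot(dr, dc)
    elif metric == "manhattan":
        dist = dr + dc
    else:
        raise ValueError(f"unknown metric {metric!r}")
    with np.errstate(divide="ignore"):
        w = np.where(dist > 0, 1.0 / dist, 0.0)
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return GridWeights(coords=coords.astype(int), w=w)


def matrix_observations(m: SignificanceMatrix) -> np.ndarray:
    """Half-matrix observation vector over the 42 off-diagonal cells.

    The cell (r, c) with r < c carries 1 when the pair is significant;
    its mirror carries 0.  Cell order matches
    ``inverse_distance_weights()`` (row-major over off-diagonal cells).
    """
    return np.array(
        [1.0 if r < c and m.sig[r, c] else 0.0 for r in range(N_REGIONS) for c in range(N_REGIONS) if r != c]
    )


def morans_i(x: np.ndarray, weights: GridWeights) -> MoranResult:
    """Moran's I of observations ``x`` under ``weights``, per the formula above."""
    x = np.asarray(x, dtype=float)
    if x.size != weights.n:
        raise ValueError(f"expected {weights.n} observations, got {x.size}")
    z = x - x.mean()
    s2 = float((z**2).mean())
    if s2 == 0.0:
        raise ValueError("Moran's I undefined for constant observations (S^2 = 0)")
    num = float(z @ weights.w @ z)
    return MoranResult(I=num / (s2 * float(weights.w.sum())), x_bar=float(x.mean()), S2=s2)


_DEFAULT_WEIGHTS: GridWeights | None = None


def default_weights() -> GridWeights:
    """The project-convention weights (cached)."""
    global _DEFAULT_WEIGHTS
    if _DEFAULT_WEIGHTS is None:
        _DEFAULT_WEIGHTS = inverse_distance_weights()
    return _DEFAULT_WEIGHTS


def morans_i_for_matrix(
    m: SignificanceMatrix, weights: GridWeights | None = None
) -> MoranResult:
    """Score one significance matrix under the project convention."""
    w = weights if weights is not None else default_weights()
    return morans_i(matrix_observations(m), w)


def shuffle_null(
    m: SignificanceMatrix,
    weights: GridWeights | None = None,
    n_shuffles: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Moran's I under random rearrangement of the matrix cells.

    Each shuffle permutes the observation values uniformly across all
    cell positions and recomputes I, simulating significance occurring
    at random positions.  The default of 10 shuffles per site matches
    the pooled-null usage; raise it for per-site inference.
    """
    w = weights if weights is not None else default_weights()
    x = matrix_observations(m)
    if x.sum() == 0:
        raise ValueError("shuffle null requires at least one significant cell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_shuffles == 0:
        return np.array([])
    perms = np.stack([rng.permutation(x) for _ in range(n_shuffles)])
    z = perms - perms.mean(axis=1, keepdims=True)
    s2 = (z**2).mean(axis=1)
    num = np.einsum("ki,ij,kj->k", z, w.w, z)
    return num / (s2 * w.w.sum())
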