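"""Per-site pairwise-significance matrices across the seven tissue regions.

Each CpG site carries one methylation value per (patient, region) cell,
with the seven regions ordered from the tumor core outwards:

    TC (tumor core), TE (tumor edge), P5, P10, P15, P20 (adjacent tissue
    at increasing distance beyond the visual tumor boundary, in mm), and
    PN (paired-distal normal).

For every unordered region pair a paired one-tailed Wilcoxon signed-rank
test is run in both directions across patients; a pair is significant if
the smaller one-tailed P falls below ``alpha``.  The 21 pair outcomes form
a symmetric 7x7 boolean matrix (zero diagonal) together with an
antisymmetric direction matrix.  Downstream, the matrix is scored for
spatial regularity (``methgrad.moran``) and summarized as a 42-dimensional
binary status vector for site-to-site similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._em import fit_gaussian_mixture_1d

REGIONS: tuple[str, ...] = ("TC", "TE", "P5", "P10", "P15", "P20", "PN")
REGION_ORDINAL: dict[str, int] = {name: i for i, name in enumerate(REGIONS)}
N_REGIONS = len(REGIONS)
TUMOR_REGIONS: tuple[str, str] = ("TC", "TE")
NORMAL_REGIONS: tuple[str, ...] = ("P5", "P10", "P15", "P20", "PN")


def region_ordinal(name: str) -> int:
    """Ordinal (0-based) of a region label in the fixed TC..PN order."""
    try:
        return REGION_ORDINAL[name]
    except KeyError:
        raise ValueError(f"unknown region label {name!r}; expected one of {REGIONS}")


@dataclass
class SignificanceMatrix:
    """7x7 pairwise-significance outcome for one CpG site.

    ``sig`` is symmetric boolean with a false diagonal; ``dir`` holds
    -1/0/+1 with ``dir[i, j] = +1`` meaning region ``i`` has significantly
    *higher* methylation than region ``j`` (sign of the median paired
    difference, antisymmetric, nonzero only where ``sig`` is true).
    """

    sig: np.ndarray
    dir: np.ndarray
    p_low: np.ndarray | None = field(default=None, repr=False)
    p_high: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sig = np.asarray(self.sig, dtype=bool)
        self.dir = np.asarray(self.dir, dtype=np.int8)
        if self.sig.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("sig must be 7x7")
        if not np.array_equal(self.sig, self.sig.T):
            raise ValueError("sig must be symmetric")
        if self.sig.diagonal().any():
            raise ValueError("sig diagonal must be false")
        if not np.array_equal(self.dir, -self.dir.T):
            raise ValueError("dir must be antisymmetric")
        if (self.dir[~self.sig] != 0).any():
            raise ValueError("dir must be zero where sig is false")

    @property
    def n_significant_pairs(self) -> int:
        return int(self.sig.sum() // 2)

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]],
        directions: list[int] | None = None,
    ) -> "SignificanceMatrix":
        """Build a matrix from a list of significant region-label pairs.

        ``directions[k]`` is the sign of (first minus second) for pair k;
        defaults to -1 (first region lower), the common tumor-hypomethylated
        orientation when pairs are given tumor-side first.
        """
        sig = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
        dr = np.zeros((N_REGIONS, N_REGIONS), dtype=np.int8)
        if directions is None:
            directions = [-1] * len(pairs)
        for (a, b), d in zip(pairs, directions):
            i, j = region_ordinal(a), region_ordinal(b)
            if i == j:
                raise ValueError("pair must name two distinct regions")
            sig[i, j] = sig[j, i] = True
            dr[i, j] = d
            dr[j, i] = -d
        return cls(sig=sig, dir=dr)


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-tailed paired Wilcoxon P values (x<y, x>y), zeros dropped.

    Exact null distribution is used for n <= 25 (scipy's default when
    there are no ties); the normal approximation with continuity
    correction otherwise.
    """
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, 1.0
    method = "exact" if n <= 25 and np.unique(np.abs(d)).size == n else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_less = stats.wilcoxon(
            d, alternative="less", zero_method="wilcox", method=method, correction=True
        ).pvalue
        p_greater = stats.wilcoxon(
            d, alternative="greater", zero_method="wilcox", method=method, correction=True
        ).pvalue
    return float(p_less), float(p_greater)


def pairwise_region_tests(
    values: np.ndarray,
    alpha: float = 0.05,
    min_pairs: int = 6,
) -> SignificanceMatrix:
    """Test every region pair of one site and assemble its matrix.

    Parameters
    ----------
    values
        (n_patients, 7) methylation fractions, NaN for missing cells,
        columns in the fixed TC..PN order.
    alpha
        Per-pair one-tailed significance level (0.05).
    min_pairs
        Minimum number of complete (both-regions-observed) patient pairs
        for a pair to be testable; untestable pairs are reported as not
        significant.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != N_REGIONS:
        raise ValueError("values must be (n_patients, 7)")
    if np.isfinite(values).any(axis=1).sum() < 3:
        raise ValueError("fewer than 3 patients with any data")

    sig = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    dr = np.zeros((N_REGIONS, N_REGIONS), dtype=np.int8)
    p_low = np.full((N_REGIONS, N_REGIONS), np.nan)
    p_high = np.full((N_REGIONS, N_REGIONS), np.nan)

    for i in range(N_REGIONS):
        for j in range(i + 1, N_REGIONS):
            ok = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            if ok.sum() < min_pairs:
                continue
            pl, pg = _paired_wilcoxon(values[ok, i], values[ok, j])
            p_low[i, j] = p_low[j, i] = pl
            p_high[i, j] = p_high[j, i] = pg
            if min(pl, pg) < alpha:
                sig[i, j] = sig[j, i] = True
                d = -1 if pl < pg else +1  # i lower than j when the "less" tail wins
                dr[i, j] = d
                dr[j, i] = -d
    return SignificanceMatrix(sig=sig, dir=dr, p_low=p_low, p_high=p_high)


# --- status vectors -------------------------------------------------------

_OFFDIAG = [(r, c) for r in range(N_REGIONS) for c in range(N_REGIONS) if r != c]


def status_vector(m: SignificanceMatrix) -> np.ndarray:
    """42-dim binary vector: row-major off-diagonal cells of ``sig``.

    Each significant unordered pair contributes two ones (both ordered
    cells), so ``vector.sum() == 2 * n_significant_pairs``.
    """
    return np.array([m.sig[r, c] for r, c in _OFFDIAG], dtype=float)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero status vector")
    return float(a @ b / (na * nb))


# --- neighborhood analysis ------------------------------------------------


def neighbor_significant_proportion(
    sites: pd.DataFrame,
    window: int = 30,
    bins: np.ndarray | None = None,
    neighbor_sites: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-bin fraction of sites with >= 1 other significant site within ±window bp.

    ``sites`` needs ``chrom`` and ``pos`` columns (1-based); ``bins`` is a
    per-site bin id aligned with ``sites`` (one bin for all sites when
    omitted).  The candidate neighbor set defaults to the scored sites
    themselves (they are significant-difference sites by construction);
    pass ``neighbor_sites`` to use a different significant-site universe.
    The window is closed: a neighbor exactly ``window`` bp away counts.
    Empty bins are reported as NaN.
    """
    if neighbor_sites is None:
        neighbor_sites = sites
    has = has_neighbor_within(sites, neighbor_sites, window)
    if bins is None:
        bins = np.zeros(len(sites), dtype=int)
    bins = np.asarray(bins)
    out = {}
    for b in np.unique(bins):
        mask = bins == b
        out[b] = float(has[mask].mean()) if mask.any() else np.nan
    return pd.Series(out, name="neighbor_proportion").sort_index()


def has_neighbor_within(
    sites: pd.DataFrame, neighbor_sites: pd.DataFrame, window: int = 30
) -> np.ndarray:
    """Boolean per site: another site (distinct coordinate, or a second
    occupant of the same coordinate) lies within ±window bp on the same
    chromosome."""
    result = np.zeros(len(sites), dtype=bool)
    pos_by_chrom = {
        chrom: np.sort(np.asarray(grp["pos"])) for chrom, grp in neighbor_sites.groupby("chrom")
    }
    chroms = np.asarray(sites["chrom"])
    positions = np.asarray(sites["pos"])
    for chrom, cand in pos_by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        pos = positions[sel]
        n_in = np.searchsorted(cand, pos + window, side="right") - np.searchsorted(
            cand, pos - window, side="left"
        )
        # a site at its own coordinate does not count as its own neighbor
        i = np.searchsorted(cand, pos)
        self_hit = (i < cand.size) & (cand[np.minimum(i, cand.size - 1)] == pos)
        result[sel] = (n_in - self_hit.astype(int)) >= 1
    return result


# --- binning of Moran's I values ------------------------------------------


@dataclass
class BinAssignment:
    """Bin ids per value plus human-readable bin labels."""

    ids: np.ndarray
    labels: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.labels)


def bin_sites(
    values: np.ndarray,
    strategy: str = "fixed_width",
    *,
    width: float = 0.025,
    lo: float = -0.025,
    hi: float = 0.2,
    k: int | None = None,
    seed: int = 0,
) -> BinAssignment:
    """Assign Moran's-I values to bins under one of four schemes.

    fixed_width
        An open start bin (<= ``lo``), interior bins of ``width`` on
        (lo, hi], and an open end bin (> ``hi``).  The defaults give the
        11-bin scheme: <=-0.025, nine 0.025-wide interior bins, >0.2.
    quantile
        ``k`` equal-sized groups.
    gmm_em
        ``k``-component 1-D Gaussian mixture fit by EM; assignment by
        maximum posterior, bins ordered by component mean.
    fisher_jenks
        Natural-breaks optimization minimizing within-bin sum of squared
        deviations (dynamic program).
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if strategy == "fixed_width":
        n_interior = int(round((hi - lo) / width))
        edges = lo + width * np.arange(n_interior + 1)
        ids = np.searchsorted(edges, values, side="left")
        labels = [f"<= {lo:g}"]
        labels += [f"({edges[i]:g}, {edges[i+1]:g}]" for i in range(n_interior)]
        labels += [f"> {hi:g}"]
        return BinAssignment(ids=ids, labels=labels)
    if k is None:
        raise ValueError(f"strategy {strategy!r} requires k")
    if k > np.unique(values).size:
        raise ValueError("k exceeds the number of distinct values")
    if strategy == "quantile":
        ids = pd.qcut(values, k, labels=False, duplicates="drop")
        return BinAssignment(ids=np.asarray(ids), labels=[f"q{i}" for i in range(k)])
    if strategy == "gmm_em":
        fit = fit_gaussian_mixture_1d(values, k, seed=seed)
        order = np.argsort(fit.means)
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)
        ids = rank[np.argmax(fit.responsibilities(values), axis=1)]
        labels = [f"gmm{i} (mu={fit.means[order[i]]:.3g})" for i in range(k)]
        return BinAssignment(ids=ids, labels=labels)
    if strategy == "fisher_jenks":
        breaks = fisher_jenks_breaks(values, k)
        ids = np.searchsorted(breaks, values, side="left")
        labels = [f"jenks{i}" for i in range(k)]
        return BinAssignment(ids=ids, labels=labels)
    raise ValueError(f"unknown strategy {strategy!r}")


def fisher_jenks_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Upper break values (k-1 of them) minimizing within-bin SSD.

    Exact O(k n^2) dynamic program over the sorted values; a value v is
    assigned to the first bin whose break is >= v (bins are contiguous in
    sorted order, as the optimum must be).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 1 or k > np.unique(x).size:
        raise ValueError("need 1 <= k <= number of distinct values")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:  # values x[i..j-1]
        s = csum[j] - csum[i]
        q = csq[j] - csq[i]
        return q - s * s / (j - i)

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = np.inf, g - 1
            for i in range(g - 1, j):
                c = cost[g - 1, i] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cost[g, j] = best
            back[g, j] = arg
    # recover bin boundaries
    bounds = [n]
    j = n
    for g in range(k, 0, -1):
        j = back[g, j]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, ..., n]
    return np.array([x[b - 1] for b in bounds[1:-1]])


def fisher_jenks_cost(values: np.ndarray, k: int) -> float:
    """Optimal within-bin SSD achieved by ``fisher_jenks_breaks``."""
    x = np.sort(np.asarray(values, dtype=float))
    breaks = fisher_jenks_breaks(x, k)
    ids = np.searchsorted(breaks, x, side="left")
    total = 0.0
    for b in np.unique(ids):
        grp = x[ids == b]
        total += float(((grp - grp.mean()) ** 2).sum())
    return total
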