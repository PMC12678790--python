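"""Steep / shallow trend classification of significant CpG sites.

Direction convention (single source of truth for the whole package):
"rise" and "decline" describe methylation in the tumor-to-normal
direction TC -> PN.  A site is ``*_rise`` iff methylation increases from
TC to PN (Kendall tau > 0 over the region ordinals; equivalently the
tumor side is the lower one), ``*_decline`` iff it decreases.

Rules
-----
steep
    Significant differences occur *only* between the tumor rows
    {TC, TE} and the distal columns {P5, P10, P15, P20, PN}, with at
    least ``steep_min_sig`` (3) significant pairs for TC and for TE
    against that set, all sharing one direction.  The change is
    concentrated at the visual tumor boundary (between TE and P5).
shallow
    Evaluated on sites not called steep.  Kendall tau-b between the
    region ordinal and methylation (pooled over all patients' cells)
    must have P < ``tau_p_max`` (0.01); at least one significant pair
    must link {TC, TE} with PN; at least one significant pair must lie
    within {P5..PN}; and every significant pair's direction must agree
    with sign(tau) (no non-monotone significance).  The change creeps
    gradually across all seven positions.
unordered
    Everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sigmatrix import (
    N_REGIONS,
    REGIONS,
    SignificanceMatrix,
    pairwise_region_tests,
)

TUMOR_IDX = (0, 1)  # TC, TE
NORMAL_IDX = (2, 3, 4, 5, 6)  # P5..PN
PN_IDX = 6

CLASSES = ("steep_rise", "steep_decline", "shallow_rise", "shallow_decline", "unordered")


@dataclass
class ClassifyParams:
    alpha_pair: float = 0.05
    tau_p_max: float = 0.01
    steep_min_sig: int = 3
    min_pairs: int = 6
    min_kendall_cells: int = 20


def kendall_trend(values: np.ndarray, min_cells: int = 20) -> tuple[float, float]:
    """Kendall tau-b of methylation vs region ordinal, pooled over patients.

    ``values`` is (n_patients, 7) with NaN for missing cells.  Returns
    (tau, two-sided P from the tie-corrected normal approximation);
    (nan, nan) when all values are tied or fewer than ``min_cells``
    cells are observed.
    """
    values = np.asarray(values, dtype=float)
    ordinals = np.broadcast_to(np.arange(N_REGIONS), values.shape)
    ok = np.isfinite(values)
    if ok.sum() < min_cells:
        return (np.nan, np.nan)
    x = ordinals[ok]
    y = values[ok]
    if np.unique(y).size == 1:
        return (np.nan, np.nan)
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return (float(res.statistic), float(res.pvalue))


def is_steep(m: SignificanceMatrix, params: ClassifyParams | None = None) -> tuple[bool, int]:
    """Steep decision for one matrix; returns (is_steep, direction).

    direction is +1 for rise (methylation increases TC -> PN), -1 for
    decline, 0 when not steep.
    """
    params = params or ClassifyParams()
    sig, dr = m.sig, m.dir
    # (a) significance confined to tumor x distal pairs
    cross = np.zeros_like(sig)
    for t in TUMOR_IDX:
        for nrm in NORMAL_IDX:
            cross[t, nrm] = cross[nrm, t] = True
    if (sig & ~cross).any():
        return (False, 0)
    tc_n = int(sig[0, list(NORMAL_IDX)].sum())
    te_n = int(sig[1, list(NORMAL_IDX)].sum())
    if tc_n < params.steep_min_sig or te_n < params.steep_min_sig:
        return (False, 0)
    # (c) one common direction across all significant pairs
    signs = {int(dr[t, nrm]) for t in TUMOR_IDX for nrm in NORMAL_IDX if sig[t, nrm]}
    if len(signs) != 1:
        return (False, 0)
    tumor_sign = signs.pop()  # +1: tumor higher than distal -> decline toward PN
    return (True, -tumor_sign)


def is_shallow(
    m: SignificanceMatrix,
    tau: float,
    tau_p: float,
    params: ClassifyParams | None = None,
) -> tuple[bool, int]:
    """Shallow decision for a site not called steep; returns (is_shallow, direction)."""
    params = params or ClassifyParams()
    if not np.isfinite(tau) or not np.isfinite(tau_p) or tau == 0:
        return (False, 0)
    if tau_p >= params.tau_p_max:
        return (False, 0)
    sig, dr = m.sig, m.dir
    if not any(sig[t, PN_IDX] for t in TUMOR_IDX):
        return (False, 0)
    nrm = list(NORMAL_IDX)
    if not sig[np.ix_(nrm, nrm)].any():
        return (False, 0)
    # monotone significance: every significant pair's direction matches sign(tau).
    # tau > 0 means methylation grows with the ordinal, so for i < j the lower-
    # ordinal region is the lower one: dir[i, j] must be -sign(tau).
    want = -int(np.sign(tau))
    for i in range(N_REGIONS):
        for j in range(i + 1, N_REGIONS):
            if sig[i, j] and int(dr[i, j]) != want:
                return (False, 0)
    return (True, int(np.sign(tau)))


def classify_site(
    values: np.ndarray,
    m: SignificanceMatrix | None = None,
    params: ClassifyParams | None = None,
) -> dict:
    """Classify one site; returns a record with class, tau, tau_p, direction."""
    params = params or ClassifyParams()
    if m is None:
        m = pairwise_region_tests(values, alpha=params.alpha_pair, min_pairs=params.min_pairs)
    steep, direction = is_steep(m, params)
    tau, tau_p = (np.nan, np.nan)
    if steep:
        cls = "steep_rise" if direction > 0 else "steep_decline"
    else:
        tau, tau_p = kendall_trend(values, min_cells=params.min_kendall_cells)
        shallow, direction = is_shallow(m, tau, tau_p, params)
        if shallow:
            cls = "shallow_rise" if direction > 0 else "shallow_decline"
        else:
            cls, direction = "unordered", 0
    return {
        "class": cls,
        "direction": direction,
        "tau": tau,
        "tau_p": tau_p,
        "n_significant_pairs": m.n_significant_pairs,
    }


def classify_sites(
    site_values: dict,
    matrices: dict | None = None,
    params: ClassifyParams | None = None,
) -> pd.DataFrame:
    """Classify a cohort of sites.

    ``site_values`` maps a site key (e.g. ``(chrom, pos)``) to its
    (n_patients, 7) value array; ``matrices`` optionally supplies
    precomputed significance matrices under the same keys (they must be
    aligned — a key present in ``matrices`` but not in ``site_values``
    is rejected).  The steep rule is evaluated first, then the Kendall
    screen on the remainder; every site receives exactly one class.
    """
    params = params or ClassifyParams()
    if matrices is not None:
        extra = set(matrices) - set(site_values)
        if extra:
            raise ValueError(f"matrices supplied for unknown sites: {sorted(extra)[:3]}...")
    rows = []
    for key, values in site_values.items():
        m = matrices.get(key) if matrices is not None else None
        rec = classify_site(np.asarray(values, dtype=float), m, params)
        rec["site"] = key
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("site")
    # steep and shallow are disjoint by construction; guard the invariant anyway
    assert not (
        df["class"].str.startswith("steep") & df["class"].str.startswith("shallow")
    ).any()
    return df


def class_counts(classified: pd.DataFrame) -> dict:
    """Summary counts per trend class."""
    counts = classified["class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CLASSES}
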