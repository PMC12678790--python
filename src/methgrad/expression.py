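"""RT-qPCR relative expression across the seven regions and trend calling.

Expression is quantified by the cycle-threshold method: for each region
the replicate-mean Ct of the target gene is referenced to the
replicate-mean Ct of the internal control (ACTB),

    expr = 2 ** -(Ct_target - Ct_ref),

then standardized to the tumor-core value so TC = 1.  Per-profile
spatial trends are called steep / shallow / none.  The trend rule is an
explicit design choice of this package and is parameterized so it can
be swapped without touching I/O:

shallow
    monotone trend: Kendall |tau| over the region ordinals at least
    ``tau_min`` (0.62, the two-sided P<0.05 point for n=7) AND the
    TE->P5 step smaller than half the profile range;
steep
    TE->P5 step at least half the profile range with flat flanks (the
    spread within TC/TE and within P5..PN each no larger than the step);
none
    everything else, including constant profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sigmatrix import REGIONS


@dataclass
class ExpressionProfile:
    patient: str
    gene: str
    relative: pd.Series  # per-region expression, TC-normalized
    sd: pd.Series  # propagated replicate SD of delta-Ct, expression scale
    tc_normalized: bool


def relative_expression(measurements: pd.DataFrame) -> ExpressionProfile:
    """TC-normalized relative expression for one patient x gene.

    ``measurements`` is long-format with columns region, ct (target
    replicates) and ref_ct (reference-gene replicates), one row per
    replicate.  Replicates are aggregated as mean Ct before the power
    transform.  Missing TC leaves the profile unnormalized with
    ``tc_normalized=False``.
    """
    need = {"region", "ct", "ref_ct"}
    if not need <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(need)}")
    patient = str(measurements["patient"].iloc[0]) if "patient" in measurements else ""
    gene = str(measurements["gene"].iloc[0]) if "gene" in measurements else ""
    rel, sds = {}, {}
    for region, grp in measurements.groupby("region"):
        dct = grp["ct"].mean() - grp["ref_ct"].mean()
        expr = 2.0 ** (-dct)
        # replicate SD of delta-Ct propagated to the expression scale
        var_d = grp["ct"].var(ddof=1) / len(grp) + grp["ref_ct"].var(ddof=1) / len(grp)
        sd_d = float(np.sqrt(var_d)) if np.isfinite(var_d) else 0.0
        rel[region] = expr
        sds[region] = expr * np.log(2.0) * sd_d
    values = pd.Series(rel).reindex([r for r in REGIONS if r in rel])
    sd = pd.Series(sds).reindex(values.index)
    tc_normalized = "TC" in values.index
    if tc_normalized:
        tc = values["TC"]
        values = values / tc
        sd = sd / tc
    return ExpressionProfile(patient, gene, values, sd, tc_normalized)


@dataclass
class ExpressionTrend:
    category: str  # steep | shallow | none
    tau: float
    tau_p: float


def classify_expression_trend(
    profile: pd.Series,
    tau_min: float = 0.62,
    step_fraction: float = 0.5,
) -> ExpressionTrend:
    """Call the spatial trend of one per-region expression profile."""
    values = profile.reindex([r for r in REGIONS if r in profile.index]).astype(float)
    values = values.dropna()
    if len(values) < 5:
        return ExpressionTrend("none", np.nan, np.nan)
    x = np.array([REGIONS.index(r) for r in values.index], dtype=float)
    y = values.to_numpy()
    rng_total = float(y.max() - y.min())
    if rng_total == 0:
        return ExpressionTrend("none", np.nan, np.nan)
    res = stats.kendalltau(x, y, variant="b")
    tau, tau_p = float(res.statistic), float(res.pvalue)
    step = (
        abs(values["TE"] - values["P5"]) if {"TE", "P5"} <= set(values.index) else np.nan
    )
    if np.isfinite(step) and step >= step_fraction * rng_total:
        tumor = values.reindex(["TC", "TE"]).dropna().to_numpy()
        distal = values.reindex(["P5", "P10", "P15", "P20", "PN"]).dropna().to_numpy()
        flank = max(
            float(tumor.max() - tumor.min()) if tumor.size else 0.0,
            float(distal.max() - distal.min()) if distal.size else 0.0,
        )
        if flank <= step:
            return ExpressionTrend("steep", tau, tau_p)
    if abs(tau) >= tau_min and (not np.isfinite(step) or step < step_fraction * rng_total):
        return ExpressionTrend("shallow", tau, tau_p)
    return ExpressionTrend("none", tau, tau_p)
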