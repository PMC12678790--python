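"""Tumor-vs-adjacent methylation-difference prognostic risk model.

For each target CpG site the relative difference between the adjacent
tissue and the tumor is

    d = 100 * (adjacent - tumor) / tumor   [percent, clamped to ±100],

and a patient-site is called low-difference ("shallow-like", the tumor
influence extends into the adjacent tissue) when |d| falls below a
threshold swept over 3-15%.  Risk groups from single sites or from a
combined rule (at least N of a named site set low-difference => high
risk) are compared with Kaplan-Meier curves, the Mantel-Cox log-rank
test, and a univariate proportional-hazards hazard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

LOW, HIGH = "low_difference", "high_difference"


def relative_difference(tumor: float, adjacent: float, denominator: str = "tumor") -> float:
    """Signed percent difference of adjacent vs tumor methylation.

    denominator="tumor" is the stated formula (not actually bounded by
    +100, hence the documented clamp with a warning);
    denominator="max" divides by max(tumor, adjacent), which is bounded.
    """
    if not (0.0 <= tumor <= 1.0 and 0.0 <= adjacent <= 1.0):
        raise ValueError("methylation fractions must be in [0, 1]")
    if denominator == "tumor":
        if tumor == 0.0:
            raise ZeroDivisionError("tumor methylation is 0; relative difference undefined")
        d = 100.0 * (adjacent - tumor) / tumor
    elif denominator == "max":
        m = max(tumor, adjacent)
        if m == 0.0:
            raise ZeroDivisionError("both fractions are 0")
        d = 100.0 * (adjacent - tumor) / m
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if abs(d) > 100.0:
        warnings.warn(f"relative difference {d:.1f}% clamped to ±100%")
        d = float(np.clip(d, -100.0, 100.0))
    return d


def classify_difference(d: float, threshold: float) -> str:
    """low_difference iff |d| < threshold (strict); threshold usually in [3, 15]%."""
    if not 3.0 <= threshold <= 15.0:
        warnings.warn(f"threshold {threshold}% outside the usual 3-15% sweep range")
    return LOW if abs(d) < threshold else HIGH


def add_differences(records: pd.DataFrame, denominator: str = "tumor") -> pd.DataFrame:
    """Annotate long records (patient, site, tumor_meth, adjacent_meth, ...) with d.

    Rows with zero tumor methylation are excluded with a warning.
    """
    out = records.copy()
    bad = out["tumor_meth"] == 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} records with tumor methylation 0")
        out = out[~bad]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["d"] = [
            relative_difference(t, a, denominator)
            for t, a in zip(out["tumor_meth"], out["adjacent_meth"])
        ]
    return out


@dataclass
class RiskStratification:
    rule: str
    risk_class: pd.Series  # per patient: True = high risk
    hr: float
    hr_ci: tuple[float, float]
    logrank_p: float
    logrank_chi2: float
    n_high: int
    n_low: int
    km_high: pd.DataFrame | None = field(default=None, repr=False)
    km_low: pd.DataFrame | None = field(default=None, repr=False)
    defined: bool = True


def _patient_table(records: pd.DataFrame) -> pd.DataFrame:
    cols = ["time", "event"] + (["stage"] if "stage" in records else [])
    return records.groupby("patient")[cols].first()


def _stratify(
    patients: pd.DataFrame, high_risk: pd.Series, rule: str, hr_estimator: str = "cox"
) -> RiskStratification:
    """KM / log-rank / HR for a binary risk split of the patient table."""
    high_risk = high_risk.reindex(patients.index)
    n_high, n_low = int(high_risk.sum()), int((~high_risk).sum())
    if n_high == 0 or n_low == 0:
        return RiskStratification(
            rule, high_risk, np.nan, (np.nan, np.nan), np.nan, np.nan, n_high, n_low, defined=False
        )
    t, e = patients["time"], patients["event"].astype(bool)
    lr = logrank_test(t[high_risk], t[~high_risk], e[high_risk], e[~high_risk])
    km_high = KaplanMeierFitter().fit(t[high_risk], e[high_risk], label="high_risk")
    km_low = KaplanMeierFitter().fit(t[~high_risk], e[~high_risk], label="low_risk")
    if hr_estimator == "cox":
        hr, ci = _cox_hr(t, e, high_risk)
    elif hr_estimator == "logrank_oe":
        hr, ci = _oe_hr(t, e, high_risk)
    else:
        raise ValueError(f"unknown hr_estimator {hr_estimator!r}")
    return RiskStratification(
        rule=rule,
        risk_class=high_risk,
        hr=hr,
        hr_ci=ci,
        logrank_p=float(lr.p_value),
        logrank_chi2=float(lr.test_statistic),
        n_high=n_high,
        n_low=n_low,
        km_high=km_high.survival_function_,
        km_low=km_low.survival_function_,
    )


def _cox_hr(t, e, group) -> tuple[float, tuple[float, float]]:
    df = pd.DataFrame({"time": t, "event": e.astype(int), "group": group.astype(int)})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return (np.nan, (np.nan, np.nan))
    hr = float(np.exp(cph.params_["group"]))
    lo, hi = cph.confidence_intervals_.loc["group"]
    with np.errstate(over="ignore"):
        return (hr, (float(np.exp(lo)), float(np.exp(hi))))


def _oe_hr(t, e, group) -> tuple[float, tuple[float, float]]:
    """Log-rank O/E hazard-ratio estimator (Mantel-Haenszel style)."""
    o1, e1, o0, e0 = _logrank_oe(t, e, group)
    if e1 == 0 or e0 == 0 or o0 == 0:
        return (np.nan, (np.nan, np.nan))
    hr = (o1 / e1) / (o0 / e0)
    se = np.sqrt(1.0 / e1 + 1.0 / e0)
    return (float(hr), (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se))))


def _logrank_oe(t, e, group):
    """Observed and expected event counts per group over the event times."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=bool)
    g = np.asarray(group, dtype=bool)
    o1 = e[g].sum()
    o0 = e[~g].sum()
    e1 = 0.0
    for et in np.unique(t[e]):
        at_risk = t >= et
        d = (e & (t == et)).sum()
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        e1 += d * n1 / n
    e0 = (o1 + o0) - e1
    return float(o1), float(e1), float(o0), float(e0)


def single_site_stratify(
    records: pd.DataFrame,
    site: str,
    threshold: float,
    denominator: str = "tumor",
    hr_estimator: str = "cox",
) -> RiskStratification:
    """Risk split on one site: low-difference patients form the high-risk group."""
    rec = add_differences(records[records["site"] == site], denominator)
    if rec.empty:
        raise ValueError(f"no records for site {site!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        low = rec.set_index("patient")["d"].abs() < threshold
    patients = _patient_table(records)
    return _stratify(patients, low.reindex(patients.index).fillna(False), f"single:{site}@{threshold}%", hr_estimator)


def combined_model(
    records: pd.DataFrame,
    site_set: list[str],
    n_min: int,
    threshold: float,
    denominator: str = "tumor",
    hr_estimator: str = "cox",
) -> RiskStratification:
    """High-risk iff at least ``n_min`` of ``site_set`` are low-difference.

    Patients missing some sites are counted over their available sites.
    """
    if not 1 <= n_min <= len(site_set):
        raise ValueError("need 1 <= n_min <= |site_set|")
    rec = add_differences(records[records["site"].isin(site_set)], denominator)
    low_counts = (
        rec.assign(low=rec["d"].abs() < threshold).groupby("patient")["low"].sum()
    )
    n_sites_seen = rec.groupby("patient")["site"].nunique()
    if (n_sites_seen < len(site_set)).any():
        warnings.warn("some patients are missing target sites; counting available sites")
    patients = _patient_table(records)
    high = (low_counts >= n_min).reindex(patients.index).fillna(False)
    return _stratify(patients, high, f"combined:N>={n_min}@{threshold}%", hr_estimator)


def threshold_sweep(
    records: pd.DataFrame,
    sites: list[str],
    thresholds: np.ndarray | list[float] = tuple(range(3, 16)),
    denominator: str = "tumor",
    hr_estimator: str = "cox",
) -> pd.DataFrame:
    """HR table over (site, threshold); low-group size is monotone in threshold."""
    rows = []
    prev_sizes: dict[str, int] = {}
    for thr in thresholds:
        for site in sites:
            s = single_site_stratify(records, site, float(thr), denominator, hr_estimator)
            # monotone set inclusion: raising the threshold can only add low-difference patients
            assert s.n_high >= prev_sizes.get(site, 0), "low-difference group shrank"
            prev_sizes[site] = s.n_high
            rows.append(
                {
                    "site": site,
                    "threshold": float(thr),
                    "n_low_difference": s.n_high,
                    "hr": s.hr,
                    "hr_lo": s.hr_ci[0],
                    "hr_hi": s.hr_ci[1],
                    "logrank_p": s.logrank_p,
                    "defined": s.defined,
                }
            )
    return pd.DataFrame(rows)


def stage_crosstab(strat: RiskStratification, stages: pd.Series) -> tuple[pd.DataFrame, float, int]:
    """Risk class x TNM stage contingency table with an association P.

    Returns (table, p_value, n_missing_stage).  Fisher's exact test is
    used for 2x2 tables with any expected count below 5, otherwise the
    chi-squared test.
    """
    from scipy import stats

    stages = stages.reindex(strat.risk_class.index)
    missing = int(stages.isna().sum())
    ok = stages.notna()
    table = pd.crosstab(
        strat.risk_class[ok].map({True: "high_risk", False: "low_risk"}), stages[ok]
    )
    if table.shape[0] < 2 or table.shape[1] < 2:
        return table, np.nan, missing
    chi2, p, _, expected = stats.chi2_contingency(table)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table)
    return table, float(p), missing
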