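"""Reading per-sample methylation tables and assembling the cohort matrix.

Input files are Bismark-coverage-style TSV with six columns
(chromosome, start, end, methylation %, count methylated, count
unmethylated; positions 1-based inclusive, start == end for a CpG).
The cohort is a site x sample matrix of methylation fractions with two
quality filters:

* cells with coverage below ``min_coverage`` (15x) are set missing;
* sites are kept only when detected in enough samples, either at a
  fixed count (e.g. 68 of 84) or at a threshold derived from a
  two-component Gaussian mixture fit (EM) to the per-site detection
  counts — the smallest count whose posterior for the high-mean
  component reaches 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._em import DegenerateMixtureError, GaussianMixture1D, fit_gaussian_mixture_1d
from .sigmatrix import REGIONS

COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "meth_count", "unmeth_count"]


class CoverageFormatError(ValueError):
    pass


def read_bismark_coverage(path: str | Path) -> pd.DataFrame:
    """Read one Bismark coverage file into a sorted records table.

    Returns a DataFrame with columns chrom, pos (1-based), meth_count,
    unmeth_count, sorted by (chrom, pos).  The methylation-% column is
    cross-checked against the counts; a discrepancy beyond 0.5
    percentage points raises a warning (the counts win).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=COVERAGE_COLUMNS,
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "pos", "meth_count", "unmeth_count"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise CoverageFormatError(f"{path}: malformed coverage file: {exc}") from exc
    for col in ("start", "end", "meth_count", "unmeth_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 1
            raise CoverageFormatError(f"{path}: malformed line {line}: non-numeric {col!r}")
        df[col] = vals.astype(int)
    if (df[["meth_count", "unmeth_count"]] < 0).any().any():
        raise CoverageFormatError(f"{path}: negative counts")
    cov = df["meth_count"] + df["unmeth_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * df["meth_count"] / cov, np.nan)
    bad = np.abs(pct - pd.to_numeric(df["meth_pct"], errors="coerce")) > 0.5
    if np.nansum(bad) > 0:
        warnings.warn(
            f"{path}: methylation %% disagrees with counts at {int(np.nansum(bad))} lines; "
            "using counts"
        )
    out = df.rename(columns={"start": "pos"})[["chrom", "pos", "meth_count", "unmeth_count"]]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_bismark_coverage(records: pd.DataFrame, path: str | Path) -> None:
    """Write a records table (chrom, pos, meth_count, unmeth_count) as coverage TSV."""
    cov = records["meth_count"] + records["unmeth_count"]
    pct = np.where(cov > 0, 100.0 * records["meth_count"] / cov, 0.0)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"],
            "end": records["pos"],
            "meth_pct": [f"{v:.6g}" for v in pct],
            "meth_count": records["meth_count"],
            "unmeth_count": records["unmeth_count"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CohortMatrix:
    """Site x sample methylation fractions plus per-cell coverage.

    ``meth`` and ``coverage`` share a (chrom, pos) row MultiIndex and a
    (patient, region) column MultiIndex; missing cells are NaN in
    ``meth`` and 0 in ``coverage``.
    """

    meth: pd.DataFrame
    coverage: pd.DataFrame

    @property
    def sites(self) -> pd.MultiIndex:
        return self.meth.index

    @property
    def samples(self) -> pd.MultiIndex:
        return self.meth.columns

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def detection_counts(self) -> pd.Series:
        """Number of samples with data, per site."""
        return self.meth.notna().sum(axis=1)

    def site_values(self, chrom: str, pos: int) -> np.ndarray:
        """One site's (n_patients, 7) value array in the fixed region order."""
        row = self.meth.loc[(chrom, pos)]
        patients = self.meth.columns.get_level_values(0).unique()
        out = np.full((len(patients), len(REGIONS)), np.nan)
        for pi, patient in enumerate(patients):
            for ri, region in enumerate(REGIONS):
                if (patient, region) in row.index:
                    out[pi, ri] = row[(patient, region)]
        return out

    def iter_site_values(self):
        """Yield ((chrom, pos), values) efficiently for all sites."""
        patients = list(self.meth.columns.get_level_values(0).unique())
        col_index = np.full((len(patients), len(REGIONS)), -1, dtype=int)
        for k, (patient, region) in enumerate(self.meth.columns):
            col_index[patients.index(patient), REGIONS.index(region)] = k
        arr = self.meth.to_numpy()
        for row_i, key in enumerate(self.meth.index):
            vals = np.full(col_index.shape, np.nan)
            ok = col_index >= 0
            vals[ok] = arr[row_i, col_index[ok]]
            yield key, vals

    def subset(self, keep: pd.Series | np.ndarray) -> "CohortMatrix":
        return CohortMatrix(meth=self.meth.loc[keep], coverage=self.coverage.loc[keep])


def assemble_cohort(
    sample_records: dict[tuple[str, str], pd.DataFrame],
    min_coverage: int = 15,
) -> CohortMatrix:
    """Assemble per-sample record tables into a CohortMatrix.

    ``sample_records`` maps (patient, region) to a records table as
    returned by :func:`read_bismark_coverage`.  Every region label must
    be one of TC..PN; duplicate (patient, region) keys cannot occur in a
    dict, but a region label outside the seven is rejected.  The union
    of all sites is retained; cells with coverage below ``min_coverage``
    (strictly less) are set missing.
    """
    for patient, region in sample_records:
        if region not in REGIONS:
            raise ValueError(f"unknown region label {region!r} for patient {patient!r}")
    frames_m, frames_c = {}, {}
    for key in sorted(sample_records, key=lambda k: (str(k[0]), REGIONS.index(k[1]))):
        rec = sample_records[key]
        idx = pd.MultiIndex.from_arrays([rec["chrom"], rec["pos"]], names=["chrom", "pos"])
        if idx.duplicated().any():
            raise ValueError(f"duplicate site in sample {key}")
        cov = (rec["meth_count"] + rec["unmeth_count"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, rec["meth_count"].to_numpy() / cov, np.nan)
        frac = np.where(cov >= min_coverage, frac, np.nan)
        cov = np.where(cov >= min_coverage, cov, 0)
        frames_m[key] = pd.Series(frac, index=idx)
        frames_c[key] = pd.Series(cov, index=idx)
    meth = pd.DataFrame(frames_m).sort_index()
    coverage = pd.DataFrame(frames_c).reindex(meth.index).fillna(0).astype(int)
    meth.columns = pd.MultiIndex.from_tuples(meth.columns, names=["patient", "region"])
    coverage.columns = meth.columns
    return CohortMatrix(meth=meth, coverage=coverage)


@dataclass
class DetectionFilterResult:
    detection_count: pd.Series
    threshold: int
    kept: pd.Series
    mixture: GaussianMixture1D | None = field(default=None, repr=False)
    mode: str = "fixed"


def detection_frequency_filter(
    cohort: CohortMatrix,
    mode: str = "em",
    fixed_threshold: int | None = None,
) -> DetectionFilterResult:
    """Select sites detected often enough across samples.

    mode="fixed" keeps sites with detection count >= ``fixed_threshold``
    ("at least N samples").  mode="em" fits a two-component Gaussian
    mixture to the per-site detection counts and sets the threshold to
    the smallest count whose posterior for the high-mean component is
    >= 0.5; a degenerate fit falls back to keeping everything with a
    warning.
    """
    if cohort.meth.empty:
        raise ValueError("empty cohort matrix")
    counts = cohort.detection_counts()
    if mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed mode requires fixed_threshold")
        threshold = int(fixed_threshold)
        if not 1 <= threshold <= cohort.n_samples:
            raise ValueError("fixed_threshold must be within [1, n_samples]")
        return DetectionFilterResult(counts, threshold, counts >= threshold, None, "fixed")
    if mode != "em":
        raise ValueError(f"unknown mode {mode!r}")
    try:
        fit = fit_gaussian_mixture_1d(counts.to_numpy(dtype=float), k=2)
    except DegenerateMixtureError:
        warnings.warn("detection counts have a single support point; keeping all sites")
        return DetectionFilterResult(counts, int(counts.min()), counts >= counts.min(), None, "fixed")
    high = int(np.argmax(fit.means))
    support = np.arange(0, cohort.n_samples + 1, dtype=float)
    post_high = fit.responsibilities(support)[:, high]
    crossing = np.flatnonzero(post_high >= 0.5)
    if crossing.size == 0:
        warnings.warn("no detection count reaches posterior 0.5 for the high component; keeping all")
        threshold = int(counts.min())
    else:
        threshold = int(support[crossing[0]])
    return DetectionFilterResult(counts, threshold, counts >= threshold, fit, "em")


def em_detection_threshold(counts: np.ndarray, n_samples: int) -> int:
    """Stand-alone EM threshold on raw detection counts (convenience)."""
    fit = fit_gaussian_mixture_1d(np.asarray(counts, dtype=float), k=2)
    high = int(np.argmax(fit.means))
    support = np.arange(0, n_samples + 1, dtype=float)
    post = fit.responsibilities(support)[:, high]
    crossing = np.flatnonzero(post >= 0.5)
    if crossing.size == 0:
        raise ValueError("posterior for the high component never reaches 0.5")
    return int(support[crossing[0]])
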