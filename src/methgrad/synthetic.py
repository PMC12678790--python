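"""Synthetic cohorts with the spatial structure the analysis assumes.

The generator emulates the discovery design — 12 patients each sampled
at seven ordered positions from the tumor core to distal normal tissue
(TC, TE, P5, P10, P15, P20, PN) — with CpG sites planted under known
spatial trends so every downstream stage can be scored against truth:

steep_rise / steep_decline
    The whole effect sits at the TE|P5 visual tumor boundary: TC and TE
    are shifted by the effect size relative to the common base level of
    P5..PN ("rise" meaning methylation increases from TC toward PN).
shallow_rise / shallow_decline
    The effect is interpolated linearly across the seven ordinal
    positions, from the base level at TC to base ± effect at PN.
flat
    All regions at the base level.
fluctuating
    Region means drawn independently per site.

Per-cell methylated/unmethylated read counts are beta-binomial around
the cell mean (patient offsets plus cell jitter), coverage is Poisson,
and cells are dropped uniformly at random.  One global integer seed
drives a named sub-stream per site, so any site is reproducible under
partial regeneration.

The prognosis generator emulates the 59-patient validation cohort:
per-patient tumor/adjacent methylation at a handful of target CpG
sites, with exponential survival whose hazard is multiplied by a
planted hazard ratio when at least two sites show a low tumor-adjacent
relative difference ("shallow-like" patients), and heavy independent
censoring (about 18 expected events in 59 patients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sigmatrix import REGIONS

PATTERN_KINDS = (
    "steep_rise",
    "steep_decline",
    "shallow_rise",
    "shallow_decline",
    "flat",
    "fluctuating",
)


@dataclass(frozen=True)
class PlantedPattern:
    kind: str
    base_level: float = 0.3
    effect_size: float = 0.3
    per_patient_sd: float = 0.05
    per_cell_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not 0.0 <= self.base_level <= 1.0:
            raise ValueError("base_level must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients: int = 12
    region_labels: tuple[str, ...] = REGIONS
    sites_per_pattern: int = 100
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.01  # beta-binomial overdispersion of cell counts
    missing_rate: float = 0.05
    seed: int = 7
    chrom: str = "chr1"
    cluster_size: int = 3  # consecutive same-pattern sites per genomic cluster
    intra_cluster_gap: int = 25  # bp between sites inside a cluster (CpG-island-like density)
    inter_cluster_gap: int = 5000  # bp between clusters

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients")
        if tuple(self.region_labels) != REGIONS:
            raise ValueError(f"region labels must be {REGIONS}")
        if self.coverage_mean < 15:
            raise ValueError("coverage_mean must be >= 15 so the coverage filter is exercised")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")


def default_patterns(
    effect_size: float = 0.3,
    per_patient_sd: float = 0.05,
    per_cell_sd: float = 0.02,
) -> list[PlantedPattern]:
    """One pattern of each kind at field-realistic levels.

    Base levels are staggered so rises and declines stay inside [0, 1]
    with headroom for noise.
    """
    bases = {
        "steep_rise": 0.50,  # tumor side at base - effect
        "steep_decline": 0.30,  # tumor side at base + effect
        "shallow_rise": 0.25,  # PN side at base + effect
        "shallow_decline": 0.55,  # PN side at base - effect
        "flat": 0.45,
        "fluctuating": 0.45,
    }
    return [
        PlantedPattern(kind, bases[kind], effect_size, per_patient_sd, per_cell_sd)
        for kind in PATTERN_KINDS
    ]


def region_mean_profile(pattern: PlantedPattern, rng: np.random.Generator) -> np.ndarray:
    """Planted per-region mean methylation for one site (length 7)."""
    base, eff = pattern.base_level, pattern.effect_size
    k = pattern.kind
    if k == "flat":
        prof = np.full(7, base)
    elif k == "steep_rise":
        # tumor side shifted down; P5..PN at base; methylation rises TC -> PN
        prof = np.array([base - eff, base - eff, base, base, base, base, base])
    elif k == "steep_decline":
        prof = np.array([base + eff, base + eff, base, base, base, base, base])
    elif k == "shallow_rise":
        prof = base + eff * np.linspace(0.0, 1.0, 7)
    elif k == "shallow_decline":
        prof = base - eff * np.linspace(0.0, 1.0, 7)
    elif k == "fluctuating":
        prof = rng.uniform(base - eff, base + eff, size=7)
    else:  # pragma: no cover
        raise AssertionError(k)
    if (prof < 0).any() or (prof > 1).any():
        warnings.warn(f"{k}: planted mean outside [0, 1]; clamping")
        prof = np.clip(prof, 0.0, 1.0)
    return prof


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    """Named sub-stream per site, stable under partial regeneration."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(site_index,)))


def generate_methylation_cohort(
    config: SyntheticCohortConfig | None = None,
    patterns: list[PlantedPattern] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort of per-(site, patient, region) read counts.

    Returns ``(cells, truth)``: ``cells`` has columns chrom, pos,
    patient, region, meth_count, unmeth_count (missing cells absent);
    ``truth`` has one row per site with chrom, pos and the planted
    pattern kind.  Sites of each pattern are laid out left to right in
    genomic clusters of ``cluster_size`` so region merging and
    neighborhood analyses see realistic local structure.
    """
    config = config or SyntheticCohortConfig()
    patterns = patterns if patterns is not None else default_patterns()
    patients = [f"P{i+1:02d}" for i in range(config.n_patients)]

    cell_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    pos = 10_000
    site_index = 0
    for pattern in patterns:
        for s in range(config.sites_per_pattern):
            if site_index > 0:
                in_cluster = s > 0 and config.cluster_size > 1 and s % config.cluster_size != 0
                pos += config.intra_cluster_gap if in_cluster else config.inter_cluster_gap
            rng = _site_rng(config.seed, site_index)
            prof = region_mean_profile(pattern, rng)
            patient_offsets = rng.normal(0.0, pattern.per_patient_sd, size=config.n_patients)
            for pi, patient in enumerate(patients):
                for ri, region in enumerate(REGIONS):
                    if rng.random() < config.missing_rate:
                        continue
                    mu = prof[ri] + patient_offsets[pi]
                    if pattern.per_cell_sd > 0:
                        mu += rng.normal(0.0, pattern.per_cell_sd)
                    mu = float(np.clip(mu, 0.0, 1.0))
                    cov = int(rng.poisson(config.coverage_mean))
                    if cov == 0:
                        continue
                    if pattern.per_cell_sd == 0:
                        # noise-free switch: counts deterministic at the cell mean
                        meth = int(round(mu * cov))
                    elif mu <= 0.0:
                        meth = 0
                    elif mu >= 1.0:
                        meth = cov
                    else:
                        conc = 1.0 / config.coverage_dispersion
                        p = rng.beta(mu * conc, (1.0 - mu) * conc)
                        meth = int(rng.binomial(cov, p))
                    cell_rows.append(
                        (config.chrom, pos, patient, region, meth, cov - meth)
                    )
            truth_rows.append((config.chrom, pos, pattern.kind))
            site_index += 1
    cells = pd.DataFrame(
        cell_rows,
        columns=["chrom", "pos", "patient", "region", "meth_count", "unmeth_count"],
    )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "kind"])
    return cells, truth


def cohort_to_sample_tables(cells: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Split cohort cell rows into per-(patient, region) coverage-record tables."""
    out = {}
    for (patient, region), grp in cells.groupby(["patient", "region"], sort=True):
        out[(patient, region)] = (
            grp[["chrom", "pos", "meth_count", "unmeth_count"]]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
    return out


def write_cohort(
    cells: pd.DataFrame, truth: pd.DataFrame, out_dir: str | Path
) -> list[Path]:
    """Write per-sample Bismark-coverage TSVs plus the truth-label TSV."""
    from .meth_io import write_bismark_coverage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (patient, region), rec in cohort_to_sample_tables(cells).items():
        p = out_dir / f"{patient}_{region}.cov.tsv"
        write_bismark_coverage(rec, p)
        paths.append(p)
    tp = out_dir / "truth.tsv"
    truth.to_csv(tp, sep="\t", index=False)
    paths.append(tp)
    return paths


# --- prognosis cohort -----------------------------------------------------


@dataclass(frozen=True)
class SyntheticPrognosisConfig:
    n_patients: int = 59
    n_sites: int = 6
    planted_hr: float = 4.0
    censor_rate: float = 0.7  # gives ~18 expected events in 59 patients
    baseline_scale: float = 48.0  # months; mean survival of the low-risk group
    low_diff_prob: float = 0.25  # per-site probability of a low tumor-adjacent difference
    min_low_sites: int = 2  # sites with low difference needed for high-risk truth
    threshold_percent: float = 5.0  # |relative difference| below this is "low"
    seed: int = 7

    def __post_init__(self) -> None:
        if self.planted_hr <= 0:
            raise ValueError("planted_hr must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_sites < 1 or self.n_patients < 2:
            raise ValueError("need at least 2 patients and 1 site")


def generate_prognosis_cohort(config: SyntheticPrognosisConfig | None = None) -> pd.DataFrame:
    """Per-patient tumor/adjacent methylation, survival, and truth risk class.

    Returns a long table with one row per (patient, site): columns
    patient, site, tumor_meth, adjacent_meth, time, event, stage,
    truth_high_risk.  Low-difference sites get |relative difference|
    drawn inside the threshold; high-difference sites well outside it.
    Survival is exponential with the hazard multiplied by ``planted_hr``
    for patients whose low-difference site count reaches
    ``min_low_sites``; censoring is independent (a censored patient's
    time is uniform on (0, T)).
    """
    config = config or SyntheticPrognosisConfig()
    rng = np.random.default_rng(config.seed)
    sites = [f"site{j+1}" for j in range(config.n_sites)]
    rows = []
    n_events = 0
    for i in range(config.n_patients):
        patient = f"V{i+1:03d}"
        low = rng.random(config.n_sites) < config.low_diff_prob
        tumor = rng.uniform(0.2, 0.6, size=config.n_sites)
        # low-difference sites sit safely inside the reference threshold;
        # high-difference magnitudes start at 1.6x the threshold (8% at the
        # 5% reference) so sweeping the threshold well past the planted
        # separation starts misclassifying them
        d = np.where(
            low,
            rng.uniform(-0.9, 0.9, size=config.n_sites) * config.threshold_percent,
            np.sign(rng.uniform(-1, 1, size=config.n_sites))
            * rng.uniform(1.6, 12.0, size=config.n_sites)
            * config.threshold_percent,
        )
        adjacent = np.clip(tumor * (1.0 + d / 100.0), 0.0, 1.0)
        high_risk = bool(low.sum() >= config.min_low_sites)
        hazard = (1.0 / config.baseline_scale) * (config.planted_hr if high_risk else 1.0)
        t = float(rng.exponential(1.0 / hazard))
        # censoring independent of the survival time given the risk class,
        # calibrated so P(censored) = censor_rate for every patient
        if config.censor_rate > 0:
            c_rate = hazard * config.censor_rate / (1.0 - config.censor_rate)
            c = float(rng.exponential(1.0 / c_rate))
        else:
            c = np.inf
        event = t <= c
        time = min(t, c)
        n_events += int(event)
        stage = ("III-IV" if rng.random() < 0.6 else "I-II") if high_risk else (
            "III-IV" if rng.random() < 0.25 else "I-II"
        )
        for j, site in enumerate(sites):
            rows.append(
                (
                    patient,
                    site,
                    float(tumor[j]),
                    float(adjacent[j]),
                    max(time, 1e-6),
                    event,
                    stage,
                    high_risk,
                )
            )
    if n_events == 0:
        warnings.warn("all patients censored; log-rank comparisons will be undefined")
    return pd.DataFrame(
        rows,
        columns=[
            "patient",
            "site",
            "tumor_meth",
            "adjacent_meth",
            "time",
            "event",
            "stage",
            "truth_high_risk",
        ],
    )


# --- annotation fixtures --------------------------------------------------


def generate_annotation_fixture(
    n_genes: int,
    seed: int,
    out_dir: str | Path,
    chrom: str = "chr1",
    span: tuple[int, int] = (0, 3_000_000),
) -> dict[str, Path]:
    """Write a synthetic GTF of gene models plus BED feature tracks.

    Genes alternate strands along ``chrom`` inside ``span`` with
    2-10 kb bodies; two BED tracks (CpG-island-like and TF-binding-like
    intervals) overlap the gene starts.  Output is byte-identical for a
    given seed.  GTF coordinates are 1-based inclusive with
    Ensembl-style attributes; BED is 0-based half-open.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lo, hi = span
    slot = max((hi - lo) // n_genes, 12_000)
    gtf_lines = []
    cpg_rows, tf_rows = [], []
    seen_ids = set()
    for g in range(n_genes):
        gene_id = f"SYNG{g+1:06d}"
        if gene_id in seen_ids:
            raise ValueError(f"duplicate gene id {gene_id}")
        seen_ids.add(gene_id)
        strand = "+" if g % 2 == 0 else "-"
        start0 = lo + g * slot + int(rng.integers(2_000, 4_000))
        length = int(rng.integers(2_000, 10_000))
        end0 = start0 + length
        # GTF is 1-based inclusive
        attrs = (
            f'gene_id "{gene_id}"; gene_name "SYN{g+1}"; gene_type "protein_coding";'
        )
        gtf_lines.append(
            f"{chrom}\tsynthetic\tgene\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"
        )
        # a CpG-island-like interval over the TSS, a TF site inside the body
        tss0 = start0 if strand == "+" else end0 - 1
        cpg_rows.append((chrom, max(tss0 - 300, 0), tss0 + 300, f"CpG_{g+1}"))
        tf_start = start0 + int(rng.integers(0, max(length - 200, 1)))
        tf_rows.append((chrom, tf_start, tf_start + 200, f"TF_{g+1}"))
    paths = {
        "gtf": out_dir / "genes.gtf",
        "cpg_islands": out_dir / "cpg_islands.bed",
        "tf_binding": out_dir / "tf_binding.bed",
    }
    paths["gtf"].write_text("\n".join(gtf_lines) + "\n")
    for key, rows in (("cpg_islands", cpg_rows), ("tf_binding", tf_rows)):
        paths[key].write_text(
            "".join(f"{c}\t{s}\t{e}\t{name}\n" for c, s, e, name in rows)
        )
    return paths
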