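"""Methylation-changing regions: merging, categorization, gene annotation.

A changing region is a run of at least ``min_sites`` (3) classified
changing CpG sites on one chromosome with consecutive inter-site gaps
not exceeding ``max_gap`` (250 bp), all sharing one direction.  Regions
are categorized by their member classes: pure steep, pure shallow, or
mixed (both kinds, one direction); a direction-agnostic merge pass can
additionally produce bidirectional regions which are flagged
``discarded_bidirectional`` and excluded downstream.

Coordinates are 0-based half-open internally and in BED output; site
positions arrive 1-based (Bismark convention) and GTF is read 1-based
inclusive — the conversions live in :func:`pos_to_interval` and
:func:`gtf_span_to_interval` only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .meth_io import CohortMatrix

CHANGING_CLASSES = ("steep_rise", "steep_decline", "shallow_rise", "shallow_decline")

PROMOTER_BP = 2000


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based CpG position -> 0-based half-open single-base interval."""
    return (pos - 1, pos)


def gtf_span_to_interval(start: int, end: int) -> tuple[int, int]:
    """GTF 1-based inclusive span -> 0-based half-open interval."""
    return (start - 1, end)


@dataclass
class ChangingRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    member_positions: list[int]  # 1-based site positions
    member_classes: list[str]
    category: str = ""

    def __post_init__(self) -> None:
        if not self.category:
            self.category = categorize_members(self.member_classes)

    @property
    def n_sites(self) -> int:
        return len(self.member_positions)

    @property
    def direction(self) -> str:
        if self.category == "discarded_bidirectional":
            return "mixed"
        return "rise" if self.category.endswith("rise") else "decline"


def categorize_members(classes: list[str]) -> str:
    """Region category from its member site classes.

    Pure one-kind/one-direction runs give steep_* / shallow_*; both
    kinds in one direction give mixed_*; both directions present gives
    discarded_bidirectional.
    """
    kinds = {c.split("_")[0] for c in classes}
    dirs = {c.split("_")[1] for c in classes}
    if len(dirs) > 1:
        return "discarded_bidirectional"
    d = dirs.pop()
    return (kinds.pop() if len(kinds) == 1 else "mixed") + "_" + d


def categorize_region(region: ChangingRegion) -> str:
    return categorize_members(region.member_classes)


def merge_changing_sites(
    sites: pd.DataFrame,
    max_gap: int = 250,
    min_sites: int = 3,
    direction_aware: bool = True,
) -> list[ChangingRegion]:
    """Merge classified sites into changing regions.

    ``sites`` needs columns chrom, pos (1-based) and class; only
    steep/shallow classes are eligible.  Sites must be position-sorted
    within each chromosome.  With ``direction_aware`` (default), runs
    are broken where the direction flips, per "the same trend"; the
    direction-agnostic mode merges on gap alone and flags regions
    containing both directions as discarded_bidirectional.
    """
    regions: list[ChangingRegion] = []
    eligible = sites[sites["class"].isin(CHANGING_CLASSES)]
    for chrom, grp in eligible.groupby("chrom", sort=True):
        pos = np.asarray(grp["pos"])
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites on {chrom} are not position-sorted")
        cls = list(grp["class"])
        run_start = 0
        for i in range(1, len(pos) + 1):
            end_of_run = i == len(pos) or pos[i] - pos[i - 1] > max_gap
            if not end_of_run and direction_aware:
                end_of_run = cls[i].split("_")[1] != cls[i - 1].split("_")[1]
            if end_of_run:
                if i - run_start >= min_sites:
                    members = list(map(int, pos[run_start:i]))
                    regions.append(
                        ChangingRegion(
                            chrom=chrom,
                            start=members[0] - 1,
                            end=members[-1],
                            member_positions=members,
                            member_classes=cls[run_start:i],
                        )
                    )
                run_start = i
    return regions


def region_methylation_profile(region: ChangingRegion, cohort: CohortMatrix) -> pd.Series:
    """Per-sample median methylation over the region's member sites.

    Missing cells are excluded from each median; a sample with every
    member missing yields NaN.  An even number of observed members
    gives the midpoint of the central pair (pandas median).
    """
    idx = [(region.chrom, p) for p in region.member_positions]
    present = [k for k in idx if k in cohort.meth.index]
    if not present:
        raise KeyError(f"no member sites of {region.chrom}:{region.start}-{region.end} in cohort")
    return cohort.meth.loc[present].median(axis=0, skipna=True)


# --- gene models ----------------------------------------------------------


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    body: tuple[int, int]  # 0-based half-open full transcription span
    promoter: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        if self.promoter == (0, 0):
            self.promoter = promoter_interval(self.body, self.strand)
        if self.body[1] <= self.body[0]:
            raise ValueError("degenerate gene body")


def promoter_interval(body: tuple[int, int], strand: str) -> tuple[int, int]:
    """2 kb upstream of the TSS, strand-aware, abutting the gene body."""
    start, end = body
    if strand == "+":
        return (max(start - PROMOTER_BP, 0), start)
    if strand == "-":
        return (end, end + PROMOTER_BP)
    raise ValueError(f"bad strand {strand!r}")


def load_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Read gene features from a GENCODE/Ensembl-style GTF.

    Gene body = the full transcription span of the ``gene`` feature;
    promoter = 2 kb upstream of the strand-aware TSS.  Genes without a
    strand are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            warnings.warn(f"gene {feat.id} has no strand; skipped")
            continue
        body = gtf_span_to_interval(feat.start, feat.end)
        name = feat.attributes.get("gene_name", [feat.id])[0]
        models.append(
            GeneModel(
                gene_id=feat.attributes.get("gene_id", [feat.id])[0],
                gene_name=name,
                chrom=feat.seqid,
                strand=feat.strand,
                body=body,
            )
        )
    return models


@dataclass
class AnnotationHit:
    region: ChangingRegion
    gene: GeneModel
    compartment: str  # gene_body | promoter


def _normalize_chrom(name: str) -> str:
    return name if name.startswith("chr") else f"chr{name}"


def map_regions_to_genes(
    regions: list[ChangingRegion], genes: list[GeneModel]
) -> list[AnnotationHit]:
    """Intersect regions with gene bodies and promoters.

    A region may hit several genes and both compartments of one gene.
    chr-prefix conventions are normalized with a warning on mismatch.
    """
    gene_chroms = {g.chrom for g in genes}
    region_chroms = {r.chrom for r in regions}
    normalize = False
    if region_chroms and gene_chroms and not (region_chroms & gene_chroms):
        if {_normalize_chrom(c) for c in region_chroms} & {
            _normalize_chrom(c) for c in gene_chroms
        }:
            warnings.warn("chromosome naming differs (chr1 vs 1); normalizing")
            normalize = True
    hits = []
    for r in regions:
        r_chrom = _normalize_chrom(r.chrom) if normalize else r.chrom
        for g in genes:
            g_chrom = _normalize_chrom(g.chrom) if normalize else g.chrom
            if r_chrom != g_chrom:
                continue
            for compartment, (s, e) in (("gene_body", g.body), ("promoter", g.promoter)):
                if r.start < e and s < r.end:
                    hits.append(AnnotationHit(region=r, gene=g, compartment=compartment))
    return hits


# --- feature tracks -------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": int, "end": int})


def merge_intervals(track: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge overlapping intervals per chromosome; returns sorted (n, 2) arrays."""
    merged = {}
    for chrom, grp in track.groupby("chrom"):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        out = []
        for s, e in iv:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    return merged


def sites_in_track(sites: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean membership of 1-based site positions in a BED track."""
    merged = merge_intervals(track)
    result = np.zeros(len(sites), dtype=bool)
    chroms = np.asarray(sites["chrom"])
    positions = np.asarray(sites["pos"])
    for chrom, iv in merged.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        p0 = positions[sel] - 1  # 0-based point
        k = np.searchsorted(iv[:, 0], p0, side="right") - 1
        ok = (k >= 0) & (p0 < iv[np.clip(k, 0, len(iv) - 1), 1])
        result[sel] = ok
    return result


def feature_overlap_proportions(
    site_sets: dict[str, pd.DataFrame],
    tracks: dict[str, pd.DataFrame | str | Path],
) -> pd.DataFrame:
    """Proportion of each site set lying inside each feature track."""
    out = {}
    for track_name, track in tracks.items():
        if not isinstance(track, pd.DataFrame):
            track = read_bed(track)
        col = {}
        for set_name, sites in site_sets.items():
            col[set_name] = (
                float(sites_in_track(sites, track).mean()) if len(sites) else np.nan
            )
        out[track_name] = col
    return pd.DataFrame(out)


def regions_to_bed(regions: list[ChangingRegion]) -> pd.DataFrame:
    """Regions as a BED-style frame (0-based half-open) with category."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "category": [r.category for r in regions],
            "n_sites": [r.n_sites for r in regions],
        }
    )
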