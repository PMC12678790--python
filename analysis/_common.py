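"""Shared helpers for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

from methgrad import classify, meth_io, sigmatrix, synthetic

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def filtered_cohort():
    """Default discovery cohort, assembled and detection-filtered, with truth."""
    cfg = synthetic.SyntheticCohortConfig()
    cells, truth = synthetic.generate_methylation_cohort(cfg)
    cohort = meth_io.assemble_cohort(synthetic.cohort_to_sample_tables(cells))
    det = meth_io.detection_frequency_filter(cohort, "fixed", 68)
    return cfg, cohort.subset(det.kept), truth


def site_matrices(cohort):
    values = dict(cohort.iter_site_values())
    matrices = {k: sigmatrix.pairwise_region_tests(v) for k, v in values.items()}
    return values, matrices


def classified_sites(cohort, truth, values=None, matrices=None):
    if values is None:
        values, matrices = site_matrices(cohort)
    out = classify.classify_sites(values, matrices)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["chrom", "pos"])
    return out.join(truth.set_index(["chrom", "pos"])["kind"])
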