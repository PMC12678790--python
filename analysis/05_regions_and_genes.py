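#!/usr/bin/env python
"""Merge classified sites into changing regions and annotate them.

Regions = runs of >= 3 same-direction changed sites with gaps <= 250 bp;
they are mapped onto gene bodies and 2-kb promoters of the synthetic
gene models, and site sets are intersected with the CpG-island-like and
TF-binding-like BED tracks.
"""

import pandas as pd

from _common import ROOT, RESULTS, classified_sites, filtered_cohort

from methgrad import regions, synthetic


def main() -> None:
    cfg, cohort, truth = filtered_cohort()
    classified = classified_sites(cohort, truth).reset_index()

    region_list = regions.merge_changing_sites(classified[["chrom", "pos", "class"]])
    bed = regions.regions_to_bed(region_list)
    bed.to_csv(RESULTS / "05_regions.tsv", sep="\t", index=False)
    print(f"{len(region_list)} changing regions")
    print(bed["category"].value_counts().to_string())

    fixture = synthetic.generate_annotation_fixture(
        60, seed=cfg.seed, out_dir=ROOT / "scratch" / "annotation"
    )
    genes = regions.load_gene_models(fixture["gtf"])
    hits = regions.map_regions_to_genes(region_list, genes)
    print(f"\n{len(hits)} region-gene hits over {len(genes)} synthetic genes")
    by_comp = pd.Series([h.compartment for h in hits]).value_counts()
    print(by_comp.to_string() if len(hits) else "(none)")

    site_sets = {
        fam: classified.loc[classified["class"].str.startswith(fam), ["chrom", "pos"]]
        for fam in ("steep", "shallow")
    }
    site_sets["all"] = classified[["chrom", "pos"]]
    tracks = {name: fixture[name] for name in ("cpg_islands", "tf_binding")}
    prop = regions.feature_overlap_proportions(site_sets, tracks)
    prop.round(4).to_csv(RESULTS / "05_feature_overlap.tsv", sep="\t")
    print("\nproportion of sites inside each feature track:")
    print(prop.round(3).to_string())


if __name__ == "__main__":
    main()
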