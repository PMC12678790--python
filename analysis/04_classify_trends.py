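#!/usr/bin/env python
"""Steep/shallow trend classification scored against generator truth.

Writes the confusion matrix and per-family sensitivity/FDR to results/.
The strict steep rule (significance confined to tumor x distal pairs)
loses truly steep sites to chance significances among the 11 null
pairs; the printed numbers quantify that honestly.
"""

import pandas as pd

from _common import RESULTS, classified_sites, filtered_cohort

from methgrad.classify import class_counts


def main() -> None:
    _, cohort, truth = filtered_cohort()
    classified = classified_sites(cohort, truth)

    confusion = pd.crosstab(classified["kind"], classified["class"])
    confusion.to_csv(RESULTS / "04_confusion.tsv", sep="\t")
    print("planted kind (rows) vs called class (columns):")
    print(confusion.to_string())
    print("\nclass counts:", class_counts(classified))

    rows = []
    for fam in ("steep", "shallow"):
        planted = classified["kind"].str.startswith(fam)
        called = classified["class"].str.startswith(fam)
        recovered = planted & (classified["class"] == classified["kind"])
        rows.append(
            {
                "family": fam,
                "sensitivity": recovered.sum() / planted.sum(),
                "fdr": (called & ~planted).sum() / max(called.sum(), 1),
            }
        )
    perf = pd.DataFrame(rows)
    perf.round(3).to_csv(RESULTS / "04_recovery.tsv", sep="\t", index=False)
    print("\n" + perf.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
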