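#!/usr/bin/env python
"""Mine redescriptions linking CSF biomarker profiles (with MMSE, age
and APOE) to CSF and plasma element profiles: 10 runs x 30 alternations
of tree-based rule induction, 20-tree forest supplement, conjunctive
refinement; keep redescriptions with support in the configured bounds,
Jaccard >= 0.5 and p <= 0.01, and label diagnosis specificity."""

import json
import os

import pandas as pd

from csfmetals import count_cooccurrence, mine, read_cohort
from csfmetals.mining import default_params
from csfmetals.pipeline import summary_table

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 7

COMBOS = (
    (("csf_biomarkers", "csf_elements"), "pair1"),
    (("csf_biomarkers", "plasma_elements"), "pair2"),
    (("csf_biomarkers", "csf_elements", "plasma_elements"), "tripple"),
)


def main():
    ds = read_cohort(os.path.join(OUT, "cohort.csv"))
    all_rds = []
    for views, tag in COMBOS:
        params = default_params(views, seed=SEED)
        rds = mine(ds, views, params)
        all_rds.extend(rds)
        with open(os.path.join(OUT, f"redescriptions_{tag}.json"), "w") as fh:
            json.dump([rd.to_dict() for rd in rds], fh, indent=1, sort_keys=True)
        summary_table(rds, views).to_csv(
            os.path.join(OUT, f"redescriptions_{tag}.tsv"), sep="\t", index=False)
        labels = pd.Series([rd.specificity_label for rd in rds])
        print(f"{tag} ({' + '.join(views[1:])}): {len(rds)} redescriptions "
              f"(bounds {params.min_support}-{params.max_support})")
        if len(rds):
            print("   by specificity:", dict(labels.value_counts()))
            best = rds[0]
            print(f"   most significant: JS={best.jaccard:.5f} "
                  f"p={best.p_value:.3g} [{best.specificity_label}]")
            for q in best.queries:
                print("     ", q.text())
    rows = []
    bios = ds.view_columns["csf_biomarkers"]
    elements = (ds.view_columns["csf_elements"]
                + ds.view_columns["plasma_elements"])
    for bm in bios:
        for el in elements:
            c = count_cooccurrence(all_rds, bm, el)
            if c:
                rows.append({"biomarker": bm, "element": el, "count": c})
    co = pd.DataFrame(rows, columns=["biomarker", "element", "count"])
    co.sort_values("count", ascending=False).to_csv(
        os.path.join(OUT, "cooccurrence_counts.csv"), index=False)
    if len(co):
        top = co.sort_values("count", ascending=False).head(5)
        print("most frequent biomarker-element co-occurrences:")
        for _, r in top.iterrows():
            print(f"   {r.biomarker} with {r.element}: {r['count']}")


if __name__ == "__main__":
    main()
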