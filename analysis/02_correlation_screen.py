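#!/usr/bin/env python
"""Screen every CSF biomarker against every element concentration
(pairwise-complete Spearman, Pearson alongside), gate at p <= 0.001, and
re-test gate-passing pairs adjusted for age, gender, diagnosis and
disease duration."""

import os

from csfmetals import read_cohort, screen
from csfmetals.screen import DEFAULT_COVARIATES, adjust, records_to_frame

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    ds = read_cohort(os.path.join(OUT, "cohort.csv"))
    records = screen(ds, gate=0.001)
    for rec in records:
        if rec.passes_gate:
            adjust(rec, ds, DEFAULT_COVARIATES, gate=0.001)
    frame = records_to_frame(records)
    frame.to_csv(os.path.join(OUT, "correlations.csv"), index=False)
    n_pass = sum(r.passes_gate for r in records)
    kept = sum(1 for r in records for a in r.adjusted_results if a.retained)
    print(f"{len(records)} biomarker x element pairs screened; "
          f"{n_pass} pass the p<=0.001 gate; "
          f"{kept} remain significant after full confounder adjustment")
    top = sorted((r for r in records if r.passes_gate),
                 key=lambda r: -abs(r.r))[:5]
    for r in top:
        print(f"  {r.biomarker} x {r.element}: rs={r.r:.3f}, "
              f"p={r.p:.2e} (n={r.n})")


if __name__ == "__main__":
    main()
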