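#!/usr/bin/env python
"""Validation studies on ground-truth cohorts: recovery of planted
cross-view subgroups, and the false-discovery audit on cohorts whose
views are fully independent."""

import os

import numpy as np
import pandas as pd

from csfmetals import MinerParams, generate_cohort, jaccard, mine
from csfmetals.scenarios import null_config, planted_config

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
N_PLANTED_SEEDS = 3
N_NULL_SEEDS = 3


def main():
    os.makedirs(OUT, exist_ok=True)
    rows = []
    for seed in range(1, N_PLANTED_SEEDS + 1):
        ds = generate_cohort(planted_config(seed))
        rds = mine(ds, ("csf_biomarkers", "csf_elements"), MinerParams(seed=seed))
        for i, mem in enumerate(ds.planted_members):
            best = max((jaccard([rd.support, set(mem)])[2] for rd in rds),
                       default=0.0)
            rows.append({"study": "planted", "seed": seed, "plant": i,
                         "n_emitted": len(rds), "best_overlap": round(best, 4),
                         "recovered": best >= 0.8})
    for seed in range(N_NULL_SEEDS):
        ds = generate_cohort(null_config(seed))
        rds = mine(ds, ("csf_biomarkers", "csf_elements"), MinerParams(seed=seed))
        rows.append({"study": "null", "seed": seed, "plant": None,
                     "n_emitted": len(rds), "best_overlap": None,
                     "recovered": None})
    frame = pd.DataFrame(rows)
    frame.to_csv(os.path.join(OUT, "validation_studies.csv"), index=False)
    planted = frame[frame.study == "planted"]
    print(f"planted subgroups recovered (overlap >= 0.8): "
          f"{int(planted.recovered.sum())}/{len(planted)}")
    null = frame[frame.study == "null"]
    print(f"independent-view cohorts: mean emitted redescriptions "
          f"{null.n_emitted.mean():.2f} (counts {list(null.n_emitted)})")


if __name__ == "__main__":
    main()
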