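#!/usr/bin/env python
"""Reduce each element view to six varimax-rotated factors (with KMO and
Bartlett adequacy checks), assign elements to factors at the 0.4 loading
threshold, and regress every CSF biomarker on the factor scores."""

import json
import os

from csfmetals import fit_factors, read_cohort, regress_on_factors
from csfmetals.factors import regressions_to_frame

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    ds = read_cohort(os.path.join(OUT, "cohort.csv"))
    regs = []
    for view, tag in (("csf_elements", "csf"), ("plasma_elements", "plasma")):
        sol = fit_factors(ds, view, n_factors=6, threshold=0.4)
        with open(os.path.join(OUT, f"factors_{tag}.json"), "w") as fh:
            json.dump(sol.to_dict(), fh, indent=1, sort_keys=True)
        print(f"{tag}: KMO={sol.kmo_overall:.3f}, Bartlett p={sol.bartlett[2]:.1e}, "
              f"variance explained {100 * sol.variance_explained_total:.1f}%")
        for fac, members in sol.groups.items():
            if members:
                print(f"  {fac}: " + ", ".join(
                    f"{e.split('_')[0]} ({l:.3f})" for e, l in members))
        for bm in ds.view_columns["csf_biomarkers"]:
            try:
                regs.extend(regress_on_factors(ds, sol, bm))
            except ValueError:
                pass
    frame = regressions_to_frame(regs)
    frame.to_csv(os.path.join(OUT, "factor_regressions.csv"), index=False)
    sig = frame[frame.p <= 0.05]
    print(f"{len(sig)} of {len(frame)} biomarker-factor regressions "
          f"significant at alpha = 0.05")


if __name__ == "__main__":
    main()
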