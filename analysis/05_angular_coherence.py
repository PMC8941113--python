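"""Angular coherence of labeled groups on embedded discs.

Uses the S1 benchmark instances: labels are assigned from the planted angular
sectors (mimicking functional subnetworks occupying angular neighborhoods of
the disc, with a deliberately diffuse sector as contrast), then measured on
the *inferred* embedding. Also demonstrates the left/right paired comparison
on split sectors. Writes results/coherence_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hypercore import coherence as coh
from hypercore import hypembed as he, netbuild as nb, synthetic_data as sd
from hypercore.io_formats import LabelMap

RESULTS = Path(__file__).resolve().parents[1] / "results"


def sector_labels(theta_true, nodes):
    """Two tight sectors (VN1-like, SMN1-like), one diffuse group (DAN-like),
    plus left/right halves of one sector for the paired comparison."""
    membership = {}
    rng = np.random.default_rng(0)
    for v in nodes:
        th = theta_true[v]
        labs = set()
        if th < 0.6:
            labs.add("VN1")
            labs.add("L CEN" if th < 0.3 else "R CEN")
        elif 2.0 < th < 2.8:
            labs.add("SMN1")
        if rng.random() < 0.1:  # diffuse group scattered over the disc
            labs.add("DAN")
        if labs:
            membership[v] = labs
    return LabelMap("functional-15", membership,
                    ["VN1", "SMN1", "DAN", "L CEN", "R CEN"])


def main():
    RESULTS.mkdir(exist_ok=True)
    per_subject = []
    left, right = [], []
    for seed in range(1, 7):
        g, truth = sd.sample_s1_network(500, 2.5, 10.0, 2.5, seed=seed)
        lcc, _ = nb.largest_component(g)
        nodes = sorted(lcc.nodes())
        e = he.embed(lcc, seed=seed)
        labels = sector_labels(truth.theta_true, nodes)
        results = coh.group_coherence(e, labels)
        per_subject.append(results)
        by = {r.label: r.xi for r in results}
        if "L CEN" in by and "R CEN" in by:
            left.append(by["L CEN"])
            right.append(by["R CEN"])
    table = coh.cohort_coherence_table(per_subject)
    table.to_csv(RESULTS / "coherence_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nTight angular sectors score high coherence; the scattered "
          "group stays near the null.")
    if len(left) >= 6:
        stat, p = coh.laterality_test(left, right)
        print(f"left vs right half-sector Wilcoxon: W={stat:.1f}, p={p:.3f}")
    else:
        print("(fewer than 6 instances with both half-sectors embedded; "
              "laterality test skipped)")


if __name__ == "__main__":
    main()
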