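#!/usr/bin/env python
"""Driver-frequency comparison and mutual exclusivity / co-occurrence.

Applies the hypermutation (>1000 coding mutations) and 1%-frequency
filters, compares per-gene driver frequencies across cohorts by Fisher
exact + BH, and tests pairwise co-occurrence among drivers and the
planted chr16 deletion (expecting the AXIN1-chr16del association).
"""

from pathlib import Path

import pandas as pd

from hccpipe import cnv as V
from hccpipe import stats as T
from hccpipe.simulate import DELETION_ARMS, read_fixture

ROOT = Path(__file__).resolve().parents[1] / "results"
data = read_fixture(ROOT / "cohorts")
cohort = data["clinical"].set_index("sample_id")["cohort"]

fmaf, events = T.apply_cohort_filters(data["maf"], data["clinical"])
print(f"{events.shape[1]} driver genes after filters, "
      f"{events.shape[0]} samples retained")

freq = T.compare_event_frequencies(events, cohort.reindex(events.index))
freq.to_csv(ROOT / "driver_frequency_comparison.tsv", sep="\t", index=False)
sig = freq[freq["significant"]]
print("drivers at q<0.1:")
print(sig[["event", "freq_a", "freq_b", "q"]].round(4).to_string(index=False))

_, calls = V.instability_table(data["seg"])
chr16del = (calls[list(DELETION_ARMS)] == "del").all(axis=1).astype(int)
mat = events.join(chr16del.rename("chr16del"), how="left").fillna(0).astype(int)
pairs = T.fisher_pairwise(mat)
pairs.to_csv(ROOT / "mutual_exclusivity.tsv", sep="\t", index=False)
# the AXIN1-chr16del association is planted inside cohort A (via P2)
mat_a = mat.loc[[s for s in mat.index if cohort.get(s) == "A"]]
pairs_a = T.fisher_pairwise(mat_a)
hit = pairs_a[((pairs_a["event_a"] == "AXIN1") & (pairs_a["event_b"] == "chr16del"))
              | ((pairs_a["event_b"] == "AXIN1") & (pairs_a["event_a"] == "chr16del"))]
print("AXIN1 x chr16 deletion (cohort A):")
print(hit[["odds_ratio", "p", "q", "direction"]].round(6).to_string(index=False))
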