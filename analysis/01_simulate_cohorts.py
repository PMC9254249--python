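#!/usr/bin/env python
"""Generate the default two-cohort synthetic study and write it to disk.

Cohort A is the Asian-like cohort (higher TMB, frequent chr16-like
deletion co-occurring with a P2-like subtype, AA/liver signature groups);
cohort B is European-like.  Downstream scripts read the fixture from
results/cohorts/.
"""

from pathlib import Path

from hccpipe.simulate import SimulationConfig, simulate_cohorts, write_fixture

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"

config = SimulationConfig(n_a=150, n_b=150, seed=SEED)
bundle = simulate_cohorts(config)
paths = write_fixture(bundle, OUT)

t = bundle.truth.samples
print(f"wrote {len(t)} samples to {OUT}")
for cohort, grp in t.groupby("cohort"):
    tmb = bundle.maf[bundle.maf["coding"] == 1].groupby("sample_id").size()
    print(
        f"cohort {cohort}: n={len(grp)}, "
        f"median coding TMB={tmb.reindex(grp.index).median():.0f}, "
        f"chr16 deletion={grp['deleted_arm'].mean():.2f}, "
        f"subtypes={grp['subtype'].value_counts().to_dict()}"
    )
print(f"censoring rate: {1 - t['os_event'].mean():.2f}")
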