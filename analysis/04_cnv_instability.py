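#!/usr/bin/env python
"""Genome instability: GII, arm SCNA scores, cohort arm-frequency tests,
TMB comparison with covariate adjustment, and CNV-expression correlation.
"""

from pathlib import Path

from scipy.stats import mannwhitneyu

from hccpipe import cnv as V
from hccpipe import stats as T
from hccpipe.simulate import read_fixture

ROOT = Path(__file__).resolve().parents[1] / "results"
data = read_fixture(ROOT / "cohorts")
cohort = data["clinical"].set_index("sample_id")["cohort"]

scores, calls = V.instability_table(data["seg"])
scores.to_csv(ROOT / "instability_scores.tsv", sep="\t")
a = scores.loc[cohort == "A", "arm_scna_score"]
b = scores.loc[cohort == "B", "arm_scna_score"]
print(f"arm SCNA score: A mean={a.mean():.2f}, B mean={b.mean():.2f}, "
      f"one-sided p={mannwhitneyu(a, b, alternative='greater').pvalue:.2e}")

arm_cmp = V.compare_arm_frequencies(calls, cohort)
arm_cmp.to_csv(ROOT / "arm_frequency_comparison.tsv", sep="\t")
sig = arm_cmp[arm_cmp["significant"]]
print(f"arms at q<0.1: {list(sig.index)}")
print(sig[["freq_a", "freq_b", "q"]].round(4))

tmb = data["maf"][data["maf"]["coding"] == 1].groupby("sample_id").size() \
    .reindex(cohort.index, fill_value=0)
covs = data["clinical"].set_index("sample_id")[["viral_status", "sex", "age"]]
covs = covs.join(data["purity"].set_index("sample_id")["purity"])
res = T.adjusted_tmb_comparison(tmb, cohort, covs)
print(f"TMB cohort effect (log10 scale): {res['coef']:.3f} "
      f"[{res['ci_low']:.3f}, {res['ci_high']:.3f}], adjusted p={res['p_adjusted_model']:.2e}, "
      f"unadjusted rank-sum p={res['p_wilcoxon']:.2e}")

arm_cn = V.arm_mean_cn(data["seg"])
corr = V.cnv_expression_correlation(arm_cn, data["expression"])
corr[corr["significant"]].to_csv(ROOT / "cnv_expression_significant.tsv",
                                 sep="\t", index=False)
chr16 = corr[corr["arm"].isin(["chr16p", "chr16q"]) & corr["significant"]]
print(f"significant CNV-expression pairs: {corr['significant'].sum()} "
      f"({len(chr16)} involving the chr16 deletion arms)")
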