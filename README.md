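# hccpipe

A tested re-implementation of the computational core of a multi-layer,
two-cohort comparison of hepatocellular carcinoma (HCC) genomes — the
kind of analysis that asks how an Asian-like and a European-like cohort
differ in mutation burden, mutational processes, copy-number instability,
transcriptomic subtypes and survival predictability.  The original
cohorts are controlled-access, so the package ships a synthetic-cohort
generator with planted ground truth for every layer, and every estimator
is scored against that truth.

It is aimed at cancer-genomics analysts who want the individual building
blocks (CCF inference, signature deconvolution, instability scores,
consensus-NMF subtyping, survival forests) as a library, plus an
end-to-end worked study under `analysis/`.

## What is implemented

* **CCF and timing** — per-mutation cancer cell fraction by minimizing
  the binomial deviance of `VAF = purity·CCF / (CN_n(1−purity) +
  purity·CN_m)` on [0, 1]; early (clonal) at CCF ≥ 0.8; read-support
  filters depth ≥ 10, alt ≥ 3, VAF ≥ 0.05.
* **ITH metrics** — pLM, MATH (`100·1.4826·MAD(VAF)/median(VAF)`) and the
  Shannon index over subclones from a BIC-selected 1-D Gaussian mixture.
* **Signatures** — SBS-96 deconvolution by simplex-constrained least
  squares with the 6% zeroing convention, the mean>2% / max≥20% retention
  rule, Ward signature groups, and paired early-vs-late signed-rank
  timing tests.
* **Copy-number instability** — GII (fraction of genome off the median
  ploidy), arm-level calls and SCNA burden, per-arm cohort Fisher/BH
  comparison, and the CNV-expression cis/trans correlation map.
* **Association statistics** — hypermutation/frequency filters, exact
  pairwise co-occurrence/mutual-exclusivity tests, cohort driver
  frequency comparison, covariate-adjusted TMB model, BH correction.
* **Subtyping** — consensus Brunet (KL) NMF with the
  cophenetic+silhouette rank rule, top-100 Cohen's-d templates,
  nearest-template prediction with permutation FDR and an "NS" fallback,
  and mutual-NTP cross-cohort subtype correspondence.
* **Survival harness** — the clinical/molecular/driver/ITH feature table,
  repeated shadow-feature random-survival-forest selection (50 × 75%
  subsamples, keep at ≥ 25), paired 75/25 c-index distributions per
  feature category and cohort, VIMP mean-rank importance, and the
  univariate Cox correlation network.

## Worked example

```
python analysis/01_simulate_cohorts.py
python analysis/02_ccf_ith.py
python analysis/04_cnv_instability.py
python analysis/07_survival_models.py
```

prints, among other things:

```
cohort A: n=150, median coding TMB=145, chr16 deletion=0.41, subtypes={'P1': 53, 'M1': 36, 'M2': 33, 'P2': 28}
cohort B: n=150, median coding TMB=96,  chr16 deletion=0.13, subtypes={'P': 65, 'M1': 46, 'M2': 39}
plm: A median=0.547, B median=0.588, rank-sum p=0.636
arm SCNA score: A mean=3.11, B mean=1.43, one-sided p=6.31e-18
arms at q<0.1: ['chr2p', 'chr4p', 'chr13q', 'chr16p', 'chr16q', 'chr17p', 'chr17q', 'chr20q']
all-features c-index: A=0.663, B=0.555, one-sided p(A>B)=0.000
cohort-A ablation: c-index 0.663 -> 0.575 without P2 (one-sided p=1.11e-04)
```

Reading this: cohort A carries the higher mutation burden and the
frequent chr16 deletion; intra-tumor heterogeneity is similar across
cohorts; the planted deletion plus background instability drives a large
arm-SCNA contrast with the chr16 arms leading the per-arm comparison; and
survival models predict much better in cohort A, an advantage that
collapses toward the cohort-B level once the A-specific P2 subtype's
patients are removed.  `analysis/03`, `05` and `06` cover signature
groups (group × cohort χ² p = 4.6e-18), the TP53 frequency difference
(q = 9e-4) with the AXIN1×chr16-deletion co-occurrence inside cohort A
(OR 2.7, p = 0.02), and subtype transfer (3 cross-cohort matches plus one
A-specific subtype at design ranks 4/3, label recovery ARI = 1.0).

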