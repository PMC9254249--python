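# Methods

`hccpipe` re-implements, as a tested library plus a set of analysis
drivers, the computational core of a multi-layer two-cohort comparison of
hepatocellular carcinoma (HCC) genomes: cancer-cell-fraction (CCF)
inference with mutation timing, intra-tumor heterogeneity (ITH) metrics,
mutational-signature deconvolution and grouping, copy-number instability
scoring, cohort association statistics, consensus-NMF transcriptomic
subtyping with cross-cohort transfer, and an integrative
random-survival-forest harness.  Because the original cohorts are
controlled-access, every stage is exercised on synthetic two-cohort data
with planted ground truth; this note records the models, the defaults and
why, and what the synthetic design does and does not establish.

## CCF inference and timing

For each somatic SNV the expected variant allele fraction is

    VAF = purity * CCF / (CN_normal * (1 - purity) + purity * CN_mutation)

with `CN_normal` = 2 on autosomes (1 on male chrX) and `CN_mutation`
interpreted as the local total tumor copy number with mutation
multiplicity fixed at 1; a multiplicity diagnostic
`m = clamp(round(vaf/purity * (purity*CN_t + (1-purity)*CN_n)), 1, CN_t)`
is reported to flag amplified mutations but never enters the fit.  The
CCF estimate minimizes the binomial deviance `-2 log Binom(alt | depth,
VAF(ccf))` on [0, 1].  Because VAF is strictly increasing in CCF, the
minimizer is the clamped inverse of the observed VAF; the scalar API uses
a bounded Brent search cross-checked against both this closed form and an
exhaustive 1e-3 grid, while the vectorized table path uses the closed
form directly.  Mutations need depth >= 10, alt reads >= 3 and VAF >=
0.05 to enter; CCF >= 0.8 is early (clonal), below is late, with ties at
exactly 0.8 early.

At exome depth (~100x) the per-mutation MLE has an intrinsic error floor:
for a clonal diploid mutation `sd(ccf) = 2*sqrt(v(1-v)/depth)/purity`,
about 0.14 at purity 0.65, halved by the [0, 1] clamp.  Pooled over the
default cohort (purity uniform on 0.4-0.9) the RMSE against planted clone
CCFs is ~0.105-0.11; deeper sequencing or purer tumors, not a different
optimizer, is what reduces it.  The purity range emulates a post-QC WES
cohort: clonality pipelines conventionally exclude tumors below ~0.4
purity, where per-mutation CCFs are close to unidentifiable.

## Subclones and ITH

Subclones are recovered by a 1-D Gaussian mixture on CCFs, EM-fitted for
k = 1..5 with BIC selection.  Two regularizations deal with the clamp at
CCF = 1: component variance is floored at the measurement-noise scale
(`reg_covar` 2.5e-3, sd ~0.05, the binomial CCF noise at 100-200x), and
clusters whose means sit closer than 0.1 CCF are merged — subclones that
close are not resolvable at exome depth.  Clusters with fewer than 2
mutations merge into their nearest neighbor.  Per sample we report pLM
(fraction of mutations with CCF < 0.8), the MATH score
`100 * 1.4826 * MAD(VAF) / median(VAF)`, and the Shannon index over
subclone occupancies.  Shannon uses mutation-count fractions by default;
a variant over normalized cluster mean CCFs is exposed
(`shannon_on_mean_ccf`) because both definitions circulate in the field
even though mean CCFs are not a probability vector.

## Mutational signatures

Profiles are SBS-96 counts in the canonical substitution-major context
order.  The bundled catalog holds 10 synthetic, mutually distinct rows
labelled with the liver-cancer signature names (SBS1, SBS4, SBS5, SBS6,
SBS12, SBS16, SBS18, SBS22, SBS24, SBS29); it is a synthetic stand-in,
not redistributed COSMIC data, and real COSMIC TSVs load through
`SignatureCatalog.from_tsv`.  Exposures minimize
`||normalize(profile) - w'S||^2` subject to `w >= 0, sum(w) <= 1` (NNLS,
polished on the simplex face when the relaxed optimum is infeasible);
weights under 6% are zeroed and the rest rescaled, following the
established deconvolution convention.  The forward-selection heuristic of
the reference R tool is deliberately not reproduced — the objective is
identical and the solver is verified against an independent
NNLS-then-project oracle.  Signatures are retained cohort-wide when mean
exposure > 2% or any sample reaches 20%, with one refit.  Patients are
grouped by Ward clustering of exposure vectors (default k = 5).  Signature
timing deconvolutes early and late mutations separately (samples need >=
20 mutations on each side — the source procedure states no minimum; 20
bounds the variance of either fit) and compares exposures per signature
with a two-sided paired Wilcoxon signed-rank test under BH correction.
Profiles are used as raw 96-proportions; exome/genome trinucleotide
renormalization is left as an input-preparation step.

## Copy-number instability

The genome instability index is the fraction of covered bases whose
integer copy number differs from the bp-length-weighted median ploidy
(ties broken toward 2), so whole-genome doubling scores 0.  Arm calls
compare each arm against the rounded median ploidy: `amp`/`del` requires
the deviating state to cover >= 50% of the arm.  The arm SCNA score is
the count of altered arms (amp/del split reported); a magnitude-weighted
variant (sum of |deviation| over altered arms) is optional but not the
default, since only the count-scale comparisons are needed downstream.
Cohort arm frequencies are compared per arm with two-sided Fisher exact
tests under BH (q < 0.1), and arm-level dosage is correlated with every
gene's expression (Spearman, BH) for the cis/trans map.  Coordinates are
1-based inclusive (SEG); BED converters are provided.

## Association statistics

The cohort filters drop samples with more than 1000 coding mutations and
genes mutated in under 1% of retained samples.  Mutual exclusivity /
co-occurrence uses a single two-sided Fisher exact test per pair with the
direction read off the odds ratio — the two tails of the same test —
rather than two one-sided tests, matching standard oncoprint practice and
keeping the FDR accounting simple.  Zero cells report the odds ratio
symbolically as 0 or infinity; p-values are exact regardless.  TMB
(coding mutations per sample) is compared across cohorts by rank-sum and
by OLS on log10(TMB+1) with a cohort indicator plus configurable
covariates (viral status, sex, age, purity by default); the model's
condition number is reported to flag collinearity.

## Transcriptomic subtyping

Genes pass a low-count filter (>= 5 counts in >= 10 patients, when raw
counts are supplied) and the top 3000 by median absolute deviation enter
NMF (desk-scale runs use proportionally smaller cuts).  NMF uses
KL-divergence multiplicative updates (Brunet) — implemented here so the
per-iteration objective trace can be asserted monotone — with consensus
over many random initializations (200 by convention; 20 in the fast
profile), samples co-clustered by dominant metagene.  The rank is chosen
as the largest k whose consensus cophenetic correlation and mean
silhouette both lie within 0.02 of their maxima; the two criteria can
disagree and this tie rule makes the choice reproducible.  On the
synthetic cohorts the basal proliferation/metabolism axis is perfectly
clean, so both statistics peak at k = 2 and the rule conservatively stops
there; the rule is therefore validated on a flat 3-block design, and the
cross-cohort topology analysis fits each cohort at its design rank (4 for
A, 3 for B).  Templates are the top-100 genes by one-vs-rest Cohen's d
(positive d only).

Nearest-template prediction standardizes each gene across the queried
samples and scores `1 - Pearson r` between a sample's standardized values
over the template-gene union and each template's 0/1 indicator;
significance comes from seeded gene-label permutations (default 1000),
BH-adjusted across samples, with q >= 0.1 falling back to "NS".  Because
standardization is across the query cohort, NTP needs a heterogeneous
query set — classifying a handful of near-identical samples alone is
ill-posed.  Cross-cohort subtype correspondence replaces the external
SubMap tool with mutual NTP: score(i, j) is the geometric mean of the two
cross-assignment rates, matched one-to-one by maximum-weight assignment
with a 0.25 match threshold.  Pathway-style activity is a rank-free mean
z-score over member genes (>= 3 present), sufficient for the orderings
used here; a GSVA-style rank variant is a documented extension point.

## Survival harness

The feature table holds clinical (age, sex, stage, grade, HBV, HCV,
cohort), molecular (purity, ploidy, log-TMB, SCNA, GII, gene-set scores,
subtype indicators, signature exposures with cohort mean >= 5%, CNV
events altered in >= 40% of either cohort), driver (genes with >= 15
mutated patients) and ITH (pLM, MATH, Shannon) blocks — the 7/22/12/3
category layout at full scale.  Features missing in > 20% of patients are
dropped, the rest median-imputed; constant columns are removed.

The learner contract is fit / predict-risk / permutation-VIMP; the
default backend is a random survival forest (the tuned configuration —
node size 10, 3 candidate features per split, 1500 trees — is the
full-scale default, with smaller forests for the fast profile), and a
penalized Cox model is the fallback.  Feature selection runs 50 seeded
75% subsamples; in each run five shadow features (permuted copies of real
columns) are injected and a feature is selected when its VIMP exceeds the
best shadow — a concrete criterion with a controllable null rate, since
the source procedure does not print its per-run rule.  Features selected
in >= 25 runs pass; per-cohort lists are unioned.  Evaluation uses 50
seeded 75/25 splits with Harrell's c-index (ties in risk score 0.5) on
the test side, the same split sequence across feature categories so
distributions are paired; cohort A is the reference in cross-cohort
rank tests.  Importance is the mean VIMP rank over repeated full-model
fits.  The univariate Cox network fits one standardized-covariate Cox
model per feature (hazard ratio, p) and connects feature pairs whose
correlation (Spearman, phi, or point-biserial as types dictate) has
p < 0.05, with edge width -log10(p).

## The synthetic cohorts

`simulate_cohorts` generates an Asian-like cohort A and European-like
cohort B on a miniature genome of 22 named arms (~3 Mb, names borrowed
from real chromosomes so the planted deletion is "chr16"):

* **Mutations.**  Coding-scale burden Poisson(120) per B sample, scaled
  1.5x in A; 1-4 subclones with one clone pinned at CCF 1 and the rest
  uniform on 0.15-0.7; per-mutation contexts drawn from the sample's true
  signature mixture (cohort-specific archetypes: aristolochic-acid and
  liver groups enriched in A, clock/smoking in B); depth negative
  binomial (mean 100, size 50); alt reads binomial at the VAF implied by
  purity, local CN and clone CCF with multiplicity 1.
* **Copy number.**  Per-arm integer CN; background alteration probability
  0.12 (A) vs 0.06 (B); the chr16 arms are deleted with probability 0.4
  (A) vs 0.1 (B), in A conditionally concentrated in P2 samples
  (P(del | P2) = 0.85) so the deletion co-occurs with the subtype while
  keeping the configured margin.
* **Expression.**  1200 genes: eight 60-gene programs plus housekeeping
  background (noise sd 0.6 vs 1.0 for program genes — program genes carry
  the biological variance, which is what MAD selection keys on).  Each
  subtype adds one unique +2.5 sd marker program over a +-1.5 sd basal
  proliferation/metabolism axis (P1 = EMT/inflammation, P2 = MYC/UPR,
  M1 = immune, M2 = Wnt; cohort B's P subtype mirrors P1), following the
  field's subtype phenotypes.  An MDSC program tracks a latent myeloid
  score elevated by 2 sd in P2; a trans program drops 1.5 sd under the
  chr16 deletion; every gene gains 0.5 x (local CN - 2) cis dosage.
* **Survival.**  Exponential proportional hazards on
  eta = 0.9*[P2] + 0.35*MDSC + 0.7*[DOCK2] + 0.08*(altered arms), baseline
  median 30 months, with uniform censoring on [0, 3/lambda0] giving ~30%
  censoring.  Clinical covariates (age, sex, viral status) follow the
  reported cohort contrasts (A: younger, more male, 60% HBV).

All randomness flows from one seeded generator; a null configuration
(`SimulationConfig.null()`) equalizes every generating rate across
cohorts for calibration runs.

**What the synthetic design does not show.**  Real cohorts have
correlated purity/ploidy error, subclonal copy number, signature
flat-field ambiguity (the synthetic catalog rows are far better separated
than real COSMIC signatures), batch effects in expression, and
non-proportional hazards; passing these tests demonstrates that the
implementations recover what they are defined to recover, not that the
biological conclusions transfer.  Rare-subtype marker programs sit below
MAD's radar by construction when the subtype is small — a real property
of MAD selection worth remembering when interpreting top-k gene lists.

## Benchmark problem sizes

The recovery benchmarks (also run by `scripts/acceptance.py`) use: 50
samples for CCF recovery; 20 replicates for subclone-number recovery; 200
null cohorts of 60 samples (100 early + 100 late mutations each) for
timing-test calibration and 30 replicates for its power; 100 replicates of
n = 150/cohort for arm-frequency power; every 2x2 table with <= 30
observations for the Fisher oracle; 200 null matrices for the pairwise
false-positive rate; 60-sample designs with 20 NMF runs/rank for
subtyping; and 150 patients, 100-tree forests, 50 selection runs and 50
evaluation splits for the survival harness (noise calibration averages
over 5 independent datasets x 10 splits, since a single finite dataset's
chance correlations shift its own split distribution coherently).  These sizes are the
package's benchmark defaults, chosen to make the distributional claims
stable at desk scale.
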