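"""End-to-end orchestration: from a cohort bundle to the survival feature table.

Runs the per-layer estimators in order — mutation filtering, CCF/timing,
subclone clustering and ITH, signature deconvolution with retention and
grouping, copy-number instability scoring, driver event matrices, gene-set
scores — and assembles the per-patient feature table (clinical /
molecular / driver / ITH) that feeds the survival harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from . import cnv as cnv_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from . import subtyping as sub_mod
from . import survival as surv_mod
from .simulate import CohortBundle


@dataclass
class PipelineResult:
    ccf: pd.DataFrame  # per-mutation, aligned with the filtered MAF
    filtered_maf: pd.DataFrame
    ith: pd.DataFrame  # per-sample plm/math/shannon/n_clusters
    exposures: pd.DataFrame  # per-sample signature weights (post retention)
    signature_groups: pd.Series
    instability: pd.DataFrame  # per-sample gii/arm_scna_score
    arm_call_matrix: pd.DataFrame
    driver_events: pd.DataFrame
    gene_set_scores: pd.DataFrame = field(default_factory=pd.DataFrame)
    feature_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    feature_categories: pd.Series = field(default_factory=pd.Series)


def run_layers(
    bundle: CohortBundle,
    catalog: sig_mod.SignatureCatalog | None = None,
    seed: int = 0,
    signature_k: int = 5,
) -> PipelineResult:
    """Run every per-layer estimator on a simulated (or loaded) bundle."""
    catalog = catalog or sig_mod.synthetic_catalog()
    maf = ccf_mod.filter_mutations(bundle.maf)

    purity = bundle.purity.set_index("sample_id")
    est_parts = []
    for sid, sub in maf.groupby("sample_id"):
        prof = ccf_mod.SampleProfile(
            sid, float(purity.loc[sid, "purity"]), float(purity.loc[sid, "ploidy"]),
            str(purity.loc[sid, "sex"]),
        )
        seg = bundle.segments[bundle.segments["sample_id"] == sid]
        est_parts.append(ccf_mod.estimate_ccf_table(sub, prof, seg))
    estimates = pd.concat(est_parts).loc[maf.index]

    ith = ccf_mod.sample_ith_table(maf, estimates, seed=seed)

    counts = sig_mod.count_contexts(maf)
    _, exposures = sig_mod.iterative_retention(counts, catalog)
    k = min(signature_k, exposures.shape[0])
    groups = sig_mod.signature_groups(exposures, k=k)

    instability, calls = cnv_mod.instability_table(bundle.segments)

    _, events = stats_mod.apply_cohort_filters(maf, bundle.clinical)

    scores = {}
    progs = getattr(bundle.truth, "program_genes", None)
    if progs:
        for name in ("MDSC", "IMMUNE", "PROLIF"):
            if name in progs:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores[f"{name.lower()}_score"] = sub_mod.gene_set_score(
                        bundle.expression, progs[name], name.lower()
                    )
    gss = pd.DataFrame(scores)

    return PipelineResult(
        ccf=estimates, filtered_maf=maf, ith=ith, exposures=exposures,
        signature_groups=groups, instability=instability,
        arm_call_matrix=calls, driver_events=events, gene_set_scores=gss,
    )


def assemble_features(
    bundle: CohortBundle,
    layers: PipelineResult,
    subtype_labels: pd.Series | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the survival feature table from the layer outputs.

    ``subtype_labels`` (e.g. from consensus NMF or the planted truth) are
    expanded to per-subtype indicators; the molecular block further holds
    purity, ploidy, TMB, SCNA burden, GII, gene-set scores, retained
    signature exposures and frequent CNV events.
    """
    clinical = bundle.clinical
    idx = clinical["sample_id"]
    purity = bundle.purity.set_index("sample_id").reindex(idx)

    coding = bundle.maf[bundle.maf["coding"].astype(int) == 1]
    tmb = coding.groupby("sample_id").size().reindex(idx, fill_value=0).astype(float)

    mol = pd.DataFrame(index=idx)
    mol["purity"] = purity["purity"].to_numpy()
    mol["ploidy"] = purity["ploidy"].to_numpy()
    mol["tmb"] = np.log10(tmb + 1.0)
    inst = layers.instability.reindex(idx)
    mol["scna"] = inst["arm_scna_score"].to_numpy()
    mol["gii"] = inst["gii"].to_numpy()
    if not layers.gene_set_scores.empty:
        mol = pd.concat([mol, layers.gene_set_scores.reindex(idx)], axis=1)
    if subtype_labels is not None:
        labs = subtype_labels.reindex(idx)
        for lab in sorted(labs.dropna().unique()):
            mol[f"subtype_{lab}"] = (labs == lab).astype(float)

    cnv_events = (layers.arm_call_matrix != "neutral").astype(int)
    cohort = clinical.set_index("sample_id")["cohort"]
    return surv_mod.build_feature_table(
        clinical,
        molecular=mol,
        driver_events=layers.driver_events,
        ith=layers.ith[["plm", "math", "shannon"]],
        signature_exposures=layers.exposures,
        cnv_events=cnv_events,
        cohort=cohort,
        **kwargs,
    )
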