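"""Synthetic two-cohort generator with planted ground truth.

Emulates the multi-layer contrasts seen between an Asian-like cohort "A"
and a European-like cohort "B" in liver cancer: higher mutation burden in
A, a more frequent planted chr16 deletion in A that co-occurs with a
"P2"-like transcriptomic subtype unique to A, cohort-specific mutational
signature compositions, and a survival signal tied to the planted subtype,
an MDSC-like expression program, one driver gene and copy-number burden.

Every layer is generated from an explicit model on a desk-scale miniature
genome (22 named arms, ~3 Mb), so each downstream estimator can be scored
against the planted truth:

* per sample: purity, 1-4 subclones with one clonal cluster pinned at
  CCF = 1, per-clone mutation counts from a Poisson TMB model;
* per mutation: trinucleotide context drawn from the sample's true
  signature mixture, alt reads Binomial(depth, VAF) with the VAF implied
  by purity, local integer copy number and the clone CCF (multiplicity 1),
  depth negative-binomial around ``depth_mean``;
* copy segments tiling the miniature genome with cohort-specific arm
  alteration probabilities;
* a block-structured expression matrix (proliferation / metabolism /
  inflammation-EMT / MYC-UPR / MDSC programs plus cis dosage and a trans
  program tied to the planted deletion) with Gaussian noise;
* exponential proportional-hazards survival with uniform censoring tuned
  for roughly 30% censored observations.

All randomness flows from a single seeded generator held in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .ccf import expected_vaf
from .cnv import default_arm_table
from .signatures import CONTEXTS_96, SignatureCatalog, synthetic_catalog

SUBTYPES_A = ["P1", "P2", "M1", "M2"]
SUBTYPES_B = ["P", "M1", "M2"]
DELETION_ARMS = ("chr16p", "chr16q")  # the planted "chr16-like" deletion

DRIVER_GENES = [
    "TP53", "CTNNB1", "AXIN1", "ARID1A", "ARID2", "RB1",
    "DOCK2", "ALB", "CDKN2A", "KEAP1", "TSC2", "NFE2L2",
]
# baseline per-cohort driver mutation frequencies; TP53 is the planted
# cohort-differential driver, AXIN1 is additionally enriched in subtype P2
DRIVER_FREQ_A = {
    "TP53": 0.40, "CTNNB1": 0.25, "AXIN1": 0.15, "ARID1A": 0.15,
    "ARID2": 0.08, "RB1": 0.08, "DOCK2": 0.20, "ALB": 0.12,
    "CDKN2A": 0.08, "KEAP1": 0.06, "TSC2": 0.05, "NFE2L2": 0.03,
}
DRIVER_FREQ_B = {**DRIVER_FREQ_A, "TP53": 0.15}
AXIN1_P2_FREQ = 0.60

# per-sample exposure archetypes over the bundled 10-signature catalog
ARCHETYPES = {
    "clock": {"SBS5": 0.60, "SBS1": 0.25, "SBS18": 0.15},
    "smoking": {"SBS4": 0.45, "SBS5": 0.35, "SBS1": 0.20},
    "aa": {"SBS22": 0.55, "SBS5": 0.30, "SBS1": 0.15},
    "liver": {"SBS12": 0.35, "SBS16": 0.35, "SBS5": 0.30},
    "msi": {"SBS6": 0.50, "SBS5": 0.30, "SBS1": 0.20},
}
ARCHETYPE_PROBS_A = {"clock": 0.20, "smoking": 0.10, "aa": 0.30, "liver": 0.30, "msi": 0.10}
ARCHETYPE_PROBS_B = {"clock": 0.55, "smoking": 0.25, "aa": 0.05, "liver": 0.10, "msi": 0.05}

# Expression program blocks.  Each subtype carries the basal axis
# (proliferation vs metabolism) plus one unique marker program, mirroring
# the field's subtype phenotypes: EMT/inflammation (P1), MYC/UPR stress
# (P2), immune infiltration (M1), Wnt/CTNNB1 targets (M2).  MDSC tracks a
# latent myeloid score elevated in P2 and TRANS is the trans-effect target
# of the planted chr16 deletion.
EXPRESSION_PROGRAMS = ["PROLIF", "METAB", "EMT", "MYCUPR", "IMMUNE", "WNT", "MDSC", "TRANS"]
# program activation (units of the program-gene noise SD) per subtype
SUBTYPE_PROGRAMS = {
    "P1": {"PROLIF": 1.5, "EMT": 2.5, "METAB": -1.0},
    "P2": {"PROLIF": 1.5, "MYCUPR": 2.5, "METAB": -1.0},
    "P": {"PROLIF": 1.5, "EMT": 2.0, "METAB": -1.0},
    "M1": {"METAB": 1.5, "IMMUNE": 2.5},
    "M2": {"METAB": 1.5, "WNT": 2.5},
}


@dataclass
class SimulationConfig:
    """Study conditions for the two synthetic cohorts."""

    n_a: int = 150
    n_b: int = 150
    seed: int = 0
    depth_mean: float = 100.0
    depth_dispersion: float = 50.0  # NB size parameter; larger = closer to Poisson
    purity_range: tuple[float, float] = (0.4, 0.9)
    tmb_mean: float = 120.0  # expected mutations per cohort-B sample
    tmb_shift: float = 1.5  # multiplicative burden factor for cohort A
    arm_del_freq_a: float = 0.4
    arm_del_freq_b: float = 0.1
    background_alt_prob_a: float = 0.12  # per-arm amp/del probability off the planted arm
    background_alt_prob_b: float = 0.06
    subtype_props_a: tuple[float, ...] = (0.30, 0.20, 0.25, 0.25)
    subtype_props_b: tuple[float, ...] = (0.40, 0.30, 0.30)
    n_genes: int = 1200
    program_size: int = 60  # genes per planted expression program
    background_noise_sd: float = 0.6  # housekeeping-like genes vary less than programs
    coding_fraction: float = 0.8
    exposure_concentration: float = 60.0
    archetype_probs_a: dict = field(default_factory=lambda: dict(ARCHETYPE_PROBS_A))
    archetype_probs_b: dict = field(default_factory=lambda: dict(ARCHETYPE_PROBS_B))
    driver_freq_a: dict = field(default_factory=lambda: dict(DRIVER_FREQ_A))
    driver_freq_b: dict = field(default_factory=lambda: dict(DRIVER_FREQ_B))
    hazard_coefs: dict = field(
        default_factory=lambda: {"subtype_P2": 0.9, "mdsc": 0.35, "driver_DOCK2": 0.7, "scna": 0.08}
    )
    baseline_hazard: float = np.log(2) / 30.0  # per month; median ~30 months at eta = 0

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("cohort sizes must be nonnegative")
        for props, n in ((self.subtype_props_a, 4), (self.subtype_props_b, 3)):
            if len(props) != n:
                raise ValueError(f"expected {n} subtype proportions, got {len(props)}")
            if not np.isclose(sum(props), 1.0):
                raise ValueError("subtype proportions must sum to 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity bounds must satisfy 0 < lo <= hi <= 1")
        for f in (self.arm_del_freq_a, self.arm_del_freq_b,
                  self.background_alt_prob_a, self.background_alt_prob_b):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @classmethod
    def null(cls, **kwargs) -> "SimulationConfig":
        """A no-difference configuration: both cohorts share every
        generating rate (calibration runs)."""
        base = cls(**kwargs)
        base.tmb_shift = 1.0
        base.arm_del_freq_b = base.arm_del_freq_a
        base.background_alt_prob_b = base.background_alt_prob_a
        base.archetype_probs_b = dict(base.archetype_probs_a)
        base.driver_freq_b = dict(base.driver_freq_a)
        return base


@dataclass
class GroundTruth:
    """Planted per-sample, per-clone and per-mutation truth."""

    samples: pd.DataFrame  # purity, subtype, n_clones, mdsc latent, eta, ...
    clones: pd.DataFrame  # sample_id, clone, ccf, n_mutations
    exposures: pd.DataFrame  # samples x signatures
    arm_calls: pd.DataFrame  # samples x arms in {amp, del, neutral}
    mutations: pd.DataFrame  # aligned with the MAF: true clone, true ccf
    program_genes: dict  # program name -> gene list

    def to_json(self, path) -> None:
        payload = {
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "clones": self.clones.to_dict(orient="list"),
            "exposures": {
                "index": list(self.exposures.index),
                "columns": list(self.exposures.columns),
                "values": self.exposures.to_numpy().tolist(),
            },
            "arm_calls": {
                "index": list(self.arm_calls.index),
                "columns": list(self.arm_calls.columns),
                "values": self.arm_calls.to_numpy().tolist(),
            },
            "mutations": self.mutations.to_dict(orient="list"),
            "program_genes": self.program_genes,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        samples = pd.DataFrame(d["samples"]).set_index("sample_id")
        exps = pd.DataFrame(
            d["exposures"]["values"], index=d["exposures"]["index"],
            columns=d["exposures"]["columns"],
        )
        arms = pd.DataFrame(
            d["arm_calls"]["values"], index=d["arm_calls"]["index"],
            columns=d["arm_calls"]["columns"],
        )
        return cls(samples, pd.DataFrame(d["clones"]), exps, arms,
                   pd.DataFrame(d["mutations"]), d["program_genes"])


@dataclass
class CohortBundle:
    maf: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    purity: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _exposure_for(rng, probs: dict, names: list[str], conc: float) -> np.ndarray:
    arch = list(ARCHETYPES)
    p = np.array([probs[a] for a in arch], dtype=float)
    choice = arch[rng.choice(len(arch), p=p / p.sum())]
    base = np.array([ARCHETYPES[choice].get(n, 0.0) for n in names])
    base = base + 0.01  # keep the Dirichlet proper
    w = rng.dirichlet(base / base.sum() * conc)
    return w


def _program_gene_map(n_genes: int, size: int) -> dict:
    genes = {}
    start = 0
    for prog in EXPRESSION_PROGRAMS:
        genes[prog] = [f"{prog}_{i:03d}" for i in range(size)]
        start += size
    n_bg = n_genes - start
    if n_bg < 0:
        raise ValueError("n_genes too small for the planted programs")
    genes["BACKGROUND"] = [f"BG_{i:04d}" for i in range(n_bg)]
    return genes


def simulate_cohorts(config: SimulationConfig, catalog: SignatureCatalog | None = None) -> CohortBundle:
    """Generate the full two-cohort bundle with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    catalog = catalog or synthetic_catalog()
    arms = default_arm_table()
    arm_names = list(arms["arm"])
    arm_len = (arms["end"] - arms["start"] + 1).to_numpy(float)
    arm_p = arm_len / arm_len.sum()

    program_genes = _program_gene_map(config.n_genes, config.program_size)
    all_genes = [g for gl in program_genes.values() for g in gl]
    gene_program = np.array([g.split("_")[0] for g in all_genes])
    gene_is_program = gene_program != "BG"
    # genes assigned to arms round-robin; one-hot genes x arms for cis dosage
    gene_arm_idx = np.arange(len(all_genes)) % len(arm_names)
    gene_arm_cn_index = np.zeros((len(all_genes), len(arm_names)))
    gene_arm_cn_index[np.arange(len(all_genes)), gene_arm_idx] = 1.0

    maf_rows, seg_rows, clone_rows, mut_truth = [], [], [], []
    sample_rows, exp_rows, armcall_rows = [], {}, {}
    expr_cols = {}

    specs = [("A", config.n_a), ("B", config.n_b)]
    for cohort, n in specs:
        if cohort == "A":
            subtype_names, props = SUBTYPES_A, config.subtype_props_a
            del_freq, bg_alt = config.arm_del_freq_a, config.background_alt_prob_a
            arch_probs, driver_freq = config.archetype_probs_a, config.driver_freq_a
            tmb = config.tmb_mean * config.tmb_shift
        else:
            subtype_names, props = SUBTYPES_B, config.subtype_props_b
            del_freq, bg_alt = config.arm_del_freq_b, config.background_alt_prob_b
            arch_probs, driver_freq = config.archetype_probs_b, config.driver_freq_b
            tmb = config.tmb_mean

        # deletion-arm probability conditional on subtype so that the planted
        # deletion co-occurs with P2 in cohort A at the configured margin
        if cohort == "A" and del_freq > 0:
            w_p2 = props[subtype_names.index("P2")]
            p_del_p2 = min(1.0, del_freq + 0.45)
            p_del_rest = max(0.0, (del_freq - w_p2 * p_del_p2) / max(1 - w_p2, 1e-9))
        else:
            p_del_p2 = p_del_rest = del_freq

        for i in range(n):
            sid = f"{cohort}{i:03d}"
            purity = float(rng.uniform(*config.purity_range))
            subtype = subtype_names[rng.choice(len(props), p=np.asarray(props))]
            sex = "male" if rng.random() < (0.79 if cohort == "A" else 0.56) else "female"
            age = float(rng.normal(55 if cohort == "A" else 66, 10))
            viral = rng.choice(
                ["HBV", "HCV", "none"],
                p=[0.6, 0.1, 0.3] if cohort == "A" else [0.25, 0.15, 0.6],
            )
            stage = rng.choice(["I", "II", "III", "IV"], p=[0.35, 0.3, 0.25, 0.1])
            grade = rng.choice(["G1", "G2", "G3", "G4"], p=[0.15, 0.45, 0.3, 0.1])

            # --- copy number over the miniature genome ---
            deleted = rng.random() < (p_del_p2 if subtype == "P2" else p_del_rest)
            calls = {}
            arm_cn = {}
            for a_i, arm in arms.iterrows():
                name = arm["arm"]
                if name in DELETION_ARMS:
                    cn = 1 if deleted else 2
                elif rng.random() < bg_alt:
                    cn = 3 if rng.random() < 0.5 else 1
                else:
                    cn = 2
                arm_cn[name] = cn
                calls[name] = "neutral" if cn == 2 else ("amp" if cn > 2 else "del")
                seg_rows.append({
                    "sample_id": sid, "chrom": arm["chrom"],
                    "start": int(arm["start"]), "end": int(arm["end"]),
                    "integer_cn": cn,
                })
            armcall_rows[sid] = calls
            n_altered = sum(1 for v in calls.values() if v != "neutral")

            # --- clones ---
            n_clones = int(rng.integers(1, 5))
            ccfs = np.concatenate([[1.0], np.sort(rng.uniform(0.15, 0.7, n_clones - 1))[::-1]])
            weights = rng.dirichlet(np.full(n_clones, 2.0))
            n_mut = int(rng.poisson(tmb))

            # --- exposures ---
            w = _exposure_for(rng, arch_probs, catalog.names, config.exposure_concentration)
            exp_rows[sid] = pd.Series(w, index=catalog.names)
            p_ctx = w @ catalog.matrix
            p_ctx = p_ctx / p_ctx.sum()

            # --- mutations ---
            clone_of = rng.choice(n_clones, size=n_mut, p=weights)
            arm_of = rng.choice(len(arm_names), size=n_mut, p=arm_p)
            ctx_of = rng.choice(96, size=n_mut, p=p_ctx)
            depth = rng.negative_binomial(
                config.depth_dispersion,
                config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
                size=n_mut,
            )
            depth = np.maximum(depth, 1)
            clone_counts = np.bincount(clone_of, minlength=n_clones)
            for c in range(n_clones):
                clone_rows.append({"sample_id": sid, "clone": c, "ccf": float(ccfs[c]),
                                   "n_mutations": int(clone_counts[c])})

            # planted driver mutations (clonal with prob 0.8)
            driver_hits = []
            for gene in DRIVER_GENES:
                f = driver_freq.get(gene, 0.0)
                if gene == "AXIN1" and subtype == "P2":
                    f = AXIN1_P2_FREQ
                if rng.random() < f:
                    driver_hits.append(gene)

            genes_col = ["."] * n_mut
            for gene in driver_hits:
                clone = 0 if rng.random() < 0.8 else int(rng.integers(0, n_clones))
                clone_of = np.append(clone_of, clone)
                arm_of = np.append(arm_of, rng.choice(len(arm_names), p=arm_p))
                ctx_of = np.append(ctx_of, rng.choice(96, p=p_ctx))
                depth = np.append(depth, max(int(rng.negative_binomial(
                    config.depth_dispersion,
                    config.depth_dispersion / (config.depth_dispersion + config.depth_mean))), 1))
                genes_col.append(gene)

            total = len(clone_of)
            pos = np.empty(total, dtype=int)
            cn_local = np.empty(total, dtype=float)
            for j in range(total):
                arm = arms.iloc[arm_of[j]]
                pos[j] = int(rng.integers(arm["start"], arm["end"] + 1))
                cn_local[j] = max(arm_cn[arm["arm"]], 1)
            vaf = expected_vaf(ccfs[clone_of], purity, 2.0, cn_local)
            alt = rng.binomial(depth, vaf)
            coding = (rng.random(total) < config.coding_fraction).astype(int)
            coding[n_mut:] = 1  # drivers are coding by construction
            for j in range(total):
                ctx = CONTEXTS_96[ctx_of[j]]
                maf_rows.append({
                    "sample_id": sid, "chrom": arms.iloc[arm_of[j]]["chrom"],
                    "pos": int(pos[j]), "ref": ctx[2], "alt": ctx[4],
                    "t_depth": int(depth[j]), "t_alt_count": int(alt[j]),
                    "context96": ctx, "coding": int(coding[j]),
                    "gene": genes_col[j],
                })
                mut_truth.append({
                    "sample_id": sid, "clone": int(clone_of[j]),
                    "true_ccf": float(ccfs[clone_of[j]]),
                    "local_cn": int(cn_local[j]),
                })

            # --- expression ---
            mdsc_latent = float(rng.normal(0, 1) + (2.0 if subtype == "P2" else 0.0))
            noise_sd = np.where(gene_is_program, 1.0, config.background_noise_sd)
            x = rng.normal(0.0, 1.0, len(all_genes)) * noise_sd + 6.0
            activ = SUBTYPE_PROGRAMS.get(subtype, {})
            shift = np.zeros(len(all_genes))
            for prog, amount in activ.items():
                shift[gene_program == prog] = amount
            shift[gene_program == "MDSC"] = mdsc_latent
            if deleted:
                shift[gene_program == "TRANS"] = -1.5
            cis = 0.5 * (gene_arm_cn_index @ np.array(
                [arm_cn[a] - 2.0 for a in arm_names]))
            expr_cols[sid] = np.clip(x + shift + cis + 0.0, 0.0, None)

            # --- survival ---
            hc = config.hazard_coefs
            eta = (
                hc.get("subtype_P2", 0.0) * (subtype == "P2")
                + hc.get("mdsc", 0.0) * mdsc_latent
                + hc.get("driver_DOCK2", 0.0) * ("DOCK2" in driver_hits)
                + hc.get("scna", 0.0) * n_altered
            )
            rate = config.baseline_hazard * np.exp(eta)
            t = float(rng.exponential(1.0 / rate))
            t_max = 3.0 / config.baseline_hazard  # ~30% censoring at eta = 0
            c = float(rng.uniform(0, t_max))
            os_time = max(min(t, c), 1e-3)
            os_event = int(t <= c)

            sample_rows.append({
                "sample_id": sid, "cohort": cohort, "purity": purity,
                "subtype": subtype, "n_clones": n_clones,
                "mdsc_latent": mdsc_latent, "eta": float(eta),
                "deleted_arm": bool(deleted), "n_altered_arms": n_altered,
                "drivers": ",".join(driver_hits),
                "age": age, "sex": sex, "viral_status": viral,
                "stage": stage, "grade": grade,
                "os_time": os_time, "os_event": os_event,
            })

    maf = pd.DataFrame(maf_rows, columns=io.MAF_COLUMNS + ["gene"])
    segments = pd.DataFrame(seg_rows, columns=io.SEG_COLUMNS)
    samples = pd.DataFrame(sample_rows).set_index("sample_id") if sample_rows \
        else pd.DataFrame(columns=["cohort"]).rename_axis("sample_id")
    expression = pd.DataFrame(expr_cols, index=all_genes)
    expression.index.name = "gene"
    clinical = samples.reset_index()[io.CLINICAL_COLUMNS] if len(samples) \
        else pd.DataFrame(columns=io.CLINICAL_COLUMNS)
    purity = (
        samples.reset_index()[["sample_id", "purity", "sex"]].assign(ploidy=2.0)
        [io.PURITY_COLUMNS]
        if len(samples) else pd.DataFrame(columns=io.PURITY_COLUMNS)
    )
    truth = GroundTruth(
        samples=samples,
        clones=pd.DataFrame(clone_rows, columns=["sample_id", "clone", "ccf", "n_mutations"]),
        exposures=pd.DataFrame(exp_rows).T if exp_rows else pd.DataFrame(),
        arm_calls=pd.DataFrame(armcall_rows).T if armcall_rows else pd.DataFrame(),
        mutations=pd.DataFrame(mut_truth, columns=["sample_id", "clone", "true_ccf", "local_cn"]),
        program_genes=program_genes,
    )
    return CohortBundle(maf, segments, expression, clinical, purity, truth, config)


def write_fixture(bundle: CohortBundle, out_dir) -> dict:
    """Write the bundle as TSV/SEG/JSON files; returns the path map."""
    out = io.ensure_dir(out_dir)
    paths = {
        "maf": out / "mutations.maf.tsv",
        "seg": out / "segments.seg",
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "purity": out / "purity.tsv",
        "truth": out / "truth.json",
    }
    io.write_maf(bundle.maf, paths["maf"])
    io.write_seg(bundle.segments, paths["seg"])
    io.write_expression(bundle.expression, paths["expression"])
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    bundle.purity.to_csv(paths["purity"], sep="\t", index=False)
    bundle.truth.to_json(paths["truth"])
    return paths


def read_fixture(out_dir) -> dict:
    """Read back a written fixture as a dict of tables."""
    out = Path(out_dir)
    return {
        "maf": io.read_maf(out / "mutations.maf.tsv"),
        "seg": io.read_seg(out / "segments.seg"),
        "expression": io.read_expression(out / "expression.tsv"),
        "clinical": io.read_clinical(out / "clinical.tsv"),
        "purity": io.read_purity(out / "purity.tsv"),
        "truth": GroundTruth.from_json(out / "truth.json"),
    }
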