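"""Synthetic two-population genotype/transcriptome generator with ground truth.

Emulates the study design the pipeline targets: two populations whose allele
frequencies diverge under the Balding-Nichols model, Hardy-Weinberg
genotypes, exon-skipping splice events whose logit-PSI carries a planted
additive cis effect, junction reads sampled binomially from a Poisson total,
log2 expression with planted promoter-eQTL and between-population effects,
blood phenotypes linearly coupled to splicing, and qPCR Ct tables with
planted fold changes.  Every draw is a pure function of (config, seed):
identical seeds give byte-identical outputs, and :class:`SimTruth` records
every generating parameter so downstream estimators can be scored against
the truth.

Gene layout is deterministic: genes of four exons are spaced along one
chromosome; the first ``n_events`` genes carry a second isoform skipping the
third exon, a candidate splice variant in the upstream flanking intron and a
candidate promoter variant 500 bp upstream of the TSS, both guaranteed to
fall inside the cis windows the qtl module constructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io import (
    GenotypeMatrix,
    JunctionCountMatrix,
    SampleTable,
    TranscriptModel,
    ValidationError,
    VariantRecord,
)
from .expression import ExpressionMatrix, tpm_normalize
from .splicing import AsEvent, enumerate_events
from .validation import CtTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_gene_models",
    "simulate_genotypes",
    "simulate_splicing_counts",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_qpcr_cts",
    "simulate_genome",
    "simulate_dataset",
]

CHROM = "1"
GENE_SPACING = 6_000
FIRST_GENE_START = 10_000
POP1 = "highland"
POP2 = "lowland"
REFERENCE_GENE = "HPRT1"

# four-exon gene template, offsets relative to the gene origin
_EXONS = [(0, 199), (700, 849), (1250, 1399), (1900, 2099)]
_SKIPPED_EXON_INDEX = 2


@dataclass
class SimConfig:
    """All tunable generator parameters (defaults are the study conditions).

    Cohort sizes default to the study's extended RNA cohort (67 vs 18);
    ``fst_divergence`` is the Balding-Nichols parameter per population;
    ``beta_psi`` is the additive effect per alt allele on logit(PSI) and
    ``beta_expr`` on log2 expression; ``coverage_mean`` is the mean total
    junction-read count per event and sample; ``pheno_effect`` the
    hemoglobin change (g/dL) per unit PSI.
    """

    n_pop1: int = 67
    n_pop2: int = 18
    n_variants: int = 200
    fst_divergence: float = 0.1
    n_genes: int = 40
    n_events: int = 40
    causal_fraction: float = 0.3
    beta_psi: float = 0.8
    beta_expr: float = 1.0
    coverage_mean: float = 100.0
    pheno_effect: float = 4.0
    psi_noise_sd: float = 0.3
    baseline_psi_min: float = 0.2
    baseline_psi_max: float = 0.8
    psi_pop1_shift_logit: float = 0.0  # population-level differential splicing
    expr_noise_sd: float = 0.5
    pheno_noise_sd: float = 1.5
    ct_noise_sd: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    overdispersion: float = 0.0  # beta-binomial correlation; 0 = plain binomial
    qpcr_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pop1", "n_pop2", "n_variants", "n_genes", "n_events", "qpcr_n"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0 <= self.fst_divergence < 1):
            raise ValidationError("fst_divergence must lie in [0, 1)")
        if self.coverage_mean <= 0:
            raise ValidationError("coverage_mean must be > 0")
        if self.n_events > self.n_genes:
            raise ValidationError("n_events cannot exceed n_genes")
        if self.n_variants < self.n_events + self.n_genes:
            raise ValidationError(
                "n_variants must cover one splice and one promoter candidate "
                f"per gene (need >= {self.n_events + self.n_genes})"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset."""

    variant_ids: list[str] = field(default_factory=list)
    ancestral_af: np.ndarray | None = None
    pop_af: dict[str, np.ndarray] = field(default_factory=dict)
    splice_candidate: dict[str, str] = field(default_factory=dict)  # event -> variant
    promoter_candidate: dict[str, str] = field(default_factory=dict)  # gene -> variant
    causal_sqtl: dict[str, tuple[str, float]] = field(default_factory=dict)
    causal_eqtl: dict[str, tuple[str, float]] = field(default_factory=dict)
    baseline_psi: dict[str, float] = field(default_factory=dict)
    true_psi: pd.DataFrame | None = None
    true_de: dict[str, float] = field(default_factory=dict)
    pheno_coefficients: dict[str, float] = field(default_factory=dict)
    qpcr_folds: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "variant_ids": self.variant_ids,
            "ancestral_af": None if self.ancestral_af is None else self.ancestral_af.tolist(),
            "pop_af": {k: v.tolist() for k, v in self.pop_af.items()},
            "splice_candidate": self.splice_candidate,
            "promoter_candidate": self.promoter_candidate,
            "causal_sqtl": {k: list(v) for k, v in self.causal_sqtl.items()},
            "causal_eqtl": {k: list(v) for k, v in self.causal_eqtl.items()},
            "baseline_psi": self.baseline_psi,
            "true_de": self.true_de,
            "pheno_coefficients": self.pheno_coefficients,
            "qpcr_folds": self.qpcr_folds,
        }


# ---------------------------------------------------------------------------
# gene models and layout
# ---------------------------------------------------------------------------


def _gene_origin(g: int) -> int:
    return FIRST_GENE_START + g * GENE_SPACING


def simulate_gene_models(config: SimConfig) -> list[TranscriptModel]:
    """Deterministic gene models: the first ``n_events`` genes get a second
    isoform skipping the third exon; all transcripts carry a CDS."""
    models = []
    for g in range(config.n_genes):
        o = _gene_origin(g)
        gene_id = f"G{g:04d}"
        exons = [(o + s, o + e) for s, e in _EXONS]
        t1 = TranscriptModel(gene_id, f"{gene_id}.T1", CHROM, "+", exons)
        t1.cds = (51, t1.length - 50)
        t1.__post_init__()
        models.append(t1)
        if g < config.n_events:
            skipped = [x for i, x in enumerate(exons) if i != _SKIPPED_EXON_INDEX]
            models.append(TranscriptModel(gene_id, f"{gene_id}.T2", CHROM, "+", skipped))
    return models


def simulate_events(config: SimConfig) -> list[AsEvent]:
    """The dataset's AS events (one ES event per event gene)."""
    return enumerate_events(simulate_gene_models(config))


def _variant_plan(config: SimConfig, rng: np.random.Generator):
    """Positions and roles of all variants: one splice candidate per event
    gene (inside the skipped exon's upstream flanking intron), one promoter
    candidate per gene (500 bp upstream of the TSS), background elsewhere."""
    planned: list[tuple[int, str, int]] = []  # (pos, role, gene index)
    for g in range(config.n_genes):
        o = _gene_origin(g)
        planned.append((o - 500, "promoter", g))
        if g < config.n_events:
            planned.append((o + 1000, "splice", g))  # inside intron 2
    n_bg = config.n_variants - len(planned)
    region_end = _gene_origin(config.n_genes) + 3000
    taken = {p for p, _, _ in planned}
    candidates = rng.permutation(np.arange(1_000, region_end))
    bg = [int(p) for p in candidates if p not in taken][:n_bg]
    planned.extend((p, "background", -1) for p in sorted(bg))
    planned.sort()
    return planned


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Two-population Hardy-Weinberg genotypes under Balding-Nichols drift.

    Ancestral frequency p ~ Uniform(0.05, 0.95); each population's frequency
    is Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_divergence`` (exactly p
    when F = 0); genotypes are Binomial(2, p_pop) within population.
    """
    rng = np.random.default_rng([config.seed, 1])
    plan = _variant_plan(config, rng)
    n_var = len(plan)
    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    F = config.fst_divergence
    truth = SimTruth()
    pop_freqs = {}
    for pop in (POP1, POP2):
        if F == 0:
            pf = p_anc.copy()
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pf = rng.beta(a, b)
        pop_freqs[pop] = np.clip(pf, 1e-3, 1 - 1e-3)
    samples = [f"A{i + 1:03d}" for i in range(config.n_pop1)] + [
        f"B{i + 1:03d}" for i in range(config.n_pop2)
    ]
    population = {s: POP1 for s in samples[: config.n_pop1]}
    population.update({s: POP2 for s in samples[config.n_pop1 :]})
    dosage = np.vstack(
        [
            rng.binomial(2, pop_freqs[POP1], size=(config.n_pop1, n_var)),
            rng.binomial(2, pop_freqs[POP2], size=(config.n_pop2, n_var)),
        ]
    ).astype(float)
    variants = [
        VariantRecord(CHROM, pos, f"rs{i + 1:06d}", "C", "T")
        for i, (pos, _, _) in enumerate(plan)
    ]
    gm = GenotypeMatrix(variants, samples, dosage, population)
    truth.variant_ids = [v.id for v in variants]
    truth.ancestral_af = p_anc
    truth.pop_af = pop_freqs
    for i, (pos, role, g) in enumerate(plan):
        if role == "promoter":
            truth.promoter_candidate[f"G{g:04d}"] = variants[i].id
        elif role == "splice":
            skip = (_gene_origin(g) + _EXONS[_SKIPPED_EXON_INDEX][0],
                    _gene_origin(g) + _EXONS[_SKIPPED_EXON_INDEX][1])
            event_id = f"G{g:04d}:ES:{CHROM}:{skip[0]}-{skip[1]}"
            truth.splice_candidate[event_id] = variants[i].id
    return gm, truth


# ---------------------------------------------------------------------------
# junction reads
# ---------------------------------------------------------------------------


def simulate_splicing_counts(
    genotypes: GenotypeMatrix,
    events: list[AsEvent],
    truth: SimTruth,
    config: SimConfig,
) -> JunctionCountMatrix:
    """Junction reads per event: per sample, true PSI =
    logistic(baseline_logit + beta_psi * dosage + N(0, psi_noise_sd)); total
    reads T ~ Poisson(coverage_mean); inclusion reads ~ Binomial(T, PSI),
    split evenly (binomially) between the two inclusion junctions; skipping
    reads = T - inclusion.  A ``causal_fraction`` of events receives the
    planted effect at its splice-candidate variant; truth records the causal
    pairs, baselines and the true PSI matrix."""
    rng = np.random.default_rng([config.seed, 2])
    event_ids = sorted(ev.event_id for ev in events)
    n_causal = int(round(config.causal_fraction * len(event_ids)))
    causal = set(rng.choice(event_ids, size=n_causal, replace=False)) if n_causal else set()
    n = genotypes.n_samples
    is_pop1 = genotypes.population_mask(POP1).astype(float)
    meta_rows, count_rows, keys = [], [], []
    psi_rows = {}
    for ev in sorted(events, key=lambda e: e.event_id):
        baseline = float(rng.uniform(config.baseline_psi_min, config.baseline_psi_max))
        truth.baseline_psi[ev.event_id] = baseline
        beta = 0.0
        vid = truth.splice_candidate.get(ev.event_id)
        if ev.event_id in causal and vid is not None:
            beta = config.beta_psi
            truth.causal_sqtl[ev.event_id] = (vid, beta)
        dos = np.nan_to_num(genotypes.dosage_of(vid), nan=0.0) if vid else np.zeros(n)
        eta = (
            logit(baseline)
            + beta * dos
            + config.psi_pop1_shift_logit * is_pop1
            + rng.normal(0, config.psi_noise_sd, size=n)
        )
        psi = expit(eta)
        psi_rows[ev.event_id] = psi
        total = rng.poisson(config.coverage_mean, size=n)
        if config.overdispersion > 0:
            rho = config.overdispersion
            p_draw = rng.beta(psi * (1 - rho) / rho, (1 - psi) * (1 - rho) / rho)
        else:
            p_draw = psi
        # an including transcript exposes two junctions, a skipping one only
        # one, so a junction read is an inclusion read with prob 2p/(1+p);
        # the mean-of-inclusion-junctions PSI estimator is then unbiased
        p_read = 2 * p_draw / (1 + p_draw)
        incl = rng.binomial(total, p_read)
        j1 = rng.binomial(incl, 0.5)
        skip = total - incl
        cmap = ev.coord_map
        s_span, e_span = ev.span
        x = cmap["skipped"]
        rows = [
            ((s_span, x[0] - 1, ""), j1),
            ((x[1] + 1, e_span, ""), incl - j1),
            ((s_span, e_span, ""), skip),
        ]
        for (s, e, tag), counts in rows:
            keys.append(f"{ev.chrom}:{s}-{e}:{ev.strand}" + (f":{tag}" if tag else ""))
            meta_rows.append(
                {"chrom": ev.chrom, "intron_start": s, "intron_end": e, "strand": ev.strand, "tag": tag}
            )
            count_rows.append(counts)
    meta = pd.DataFrame(meta_rows, index=pd.Index(keys, name="key"))
    counts = pd.DataFrame(np.array(count_rows), index=meta.index, columns=genotypes.samples)
    truth.true_psi = pd.DataFrame(psi_rows, index=genotypes.samples).T
    return JunctionCountMatrix(meta, counts)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
) -> ExpressionMatrix:
    """log2 expression = baseline + beta_expr * dosage (causal genes)
    + de_log2fc * 1[population 1] (planted DE genes) + N(0, expr_noise_sd);
    exported as rounded counts and TPM."""
    rng = np.random.default_rng([config.seed, 3])
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    n_causal = int(round(config.causal_fraction * config.n_genes))
    causal = set(rng.choice(genes, size=n_causal, replace=False)) if n_causal else set()
    n_de = int(round(config.de_fraction * config.n_genes))
    de_list = sorted(rng.choice(genes, size=n_de, replace=False)) if n_de else []
    # alternate planted direction so the library totals stay balanced and
    # TPM renormalization does not compress the observed fold changes
    de_sign = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(de_list)}
    is_pop1 = genotypes.population_mask(POP1).astype(float)
    n = genotypes.n_samples
    rows = {}
    for gene in genes:
        baseline = float(rng.uniform(3, 8))
        log2x = baseline + rng.normal(0, config.expr_noise_sd, size=n)
        if gene in causal:
            vid = truth.promoter_candidate[gene]
            dos = np.nan_to_num(genotypes.dosage_of(vid), nan=0.0)
            log2x = log2x + config.beta_expr * dos
            truth.causal_eqtl[gene] = (vid, config.beta_expr)
        if gene in de_sign:
            log2x = log2x + de_sign[gene] * config.de_log2fc * is_pop1
            truth.true_de[gene] = de_sign[gene] * config.de_log2fc
        rows[gene] = np.round(2.0 ** log2x).astype(int)
    counts = pd.DataFrame(rows, index=genotypes.samples).T
    models = {t.gene_id: t for t in simulate_gene_models(config) if t.transcript_id.endswith(".T1")}
    lengths = pd.Series({g: models[g].length for g in genes}, name="length_nt")
    return tpm_normalize(counts, lengths)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

_PHENO = {  # intercept, effect multiplier (x pheno_effect), noise sd
    "hb": (14.0, 1.0, None),  # noise = config.pheno_noise_sd
    "wbc": (6.0, 0.4, 1.2),
    "platelets": (250.0, 12.0, 40.0),
}


def simulate_phenotypes(
    true_psi: pd.DataFrame,
    config: SimConfig,
    populations: dict[str, str] | None = None,
) -> SampleTable:
    """Blood phenotypes linearly coupled to the focal event's true PSI:
    Hb = 14 + pheno_effect * PSI + N(0, pheno_noise_sd) g/dL; WBC and
    platelets analogous with their own coefficients.  The focal event is the
    first row of ``true_psi``; mediation runs through splicing, not directly
    through genotype."""
    rng = np.random.default_rng([config.seed, 4])
    psi = true_psi.iloc[0].to_numpy(dtype=float)
    samples = list(true_psi.columns)
    data = {}
    for name, (intercept, mult, sd) in _PHENO.items():
        sd = config.pheno_noise_sd if sd is None else sd
        data[name] = intercept + mult * config.pheno_effect * psi + rng.normal(0, sd, len(samples))
    df = pd.DataFrame(data, index=pd.Index(samples, name="sample"))
    df["population"] = [populations.get(s, "") if populations else "" for s in samples]
    df["altitude"] = 3650.0
    return SampleTable(df)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr_cts(
    fold_changes: dict[str, dict[str, float]],
    config: SimConfig,
    control_group_label: str = "control",
) -> CtTable:
    """Ct tables with planted fold changes per (gene, group).

    Reference-gene Ct ~ N(20, ct_noise_sd); target Ct = reference Ct + 2
    (the control delta-Ct) - log2(fold) + N(0, ct_noise_sd).  Groups absent
    from a gene's mapping (including the control group) get fold 1.
    """
    rng = np.random.default_rng([config.seed, 5])
    groups = sorted({g for folds in fold_changes.values() for g in folds} | {control_group_label})
    rows = []
    for grp in groups:
        for i in range(config.qpcr_n):
            sample = f"{grp}{i + 1:02d}"
            ref_ct = float(rng.normal(20.0, config.ct_noise_sd))
            rows.append({"sample": sample, "gene": REFERENCE_GENE, "ct": ref_ct, "group": grp})
            for gene in sorted(fold_changes):
                fold = fold_changes[gene].get(grp, 1.0)
                ct = ref_ct + 2.0 - np.log2(fold) + float(rng.normal(0, config.ct_noise_sd))
                rows.append({"sample": sample, "gene": gene, "ct": ct, "group": grp})
    return CtTable(pd.DataFrame(rows), REFERENCE_GENE)


# ---------------------------------------------------------------------------
# genome sequence + full dataset
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> dict[str, str]:
    """Random genome sequence covering the gene layout (for ORF annotation)."""
    rng = np.random.default_rng([config.seed, 6])
    length = _gene_origin(config.n_genes) + 3000
    bases = np.array(list("ACGT"))
    return {CHROM: "".join(bases[rng.integers(0, 4, size=length)])}


@dataclass
class SimDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    truth: SimTruth
    transcripts: list[TranscriptModel]
    events: list[AsEvent]
    junctions: JunctionCountMatrix
    expression: ExpressionMatrix
    samples: SampleTable
    genome: dict[str, str]
    qpcr: CtTable


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full coupled dataset for an end-to-end pipeline run."""
    genotypes, truth = simulate_genotypes(config)
    transcripts = simulate_gene_models(config)
    events = enumerate_events(transcripts)
    junctions = simulate_splicing_counts(genotypes, events, truth, config)
    expression = simulate_expression(genotypes, truth, config)
    samples = simulate_phenotypes(truth.true_psi, config, genotypes.population)
    genome = simulate_genome(config)
    folds = {"NFKB1_AS": {POP1: 2.0}}
    truth.qpcr_folds = folds
    qpcr = simulate_qpcr_cts(folds, config, control_group_label=POP2)
    return SimDataset(
        config, genotypes, truth, transcripts, events, junctions, expression, samples, genome, qpcr
    )
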