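# Methods

`spliceqtl` implements the computational core of an integrative
genome/transcriptome analysis of two diverged human populations: quantify
alternative splicing from junction reads, test expression and splicing for
between-population differences, map cis-acting variants for both molecular
phenotypes, score population allele-frequency differentiation and selection,
annotate the coding consequence of exon skipping, and reproduce the
qPCR/phenotype validation statistics. This note records the models, the
defaults and the choices made where the design was genuinely open.

## Splicing quantification

Alternative-splicing events are enumerated by pairwise comparison of exon
chains within a gene and classified into the five canonical classes (ES,
A5SS, A3SS, IR, MXE). Two details matter:

- Deduplication keys are the event's defining coordinates. For A5SS/A3SS the
  key includes both exon variants, not just the shared intron boundary: two
  isoform pairs can share a boundary yet differ in the alternative exon, and
  collapsing them loses events (this was caught by the brute-force
  property test).
- IR carries no conventional inclusion junction in a junction-only count
  matrix, so IR inclusion evidence enters as two pseudo-junction rows keyed
  by the retained intron with `IR5`/`IR3` tags. This keeps a single input
  format at the cost of requiring upstream tools to export boundary-read
  counts under those keys.

PSI is junction-count-only: I is the arithmetic mean of the event's
inclusion-junction counts, S the mean of the skipping-junction counts, and
PSI = I/(I+S), missing when I+S falls below `min_reads` (default 10; no
published threshold exists, 10 informative reads bounds the binomial SE of
PSI by ~0.16). No effective-length normalization or hierarchical read model
is applied; the differential test is a transparent two-sided rank-sum test
on per-sample PSI (exact for ≤ 8 per group without ties, tie-corrected
normal approximation otherwise) with BH correction. Significance is the
compound rule adj. p < 0.05 AND |ΔPSI| > 0.1, so overwhelming evidence for a
tiny shift is never called.

## Isoform consequence (frame / PTC / NMD)

For an exon-skipping event on a coding transcript, the skipped exon is
removed from the spliced sequence, the reading frame is re-threaded from the
(possibly shifted) CDS start, and the first stop codon is located by codon
scanning. Frame status is `in_frame` iff the removed length (net of any
replacement exon for MXE) is a multiple of 3. NMD is predicted when the
first stop lies strictly more than 55 nt upstream of the final exon–exon
junction of the altered transcript — the standard 55-nt rule; the distance
is measured from the stop codon's last base to the junction, so a stop in
the final exon always escapes. Exons entirely outside the CDS, and event
types other than ES/MXE, yield `non_coding`.

## Expression

TPM: rate_g = count_g / length_kb_g, scaled so each sample sums to 10^6.
Differential expression is a Welch two-sided t-test on log2(TPM+1) with BH
correction — a deliberately transparent substitute for a negative-binomial
model; the package's claims concern pipeline logic and thresholds, not
dispersion modeling. Fold change is computed on group mean TPM with
pseudo-count 1, and the DEG rule is adj. p < 0.05 AND linear |FC| > 1.5
(the threshold is read on the linear scale, in either direction). With zero
variance in both groups, equal means give p = 1 by convention.

BH adjustment is the statsmodels step-up with monotonicity enforcement.
Note that BH is not an idempotent map in general (re-adjusting adjusted
values can change them); tests assert dominance, monotonicity and
permutation-equivariance, plus fixed-point behavior on the worked example.

## cis-QTL mapping

Windows: promoters are strand-aware [TSS − 1500, TSS + 200] (mirrored on
the minus strand, clipped at 1; 1701 bp unless clipped), one per transcript,
unioned per gene. Splice windows cover the AS exon(s) plus flanking introns:
ES/MXE use the span from the upstream flanking-intron start to the
downstream flanking-intron end; A5SS/A3SS the union of both exon variants
and the variable intron; IR the retained intron itself (it is simultaneously
the alternative region and its own flank).

Each (variant, feature) pair is fit by OLS of the phenotype (PSI, or TPM
with an optional log2(x+1) flag) on additive dosage 0/1/2, no covariates.
Missing values are dropped pairwise; monomorphic dosages are reported NA
with a reason code; a zero-variance phenotype gets beta = 0, p = 1 (no
evidence, mirroring the expression convention — this also makes the
constant-phenotype permutation limit come out at p_empirical = 1).

Empirical p-values permute the phenotype vector's sample labels against the
genotypes — the source description of the permutation scheme admits several
readings, and label permutation of the molecular phenotype is the standard
QTL choice — with p_emp = (1 + #{p_perm ≤ p_nom}) / (n_perm + 1) and one
permutation schedule per seed shared across associations (default n_perm =
1000). The pseudo-count keeps p_emp ≥ 1/(n_perm+1) and the estimator
uniform under the null, which the test suite checks by KS test.

## Population differentiation and selection

Adapted variants: per-variant 2×2 Pearson chi-square on allele counts
(study population vs a large reference panel), no continuity correction
(counts are allele counts with large reference n), BH across variants, and
the compound call adj. p < 0.05 AND Δ > 0.3. Δ is the same-(alt)-allele
difference |af_pop − af_ref| by default. The folded alternative
(|maf_pop − maf_ref|) is available behind a flag but can hide a large shift
whenever the minor allele differs between the populations — e.g. 0.878 vs
0.334 folds to 0.122 vs 0.334 (Δ = 0.212, below threshold) while the
same-allele shift is 0.544; the unfolded reading is the one under which such
a variant is called, matching the analysis the package reproduces.

Fst is Hudson's estimator, numerator (p1−p2)² − p1(1−p1)/(2n1−1) −
p2(1−p2)/(2n2−1), denominator p1(1−p2) + p2(1−p1); windowed values are the
ratio of summed numerators to summed denominators (ratio of averages),
chosen for its closed form and robustness to sample-size imbalance. PBS uses
T = −log(1 − Fst) with Fst clamped to [0, 1−1e−12] and negative estimates
floored at 0; PBSn1 = PBS_a⁺ / (1 + PBS_a⁺ + PBS_b⁺ + PBS_c⁺), which bounds
the focal branch by the total tree length and lies in [0, 1). LD is the
squared Pearson correlation of dosage vectors (composite LD, no phasing).

## qPCR and phenotype statistics

2^−ΔΔCt with fixed efficiency 2: ΔCt = Ct_target − Ct_reference per sample;
ΔΔCt subtracts the arithmetic mean ΔCt of the control group (per gene);
fold = 2^−ΔΔCt. A plate shift moving target and reference equally cancels
exactly. Group comparisons: Mann–Whitney (exact/asymptotic as above, p = 1
for fully tied inputs), Welch unpaired t, paired t. Spearman correlation
uses average ranks, the t approximation for n ≥ 10 and exact permutation
enumeration below that.

## The synthetic-data generator

The generator emulates the study design, not the raw reads:

- **Genotypes.** Ancestral frequencies ~ Uniform(0.05, 0.95); each
  population's frequency is Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  with divergence F (exactly p at F = 0), genotypes Binomial(2, p_pop).
  With both populations drifting independently at parameter F, the
  between-population Hudson Fst has expectation ≈ F, which the calibration
  tests verify to ±0.02.
- **Junction reads.** Per sample, true PSI = logistic(baseline logit +
  β_psi·dosage + population shift + N(0, σ)); total reads T ~
  Poisson(coverage_mean). An including transcript exposes two junctions
  against one for skipping, so a junction read is an inclusion read with
  probability 2p/(1+p); inclusion reads ~ Binomial(T, 2p/(1+p)), split
  binomially between the two inclusion junctions, skipping = T − inclusion.
  Under this read model the mean-of-inclusion-junctions PSI estimator is
  consistent (the naive "Binomial(T, p)" model would bias it toward
  (p/2)/(1−p/2)). Optional beta-binomial overdispersion is off by default —
  no read-noise model is published for these data.
- **Expression.** log2 expression = baseline + β_expr·dosage (promoter
  variant) + ±de_log2fc·1[pop1] + N(0, σ); planted DE directions alternate
  so library totals stay balanced and TPM renormalization does not compress
  the observed fold changes. Exported as rounded counts and TPM.
- **Phenotypes.** Hb = 14 + 4·PSI + N(0, 1.5) g/dL (per unit PSI of the
  focal event), WBC and platelets analogous with their own coefficients —
  coupling is linear in PSI, not genotype, so mediation through splicing is
  the planted causal structure.
- **qPCR.** Reference Ct ~ N(20, σ_ct); target Ct = reference + 2 −
  log2(fold) + N(0, σ_ct).

Defaults are the study's conditions: cohorts of 67 and 18 (the extended RNA
cohort), divergence F = 0.1 (continental-scale), β_psi = 0.8 per allele on
logit PSI, β_expr = 1 (2-fold per allele), coverage 100 junction reads per
event, Ct noise 0.1 cycles. Candidate cis variants are planted inside the
exact windows the qtl module constructs (upstream flanking intron for
splicing; 500 bp upstream of the TSS for expression), so parameter-recovery
tests exercise the real window logic. Every generator is a pure function of
(config, seed); identical seeds give byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium between
variants (each site drifts independently), read-level artifacts (mapping
bias, GC, duplicates), isoform-complexity beyond one skipped exon per gene,
covariate structure (sex, batch, admixture), and missing genotypes. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the stated generative model — not robustness to the
confounders of real cohort data.

## Numerical and procedural choices

- Junctions are keyed by the intron's first and last base (1-based,
  inclusive) plus strand — unambiguous and BED-convertible by subtracting 1
  from the start. All internal coordinates are 1-based inclusive.
- Genotype parsing accepts biallelic records only and rejects multi-allelic
  sites loudly; missing genotypes propagate as NaN and are dropped pairwise
  downstream, never imputed.
- Result tables are written with a fixed float format and a declared sort
  key; the pipeline manifest hashes every artifact, and a rerun with the
  same config and seed is byte-identical.
- Problem sizes in the test and acceptance runs (e.g. 200 replicates for
  effect recovery, 200 permutations for the uniformity check, 2000 variants
  for calibration) are chosen so each check's sampling error is well below
  the tolerance it asserts while the whole suite stays interactive.

## Known limitations

- rMATS-style effective-length normalization and its likelihood model are
  intentionally not reimplemented; PSI here is the junction-count estimator
  described above.
- DESeq2-style dispersion shrinkage is intentionally not reimplemented; the
  Welch test on log2(TPM+1) is less powerful at very low counts.
- The empirical-p scheme is per-association; no beta-approximation
  extrapolation or multiple-variant conditional analysis is provided.
- The selection scan reports per-variant and windowed statistics but no
  genome-wide percentile ranking, which requires an external genome-wide
  reference distribution.
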