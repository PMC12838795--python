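# Methods

`rvpathrx` implements a rare-variant pathway analysis contrasting two clinical
response groups in a small whole-exome-sequenced cohort: suboptimal responders
(SR, the "case" group, coded 1) versus optimal responders (OR, coded 0). This
note records the statistical model of each stage, the parameters that matter,
the numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## 1. Genotype quality control

Per-genotype masking sets a call to missing iff

* read depth DP < `min_dp` (default 20), or
* genotype quality GQ < `min_gq` (default 20), or
* the call is heterozygous and the allele balance AB = alt/(ref+alt) computed
  from AD is < `min_het_ab` (default 0.2).

All thresholds are strict `<`. A call lacking the relevant FORMAT field is
left alone for that sub-filter — the least destructive reading when a record
carries GT only. A heterozygote whose AD sums to zero reads is treated as
AB = 0 and masked (logged). Masking is idempotent and never changes a
surviving genotype's value.

Multiallelic records are then decomposed into one biallelic record per ALT;
per-sample genotypes are recoded against each ALT with other alternate alleles
counting as reference for that record, so a 1/2 call becomes het in both
daughter records. Shared REF/ALT suffix then prefix are trimmed with the
position advanced (reference-free; full left-alignment against a FASTA is out
of scope, which matters only for indels in repeat context).

Finally, variants missing in strictly more than `max_missing_fraction`
(default 5%) of samples are excluded. At n = 63 this drops a variant with 4
missing calls (6.35%) and keeps one with 3 (4.76%). The filter order —
mask → split/trim → missingness — is fixed and recorded in the QC report.

## 2. Variant classification

Annotations arrive as a table (the contract with VEP + dbNSFP + LOFTEE, which
this package never executes), possibly several rows per variant. One row is
picked per (variant, gene): canonical transcripts outrank non-canonical ones;
within a stratum, consequences are compared as the sorted multiset of
Sequence-Ontology term ranks, so a compound `missense_variant&
splice_region_variant` outranks plain `missense_variant`; remaining ties break
on transcript id. The severity ranking ships as package data (the Ensembl VEP
published order) and is overridable.

Damage classes:

* **pLoF** — LOFTEE high-confidence *and* picked consequence in {frameshift,
  start lost, stop lost, stop gained, splice donor, splice acceptor}.
* **damaging missense** — picked consequence is missense and the *consensus
  score* (mean of whichever of REVEL and MetaRNN are present) is strictly
  \> 0.5. Averaging two ensemble predictors stabilises the call when the tools
  disagree or one is missing; a variant with neither score cannot be damaging
  missense.
* pLoF takes precedence so no variant is double-counted.

Rarity: the two gnomAD AF columns (exomes, genomes) collapse by max-of-available
(both absent → 0, i.e. novel variants are rare), and the variant is rare iff
that frequency is strictly < 0.05. "Frequency seen in either resource" is
ambiguous between max and min; max is the conservative default (common in
either resource disqualifies), min is available behind `af_rule="min"`.
Cohort-internal allele frequency does not enter the rarity gate.

The analysis set is: damaging ∧ rare ∧ carried (≥1 non-missing het/hom-alt
genotype after QC).

## 3. Gene-sets, ORA and the combined score

A sample *carries* a gene when it has ≥1 qualifying variant in it (dominance
coding — hom-alt and het count equally, matching person-level carrier
counting). The SR gene-set is every gene carried by ≥1 SR individual;
symmetrically for OR; the sets may overlap.

Each group's gene-set is tested against every pathway with the one-sided
hypergeometric (Fisher over-representation) tail P[X ≥ k], after intersecting
the query with the universe (default: the union of all pathway genes;
overridable). Benjamini–Hochberg adjustment is applied across pathways.

The combined score is Enrichr-style:

    c = −ln(p) · |z|

where z measures the deviation of the pathway's observed rank (by Fisher p,
midranks for ties) from its expected rank under `B` Monte-Carlo random queries
of the same size drawn uniformly from the universe (default B = 2000, seeded;
B and seed are recorded in output headers). A degenerate null rank sd yields
z = 0. By default p is the BH-adjusted p-value; `combined_p="raw"` uses the
raw Fisher p (the convention of the original web tool). The volcano table
reports ΔCombined = combined_OR − combined_SR per pathway (SR-specific
enrichment is negative), the minimum adjusted p across the two runs, and a
significance label at adjusted p < 0.05 per group.

## 4. Carrier burden

Per pathway, individuals carrying ≥1 qualifying variant in ≥1 pathway gene
are counted once each, giving a 2×2 table (carriers/non-carriers × SR/OR).
Individuals with entirely missing genotypes over the pathway's variants count
as non-carriers. The test is the two-sided Fisher exact test under the
point-probability rule — the p-value sums every table with the observed
margins whose probability does not exceed the observed table's (a 1e-7
relative slack absorbs floating-point ties; distinct hypergeometric
probabilities at these margins differ by more than 4e-7 relatively, so the
slack can only merge genuine ties). The reported odds ratio is the
unconditional sample odds ratio (a·d)/(b·c) (+∞ when b·c = 0 with a·d > 0,
undefined/'.' when both products are 0), not the conditional MLE.

Being an exact discrete test, its true size at α = 0.05 is below nominal; at
the cohort's group sizes and a 28% carrier rate, complete enumeration over
binomial carrier counts gives an exact size of 0.038. The calibration tests
therefore compare the empirical rejection rate against this exact size rather
than against 0.05 itself, plus a validity bound (no inflation above nominal).

## 5. SKAT-O

Per pathway, the qualifying variants over its genes (each variant once per
pathway) form an n×m dosage matrix G (0/1/2; missing dosages mean-imputed per
variant to twice the cohort MAF by default, zero-imputation behind a flag;
imputation never changes m). The null model is a logistic regression of the
binary response on intercept + age + sex (female = 0, male = 1), fitted by
IRLS to score-norm < 1e-8 (max 50 iterations). Fitted probabilities within
1e-7 of 0 or 1 raise a separation error advising covariate review — a wider
guard than machine tolerance because IRLS at this convergence tolerance never
drives probabilities past ~1e-9, so an astronomically tight guard could never
fire.

With S_j = Σ_i G_ij w_j (y_i − μ̂_i) and weights w_j = Beta(MAF_j; 1, 25)
(cohort MAF, folded, computed on non-missing post-QC calls; uncarried
variants are dropped with a log entry; Beta(1,1) gives the unweighted test),
the statistic family is

    Q_ρ = (1 − ρ) Σ_j S_j² + ρ (Σ_j S_j)² ,   ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.

ρ = 0 is the variance-component kernel statistic (sensitive to bidirectional
effects), ρ = 1 the squared weighted burden score (unidirectional effects).
Under the null each Q_ρ is a mixture Σ_k λ_k χ²₁ with λ_k the eigenvalues of
R_ρ^{1/2} Z'P₀Z R_ρ^{1/2}, where Z is the weighted dosage matrix,
P₀ = V − VX(X'VX)⁻¹X'V the variance-adjusted projection through the null
design, and R_ρ the compound-symmetry mixing matrix. ρ = 1 is rank one and is
evaluated exactly as a scaled 1-df chi-square.

The optimal test takes p_min over the grid and converts it by the
one-dimensional integration of the min-p statistic's null law: the kernel is
decomposed along the common (burden) direction, each ρ's p_min-quantile is
obtained by moment-matched inversion, and the conditional survival of the
remainder mixture is integrated against the burden component's 1-df
chi-square (substituting x = t² turns the density singularity at 0 into a
half-normal, integrated with 64-point Gauss–Legendre on [0, √42]; the ρ = 1
grid point enters the conditional thresholds with an 0.999 guard so the
1−ρ denominator stays positive). A failed integration falls back to the
Bonferroni envelope |grid|·p_min (logged), and p_opt is always clamped to
[p_min, min(1, |grid|·p_min)]. With m = 1 all Q_ρ coincide and p_opt is the
common per-ρ p.

Quadratic-form tails are computed by characteristic-function inversion
(Imhof's integral, absolute error target 1e-6, adaptive quadrature), with
closed-form chi-square for one or equal eigenvalues and a skewness-matched
noncentral chi-square (moment-matching) fallback when the inversion reports
trouble; the method used is recorded. Inside the min-p integration the 64
thresholds share one mixture, so they are evaluated together on a shared
inversion grid whose upper limit comes from the integrand's decay envelope
and an integration-by-parts bound on the oscillatory tail (validated against
the adaptive scalar path to ~1e-7).

BH FDR is applied across tested pathways (q < 0.05 flags significance);
pathways with no qualifying variants report p_opt = '.'.

**Small-sample behavior (measured, not assumed).** No small-sample moment
adjustment for binary traits is applied. At n = 63 with rare variants the
test is conservative: over 2000 null synthetic cohorts the empirical type-I
error at α = 0.05 is ≈ 0.025. Against an exact permutation oracle at n = 60
the analytic p_opt differs by 0.005–0.09 depending on the draw, driven by the
permutation law's tie atoms (integer dosages × ±½ residuals), its n/(n−1)
score variance, and the min-p integration's own approximation. Conclusions at
this cohort size are therefore valid but mildly conservative; borderline
q-values should not be over-read.

## 6. Clinical comparison battery

r×2 contingency tables use the exact conditional test (Freeman–Halton
generalization of Fisher's exact test) by exhaustive enumeration of tables
with the observed margins under the point-probability rule (total count
bounded at 10,000; no Monte-Carlo mode). Zero rows do not affect the p-value,
and the 2×2 case reduces exactly to the carrier-burden test. Mann–Whitney U
uses midranks, exact enumeration when n_x+n_y ≤ 20 without ties, otherwise
the tie-corrected normal approximation with continuity correction. Wilcoxon
signed-rank drops zero differences, midranks |d|, exact for n ≤ 15 without
ties, else continuity-corrected normal; all-zero differences return p = 1
with a warning. Standard (not mid-p) conventions throughout. Median/IQR
descriptives are emitted alongside.

## 7. Synthetic cohort generator

The generator emulates the study conditions so every stage can be tested with
no external data: 31 SR + 32 OR samples; ages ~ N(55, 12²) clipped to
[20, 85]; 45% male; 12 pathways × 15 genes plus 60 background genes.

Each pathway receives 8 planted qualifying variants in *distinct* genes
(distinct so the gene-level ORA signal does not saturate — a gene enters a
query set once however many individuals carry it). A planted variant makes a
sample a het carrier with probability q solving 1 − (1 − q)^8 = the pathway's
target carrier rate: 28% in both groups for null pathways (the
optimal-responder regime), and per-`EffectSpec` rates for effect pathways
(the study regime plants one pathway at 58% SR vs 28% OR). `direction_mix`
swaps the group rates for that fraction of a pathway's variants, producing
opposing-direction effects that person-level carrier counting cannot detect
but the kernel test can. Planted variants are damaging by construction
(LOFTEE-HC stop gains with probability 0.25, otherwise missense with
consensus scores drawn conditional on exceeding 0.5) and rare by construction
(emitted gnomAD AFs capped below the 0.05 gate).

Pathway genes also receive benign/common decoys and background genes receive
variants under a log-uniform MAF law on [5e-4, 0.2] with Hardy–Weinberg
binomial(2, MAF) genotypes; REVEL/MetaRNN scores are Beta(8, 3) for damaging
and Beta(2, 6) for benign variants with 10% missingness each. Decoy and
background classes are bookkept *honestly* from the emitted scores — a decoy
that lands above the damaging threshold is recorded in the truth table and
its carriers join the pathway's true qualifying-carrier set, so truth never
silently diverges from what a correct pipeline computes. gnomAD exome/genome
AFs are independent lognormal perturbations (σ_log = 0.3) of the true MAF,
with 5% missingness, so the two columns disagree realistically and exercise
the max/min rarity rule.

QC corruption, when enabled, degrades a recorded set of called genotypes (DP
below 20, GQ below 20, or het AB below 0.2; one mode per call) while clean
calls are generated to pass all default thresholds, making "masked set =
corrupted set" an exact two-path invariant. Identical (config, seed) produce
byte-identical file bundles.

**What the generator does not emulate:** linkage disequilibrium (genotypes
are independent across variants; the analysis operates on carrier indicators
and score statistics, so LD realism is unnecessary for unit-level validation
but passing tests say nothing about LD-induced correlation between pathway
tests on real exomes); population structure and relatedness; sequencing
read-level artifacts; annotation errors (the truth table is noiseless);
chrX/chrY hemizygosity (all contigs are treated autosomally and X/Y are
flagged in logs). Carrier-rate planting is variant-exchangeable within a
pathway, unlike real gene-level clustering of damaging alleles.

**Measured end-to-end yields at the study regime** (these are outputs of the
test suite and acceptance script, not assertions chosen in advance): the
carrier-rate targets are recovered in expectation (mean rates ≈ 0.58/0.28)
and the median burden odds ratio lands near the population value 3.5; the
burden test's power at α = 0.05 is ≈ 0.66 (matching exact enumeration over
binomial carrier counts), so the planted pathway ranks first by burden p in
only ≈ 69% of replicates against 11 null pathways — rank-first recovery is
power-limited at these group sizes, not a pipeline defect.

## 8. Problem sizes used in the test suite

Calibration and oracle checks are sized to run on one CPU in minutes: 2000
null cohorts for type-I error, 200 replicates at the effect regime, a 10⁵
permutation oracle on one 60×4 pathway, 10⁶-draw sampling oracles for the
quadratic-form engine, and complete enumeration oracles wherever the support
is finite (2×2 tables with row sums ≤ 40, universes ≤ 12 for the
over-representation tail, binomial carrier counts for exact size and power).

## 9. Known limitations

* SKAT-O p-values are asymptotic; see §5 for the measured small-sample
  conservativeness. Resampling-based p-values are out of scope.
* The rarity gate trusts the annotation table's AF columns; no live gnomAD
  lookup.
* Reference-free allele trimming cannot left-align indels through repeat
  context.
* The exact r×2 test enumerates; tables with totals beyond 10,000 are
  rejected rather than approximated.
* The ORA universe defaults to the pathway-database union; enrichment against
  a whole-exome universe requires passing one explicitly.
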