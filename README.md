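# rvpathrx

Rare-variant pathway analysis of differential drug response in small
whole-exome-sequenced cohorts.

## The problem

When a biologic works for some patients and not others, and the cohort is
small (here: 63 Crohn's disease patients on vedolizumab, 31 suboptimal (SR)
vs 32 optimal responders (OR)), single-variant association is hopeless —
the signal, if any, lives in *rare, functionally damaging* variants spread
across genes that share a biological pathway. `rvpathrx` implements that
analysis end to end for people doing pharmacogenomics on call-ready VCFs:

1. **Genotype QC** — mask calls with DP < 20, GQ < 20 or heterozygous allele
   balance < 0.2; split multiallelics; drop variants missing in > 5% of
   samples.
2. **Variant classification** — per variant–gene pair, pick the canonical/
   most-severe annotation; call a variant *damaging* if it is LOFTEE
   high-confidence loss-of-function or missense with consensus score
   mean(REVEL, MetaRNN) > 0.5; call it *rare* if max gnomAD AF < 0.05.
3. **Group gene-sets** — genes carried (≥ 1 qualifying variant) by ≥ 1
   individual per response group, with gene×individual carrier matrices.
4. **Pathway over-representation** — one-sided Fisher/hypergeometric test per
   pathway per group, BH adjustment, Enrichr-style combined score
   c = −ln(p)·|z| with a Monte-Carlo rank-deviation z, and the per-pathway
   ΔCombined = c_OR − c_SR volcano table.
5. **Carrier burden** — per pathway, the 2×2 exact test (point-probability
   rule) on carriers vs non-carriers by group, with the sample odds ratio.
6. **SKAT-O** — per pathway, the optimal sequence kernel association test
   interpolating burden (ρ=1) and variance-component (ρ=0) statistics over a
   ρ-grid, with a logistic null model adjusted for age and sex, Beta(1, 25)
   MAF weights, quadratic-form p-values by characteristic-function inversion
   (moment-matching fallback), and BH FDR across pathways.
7. **Clinical battery** — exact r×2 contingency tests (Freeman–Halton),
   Mann–Whitney U and Wilcoxon signed-rank comparisons for the cohort table.
8. **Synthetic cohorts** — a generator that emulates the study design (group
   sizes, MAF spectrum, score distributions, pathway-structured gene
   membership, injectable carrier-rate effects with optional opposing
   directions, QC corruption) and emits ground truth for every planted fact.

The statistic at the core of stage 6, per pathway with weighted genotype
scores S_j = Σ_i w_j G_ij (y_i − μ̂_i):

    Q_ρ = (1 − ρ) Σ_j S_j²  +  ρ (Σ_j S_j)² ,

whose null law per ρ is a weighted chi-square mixture from the eigenvalues of
the projected kernel, combined over the grid by the min-p integration. See
`docs/methods.md` for the full model, conventions, numerical choices and
measured small-sample behavior.

## Worked example

Generate a synthetic cohort at the study regime (one pathway planted with a
58% vs 28% carrier-rate contrast) and run the whole pipeline:

```python
from rvpathrx import simulate_cohort, study_config, run_pipeline
from rvpathrx.carrier_burden import burden_to_frame

bundle = simulate_cohort(study_config(seed=2))
res = run_pipeline(bundle.cv, bundle.annotations, bundle.db, bundle.design,
                   burden_pathways=list(bundle.db.pathways),
                   skato_pathways=list(bundle.db.pathways), seed=2)
print(len(res.rare_damaging), "rare damaging carried variants")
print(burden_to_frame(res.burden).head(2).round(3).to_string(index=False))
```

prints

```
101 rare damaging carried variants
pathway  carriers_sr  carriers_or  pct_sr  pct_or  odds_ratio     p
   PW11           15            8  48.387   25.00       2.812 0.070
   PW01           17           10  54.839   31.25       2.671 0.077
```

Reading it: 101 variants survived the damaging ∧ rare ∧ carried filter. The
planted pathway PW01 shows 54.8% SR vs 31.3% OR carriers — close to its
58%/28% targets — with a sample odds ratio of 2.7; in this particular
replicate a null pathway (PW11) drew an almost equally large contrast, which
is the expected behavior at these group sizes: the exact power of the 2×2
test at the planted contrast is only 0.66 at α = 0.05, so roughly a third of
replicates leave the planted pathway undetected or outranked. The same
regime's recovery *in expectation* (mean carrier rates, median odds ratio
≈ 3.5, power matching exact enumeration) is what the acceptance script
measures over replicates.

The same stages are available as a CLI for file-based work:

```bash
rvpathrx simulate --seed 2 --out-dir data
rvpathrx run-all --vcf data/cohort.vcf --annotations data/annotations.tsv \
    --phenotypes data/phenotypes.tsv --gmt data/pathways.gmt \
    --out-dir results --seed 2
```

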