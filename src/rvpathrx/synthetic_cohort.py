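"""Synthetic WES cohort generator with known ground truth.

Emits the four inputs the pipeline consumes — cohort VCF, annotation TSV,
pathway GMT and phenotype TSV — together with a :class:`TruthTable` recording
every planted fact (per-variant true class, carrier counts, per-pathway
effects and qualifying carriers, corrupted calls), so that every downstream
stage can be tested against bookkeeping rather than re-derived truth.

Structure of the simulated exome
--------------------------------
* ``n_pathways`` gene-sets of ``genes_per_pathway`` genes each, plus
  ``n_background_genes`` genes outside every pathway.
* Each pathway carries ``qualifying_variants_per_pathway`` *planted* rare
  damaging variants (damaging by construction: deleteriousness scores are
  drawn conditional on a consensus above the 0.5 threshold, or the variant is
  a LOFTEE-HC stop gain; emitted gnomAD AFs are kept below the rarity bound).
  Per sample, a planted variant makes the sample a het carrier with
  probability q solving 1 − (1 − q)^m = target pathway carrier rate. Null
  pathways use the same baseline rate in both groups; an :class:`EffectSpec`
  changes the group rates for chosen pathways, and its ``direction_mix``
  swaps the group rates for that fraction of the pathway's variants —
  opposing-direction effects that carrier counting cannot see.
* Pathway genes additionally receive benign/common decoy variants, and
  background genes receive variants under the configured MAF law with
  Hardy–Weinberg binomial(2, MAF) genotypes; their true class is bookkept
  honestly from the emitted scores, so a decoy that lands above the
  damaging threshold is recorded (and its carriers join the pathway's true
  qualifying-carrier set) rather than silently contaminating the truth.
* gnomAD exome/genome AFs are independently noise-perturbed copies of the
  true MAF, so the two columns disagree realistically.

Identical ``(config, seed)`` produce byte-identical file bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (AnnotationRecord, CohortDesign, CohortVariants,
                         PathwayDB, write_annotations, write_gmt,
                         write_phenotypes, write_vcf)

__all__ = ["EffectSpec", "SyntheticConfig", "TruthTable", "SyntheticBundle",
           "simulate_cohort", "inject_qc_corruption", "study_config"]

RARE_BOUND = 0.05


@dataclass(frozen=True)
class EffectSpec:
    """Group-differential carrier-rate effect for one pathway.

    ``carrier_rate_sr`` / ``carrier_rate_or`` are the target pathway-level
    carrier rates; ``direction_mix`` in [0, 1] is the fraction of the
    pathway's planted variants whose group rates are swapped (0 = purely
    unidirectional SR effect, 0.5 = balanced opposing effects).
    """

    pathway: str
    carrier_rate_sr: float
    carrier_rate_or: float
    direction_mix: float = 0.0

    def __post_init__(self):
        for v in (self.carrier_rate_sr, self.carrier_rate_or, self.direction_mix):
            if not (0.0 <= v <= 1.0):
                raise ValueError("rates and direction_mix must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs. Defaults emulate the study conditions: 31 vs 32
    samples, a rare-variant MAF spectrum, deleteriousness scores above/below
    the 0.5 consensus threshold for damaging/benign variants, and a 28%
    baseline pathway carrier rate (the optimal-responder regime)."""

    n_sr: int = 31
    n_or: int = 32
    n_pathways: int = 12
    genes_per_pathway: int = 15
    n_background_genes: int = 60
    qualifying_variants_per_pathway: int = 8
    benign_variants_per_pathway: int = 3
    background_variants_per_gene_mean: float = 2.0
    base_carrier_rate: float = 0.28
    maf_log10_range: tuple = (math.log10(5e-4), math.log10(0.2))
    damaging_score_beta: tuple = (8.0, 3.0)   # consensus mean ~0.73
    benign_score_beta: tuple = (2.0, 6.0)     # consensus mean 0.25
    score_missing_rate: float = 0.10
    af_missing_rate: float = 0.05
    af_noise_sd_log: float = 0.30
    plof_fraction: float = 0.25
    background_damaging_fraction: float = 0.20
    extra_transcript_fraction: float = 0.10
    effects: tuple = ()
    corrupt_dp_rate: float = 0.0
    corrupt_gq_rate: float = 0.0
    corrupt_ab_rate: float = 0.0
    age_mean: float = 55.0
    age_sd: float = 12.0
    male_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_sr < 2 or self.n_or < 2:
            raise ValueError("group sizes must be >= 2")
        for name in ("base_carrier_rate", "score_missing_rate", "af_missing_rate",
                     "plof_fraction", "background_damaging_fraction",
                     "extra_transcript_fraction", "male_fraction",
                     "corrupt_dp_rate", "corrupt_gq_rate", "corrupt_ab_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        names = [e.pathway for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pathway in effects")


def study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-regime configuration: one pathway with the 58% vs 28%
    carrier-rate contrast on top of the null baseline."""
    params = dict(effects=(EffectSpec("PW01", 0.58, 0.28),), seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class TruthTable:
    """Ground truth emitted alongside the data bundle.

    ``variants``: one row per variant — true class, true MAF, emitted max
    gnomAD AF, rarity, carrier counts by group, planted pathway ('.' if none).
    ``pathway_effects``: configured rates per pathway.
    ``pathway_carriers``: per pathway, the true qualifying carriers by group
    (planted carriers plus any decoy that honestly qualified).
    ``corrupted_calls``: calls degraded by :func:`inject_qc_corruption`.
    """

    variants: pd.DataFrame
    pathway_effects: pd.DataFrame
    pathway_carriers: dict
    corrupted_calls: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["variant_index", "sample_id", "mode"]))

    def n_rare_damaging_carried(self) -> int:
        v = self.variants
        return int((v["true_rare"] & (v["true_class"] != "none")
                    & (v["n_carriers"] > 0)).sum())


@dataclass
class SyntheticBundle:
    """In-memory bundle of everything :func:`simulate_cohort` produced."""

    cv: CohortVariants
    annotations: list
    db: PathwayDB
    design: CohortDesign
    truth: TruthTable
    config: SyntheticConfig

    def write(self, out_dir) -> dict:
        """Write the four input files plus truth TSVs; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "annotations": out / "annotations.tsv",
            "gmt": out / "pathways.gmt",
            "phenotypes": out / "phenotypes.tsv",
            "truth_variants": out / "truth_variants.tsv",
            "truth_pathways": out / "truth_pathways.tsv",
            "truth_corrupted": out / "truth_corrupted_calls.tsv",
        }
        write_vcf(self.cv, paths["vcf"])
        write_annotations(self.annotations, paths["annotations"])
        write_gmt(self.db, paths["gmt"])
        write_phenotypes(self.design, paths["phenotypes"])
        self.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False,
                                   na_rep=".")
        self.truth.pathway_effects.to_csv(paths["truth_pathways"], sep="\t",
                                          index=False, na_rep=".")
        self.truth.corrupted_calls.to_csv(paths["truth_corrupted"], sep="\t",
                                          index=False, na_rep=".")
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _per_variant_rate(pathway_rate: float, m: int) -> float:
    """Per-variant carrier probability hitting a pathway-level target:
    1 − (1 − q)^m = rate."""
    return 1.0 - (1.0 - pathway_rate) ** (1.0 / m)


class _VariantAccumulator:
    """Collects per-variant metadata and dosage rows in generation order."""

    def __init__(self):
        self.meta = []
        self.dosages = []

    def add(self, dosage, **meta):
        self.meta.append(meta)
        self.dosages.append(np.asarray(dosage, dtype=np.int8))

    def __len__(self):
        return len(self.meta)


def simulate_cohort(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete synthetic cohort with ground truth.

    QC corruption is applied afterwards iff any corruption rate is non-zero
    (see :func:`inject_qc_corruption`).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sr + cfg.n_or
    samples = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["SR"] * cfg.n_sr + ["OR"] * cfg.n_or, dtype=object)
    is_sr = group == "SR"

    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, size=n)), 20, 85)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female").astype(object)
    design = CohortDesign(samples=samples, group=group, age=age.astype(float), sex=sex)

    pathways = {}
    gene_counter = 0
    for p in range(cfg.n_pathways):
        genes = [f"GENE{gene_counter + g + 1:04d}" for g in range(cfg.genes_per_pathway)]
        gene_counter += cfg.genes_per_pathway
        pathways[f"PW{p + 1:02d}"] = frozenset(genes)
    background_genes = [f"BGENE{g + 1:04d}" for g in range(cfg.n_background_genes)]
    db = PathwayDB(pathways=pathways,
                   descriptions={k: "synthetic pathway" for k in pathways})

    effect_by_pathway = {e.pathway: e for e in cfg.effects}
    unknown = set(effect_by_pathway) - set(pathways)
    if unknown:
        raise ValueError(f"effect pathways not in GMT: {sorted(unknown)}")

    acc = _VariantAccumulator()
    qualifying_carriers = {p: np.zeros(n, dtype=bool) for p in pathways}
    pos_cursor = [1000]

    def next_pos() -> int:
        pos_cursor[0] += int(rng.integers(50, 500))
        return pos_cursor[0]

    def draw_scores(damaging: bool):
        a, b = cfg.damaging_score_beta if damaging else cfg.benign_score_beta
        revel = float(rng.beta(a, b))
        metarnn = float(rng.beta(a, b))
        if rng.random() < cfg.score_missing_rate:
            revel = None
        if rng.random() < cfg.score_missing_rate:
            metarnn = None
        return revel, metarnn

    def consensus(revel, metarnn):
        vals = [v for v in (revel, metarnn) if v is not None]
        return float(np.mean(vals)) if vals else None

    def draw_damaging_scores():
        """Scores conditioned on a consensus strictly above threshold."""
        for _ in range(100):
            revel, metarnn = draw_scores(damaging=True)
            c = consensus(revel, metarnn)
            if c is not None and c > 0.5:
                return revel, metarnn
        return 0.8, 0.8  # unreachable in practice

    def noisy_af(true_maf: float, rare_guard: bool):
        afs = []
        for _ in range(2):
            if rng.random() < cfg.af_missing_rate:
                afs.append(None)
            else:
                af = float(true_maf * math.exp(rng.normal(0.0, cfg.af_noise_sd_log)))
                if rare_guard:
                    af = min(af, 0.045)
                afs.append(min(af, 0.999))
        return afs[0], afs[1]

    def max_present(af_ex, af_gen) -> float:
        return max([a for a in (af_ex, af_gen) if a is not None], default=0.0)

    # --- planted qualifying variants ---------------------------------------
    m_q = cfg.qualifying_variants_per_pathway
    for pname in pathways:
        genes_sorted = sorted(pathways[pname])
        eff = effect_by_pathway.get(pname)
        rate_sr = eff.carrier_rate_sr if eff else cfg.base_carrier_rate
        rate_or = eff.carrier_rate_or if eff else cfg.base_carrier_rate
        mix = eff.direction_mix if eff else 0.0
        n_swapped = int(round(mix * m_q))
        q_sr, q_or = _per_variant_rate(rate_sr, m_q), _per_variant_rate(rate_or, m_q)
        # distinct genes per qualifying variant keep the gene-level signal
        # from saturating (a gene enters a query set once, however many
        # individuals carry it)
        gene_idx = rng.choice(len(genes_sorted), size=min(m_q, len(genes_sorted)),
                              replace=False)
        for j in range(m_q):
            qs, qo = (q_or, q_sr) if j < n_swapped else (q_sr, q_or)
            carrier = rng.random(n) < np.where(is_sr, qs, qo)
            qualifying_carriers[pname] |= carrier
            is_plof = rng.random() < cfg.plof_fraction
            if is_plof:
                revel = metarnn = None
                consequence, loftee, true_class = "stop_gained", "HC", "plof"
            else:
                revel, metarnn = draw_damaging_scores()
                consequence, loftee, true_class = "missense_variant", None, "damaging_missense"
            af_ex, af_gen = noisy_af(min(qs, 0.04), rare_guard=True)
            acc.add(carrier.astype(np.int8),
                    pos=next_pos(),
                    gene=genes_sorted[int(gene_idx[j % len(gene_idx)])],
                    consequence=consequence, loftee=loftee,
                    revel=revel, metarnn=metarnn, af_ex=af_ex, af_gen=af_gen,
                    true_class=true_class, planted_pathway=pname,
                    true_maf=min(qs, 0.04) / 2.0)

        # benign/common decoys inside pathway genes (class bookkept honestly)
        for _ in range(cfg.benign_variants_per_pathway):
            maf = 10 ** rng.uniform(*cfg.maf_log10_range)
            dosage = rng.binomial(2, maf, size=n).astype(np.int8)
            revel, metarnn = draw_scores(damaging=False)
            common = rng.random() < 0.5
            af_ex, af_gen = noisy_af(max(maf, 0.10) if common else maf,
                                     rare_guard=False)
            consequence = ("missense_variant" if rng.random() < 0.7
                           else "synonymous_variant")
            c = consensus(revel, metarnn)
            true_class = ("damaging_missense"
                          if consequence == "missense_variant"
                          and c is not None and c > 0.5 else "none")
            if (true_class != "none" and max_present(af_ex, af_gen) < RARE_BOUND
                    and dosage.any()):
                qualifying_carriers[pname] |= dosage >= 1
            acc.add(dosage, pos=next_pos(),
                    gene=genes_sorted[int(rng.integers(len(genes_sorted)))],
                    consequence=consequence, loftee=None,
                    revel=revel, metarnn=metarnn, af_ex=af_ex, af_gen=af_gen,
                    true_class=true_class, planted_pathway=".", true_maf=maf)

    # --- background variants outside every pathway --------------------------
    for gene in background_genes:
        for _ in range(int(rng.poisson(cfg.background_variants_per_gene_mean))):
            maf = 10 ** rng.uniform(*cfg.maf_log10_range)
            dosage = rng.binomial(2, maf, size=n).astype(np.int8)
            damaging = rng.random() < cfg.background_damaging_fraction
            is_plof = damaging and rng.random() < cfg.plof_fraction
            af_ex, af_gen = noisy_af(maf, rare_guard=False)
            if is_plof:
                revel = metarnn = None
                consequence, loftee, true_class = "stop_gained", "HC", "plof"
            else:
                revel, metarnn = draw_scores(damaging=damaging)
                consequence = ("missense_variant" if (damaging or rng.random() < 0.7)
                               else "synonymous_variant")
                loftee = None
                c = consensus(revel, metarnn)
                true_class = ("damaging_missense"
                              if consequence == "missense_variant"
                              and c is not None and c > 0.5 else "none")
            acc.add(dosage, pos=next_pos(), gene=gene, consequence=consequence,
                    loftee=loftee, revel=revel, metarnn=metarnn,
                    af_ex=af_ex, af_gen=af_gen, true_class=true_class,
                    planted_pathway=".", true_maf=maf)

    # --- assemble CohortVariants --------------------------------------------
    n_v = len(acc)
    dosage_mat = (np.vstack(acc.dosages) if n_v else np.empty((0, n), np.int8))

    dp = (20 + rng.poisson(40, size=(n_v, n))).astype(np.int32)
    gq = rng.integers(30, 100, size=(n_v, n)).astype(np.int32)
    ad = np.zeros((n_v, n, 2), dtype=np.int32)
    hom_ref, het, hom_alt = dosage_mat == 0, dosage_mat == 1, dosage_mat == 2
    ad[hom_ref, 0] = dp[hom_ref]
    ad[hom_alt, 1] = dp[hom_alt]
    if het.any():
        alt_reads = rng.binomial(dp[het], 0.5)
        lo = np.ceil(0.25 * dp[het]).astype(np.int64)
        hi = np.floor(0.75 * dp[het]).astype(np.int64)
        alt_reads = np.clip(alt_reads, lo, np.maximum(lo, hi))
        ad[het, 1] = alt_reads
        ad[het, 0] = dp[het] - alt_reads

    a1 = (dosage_mat == 2).astype(np.int16)   # unphased: het = 0/1, hom_alt = 1/1
    a2 = (dosage_mat >= 1).astype(np.int16)

    refs, alts = [], []
    for _ in range(n_v):
        r = _BASES[int(rng.integers(4))]
        alt_choices = [b for b in _BASES if b != r]
        refs.append(r)
        alts.append((alt_choices[int(rng.integers(3))],))

    variants = pd.DataFrame({
        "chrom": ["1"] * n_v,
        "pos": np.array([m["pos"] for m in acc.meta], dtype=np.int64),
        "id": [f"var{i + 1:05d}" for i in range(n_v)],
        "ref": refs,
        "alts": alts,
    })
    cv = CohortVariants(samples=samples, variants=variants, a1=a1, a2=a2,
                        dp=dp, gq=gq, ad=ad)

    annotations = []
    for i, m in enumerate(acc.meta):
        key = dict(chrom="1", pos=int(m["pos"]), ref=refs[i], alt=alts[i][0],
                   gene=m["gene"])
        annotations.append(AnnotationRecord(
            transcript=f"TX{i + 1:05d}.1", canonical=True,
            consequences=tuple(m["consequence"].split("&")),
            revel=m["revel"], metarnn=m["metarnn"], loftee=m["loftee"],
            af_gnomad_exomes=m["af_ex"], af_gnomad_genomes=m["af_gen"], **key))
        if rng.random() < cfg.extra_transcript_fraction:
            # a less severe non-canonical transcript that picking must ignore
            annotations.append(AnnotationRecord(
                transcript=f"TX{i + 1:05d}.2", canonical=False,
                consequences=("intron_variant",),
                revel=None, metarnn=None, loftee=None,
                af_gnomad_exomes=m["af_ex"], af_gnomad_genomes=m["af_gen"], **key))

    max_af = [max_present(m["af_ex"], m["af_gen"]) for m in acc.meta]
    n_carriers = (dosage_mat >= 1).sum(axis=1)
    n_carriers_sr = (dosage_mat[:, is_sr] >= 1).sum(axis=1)
    truth_variants = pd.DataFrame({
        "chrom": "1", "pos": variants["pos"],
        "ref": refs, "alt": [a[0] for a in alts],
        "gene": [m["gene"] for m in acc.meta],
        "true_class": [m["true_class"] for m in acc.meta],
        "true_maf": [m["true_maf"] for m in acc.meta],
        "true_max_gnomad_af": max_af,
        "true_rare": [af < RARE_BOUND for af in max_af],
        "n_carriers": n_carriers,
        "n_carriers_sr": n_carriers_sr,
        "n_carriers_or": n_carriers - n_carriers_sr,
        "planted_pathway": [m["planted_pathway"] for m in acc.meta],
    })
    effects_rows = []
    for pname in pathways:
        eff = effect_by_pathway.get(pname)
        effects_rows.append(dict(
            pathway=pname,
            carrier_rate_sr=eff.carrier_rate_sr if eff else cfg.base_carrier_rate,
            carrier_rate_or=eff.carrier_rate_or if eff else cfg.base_carrier_rate,
            direction_mix=eff.direction_mix if eff else 0.0,
            n_qualifying=m_q,
        ))
    pathway_carrier_truth = {
        pname: {
            "sr": [s for s, c, sr in zip(samples, mask, is_sr) if c and sr],
            "or": [s for s, c, sr in zip(samples, mask, is_sr) if c and not sr],
        }
        for pname, mask in qualifying_carriers.items()
    }
    truth = TruthTable(
        variants=truth_variants,
        pathway_effects=pd.DataFrame(effects_rows),
        pathway_carriers=pathway_carrier_truth,
    )
    bundle = SyntheticBundle(cv=cv, annotations=annotations, db=db,
                             design=design, truth=truth, config=cfg)
    if cfg.corrupt_dp_rate or cfg.corrupt_gq_rate or cfg.corrupt_ab_rate:
        bundle = inject_qc_corruption(bundle, cfg)
    return bundle


def inject_qc_corruption(bundle: SyntheticBundle, cfg: SyntheticConfig) -> SyntheticBundle:
    """Degrade a recorded set of calls so the default QC thresholds mask
    exactly that set.

    Each *called* genotype is independently corrupted with the configured
    rates: DP dropped below 20, or GQ below 20, or (heterozygotes only) the
    allele balance pushed below 0.2. A call receives at most one corruption
    mode; clean calls are generated to pass all default thresholds, so the
    masked set equals the corrupted set. Zero rates make this the identity.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    cv = bundle.cv.copy()
    n_v, n_s = cv.n_variants, cv.n_samples
    called = (cv.a1 >= 0) & (cv.a2 >= 0)
    het = called & (cv.a1 != cv.a2)

    u = rng.random((n_v, n_s))
    p_dp, p_gq, p_ab = cfg.corrupt_dp_rate, cfg.corrupt_gq_rate, cfg.corrupt_ab_rate
    mode = np.full((n_v, n_s), "", dtype=object)
    mode[called & (u < p_dp)] = "dp"
    mode[called & (u >= p_dp) & (u < p_dp + p_gq)] = "gq"
    mode[het & (u >= p_dp + p_gq) & (u < p_dp + p_gq + p_ab)] = "ab"

    records = []
    for i, j in np.argwhere(mode == "dp"):
        tot = int(rng.integers(2, 20))
        cv.dp[i, j] = tot
        if cv.a1[i, j] != cv.a2[i, j]:
            alt = max(1, int(round(0.5 * tot)))
            cv.ad[i, j] = (tot - alt, alt)
        elif cv.a1[i, j] == 0:
            cv.ad[i, j] = (tot, 0)
        else:
            cv.ad[i, j] = (0, tot)
        records.append((int(i), cv.samples[int(j)], "dp"))
    for i, j in np.argwhere(mode == "gq"):
        cv.gq[i, j] = int(rng.integers(0, 20))
        records.append((int(i), cv.samples[int(j)], "gq"))
    for i, j in np.argwhere(mode == "ab"):
        tot = int(cv.dp[i, j])
        alt = int(math.floor(0.19 * tot))
        cv.ad[i, j] = (tot - alt, alt)
        records.append((int(i), cv.samples[int(j)], "ab"))

    corrupted = pd.DataFrame(records, columns=["variant_index", "sample_id", "mode"])
    corrupted = corrupted.sort_values(["variant_index", "sample_id"]).reset_index(drop=True)
    truth = TruthTable(
        variants=bundle.truth.variants,
        pathway_effects=bundle.truth.pathway_effects,
        pathway_carriers=bundle.truth.pathway_carriers,
        corrupted_calls=corrupted,
    )
    return SyntheticBundle(cv=cv, annotations=bundle.annotations, db=bundle.db,
                           design=bundle.design, truth=truth, config=bundle.config)
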