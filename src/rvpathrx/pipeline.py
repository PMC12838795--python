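"""End-to-end orchestration: QC → classification → gene-sets → ORA → burden →
SKAT-O, from in-memory objects or from the four input files."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .carrier_burden import run_burden
from .geneset_mapping import map_variants_to_group_genes
from .genotype_qc import QcThresholds, run_qc
from .io_formats import CohortDesign, CohortVariants, PathwayDB
from .pathway_ora import run_ora, volcano
from .skat_o import DEFAULT_RHO_GRID, run_skato
from .variant_classification import build_rare_damaging_set, classify_annotations

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    qc_cv: CohortVariants
    qc_report: object
    classified: list
    rare_damaging: list
    gene_sets: object
    ora_sr: list
    ora_or: list
    volcano: list
    burden: list
    skato: list


def run_pipeline(cv: CohortVariants, annotations: list, db: PathwayDB,
                 design: CohortDesign, thresholds: QcThresholds = QcThresholds(),
                 alpha: float = 0.05, fdr: float = 0.05, ora_B: int = 2000,
                 seed: int = 0, rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
                 burden_pathways: Optional[Sequence[str]] = None,
                 skato_pathways: Optional[Sequence[str]] = None,
                 af_rule: str = "max", combined_p: str = "adjusted") -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``burden_pathways`` / ``skato_pathways`` default to the pathways with an
    ORA-significant enrichment (BH-adjusted p < ``alpha``) in either group,
    mirroring the usual practice of following up enriched pathways only; pass
    explicit lists (e.g. all of ``db.pathways``) to override.
    """
    design = design.aligned_to(cv.samples)
    qc_cv, qc_report = run_qc(cv, thresholds)
    classified = classify_annotations(annotations, af_rule=af_rule)
    rare_damaging = build_rare_damaging_set(classified, qc_cv)
    gene_sets = map_variants_to_group_genes(rare_damaging, qc_cv, design)

    ora_sr = run_ora(gene_sets.sr_genes, db, alpha=alpha, B=ora_B, seed=seed,
                     combined_p=combined_p)
    ora_or = run_ora(gene_sets.or_genes, db, alpha=alpha, B=ora_B, seed=seed,
                     combined_p=combined_p)
    volc = volcano(ora_sr, ora_or, alpha=alpha)

    if burden_pathways is None or skato_pathways is None:
        enriched = [r.pathway for r in ora_sr if r.p_adj < alpha]
        enriched += [r.pathway for r in ora_or if r.p_adj < alpha
                     and r.pathway not in enriched]
        if not enriched:
            logger.info("no ORA-enriched pathway; association stages test all pathways")
            enriched = list(db.pathways)
        if burden_pathways is None:
            burden_pathways = enriched
        if skato_pathways is None:
            skato_pathways = enriched

    burden = run_burden(list(burden_pathways), db, rare_damaging, qc_cv, design)
    skato = run_skato(list(skato_pathways), db, rare_damaging, qc_cv, design,
                      rho_grid=rho_grid, fdr=fdr)
    return PipelineResult(qc_cv=qc_cv, qc_report=qc_report, classified=classified,
                          rare_damaging=rare_damaging, gene_sets=gene_sets,
                          ora_sr=ora_sr, ora_or=ora_or, volcano=volc,
                          burden=burden, skato=skato)
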