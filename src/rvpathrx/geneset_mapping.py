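"""Group-specific gene-sets and gene×individual carrier matrices.

A sample *carries* a gene when it has at least one non-missing het or hom_alt
genotype over the gene's rare damaging variants (dominance coding). The
SR-specific gene-set is the set of genes carried by at least one SR individual;
symmetrically for OR. The two sets may overlap. Genes never seen in the pathway
database still enter the gene-sets — they simply cannot contribute to pathway
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CohortDesign, CohortVariants, PathwayDB
from .variant_classification import ClassifiedVariant

__all__ = ["GroupGeneSets", "gene_carrier_matrix", "map_variants_to_group_genes",
           "carrier_matrix"]


@dataclass
class GroupGeneSets:
    """SR- and OR-specific gene-sets with per-gene carrier lists by group."""

    sr_genes: frozenset
    or_genes: frozenset
    carriers_by_gene_sr: dict = field(default_factory=dict)
    carriers_by_gene_or: dict = field(default_factory=dict)


def gene_carrier_matrix(rare_damaging: Iterable[ClassifiedVariant],
                        cv: CohortVariants) -> pd.DataFrame:
    """Binary genes × samples carrier matrix over *all* genes seen in the
    rare damaging set. A missing genotype never yields a 1."""
    codes = cv.gt_codes()
    key_to_row = {key: i for i, key in enumerate(cv.variant_keys())}
    genes: dict = {}
    for c in rare_damaging:
        i = key_to_row.get(c.key)
        if i is None:
            continue
        carrier = codes[i] >= 1
        if c.gene in genes:
            genes[c.gene] |= carrier
        else:
            genes[c.gene] = carrier.copy()
    mat = pd.DataFrame.from_dict(genes, orient="index", columns=cv.samples,
                                 dtype=np.int8)
    mat.index.name = "gene"
    return mat.sort_index()


def map_variants_to_group_genes(rare_damaging: Iterable[ClassifiedVariant],
                                cv: CohortVariants,
                                design: CohortDesign) -> GroupGeneSets:
    """Build the SR-specific and OR-specific gene-sets from carried rare
    damaging variants. A gene carried in both groups appears in both sets."""
    design = design.aligned_to(cv.samples)
    mat = gene_carrier_matrix(rare_damaging, cv)
    is_sr = design.group == "SR"
    sr_genes, or_genes = set(), set()
    carriers_sr, carriers_or = {}, {}
    samples = np.asarray(cv.samples, dtype=object)
    for gene, row in mat.iterrows():
        carried = row.to_numpy(dtype=bool)
        sr_list = list(samples[carried & is_sr])
        or_list = list(samples[carried & ~is_sr])
        if sr_list:
            sr_genes.add(gene)
            carriers_sr[gene] = sr_list
        if or_list:
            or_genes.add(gene)
            carriers_or[gene] = or_list
    return GroupGeneSets(
        sr_genes=frozenset(sr_genes), or_genes=frozenset(or_genes),
        carriers_by_gene_sr=carriers_sr, carriers_by_gene_or=carriers_or,
    )


def carrier_matrix(pathways: Sequence[str], db: PathwayDB,
                   rare_damaging: Iterable[ClassifiedVariant],
                   cv: CohortVariants) -> pd.DataFrame:
    """Gene×individual binary matrix for the requested pathways (heatmap data).

    Rows are the pathway genes grouped by pathway (MultiIndex pathway/gene);
    genes with no carriers are retained as explicit zero rows so the matrix
    shape is reproducible from the pathway definitions alone.
    """
    unknown = [p for p in pathways if p not in db]
    if unknown:
        raise KeyError(f"unknown pathway name(s): {unknown}")
    full = gene_carrier_matrix(rare_damaging, cv)
    blocks, index = [], []
    for p in pathways:
        for gene in sorted(db[p]):
            if gene in full.index:
                blocks.append(full.loc[gene].to_numpy(dtype=np.int8))
            else:
                blocks.append(np.zeros(cv.n_samples, dtype=np.int8))
            index.append((p, gene))
    mat = pd.DataFrame(
        np.vstack(blocks) if blocks else np.empty((0, cv.n_samples), np.int8),
        index=pd.MultiIndex.from_tuples(index, names=["pathway", "gene"]),
        columns=cv.samples,
    )
    return mat
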