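"""Shared fixtures: hand-built tiny cohorts and session-scoped synthetic bundles."""

import numpy as np
import pandas as pd
import pytest

from rvpathrx.io_formats import ABSENT, CohortDesign, CohortVariants
from rvpathrx.synthetic_cohort import SyntheticConfig, simulate_cohort, study_config


def build_cohort(samples, variant_rows, a1, a2, dp=None, gq=None, ad=None):
    """Construct a CohortVariants from plain lists.

    ``variant_rows`` is a list of (chrom, pos, ref, alts_tuple); matrices are
    nested lists indexed [variant][sample]. DP/GQ default to generous values,
    AD to consistent depths, so QC keeps everything unless told otherwise.
    """
    n_v, n_s = len(variant_rows), len(samples)
    a1 = np.asarray(a1, dtype=np.int16)
    a2 = np.asarray(a2, dtype=np.int16)
    dp = (np.full((n_v, n_s), 60, dtype=np.int32) if dp is None
          else np.asarray(dp, dtype=np.int32))
    gq = (np.full((n_v, n_s), 90, dtype=np.int32) if gq is None
          else np.asarray(gq, dtype=np.int32))
    if ad is None:
        max_alleles = max((1 + len(v[3]) for v in variant_rows), default=2)
        ad_arr = np.full((n_v, n_s, max_alleles), ABSENT, dtype=np.int32)
        for i in range(n_v):
            for j in range(n_s):
                if a1[i, j] < 0 or a2[i, j] < 0:
                    continue
                ad_arr[i, j, :] = 0
                for allele in (a1[i, j], a2[i, j]):
                    ad_arr[i, j, allele] += 30
    else:
        ad_arr = np.asarray(ad, dtype=np.int32)
    variants = pd.DataFrame(
        [{"chrom": c, "pos": p, "id": None, "ref": r, "alts": tuple(alts)}
         for c, p, r, alts in variant_rows]
    )
    return CohortVariants(samples=list(samples), variants=variants,
                          a1=a1, a2=a2, dp=dp, gq=gq, ad=ad_arr)


def make_design(samples, groups, ages=None, sexes=None):
    n = len(samples)
    return CohortDesign(
        samples=list(samples),
        group=np.asarray(groups, dtype=object),
        age=np.asarray(ages if ages is not None else [50.0] * n, dtype=float),
        sex=np.asarray(sexes if sexes is not None else ["male"] * n, dtype=object),
    )


@pytest.fixture(scope="session")
def null_bundle():
    """Synthetic cohort with no planted group effect."""
    return simulate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def effect_bundle():
    """Synthetic cohort at the study effect regime (58% vs 28% carriers)."""
    return simulate_cohort(study_config(seed=17))


@pytest.fixture(scope="session")
def corrupted_bundle():
    """Cohort with recorded low-DP/GQ/AB corruption for QC two-path checks."""
    return simulate_cohort(SyntheticConfig(
        seed=23, corrupt_dp_rate=0.02, corrupt_gq_rate=0.02, corrupt_ab_rate=0.02))
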