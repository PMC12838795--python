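"""Genotype masking, biallelic splitting/trimming, and missingness filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rvpathrx.genotype_qc import (QcThresholds, drop_high_missingness_variants,
                                  mask_low_quality_genotypes, run_qc,
                                  split_and_trim_alleles, _trim_alleles)
from .conftest import build_cohort


def single_variant_cohort(gt_pairs, dp, gq, ad):
    samples = [f"S{i}" for i in range(len(gt_pairs))]
    a1 = [[p[0] for p in gt_pairs]]
    a2 = [[p[1] for p in gt_pairs]]
    return build_cohort(samples, [("1", 100, "A", ("G",))], a1, a2,
                        dp=[dp], gq=[gq], ad=[ad])


class TestMasking:
    def test_low_depth_het_masked(self):
        cv = single_variant_cohort([(0, 1)], dp=[19], gq=[60], ad=[[15, 15]])
        out = mask_low_quality_genotypes(cv, QcThresholds())
        assert out.gt_labels()[0, 0] == "missing"

    def test_low_allele_balance_masks_het_only(self):
        # ab = 6/40 = 0.15 for both calls; only the het is masked
        cv = build_cohort(["S1", "S2"], [("1", 100, "A", ("G",))],
                          a1=[[0, 1]], a2=[[1, 1]],
                          dp=[[40, 40]], gq=[[60, 60]], ad=[[[34, 6], [34, 6]]])
        out = mask_low_quality_genotypes(cv, QcThresholds())
        assert out.gt_labels()[0].tolist() == ["missing", "hom_alt"]

    def test_boundaries_are_strict(self):
        cv = single_variant_cohort([(0, 1)], dp=[20], gq=[20], ad=[[32, 8]])  # ab = 0.2
        out = mask_low_quality_genotypes(cv, QcThresholds())
        assert out.gt_labels()[0, 0] == "het"

    def test_absent_fields_skip_subfilter(self):
        cv = single_variant_cohort([(0, 1)], dp=[-1], gq=[-1], ad=[[-1, -1]])
        out = mask_low_quality_genotypes(cv, QcThresholds())
        assert out.gt_labels()[0, 0] == "het"

    def test_zero_total_reads_het_masked(self):
        cv = single_variant_cohort([(0, 1)], dp=[40], gq=[60], ad=[[0, 0]])
        out = mask_low_quality_genotypes(cv, QcThresholds())
        assert out.gt_labels()[0, 0] == "missing"

    def test_idempotent_and_value_preserving(self, corrupted_bundle):
        cv = corrupted_bundle.cv
        once = mask_low_quality_genotypes(cv)
        twice = mask_low_quality_genotypes(once)
        np.testing.assert_array_equal(once.a1, twice.a1)
        np.testing.assert_array_equal(once.a2, twice.a2)
        # surviving genotypes keep their original value
        kept = (once.a1 >= 0)
        np.testing.assert_array_equal(once.a1[kept], cv.a1[kept])
        np.testing.assert_array_equal(once.a2[kept], cv.a2[kept])

    def test_masked_set_equals_injected_corruption(self, corrupted_bundle):
        """Two-path check: the generator's corrupted calls are exactly the
        calls QC masks at default thresholds."""
        cv = corrupted_bundle.cv
        masked = mask_low_quality_genotypes(cv)
        got = {(i, cv.samples[j])
               for i, j in zip(*np.where((masked.a1 < 0) & (cv.a1 >= 0)))}
        truth = corrupted_bundle.truth.corrupted_calls
        expected = set(zip(truth["variant_index"], truth["sample_id"]))
        assert got == expected

    def test_extreme_threshold_masks_every_call(self, null_bundle):
        out = mask_low_quality_genotypes(null_bundle.cv, QcThresholds(min_dp=10_000))
        assert (out.a1 < 0).all()


class TestSplitTrim:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (100, "AT", "AG", (101, "T", "G")),
        (100, "AT", "A", (100, "AT", "A")),
        (100, "A", "A", (100, "A", "A")),   # degenerate, untouched
        (100, "CAG", "CTG", (101, "A", "T")),
        (100, "GCC", "GC", (100, "GC", "G")),  # suffix then prefix
    ])
    def test_trim_rules(self, pos, ref, alt, expected):
        assert _trim_alleles(pos, ref, alt) == expected

    def test_multiallelic_split(self):
        cv = build_cohort(["S1"], [("1", 100, "AT", ("AG", "A"))],
                          a1=[[1]], a2=[[2]],
                          dp=[[50]], gq=[[80]], ad=[[[10, 20, 20]]])
        out = split_and_trim_alleles(cv)
        assert out.n_variants == 2
        assert (out.variants.loc[0, "pos"], out.variants.loc[0, "ref"],
                out.variants.loc[0, "alts"]) == (101, "T", ("G",))
        assert (out.variants.loc[1, "pos"], out.variants.loc[1, "ref"],
                out.variants.loc[1, "alts"]) == (100, "AT", ("A",))
        # GT 1/2 becomes het against each alt
        assert out.gt_labels()[0, 0] == "het"
        assert out.gt_labels()[1, 0] == "het"
        # AD collapses to the (ref, that-alt) pair
        assert out.ad[0, 0].tolist() == [10, 20]

    @pytest.mark.parametrize("pair,expected_alt1,expected_alt2", [
        ((0, 0), "hom_ref", "hom_ref"),
        ((0, 1), "het", "hom_ref"),
        ((1, 1), "hom_alt", "hom_ref"),
        ((0, 2), "hom_ref", "het"),
        ((1, 2), "het", "het"),
        ((2, 2), "hom_ref", "hom_alt"),
        ((-1, -1), "missing", "missing"),
    ])
    def test_recoding_over_genotype_grid(self, pair, expected_alt1, expected_alt2):
        cv = build_cohort(["S1"], [("1", 100, "A", ("C", "G"))],
                          a1=[[pair[0]]], a2=[[pair[1]]])
        out = split_and_trim_alleles(cv)
        assert out.gt_labels()[0, 0] == expected_alt1
        assert out.gt_labels()[1, 0] == expected_alt2

    def test_biallelic_snv_unchanged(self, null_bundle):
        cv = null_bundle.cv
        out = split_and_trim_alleles(cv)
        assert out.n_variants == cv.n_variants
        np.testing.assert_array_equal(out.gt_codes(), cv.gt_codes())

    def test_record_count_identity(self):
        rows = [("1", 100, "A", ("C",)), ("1", 200, "A", ("C", "G")),
                ("1", 300, "A", ("C", "G", "T"))]
        cv = build_cohort(["S1"], rows, a1=[[0]] * 3, a2=[[1]] * 3)
        out = split_and_trim_alleles(cv)
        assert out.n_variants == sum(len(r[3]) for r in rows)


class TestMissingness:
    def _cohort_with_missing(self, n_missing, n=63):
        a1 = [[-1] * n_missing + [0] * (n - n_missing)]
        a2 = [[-1] * n_missing + [1] * (n - n_missing)]
        return build_cohort([f"S{i}" for i in range(n)],
                            [("1", 100, "A", ("G",))], a1, a2)

    def test_above_bound_dropped(self):
        out, rep = drop_high_missingness_variants(self._cohort_with_missing(4))
        assert out.n_variants == 0 and rep.n_after_missingness == 0

    def test_below_bound_kept(self):
        out, _ = drop_high_missingness_variants(self._cohort_with_missing(3))
        assert out.n_variants == 1

    def test_complete_variant_always_kept(self):
        out, _ = drop_high_missingness_variants(
            self._cohort_with_missing(0), QcThresholds(max_missing_fraction=0.0))
        assert out.n_variants == 1

    def test_zero_samples_error(self):
        cv = build_cohort([], [], np.empty((0, 0)), np.empty((0, 0)),
                          dp=np.empty((0, 0)), gq=np.empty((0, 0)),
                          ad=np.empty((0, 0, 2)))
        with pytest.raises(ValueError, match="zero samples"):
            drop_high_missingness_variants(cv)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
       alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
       pos=st.integers(min_value=1, max_value=10_000))
def test_trimming_is_idempotent_and_shifts_position_by_prefix(ref, alt, pos):
    new_pos, r, a = _trim_alleles(pos, ref, alt)
    assert len(r) >= 1 and len(a) >= 1
    # position advances exactly by the number of removed prefix bases
    assert ref[new_pos - pos:] .startswith(r[0])
    assert 0 <= new_pos - pos <= len(ref) - len(r)
    assert _trim_alleles(new_pos, r, a) == (new_pos, r, a)


def test_qc_funnel_counts_monotone(corrupted_bundle):
    out, rep = run_qc(corrupted_bundle.cv)
    assert rep.n_input_variants >= rep.n_after_split >= rep.n_after_missingness
    assert rep.n_after_missingness == out.n_variants
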