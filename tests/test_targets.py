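import logging
import math

import pytest
from hypothesis import given, strategies as st

import tftargets as tt
from tftargets.records import (
    F3T_IN,
    F3T_IN_KD,
    NON_TARGET,
    GeneRecord,
    PeakRecord,
    RegulationRecord,
    ValidationError,
)
from tftargets.targets import (
    CallThresholds,
    assign_peaks_to_genes,
    call_targets,
    refine_with_knockdown,
)

from _oracles import per_base_bound_oracle


def gene(gene_id="g1", chrom="chr1", tss=100_000, strand="+"):
    return GeneRecord(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss)


def peak(chrom="chr1", start=0, end=100, score=1.0, cond="c"):
    return PeakRecord(chrom=chrom, start=start, end=end, score=score,
                      condition_id=cond)


def de(gene_id, log2fc, padj, pvalue=None, contrast="ind"):
    if pvalue is None:
        pvalue = 0.0 if math.isnan(padj) else padj
    return RegulationRecord(gene_id=gene_id, contrast_id=contrast,
                            log2fc=log2fc, pvalue=pvalue, padj=padj)


# ---------------------------------------------------------------------------
# window assignment


def test_peak_within_20kb_window_marks_gene_bound():
    binding = assign_peaks_to_genes(
        [peak(start=80_500, end=80_600)], [gene(tss=100_000)], window=20_000)
    assert binding.bound("g1")


@pytest.mark.parametrize("start, end, expect", [
    (70_000, 70_010, True),    # peak start exactly at tss + W
    (70_001, 70_011, False),   # one base past the window
    (29_990, 30_000, False),   # half-open peak ends at the window start
    (29_991, 30_001, True),    # last peak base is the window start
])
def test_window_boundaries_inclusive_at_tss_plus_minus_w(start, end, expect):
    binding = assign_peaks_to_genes(
        [peak(start=start, end=end)], [gene(tss=50_000)], window=20_000)
    assert binding.bound("g1") is expect


def test_window_clamped_at_chromosome_start():
    binding = assign_peaks_to_genes(
        [peak(start=0, end=10)], [gene(tss=5_000)], window=20_000)
    assert binding.bound("g1")


def test_no_peaks_leaves_every_gene_unbound():
    genes = [gene("g1", tss=1000), gene("g2", tss=2000)]
    binding = assign_peaks_to_genes([], genes, window=500, condition_id="c")
    assert binding.bound_genes() == set()
    assert binding.max_peak_score("g1") is None


def test_one_peak_can_be_assigned_to_multiple_genes():
    genes = [gene("g1", tss=10_000), gene("g2", tss=11_000)]
    binding = assign_peaks_to_genes([peak(start=10_400, end=10_500)], genes,
                                    window=1_000)
    assert binding.bound_genes() == {"g1", "g2"}


def test_max_peak_score_is_maximum_over_assigned_peaks():
    binding = assign_peaks_to_genes(
        [peak(start=900, end=950, score=3.0), peak(start=1100, end=1150, score=8.5)],
        [gene(tss=1_000)], window=500)
    assert binding.max_peak_score("g1") == 8.5


def test_unknown_chromosome_peaks_are_skipped_and_counted(caplog):
    with caplog.at_level(logging.WARNING):
        binding = assign_peaks_to_genes(
            [peak(chrom="chrUn", start=0, end=10)], [gene(tss=1000)],
            window=500, condition_id="c")
    assert binding.n_skipped_peaks == 1
    assert binding.skipped_chroms == ("chrUn",)
    assert "ignored" in caplog.text


def test_assignment_matches_per_base_oracle_on_random_instance():
    import numpy as np

    rng = np.random.default_rng(42)
    W = 1_000
    genes = [gene(f"g{i}", chrom=f"chr{rng.integers(1, 4)}",
                  tss=int(rng.integers(0, 30_000)))
             for i in range(60)]
    peaks = []
    for i in range(80):
        start = int(rng.integers(0, 30_000))
        peaks.append(peak(chrom=f"chr{rng.integers(1, 4)}", start=start,
                          end=start + int(rng.integers(1, 60))))
    binding = assign_peaks_to_genes(peaks, genes, window=W, condition_id="c")
    oracle = per_base_bound_oracle(genes, peaks, W)
    assert {g.gene_id: binding.bound(g.gene_id) for g in genes} == oracle


@given(st.integers(min_value=0, max_value=3_000),
       st.integers(min_value=0, max_value=3_000),
       st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 300)),
                max_size=25))
def test_bound_set_is_monotone_in_window_width(w1, w2, raw_peaks):
    """Widening the window can only add bound genes, never remove them."""
    w1, w2 = min(w1, w2), max(w1, w2)
    genes = [gene("g1", tss=5_000), gene("g2", tss=7_500)]
    peaks = [peak(start=s, end=s + l) for s, l in raw_peaks]
    b1 = assign_peaks_to_genes(peaks, genes, window=w1, condition_id="c")
    b2 = assign_peaks_to_genes(peaks, genes, window=w2, condition_id="c")
    assert b1.bound_genes() <= b2.bound_genes()


@given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 300)),
                max_size=25))
def test_bound_set_is_strand_symmetric(raw_peaks):
    peaks = [peak(start=s, end=s + l) for s, l in raw_peaks]
    plus = [gene("g1", tss=5_000, strand="+"), gene("g2", tss=7_500, strand="+")]
    minus = [gene("g1", tss=5_000, strand="-"), gene("g2", tss=7_500, strand="-")]
    b_plus = assign_peaks_to_genes(peaks, plus, window=1_500, condition_id="c")
    b_minus = assign_peaks_to_genes(peaks, minus, window=1_500, condition_id="c")
    assert b_plus.bound_genes() == b_minus.bound_genes()


def test_negative_window_rejected():
    with pytest.raises(ValidationError):
        assign_peaks_to_genes([], [gene()], window=-1, condition_id="c")


# ---------------------------------------------------------------------------
# target calling


def _binding_for(genes, peaks, window=20_000):
    return assign_peaks_to_genes(peaks, genes, window=window, condition_id="c")


def test_unbound_gene_is_never_a_target_even_if_regulated():
    binding = _binding_for([gene(tss=100_000)], [])
    (st_,) = call_targets(binding, [de("g1", 1.2, 0.01)])
    assert st_.target_class == NON_TARGET and st_.direction == "up"


def test_bound_and_significant_gene_is_induction_target():
    binding = _binding_for([gene(tss=100_000)], [peak(start=99_000, end=99_200)])
    (st_,) = call_targets(binding, [de("g1", 1.2, 0.01)])
    assert st_.target_class == F3T_IN
    assert st_.direction == "up" and st_.bound


def test_bound_but_insignificant_gene_is_non_target():
    binding = _binding_for([gene(tss=100_000)], [peak(start=99_000, end=99_200)])
    (st_,) = call_targets(binding, [de("g1", 1.2, 0.20)])
    assert st_.target_class == NON_TARGET and st_.direction == "none"


@pytest.mark.parametrize("log2fc, padj, lfc_min, expect", [
    (-0.8, 0.01, 0.0, "down"),
    (0.0, 0.01, 0.0, "none"),      # zero fold change is never a direction
    (0.5, 0.01, 1.0, "none"),      # below the fold-change floor
    (1.5, 0.01, 1.0, "up"),
    (1.5, float("nan"), 0.0, "none"),  # missing padj is non-significant
])
def test_regulation_direction_rules(log2fc, padj, lfc_min, expect):
    binding = _binding_for([gene(tss=100_000)], [peak(start=99_000, end=99_200)])
    (st_,) = call_targets(binding, [de("g1", log2fc, padj)],
                          CallThresholds(lfc_min=lfc_min))
    assert st_.direction == expect


def test_gene_missing_from_de_table_is_not_regulated():
    binding = _binding_for([gene(tss=100_000)], [peak(start=99_000, end=99_200)])
    (st_,) = call_targets(binding, [])
    assert st_.direction == "none" and st_.target_class == NON_TARGET


# ---------------------------------------------------------------------------
# knockdown refinement


def _f3t_in_statuses():
    binding = _binding_for([gene(tss=100_000)], [peak(start=99_000, end=99_200)])
    return call_targets(binding, [de("g1", 1.2, 0.01)])


def test_knockdown_promotes_induction_target():
    refined = refine_with_knockdown(_f3t_in_statuses(), [de("g1", -0.5, 0.01)])
    assert refined[0].target_class == F3T_IN_KD
    assert refined[0].kd_regulated


def test_knockdown_never_promotes_non_targets():
    binding = _binding_for([gene(tss=100_000)], [])
    statuses = call_targets(binding, [de("g1", 1.2, 0.01)])
    refined = refine_with_knockdown(statuses, [de("g1", -2.0, 0.001)])
    assert refined[0].target_class == NON_TARGET


def test_anticorrelation_flag_blocks_same_sign_knockdown():
    th = CallThresholds(require_kd_anticorrelation=True)
    same = refine_with_knockdown(_f3t_in_statuses(), [de("g1", 0.8, 0.01)], th)
    assert same[0].target_class == F3T_IN
    opposite = refine_with_knockdown(_f3t_in_statuses(), [de("g1", -0.8, 0.01)], th)
    assert opposite[0].target_class == F3T_IN_KD


def test_insignificant_knockdown_leaves_status_unchanged():
    refined = refine_with_knockdown(_f3t_in_statuses(), [de("g1", -0.5, 0.5)])
    assert refined[0].target_class == F3T_IN and not refined[0].kd_regulated


def test_kd_class_is_subset_of_induction_class(small_noisy_dataset):
    """Every knockdown-supported target must also be an induction target."""
    from tftargets.pipeline import analyze_dataset

    res = analyze_dataset(small_noisy_dataset)
    for statuses in res.statuses_by_condition.values():
        kd = {s.gene_id for s in statuses if s.target_class == F3T_IN_KD}
        ind_called = {s.gene_id for s in statuses if s.is_target}
        assert kd <= ind_called


# ---------------------------------------------------------------------------
# thresholds validation


@pytest.mark.parametrize("kwargs", [
    {"alpha": 0.0}, {"alpha": 1.5}, {"lfc_min": -0.1},
])
def test_invalid_thresholds_rejected(kwargs):
    with pytest.raises(ValidationError):
        CallThresholds(**kwargs)
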