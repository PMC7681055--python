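import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tftargets as tt
from tftargets.records import ValidationError
from tftargets.reprogramming import (
    ConditionDesign,
    classify_reprogramming,
    occupancy_stats,
    proportion_test_pairwise,
    score_distribution_test,
    two_proportion_chisq,
    venn_summary,
)

from _oracles import (
    fate_oracle,
    pearson_2x2_oracle,
    yates_two_prop_oracle,
)
from conftest import make_status

DESIGN = ConditionDesign()
CONDS = DESIGN.all_conditions


def statuses_for_pattern(m_ctrl, m_dis, m_kd, d_ctrl="up", d_dis="up",
                         d_kd="up", m_ctrl_kd=False):
    """One-gene status set across the four conditions."""
    return {
        DESIGN.control_scramble: [make_status("g", DESIGN.control_scramble,
                                              m_ctrl, d_ctrl)],
        DESIGN.control_kd: [make_status("g", DESIGN.control_kd, m_ctrl_kd)],
        DESIGN.disease_scramble: [make_status("g", DESIGN.disease_scramble,
                                              m_dis, d_dis)],
        DESIGN.disease_kd: [make_status("g", DESIGN.disease_kd, m_kd, d_kd)],
    }


# ---------------------------------------------------------------------------
# fate classification


def test_lost_target_restored_by_modifier_silencing_is_dependent():
    """Losing a control target in disease and regaining it under modifier
    knockdown means the modifier drives the loss."""
    statuses = statuses_for_pattern(True, False, True)
    (call,) = classify_reprogramming(statuses, DESIGN)
    assert call.fate == tt.LOST
    assert call.modifier_dependence == tt.DEPENDENT


def test_gene_absent_everywhere_is_never_target():
    (call,) = classify_reprogramming(statuses_for_pattern(False, False, False),
                                     DESIGN)
    assert call.fate == tt.NEVER
    assert call.modifier_dependence == tt.NOT_APPLICABLE


@pytest.mark.parametrize("pattern", list(itertools.product([False, True],
                                                           repeat=3)))
@pytest.mark.parametrize("strict", [False, True])
@pytest.mark.parametrize("d_kd", ["up", "down"])
def test_all_membership_patterns_match_truth_table_oracle(pattern, strict, d_kd):
    m_ctrl, m_dis, m_kd = pattern
    d_ctrl = "up" if m_ctrl else "none"
    d_dis = "up" if m_dis else "none"
    d_kd_eff = d_kd if m_kd else "none"
    statuses = statuses_for_pattern(m_ctrl, m_dis, m_kd, d_ctrl, d_dis,
                                    d_kd_eff)
    (call,) = classify_reprogramming(statuses, DESIGN, strict_direction=strict)
    fate, dependence = fate_oracle(m_ctrl, m_dis, m_kd, d_ctrl, d_dis,
                                   d_kd_eff, strict)
    assert (call.fate, call.modifier_dependence) == (fate, dependence)


@given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans(),
                          st.booleans(), st.booleans(), st.booleans()),
                min_size=1, max_size=30),
       st.booleans())
def test_classification_equals_oracle_on_random_gene_sets(rows, strict):
    statuses = {c: [] for c in CONDS}
    expected = {}
    for i, (m_ctrl, m_dis, m_kd, up_ctrl, up_dis, up_kd) in enumerate(rows):
        gid = f"g{i}"
        d_ctrl = ("up" if up_ctrl else "down") if m_ctrl else "none"
        d_dis = ("up" if up_dis else "down") if m_dis else "none"
        d_kd = ("up" if up_kd else "down") if m_kd else "none"
        statuses[DESIGN.control_scramble].append(
            make_status(gid, DESIGN.control_scramble, m_ctrl, d_ctrl))
        statuses[DESIGN.control_kd].append(
            make_status(gid, DESIGN.control_kd, False))
        statuses[DESIGN.disease_scramble].append(
            make_status(gid, DESIGN.disease_scramble, m_dis, d_dis))
        statuses[DESIGN.disease_kd].append(
            make_status(gid, DESIGN.disease_kd, m_kd, d_kd))
        expected[gid] = fate_oracle(m_ctrl, m_dis, m_kd, d_ctrl, d_dis, d_kd,
                                    strict)
    calls = classify_reprogramming(statuses, DESIGN, strict_direction=strict)
    assert len(calls) == len(rows)
    for call in calls:
        assert (call.fate, call.modifier_dependence) == expected[call.gene_id]
        if not strict and call.fate in (tt.LOST, tt.GAINED):
            assert call.modifier_dependence in (tt.DEPENDENT, tt.INDEPENDENT)


def test_direction_concordance_reported_for_conserved_genes():
    concordant = statuses_for_pattern(True, True, True, "up", "up")
    (call,) = classify_reprogramming(concordant, DESIGN)
    assert call.fate == tt.CONSERVED and call.direction_concordant is True
    flipped = statuses_for_pattern(True, True, True, "up", "down")
    (call,) = classify_reprogramming(flipped, DESIGN)
    assert call.direction_concordant is False


def test_gene_missing_a_condition_raises_naming_gene_and_condition():
    statuses = statuses_for_pattern(True, True, True)
    statuses[DESIGN.disease_kd] = []
    with pytest.raises(ValidationError, match="'g'.*disease_kd"):
        classify_reprogramming(statuses, DESIGN)


def test_strict_direction_mismatch_falls_to_unresolved():
    # gained gene, modifier-kd member with flipped direction
    statuses = statuses_for_pattern(False, True, True, "none", "up", "down")
    (call,) = classify_reprogramming(statuses, DESIGN, strict_direction=True)
    assert call.fate == tt.GAINED
    assert call.modifier_dependence == tt.UNRESOLVED


# ---------------------------------------------------------------------------
# Venn summary


def test_venn_summary_of_zero_genes_is_all_zero():
    statuses = {c: [] for c in CONDS}
    summary = venn_summary([], statuses, DESIGN)
    assert summary.n_conserved == summary.n_lost == summary.n_gained == 0
    assert all(v == 0 for v in summary.n_targets.values())


def test_printed_partition_satisfies_venn_identities():
    """The reference partition is internally consistent: 82 + 137 = 219
    control targets and 82 + 190 = 272 disease targets."""
    assert 82 + 137 == 219
    assert 82 + 190 == 272


def test_venn_identities_hold_on_noisy_dataset(small_noisy_dataset):
    from tftargets.pipeline import analyze_dataset

    res = analyze_dataset(small_noisy_dataset)
    v = res.venn
    assert v.n_targets[DESIGN.control_scramble] == v.n_conserved + v.n_lost
    assert v.n_targets[DESIGN.disease_scramble] == v.n_conserved + v.n_gained
    assert v.n_lost + v.n_gained == (v.n_modifier_dependent +
                                     v.n_modifier_independent + v.n_unresolved)


# ---------------------------------------------------------------------------
# pairwise proportion tests


def test_identical_proportions_give_zero_statistic_and_p_one():
    stat, p = two_proportion_chisq(30, 100, 30, 100)
    assert stat == 0.0 and p == 1.0


def test_two_proportion_chisq_matches_textbook_oracle():
    stat, p = two_proportion_chisq(30, 100, 60, 100)
    o_stat, o_p = yates_two_prop_oracle(30, 100, 60, 100)
    assert stat == pytest.approx(o_stat, rel=1e-12)
    assert p == pytest.approx(o_p, rel=1e-12)


@given(st.integers(1, 200), st.integers(1, 200),
       st.integers(0, 200), st.integers(0, 200))
def test_two_proportion_chisq_equals_oracle_on_random_tables(n1, n2, k1, k2):
    k1, k2 = min(k1, n1), min(k2, n2)
    stat, p = two_proportion_chisq(k1, n1, k2, n2)
    o_stat, o_p = yates_two_prop_oracle(k1, n1, k2, n2)
    assert stat == pytest.approx(o_stat, rel=1e-9, abs=1e-12)
    assert p == pytest.approx(o_p, rel=1e-9, abs=1e-12)


def test_count_exceeding_total_raises():
    with pytest.raises(ValidationError):
        two_proportion_chisq(101, 100, 5, 100)
    with pytest.raises(ValidationError):
        two_proportion_chisq(0, 0, 5, 100)


def test_pairwise_proportions_cover_all_six_pairs_with_holm():
    counts = {"a": (30, 100), "b": (60, 100), "c": (30, 100), "d": (90, 100)}
    df = proportion_test_pairwise(counts)
    assert len(df) == 6
    # Holm-adjusted p-values are monotone when raw p-values are sorted
    s = df.sort_values("pvalue")
    assert (np.diff(s["padj_holm"].to_numpy()) >= -1e-15).all()
    assert ((df["padj_holm"] >= df["pvalue"] - 1e-15)).all()


# ---------------------------------------------------------------------------
# score distribution tests


def test_identical_score_vectors_give_zero_statistic_and_p_one():
    v = np.linspace(1, 50, 200)
    res = score_distribution_test({"a": v, "b": v.copy()})
    assert res.global_statistic == pytest.approx(0.0)
    assert res.global_pvalue == pytest.approx(1.0)


def test_two_bin_test_reduces_to_closed_form_2x2_chisq():
    rng = np.random.default_rng(3)
    a = rng.gamma(2.0, 1.0, size=300)
    b = rng.gamma(2.0, 1.6, size=260)
    res = score_distribution_test({"a": a, "b": b}, n_bins=2)
    median = np.quantile(np.concatenate([a, b]), 0.5)
    a_lo = int((a < median).sum())
    b_lo = int((b < median).sum())
    stat, p = pearson_2x2_oracle(a_lo, len(a) - a_lo, b_lo, len(b) - b_lo)
    assert res.global_statistic == pytest.approx(stat, rel=1e-12)
    assert res.global_pvalue == pytest.approx(p, rel=1e-12)


def test_fewer_observations_than_bins_raises():
    with pytest.raises(ValidationError, match="fewer"):
        score_distribution_test({"a": [1.0] * 5, "b": [2.0] * 20}, n_bins=10)


def test_shifted_gamma_scale_is_detected_across_seeds():
    """A scale shift between two gamma samples (n = 2,000) must be rejected
    at p < 0.01 for every seed."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        res = score_distribution_test({
            "a": rng.gamma(2.0, 1.0, size=2_000),
            "b": rng.gamma(2.0, 1.3, size=2_000)})
        assert res.global_pvalue < 0.01


def test_low_expected_counts_emit_warning():
    rng = np.random.default_rng(0)
    with pytest.warns(UserWarning, match="expected"):
        score_distribution_test({"a": rng.gamma(2, 1, 12),
                                 "b": rng.gamma(2, 1, 12)}, n_bins=10)


def test_duplicate_quantile_edges_are_merged():
    # heavily tied data collapses several decile edges
    a = np.array([1.0] * 150 + [2.0] * 50)
    b = np.array([1.0] * 100 + [2.0] * 100)
    res = score_distribution_test({"a": a, "b": b}, n_bins=10)
    assert len(res.bin_edges) - 1 <= 2
    assert 0.0 <= res.global_pvalue <= 1.0


# ---------------------------------------------------------------------------
# occupancy statistics assembly


def test_occupancy_stats_counts_regulated_genes_and_their_binding(
        small_noiseless_dataset):
    from tftargets.pipeline import analyze_dataset

    res = analyze_dataset(small_noiseless_dataset)
    occ = res.occupancy
    for cond, statuses in res.statuses_by_condition.items():
        de = [s for s in statuses if s.direction != "none"]
        assert occ.bound_counts[cond] == (sum(s.bound for s in de), len(de))
    assert len(occ.proportion_tests) == 6
    assert 0.0 <= occ.score_test.global_pvalue <= 1.0
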