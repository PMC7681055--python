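"""Target-fate classification across the genotype x modifier design.

The design crosses genotype (control vs disease) with a modifier siRNA
treatment (scramble vs modifier knockdown), giving four conditions. A gene's
*fate* compares its target membership between the two scramble conditions:

    conserved          member in both scramble conditions
    lost_in_disease    member in control only
    gained_in_disease  member in disease only
    never_target       member in neither

For lost/gained genes, the disease + modifier-knockdown condition decides
modifier dependence: *dependent* when silencing the modifier corrects the
disease status back to the control status, *independent* when the disease
status persists. The control + modifier-knockdown condition is summarised as
a target count but does not enter fate or dependence.

The module also computes the occupancy statistics over the regulated genes:
pairwise two-sample proportion chi-square tests (continuity-corrected,
Holm-adjusted, matching R's pairwise.prop.test) on the bound fraction, and
Pearson chi-square tests on binned peak-score distributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    CONSERVED,
    DEPENDENT,
    GAINED,
    INDEPENDENT,
    LOST,
    NEVER,
    NOT_APPLICABLE,
    UNRESOLVED,
    ReprogrammingCall,
    TargetStatus,
    ValidationError,
)
from .setstats import holm_adjust


@dataclass(frozen=True)
class ConditionDesign:
    """The four condition ids of the genotype x treatment design."""

    control_scramble: str = "control_scramble"
    control_kd: str = "control_kd"
    disease_scramble: str = "disease_scramble"
    disease_kd: str = "disease_kd"

    def __post_init__(self):
        ids = self.all_conditions
        if len(set(ids)) != 4:
            raise ValidationError(f"condition ids must be distinct, got {ids}")

    @property
    def all_conditions(self) -> tuple[str, str, str, str]:
        return (self.control_scramble, self.control_kd,
                self.disease_scramble, self.disease_kd)

    @property
    def reference(self) -> str:
        return self.control_scramble


def _index_statuses(statuses_by_condition: Mapping[str, Iterable[TargetStatus]]
                    ) -> dict[str, dict[str, TargetStatus]]:
    indexed: dict[str, dict[str, TargetStatus]] = {}
    for cond, statuses in statuses_by_condition.items():
        by_gene: dict[str, TargetStatus] = {}
        for st in statuses:
            if st.gene_id in by_gene:
                raise ValidationError(
                    f"duplicate status for gene {st.gene_id!r} in "
                    f"condition {cond!r}")
            by_gene[st.gene_id] = st
        indexed[cond] = by_gene
    return indexed


def classify_reprogramming(
        statuses_by_condition: Mapping[str, Iterable[TargetStatus]],
        design: Optional[ConditionDesign] = None,
        strict_direction: bool = False) -> list[ReprogrammingCall]:
    """Classify every gene's fate and modifier dependence.

    Parameters
    ----------
    statuses_by_condition : mapping condition_id -> statuses
        Must contain all four design conditions and every gene in each.
    strict_direction : bool
        When True, a membership match for the dependence call additionally
        requires the regulation direction to match; direction mismatches
        fall to "unresolved". With the default False, dependence is always
        resolved for lost/gained genes.
    """
    design = design or ConditionDesign()
    indexed = _index_statuses(statuses_by_condition)
    for cond in design.all_conditions:
        if cond not in indexed:
            raise ValidationError(f"missing condition {cond!r}")
    universe: set[str] = set()
    for by_gene in indexed.values():
        universe |= set(by_gene)
    for cond in design.all_conditions:
        for gene_id in universe:
            if gene_id not in indexed[cond]:
                raise ValidationError(
                    f"gene {gene_id!r} has no status in condition {cond!r}")

    ctrl = indexed[design.control_scramble]
    dis = indexed[design.disease_scramble]
    dis_kd = indexed[design.disease_kd]

    calls: list[ReprogrammingCall] = []
    for gene_id in sorted(universe):
        s_ctrl, s_dis, s_kd = ctrl[gene_id], dis[gene_id], dis_kd[gene_id]
        m_ctrl, m_dis, m_kd = s_ctrl.is_target, s_dis.is_target, s_kd.is_target
        if m_ctrl and m_dis:
            calls.append(ReprogrammingCall(
                gene_id=gene_id, fate=CONSERVED,
                modifier_dependence=NOT_APPLICABLE,
                direction_concordant=(s_ctrl.direction == s_dis.direction)))
            continue
        if not m_ctrl and not m_dis:
            calls.append(ReprogrammingCall(
                gene_id=gene_id, fate=NEVER,
                modifier_dependence=NOT_APPLICABLE))
            continue
        fate = LOST if m_ctrl else GAINED
        # the two scramble baselines differ, so m_kd matches exactly one
        dependence = DEPENDENT if m_kd == m_ctrl else INDEPENDENT
        if strict_direction and m_kd:
            # membership match against a member baseline also needs direction
            ref = s_ctrl if dependence == DEPENDENT else s_dis
            if ref.is_target and s_kd.direction != ref.direction:
                dependence = UNRESOLVED
        calls.append(ReprogrammingCall(gene_id=gene_id, fate=fate,
                                       modifier_dependence=dependence))
    return calls


def calls_to_frame(calls: Iterable[ReprogrammingCall]) -> pd.DataFrame:
    rows = [{
        "gene_id": c.gene_id,
        "fate": c.fate,
        "modifier_dependence": c.modifier_dependence,
        "direction_concordant": c.direction_concordant,
    } for c in calls]
    return pd.DataFrame(rows, columns=["gene_id", "fate",
                                       "modifier_dependence",
                                       "direction_concordant"])


# ---------------------------------------------------------------------------
# Venn partition summary


@dataclass
class VennSummary:
    """Counts of the four-condition target partition.

    Construction enforces the partition identities:
    n_targets(control, scramble) = conserved + lost;
    n_targets(disease, scramble) = conserved + gained;
    lost + gained = dependent + independent + unresolved.
    """

    n_targets: dict[str, int]
    n_conserved: int
    n_lost: int
    n_gained: int
    n_never: int
    n_modifier_dependent: int
    n_modifier_independent: int
    n_unresolved: int
    design: ConditionDesign = field(default_factory=ConditionDesign)

    def __post_init__(self):
        if self.n_targets[self.design.control_scramble] != \
                self.n_conserved + self.n_lost:
            raise ValidationError(
                "partition identity violated: n_targets(control, scramble) "
                "!= conserved + lost")
        if self.n_targets[self.design.disease_scramble] != \
                self.n_conserved + self.n_gained:
            raise ValidationError(
                "partition identity violated: n_targets(disease, scramble) "
                "!= conserved + gained")
        if self.n_lost + self.n_gained != (self.n_modifier_dependent +
                                           self.n_modifier_independent +
                                           self.n_unresolved):
            raise ValidationError(
                "partition identity violated: lost + gained != dependent + "
                "independent + unresolved")

    def to_dict(self) -> dict:
        return {
            "n_targets": dict(self.n_targets),
            "n_conserved": self.n_conserved,
            "n_lost": self.n_lost,
            "n_gained": self.n_gained,
            "n_never": self.n_never,
            "n_modifier_dependent": self.n_modifier_dependent,
            "n_modifier_independent": self.n_modifier_independent,
            "n_unresolved": self.n_unresolved,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def venn_summary(calls: Iterable[ReprogrammingCall],
                 statuses_by_condition: Mapping[str, Iterable[TargetStatus]],
                 design: Optional[ConditionDesign] = None) -> VennSummary:
    """Summarise fate calls and per-condition target counts."""
    design = design or ConditionDesign()
    indexed = _index_statuses(statuses_by_condition)
    n_targets = {cond: sum(st.is_target for st in indexed[cond].values())
                 for cond in design.all_conditions}
    calls = list(calls)
    fates = pd.Series([c.fate for c in calls]).value_counts()
    deps = pd.Series([c.modifier_dependence for c in calls]).value_counts()
    return VennSummary(
        n_targets=n_targets,
        n_conserved=int(fates.get(CONSERVED, 0)),
        n_lost=int(fates.get(LOST, 0)),
        n_gained=int(fates.get(GAINED, 0)),
        n_never=int(fates.get(NEVER, 0)),
        n_modifier_dependent=int(deps.get(DEPENDENT, 0)),
        n_modifier_independent=int(deps.get(INDEPENDENT, 0)),
        n_unresolved=int(deps.get(UNRESOLVED, 0)),
        design=design)


# ---------------------------------------------------------------------------
# Occupancy statistics


def two_proportion_chisq(k1: int, n1: int, k2: int, n2: int,
                         correction: bool = True) -> tuple[float, float]:
    """Two-sample proportion chi-square test with continuity correction.

    Matches R's ``prop.test(c(k1, k2), c(n1, n2))``: the Yates correction is
    clamped at |observed - expected| so the statistic never goes negative.
    Returns (statistic, p-value) with 1 degree of freedom.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValidationError(f"group size must be > 0, got {n}")
        if k < 0 or k > n:
            raise ValidationError(f"count k={k} outside [0, n={n}]")
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n1 * p_pool, n1 * (1 - p_pool),
                         n2 * p_pool, n2 * (1 - p_pool)])
    observed = np.array([k1, n1 - k1, k2, n2 - k2], dtype=float)
    dev = np.abs(observed - expected)
    yates = min(0.5, dev.min()) if correction else 0.0
    statistic = float((((dev - yates) ** 2) / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def proportion_test_pairwise(bound_counts: Mapping[str, tuple[int, int]],
                             correction: bool = True) -> pd.DataFrame:
    """All pairwise proportion tests across conditions, Holm-adjusted.

    ``bound_counts`` maps condition_id -> (k bound, n total). Returns a frame
    with one row per condition pair: statistic, raw p and Holm-adjusted p.
    """
    conds = list(bound_counts)
    rows = []
    for a, b in combinations(conds, 2):
        k1, n1 = bound_counts[a]
        k2, n2 = bound_counts[b]
        statistic, p = two_proportion_chisq(k1, n1, k2, n2, correction=correction)
        rows.append({"condition_a": a, "condition_b": b,
                     "statistic": statistic, "pvalue": p})
    df = pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                     "statistic", "pvalue"])
    df["padj_holm"] = holm_adjust(df["pvalue"].to_numpy()) if len(df) else []
    return df


@dataclass
class ScoreDistributionTest:
    """Chi-square comparison of binned peak-score distributions."""

    bin_edges: np.ndarray
    counts: pd.DataFrame  # conditions x bins
    global_statistic: float
    global_pvalue: float
    pairwise: pd.DataFrame  # condition_a, condition_b, statistic, pvalue, padj_holm
    low_expected_warning: bool = False


def _quantile_bins(pooled: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(pooled, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)  # merge empty pooled bins with neighbours
    if len(edges) < 2:
        raise ValidationError("scores are constant; cannot form bins")
    return edges


def _bin_counts(scores: Mapping[str, np.ndarray],
                edges: np.ndarray) -> pd.DataFrame:
    table = {}
    inner = edges[1:-1]
    n_bins = len(edges) - 1
    for cond, vec in scores.items():
        idx = np.searchsorted(inner, vec, side="right")
        table[cond] = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(table).T


def _chisq_on_table(counts: pd.DataFrame) -> tuple[float, float, bool]:
    obs = counts.to_numpy(dtype=float)
    obs = obs[:, obs.sum(axis=0) > 0]  # drop bins empty in every group
    statistic, p, _, expected = stats.chi2_contingency(obs, correction=False)
    low = bool((expected < 5).any())
    return float(statistic), float(p), low


def score_distribution_test(scores: Mapping[str, Sequence[float]],
                            n_bins: int = 10) -> ScoreDistributionTest:
    """Global and pairwise Pearson chi-square tests on score distributions.

    Scores are pooled across conditions and cut at the pooled quantiles
    (deciles by default); the per-condition bin counts form an R x C table
    tested by Pearson chi-square. Pairwise comparisons re-pool and re-bin
    each pair; their p-values are Holm-adjusted. Duplicated quantile edges
    (empty pooled bins) are merged, and a warning is emitted when any
    expected count is below 5.
    """
    arrays = {c: np.asarray(v, dtype=float) for c, v in scores.items()}
    for cond, vec in arrays.items():
        if len(vec) < n_bins:
            raise ValidationError(
                f"condition {cond!r} has {len(vec)} scores, fewer than "
                f"n_bins={n_bins}")
    pooled = np.concatenate(list(arrays.values()))
    edges = _quantile_bins(pooled, n_bins)
    counts = _bin_counts(arrays, edges)
    statistic, pvalue, low = _chisq_on_table(counts)

    rows = []
    for a, b in combinations(arrays, 2):
        pair_edges = _quantile_bins(np.concatenate([arrays[a], arrays[b]]),
                                    n_bins)
        pair_counts = _bin_counts({a: arrays[a], b: arrays[b]}, pair_edges)
        s, p, pair_low = _chisq_on_table(pair_counts)
        low = low or pair_low
        rows.append({"condition_a": a, "condition_b": b,
                     "statistic": s, "pvalue": p})
    pairwise = pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                           "statistic", "pvalue"])
    pairwise["padj_holm"] = (holm_adjust(pairwise["pvalue"].to_numpy())
                             if len(pairwise) else [])
    if low:
        warnings.warn("some expected bin counts are below 5; the chi-square "
                      "approximation may be inaccurate", stacklevel=2)
    return ScoreDistributionTest(bin_edges=edges, counts=counts,
                                 global_statistic=statistic,
                                 global_pvalue=pvalue, pairwise=pairwise,
                                 low_expected_warning=low)


@dataclass
class OccupancyStats:
    """Binding-occupancy statistics over the regulated genes per condition."""

    bound_counts: dict[str, tuple[int, int]]  # cond -> (bound DE, total DE)
    proportion_tests: pd.DataFrame
    score_test: ScoreDistributionTest

    def to_dict(self) -> dict:
        return {
            "bound_counts": {c: {"bound": k, "total": n}
                             for c, (k, n) in self.bound_counts.items()},
            "proportion_tests": self.proportion_tests.to_dict(orient="records"),
            "score_global_statistic": self.score_test.global_statistic,
            "score_global_pvalue": self.score_test.global_pvalue,
            "score_pairwise": self.score_test.pairwise.to_dict(orient="records"),
            "score_bin_edges": [float(x) for x in self.score_test.bin_edges],
            "low_expected_warning": self.score_test.low_expected_warning,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def occupancy_stats(statuses_by_condition: Mapping[str, Iterable[TargetStatus]],
                    n_bins: int = 10) -> OccupancyStats:
    """Compute occupancy statistics from per-condition target statuses.

    Per condition, the regulated (DE) genes are those with a significant
    induction direction; the proportion tests compare the bound fraction of
    those genes across conditions, and the score test compares the maximal
    assigned peak score of the bound, regulated genes.
    """
    indexed = _index_statuses(statuses_by_condition)
    bound_counts: dict[str, tuple[int, int]] = {}
    scores: dict[str, np.ndarray] = {}
    for cond, by_gene in indexed.items():
        de = [st for st in by_gene.values() if st.direction != "none"]
        k = sum(st.bound for st in de)
        bound_counts[cond] = (k, len(de))
        scores[cond] = np.array([st.max_peak_score for st in de
                                 if st.bound and st.max_peak_score is not None],
                                dtype=float)
    prop = proportion_test_pairwise(bound_counts)
    score_test = score_distribution_test(scores, n_bins=n_bins)
    return OccupancyStats(bound_counts=bound_counts, proportion_tests=prop,
                          score_test=score_test)
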