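"""Peak-to-gene window assignment and direct-target calling.

A gene is *bound* when at least one peak interval intersects the symmetric
window [max(0, tss - W), tss + W] (endpoints inclusive; peaks are 0-based
half-open). Direct targets are bound genes that are significantly up- or
down-regulated upon TF nuclear induction; knockdown differential expression
promotes them to the induction+knockdown class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from .records import (
    F3T_IN,
    F3T_IN_KD,
    NON_TARGET,
    GeneRecord,
    PeakRecord,
    RegulationRecord,
    TargetStatus,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20_000  # bp on each side of the TSS


@dataclass(frozen=True)
class CallThresholds:
    """Significance thresholds for the regulation side of a target call.

    alpha : adjusted-p cutoff (default 0.05).
    lfc_min : minimum |log2 fold change| (default 0, i.e. any significant
        change counts).
    require_kd_anticorrelation : if True, knockdown evidence must have the
        opposite fold-change sign to the induction direction.
    """

    alpha: float = 0.05
    lfc_min: float = 0.0
    require_kd_anticorrelation: bool = False

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lfc_min < 0:
            raise ValidationError(f"lfc_min must be >= 0, got {self.lfc_min}")


@dataclass
class BindingMap:
    """Per-condition mapping gene_id -> peaks intersecting its TSS window.

    Every annotated gene appears as a key (with an empty list when unbound),
    so downstream calling can iterate the full gene universe.
    """

    condition_id: str
    window: int
    peaks_by_gene: dict[str, list[PeakRecord]]
    n_skipped_peaks: int = 0
    skipped_chroms: tuple[str, ...] = ()

    def bound(self, gene_id: str) -> bool:
        return bool(self.peaks_by_gene[gene_id])

    def max_peak_score(self, gene_id: str) -> Optional[float]:
        peaks = self.peaks_by_gene[gene_id]
        return max(p.score for p in peaks) if peaks else None

    def bound_genes(self) -> set[str]:
        return {g for g, ps in self.peaks_by_gene.items() if ps}


def window_bounds(tss: int, window: int) -> tuple[int, int]:
    """Inclusive window endpoints around a TSS, clamped at 0."""
    return max(0, tss - window), tss + window


def assign_peaks_to_genes(peaks: Iterable[PeakRecord],
                          genes: Iterable[GeneRecord],
                          window: int = DEFAULT_WINDOW,
                          condition_id: Optional[str] = None) -> BindingMap:
    """Assign each peak to every gene whose TSS window it intersects.

    A half-open peak [start, end) intersects the inclusive window [lo, hi]
    iff start <= hi and end > lo. A peak may be assigned to multiple genes.
    Peaks on chromosomes absent from the annotation are skipped with a
    logged warning.
    """
    if window < 0:
        raise ValidationError(f"window must be >= 0, got {window}")
    genes = list(genes)
    peaks = list(peaks)
    if condition_id is None:
        conds = {p.condition_id for p in peaks}
        if len(conds) > 1:
            raise ValidationError(
                f"peaks span multiple conditions {sorted(conds)}; pass "
                "condition_id explicitly or split the peaks")
        condition_id = next(iter(conds)) if conds else ""

    trees: dict[str, IntervalTree] = {}
    gene_ids_seen: set[str] = set()
    for g in genes:
        if g.gene_id in gene_ids_seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in annotation")
        gene_ids_seen.add(g.gene_id)
        lo, hi = window_bounds(g.tss, window)
        # store as half-open [lo, hi + 1) so tree overlap == inclusive window
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g.gene_id)

    peaks_by_gene: dict[str, list[PeakRecord]] = {g.gene_id: [] for g in genes}
    n_skipped = 0
    skipped_chroms: set[str] = set()
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            n_skipped += 1
            skipped_chroms.add(p.chrom)
            continue
        for hit in tree.overlap(p.start, p.end):
            peaks_by_gene[hit.data].append(p)
    if n_skipped:
        logger.warning(
            "%d peak(s) on chromosome(s) %s absent from the annotation were "
            "ignored", n_skipped, sorted(skipped_chroms))
    return BindingMap(condition_id=condition_id, window=window,
                      peaks_by_gene=peaks_by_gene, n_skipped_peaks=n_skipped,
                      skipped_chroms=tuple(sorted(skipped_chroms)))


def regulation_direction(rec: Optional[RegulationRecord],
                         th: CallThresholds) -> str:
    """Direction of significant regulation: "up", "down" or "none".

    Missing records and missing adjusted p-values give "none". A log2FC of
    exactly 0 is "none" even when lfc_min is 0.
    """
    if rec is None or not rec.significant(th.alpha):
        return "none"
    if rec.log2fc > 0 and rec.log2fc >= th.lfc_min:
        return "up"
    if rec.log2fc < 0 and rec.log2fc <= -th.lfc_min:
        return "down"
    return "none"


def call_targets(binding: BindingMap,
                 induction_de: Iterable[RegulationRecord],
                 thresholds: Optional[CallThresholds] = None) -> list[TargetStatus]:
    """Call per-gene direct-target status from binding plus induction DE.

    A gene is an induction-supported target (F3T_IN) iff it is bound and
    significantly regulated in the induction contrast. Genes present in the
    annotation but absent from the DE table are treated as not regulated
    (counted and logged).
    """
    th = thresholds or CallThresholds()
    de_by_gene: dict[str, RegulationRecord] = {}
    for rec in induction_de:
        if rec.gene_id in de_by_gene:
            raise ValidationError(
                f"duplicate DE record for gene {rec.gene_id!r}")
        de_by_gene[rec.gene_id] = rec

    statuses: list[TargetStatus] = []
    n_missing = 0
    for gene_id in binding.peaks_by_gene:
        rec = de_by_gene.get(gene_id)
        if rec is None:
            n_missing += 1
        direction = regulation_direction(rec, th)
        bound = binding.bound(gene_id)
        cls = F3T_IN if bound and direction != "none" else NON_TARGET
        statuses.append(TargetStatus(
            gene_id=gene_id, condition_id=binding.condition_id, bound=bound,
            direction=direction, kd_regulated=False, target_class=cls,
            max_peak_score=binding.max_peak_score(gene_id)))
    if n_missing:
        logger.info("%d gene(s) in the annotation had no DE record and were "
                    "treated as not regulated", n_missing)
    return statuses


def refine_with_knockdown(statuses: Iterable[TargetStatus],
                          kd_de: Iterable[RegulationRecord],
                          thresholds: Optional[CallThresholds] = None
                          ) -> list[TargetStatus]:
    """Promote induction-supported targets with knockdown evidence.

    A gene with class F3T_IN whose knockdown adjusted p passes alpha (and,
    when required, whose knockdown fold change is anti-correlated with the
    induction direction) becomes F3T_IN_KD. All other statuses are returned
    unchanged; refinement never promotes non-targets.
    """
    th = thresholds or CallThresholds()
    kd_by_gene = {rec.gene_id: rec for rec in kd_de}
    refined: list[TargetStatus] = []
    for st in statuses:
        rec = kd_by_gene.get(st.gene_id)
        kd_significant = rec is not None and rec.significant(th.alpha)
        if st.target_class == F3T_IN and kd_significant:
            ok = True
            if th.require_kd_anticorrelation:
                wanted = "down" if st.direction == "up" else "up"
                ok = (rec.log2fc < 0 and wanted == "down") or \
                     (rec.log2fc > 0 and wanted == "up")
            if ok:
                refined.append(TargetStatus(
                    gene_id=st.gene_id, condition_id=st.condition_id,
                    bound=st.bound, direction=st.direction, kd_regulated=True,
                    target_class=F3T_IN_KD, max_peak_score=st.max_peak_score))
                continue
        refined.append(st)
    return refined


def statuses_to_frame(statuses: Iterable[TargetStatus]) -> pd.DataFrame:
    """Tabulate target statuses (one row per gene x condition)."""
    rows = [{
        "gene_id": s.gene_id,
        "condition_id": s.condition_id,
        "bound": s.bound,
        "direction": s.direction,
        "kd_regulated": s.kd_regulated,
        "class": s.target_class,
        "max_peak_score": s.max_peak_score,
    } for s in statuses]
    return pd.DataFrame(rows, columns=["gene_id", "condition_id", "bound",
                                       "direction", "kd_regulated", "class",
                                       "max_peak_score"])


def write_target_status(statuses: Iterable[TargetStatus], path) -> None:
    statuses_to_frame(statuses).to_csv(path, sep="\t", index=False, na_rep="NA")
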