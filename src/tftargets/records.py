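"""Core domain records shared by all pipeline stages.

Coordinates are 0-based half-open throughout (BED convention); the TSS
annotation is declared 0-based. Records validate their own invariants on
construction so that downstream code never sees malformed data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-")

# Target classes: induction-supported targets, and the subset additionally
# supported by knockdown differential expression.
F3T_IN = "F3T_IN"
F3T_IN_KD = "F3T_IN_KD"
NON_TARGET = "non_target"
TARGET_CLASSES = (F3T_IN, F3T_IN_KD, NON_TARGET)


class ValidationError(ValueError):
    """An in-memory record or collection violated a type invariant."""


class FormatError(ValidationError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path: Optional[str] = None,
                 lineno: Optional[int] = None):
        self.path = path
        self.lineno = lineno
        prefix = ""
        if path is not None:
            prefix = f"{path}"
            if lineno is not None:
                prefix += f":{lineno}"
            prefix += ": "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class GeneRecord:
    """A gene's TSS anchor used for binding-window assignment."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    symbol: str = ""
    species: str = ""

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not isinstance(self.tss, int) or isinstance(self.tss, bool):
            raise ValidationError(f"gene {self.gene_id}: tss must be an integer")
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: tss must be >= 0")


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP peak interval (0-based half-open) with its score.

    ``score`` is whichever narrowPeak column the reader was told to use
    (column 5 "score" by default, or column 7 "signalValue"). The remaining
    narrowPeak columns are retained so files round-trip losslessly.
    """

    chrom: str
    start: int
    end: int
    score: float
    condition_id: str = ""
    name: str = "."
    strand: str = "."
    signal_value: Optional[float] = None
    log_p: float = -1.0
    log_q: float = -1.0
    summit_offset: Optional[int] = None

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end}: negative coordinate")
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if not (self.score >= 0):
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end}: score must be >= 0")
        if self.summit_offset is not None:
            if self.summit_offset < 0 or self.summit_offset >= self.end - self.start:
                raise ValidationError(
                    f"peak {self.chrom}:{self.start}-{self.end}: summit offset "
                    f"{self.summit_offset} outside the peak")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegulationRecord:
    """One gene x contrast differential-expression result.

    ``padj`` may be NaN (encoded "NA" on disk); such rows are retained but
    always treated as non-significant.
    """

    gene_id: str
    contrast_id: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id}: pvalue {self.pvalue} outside [0, 1]")
        if not math.isnan(self.padj) and not (0.0 <= self.padj <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id}: padj {self.padj} outside [0, 1]")

    @property
    def padj_missing(self) -> bool:
        return math.isnan(self.padj)

    def significant(self, alpha: float) -> bool:
        """Adjusted-p significance; missing padj is never significant."""
        return (not self.padj_missing) and self.padj <= alpha


class GeneSetCollection:
    """Named gene sets as parsed from a GMT file.

    Set names are unique and every set is non-empty. Membership lists keep
    their file order for lossless round-trips; set lookups go through
    :meth:`members`.
    """

    def __init__(self):
        self._members: dict[str, tuple[str, ...]] = {}
        self._descriptions: dict[str, str] = {}

    def add(self, name: str, genes, description: str = "") -> None:
        if not name:
            raise ValidationError("gene set name must be non-empty")
        if name in self._members:
            raise ValidationError(f"duplicate gene set name: {name!r}")
        genes = tuple(genes)
        if not genes:
            raise ValidationError(f"gene set {name!r} is empty")
        self._members[name] = genes
        self._descriptions[name] = description

    def names(self) -> list[str]:
        return list(self._members)

    def members(self, name: str) -> frozenset[str]:
        return frozenset(self._members[name])

    def members_ordered(self, name: str) -> tuple[str, ...]:
        return self._members[name]

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, name: str) -> bool:
        return name in self._members

    def __iter__(self):
        return iter(self._members)


@dataclass(frozen=True)
class TargetStatus:
    """Per gene x condition direct-target call with its evidence."""

    gene_id: str
    condition_id: str
    bound: bool
    direction: str  # "up" | "down" | "none"
    kd_regulated: bool
    target_class: str  # F3T_IN | F3T_IN_KD | non_target
    max_peak_score: Optional[float] = None

    def __post_init__(self):
        if self.direction not in ("up", "down", "none"):
            raise ValidationError(f"invalid direction {self.direction!r}")
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(f"invalid target class {self.target_class!r}")
        if self.target_class in (F3T_IN, F3T_IN_KD):
            if not self.bound or self.direction == "none":
                raise ValidationError(
                    f"gene {self.gene_id}: target class {self.target_class} "
                    "requires binding and a regulation direction")
        if self.target_class == F3T_IN_KD and not self.kd_regulated:
            raise ValidationError(
                f"gene {self.gene_id}: F3T_IN_KD requires knockdown evidence")

    @property
    def is_target(self) -> bool:
        return self.target_class != NON_TARGET


# Reprogramming fates across the genotype x modifier-silencing design.
CONSERVED = "conserved"
LOST = "lost_in_disease"
GAINED = "gained_in_disease"
NEVER = "never_target"
FATES = (CONSERVED, LOST, GAINED, NEVER)

DEPENDENT = "dependent"
INDEPENDENT = "independent"
UNRESOLVED = "unresolved"
NOT_APPLICABLE = "not_applicable"
DEPENDENCE_LABELS = (DEPENDENT, INDEPENDENT, UNRESOLVED, NOT_APPLICABLE)


@dataclass(frozen=True)
class ReprogrammingCall:
    """A gene's target fate across conditions plus modifier dependence."""

    gene_id: str
    fate: str
    modifier_dependence: str
    direction_concordant: Optional[bool] = None

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValidationError(f"invalid fate {self.fate!r}")
        if self.modifier_dependence not in DEPENDENCE_LABELS:
            raise ValidationError(
                f"invalid dependence label {self.modifier_dependence!r}")
        if self.fate in (NEVER, CONSERVED):
            if self.modifier_dependence != NOT_APPLICABLE:
                raise ValidationError(
                    f"gene {self.gene_id}: fate {self.fate} requires "
                    "modifier_dependence = not_applicable")
        if self.fate != CONSERVED and self.direction_concordant is not None:
            raise ValidationError(
                f"gene {self.gene_id}: direction_concordant is defined only "
                "for conserved genes")
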