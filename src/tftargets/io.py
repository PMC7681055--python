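"""Readers and writers for every external format the pipeline touches.

Formats: narrowPeak / BED peak calls, a TSS annotation TSV, differential-
expression TSVs, GMT gene-set collections, and a 4-column ortholog TSV.
Every reader either returns records satisfying all type invariants or raises
a :class:`~tftargets.records.FormatError` naming the file and line; there is
no silent coercion. ``write . read`` and ``read . write`` are identities on
valid inputs, which the test suite checks on generated fixtures.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    VALID_STRANDS,
    FormatError,
    GeneRecord,
    GeneSetCollection,
    PeakRecord,
    RegulationRecord,
    ValidationError,
)

ORTHOLOG_RELATIONS = ("one2one", "one2many", "many2many")
ORTHOLOG_COLUMNS = ("source_gene_id", "target_gene_id", "confidence", "relation")
TSS_COLUMNS = ("gene_id", "symbol", "chrom", "strand", "tss", "species")
DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "padj")


def _fmt(x: float) -> str:
    """Canonical float formatting used by all writers (round-trip stable)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.10g}"


def _is_comment(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith("#") or s.startswith("track") or s.startswith("browser")


# ---------------------------------------------------------------------------
# narrowPeak / BED


def read_narrowpeak(path, condition_id: str,
                    score_column: str = "score") -> list[PeakRecord]:
    """Read a narrowPeak (BED6+4) or plain BED (>= 5 column) peak file.

    Parameters
    ----------
    path : str or Path
        Peak file; lines starting with ``#``, ``track`` or ``browser`` are
        skipped.
    condition_id : str
        Label attached to every returned peak.
    score_column : {"score", "signalValue"}
        Which column feeds :attr:`PeakRecord.score`: BED column 5 ("score",
        default) or narrowPeak column 7 ("signalValue").
    """
    if score_column not in ("score", "signalValue"):
        raise ValueError(f"score_column must be 'score' or 'signalValue', "
                         f"got {score_column!r}")
    path = Path(path)
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"expected >= 5 tab-separated columns, got {len(fields)}; "
                    "the score column is required", str(path), lineno)
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise FormatError("non-integer peak coordinates", str(path), lineno)
            if start < 0 or end < 0:
                raise FormatError("negative peak coordinate", str(path), lineno)
            if start >= end:
                raise FormatError(
                    f"malformed interval: start {start} >= end {end}",
                    str(path), lineno)
            name = fields[3]
            try:
                col5 = float(fields[4])
            except ValueError:
                raise FormatError("non-numeric score column", str(path), lineno)
            strand = fields[5] if len(fields) > 5 else "."
            signal = None
            log_p = -1.0
            log_q = -1.0
            summit: Optional[int] = None
            if len(fields) >= 10:  # full narrowPeak
                try:
                    signal = float(fields[6])
                    log_p = float(fields[7])
                    log_q = float(fields[8])
                    summit_raw = int(fields[9])
                except ValueError:
                    raise FormatError("malformed narrowPeak columns 7-10",
                                      str(path), lineno)
                summit = None if summit_raw < 0 else summit_raw
            if score_column == "signalValue":
                if signal is None:
                    raise FormatError(
                        "score column 'signalValue' requested but the file "
                        "has no column 7", str(path), lineno)
                score = signal
            else:
                score = col5
            try:
                peaks.append(PeakRecord(
                    chrom=fields[0], start=start, end=end, score=score,
                    condition_id=condition_id, name=name, strand=strand,
                    signal_value=signal, log_p=log_p, log_q=log_q,
                    summit_offset=summit))
            except ValidationError as exc:
                raise FormatError(str(exc), str(path), lineno)
    return peaks


def write_narrowpeak(peaks: Iterable[PeakRecord], path) -> None:
    """Write peaks as 10-column narrowPeak (column 5 carries the score)."""
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            signal = p.score if p.signal_value is None else p.signal_value
            fh.write("\t".join([
                p.chrom, str(p.start), str(p.end), p.name, _fmt(p.score),
                p.strand, _fmt(signal), _fmt(p.log_p), _fmt(p.log_q),
                str(summit),
            ]) + "\n")


# ---------------------------------------------------------------------------
# TSS annotation


def read_tss_table(path) -> list[GeneRecord]:
    """Read the TSS annotation TSV (gene_id, symbol, chrom, strand, tss, species)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {', '.join(missing)}", str(path))
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = row.gene_id
        if gid in seen:
            raise FormatError(f"duplicate gene_id {gid!r}", str(path), i)
        seen.add(gid)
        if row.strand not in VALID_STRANDS:
            raise FormatError(
                f"gene {gid!r}: strand must be '+' or '-', got {row.strand!r}",
                str(path), i)
        try:
            tss = int(row.tss)
        except ValueError:
            raise FormatError(f"gene {gid!r}: non-integer tss {row.tss!r}",
                              str(path), i)
        try:
            genes.append(GeneRecord(gene_id=gid, symbol=row.symbol,
                                    chrom=row.chrom, strand=row.strand,
                                    tss=tss, species=row.species))
        except ValidationError as exc:
            raise FormatError(str(exc), str(path), i)
    return genes


def write_tss_table(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSS_COLUMNS) + "\n")
        for g in genes:
            fh.write("\t".join([g.gene_id, g.symbol, g.chrom, g.strand,
                                str(g.tss), g.species]) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables


def read_de_table(path, contrast_id: str) -> list[RegulationRecord]:
    """Read a DE TSV (gene_id, log2fc, pvalue, padj; "NA" padj allowed).

    Rows with missing padj are retained; they are flagged non-significant by
    :meth:`RegulationRecord.significant`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {', '.join(missing)}", str(path))
    records: list[RegulationRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = row.gene_id
        if gid in seen:
            raise FormatError(f"duplicate gene_id {gid!r}", str(path), i)
        seen.add(gid)
        try:
            log2fc = float(row.log2fc)
            pvalue = float(row.pvalue)
            padj = math.nan if row.padj == "NA" else float(row.padj)
        except ValueError:
            raise FormatError(f"gene {gid!r}: non-numeric DE fields", str(path), i)
        try:
            records.append(RegulationRecord(gene_id=gid, contrast_id=contrast_id,
                                            log2fc=log2fc, pvalue=pvalue,
                                            padj=padj))
        except ValidationError as exc:
            raise FormatError(str(exc), str(path), i)
    return records


def write_de_table(records: Iterable[RegulationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DE_COLUMNS) + "\n")
        for r in records:
            padj = "NA" if r.padj_missing else _fmt(r.padj)
            fh.write("\t".join([r.gene_id, _fmt(r.log2fc), _fmt(r.pvalue),
                                padj]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line (name, description, members...)."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} fields; need at least "
                    "name, description and one member", str(path), lineno)
            name, description, *members = fields
            members = [m for m in members if m]
            try:
                collection.add(name, members, description)
            except ValidationError as exc:
                raise FormatError(str(exc), str(path), lineno)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            fh.write("\t".join([name, collection.description(name),
                                *collection.members_ordered(name)]) + "\n")


# ---------------------------------------------------------------------------
# Ortholog table


class OrthologTable:
    """Cross-species gene mapping rows: (source, target, confidence, relation)."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(
                f"ortholog table missing columns: {', '.join(missing)}")
        df = df.loc[:, list(ORTHOLOG_COLUMNS)].copy()
        df["confidence"] = df["confidence"].astype(float)
        if (df["confidence"] < 0).any():
            raise ValidationError("ortholog confidence must be >= 0")
        bad = ~df["relation"].isin(ORTHOLOG_RELATIONS)
        if bad.any():
            raise ValidationError(
                f"invalid ortholog relation(s): "
                f"{sorted(df.loc[bad, 'relation'].unique())}")
        dup = df.duplicated(subset=["source_gene_id", "target_gene_id"])
        if dup.any():
            pair = df.loc[dup, ["source_gene_id", "target_gene_id"]].iloc[0]
            raise ValidationError(
                f"duplicate ortholog pair ({pair.source_gene_id!r}, "
                f"{pair.target_gene_id!r})")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_ortholog_table(path) -> OrthologTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"source_gene_id": str,
                                            "target_gene_id": str,
                                            "relation": str})
    try:
        return OrthologTable(df)
    except ValidationError as exc:
        raise FormatError(str(exc), str(path))


def write_ortholog_table(table: OrthologTable, path) -> None:
    df = table.df.copy()
    df["confidence"] = df["confidence"].map(_fmt)
    df.to_csv(path, sep="\t", index=False)
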