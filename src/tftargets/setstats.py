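"""Ortholog mapping, set-overlap significance and gene-set enrichment.

Overlap significance uses the hypergeometric upper tail P(X >= k), which is
identical to a one-sided Fisher exact test on the 2x2 membership table.
Enrichment over a GMT collection reports, per set, the one-sided Fisher p,
the sample odds ratio (Haldane 0.5 correction when any cell is zero) and the
Benjamini-Hochberg FDR across tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OrthologTable
from .records import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size and (np.isnan(pvals).any() or (pvals < 0).any()
                       or (pvals > 1).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    return pvals


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, clipped to [0, 1]."""
    pvals = _check_pvals(pvals)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    pvals = _check_pvals(pvals)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Ortholog mapping


@dataclass
class OrthologMappingReport:
    n_source: int
    n_mapped: int
    unmapped_count: int
    unmapped_genes: tuple[str, ...]


def map_orthologs(source_genes: Iterable[str], table: OrthologTable
                  ) -> tuple[set[str], OrthologMappingReport]:
    """Map each source gene to its single best ortholog.

    Best = relation one2one preferred, then highest confidence, then the
    lexicographically smallest target id. Unmapped sources are reported, not
    errors. Returns the deduplicated target set plus the mapping report.
    """
    source_genes = set(source_genes)
    df = table.df
    sub = df[df["source_gene_id"].isin(source_genes)].copy()
    sub["_one2one"] = (sub["relation"] != "one2one").astype(int)
    sub = sub.sort_values(["source_gene_id", "_one2one", "confidence",
                           "target_gene_id"],
                          ascending=[True, True, False, True])
    best = sub.drop_duplicates(subset="source_gene_id", keep="first")
    targets = set(best["target_gene_id"])
    mapped_sources = set(best["source_gene_id"])
    unmapped = tuple(sorted(source_genes - mapped_sources))
    report = OrthologMappingReport(
        n_source=len(source_genes), n_mapped=len(mapped_sources),
        unmapped_count=len(unmapped), unmapped_genes=unmapped)
    return targets, report


# ---------------------------------------------------------------------------
# Hypergeometric overlap


@dataclass
class OverlapResult:
    """Significance of the overlap between two gene sets in a universe."""

    k: int
    size_a: int
    size_b: int
    universe_n: int
    percent: float  # 100 * k / size_b
    pvalue: float

    def to_dict(self) -> dict:
        return {"k": self.k, "size_a": self.size_a, "size_b": self.size_b,
                "universe_n": self.universe_n, "percent": self.percent,
                "pvalue": self.pvalue}


def hypergeom_upper_tail(k: int, universe_n: int, size_a: int,
                         size_b: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe_n, size_a, size_b draws)."""
    return float(stats.hypergeom.sf(k - 1, universe_n, size_a, size_b))


def hypergeom_overlap(set_a: Set[str], set_b: Set[str],
                      universe: Set[str]) -> OverlapResult:
    """Hypergeometric upper-tail significance of |A intersect B|.

    Sets not contained in the universe are restricted to it with a logged
    warning. The reported percent uses |B| (the mapped/query set) as the
    denominator.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        n_out = len(a - universe) + len(b - universe)
        logger.warning("%d gene(s) outside the universe were dropped from "
                       "the overlap test", n_out)
        a &= universe
        b &= universe
    k = len(a & b)
    percent = 100.0 * k / len(b) if b else 0.0
    pvalue = hypergeom_upper_tail(k, len(universe), len(a), len(b))
    return OverlapResult(k=k, size_a=len(a), size_b=len(b),
                         universe_n=len(universe), percent=percent,
                         pvalue=pvalue)


# ---------------------------------------------------------------------------
# GMT enrichment


def enrich_gmt(query: Set[str], collection: GeneSetCollection,
               universe: Set[str]) -> pd.DataFrame:
    """One-sided Fisher enrichment of a query set against a GMT collection.

    Per set: k = |query intersect set|, K = |set| in the universe, n = |query|
    in the universe, N = |universe|; p = hypergeometric upper tail P(X >= k);
    odds ratio = sample OR with Haldane 0.5 correction when any 2x2 cell is
    zero; FDR = Benjamini-Hochberg across tested sets. Sets with an empty
    intersection with the universe are dropped. Rows sorted ascending by p
    (ties broken by set name).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query) & universe
    if not query:
        raise ValidationError("query set is empty after restriction to the "
                              "universe")
    n = len(query)
    N = len(universe)
    rows = []
    for name in collection:
        members = collection.members(name) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        a, b = k, K - k
        c, d = n - k, N - K - (n - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds_ratio = (a * d) / (b * c)
        pvalue = hypergeom_upper_tail(k, N, K, n)
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "odds_ratio": odds_ratio, "pvalue": pvalue})
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                     "odds_ratio", "pvalue"])
    if len(df):
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
        df = df.sort_values(["pvalue", "set_name"]).reset_index(drop=True)
    else:
        df["fdr"] = []
    return df
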