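"""Synthetic four-condition ChIP + differential-expression data generator.

The generator emulates the study design the pipeline is built for: an
isogenic control/disease genotype pair, each treated with a scramble or a
modifier-silencing siRNA (four conditions), with TF nuclear-induction and
TF-knockdown DE contrasts per condition. Each gene is planted with a target
fate (conserved / lost-in-disease / gained-in-disease / never a target) and,
for lost/gained genes, a modifier-dependence label; disease conditions carry
elevated background binding and a multiplicative peak-score shift, emulating
elevated TF occupancy.

Evidence model
--------------
Per gene x condition the generator first plants the evidence pair
(bound, DE-significant) implied by the fate truth table, then flips each
label independently with probability ``epsilon``. Numeric columns are drawn
conditional on the labels: peaks are placed only inside the owning gene's
TSS window (gene windows are laid out non-overlapping, with decoy peaks in
the inter-window gaps), significant genes receive log2 fold changes from a
two-sample z-approximation whose magnitude is floored at the BH rejection
boundary, and null genes receive p-values uniform on (alpha, 1] so that BH
can never promote them. Consequently, at epsilon = 0 the pipeline recovers
every planted fate and dependence label exactly, and epsilon is the sole
source of misclassification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import (
    CONSERVED,
    DEPENDENT,
    GAINED,
    INDEPENDENT,
    LOST,
    NEVER,
    NOT_APPLICABLE,
    GeneRecord,
    PeakRecord,
    RegulationRecord,
    ReprogrammingCall,
    ValidationError,
)
from .reprogramming import ConditionDesign
from .setstats import bh_adjust
from . import io as tio

FATE_CODES = {CONSERVED: 0, LOST: 1, GAINED: 2, NEVER: 3}
CODE_FATES = {v: k for k, v in FATE_CODES.items()}

INDUCTION = "induction"
KNOCKDOWN = "knockdown"

_JITTER = 800  # bp of TSS jitter on the layout grid


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic dataset.

    The defaults are the study conditions: 10,000 annotated genes; the
    planted partition 82 conserved / 137 lost / 190 gained with 111
    modifier-dependent genes; a +/-20 kb binding window; elevated disease
    occupancy (1.5x background binding and 1.5x peak scores, with the
    indirect-regulation rate reduced by the same factor); and a 5% evidence
    flip rate.
    """

    n_genes: int = 10_000
    n_chroms: int = 8
    window: int = 20_000
    peak_length: int = 200
    # planted fates: exact counts (never = remainder) ...
    class_counts: Optional[dict] = None
    n_dependent: Optional[int] = None
    # ... or multinomial proportions with a dependence fraction
    class_proportions: Optional[dict] = None
    dependent_fraction: Optional[float] = None
    # binding model
    p_bg: float = 0.05
    p_t: float = 1.0
    occupancy_multiplier: float = 1.5
    gamma_shape: float = 2.0
    gamma_scale: float = 1.0
    score_shift: float = 1.5
    # DE model
    effect_mean: float = 1.5
    effect_sd: float = 0.5
    null_lfc_sd: float = 0.25
    n_replicates: int = 3
    alpha_sim: float = 0.05
    p_indirect: float = 0.04
    p_kd_regulated: float = 0.5
    ctrl_kd_gain: float = 0.03
    # noise
    epsilon: float = 0.05
    n_decoy_peaks: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValidationError("n_genes and n_chroms must be positive")
        if self.window < 0 or self.peak_length <= 0:
            raise ValidationError("window must be >= 0 and peak_length > 0")
        if self.peak_length >= self.window:
            raise ValidationError("peak_length must be smaller than the window")
        for name in ("p_bg", "p_t", "p_indirect", "p_kd_regulated",
                     "ctrl_kd_gain", "epsilon"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("gamma_shape", "gamma_scale", "score_shift",
                     "effect_sd", "null_lfc_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.occupancy_multiplier <= 0:
            raise ValidationError("occupancy_multiplier must be > 0")
        if not (0.0 < self.alpha_sim < 1.0):
            raise ValidationError("alpha_sim must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        bg_disease = self.p_bg * self.occupancy_multiplier
        if bg_disease > 1.0:
            raise ValidationError(
                "p_bg * occupancy_multiplier exceeds 1; infeasible binding model")
        if self.p_t < max(self.p_bg, bg_disease):
            raise ValidationError(
                "target binding probability p_t below the background rate; "
                "infeasible binding model")
        if self.class_counts is not None and self.class_proportions is not None:
            raise ValidationError(
                "give class_counts or class_proportions, not both")
        if self.class_proportions is not None:
            total = sum(self.class_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"class proportions must sum to 1, got {total}")
            if any(v < 0 for v in self.class_proportions.values()):
                raise ValidationError("class proportions must be >= 0")
            if self.dependent_fraction is None or \
                    not (0.0 <= self.dependent_fraction <= 1.0):
                raise ValidationError(
                    "class_proportions requires dependent_fraction in [0, 1]")

    def resolved_counts(self) -> Optional[tuple[int, int, int, int]]:
        """(conserved, lost, gained, dependent) when counts mode applies."""
        if self.class_proportions is not None:
            return None
        counts = self.class_counts or {CONSERVED: 82, LOST: 137, GAINED: 190}
        c = int(counts.get(CONSERVED, 0))
        l = int(counts.get(LOST, 0))
        g = int(counts.get(GAINED, 0))
        if c + l + g > self.n_genes:
            raise ValidationError("planted class counts exceed n_genes")
        dep = self.n_dependent if self.n_dependent is not None else 111
        dep = min(int(dep), l + g)
        return c, l, g, dep


@dataclass
class SimulatedDataset:
    """In-memory simulated inputs plus the planted ground truth."""

    config: SimulationConfig
    design: ConditionDesign
    genes: list[GeneRecord]
    peaks: dict[str, list[PeakRecord]]
    de: dict[tuple[str, str], list[RegulationRecord]]
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, str]:
        """Write every input file plus the truth table; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        tss_path = outdir / "tss.tsv"
        tio.write_tss_table(self.genes, tss_path)
        paths["tss"] = str(tss_path)
        for cond in self.design.all_conditions:
            p = outdir / f"peaks_{cond}.narrowPeak"
            tio.write_narrowpeak(self.peaks[cond], p)
            paths[f"peaks_{cond}"] = str(p)
            for contrast in (INDUCTION, KNOCKDOWN):
                d = outdir / f"de_{cond}_{contrast}.tsv"
                tio.write_de_table(self.de[(cond, contrast)], d)
                paths[f"de_{cond}_{contrast}"] = str(d)
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = str(truth_path)
        return paths


def _plant_fates(cfg: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-gene fate codes and modifier-dependence flags."""
    n = cfg.n_genes
    dependent = np.zeros(n, dtype=bool)
    if cfg.class_proportions is not None:
        p = [cfg.class_proportions.get(f, 0.0)
             for f in (CONSERVED, LOST, GAINED, NEVER)]
        fate = rng.choice(4, size=n, p=np.array(p) / sum(p))
        changed = (fate == 1) | (fate == 2)
        dependent[changed] = rng.random(changed.sum()) < cfg.dependent_fraction
    else:
        c, l, g, dep = cfg.resolved_counts()
        fate = np.full(n, 3, dtype=np.int64)
        perm = rng.permutation(n)
        fate[perm[:c]] = 0
        fate[perm[c:c + l]] = 1
        fate[perm[c + l:c + l + g]] = 2
        changed_idx = perm[c:c + l + g]
        dep_idx = rng.choice(changed_idx, size=dep, replace=False)
        dependent[dep_idx] = True
    return fate, dependent


def _membership(cfg: SimulationConfig, fate: np.ndarray, dependent: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """n_genes x 4 boolean membership matrix (ctrl_scr, ctrl_kd, dis_scr, dis_kd)."""
    n = cfg.n_genes
    m = np.zeros((n, 4), dtype=bool)
    cons, lost, gained, never = (fate == 0), (fate == 1), (fate == 2), (fate == 3)
    m[cons] = True
    m[lost, 0] = True
    m[lost, 1] = True
    m[lost, 3] = dependent[lost]
    m[gained, 2] = True
    m[gained, 3] = ~dependent[gained]
    # modifier silencing recruits extra targets in the control genotype
    extra = never & (rng.random(n) < cfg.ctrl_kd_gain)
    m[extra, 1] = True
    return m


def _layout(cfg: SimulationConfig, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome index, TSS and strand per gene; windows never overlap."""
    n = cfg.n_genes
    per_chrom = math.ceil(n / cfg.n_chroms)
    spacing = 2 * cfg.window + cfg.peak_length + _JITTER + 1000
    idx = np.arange(n)
    chrom_idx = idx // per_chrom
    within = idx % per_chrom
    tss = (within + 1) * spacing + rng.integers(0, _JITTER, size=n)
    strand = rng.integers(0, 2, size=n)
    return chrom_idx, tss, strand


def _signed_lfc_and_p(sig: np.ndarray, sign: np.ndarray,
                      cfg: SimulationConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (log2fc, pvalue, padj) vectors consistent with planted labels.

    ``sig`` marks planted-significant genes; ``sign`` gives their fold-change
    sign. Significant p-values come from a z-approximation with the magnitude
    floored at the BH boundary alpha*k/m; null p-values are uniform on
    (alpha, 1], so the BH-rejected set equals ``sig`` exactly.
    """
    n = len(sig)
    k = int(sig.sum())
    se = cfg.null_lfc_sd * math.sqrt(2.0 / cfg.n_replicates)
    lfc = np.empty(n)
    pvalue = np.empty(n)

    if k:
        cutoff = cfg.alpha_sim * k / n * 0.999
        z_min = norm.isf(cutoff / 2.0)
        magnitude = np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd, size=k))
        z = np.abs(magnitude / se + rng.standard_normal(k))
        z = np.maximum(z, z_min)
        lfc[sig] = sign[sig] * z * se
        pvalue[sig] = 2.0 * norm.sf(z)
    n_null = n - k
    if n_null:
        u = rng.random(n_null)
        p_null = cfg.alpha_sim + (1.0 - cfg.alpha_sim) * u
        p_null = np.maximum(p_null, np.nextafter(cfg.alpha_sim, 1.0))
        z_null = norm.isf(p_null / 2.0)
        null_sign = rng.integers(0, 2, size=n_null) * 2 - 1
        lfc[~sig] = null_sign * z_null * se
        pvalue[~sig] = p_null
    padj = bh_adjust(pvalue)
    return lfc, pvalue, padj


def _de_records(gene_ids, lfc, pvalue, padj, contrast_id) -> list[RegulationRecord]:
    return [RegulationRecord(gene_id=g, contrast_id=contrast_id,
                             log2fc=float(f), pvalue=float(p), padj=float(q))
            for g, f, p, q in zip(gene_ids, lfc, pvalue, padj)]


def simulate_dataset(config: Optional[SimulationConfig] = None,
                     **overrides) -> SimulatedDataset:
    """Generate the full four-condition dataset with planted ground truth.

    Identical configuration and seed give identical in-memory data and
    byte-identical files from :meth:`SimulatedDataset.write`. Named
    substreams (one per purpose and condition) are spawned from the single
    seed in a fixed order, and all per-gene draws are element-indexed vector
    draws, so enlarging ``n_genes`` leaves earlier genes' random draws
    unchanged (their chromosome placement may still shift, since genes are
    distributed evenly over chromosomes).
    """
    cfg = config or SimulationConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    design = ConditionDesign()
    conds = design.all_conditions
    genotype = {design.control_scramble: "control",
                design.control_kd: "control",
                design.disease_scramble: "disease",
                design.disease_kd: "disease"}

    ss = np.random.SeedSequence(cfg.seed)
    # fixed spawning order: layout, fates, membership, directions, kd flag,
    # then 5 streams per condition
    children = ss.spawn(5 + 5 * len(conds))
    rng_layout, rng_fates, rng_member, rng_dir, rng_kd = \
        (np.random.default_rng(c) for c in children[:5])
    cond_streams = {
        cond: [np.random.default_rng(c)
               for c in children[5 + 5 * i: 10 + 5 * i]]
        for i, cond in enumerate(conds)
    }

    chrom_idx, tss, strand_idx = _layout(cfg, rng_layout)
    n = cfg.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    strands = np.where(strand_idx == 1, "+", "-")

    fate, dependent = _plant_fates(cfg, rng_fates)
    member = _membership(cfg, fate, dependent, rng_member)
    direction = rng_dir.integers(0, 2, size=n) * 2 - 1  # +1 up, -1 down
    kd_regulated = rng_kd.random(n) < cfg.p_kd_regulated

    genes = [GeneRecord(gene_id=g, symbol=g.replace("G", "SYM"), chrom=c,
                        strand=s, tss=int(t), species="synthetic")
             for g, c, s, t in zip(gene_ids, chroms, strands, tss)]

    peaks: dict[str, list[PeakRecord]] = {}
    de: dict[tuple[str, str], list[RegulationRecord]] = {}
    called_member = {}
    L = cfg.peak_length

    for ci, cond in enumerate(conds):
        rng_ev, rng_pk, rng_decoy, rng_ind, rng_kdde = cond_streams[cond]
        disease = genotype[cond] == "disease"
        mult = cfg.occupancy_multiplier if disease else 1.0
        p_bg = min(1.0, cfg.p_bg * mult)
        p_ind = cfg.p_indirect / mult
        scale = cfg.gamma_scale * (cfg.score_shift if disease else 1.0)

        is_member = member[:, ci]
        # planted evidence labels
        de_label = np.where(is_member, True, rng_ev.random(n) < p_ind)
        bound_label = np.where(
            is_member, rng_ev.random(n) < cfg.p_t,
            (~de_label) & (rng_ev.random(n) < p_bg))
        # symmetric evidence flips
        bound_final = bound_label ^ (rng_ev.random(n) < cfg.epsilon)
        de_final = de_label ^ (rng_ev.random(n) < cfg.epsilon)
        called_member[cond] = bound_final & de_final

        # peaks for bound genes, strictly inside the owning gene's window
        bidx = np.flatnonzero(bound_final)
        lo = np.maximum(0, tss[bidx] - cfg.window)
        hi_start = tss[bidx] + cfg.window - L
        starts = lo + (rng_pk.random(len(bidx)) * (hi_start - lo + 1)).astype(np.int64)
        scores = rng_pk.gamma(cfg.gamma_shape, scale, size=len(bidx))
        cond_peaks = [
            PeakRecord(chrom=chroms[j], start=int(s), end=int(s) + L,
                       score=round(float(sc), 3), condition_id=cond,
                       name=f"{cond}_peak_{j}", strand=".",
                       signal_value=round(float(sc), 3),
                       summit_offset=L // 2)
            for j, s, sc in zip(bidx, starts, scores)]
        # decoy peaks in the inter-window gaps
        dgene = rng_decoy.integers(0, n, size=cfg.n_decoy_peaks)
        doffset = rng_decoy.integers(1, _JITTER + 1, size=cfg.n_decoy_peaks)
        dscores = rng_decoy.gamma(cfg.gamma_shape, scale, size=cfg.n_decoy_peaks)
        for d, (j, off, sc) in enumerate(zip(dgene, doffset, dscores)):
            s = int(tss[j] + cfg.window + off)
            cond_peaks.append(PeakRecord(
                chrom=chroms[j], start=s, end=s + L,
                score=round(float(sc), 3), condition_id=cond,
                name=f"{cond}_decoy_{d}", strand=".",
                signal_value=round(float(sc), 3), summit_offset=L // 2))
        peaks[cond] = cond_peaks

        # induction contrast
        lfc, pval, padj = _signed_lfc_and_p(de_final, direction, cfg, rng_ind)
        de[(cond, INDUCTION)] = _de_records(
            gene_ids, lfc, pval, padj, f"{cond}_{INDUCTION}")

        # knockdown contrast: anti-correlated for supported members,
        # random-signed indirect effects elsewhere
        kd_label = np.where(is_member, kd_regulated,
                            rng_kdde.random(n) < p_ind)
        kd_final = kd_label ^ (rng_kdde.random(n) < cfg.epsilon)
        kd_sign = np.where(is_member, -direction,
                           rng_kdde.integers(0, 2, size=n) * 2 - 1)
        lfc, pval, padj = _signed_lfc_and_p(kd_final, kd_sign, cfg, rng_kdde)
        de[(cond, KNOCKDOWN)] = _de_records(
            gene_ids, lfc, pval, padj, f"{cond}_{KNOCKDOWN}")

    dep_label = np.where(
        (fate == 1) | (fate == 2),
        np.where(dependent, DEPENDENT, INDEPENDENT), NOT_APPLICABLE)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "fate": [CODE_FATES[c] for c in fate],
        "modifier_dependence": dep_label,
        "direction": np.where(direction > 0, "up", "down"),
        "kd_regulated": kd_regulated,
        **{f"member_{cond}": member[:, i] for i, cond in enumerate(conds)},
    })
    return SimulatedDataset(config=cfg, design=design, genes=genes,
                            peaks=peaks, de=de, truth=truth)


# ---------------------------------------------------------------------------
# Recovery evaluation


@dataclass
class RecoveryReport:
    """Agreement between planted truth and pipeline reprogramming calls."""

    confusion: pd.DataFrame  # truth fates x called fates
    fate_accuracy: float
    dependence_accuracy: float
    per_class: pd.DataFrame  # fate, precision, recall
    n_genes: int

    def to_dict(self) -> dict:
        return {
            "fate_accuracy": self.fate_accuracy,
            "dependence_accuracy": self.dependence_accuracy,
            "n_genes": self.n_genes,
            "confusion": self.confusion.to_dict(),
            "per_class": self.per_class.to_dict(orient="records"),
        }


def evaluate_recovery(truth: pd.DataFrame,
                      calls: list[ReprogrammingCall]) -> RecoveryReport:
    """Confusion matrix and accuracy of fate / dependence recovery."""
    called = pd.DataFrame({
        "gene_id": [c.gene_id for c in calls],
        "called_fate": [c.fate for c in calls],
        "called_dependence": [c.modifier_dependence for c in calls],
    })
    if set(called["gene_id"]) != set(truth["gene_id"]):
        raise ValidationError(
            "truth table and calls cover different gene universes")
    merged = truth.merge(called, on="gene_id", validate="one_to_one")
    fates = [CONSERVED, LOST, GAINED, NEVER]
    confusion = pd.crosstab(merged["fate"], merged["called_fate"]) \
        .reindex(index=fates, columns=fates, fill_value=0)
    correct = merged["fate"] == merged["called_fate"]
    fate_accuracy = float(correct.mean())
    changed = merged["fate"].isin([LOST, GAINED])
    if changed.any():
        dep_ok = (merged.loc[changed, "modifier_dependence"] ==
                  merged.loc[changed, "called_dependence"]) & correct[changed]
        dependence_accuracy = float(dep_ok.mean())
    else:
        dependence_accuracy = 1.0
    rows = []
    for f in fates:
        tp = int(((merged["fate"] == f) & (merged["called_fate"] == f)).sum())
        n_called = int((merged["called_fate"] == f).sum())
        n_true = int((merged["fate"] == f).sum())
        rows.append({"fate": f,
                     "precision": tp / n_called if n_called else float("nan"),
                     "recall": tp / n_true if n_true else float("nan")})
    per_class = pd.DataFrame(rows)
    return RecoveryReport(confusion=confusion, fate_accuracy=fate_accuracy,
                          dependence_accuracy=dependence_accuracy,
                          per_class=per_class, n_genes=len(merged))
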