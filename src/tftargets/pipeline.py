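"""End-to-end orchestration: files in, target/fate tables and a report out.

``run_pipeline`` executes the stages in order (I/O -> target calling ->
reprogramming classification -> set statistics), writes every tabular output
plus a machine-readable JSON run report with content digests, and is
deterministic for fixed inputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import __version__
from . import io as tio
from .records import GAINED, FATES, TargetStatus, ValidationError
from .reprogramming import (
    ConditionDesign,
    OccupancyStats,
    VennSummary,
    calls_to_frame,
    classify_reprogramming,
    occupancy_stats,
    venn_summary,
)
from .setstats import enrich_gmt, hypergeom_overlap, map_orthologs
from .simulate import INDUCTION, KNOCKDOWN, SimulatedDataset
from .targets import (
    CallThresholds,
    assign_peaks_to_genes,
    call_targets,
    refine_with_knockdown,
    write_target_status,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class AnalysisResult:
    """In-memory results of the core analysis stages."""

    statuses_by_condition: dict[str, list[TargetStatus]]
    calls: list
    venn: VennSummary
    occupancy: OccupancyStats


def call_condition(genes, peaks, induction_de, kd_de,
                   window: int, thresholds: CallThresholds,
                   condition_id: Optional[str] = None) -> list[TargetStatus]:
    """Window assignment + induction call + knockdown refinement for one condition."""
    binding = assign_peaks_to_genes(peaks, genes, window=window,
                                    condition_id=condition_id)
    statuses = call_targets(binding, induction_de, thresholds)
    if kd_de is not None:
        statuses = refine_with_knockdown(statuses, kd_de, thresholds)
    return statuses


def analyze(genes, peaks_by_condition: Mapping[str, list],
            induction_de: Mapping[str, list], knockdown_de: Mapping[str, list],
            design: Optional[ConditionDesign] = None,
            window: int = 20_000,
            thresholds: Optional[CallThresholds] = None,
            strict_direction: bool = False,
            occupancy_bins: int = 10) -> AnalysisResult:
    """Run target calling, fate classification and occupancy statistics."""
    design = design or ConditionDesign()
    th = thresholds or CallThresholds()
    statuses = {}
    for cond in design.all_conditions:
        statuses[cond] = call_condition(
            genes, peaks_by_condition[cond], induction_de[cond],
            knockdown_de.get(cond), window, th, condition_id=cond)
    calls = classify_reprogramming(statuses, design,
                                   strict_direction=strict_direction)
    venn = venn_summary(calls, statuses, design)
    occ = occupancy_stats(statuses, n_bins=occupancy_bins)
    return AnalysisResult(statuses_by_condition=statuses, calls=calls,
                          venn=venn, occupancy=occ)


def analyze_dataset(dataset: SimulatedDataset,
                    thresholds: Optional[CallThresholds] = None,
                    strict_direction: bool = False,
                    occupancy_bins: int = 10) -> AnalysisResult:
    """Run the core analysis directly on an in-memory simulated dataset."""
    return analyze(
        dataset.genes, dataset.peaks,
        {c: dataset.de[(c, INDUCTION)] for c in dataset.design.all_conditions},
        {c: dataset.de[(c, KNOCKDOWN)] for c in dataset.design.all_conditions},
        design=dataset.design, window=dataset.config.window,
        thresholds=thresholds, strict_direction=strict_direction,
        occupancy_bins=occupancy_bins)


# ---------------------------------------------------------------------------
# File-driven pipeline


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_file(path, stage: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise PipelineError(f"stage {stage}: missing input file: {p}")
    return p


def load_config(path) -> dict:
    with open(_require_file(path, "config")) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("config: expected a mapping at the top level")
    return config


def run_pipeline(config_path, outdir, **overrides) -> dict:
    """Execute the full pipeline from a YAML config; returns the run report.

    The config names the TSS table, the four conditions with their peak and
    DE files, and the thresholds; ``overrides`` (window, alpha, lfc_min,
    strict_direction, score_column) take precedence over config keys.
    Outputs are written only inside ``outdir``.
    """
    config = load_config(config_path)
    config.update({k: v for k, v in overrides.items() if v is not None})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    window = int(config.get("window", 20_000))
    score_column = config.get("score_column", "score")
    strict_direction = bool(config.get("strict_direction", False))
    th = CallThresholds(
        alpha=float(config.get("alpha", 0.05)),
        lfc_min=float(config.get("lfc_min", 0.0)),
        require_kd_anticorrelation=bool(
            config.get("require_kd_anticorrelation", False)))
    design = ConditionDesign()
    warnings_list: list[str] = []
    input_digests: dict[str, str] = {}

    # stage: io
    tss_path = _require_file(config["tss"], "io")
    input_digests["tss"] = _sha256(tss_path)
    genes = tio.read_tss_table(tss_path)
    cond_cfg = config.get("conditions", {})
    missing = [c for c in design.all_conditions if c not in cond_cfg]
    if missing:
        raise PipelineError(f"stage io: config missing conditions: {missing}")
    peaks, ind_de, kd_de = {}, {}, {}
    for cond in design.all_conditions:
        spec = cond_cfg[cond]
        pk = _require_file(spec["peaks"], "io")
        input_digests[f"peaks_{cond}"] = _sha256(pk)
        peaks[cond] = tio.read_narrowpeak(pk, cond, score_column=score_column)
        de_path = _require_file(spec["induction_de"], "io")
        input_digests[f"induction_de_{cond}"] = _sha256(de_path)
        ind_de[cond] = tio.read_de_table(de_path, f"{cond}_{INDUCTION}")
        if "knockdown_de" in spec:
            kd_path = _require_file(spec["knockdown_de"], "io")
            input_digests[f"knockdown_de_{cond}"] = _sha256(kd_path)
            kd_de[cond] = tio.read_de_table(kd_path, f"{cond}_{KNOCKDOWN}")

    # stages: target_calling -> reprogramming
    try:
        result = analyze(genes, peaks, ind_de, kd_de, design=design,
                         window=window, thresholds=th,
                         strict_direction=strict_direction)
    except ValidationError as exc:
        raise PipelineError(f"stage target_calling/reprogramming: {exc}")
    for cond, statuses in result.statuses_by_condition.items():
        binding = [s for s in statuses if s.bound]
        if not binding:
            warnings_list.append(f"condition {cond}: no bound genes")

    outputs: dict[str, str] = {}

    def _emit(name: str, path: Path) -> None:
        outputs[name] = str(path)

    for cond, statuses in result.statuses_by_condition.items():
        p = outdir / f"targets_{cond}.tsv"
        write_target_status(statuses, p)
        _emit(f"targets_{cond}", p)
    calls_path = outdir / "reprogramming_calls.tsv"
    calls_to_frame(result.calls).to_csv(calls_path, sep="\t", index=False,
                                        na_rep="NA")
    _emit("reprogramming_calls", calls_path)
    venn_path = outdir / "venn_summary.json"
    result.venn.write_json(venn_path)
    _emit("venn_summary", venn_path)
    occ_path = outdir / "occupancy_stats.json"
    result.occupancy.write_json(occ_path)
    _emit("occupancy_stats", occ_path)
    if result.occupancy.score_test.low_expected_warning:
        warnings_list.append("occupancy: some expected bin counts < 5")

    # stage: set_statistics (optional)
    overlap_dict = None
    if "overlap" in config:
        ov = config["overlap"]
        table = tio.read_ortholog_table(_require_file(ov["ortholog_table"],
                                                      "set_statistics"))
        src_path = _require_file(ov["source_genes"], "set_statistics")
        source = {line.strip() for line in open(src_path) if line.strip()}
        mapped, report = map_orthologs(source, table)
        universe = {g.gene_id for g in genes}
        ref_targets = {s.gene_id
                       for s in result.statuses_by_condition[design.reference]
                       if s.is_target}
        overlap = hypergeom_overlap(ref_targets, mapped, universe)
        overlap_dict = overlap.to_dict()
        overlap_dict["unmapped_sources"] = report.unmapped_count
        p = outdir / "overlap.json"
        with open(p, "w") as fh:
            json.dump(overlap_dict, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _emit("overlap", p)
    if "enrichment" in config:
        en = config["enrichment"]
        gmt = tio.read_gmt(_require_file(en["gmt"], "set_statistics"))
        fate = en.get("query_fate", GAINED)
        if fate not in FATES:
            raise PipelineError(f"stage set_statistics: unknown query_fate "
                                f"{fate!r}")
        query = {c.gene_id for c in result.calls if c.fate == fate}
        universe = {g.gene_id for g in genes}
        enr = enrich_gmt(query, gmt, universe)
        p = outdir / "enrichment.tsv"
        enr.to_csv(p, sep="\t", index=False)
        _emit("enrichment", p)

    report = {
        "tool": "tftargets",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "input_digests": input_digests,
        "outputs": {name: {"path": path, "sha256": _sha256(path)}
                    for name, path in outputs.items()},
        "venn_summary": result.venn.to_dict(),
        "occupancy_stats": result.occupancy.to_dict(),
        "overlap": overlap_dict,
        "warnings": warnings_list,
    }
    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
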