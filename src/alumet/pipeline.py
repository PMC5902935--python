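"""Configuration-driven pipeline tying the stages into one workflow.

A YAML config names the inputs for whichever stages are to run
(expression -> DEG calling -> enrichment -> cross-study overlap; COBRA
bands -> methylation summaries -> subgroup comparison; Ct table -> fold
changes; methylation x expression correlation). Only the stages whose
sections are present execute; every output table carries the tool
version and a hash of the config, and re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from .annotation import load_insertion_table
from .enrichment import AluEnrichment, reproducible_overlap
from .expression import DifferentialExpression, ExpressionStudy, filter_presence
from .integration import (
    MethylationComparison,
    correlate_methylation_expression,
    summaries_frame,
)
from .io import read_band_csv, write_table
from .cobra import compute_methylation
from .qpcr import Comparison, CtTable, FoldChange

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger("alumet")


class PipelineConfig(dict):
    """Validated pipeline configuration (a dict with a base directory)."""

    def __init__(self, data: dict, base_dir: Path):
        super().__init__(data)
        self.base_dir = Path(base_dir)
        self.validate()

    def validate(self) -> None:
        known = {"seed", "expression", "cobra", "qpcr", "correlation"}
        unknown = set(self) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if not any(k in self for k in ("expression", "cobra", "qpcr")):
            raise ValueError("config names no runnable stage "
                             "(expression, cobra or qpcr section required)")
        for section, keys in (
            ("expression", ("studies", "annotation")),
            ("cobra", ("bands", "samples")),
            ("qpcr", ("ct", "comparisons")),
        ):
            if section in self:
                missing = [k for k in keys if k not in self[section]]
                if missing:
                    raise ValueError(f"config section {section!r} is missing {missing}")
        if "correlation" in self and not ("cobra" in self and "qpcr" in self):
            raise ValueError("correlation stage requires both cobra and qpcr sections")

    def path(self, rel) -> Path:
        p = Path(rel)
        p = p if p.is_absolute() else self.base_dir / p
        if not p.exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
        return p


def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"{path}: empty or malformed config")
    return PipelineConfig(data, base_dir=path.parent)


def _parse_comparisons(raw) -> list:
    return [Comparison(label=c["label"], case=c["case"], control=c["control"]) for c in raw]


def _run_expression(config: PipelineConfig, outdir: Path) -> None:
    section = config["expression"]
    annotation = load_insertion_table(config.path(section["annotation"]))
    alpha = float(section.get("alpha", 0.05))
    cutoff = float(section.get("cutoff", 0.70))
    min_support = int(section.get("min_support", 2))
    overlap_type = section.get("overlap_type", "all")
    overlap_direction = section.get("overlap_direction", "down")
    log.info("annotation: %d Alu-inserted genes", len(annotation))

    per_study_sets: Dict[str, set] = {}
    enrichment_tables = []
    for spec in section["studies"]:
        study = ExpressionStudy.from_files(
            config.path(spec["matrix"]), config.path(spec["samples"]), study_id=spec["id"]
        )
        n_before = study.n_genes
        study = filter_presence(study, cutoff=cutoff)
        log.info("%s: %d/%d genes pass the %.0f%% presence filter",
                 study.study_id, study.n_genes, n_before, 100 * cutoff)
        degs = DifferentialExpression(study).fit(alpha=alpha)
        log.info("%s: %d genes tested, %d DEGs (%d down)", study.study_id,
                 degs.n_tested, len(degs.deg_genes()), len(degs.deg_genes("down")))
        write_table(degs.table.reset_index(names="gene"),
                    outdir / f"degs_{study.study_id}.tsv", config=dict(config))
        enr = AluEnrichment(degs, annotation).fit(alpha=alpha)
        enrichment_tables.append(enr.table)
        log.info("%s: %d/%d enrichment strata significant", study.study_id,
                 int(enr.table["significant"].sum()), len(enr.table))
        gate = enr.stratum(overlap_type, overlap_direction)
        if gate["significant"]:
            alu_set = annotation.genes_with_type(overlap_type)
            per_study_sets[study.study_id] = degs.deg_genes(overlap_direction) & alu_set

    write_table(pd.concat(enrichment_tables, ignore_index=True),
                outdir / "enrichment.tsv", config=dict(config))
    if len(per_study_sets) >= 2:
        overlap = reproducible_overlap(per_study_sets, min_support=min_support)
        log.info("overlap: %d genes supported by >=%d of %d gated studies",
                 len(overlap.genes), min_support, len(per_study_sets))
        write_table(overlap.to_frame(), outdir / "overlap.tsv", config=dict(config))
    else:
        log.info("overlap skipped: only %d study list(s) passed the significance gate",
                 len(per_study_sets))


def _run_cobra(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    section = config["cobra"]
    profiles = read_band_csv(config.path(section["bands"]))
    summaries = summaries_frame([compute_methylation(p) for p in profiles])
    log.info("cobra: %d lanes quantified", len(summaries))
    write_table(summaries.reset_index(names="sample_id"),
                outdir / "methylation.tsv", config=dict(config))
    labels = pd.read_csv(config.path(section["samples"]), sep="\t", dtype=str)
    labels = labels.set_index("sample_id")
    tables = []
    for comp in _parse_comparisons(section.get("comparisons", [])):
        def ids_for(selector):
            sel = {"group": selector} if isinstance(selector, str) else selector
            mask = pd.Series(True, index=labels.index)
            for col, value in sel.items():
                mask &= labels[col] == value
            return labels.index[mask]

        case_ids, control_ids = ids_for(comp.case), ids_for(comp.control)
        groups = pd.Series("other", index=summaries.index)
        groups.loc[groups.index.intersection(case_ids)] = "case"
        groups.loc[groups.index.intersection(control_ids)] = "control"
        result = MethylationComparison(summaries, groups).fit(
            "case", "control", label=comp.label
        )
        t = result.table.reset_index(names="metric")
        t.insert(0, "comparison", comp.label)
        tables.append(t)
        log.info("cobra comparison %r: %d/%d metrics significant", comp.label,
                 int(result.table["significant"].sum()), len(result.table))
    if tables:
        write_table(pd.concat(tables, ignore_index=True),
                    outdir / "methylation_comparisons.tsv", config=dict(config))
    return summaries


def _run_qpcr(config: PipelineConfig, outdir: Path):
    section = config["qpcr"]
    table = CtTable.from_csv(config.path(section["ct"]))
    comparisons = _parse_comparisons(section["comparisons"])
    results = FoldChange(table).fit(comparisons)
    log.info("qpcr: %d comparisons, %d significant", len(results.table),
             int(results.table["significant"].sum()))
    write_table(results.table, outdir / "qpcr.tsv", config=dict(config))
    write_table(results.per_sample, outdir / "qpcr_per_sample.tsv", config=dict(config))
    return results


def _run_correlation(config: PipelineConfig, outdir: Path,
                     summaries: pd.DataFrame, qpcr_results) -> None:
    section = config["correlation"]
    comp_label = section["comparison"]
    per_sample = qpcr_results.per_sample
    sub = per_sample[per_sample["comparison"] == comp_label]
    if sub.empty:
        raise ValueError(f"correlation: qpcr comparison {comp_label!r} not found")
    expression = sub.set_index("sample_id")["rel_expr"]
    result = correlate_methylation_expression(
        summaries, expression, stratum_label=section.get("stratum", comp_label)
    )
    log.info("correlation (%s): n=%d matched samples", result.stratum,
             int(result.table["n"].iloc[0]))
    write_table(result.table.reset_index(names="metric"),
                outdir / f"correlation_{result.stratum}.tsv", config=dict(config))
    write_table(result.scatter, outdir / f"scatter_{result.stratum}.tsv",
                config=dict(config))


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every configured stage; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
    if "expression" in config:
        _run_expression(config, outdir)
    summaries = _run_cobra(config, outdir) if "cobra" in config else None
    qpcr_results = _run_qpcr(config, outdir) if "qpcr" in config else None
    if "correlation" in config:
        _run_correlation(config, outdir, summaries, qpcr_results)
    return outdir
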