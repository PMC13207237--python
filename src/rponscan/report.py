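"""End-to-end pipeline orchestration and publication-style output rendering.

All outputs are plain TSV/JSON without timestamps, so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import io as io_formats
from .grammar import (
    MotifGrammar,
    build_pfm,
    compare_consensus,
    consensus_summary,
    default_rponc_grammar,
)
from .regulon import (
    DeThresholds,
    RegulonCallConfig,
    call_significant,
    combine_z,
    compute_z,
    filter_candidates,
    tally,
    venn_partition,
)
from .scan import ScanConfig, scan_genome

logger = logging.getLogger("rponscan")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, loadable from YAML."""

    genome: str
    annotations: str
    de_tables: dict  # comparison label ("a"/"b") -> path
    out_dir: str
    scan: ScanConfig = field(default_factory=ScanConfig)
    thresholds: DeThresholds = field(default_factory=DeThresholds)
    call: RegulonCallConfig = field(default_factory=RegulonCallConfig)
    grammar_path: Optional[str] = None
    category_map_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        return cls(
            genome=payload["genome"],
            annotations=payload["annotations"],
            de_tables=dict(payload["de_tables"]),
            out_dir=payload["out_dir"],
            scan=ScanConfig(**payload.get("scan", {})),
            thresholds=DeThresholds(**payload.get("thresholds", {})),
            call=RegulonCallConfig(**payload.get("call", {})),
            grammar_path=payload.get("grammar"),
            category_map_path=payload.get("category_map"),
        )


def render_site_table(sites: Sequence, path=None):
    """Render regulon sites (or published site rows) as a 5-column TSV
    (gene, description, site 5'>3', position, sequence id) plus flags,
    stably sorted by (replicon, genomic position)."""
    import pandas as pd

    rows = []
    for s in sites:
        rows.append(
            {
                "gene": getattr(s, "gene_id", None) or getattr(s, "gene_label", ""),
                "description": getattr(s, "product", None)
                if getattr(s, "product", None) is not None
                else getattr(s, "description", ""),
                "site_seq": s.site_seq,
                "position": getattr(s, "offset", None)
                if hasattr(s, "offset")
                else getattr(s, "position", None),
                "seq_id": getattr(s, "replicon_id", None)
                or getattr(s, "seq_id_genoscope", ""),
                "category": getattr(s, "category", ""),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["gene", "description", "site_seq", "position", "seq_id", "category"]
    )
    sort_key = [
        (getattr(s, "replicon_id", None) or getattr(s, "seq_id_genoscope", ""),
         getattr(s, "genomic_start", 0))
        for s in sites
    ]
    frame = frame.iloc[
        sorted(range(len(frame)), key=lambda i: sort_key[i])
    ].reset_index(drop=True)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def render_logo_matrices(site_sets: dict, out_dir, labels: Optional[Sequence[str]] = None) -> dict:
    """One 4×15 PFM TSV per labelled site cohort, plus a positional
    substitution report between the first two cohorts (``"TGG → CGG"``
    style) when two or more are given."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for label, sites in site_sets.items():
        if not sites:
            raise ValueError(f"empty site set {label!r}")
        pfm = build_pfm(list(sites))
        pfm.to_tsv(out_dir / f"pfm_{label}.tsv")
        summaries[label] = consensus_summary(pfm)
    report: dict = {"consensus": {k: v.consensus for k, v in summaries.items()}}
    keys = labels or sorted(site_sets)
    if len(keys) >= 2:
        a, b = keys[0], keys[1]
        comparison = compare_consensus(summaries[a], summaries[b])
        report["substitutions"] = [
            {"position": pos, a: base_a, b: base_b}
            for pos, base_a, base_b in comparison
        ]
        shifts = [s for s in (comparison.minus24_shift, comparison.minus12_shift) if s]
        report["triplet_shifts"] = shifts
    with open(out_dir / "logo_comparison.json", "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True, ensure_ascii=False)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Scan → DE integration → filter → tallies; write all run artifacts.

    Outputs under ``config.out_dir``: sites.tsv, venn.json, pfm_sites.tsv,
    summary.json, run.log, config_echo.yaml.  Deterministic given inputs.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        def stage(name, fn, *args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged below
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, str(exc)) from exc

        grammar = (
            MotifGrammar.from_yaml(config.grammar_path)
            if config.grammar_path
            else default_rponc_grammar()
        )
        replicons = stage("read_genome", io_formats.read_fasta, config.genome)
        genes = stage("read_annotations", io_formats.read_gene_annotations, config.annotations)
        labels = sorted(config.de_tables)
        if len(labels) != 2:
            raise PipelineError("read_de", f"expected 2 DE tables, got {len(labels)}")
        de = {
            label: stage(
                f"read_de_{label}", io_formats.read_de_table,
                config.de_tables[label], label,
            )
            for label in labels
        }
        hits = stage("scan_genome", scan_genome, replicons, genes, grammar, config.scan)
        results = {
            label: stage(f"call_significant_{label}", call_significant, de[label], config.thresholds)
            for label in labels
        }
        venn = stage("venn", venn_partition, results[labels[0]], results[labels[1]])
        z_map = combine_z(*[stage(f"z_{label}", compute_z, de[label]) for label in labels])
        category_map = None
        if config.category_map_path:
            with open(config.category_map_path) as handle:
                category_map = yaml.safe_load(handle)
        sites = stage(
            "filter_candidates", filter_candidates,
            hits, venn, z_map, genes, grammar, config.call,
            category_map=category_map,
        )
        tallies = stage("tally", tally, sites, category_map)
        render_site_table(sites, out_dir / "sites.tsv")
        if sites:
            render_logo_matrices({"sites": [s.site_seq for s in sites]}, out_dir)
        venn_payload = {
            "shared": len(venn.shared),
            "unique_a": len(venn.unique_a),
            "unique_b": len(venn.unique_b),
            "tallies": venn.tallies,
            "direction_conflicts": sorted(venn.direction_conflicts),
        }
        with open(out_dir / "venn.json", "w") as handle:
            json.dump(venn_payload, handle, indent=1, sort_keys=True)
        summary = {
            "n_candidate_hits": len(hits),
            "n_surviving_sites": len(sites),
            "replicon_tallies": tallies["by_replicon_class"],
            "category_tallies": tallies["by_category"],
            "deg_counts": {
                label: {"up": len(results[label].up), "down": len(results[label].down)}
                for label in labels
            },
            "venn": {k: venn_payload[k] for k in ("shared", "unique_a", "unique_b")},
        }
        with open(out_dir / "summary.json", "w") as handle:
            json.dump(summary, handle, indent=1, sort_keys=True)
        with open(out_dir / "config_echo.yaml", "w") as handle:
            yaml.safe_dump(
                {
                    "genome": str(config.genome),
                    "annotations": str(config.annotations),
                    "de_tables": {k: str(v) for k, v in config.de_tables.items()},
                    "scan": vars(config.scan).copy(),
                    "thresholds": vars(config.thresholds).copy(),
                    "call": vars(config.call).copy(),
                },
                handle, sort_keys=True,
            )
        logger.info("pipeline complete: %d candidates, %d surviving sites",
                    len(hits), len(sites))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
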