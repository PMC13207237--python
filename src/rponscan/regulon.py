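"""Differential-expression thresholding, Venn partitioning and the
candidate-site filtering cascade.

The cascade turns raw genome-scan hits into high-confidence regulon sites
in three steps, mirroring the standard in-silico regulon reconstruction
workflow: (i) the hit's gene must be differentially expressed (fold change
> 2, padj < 0.05 by default) and transcriptome-responsive (|z| of its
log2 fold change within the comparison at or above a threshold, default
2.0); (ii) genomic context — in intergenic-only mode the site itself may
not overlap any annotated gene body; (iii) motif conservation — the site
must lie within a configurable number of mismatches of the consensus built
from the sites surviving (i) and (ii), applied once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .grammar import MotifGrammar, build_pfm, consensus_summary, count_mismatches
from .io import DeRecord, GeneModel, classify_replicon
from .scan import MotifHit


@dataclass(frozen=True)
class DeThresholds:
    """Significance thresholds: fold change > min_fold_change (strict) and
    padj < max_padj (strict)."""

    min_fold_change: float = 2.0
    max_padj: float = 0.05

    def __post_init__(self) -> None:
        if self.min_fold_change <= 1:
            raise ValueError("min_fold_change must exceed 1")
        if not 0 < self.max_padj < 1:
            raise ValueError("max_padj must be in (0, 1)")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_fold_change)


@dataclass(frozen=True)
class ComparisonResult:
    comparison_id: str
    up: frozenset
    down: frozenset

    @property
    def degs(self) -> frozenset:
        return self.up | self.down


def call_significant(
    de_records: Sequence[DeRecord], thresholds: DeThresholds = DeThresholds()
) -> ComparisonResult:
    """Partition one comparison's genes into up-/down-regulated DEGs."""
    comparison_ids = {r.comparison_id for r in de_records}
    if len(comparison_ids) > 1:
        raise ValueError(f"records from multiple comparisons: {sorted(comparison_ids)}")
    cutoff = thresholds.min_abs_log2fc
    up = frozenset(
        r.gene_id for r in de_records
        if r.log2fc > cutoff and r.padj < thresholds.max_padj
    )
    down = frozenset(
        r.gene_id for r in de_records
        if r.log2fc < -cutoff and r.padj < thresholds.max_padj
    )
    return ComparisonResult(
        comparison_id=next(iter(comparison_ids), ""), up=up, down=down
    )


def compute_z(de_records: Sequence[DeRecord]) -> dict[str, float]:
    """Standardise each gene's log2fc within its comparison (sample sd).

    ``z_i = (log2fc_i − mean) / sd`` over all genes of the comparison;
    a gene is called transcriptome-responsive when ``|z|`` meets the
    configured threshold.
    """
    if len(de_records) < 2:
        raise ValueError("need at least 2 records to standardise")
    values = np.array([r.log2fc for r in de_records], dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation across log2 fold changes")
    mean = values.mean()
    return {r.gene_id: float((r.log2fc - mean) / sd) for r in de_records}


def combine_z(*z_maps: dict[str, float]) -> dict[str, float]:
    """Per-gene z with the largest magnitude across comparisons."""
    combined: dict[str, float] = {}
    for z_map in z_maps:
        for gene, z in z_map.items():
            if gene not in combined or abs(z) > abs(combined[gene]):
                combined[gene] = z
    return combined


@dataclass(frozen=True)
class VennPartition:
    """Shared/unique decomposition of two comparisons' DEG sets, with
    per-class up/down tallies (shared-class direction taken from comparison
    a; genes whose direction disagrees between comparisons are flagged,
    not dropped)."""

    shared: frozenset
    unique_a: frozenset
    unique_b: frozenset
    tallies: dict
    direction_conflicts: frozenset

    @property
    def union(self) -> frozenset:
        return self.shared | self.unique_a | self.unique_b


def venn_partition(result_a: ComparisonResult, result_b: ComparisonResult) -> VennPartition:
    a, b = result_a.degs, result_b.degs
    shared = a & b
    unique_a = a - b
    unique_b = b - a
    tallies = {
        "shared": {
            "up": len(shared & result_a.up),
            "down": len(shared & result_a.down),
        },
        "unique_a": {
            "up": len(unique_a & result_a.up),
            "down": len(unique_a & result_a.down),
        },
        "unique_b": {
            "up": len(unique_b & result_b.up),
            "down": len(unique_b & result_b.down),
        },
    }
    conflicts = (shared & result_a.up & result_b.down) | (
        shared & result_a.down & result_b.up
    )
    return VennPartition(
        shared=frozenset(shared),
        unique_a=frozenset(unique_a),
        unique_b=frozenset(unique_b),
        tallies=tallies,
        direction_conflicts=frozenset(conflicts),
    )


@dataclass(frozen=True)
class RegulonCallConfig:
    """Knobs of the three-step filtering cascade.

    ``deg_class`` selects which Venn class feeds filter (i): ``union``
    (default), ``shared``, ``unique_a``, ``unique_b``, ``a`` or ``b``.
    ``conservation_max_mismatch`` of 15 (the site length) disables filter
    (iii); mismatches are counted IUPAC-aware against the cohort consensus.
    """

    z_threshold: float = 2.0
    require_deg_overlap: bool = True
    context_mode: str = "intergenic_only"
    conservation_max_mismatch: int = 0
    deg_class: str = "union"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.conservation_max_mismatch < 0:
            raise ValueError("conservation_max_mismatch must be >= 0")
        if self.context_mode not in ("off", "intergenic_only"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        if self.deg_class not in ("union", "shared", "unique_a", "unique_b", "a", "b"):
            raise ValueError(f"unknown deg_class {self.deg_class!r}")


@dataclass(frozen=True)
class RegulonSite:
    """A hit that survived every enabled filter, with annotation context."""

    gene_id: str
    offset: int
    site_seq: str
    genomic_start: int
    strand_scanned: str
    replicon_id: str
    product: str
    replicon_class: str
    category: str
    flags: tuple  # sorted (name, passed) pairs for the enabled filters


def _select_deg_class(venn: VennPartition, deg_class: str) -> frozenset:
    if deg_class == "union":
        return venn.union
    if deg_class == "a":
        return venn.shared | venn.unique_a
    if deg_class == "b":
        return venn.shared | venn.unique_b
    return getattr(venn, deg_class)


def _overlaps_gene_body(hit: MotifHit, genes_by_replicon: dict) -> bool:
    intervals = genes_by_replicon.get(hit.replicon_id, [])
    lo, hi = hit.genomic_start, hit.genomic_end
    return any(not (hi < s or lo > e) for s, e in intervals)


def filter_candidates(
    hits: Sequence[MotifHit],
    venn: VennPartition,
    z_map: dict[str, float],
    annotations: Sequence[GeneModel],
    grammar: Optional[MotifGrammar] = None,
    config: RegulonCallConfig = RegulonCallConfig(),
    plasmid_rule: Optional[str] = None,
    category_map: Optional[dict] = None,
) -> list[RegulonSite]:
    """Run the three-step cascade over genome-scan hits.

    Deterministic: hits are processed in input order and the conservation
    consensus is built once from the sites surviving steps (i) and (ii).
    With ``require_deg_overlap=False``, ``context_mode="off"`` and
    ``conservation_max_mismatch >= 15`` the input set passes unchanged.
    """
    gene_by_id = {g.gene_id: g for g in annotations}
    genes_by_replicon: dict = {}
    for g in annotations:
        genes_by_replicon.setdefault(g.replicon_id, []).append((g.start, g.end))
    deg_set = _select_deg_class(venn, config.deg_class)

    survivors: list[MotifHit] = []
    for hit in hits:
        if config.require_deg_overlap:
            if hit.gene_id not in deg_set:
                continue
            if abs(z_map.get(hit.gene_id, 0.0)) < config.z_threshold:
                continue
        if config.context_mode == "intergenic_only" and _overlaps_gene_body(
            hit, genes_by_replicon
        ):
            continue
        survivors.append(hit)

    if survivors and config.conservation_max_mismatch < len(survivors[0].site_seq):
        consensus = consensus_summary(build_pfm([h.site_seq for h in survivors])).consensus
        survivors = [
            h for h in survivors
            if count_mismatches(h.site_seq, consensus) <= config.conservation_max_mismatch
        ]

    kwargs = {} if plasmid_rule is None else {"rule": plasmid_rule}
    sites = []
    for hit in survivors:
        gene = gene_by_id.get(hit.gene_id)
        product = gene.product if gene else ""
        sites.append(
            RegulonSite(
                gene_id=hit.gene_id,
                offset=hit.offset,
                site_seq=hit.site_seq,
                genomic_start=hit.genomic_start,
                strand_scanned=hit.strand_scanned,
                replicon_id=hit.replicon_id,
                product=product,
                replicon_class=classify_replicon(hit.replicon_id, **kwargs),
                category=_categorise(product, category_map),
                flags=(
                    ("deg_overlap", config.require_deg_overlap),
                    ("context", config.context_mode != "off"),
                    ("conservation", config.conservation_max_mismatch < 15),
                ),
            )
        )
    return sites


def _categorise(text: str, category_map: Optional[dict]) -> str:
    """Keyword→category lookup over product/description text (first match
    in sorted category order wins); unmapped text is 'unclassified'."""
    if not category_map:
        return "unclassified"
    lowered = (text or "").lower()
    for category in sorted(category_map):
        for keyword in category_map[category]:
            if keyword.lower() in lowered:
                return category
    return "unclassified"


def tally(
    sites: Iterable,
    category_map: Optional[dict] = None,
    plasmid_rule: Optional[str] = None,
) -> dict:
    """Counts by replicon class and by category label.

    Accepts :class:`RegulonSite` objects or published
    :class:`~rponscan.io.SiteRecord` rows (the replicon class then comes
    from the Genoscope-style sequence id and categories from the
    description text).
    """
    kwargs = {} if plasmid_rule is None else {"rule": plasmid_rule}
    by_class: dict = {"chromosome": 0, "plasmid": 0}
    by_category: dict = {}
    total = 0
    for site in sites:
        seq_id = getattr(site, "replicon_id", None) or getattr(site, "seq_id_genoscope")
        text = getattr(site, "product", None)
        if text is None:
            text = getattr(site, "description", "")
        by_class[classify_replicon(seq_id, **kwargs)] += 1
        category = getattr(site, "category", None)
        if category in (None, "unclassified"):
            category = _categorise(text, category_map)
        by_category[category] = by_category.get(category, 0) + 1
        total += 1
    return {"n_sites": total, "by_replicon_class": by_class, "by_category": by_category}
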