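"""Strand-aware upstream-window extraction and genome-wide motif scanning.

Offset convention (used everywhere a "Position" is reported): offsets are
negative, counted on the gene's coding strand, with ``-1`` the base
immediately upstream of the annotated start codon.  A hit's offset anchors
its 5'-most matched base, so a 15-mer hit at ``-76`` occupies offsets
``-76 .. -62``.  Published site tables do not state which end their position
column anchors; the 5' anchor is this package's documented choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from Bio.Seq import Seq

from .grammar import MotifGrammar, find_matches
from .io import GeneModel, Replicon


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the upstream scan.

    window_length
        Upstream window size in nt (default 500, i.e. scan within −500 bp
        of annotated start codons).
    strand_mode
        ``coding_only`` (default) scans the window as read on the gene's
        coding strand; ``both`` additionally scans its reverse complement.
    boundary_mode
        ``fixed_window`` (default) always takes the full window (truncated
        only at replicon ends); ``intergenic_only`` further truncates at the
        nearest neighbouring gene boundary.
    report_mode
        ``all_hits`` (default) or ``most_proximal_only`` (keep the hit with
        the largest offset per gene, for one-row-per-gene tables).
    """

    window_length: int = 500
    strand_mode: str = "coding_only"
    boundary_mode: str = "fixed_window"
    report_mode: str = "all_hits"

    def __post_init__(self) -> None:
        if self.window_length < 15:
            raise ValueError("window_length must be >= 15")
        if self.strand_mode not in ("coding_only", "both"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if self.boundary_mode not in ("fixed_window", "intergenic_only"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.report_mode not in ("all_hits", "most_proximal_only"):
            raise ValueError(f"unknown report_mode {self.report_mode!r}")


@dataclass(frozen=True)
class UpstreamWindow:
    """The upstream region of one gene, read 5'→3' on the coding strand.

    ``genomic_start``/``genomic_end`` are 1-based inclusive genome-forward
    coordinates; for a − strand gene the stored ``sequence`` is the reverse
    complement of that genomic interval.  ``effective_length`` may be
    shorter than the configured window at replicon ends (or at neighbouring
    genes in intergenic-only mode); zero-length windows are flagged empty.
    """

    gene_id: str
    replicon_id: str
    genomic_start: int
    genomic_end: int
    strand: str
    sequence: str
    effective_length: int

    @property
    def is_empty(self) -> bool:
        return self.effective_length == 0


@dataclass(frozen=True)
class MotifHit:
    """One grammar match inside a gene's upstream window."""

    gene_id: str
    offset: int
    site_seq: str
    genomic_start: int
    strand_scanned: str  # "coding" or "template"
    replicon_id: str

    @property
    def genomic_end(self) -> int:
        return self.genomic_start + len(self.site_seq) - 1


def extract_upstream(
    gene: GeneModel,
    replicon: Replicon,
    config: ScanConfig,
    genes: Optional[Sequence[GeneModel]] = None,
) -> UpstreamWindow:
    """Extract the (possibly truncated) upstream window of *gene*.

    For a + strand gene starting at ``s`` the window covers genomic
    ``[max(1, s - L), s - 1]``; for a − strand gene ending at ``e`` it
    covers ``[e + 1, min(len, e + L)]`` and the sequence is
    reverse-complemented so that its last base is the one at offset −1.
    *genes* supplies neighbours for ``intergenic_only`` truncation.
    """
    if gene.replicon_id != replicon.replicon_id:
        raise ValueError(
            f"gene {gene.gene_id!r} is on {gene.replicon_id!r}, not {replicon.replicon_id!r}"
        )
    L = config.window_length
    if gene.strand == "+":
        lo, hi = max(1, gene.start - L), gene.start - 1
    else:
        lo, hi = gene.end + 1, min(len(replicon), gene.end + L)
    if config.boundary_mode == "intergenic_only" and genes:
        for other in genes:
            if other.gene_id == gene.gene_id or other.replicon_id != gene.replicon_id:
                continue
            # truncate at the nearest neighbouring gene body inside the window
            if other.end < hi and other.end >= lo and gene.strand == "+":
                lo = max(lo, other.end + 1)
            if other.start > lo and other.start <= hi and gene.strand == "-":
                hi = min(hi, other.start - 1)
    if hi < lo:
        return UpstreamWindow(
            gene_id=gene.gene_id, replicon_id=replicon.replicon_id,
            genomic_start=gene.start, genomic_end=gene.start - 1,
            strand=gene.strand, sequence="", effective_length=0,
        )
    segment = replicon.sequence[lo - 1 : hi]
    if gene.strand == "-":
        segment = reverse_complement(segment)
    return UpstreamWindow(
        gene_id=gene.gene_id, replicon_id=replicon.replicon_id,
        genomic_start=lo, genomic_end=hi, strand=gene.strand,
        sequence=segment, effective_length=len(segment),
    )


def _hit_genomic_start(window: UpstreamWindow, index: int, site_length: int) -> int:
    """Genome-forward start coordinate of a match at window *index*."""
    if window.strand == "+":
        return window.genomic_start + index
    # window sequence is the reverse complement of [genomic_start, genomic_end]
    return window.genomic_end - index - (site_length - 1)


def scan_window(
    grammar: MotifGrammar, window: UpstreamWindow, config: ScanConfig
) -> list[MotifHit]:
    """Scan one upstream window; hits sorted by offset ascending.

    A hit's offset is ``index − effective_length`` (its 5'-most base, counted
    back from the start codon).  In both-strand mode the reverse complement
    of the window is also scanned; template-strand hits carry the site as
    read on the template strand, with the offset of its 5'-most template
    base mirrored into the same window coordinates.
    """
    if window.is_empty:
        return []
    L = grammar.site_length
    hits: list[MotifHit] = []
    for index in find_matches(grammar, window.sequence):
        hits.append(
            MotifHit(
                gene_id=window.gene_id,
                offset=index - window.effective_length,
                site_seq=window.sequence[index : index + L],
                genomic_start=_hit_genomic_start(window, index, L),
                strand_scanned="coding",
                replicon_id=window.replicon_id,
            )
        )
    if config.strand_mode == "both":
        rc = reverse_complement(window.sequence)
        for index in find_matches(grammar, rc):
            coding_index = window.effective_length - index - L
            hits.append(
                MotifHit(
                    gene_id=window.gene_id,
                    offset=coding_index - window.effective_length,
                    site_seq=rc[index : index + L],
                    genomic_start=_hit_genomic_start(window, coding_index, L),
                    strand_scanned="template",
                    replicon_id=window.replicon_id,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand_scanned))
    return hits


def scan_genome(
    replicons: Sequence[Replicon],
    genes: Sequence[GeneModel],
    grammar: MotifGrammar,
    config: ScanConfig,
) -> list[MotifHit]:
    """Scan the upstream window of every annotated gene.

    Deterministic ordering: (replicon order as given, gene start, offset).
    ``most_proximal_only`` keeps the hit with the largest (least negative)
    offset per gene.
    """
    by_id = {r.replicon_id: r for r in replicons}
    hits: list[MotifHit] = []
    order = {r.replicon_id: i for i, r in enumerate(replicons)}
    for gene in sorted(genes, key=lambda g: (order.get(g.replicon_id, 1 << 30), g.start)):
        replicon = by_id.get(gene.replicon_id)
        if replicon is None:
            raise ValueError(f"gene {gene.gene_id!r} references unknown replicon {gene.replicon_id!r}")
        window = extract_upstream(gene, replicon, config, genes=genes)
        gene_hits = scan_window(grammar, window, config)
        if config.report_mode == "most_proximal_only" and gene_hits:
            gene_hits = [max(gene_hits, key=lambda h: h.offset)]
        hits.extend(gene_hits)
    return hits


def hit_to_genomic(hit: MotifHit, gene: GeneModel, replicon: Replicon) -> tuple[int, int, str]:
    """Map a hit's offset to 1-based inclusive genomic coordinates.

    Returns ``(genomic_start, genomic_end, genome_strand)`` where the strand
    is the genome strand the site is read on (the gene's strand for
    coding-strand hits, its opposite for template-strand hits).
    """
    if hit.gene_id != gene.gene_id:
        raise ValueError("hit does not belong to this gene")
    if gene.replicon_id != replicon.replicon_id:
        raise ValueError("gene/replicon mismatch")
    L = len(hit.site_seq)
    if gene.strand == "+":
        start = gene.start + hit.offset
    else:
        start = gene.end - hit.offset - (L - 1)
    end = start + L - 1
    if not (1 <= start and end <= len(replicon)):
        raise ValueError("hit extends outside the replicon")
    genome_strand = gene.strand
    if hit.strand_scanned == "template":
        genome_strand = "-" if gene.strand == "+" else "+"
    return start, end, genome_strand


def genomic_to_offset(genomic_start: int, gene: GeneModel, site_length: int = 15) -> int:
    """Inverse of :func:`hit_to_genomic` for coding-strand hits."""
    if gene.strand == "+":
        return genomic_start - gene.start
    return gene.end - (genomic_start + site_length - 1)
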