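"""Readers and writers for every external representation the pipeline touches.

Conventions (fixed across the package):

* genomic coordinates are 1-based and inclusive, genome-forward, as in GFF3;
* sequences are uppercase over the alphabet ``{A, C, G, T, N}``;
* motif table positions are negative offsets relative to the annotated start
  codon (``-1`` = the base immediately upstream); the Unicode minus sign
  (U+2212) used in printed tables is normalised to ASCII on input.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

#: Genoscope-style naming: a ``_p`` infix followed by a digit marks a
#: (mega)plasmid locus, e.g. ``BRADOA9_v1_p0607`` vs ``BRADOA9_v1_40695``.
DEFAULT_PLASMID_RULE = r"_p\d"

_MINUS_SIGNS = "−–—"  # unicode minus, en dash, em dash


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Replicon:
    """A single replicon (chromosome or plasmid) with its full sequence."""

    replicon_id: str
    sequence: str
    is_plasmid: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.replicon_id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"replicon {self.replicon_id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene, 1-based inclusive coordinates on its replicon."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    name: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: start > end ({self.start} > {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression statistics in one comparison."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float
    comparison_id: str
    padj_missing: bool = False


@dataclass(frozen=True)
class SiteRecord:
    """One published binding-site row (gene label, 15-mer, upstream offset).

    ``position`` may be ``None``: printed site tables occasionally omit the
    offset for a row, and such rows are retained rather than dropped.
    """

    gene_label: str
    description: str
    site_seq: str
    position: Optional[int]
    seq_id_genoscope: str
    seq_id_ncbi: str = ""

    def __post_init__(self) -> None:
        if len(self.site_seq) != 15:
            raise ValueError(
                f"site for {self.gene_label!r} is {len(self.site_seq)} nt, expected 15"
            )
        if set(self.site_seq) - set("ACGT"):
            raise ValueError(f"site for {self.gene_label!r} is not plain DNA")
        if self.position is not None and self.position >= 0:
            raise ValueError(
                f"site for {self.gene_label!r}: position must be negative, "
                f"got {self.position}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, plasmid_rule: str = DEFAULT_PLASMID_RULE) -> list[Replicon]:
    """Read replicons from a FASTA file.

    Sequences are uppercased; the header token before the first whitespace
    becomes the replicon id; ``is_plasmid`` is derived from *plasmid_rule*.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for rec in records:
        rid = rec.id
        if rid in seen:
            raise FormatError(f"{path}: duplicate replicon id {rid!r}")
        seen.add(rid)
        replicons.append(
            Replicon(
                replicon_id=rid,
                sequence=str(rec.seq).upper(),
                is_plasmid=classify_replicon(rid, plasmid_rule) == "plasmid",
            )
        )
    return replicons


def write_fasta(replicons: Sequence[Replicon], path, line_width: int = 70) -> None:
    """Write replicons as wrapped FASTA (default 70 columns)."""
    if not replicons:
        raise ValueError("write_fasta: empty replicon list")
    records = [
        SeqRecord(Seq(r.sequence), id=r.replicon_id, description="")
        for r in replicons
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def _parse_strand(symbol: str, context: str) -> str:
    symbol = symbol.strip()
    for glyph in _MINUS_SIGNS:
        symbol = symbol.replace(glyph, "-")
    if symbol not in ("+", "-"):
        raise FormatError(f"{context}: unknown strand symbol {symbol!r}")
    return symbol


def _genes_from_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    featuretypes = set(db.featuretypes())
    wanted = "gene" if "gene" in featuretypes else "CDS"
    for feat in db.features_of_type(wanted, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        name = feat.attributes.get("Name", [""])[0]
        strand = _parse_strand(feat.strand or ".", f"{path} feature {gene_id}")
        genes.append(
            GeneModel(
                gene_id=gene_id, replicon_id=feat.seqid,
                start=feat.start, end=feat.end, strand=strand,
                name=name, product=product,
            )
        )
    return genes


_TSV_GENE_COLUMNS = ["gene_id", "replicon_id", "start", "end", "strand", "product"]


def _genes_from_tsv(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        rows = [row for row in reader if row and not row[0].startswith("#")]
    if rows and rows[0][:2] == _TSV_GENE_COLUMNS[:2]:
        rows = rows[1:]  # optional header
    for row in rows:
        if len(row) < 6:
            raise FormatError(f"{path}: expected 6 columns {_TSV_GENE_COLUMNS}, got {row}")
        gene_id, replicon_id, start, end, strand, product = row[:6]
        genes.append(
            GeneModel(
                gene_id=gene_id, replicon_id=replicon_id,
                start=int(start), end=int(end),
                strand=_parse_strand(strand, f"{path} gene {gene_id}"),
                product=product,
            )
        )
    return genes


def read_gene_annotations(path, dialect: str = "auto") -> list[GeneModel]:
    """Read gene models from GFF3 or the 6-column TSV dialect.

    The TSV dialect carries ``gene_id, replicon_id, start, end, strand,
    product`` and encodes exactly the same information as a GFF3 ``gene``
    feature with ``ID=`` and ``product=`` attributes.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if dialect == "gff3":
        genes = _genes_from_gff3(path)
    elif dialect == "tsv":
        genes = _genes_from_tsv(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    ids = [g.gene_id for g in genes]
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate gene ids {sorted(dupes)}")
    return genes


def write_gene_annotations_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            handle.write(
                f"{g.replicon_id}\trponscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

DEFAULT_DE_COLUMNS = {
    "gene_id": "gene_id",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


def read_de_table(path, comparison_id: str, columns: Optional[dict] = None) -> list[DeRecord]:
    """Read one comparison's DE table (TSV with a header row).

    *columns* maps the canonical names (``gene_id``, ``log2fc``, ``pvalue``,
    ``padj``) to the file's actual column names. Rows with a missing padj are
    carried with ``padj = 1`` and flagged ``padj_missing``.
    """
    mapping = dict(DEFAULT_DE_COLUMNS)
    if columns:
        mapping.update(columns)
    frame = pd.read_csv(path, sep="\t")
    missing = [mapping[k] for k in DEFAULT_DE_COLUMNS if mapping[k] not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; expected columns "
            f"named {sorted(mapping.values())} (configurable via `columns`)"
        )
    gene_col = mapping["gene_id"]
    dupes = frame[gene_col][frame[gene_col].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicated gene_id(s) {sorted(set(dupes))}")
    records: list[DeRecord] = []
    for _, row in frame.iterrows():
        padj = row[mapping["padj"]]
        padj_missing = pd.isna(padj)
        records.append(
            DeRecord(
                gene_id=str(row[gene_col]),
                log2fc=float(row[mapping["log2fc"]]),
                pvalue=float(row[mapping["pvalue"]]),
                padj=1.0 if padj_missing else float(padj),
                comparison_id=comparison_id,
                padj_missing=bool(padj_missing),
            )
        )
    return records


def write_de_table(records: Sequence[DeRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "padj": [r.padj for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = [
    "gene_label", "description", "site_seq", "position",
    "seq_id_genoscope", "seq_id_ncbi",
]


def _parse_position(raw: str, context: str) -> Optional[int]:
    raw = (raw or "").strip()
    if not raw:
        return None
    for glyph in _MINUS_SIGNS:
        raw = raw.replace(glyph, "-")
    try:
        value = int(raw)
    except ValueError as exc:
        raise FormatError(f"{context}: unparseable position {raw!r}") from exc
    if value >= 0:
        raise FormatError(f"{context}: position must be negative, got {value}")
    return value


def read_site_table(path) -> list[SiteRecord]:
    """Read a binding-site table (TSV with the five published columns).

    Tolerates the Unicode minus sign in the position column and blank
    positions (stored as ``None``).
    """
    records: list[SiteRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "site_seq" not in reader.fieldnames:
            raise FormatError(f"{path}: expected columns {SITE_TABLE_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            label = (row.get("gene_label") or "").strip()
            context = f"{path} row {i} ({label!r})"
            site = (row.get("site_seq") or "").strip().upper()
            if len(site) != 15:
                raise FormatError(f"{context}: site is {len(site)} nt, expected 15")
            records.append(
                SiteRecord(
                    gene_label=label,
                    description=(row.get("description") or "").strip(),
                    site_seq=site,
                    position=_parse_position(row.get("position", ""), context),
                    seq_id_genoscope=(row.get("seq_id_genoscope") or "").strip(),
                    seq_id_ncbi=(row.get("seq_id_ncbi") or "").strip(),
                )
            )
    return records


def write_site_table(records: Iterable[SiteRecord], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene_label, r.description, r.site_seq,
                    "" if r.position is None else str(r.position),
                    r.seq_id_genoscope, r.seq_id_ncbi,
                ]
            )


def packaged_site_table_path() -> Path:
    """Path of the bundled published site table (80 rows)."""
    return Path(resources.files("rponscan").joinpath("data/table1_sites.tsv"))


def load_packaged_site_table() -> list[SiteRecord]:
    return read_site_table(packaged_site_table_path())


# ---------------------------------------------------------------------------
# replicon classification & BED export
# ---------------------------------------------------------------------------

def classify_replicon(seq_id: str, rule: str = DEFAULT_PLASMID_RULE) -> str:
    """Classify a sequence identifier as ``"plasmid"`` or ``"chromosome"``.

    The default rule marks identifiers containing a ``_p`` infix followed by
    a digit as plasmid; anything unmatched is chromosome.
    """
    if not seq_id:
        raise ValueError("empty sequence identifier")
    return "plasmid" if re.search(rule, seq_id) else "chromosome"


def write_bed6(intervals, path) -> None:
    """Write ``(chrom, start_1based, end_1based, name, score, strand)`` rows
    as BED6 (0-based half-open, the only coordinate conversion in the package).
    """
    with open(path, "w") as handle:
        for chrom, start, end, name, score, strand in intervals:
            handle.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n")
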