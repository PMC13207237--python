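"""Synthetic genomes, planted sigma-54 sites and DE tables with known truth.

The generator emulates the structure of a two-mutant-vs-wild-type regulon
study on a multi-replicon genome (chromosome plus a "_p"-infixed
megaplasmid): annotated genes on both strands, sites planted at known
upstream offsets on the coding strand, and two differential-expression
tables in which planted-target genes carry strong effects (mostly
downregulation, since sigma-54 acts mainly as an activator) while
background genes are null.

The background sequence is iid at the configured GC so that the analytic
grammar match probability (3/512 per window for the defaults, under
uniform composition) holds exactly.  Everything is a pure function of
``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats

from .grammar import BASES, MotifGrammar, default_rponc_grammar
from .io import (
    DeRecord,
    GeneModel,
    Replicon,
    write_de_table,
    write_fasta,
    write_gene_annotations_gff3,
)
from .scan import reverse_complement


@dataclass(frozen=True)
class EffectModel:
    """Target/background log2 fold-change distributions for the DE tables."""

    target_mean_log2fc: float = -3.0
    target_sd: float = 0.25
    background_sd: float = 0.25
    frac_down: float = 0.8

    def __post_init__(self) -> None:
        if self.target_sd <= 0 or self.background_sd <= 0:
            raise ValueError("effect sds must be positive")
        if not 0.0 <= self.frac_down <= 1.0:
            raise ValueError("frac_down must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one synthetic bundle.

    Defaults describe a desk-scale two-replicon genome: a 400-gene
    chromosome and a 100-gene megaplasmid (identifier carries the ``_p``
    infix), genes of 300–900 nt separated by 200–400 nt intergenic gaps,
    uniform base composition, 30 planted sites at offsets −120…−20, and
    two mutant-vs-WT comparisons sharing the planted target set.
    """

    seed: int = 0
    replicon_specs: tuple = (
        ("SYNDOA_v1_chrom", 400, False),
        ("SYNDOA_v1_p001", 100, True),
    )  # (replicon_id, n_genes, is_plasmid)
    gene_length_range: tuple = (300, 900)
    intergenic_length_range: tuple = (200, 400)
    gc_content: float = 0.5
    n_planted_sites: int = 30
    plant_offset_range: tuple = (-120, -20)
    effect_model: EffectModel = EffectModel()
    comparison_ids: tuple = ("wt_vs_rc", "wt_vs_db")
    site_sequences: Optional[tuple] = None  # None -> draw sites from the grammar

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        lo, hi = self.plant_offset_range
        if not (lo <= hi <= -15):
            raise ValueError("plant offsets must satisfy min <= max <= -15")
        if self.gene_length_range[0] <= 0 or self.intergenic_length_range[0] <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one bundle: planted sites and responsive genes."""

    planted: list  # of (gene_id, offset, site_seq)
    responsive_genes: dict  # comparison_id -> set of gene_id
    config: SimulationConfig

    def planted_gene_ids(self) -> set:
        return {gene_id for gene_id, _, _ in self.planted}

    def to_json(self, path) -> None:
        payload = {
            "planted": [[g, o, s] for g, o, s in self.planted],
            "responsive_genes": {k: sorted(v) for k, v in self.responsive_genes.items()},
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[Replicon], list[GeneModel], SyntheticTruth]:
    """Generate background replicons and tiled gene models.

    Genes are tiled left to right with sampled intergenic gaps and sampled
    strands; the replicon length is whatever the tiling requires plus a
    trailing gap, so gene placement never fails by construction.  The
    returned truth object is a skeleton (no sites planted yet).
    """
    rng = np.random.default_rng(config.seed)
    replicons: list[Replicon] = []
    genes: list[GeneModel] = []
    glo, ghi = config.gene_length_range
    ilo, ihi = config.intergenic_length_range
    for rep_index, (replicon_id, n_genes, _is_plasmid) in enumerate(config.replicon_specs):
        cursor = 1
        rep_genes = []
        for i in range(n_genes):
            gap = int(rng.integers(ilo, ihi + 1))
            length = int(rng.integers(glo, ghi + 1))
            start = cursor + gap
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            rep_genes.append(
                GeneModel(
                    gene_id=f"g{rep_index}_{i:04d}",
                    replicon_id=replicon_id,
                    start=start, end=end, strand=strand,
                    product="hypothetical protein",
                )
            )
            cursor = end + 1
        total = cursor + int(rng.integers(ilo, ihi + 1))
        seq = _random_sequence(rng, total, config.gc_content)
        replicons.append(
            Replicon(
                replicon_id=replicon_id,
                sequence=seq.tobytes().decode("ascii"),
                is_plasmid=_is_plasmid,
            )
        )
        genes.extend(rep_genes)
    truth = SyntheticTruth(planted=[], responsive_genes={}, config=config)
    return replicons, genes, truth


def _draw_site(rng: np.random.Generator, grammar: MotifGrammar) -> str:
    first = rng.choice(sorted(grammar.minus24_first_set))
    spacer = "".join(rng.choice(list(BASES), size=grammar.spacer_length))
    minus12 = rng.choice(sorted(grammar.minus12_element_set))
    return f"{first}{grammar.minus24_core}{spacer}{minus12}"


def plant_sites(
    replicons: Sequence[Replicon],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    grammar: Optional[MotifGrammar] = None,
    explicit: Optional[Sequence[tuple]] = None,
) -> tuple[list[Replicon], SyntheticTruth]:
    """Overwrite upstream positions with sigma-54 sites; record the truth.

    Sites are written in coding-strand orientation at the requested offset
    (the site's 5'-most base ``|offset|`` nt upstream of the start codon);
    genome-forward storage handles reverse complementation for − strand
    genes.  With *explicit* ``(gene_id, offset, site_seq)`` triples those
    are planted verbatim; otherwise ``config.n_planted_sites`` genes are
    sampled and sites come from ``config.site_sequences`` (cycled) or are
    drawn from the grammar.  Offsets always stay inside the gene's
    intergenic gap (plants never overwrite a neighbouring gene body); a
    requested offset that would collide raises.
    """
    grammar = grammar or default_rponc_grammar()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_by_id = {g.gene_id: g for g in genes}
    seqs = {r.replicon_id: bytearray(r.sequence, "ascii") for r in replicons}

    # genome-forward interval occupied by a site at `offset` upstream of `gene`
    def forward_interval(gene: GeneModel, offset: int, L: int) -> tuple[int, int]:
        if gene.strand == "+":
            start = gene.start + offset
        else:
            start = gene.end - offset - (L - 1)
        return start, start + L - 1

    gene_bodies = {}
    for g in genes:
        gene_bodies.setdefault(g.replicon_id, []).append((g.start, g.end))

    def collides(replicon_id: str, lo: int, hi: int) -> bool:
        if lo < 1 or hi > len(seqs[replicon_id]):
            return True
        return any(not (hi < s or lo > e) for s, e in gene_bodies[replicon_id])

    if explicit is not None:
        requests = [(gene_by_id[g], o, s) for g, o, s in explicit]
        for gene, offset, site in requests:
            lo, hi = forward_interval(gene, offset, len(site))
            if collides(gene.replicon_id, lo, hi):
                raise ValueError(
                    f"planted site for {gene.gene_id!r} at offset {offset} "
                    "collides with a gene body or replicon edge"
                )
    else:
        lo_off, hi_off = config.plant_offset_range
        chosen = rng.choice(len(genes), size=config.n_planted_sites, replace=False)
        requests = []
        pool = tuple(config.site_sequences) if config.site_sequences else None
        for k, gene_index in enumerate(sorted(chosen.tolist())):
            gene = genes[gene_index]
            site = pool[k % len(pool)] if pool else _draw_site(rng, grammar)
            for _ in range(50):  # resample until the site fits the gap
                offset = int(rng.integers(lo_off, hi_off + 1))
                lo, hi = forward_interval(gene, offset, len(site))
                if not collides(gene.replicon_id, lo, hi):
                    break
            else:
                raise ValueError(
                    f"could not place a site upstream of {gene.gene_id!r} within "
                    f"offsets [{lo_off}, {hi_off}]"
                )
            requests.append((gene, offset, site))

    planted = []
    for gene, offset, site in requests:
        site = site.upper()
        lo, hi = forward_interval(gene, offset, len(site))
        forward = site if gene.strand == "+" else reverse_complement(site)
        seqs[gene.replicon_id][lo - 1 : hi] = forward.encode("ascii")
        planted.append((gene.gene_id, offset, site))

    new_replicons = [
        Replicon(
            replicon_id=r.replicon_id,
            sequence=seqs[r.replicon_id].decode("ascii"),
            is_plasmid=r.is_plasmid,
        )
        for r in replicons
    ]
    planted.sort(key=lambda t: t[0])
    truth = SyntheticTruth(
        planted=planted,
        responsive_genes={c: {g for g, _, _ in planted} for c in config.comparison_ids},
        config=config,
    )
    return new_replicons, truth


def simulate_de_tables(
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> dict[str, list[DeRecord]]:
    """Two mutant-vs-WT DE tables with strong effects on planted targets.

    Target genes draw log2fc from the effect distribution (the configured
    fraction downregulated, the rest mirrored upward); background genes
    draw from the null.  P-values are a two-sided z-test of log2fc against
    the known background sd; padj is Benjamini–Hochberg within each
    comparison.
    """
    unknown = {g for genes_ in truth.responsive_genes.values() for g in genes_} - {
        g.gene_id for g in genes
    }
    if unknown:
        raise ValueError(f"truth references genes absent from the annotation: {sorted(unknown)}")
    eff = config.effect_model
    tables: dict[str, list[DeRecord]] = {}
    for c_index, comparison_id in enumerate(config.comparison_ids):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, c_index]))
        targets = truth.responsive_genes.get(comparison_id, set())
        records = []
        for gene in genes:
            if gene.gene_id in targets:
                down = rng.random() < eff.frac_down
                mean = eff.target_mean_log2fc if down else -eff.target_mean_log2fc
                lfc = float(rng.normal(mean, eff.target_sd))
            else:
                lfc = float(rng.normal(0.0, eff.background_sd))
            pvalue = float(2.0 * stats.norm.sf(abs(lfc) / eff.background_sd))
            records.append((gene.gene_id, lfc, pvalue))
        padj = stats.false_discovery_control([p for _, _, p in records], method="bh")
        tables[comparison_id] = [
            DeRecord(
                gene_id=g, log2fc=lfc, pvalue=p, padj=float(q),
                comparison_id=comparison_id,
            )
            for (g, lfc, p), q in zip(records, padj)
        ]
    return tables


@dataclass
class Bundle:
    """One fully simulated study: genome, annotation, truth, DE tables."""

    replicons: list
    genes: list
    truth: SyntheticTruth
    de_tables: dict


def simulate_bundle(
    config: SimulationConfig,
    grammar: Optional[MotifGrammar] = None,
    out_dir: Optional[Path] = None,
) -> Bundle:
    """Run the full generator; optionally write the bundle directory
    (genome.fasta, genes.gff3, truth.json, one TSV per comparison,
    config.yaml echo)."""
    replicons, genes, _ = simulate_genome(config)
    replicons, truth = plant_sites(replicons, genes, config, grammar=grammar)
    de_tables = simulate_de_tables(genes, truth, config)
    bundle = Bundle(replicons=replicons, genes=genes, truth=truth, de_tables=de_tables)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(replicons, out_dir / "genome.fasta")
        write_gene_annotations_gff3(genes, out_dir / "genes.gff3")
        truth.to_json(out_dir / "truth.json")
        for comparison_id, records in de_tables.items():
            write_de_table(records, out_dir / f"{comparison_id}.tsv")
        with open(out_dir / "config.yaml", "w") as handle:
            yaml.safe_dump(_config_echo(config), handle, sort_keys=False)
    return bundle


def _listify(value):
    if isinstance(value, tuple):
        return [_listify(v) for v in value]
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    return value


def _config_echo(config: SimulationConfig) -> dict:
    return _listify(dataclasses.asdict(config))
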