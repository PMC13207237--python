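"""The sigma-54 (RpoN) −24/−12 promoter-site model.

σ54-dependent promoters carry two short anchors: a ``GG`` dinucleotide in
the −24 element and a ``GC``-centred triplet in the −12 element, separated
by a spacer that σ54 contacts only weakly.  The site model used here is a
15-mer grammar::

    position  1        : variable base preceding the −24 GG (default {T, C, A})
    positions 2–3      : the −24 ``GG`` anchor (fixed)
    positions 4–12     : 9-nt spacer, unconstrained
    positions 13–15    : the −12 triplet, drawn from a degenerate element set
                         (default {TGC, TGT, TTT, TTA, CGT, CGC, CTT, CTA})

The 15-mer length follows the uniformly 15-nt sites of the reference
catalogue rather than the longer 17-nt literature consensus
(``YTGGCACGrNNNTTGCW``); the extra flanking bases of that consensus are
weakly constrained and are not part of the membership test.  Membership is
exact set membership — no mismatch tolerance and no score threshold — so
the per-window match probability on uniform iid sequence has the closed
form ``(|first|/4) * (1/16) * (|minus12|/64)`` = 3/512 for the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC ambiguity code for each non-empty subset of {A,C,G,T}.
IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_SETS = {code: bases for bases, code in IUPAC_CODES.items()}

DEFAULT_MINUS24_FIRST = frozenset("TCA")
DEFAULT_MINUS12_ELEMENTS = frozenset(
    {"TGC", "TGT", "TTT", "TTA", "CGT", "CGC", "CTT", "CTA"}
)


class GrammarError(ValueError):
    pass


@dataclass(frozen=True)
class MotifGrammar:
    """Degenerate −24/−12 site grammar (element sets plus spacer length)."""

    minus24_first_set: frozenset = DEFAULT_MINUS24_FIRST
    minus24_core: str = "GG"
    spacer_length: int = 9
    minus12_element_set: frozenset = DEFAULT_MINUS12_ELEMENTS

    def __post_init__(self) -> None:
        if not self.minus24_first_set or not self.minus12_element_set:
            raise GrammarError("element sets must be non-empty")
        if set("".join(self.minus24_first_set)) - set(BASES):
            raise GrammarError("minus24_first_set must be over {A,C,G,T}")
        if any(len(e) != 3 or set(e) - set(BASES) for e in self.minus12_element_set):
            raise GrammarError("minus12 elements must be 3-mers over {A,C,G,T}")
        if self.spacer_length < 0:
            raise GrammarError("spacer_length must be non-negative")

    @property
    def site_length(self) -> int:
        return 1 + len(self.minus24_core) + self.spacer_length + 3

    def match_probability(self) -> float:
        """Per-window match probability under uniform iid base composition."""
        return (
            len(self.minus24_first_set) / 4.0
            * (1.0 / 4.0) ** len(self.minus24_core)
            * len(self.minus12_element_set) / 64.0
        )

    def to_yaml(self, path) -> None:
        payload = {
            "minus24_first_set": sorted(self.minus24_first_set),
            "minus24_core": self.minus24_core,
            "spacer_length": self.spacer_length,
            "minus12_element_set": sorted(self.minus12_element_set),
        }
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MotifGrammar":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        return cls(
            minus24_first_set=frozenset(payload["minus24_first_set"]),
            minus24_core=payload.get("minus24_core", "GG"),
            spacer_length=int(payload.get("spacer_length", 9)),
            minus12_element_set=frozenset(payload["minus12_element_set"]),
        )


def default_rponc_grammar() -> MotifGrammar:
    """The default 15-mer grammar used for genome scans.

    The −12 element set unions the canonical ``TGC`` with the degenerate
    variants reported for nitrogen-fixing bacteria (``TTT, TTA, CGT, CGC,
    CTT, CTA``) plus ``TGT``, which occurs among accepted catalogue sites;
    the position-1 set adds ``A`` to the canonical pyrimidine pair for the
    same reason.  Both sets are configurable.
    """
    return MotifGrammar()


# ---------------------------------------------------------------------------
# membership and scanning
# ---------------------------------------------------------------------------

def matches(grammar: MotifGrammar, site: str) -> bool:
    """Exact membership test for one candidate site.

    Raises on wrong length or non-ACGT characters (an ambiguous window is a
    caller error here; genome scanning handles ``N`` separately).
    """
    if len(site) != grammar.site_length:
        raise GrammarError(
            f"site length {len(site)} != grammar site length {grammar.site_length}"
        )
    site = site.upper()
    if set(site) - set(BASES):
        raise GrammarError(f"site contains non-ACGT characters: {site!r}")
    core_end = 1 + len(grammar.minus24_core)
    return (
        site[0] in grammar.minus24_first_set
        and site[1:core_end] == grammar.minus24_core
        and site[-3:] in grammar.minus12_element_set
    )


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to codes A=0 C=1 G=2 T=3, anything else (N) = 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def find_matches(grammar: MotifGrammar, sequence: str) -> list[int]:
    """All 0-based start indices of grammar-matching windows, ascending.

    Windows containing ``N`` (or any non-ACGT character) never match.
    Vectorised over the whole sequence; equivalent to testing
    :func:`matches` on every window.
    """
    L = grammar.site_length
    n = len(sequence)
    if n < L:
        return []
    codes = _encode(sequence)
    first_ok = np.isin(codes[: n - L + 1], [_BASE_INDEX[b] for b in grammar.minus24_first_set])
    core = grammar.minus24_core
    core_ok = np.ones(n - L + 1, dtype=bool)
    for j, base in enumerate(core, start=1):
        core_ok &= codes[j : j + n - L + 1] == _BASE_INDEX[base]
    # encode each trailing triplet as a base-5 integer (5 to keep N distinct)
    t0 = codes[L - 3 : n - 2].astype(np.int32)
    t1 = codes[L - 2 : n - 1].astype(np.int32)
    t2 = codes[L - 1 : n].astype(np.int32)
    triplet_codes = t0 * 25 + t1 * 5 + t2
    wanted = np.array(
        sorted(
            _BASE_INDEX[e[0]] * 25 + _BASE_INDEX[e[1]] * 5 + _BASE_INDEX[e[2]]
            for e in grammar.minus12_element_set
        ),
        dtype=np.int32,
    )
    minus12_ok = np.isin(triplet_codes, wanted)
    # spacer must be plain ACGT (no N anywhere in the window)
    clean = codes < 4
    window_clean = np.ones(n - L + 1, dtype=bool)
    cumsum = np.concatenate(([0], np.cumsum(clean)))
    window_clean = (cumsum[L:] - cumsum[:-L]) == L
    return np.flatnonzero(first_ok & core_ok & minus12_ok & window_clean).tolist()


# ---------------------------------------------------------------------------
# position frequency matrices and consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts over a set of aligned equal-length sites.

    ``counts`` has shape (4, site_length) with rows indexed A, C, G, T.
    Every column sums to ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int

    @property
    def site_length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.counts / float(self.n_sequences)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("base\t" + "\t".join(str(i + 1) for i in range(self.site_length)) + "\n")
            for i, base in enumerate(BASES):
                handle.write(base + "\t" + "\t".join(str(int(c)) for c in self.counts[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "PositionFrequencyMatrix":
        rows = {}
        with open(path) as handle:
            header = handle.readline()
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                rows[parts[0]] = [int(x) for x in parts[1:]]
        counts = np.array([rows[b] for b in BASES], dtype=np.int64)
        return cls(counts=counts, n_sequences=int(counts[:, 0].sum()))


def build_pfm(sites: Sequence[str]) -> PositionFrequencyMatrix:
    """Tally per-position base counts over *sites* (non-empty, equal length)."""
    if not sites:
        raise ValueError("build_pfm: empty site list")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("build_pfm: sites have unequal lengths")
    counts = np.zeros((4, length), dtype=np.int64)
    for site in sites:
        site = site.upper()
        for pos, base in enumerate(site):
            if base not in _BASE_INDEX:
                raise ValueError(f"build_pfm: non-ACGT base {base!r} in {site!r}")
            counts[_BASE_INDEX[base], pos] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(sites))


@dataclass(frozen=True)
class ConsensusSummary:
    """Modal-base consensus plus per-column information content (bits)."""

    consensus: str
    information_content: np.ndarray
    modal_minus24_triplet: str
    modal_minus12_triplet: str
    modal_bases: str  # single modal base per column, deterministic tie-break

    @property
    def site_length(self) -> int:
        return len(self.consensus)


def _column_ic(freqs: np.ndarray) -> float:
    """2 − Shannon entropy (bits); no small-sample correction."""
    nz = freqs[freqs > 0]
    return 2.0 + float(np.sum(nz * np.log2(nz)))


def consensus_summary(pfm: PositionFrequencyMatrix) -> ConsensusSummary:
    """Consensus string (IUPAC ambiguity codes at ties) and column IC.

    The single-base ``modal_bases`` string breaks ties by alphabetical order
    (deterministic); it feeds the triplet renderings and paralog comparison.
    """
    if pfm.n_sequences < 1:
        raise ValueError("consensus of an empty PFM")
    freqs = pfm.frequencies()
    consensus_chars = []
    modal_chars = []
    ic = np.empty(pfm.site_length)
    for col in range(pfm.site_length):
        column = pfm.counts[:, col]
        top = column.max()
        tied = frozenset(BASES[i] for i in np.flatnonzero(column == top))
        consensus_chars.append(IUPAC_CODES[tied])
        modal_chars.append(min(tied))
        ic[col] = _column_ic(freqs[:, col])
    modal = "".join(modal_chars)
    return ConsensusSummary(
        consensus="".join(consensus_chars),
        information_content=ic,
        modal_minus24_triplet=modal[:3],
        modal_minus12_triplet=modal[-3:],
        modal_bases=modal,
    )


@dataclass(frozen=True)
class ConsensusComparison:
    """Positional modal-base substitutions between two consensus summaries."""

    substitutions: tuple  # of (position_1based, base_a, base_b)
    minus24_shift: Optional[str]  # e.g. "TGG → CGG", None if unchanged
    minus12_shift: Optional[str]

    def __iter__(self):
        return iter(self.substitutions)

    def __len__(self):
        return len(self.substitutions)


def compare_consensus(summary_a: ConsensusSummary, summary_b: ConsensusSummary) -> ConsensusComparison:
    """List positions where the modal base differs between two site cohorts.

    Additionally renders the −24 (positions 1–3) and −12 (positions 13–15)
    triplets in ``"TGG → CGG"`` style when either triplet changed.
    """
    if summary_a.site_length != summary_b.site_length:
        raise ValueError("consensus length mismatch")
    a, b = summary_a.modal_bases, summary_b.modal_bases
    subs = tuple(
        (pos + 1, a[pos], b[pos]) for pos in range(len(a)) if a[pos] != b[pos]
    )
    m24 = (
        f"{summary_a.modal_minus24_triplet} → {summary_b.modal_minus24_triplet}"
        if summary_a.modal_minus24_triplet != summary_b.modal_minus24_triplet
        else None
    )
    m12 = (
        f"{summary_a.modal_minus12_triplet} → {summary_b.modal_minus12_triplet}"
        if summary_a.modal_minus12_triplet != summary_b.modal_minus12_triplet
        else None
    )
    return ConsensusComparison(substitutions=subs, minus24_shift=m24, minus12_shift=m12)


def pwm_log_odds(pfm: PositionFrequencyMatrix, site: str, pseudocount: float = 0.5) -> float:
    """Log2-odds score of *site* under the PFM vs a uniform background.

    Ranking aid only — membership in the grammar, not this score, decides
    whether a window is a candidate site.
    """
    if len(site) != pfm.site_length:
        raise ValueError("site length does not match PFM")
    freqs = (pfm.counts + pseudocount) / (pfm.n_sequences + 4 * pseudocount)
    score = 0.0
    for pos, base in enumerate(site.upper()):
        score += math.log2(freqs[_BASE_INDEX[base], pos] / 0.25)
    return score


def count_mismatches(site: str, consensus: str) -> int:
    """Mismatches of *site* against an IUPAC *consensus* string.

    A position matches when the site's base belongs to the IUPAC set of the
    consensus character, so ambiguity codes (ties) never count as mismatches.
    """
    if len(site) != len(consensus):
        raise ValueError("length mismatch")
    return sum(
        1 for s, c in zip(site.upper(), consensus.upper())
        if s not in IUPAC_SETS.get(c, frozenset())
    )
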