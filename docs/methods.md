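# Methods

## The site model

σ⁵⁴-dependent promoters are recognised through two short anchors, the −24
"GG" and −12 "GC"-centred elements of the literature consensus
`YTGGCACGrNNNTTGCW`. `rponscan` deliberately models a site as a **15-mer**
— first base + GG + 9-nt spacer + 3-nt −12 triplet — because the curated
site catalogue bundled with the package is uniformly 15 nt; the two
flanking bases of the 17-nt consensus are weakly constrained and excluded
from the membership test.

Membership is **exact set membership**, not a score threshold:

* position 1 ∈ `{T, C, A}`. The consensus `Y` implies `{T, C}`; `A` is
  included because accepted catalogue sites begin with `AGG`. Configurable.
* positions 2–3 = `GG`, fixed.
* positions 4–12: unconstrained spacer. σ⁵⁴ contacts this region weakly
  and the catalogue shows no usable signal there.
* positions 13–15 ∈ `{TGC, TGT, TTT, TTA, CGT, CGC, CTT, CTA}`: the
  canonical `TGC` plus the degenerate variants reported for nitrogen-fixing
  bacteria (`TTT, TTA, CGT, CGC, CTT, CTA`) plus `TGT`, which occurs in
  accepted catalogue sites (e.g. `AGGCCTTGCGACTGT`) although it is absent
  from the usual variant lists. Configurable; all 80 catalogue sites pass.

Because membership is exact, the per-window match probability on uniform
iid sequence has the closed form `(3/4)·(1/16)·(8/64) = 3/512 ≈ 0.00586`,
which both the test suite and the acceptance script verify empirically on
1 Mb within 3 binomial standard errors (overlapping windows are weakly
dependent, but the GG anchor decorrelates neighbouring windows enough that
the binomial error bound holds comfortably in practice).

An optional PWM log₂-odds score against a uniform background
(`pwm_log_odds`, pseudocount 0.5) is provided for *ranking* hits only;
it never decides membership.

## Coordinates and offsets

All persisted coordinates are 1-based, inclusive, genome-forward (GFF3
convention); the only conversion (BED6 export) is centralised in
`io.write_bed6`. Upstream windows are read 5′→3′ on the gene's coding
strand: for a + strand gene starting at *s* the window is
`[max(1, s−500), s−1]`; for a − strand gene ending at *e* it is
`[e+1, min(len, e+500)]` reverse-complemented. Offsets are negative, with
**−1 the base immediately upstream of the start codon** and a hit anchored
at its **5′-most** matched base, so a hit at −76 occupies −76…−62.
Published tables do not state which end their position column anchors;
the 5′ anchor is this package's documented convention, and the round-trip
`offset → genomic interval → offset` is property-tested. Windows are
truncated at replicon ends; `intergenic_only` boundary mode additionally
truncates at the nearest neighbouring gene body. Start codons are taken
from the annotation as-is (no re-calling of alternative starts).

Both-strand scanning (`strand_mode="both"`) is available but off by
default: curated site tables report one site 5′→3′ per gene, consistent
with coding-strand orientation.

A catalogue caveat: three published rows print positions −14 or −12,
closer to the start codon than a 5′-anchored 15-mer allows, and one row
prints no position at all. Rows are stored verbatim (`position` is
optional), and the `offset ≤ −15` invariant applies only to scanner
output.

## The filter cascade

Raw scans are dominated by chance matches (≈ 2.8 expected per 500-nt
window per strand at the 3/512 rate), so candidate hits pass three
filters, each independently switchable:

1. **Expression**: the gene must belong to the configured DEG class
   (union/shared/unique of two comparisons; fold change > 2 strictly,
   padj < 0.05 strictly) *and* be transcriptome-responsive, |z| ≥ 2.0,
   where z standardises the gene's log₂ fold change against the mean and
   sample standard deviation of all genes in its comparison. The source
   material states only "z-score ≥ 2.0" without a formula; per-comparison
   standardisation of log₂FC is the simplest reading and is documented as
   a choice. Two-sided |z| is used because σ⁵⁴ loss produces both down-
   and upregulation. Genes absent from a DE table are treated as
   non-significant there, not dropped.
2. **Genomic context** (`intergenic_only`, default): the site itself may
   not overlap any annotated gene body. This replaces a manual
   annotation-platform inspection with a deterministic rule.
3. **Motif conservation**: the site must lie within
   `conservation_max_mismatch` (default 0) mismatches of the consensus
   built from the sites surviving steps 1–2, applied once. Mismatches are
   counted IUPAC-aware — a base matching an ambiguity code in the
   consensus is not a mismatch — replacing a manual alignment-inspection
   step. The default of 0 suits homogeneous cohorts (each site must equal
   the cohort consensus at unambiguous positions); heterogeneous cohorts
   should raise the budget, and 15 disables the filter.

Tightening any threshold can only shrink the set surviving steps 1–2;
step 3's consensus is rebuilt from that shrinking cohort, so monotonicity
of the final set is not a theorem, but it holds in every randomized
configuration tested on planted bundles, where the consensus is pinned by
the dominant planted exemplar.

Venn partitioning satisfies the identities |shared| + |unique_a| = |A|
and |shared| + |unique_b| = |B| by construction; per-class up/down tallies
take the shared class's direction from comparison *a* and flag (never
drop) genes whose direction disagrees between comparisons.

Replicon tallies classify sequence identifiers with a configurable
pattern, by default the Genoscope-style `_p`+digit infix
(`BRADOA9_v1_p0607` → plasmid, `BRADOA9_v1_40695` → chromosome).
Functional categories come from a user-supplied keyword → category map
over product text, because any such grouping is editorial; unmapped
products fall into `unclassified`.

## Consensus and logos

PFMs are raw per-position base counts (columns sum to the cohort size).
The consensus takes the modal base per column, rendering ties as IUPAC
ambiguity codes (deterministic and order-free); per-column information
content is `2 − H` bits with Shannon entropy `H` of the relative
frequencies and **no small-sample correction**, so a unanimous column
scores 2 bits, a uniform column 0, a half/half column 1. Paralog
comparison lists positions whose modal bases differ and renders the −24
(positions 1–3) and −12 (positions 13–15) triplets as e.g. `TGG → CGG`.
The logo contract is the 4×15 matrix TSV; no image rendering is attempted.

## The synthetic-data generator

`simulate_bundle` emulates the *structure* of a two-mutant-vs-wild-type
regulon study, not any particular dataset:

* **Genome**: two replicons — a 400-gene chromosome and a 100-gene
  plasmid whose identifier carries the `_p` infix — with genes of
  U(300, 900) nt tiled left-to-right, U(200, 400) nt intergenic gaps and
  random strands. Background bases are iid at GC 0.5 (uniform), so the
  3/512 analytic null holds exactly. No dinucleotide structure, operons,
  or compositional skew.
* **Planted sites** (30 by default) are written on the coding strand at
  offsets U(−120, −20) upstream of randomly chosen genes, always inside
  the intergenic gap; − strand genes receive the reverse complement
  genome-forward. Sites are drawn from the grammar by default
  (`site_sequences=None`) or planted verbatim from a supplied list;
  closed-loop tests plant the catalogue's fixJ exemplar
  `TGGCGTGAATGCCGT`, the published site/offset pair the package also uses
  as its planting example.
* **DE tables**: planted targets draw log₂FC from N(±3, 0.25²) with 80 %
  of targets downregulated (σ⁵⁴ acts mainly as an activator); background
  genes draw from N(0, 0.25²). P-values are a two-sided z-test against the
  known background sd, padj is Benjamini–Hochberg within each comparison.
  This is a structural model, not a count model: no negative-binomial
  dispersion, library sizes or replicate structure.

With these defaults the power calculation is closed-form: the cohort sd
of log₂FC is ≈ 0.77 (30 targets at |mean| 3 among 500 genes), so a
down-target's z is ≈ −3.7 with the threshold at −2 more than 5 target-sd
away — recall 1.0 across seeds is an analytic consequence of the design,
not a tuned outcome. Every output is a pure function of (config, seed).

What closed-loop passes do **not** show about real data: real genomes have
compositional structure that raises (or locally lowers) the chance-match
rate, real DE effect sizes are heteroskedastic and correlated along
operons, and real site cohorts are heterogeneous so the conservation
filter needs a nonzero mismatch budget. The generator establishes
*correctness of the machinery*, not field performance.

## Numerical and degenerate-input choices

* Sample (ddof = 1) standard deviation in z-scores; zero sd or fewer than
  two records is an error, not a silent pass.
* `N` in a window never matches; `N` passed to the single-site membership
  test is an error (caller bug), not `False`.
* Empty upstream windows (gene at a replicon edge) are returned flagged
  and yield no hits rather than raising.
* Unicode minus signs in positions and strands are normalised to ASCII on
  input; missing padj values are carried as 1.0 and flagged.
* TSV/JSON outputs carry no timestamps; reruns on identical inputs are
  byte-identical.
* Problem sizes used by the test and acceptance runs — 1 Mb background
  scans, five 500-gene bundles — were chosen as the smallest sizes at
  which the binomial error bounds and the closed-form power margin are
  comfortably resolved.

## Known limitations

* The membership grammar has no mismatch tolerance; a true site with a
  degraded anchor is invisible to the scan (the PWM score can rank such
  near-misses only among grammar matches).
* Filter 2 knows nothing about operon structure: a site upstream of an
  internal operon gene passes context but may not be a real promoter.
* The z-score reading of "transcriptome-responsive" is one of several
  defensible formulas; with heavy-tailed fold-change distributions the
  cohort sd is inflated and the filter becomes conservative.
* Replicon classification is purely lexical; genomes with other naming
  schemes must override the pattern.
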