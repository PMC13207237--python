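"""DEG calling, z-standardisation, Venn partitioning and the filter cascade."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rponscan import (
    ScanConfig,
    call_significant,
    compute_z,
    default_rponc_grammar,
    filter_candidates,
    scan_genome,
    tally,
    venn_partition,
)
from rponscan.io import DeRecord, GeneModel
from rponscan.regulon import (
    ComparisonResult,
    DeThresholds,
    RegulonCallConfig,
    combine_z,
)
from rponscan.scan import MotifHit

from conftest import make_bundle


def _rec(gene, lfc, padj=0.01, comparison="a"):
    return DeRecord(gene, lfc, padj / 2, padj, comparison)


# ---------------------------------------------------------------------------
# significance calling
# ---------------------------------------------------------------------------

def test_call_significant_strict_thresholds():
    records = [
        _rec("up", 1.5, 0.01),          # 2^1.5 > 2 and padj < 0.05 -> up
        _rec("boundary_fc", 1.0, 0.01),  # fold change exactly 2 fails strict >
        _rec("down", -3.0, 0.01),
        _rec("weak_padj", -3.0, 0.2),    # padj fails
        _rec("boundary_padj", 2.0, 0.05),  # padj exactly 0.05 fails strict <
    ]
    result = call_significant(records, DeThresholds())
    assert result.up == {"up"}
    assert result.down == {"down"}


def test_call_significant_rejects_mixed_comparisons():
    with pytest.raises(ValueError):
        call_significant([_rec("a", 1, comparison="x"), _rec("b", 1, comparison="y")])


def test_thresholds_validation():
    with pytest.raises(ValueError):
        DeThresholds(min_fold_change=1.0)
    with pytest.raises(ValueError):
        DeThresholds(max_padj=0.0)


# ---------------------------------------------------------------------------
# z standardisation
# ---------------------------------------------------------------------------

def test_compute_z_sample_sd():
    records = [_rec("a", 1.0), _rec("b", 2.0), _rec("c", 3.0)]
    z = compute_z(records)
    assert z == pytest.approx({"a": -1.0, "b": 0.0, "c": 1.0})


def test_compute_z_mean_is_zero_for_symmetric_input():
    records = [_rec(f"g{i}", v) for i, v in enumerate([-2, -1, 0, 1, 2])]
    assert compute_z(records)["g2"] == pytest.approx(0.0)


def test_compute_z_errors():
    with pytest.raises(ValueError):
        compute_z([_rec("a", 1.0)])
    with pytest.raises(ValueError):
        compute_z([_rec("a", 1.0), _rec("b", 1.0)])


def test_planted_targets_exceed_z_threshold(bundle):
    z = combine_z(*[compute_z(records) for records in bundle.de_tables.values()])
    assert all(abs(z[g]) >= 2.0 for g in bundle.truth.planted_gene_ids())


# ---------------------------------------------------------------------------
# Venn partitioning
# ---------------------------------------------------------------------------

def _result(up=(), down=(), comparison="a"):
    return ComparisonResult(comparison, frozenset(up), frozenset(down))


def test_venn_worked_example():
    a = _result(up={"a"}, down={"b", "c"})
    b = _result(up={"b", "d"}, down={"c", "e"}, comparison="b")
    part = venn_partition(a, b)
    assert (len(part.shared), len(part.unique_a), len(part.unique_b)) == (2, 1, 2)
    assert len(part.union) == 5
    assert part.direction_conflicts == {"b"}  # down in a, up in b
    assert part.tallies["shared"] == {"up": 0, "down": 2}


def test_venn_identical_and_disjoint_inputs():
    a = _result(up={"x"}, down={"y"})
    same = venn_partition(a, _result(up={"x"}, down={"y"}, comparison="b"))
    assert same.unique_a == same.unique_b == frozenset()
    disjoint = venn_partition(a, _result(up={"z"}, comparison="b"))
    assert disjoint.shared == frozenset()


@given(
    a_up=st.sets(st.integers(0, 40)), a_down=st.sets(st.integers(41, 80)),
    b_up=st.sets(st.integers(0, 40)), b_down=st.sets(st.integers(41, 80)),
)
@settings(max_examples=200, deadline=None)
def test_venn_arithmetic_identities(a_up, a_down, b_up, b_down):
    """|shared| + |unique_a| = |A| and |shared| + |unique_b| = |B| —
    the identity behind a two-comparison DEG Venn diagram."""
    a = _result(up=a_up, down=a_down)
    b = _result(up=b_up, down=b_down, comparison="b")
    part = venn_partition(a, b)
    assert len(part.shared) + len(part.unique_a) == len(a.degs)
    assert len(part.shared) + len(part.unique_b) == len(b.degs)
    assert part.shared | part.unique_a | part.unique_b == a.degs | b.degs
    assert not (part.shared & part.unique_a)
    assert not (part.shared & part.unique_b)
    assert not (part.unique_a & part.unique_b)


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def _toy_universe():
    genes = [
        GeneModel("deg", "chr", 1001, 1600, "+", product="nitrogenase NifH"),
        GeneModel("nondeg", "chr", 3001, 3600, "+", product="other"),
    ]
    hits = [
        MotifHit("deg", -76, "TGGCGTGAATGCCGT", 925, "coding", "chr"),
        MotifHit("nondeg", -76, "TGGCGTGAATGCCGT", 2925, "coding", "chr"),
    ]
    venn = venn_partition(
        _result(down={"deg"}), _result(down={"deg"}, comparison="b")
    )
    z_map = {"deg": -3.0, "nondeg": 0.1}
    return genes, hits, venn, z_map


def test_filter_excludes_non_deg_genes():
    genes, hits, venn, z_map = _toy_universe()
    sites = filter_candidates(hits, venn, z_map, genes)
    assert [s.gene_id for s in sites] == ["deg"]
    assert sites[0].product == "nitrogenase NifH"


def test_filter_all_off_is_identity():
    genes, hits, venn, z_map = _toy_universe()
    config = RegulonCallConfig(
        require_deg_overlap=False, context_mode="off", conservation_max_mismatch=15
    )
    sites = filter_candidates(hits, venn, z_map, genes, config=config)
    assert [(s.gene_id, s.offset, s.site_seq) for s in sites] == [
        (h.gene_id, h.offset, h.site_seq) for h in hits
    ]


def test_filter_context_excludes_hits_inside_gene_bodies():
    genes, hits, venn, z_map = _toy_universe()
    overlapping = MotifHit("deg", -20, "TGGCGTGAATGCCGT", 981, "coding", "chr")
    # offset -20 puts the last 10 bases at genomic 995..., still upstream;
    # instead overlap the neighbour body directly:
    inside = MotifHit("deg", -76, "TGGCGTGAATGCCGT", 1100, "coding", "chr")
    config = RegulonCallConfig(require_deg_overlap=False, conservation_max_mismatch=15)
    sites = filter_candidates([overlapping, inside], venn, z_map, genes, config=config)
    assert [s.genomic_start for s in sites] == [981]


def test_filter_conservation_drops_divergent_sites():
    genes, hits, venn, z_map = _toy_universe()
    cohort = [
        MotifHit("deg", -90, "TGGCGTGAATGCCGT", 911, "coding", "chr"),
        MotifHit("deg", -76, "TGGCGTGAATGCCGT", 925, "coding", "chr"),
        MotifHit("deg", -40, "AGGAAAAAAAAATTT", 961, "coding", "chr"),
    ]
    config = RegulonCallConfig(require_deg_overlap=False, context_mode="off",
                               conservation_max_mismatch=0)
    sites = filter_candidates(cohort, venn, z_map, genes, config=config)
    assert [s.site_seq for s in sites] == ["TGGCGTGAATGCCGT", "TGGCGTGAATGCCGT"]


def test_filter_z_threshold_applies():
    genes, hits, venn, z_map = _toy_universe()
    weak_z = {"deg": -1.5, "nondeg": 0.1}
    assert filter_candidates(hits, venn, weak_z, genes) == []


def test_closed_loop_recovers_exactly_the_planted_targets(grammar):
    bundle = make_bundle(seed=31)
    hits = scan_genome(bundle.replicons, bundle.genes, grammar, ScanConfig())
    results = {c: call_significant(t) for c, t in bundle.de_tables.items()}
    venn = venn_partition(*results.values())
    z = combine_z(*[compute_z(t) for t in bundle.de_tables.values()])
    sites = filter_candidates(hits, venn, z, bundle.genes, grammar, RegulonCallConfig())
    assert {s.gene_id for s in sites} == bundle.truth.planted_gene_ids()


def test_monotonicity_under_threshold_tightening(grammar):
    """Tightening min fold change, padj, z or the mismatch budget never
    enlarges the surviving site set (checked over randomized configs)."""
    bundle = make_bundle(seed=41)
    hits = scan_genome(bundle.replicons, bundle.genes, grammar, ScanConfig())
    z = combine_z(*[compute_z(t) for t in bundle.de_tables.values()])
    rng = np.random.default_rng(0)
    checked = 0
    for _ in range(20):
        loose = {
            "min_fold_change": float(rng.uniform(1.2, 2.5)),
            "max_padj": float(rng.uniform(0.01, 0.2)),
            "z_threshold": float(rng.uniform(0.5, 2.5)),
            "max_mismatch": int(rng.integers(0, 6)),
        }
        knob = rng.choice(list(loose))
        tight = dict(loose)
        if knob == "min_fold_change":
            tight[knob] = loose[knob] + 1.0
        elif knob == "max_padj":
            tight[knob] = loose[knob] / 10
        elif knob == "z_threshold":
            tight[knob] = loose[knob] + 1.0
        else:
            tight[knob] = max(0, loose[knob] - 2)

        def survivors(params):
            thresholds = DeThresholds(params["min_fold_change"], params["max_padj"])
            results = {c: call_significant(t, thresholds)
                       for c, t in bundle.de_tables.items()}
            venn = venn_partition(*results.values())
            config = RegulonCallConfig(
                z_threshold=params["z_threshold"],
                conservation_max_mismatch=params["max_mismatch"],
            )
            sites = filter_candidates(hits, venn, z, bundle.genes, grammar, config)
            return {(s.gene_id, s.offset, s.site_seq) for s in sites}

        assert survivors(tight) <= survivors(loose)
        checked += 1
    assert checked == 20


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def test_tally_of_published_catalogue_counts_six_plasmid_sites(table1):
    counts = tally(table1)
    assert counts["by_replicon_class"]["plasmid"] == 6
    assert counts["by_replicon_class"]["chromosome"] == 74
    assert counts["n_sites"] == 80


def test_tally_with_category_map(table1):
    category_map = {
        "nitrogen_fixation": ["nitrogen fixation", "nitrogenase", "FixJ", "nitrate"],
        "motility": ["flagellar", "chemotaxis"],
    }
    counts = tally(table1, category_map=category_map)
    # cheY + the three flagellar rows
    assert counts["by_category"]["motility"] == 4
    # fixJ, fixA, nrtA and the nitrate/nitrite transport row
    assert counts["by_category"]["nitrogen_fixation"] == 4
    assert sum(counts["by_category"].values()) == 80


def test_tally_empty_and_truth_counts(grammar):
    assert tally([])["n_sites"] == 0
    bundle = make_bundle(seed=51)
    hits = scan_genome(bundle.replicons, bundle.genes, grammar, ScanConfig())
    results = {c: call_significant(t) for c, t in bundle.de_tables.items()}
    venn = venn_partition(*results.values())
    z = combine_z(*[compute_z(t) for t in bundle.de_tables.values()])
    sites = filter_candidates(hits, venn, z, bundle.genes, grammar, RegulonCallConfig())
    counts = tally(sites)
    gene_replicon = {g.gene_id: g.replicon_id for g in bundle.genes}
    truth_plasmid = sum(
        "_p0" in gene_replicon[g] for g in bundle.truth.planted_gene_ids()
    )
    assert counts["by_replicon_class"]["plasmid"] == truth_plasmid
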