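"""Meiotic transmission: independent segregation, single crossovers,
reciprocality and Mendelian conservation, child matching."""

import pytest

from cgr.core import BreakEnd, CNVCall, DerivativeModel, GenomeRef, Junction
from cgr.inheritance import (
    INTERCHROMOSOMAL,
    INTRACHROMOSOMAL,
    ParentalGenotype,
    enumerate_crossovers,
    enumerate_segregation,
    match_child,
)


def _jct(jid, c1, p1, s1, c2, p2, s2):
    return Junction(jid, BreakEnd(c1, p1, s1), BreakEnd(c2, p2, s2))


@pytest.fixture()
def balanced_inter_parent():
    """chrA fragment [20001,30000] moved into chrB at 15000 (balanced)."""
    g = GenomeRef.from_lengths({"chrA": 80_000, "chrB": 60_000})
    derB = DerivativeModel(
        "chrB",
        [(("chrB", 1, 15_000), "+"), (("chrA", 20_001, 30_000), "+"),
         (("chrB", 15_001, 60_000), "+")],
        [_jct("j1", "chrB", 15_000, "retains_left", "chrA", 20_001, "retains_right"),
         _jct("j2", "chrA", 30_000, "retains_left", "chrB", 15_001, "retains_right")],
    )
    derA = DerivativeModel(
        "chrA",
        [(("chrA", 1, 20_000), "+"), (("chrA", 30_001, 80_000), "+")],
        [_jct("j3", "chrA", 20_000, "retains_left", "chrA", 30_001, "retains_right")],
    )
    return ParentalGenotype([derB, derA], g, INTERCHROMOSOMAL)


def test_parent_with_no_derivative_has_single_outcome():
    g = GenomeRef.from_lengths({"chr1": 50_000})
    parent = ParentalGenotype([], g, INTERCHROMOSOMAL)
    outcomes = enumerate_segregation(parent)
    assert len(outcomes) == 1 and outcomes[0].predicted_child_cnv == []


def test_segregation_enumerates_all_combinations(balanced_inter_parent):
    outcomes = enumerate_segregation(balanced_inter_parent)
    assert len(outcomes) == 4
    by_tx = {tuple(sorted(o.transmitted.items())): o for o in outcomes}
    # derivative A without derivative B: the fragment is lost -> deletion
    o = by_tx[(("chrA", "derivative"), ("chrB", "intact"))]
    assert [(c.chrom, c.start, c.end, c.type) for c in o.predicted_child_cnv] \
        == [("chrA", 20_001, 30_000, "DEL")]
    # derivative B without derivative A: the fragment rides along -> duplication
    o = by_tx[(("chrA", "intact"), ("chrB", "derivative"))]
    assert [(c.chrom, c.start, c.end, c.type) for c in o.predicted_child_cnv] \
        == [("chrA", 20_001, 30_000, "DUP")]
    # both derivatives or both intact: balanced child
    assert by_tx[(("chrA", "derivative"), ("chrB", "derivative"))].predicted_child_cnv == []
    assert by_tx[(("chrA", "intact"), ("chrB", "intact"))].predicted_child_cnv == []


def test_mendelian_conservation(balanced_inter_parent):
    for o in enumerate_segregation(balanced_inter_parent):
        assert set(o.transmitted) == {"chrA", "chrB"}
        assert all(v in ("derivative", "intact") for v in o.transmitted.values())


@pytest.fixture()
def balanced_intra_parent():
    """chr1 fragment [40001,50000] excised and reinserted at 10000."""
    g = GenomeRef.from_lengths({"chr1": 100_000})
    der = DerivativeModel(
        "chr1",
        [(("chr1", 1, 10_000), "+"), (("chr1", 40_001, 50_000), "+"),
         (("chr1", 10_001, 40_000), "+"), (("chr1", 50_001, 100_000), "+")],
        [_jct("j1", "chr1", 10_000, "retains_left", "chr1", 40_001, "retains_right"),
         _jct("j2", "chr1", 50_000, "retains_left", "chr1", 10_001, "retains_right"),
         _jct("j3", "chr1", 40_000, "retains_left", "chr1", 50_001, "retains_right")],
    )
    return ParentalGenotype([der], g, INTRACHROMOSOMAL)


def test_balanced_intra_crossover_gives_reciprocal_dup_and_del(balanced_intra_parent):
    outcomes = enumerate_crossovers(balanced_intra_parent, interval_grid_bp=5_000)
    assert outcomes, "no crossover positions found"
    profiles = {
        tuple((c.chrom, c.start, c.end, c.type) for c in o.predicted_child_cnv)
        for o in outcomes
    }
    assert (("chr1", 40_001, 50_000, "DUP"),) in profiles
    assert (("chr1", 40_001, 50_000, "DEL"),) in profiles


def test_crossover_reciprocality(balanced_intra_parent):
    """For every crossover position, the two products' deviations from the
    diploid baseline sum to the parental deviation (segment arithmetic)."""
    parent = balanced_intra_parent
    parental = {
        (c.chrom, c.start, c.end): (1 if c.is_gain else -1)
        for c in parent.parent_cnv()
    }
    outcomes = enumerate_crossovers(parent, interval_grid_bp=5_000)
    by_pos = {}
    for o in outcomes:
        by_pos.setdefault(o.crossover_pos, []).append(o)
    for pos, pair in by_pos.items():
        assert len(pair) == 2
        combined: dict = {}
        for o in pair:
            for c in o.predicted_child_cnv:
                key = (c.chrom, c.start, c.end)
                combined[key] = combined.get(key, 0) + (c.cn - 2)
        combined = {k: v for k, v in combined.items() if v}
        assert combined == parental, (pos, combined, parental)


def test_crossover_excluded_in_duplicated_and_inverted_material():
    """Positions covered more than once (a duplicated insertion) or covered
    only in inverted orientation would create further complexity and host no
    crossover."""
    g = GenomeRef.from_lengths({"chr1": 100_000})
    # fragment [40001,50000] copied (not excised) into 10000, inverted
    der = DerivativeModel(
        "chr1",
        [(("chr1", 1, 10_000), "+"), (("chr1", 40_001, 50_000), "-"),
         (("chr1", 10_001, 100_000), "+")],
        [_jct("j1", "chr1", 10_000, "retains_left", "chr1", 50_000, "retains_left"),
         _jct("j2", "chr1", 40_001, "retains_right", "chr1", 10_001, "retains_right")],
    )
    parent = ParentalGenotype([der], g, INTRACHROMOSOMAL)
    outcomes = enumerate_crossovers(parent, interval_grid_bp=1_000)
    assert outcomes  # the single-covered run between 10001 and 40000 hosts
    for o in outcomes:
        # [40001,50000] is covered twice (once inverted): excluded
        assert not (40_001 <= o.crossover_pos <= 50_000)


def test_unbalanced_intra_parent_transmits_embedded_triplication():
    """A parental insertion with simultaneous extra amplification: the
    duplication-bearing recombinant carries a triplication embedded in the
    duplication; checked against direct segment-count arithmetic."""
    g = GenomeRef.from_lengths({"chr1": 8_000_000})
    I = 500_000
    a1, a2 = 4_000_001, 4_111_000
    b1, b2 = 4_111_001, 4_144_000
    d1, d2 = 7_463_001, 7_540_000
    der = DerivativeModel(
        "chr1",
        [(("chr1", 1, I), "+"), (("chr1", a1, b2), "+"),
         (("chr1", b1, d2), "+"), (("chr1", I + 1, a2), "+"),
         (("chr1", d1, 8_000_000), "+")],
        [_jct("h1", "chr1", I, "retains_left", "chr1", a1, "retains_right"),
         _jct("h2", "chr1", b2, "retains_left", "chr1", b1, "retains_right"),
         _jct("h3", "chr1", d2, "retains_left", "chr1", I + 1, "retains_right"),
         _jct("del", "chr1", a2, "retains_left", "chr1", d1, "retains_right")],
    )
    parent = ParentalGenotype([der], g, INTRACHROMOSOMAL)
    outcomes = enumerate_crossovers(parent, interval_grid_bp=250_000)
    profiles = {
        tuple((c.start, c.end, c.type) for c in o.predicted_child_cnv)
        for o in outcomes
    }
    dup_child = ((a1, a2, "DUP"), (b1, b2, "TRP"), (b2 + 1, d2, "DUP"))
    del_child = ((b1, d1 - 1, "DEL"),)
    assert dup_child in profiles
    assert del_child in profiles


def test_match_child_reports_residual():
    g = GenomeRef.from_lengths({"chrA": 80_000, "chrB": 60_000})
    derA = DerivativeModel(
        "chrA",
        [(("chrA", 1, 20_000), "+"), (("chrA", 30_001, 80_000), "+")],
        [_jct("j", "chrA", 20_000, "retains_left", "chrA", 30_001, "retains_right")],
    )
    parent = ParentalGenotype([derA], g, INTERCHROMOSOMAL)
    outcomes = enumerate_segregation(parent)
    child = [CNVCall("chrA", 20_001, 30_000, "DEL"),
             CNVCall("chrB", 1_000, 2_000, "DUP")]  # unrelated CNV
    res = match_child(child, outcomes)
    assert len(res.matched) == 1
    assert [c.chrom for c in res.residual_child] == ["chrB"]
    assert not res.zero_residual
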