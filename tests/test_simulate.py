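"""Simulator behaviour: determinism, truth invariants, assay emulation."""

import numpy as np
import pytest

from cgr.genome import make_toy_genome
from cgr.simulate import (
    EventChain,
    JunctionConstructionError,
    SwitchEvent,
    cnv_from_walks,
    emit_junction_reads,
    emit_probe_table,
    make_end_joining_case,
    make_replicative_case,
    simulate_end_joining_insertion,
    simulate_replicative,
)


def test_make_toy_genome_contract():
    g = make_toy_genome(3, [2_000_000, 1_000_000, 500_000], 0.41, seed=7)
    assert [g.lengths[c] for c in g.names] == [2_000_000, 1_000_000, 500_000]
    # same seed -> byte-identical sequences
    g2 = make_toy_genome(3, [2_000_000, 1_000_000, 500_000], 0.41, seed=7)
    assert all(g.seq(c) == g2.seq(c) for c in g.names)
    # minimum viable genome accepted
    make_toy_genome(1, [1_000], 0.5, seed=1)
    with pytest.raises(ValueError):
        make_toy_genome(1, [0], 0.5, seed=1)
    gc = make_toy_genome(1, [200_000], 0.70, seed=3)
    frac = sum(gc.seq("chr1").count(b) for b in "GC") / 200_000
    assert abs(frac - 0.70) < 0.01


def test_switch_event_rejects_mh_with_insert():
    with pytest.raises(ValueError):
        SwitchEvent("chr1", 100, mh_len=2, untemplated_insert="AA")


def test_two_switch_chain_gives_dup_del_and_two_junctions():
    tm = make_replicative_case(5, preset="basic")
    calls = tm.truth_calls()
    assert sorted(c.type for c in calls) == ["DEL", "DUP"]
    dup = next(c for c in calls if c.type == "DUP")
    dele = next(c for c in calls if c.type == "DEL")
    assert dup.chrom == "chr2" and dele.chrom == "chr1"
    assert len(tm.truth_junctions) == 2


def test_blunt_junction_null_case():
    g = make_toy_genome(2, [60_000, 40_000], seed=21)
    chain = EventChain(
        ("chr1", 20_000),
        [
            SwitchEvent("chr2", 10_000, "+", copy_len=3_000),
            SwitchEvent("chr1", 22_000, "+"),
        ],
        ("chr1", 22_000),
        seed=21,
    )
    tm = simulate_replicative(g, chain, plant=True)
    assert [j.feature.kind for j in tm.truth_junctions] == ["blunt", "blunt"]


def test_templated_insert_with_three_parts():
    g = make_toy_genome(3, [60_000, 40_000, 40_000], seed=31)
    parts = [("chr3", 5_000, 5_030, "+"), ("chr2", 30_000, 30_040, "-"),
             ("chr3", 20_000, 20_024, "+")]
    chain = EventChain(
        ("chr1", 20_000),
        [
            SwitchEvent("chr2", 10_000, "+", copy_len=3_000,
                        templated_insert_sources=parts),
            SwitchEvent("chr1", 22_000, "+"),
        ],
        ("chr1", 22_000),
        seed=31,
    )
    tm = simulate_replicative(g, chain, plant=True)
    f = tm.truth_junctions[0].feature
    assert f.kind == "templated_insertion"
    assert len(f.template_parts) == 3
    assert f.insert_len == 31 + 41 + 25


def test_impossible_microhomology_fails_loudly():
    g = make_toy_genome(2, [60_000, 40_000], seed=41)
    chain = EventChain(
        ("chr1", 20_000),
        [
            SwitchEvent("chr2", 10_000, "+", copy_len=3_000, mh_len=12),
            SwitchEvent("chr1", 22_000, "+"),
        ],
        ("chr1", 22_000),
        seed=41,
    )
    # without planting, a 12 bp shared tract will not exist near the target
    with pytest.raises(JunctionConstructionError):
        simulate_replicative(g, chain, plant=False)
    tm = simulate_replicative(g, chain, plant=True)
    assert tm.truth_junctions[0].feature.mh_len == 12


@pytest.mark.parametrize("preset", ["basic", "chromoanasynthesis", "mixed"])
def test_truth_model_invariants(preset):
    """Length conservation and CNV-recomputability on every preset."""
    for seed in (1, 2, 3):
        tm = make_replicative_case(seed, preset=preset)
        tm.check_invariants()  # raises on violation


def test_cnv_consistency_recomputed_from_walks(chromo_truth):
    recomputed = cnv_from_walks(
        chromo_truth.derivatives, chromo_truth.genome,
        chromo_truth.rearranged_chroms,
    )
    assert sorted((s.chrom, s.start, s.end, s.cn) for s in recomputed) == sorted(
        (s.chrom, s.start, s.end, s.cn) for s in chromo_truth.truth_cnv
    )


def test_end_joining_balanced_exchange():
    g = make_toy_genome(2, [80_000, 60_000], seed=5)
    tm = simulate_end_joining_insertion(
        g, ("chr1", 20_000, 30_000), ("chr2", 15_000), seed=3
    )
    assert tm.truth_cnv == []  # balanced: no net copy change anywhere
    assert len(tm.truth_junctions) >= 3


def test_end_joining_reciprocal_and_trim():
    g = make_toy_genome(2, [80_000, 60_000], seed=5)
    rec = simulate_end_joining_insertion(
        g, ("chr1", 20_000, 30_000), ("chr2", 15_000),
        reciprocal_fragment=("chr2", 15_001, 15_815), seed=3,
    )
    assert rec.truth_cnv == []  # material exchanged, nothing gained or lost
    assert len(rec.truth_junctions) == 4
    trim = simulate_end_joining_insertion(
        g, ("chr1", 20_000, 30_000), ("chr2", 15_000), seed=3, trim_left=4_000
    )
    calls = trim.truth_calls()
    assert [(c.chrom, c.type, c.size_bp) for c in calls] == [("chr1", "DEL", 4_000)]


def test_end_joining_rejects_overlapping_reciprocal():
    g = make_toy_genome(1, [80_000], seed=5)
    with pytest.raises(ValueError):
        simulate_end_joining_insertion(
            g, ("chr1", 20_000, 30_000), ("chr1", 25_000),
            reciprocal_fragment=("chr1", 25_001, 26_000), seed=1,
        )


def test_probe_table_closed_forms_and_determinism(basic_truth):
    probes = emit_probe_table(basic_truth, spacing_bp=200, noise_sd=0.0, seed=1)
    dup = next(s for s in basic_truth.truth_cnv if s.cn == 3)
    dele = next(s for s in basic_truth.truth_cnv if s.cn == 1)
    in_dup = probes[(probes.chrom == dup.chrom)
                    & probes.pos.between(dup.start, dup.end)]
    in_del = probes[(probes.chrom == dele.chrom)
                    & probes.pos.between(dele.start, dele.end)]
    assert np.allclose(in_dup.log2ratio, np.log2(3 / 2))
    assert np.allclose(in_del.log2ratio, -1.0)
    n1 = emit_probe_table(basic_truth, 200, 0.15, seed=9)
    n2 = emit_probe_table(basic_truth, 200, 0.15, seed=9)
    assert n1.equals(n2)
    with pytest.raises(ValueError):
        emit_probe_table(basic_truth, spacing_bp=10)


def test_junction_reads_construction(basic_truth):
    reads = emit_junction_reads(basic_truth, flank_bp=500)
    assert len(reads) == len(basic_truth.truth_junctions)
    for r in reads:
        jct = next(j for j in basic_truth.truth_junctions if j.id == r.id)
        assert len(r.seq) == 1_000 + jct.feature.insert_len
        assert not r.clipped


def test_hypothetical_junctions_emit_no_read(basic_truth):
    from dataclasses import replace

    import cgr.simulate as sim

    tm = basic_truth
    hypo = sim.TruthModel(
        genome=tm.genome,
        derivatives=tm.derivatives,
        derivative_seqs=tm.derivative_seqs,
        truth_junctions=[
            sim.Junction(j.id, j.a, j.b, support="hypothetical")
            for j in tm.truth_junctions
        ],
        truth_cnv=tm.truth_cnv,
        rearranged_chroms=tm.rearranged_chroms,
        junction_layout=tm.junction_layout,
    )
    assert emit_junction_reads(hypo, 500) == []
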