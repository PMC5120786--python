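"""Breakpoint-graph reconstruction: truth recovery, hypothetical-junction
inference, copy-number conservation."""

import pytest
from conftest import merge_walk, rc_walk

from cgr.core import CNVCall, GenomeRef, calls_from_segments
from cgr.reconstruct import (
    GraphConsistencyError,
    build_graph,
    count_junctions,
    emit_derivative_sequence,
    reconstruct,
    snap_calls_to_junctions,
)
from cgr.simulate import cnv_from_walks, make_replicative_case

PRESETS = ["basic", "chromoanasynthesis", "mixed"]


def test_empty_graph_reconstructs_reference():
    g = GenomeRef.from_lengths({"chr1": 50_000})
    graph = build_graph([], [], g)
    res = reconstruct(graph)
    assert res.status == "ok"
    model = res.best.walks["chr1"]
    assert merge_walk(model.walk) == ((("chr1", 1, 50_000), "+"),)
    assert count_junctions(res.best) == 0
    assert emit_derivative_sequence(
        model, GenomeRef({"chr1": "ACGT" * 12_500})
    ) == "ACGT" * 12_500


def test_breakend_outside_chromosome_is_inconsistent():
    from cgr.core import BreakEnd, Junction

    g = GenomeRef.from_lengths({"chr1": 50_000})
    j = Junction("j", BreakEnd("chr1", 60_000, "retains_left"),
                 BreakEnd("chr1", 100, "retains_right"))
    with pytest.raises(GraphConsistencyError):
        build_graph([], [j], g)


@pytest.mark.parametrize("seed", range(1, 101))
def test_truth_walk_recovered_with_zero_hypotheticals(seed):
    """With all truth junctions supplied, the minimal reconstruction uses no
    hypothetical junction and the truth walk is in the minimal model set
    (up to whole-derivative reverse complement)."""
    tm = make_replicative_case(seed, preset=PRESETS[seed % 3])
    graph = build_graph(tm.truth_cnv, tm.truth_junctions, tm.genome)
    res = reconstruct(graph)
    assert res.status == "ok"
    assert res.best.n_hypothetical == 0
    truth = merge_walk(tm.derivative_model.walk)
    walks = [merge_walk(m.walks["chr1"].walk) for m in res.models]
    assert truth in walks or rc_walk(truth) in walks


@pytest.mark.parametrize("seed", range(1, 26))
def test_withheld_junction_rederived_as_sole_hypothetical(seed):
    tm = make_replicative_case(seed, preset=PRESETS[seed % 3])
    for k, withheld in enumerate(tm.truth_junctions):
        kept = [j for i, j in enumerate(tm.truth_junctions) if i != k]
        res = reconstruct(build_graph(tm.truth_cnv, kept, tm.genome),
                          max_hypothetical=2)
        assert res.status == "ok"
        assert res.best.n_hypothetical == 1
        want = {withheld.a.key, withheld.b.key}
        assert any(
            {m.hypothetical[0].a.key, m.hypothetical[0].b.key} == want
            for m in res.models
        ), (seed, k)


@pytest.mark.parametrize("seed", [3, 9, 15, 27])
def test_copy_number_conservation_of_every_returned_model(seed):
    """Recomputing CN from any returned walk set (plus intact homologs)
    reproduces the input calls exactly."""
    tm = make_replicative_case(seed, preset=PRESETS[seed % 3])
    graph = build_graph(tm.truth_cnv, tm.truth_junctions, tm.genome)
    res = reconstruct(graph)
    want = sorted((s.chrom, s.start, s.end, s.cn) for s in tm.truth_cnv)
    for m in res.models:
        recomputed = cnv_from_walks(
            list(m.walks.values()), tm.genome, list(m.walks.keys())
        )
        # every involved chromosome contributes one walk here, so the
        # "rearranged" bookkeeping is uniform: cn = (ploidy - 1) + uses
        assert sorted((s.chrom, s.start, s.end, s.cn) for s in recomputed) == want


def test_derivative_sequence_round_trip(chromo_truth):
    rebuilt = emit_derivative_sequence(
        chromo_truth.derivative_model, chromo_truth.genome
    )
    assert rebuilt == chromo_truth.derivative_seq


def test_hypothetical_junction_emits_gap_placeholder():
    tm = make_replicative_case(8, preset="basic")
    kept = tm.truth_junctions[:1]
    res = reconstruct(build_graph(tm.truth_cnv, kept, tm.genome))
    model = res.best.walks["chr1"]
    seq = emit_derivative_sequence(model, tm.genome)
    assert "N" * 10 in seq


def test_count_junctions_filters_by_support(basic_truth):
    res = reconstruct(
        build_graph(basic_truth.truth_cnv, basic_truth.truth_junctions,
                    basic_truth.genome)
    )
    assert count_junctions(res.best) == 2
    assert count_junctions(res.best, support="sequenced") == 2
    assert count_junctions(res.best, support="hypothetical") == 0


def test_snap_calls_to_junctions(basic_truth):
    calls = calls_from_segments(basic_truth.truth_cnv)
    blurred = [
        CNVCall(c.chrom, c.start + 90, c.end - 110, c.type, cn=c.cn)
        for c in calls
    ]
    snapped = snap_calls_to_junctions(blurred, basic_truth.truth_junctions, 200)
    graph = build_graph(snapped, basic_truth.truth_junctions, basic_truth.genome)
    res = reconstruct(graph)
    assert res.status == "ok" and res.best.n_hypothetical == 0
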