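"""Probe segmentation, pattern strings, DUP-TRP/INV-DUP detection."""

import pytest

from cgr.cnv import (
    call_cnvs,
    detect_dup_trp_inv_dup,
    parse_pattern,
    pattern_string,
    segment_probes,
)
from cgr.core import CNVCall, GenomeRef, calls_from_segments
from cgr.genome import make_toy_genome
from cgr.simulate import (
    EventChain,
    SwitchEvent,
    emit_probe_table,
    make_replicative_case,
    probe_table_from_segments,
    simulate_replicative,
)


def test_zero_noise_segmentation_recovers_truth(basic_truth):
    probes = emit_probe_table(basic_truth, 200, 0.0, seed=1)
    segs = [s for s in segment_probes(probes, basic_truth.genome)
            if s.cn != s.baseline]
    truth = sorted(basic_truth.truth_cnv, key=lambda s: (s.chrom, s.start))
    segs = sorted(segs, key=lambda s: (s.chrom, s.start))
    assert [(s.chrom, s.cn) for s in segs] == [(s.chrom, s.cn) for s in truth]
    for got, want in zip(segs, truth):
        assert abs(got.start - want.start) <= 200  # probe-resolution bounds
        assert abs(got.end - want.end) <= 200


@pytest.mark.parametrize("seed", range(1, 51))
def test_noisy_segmentation_exact_cn_recovery(seed):
    """CNVs covered by >= 20 probes are recovered with exact copy number
    under per-probe noise of 0.15 on the log2 ratio."""
    tm = make_replicative_case(seed, preset=["basic", "chromoanasynthesis"][seed % 2])
    probes = emit_probe_table(tm, 200, 0.15, seed=seed)
    segs = [s for s in segment_probes(probes, tm.genome) if s.cn != s.baseline]
    for want in (s for s in tm.truth_cnv if s.size_bp >= 20 * 200):
        assert any(
            s.chrom == want.chrom and s.cn == want.cn
            and abs(s.start - want.start) <= 800 and abs(s.end - want.end) <= 800
            for s in segs
        ), (seed, want, segs)


def test_all_baseline_input_gives_no_calls():
    g = GenomeRef.from_lengths({"chr1": 50_000})
    probes = probe_table_from_segments(g, [], 200, 0.0, seed=1)
    assert call_cnvs(probes, g) == []


def test_short_chromosome_single_baseline_segment_with_warning():
    g = GenomeRef.from_lengths({"chr1": 50_000})
    probes = probe_table_from_segments(g, [], 200, 0.0, seed=1).head(3)
    with pytest.warns(UserWarning):
        segs = segment_probes(probes, g)
    assert len(segs) == 1 and segs[0].cn == segs[0].baseline


def test_male_x_baseline_comes_from_ploidy():
    g = GenomeRef.from_lengths({"chrX": 50_000}, {"chrX": 1})
    dup = CNVCall("chrX", 10_001, 20_000, "DUP", cn=2, baseline=1)
    probes = probe_table_from_segments(g, [dup], 200, 0.0, seed=1)
    calls = call_cnvs(probes, g)
    assert len(calls) == 1 and calls[0].type == "DUP" and calls[0].cn == 2


def test_pattern_string_shapes():
    calls = [
        CNVCall("chr6", 100_001, 113_000, "DUP"),
        CNVCall("chr6", 150_001, 154_000, "DEL"),
        CNVCall("chr6", 200_001, 286_000, "DEL"),
    ]
    assert pattern_string(calls, "chr6") == "DUP-NML-DEL-NML-DEL"
    assert pattern_string([], "chr1") == "NML"
    adjacent = [
        CNVCall("chrX", 1_001, 2_000, "DUP"),
        CNVCall("chrX", 2_001, 3_000, "TRP"),
        CNVCall("chrX", 3_001, 4_000, "DUP"),
    ]
    assert pattern_string(adjacent, "chrX") == "DUP-TRP-DUP"


def test_pattern_string_round_trip():
    pat = "DUP-NML-DUP-TRP-DUP"
    assert "-".join(parse_pattern(pat)) == pat


def _dup_trp_calls():
    return [
        CNVCall("chrX", 10_001, 20_000, "DUP"),
        CNVCall("chrX", 20_001, 26_000, "TRP"),
        CNVCall("chrX", 26_001, 40_000, "DUP"),
    ]


def test_dup_trp_inv_dup_requires_inversion():
    from cgr.core import BreakEnd, Junction

    calls = _dup_trp_calls()
    inv = Junction("j", BreakEnd("chrX", 20_001, "retains_right"),
                   BreakEnd("chrX", 9_000, "retains_right"))
    direct = Junction("j", BreakEnd("chrX", 20_001, "retains_right"),
                      BreakEnd("chrX", 9_000, "retains_left"))
    ok, info = detect_dup_trp_inv_dup(calls, [inv])
    assert ok and info["junction"] == "j"
    ok, _ = detect_dup_trp_inv_dup(calls, [direct])
    assert not ok  # triplication inside a duplication but all joins direct


def test_dup_trp_inv_dup_from_simulated_chain():
    """An inverted-triplication chain: the derivative carries the central
    segment three times, the middle copy inverted."""
    g = make_toy_genome(1, [100_000], seed=77)
    s_b, e_b = 30_001, 40_000
    s_c, e_c = 40_001, 46_000
    s_d, e_d = 46_001, 56_000
    # landings fall inside already-replicated sequence, so the joints carry
    # small untemplated inserts (edge-fitted) rather than microhomology
    chain = EventChain(
        ("chr1", e_d),
        [
            SwitchEvent("chr1", e_c, "-", copy_len=e_c - s_c + 1,
                        untemplated_insert="AC"),
            SwitchEvent("chr1", s_b, "+", copy_len=e_d - s_b + 1,
                        untemplated_insert="GA"),
            SwitchEvent("chr1", e_d + 1, "+", untemplated_insert="TCA"),
        ],
        ("chr1", e_d + 1),
        seed=7,
    )
    tm = simulate_replicative(g, chain, plant=True)
    calls = calls_from_segments(tm.truth_cnv)
    assert pattern_string(calls, "chr1") == "DUP-TRP-DUP"
    ok, info = detect_dup_trp_inv_dup(calls, tm.truth_junctions, slop_bp=2)
    assert ok
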