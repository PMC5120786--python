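"""Junction annotation: anchor location, microhomology, insert taxonomy."""

import pytest

from cgr.annotate import (
    AmbiguousAnchorError,
    AnnotationConfig,
    NoJunctionError,
    annotate_junction,
    annotate_reads,
    classify_insert,
    locate_breakends,
    measure_microhomology,
)
from cgr.core import revcomp
from cgr.simulate import emit_junction_reads, make_replicative_case


def brute_force_mh(truth, junction, genome, max_k=64):
    """Independent microhomology oracle: enumerate overlap lengths directly
    against the truth breakend flank sequences (no anchor machinery)."""
    from cgr.annotate import (
        _ext_after_joint,
        _ext_before_joint,
        _head_from_joint,
        _tail_toward_joint,
    )

    best_i = 0
    for k in range(1, max_k):
        t = _tail_toward_joint(genome, junction.a, k)
        x = _ext_before_joint(genome, junction.b, k)
        if len(t) == k and t == x:
            best_i = k
        else:
            break
    best_j = 0
    for k in range(1, max_k):
        h = _head_from_joint(genome, junction.b, k)
        x = _ext_after_joint(genome, junction.a, k)
        if len(h) == k and h == x:
            best_j = k
        else:
            break
    return best_i + best_j


def test_collinear_read_is_no_junction(toy_genome):
    read = toy_genome.fetch("chr1", 5_000, 6_000)
    with pytest.raises(NoJunctionError):
        locate_breakends(read, toy_genome)


def test_repeated_anchor_is_ambiguous(toy_genome):
    g = toy_genome.copy()
    # plant two identical 60 bp copies, then read from one of them; a
    # spacer base distinct from both downstream contexts pins the anchor
    # at exactly the repeated 60-mer
    probe = g.fetch("chr1", 10_000, 10_059)
    g.set_bases("chr2", 30_000, probe)
    blocked = {g.fetch("chr1", 10_060, 10_060), g.fetch("chr2", 30_060, 30_060),
               g.fetch("chr3", 19_999, 19_999)}
    spacer = next(b for b in "ACGT" if b not in blocked)
    read = probe + spacer + g.fetch("chr3", 20_000, 20_100)
    with pytest.raises(AmbiguousAnchorError) as exc:
        locate_breakends(read, g)
    assert len(exc.value.candidates) >= 2


def test_anchor_overlap_equals_constructed_microhomology():
    tm = make_replicative_case(33, preset="chromoanasynthesis")
    reads = {r.id: r for r in emit_junction_reads(tm, 400)}
    for j in tm.truth_junctions:
        loc = locate_breakends(reads[j.id].seq, tm.genome)
        assert loc.overlap == j.feature.mh_len
        assert {loc.a.key, loc.b.key} == {j.a.key, j.b.key}


@pytest.mark.parametrize("seed", range(1, 21))
def test_measured_mh_equals_brute_force(seed):
    tm = make_replicative_case(seed, preset="mixed")
    for j in tm.truth_junctions:
        measured = measure_microhomology(j.a, j.b, tm.genome)
        assert measured == brute_force_mh(tm, j, tm.genome)
        if not j.feature.insert_len:
            # mh-type joints: flank overlap IS the feature; insert-type
            # joints may share flank bases by chance, but the inserted
            # sequence defines the joint
            assert measured == j.feature.mh_len


def test_untemplated_insert_classification(toy_genome):
    f = classify_insert("ACG", toy_genome, breakends=())
    assert f.kind == "untemplated_insertion" and f.insert_len == 3


def test_templated_insert_multi_chromosome_decomposition(toy_genome):
    a = toy_genome.fetch("chr2", 7_000, 7_040)
    b = toy_genome.fetch("chr3", 9_000, 9_060, "-")
    f = classify_insert(a + b, toy_genome, breakends=())
    assert f.kind == "templated_insertion"
    assert [p[0] for p in f.template_parts] == ["chr2", "chr3"]
    assert f.template_parts[0][1:] == (7_000, 7_040, "+")
    assert f.template_parts[1][1:] == (9_000, 9_060, "-")


def test_partial_decomposition_flagged(toy_genome):
    templ = toy_genome.fetch("chr2", 7_000, 7_040)
    f = classify_insert(templ + "ACGTACGTACGTAAC", toy_genome, breakends=())
    # genuine part recovered, unresolvable remainder reported
    assert f.kind == "templated_insertion"
    assert f.notes


def test_annotation_idempotent_and_strand_symmetric():
    tm = make_replicative_case(44, preset="mixed")
    for r in emit_junction_reads(tm, 350):
        j1 = annotate_junction(r.id, r.seq, tm.genome)
        j2 = annotate_junction(r.id, r.seq, tm.genome)
        assert j1.a == j2.a and j1.b == j2.b and j1.feature == j2.feature
        jr = annotate_junction(r.id, revcomp(r.seq), tm.genome)
        # same breakend loci and feature; strands flip with the read
        assert {jr.a.key, jr.b.key} == {j1.a.key, j1.b.key}
        assert jr.feature.kind == j1.feature.kind
        assert jr.feature.mh_len == j1.feature.mh_len
        for e_fwd, e_rev in ((j1.a, jr.a), (j1.b, jr.b)):
            assert e_rev.strand != e_fwd.strand


def test_features_are_mutually_exclusive_on_emission():
    for seed in range(50, 60):
        tm = make_replicative_case(seed, preset="mixed")
        anns, _ = annotate_reads(emit_junction_reads(tm, 300), tm.genome)
        for j in anns:
            f = j.feature
            assert not (f.mh_len > 0 and f.insert_len > 0)
            assert (f.kind == "templated_insertion") == bool(f.template_parts)


def test_unresolved_reads_reported_not_raised(toy_genome):
    g = toy_genome.copy()
    probe = g.fetch("chr1", 10_000, 10_059)
    g.set_bases("chr2", 30_000, probe)
    blocked = {g.fetch("chr1", 10_060, 10_060), g.fetch("chr2", 30_060, 30_060),
               g.fetch("chr3", 19_999, 19_999)}
    spacer = next(b for b in "ACGT" if b not in blocked)
    reads = [("amb", probe + spacer + g.fetch("chr3", 20_000, 20_100))]
    junctions, unresolved = annotate_reads(reads, g)
    assert junctions == []
    assert unresolved and unresolved[0][0] == "amb"
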