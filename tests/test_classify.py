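"""Mechanism classification: feature extraction, rule cascade, monotonicity,
agreement with the generative model on noise-free simulations."""

import dataclasses

import pytest

from cgr.classify import (
    LABEL_BALANCED,
    LABEL_BASIC,
    LABEL_CHROMOANASYNTHESIS,
    LABEL_UNCLASSIFIED,
    CaseFeatures,
    ClassifierThresholds,
    annotate_repeats,
    classify,
    extract_features,
    merged_gain_regions,
)
from cgr.core import BreakEnd, CNVCall, Junction
from cgr.simulate import make_end_joining_case, make_replicative_case


def test_merged_gain_regions_counts_embedded_triplication_once():
    calls = [
        CNVCall("chrX", 1_001, 2_000, "DUP"),
        CNVCall("chrX", 2_001, 3_000, "TRP"),
        CNVCall("chrX", 3_001, 4_000, "DUP"),
        CNVCall("chr5", 9_001, 9_500, "DUP"),
    ]
    assert len(merged_gain_regions(calls)) == 2


def test_extract_features_empty_case():
    f = extract_features(None, [], [])
    assert f.n_gains == 0 and f.max_mh == 0 and f.n_templated_insertions == 0
    assert f.net_balanced  # nothing unbalanced about nothing


def test_extract_features_from_simulated_truth(chromo_truth):
    f = extract_features(None, chromo_truth.truth_calls(),
                         chromo_truth.truth_junctions)
    assert f.n_gains == 2
    assert f.n_templated_insertions >= 1
    assert f.deletion_at_insertion_site
    assert f.n_chromosomes == 3


def _features(**kw):
    base = dict(n_gains=1, deletion_at_insertion_site=True, max_mh=1)
    base.update(kw)
    return CaseFeatures(**base)


def test_rule_cascade_labels():
    assert classify(_features(n_gains=2, max_mh=5)).label == LABEL_CHROMOANASYNTHESIS
    assert classify(_features(has_trp=True, n_templated_insertions=1)).label \
        == LABEL_CHROMOANASYNTHESIS
    assert classify(_features()).label == LABEL_BASIC
    assert classify(_features(n_gains=0, net_balanced=True, max_mh=6)).label \
        == LABEL_BALANCED
    assert classify(_features(n_gains=2)).label == LABEL_UNCLASSIFIED


def test_single_gain_with_templated_insert_is_flagged_novelty():
    call = classify(_features(n_templated_insertions=1))
    assert call.label == LABEL_CHROMOANASYNTHESIS
    assert call.notes  # combination outside the described case classes


def test_evidence_trail_is_complete_and_consistent():
    call = classify(_features(n_gains=2, max_mh=7))
    names = [n for n, _, _ in call.evidence]
    assert any("n_gains" in n for n in names)
    assert any("max_mh" in n for n in names)
    assert any("net_balanced" in n for n in names)
    assert any("de_novo" in n for n in names)  # reported, never used
    assert any(ok for _, _, ok in call.evidence)


def test_monotonicity_gains_and_mh_never_demote_to_basic():
    f = _features(n_gains=2, max_mh=5)
    assert classify(f).label == LABEL_CHROMOANASYNTHESIS
    for change in (dict(has_trp=True), dict(max_mh=12), dict(n_gains=4),
                   dict(n_templated_insertions=2)):
        assert classify(dataclasses.replace(f, **change)).label \
            == LABEL_CHROMOANASYNTHESIS


def test_threshold_validation():
    with pytest.raises(ValueError):
        classify(_features(), ClassifierThresholds(mh_chromoanasynthesis_cutoff=99))


@pytest.mark.parametrize("seed", range(1, 101))
def test_full_agreement_with_generative_model(seed):
    """On noise-free truth features the classifier matches the generator:
    iterative replicative chains with extra gains -> chromoanasynthesis;
    single-switch duplication insertions -> basic; end-joining balanced
    exchanges -> balanced."""
    kind = ["basic", "chromoanasynthesis", "balanced"][seed % 3]
    if kind == "balanced":
        tm = make_end_joining_case(seed)
        want = LABEL_BALANCED
    else:
        tm = make_replicative_case(seed, preset=kind)
        want = LABEL_BASIC if kind == "basic" else LABEL_CHROMOANASYNTHESIS
    f = extract_features(None, tm.truth_calls(), tm.truth_junctions)
    assert classify(f).label == want


def test_annotate_repeats_lookup():
    j1 = Junction("j1", BreakEnd("chr1", 150, "retains_left"),
                  BreakEnd("chr2", 900, "retains_right"))
    bed = [("chr1", 100, 200, "L2a"), ("chr2", 0, 50, "AluSx1")]
    labels = annotate_repeats([j1], bed)
    assert labels["j1"] == ("L2a", "-")
    assert annotate_repeats([j1], [])["j1"] == ("-", "-")
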