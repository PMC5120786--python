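"""The nine transcribed case fixtures are the pipeline's acceptance surface:
every expected value in every fixture must be reproduced."""

import pytest

from cgr.fixtures import list_cases, load_fixture, run_case

ALL_CASES = ["Cplex4", "Cplex5", "Cplex6", "Cplex9", "Cplex11", "Cplex12",
             "PLP1_family", "Family3", "Family12"]


def test_case_inventory():
    assert sorted(list_cases()) == sorted(ALL_CASES)
    with pytest.raises(KeyError):
        load_fixture("Cplex99")


def test_fixture_features_match_printed_strings():
    fx = load_fixture("Cplex4")
    assert [j.feature.describe() for j in fx.sequenced_junctions()] \
        == ["1bp MH", "1bp MH"]
    assert len(load_fixture("Cplex5").sequenced_junctions()) == 4


def test_printed_insert_length_discrepancy_is_flagged_not_fixed():
    fx = load_fixture("Cplex11")
    jct2 = next(j for j in fx.junctions if j.id == "Cplex11_Jct2")
    assert jct2.feature.insert_len == 13_357  # as printed
    assert sum(e - s + 1 for _, s, e, _ in jct2.feature.template_parts) == 13_359
    assert any("Cplex11_Jct2" in w for w in fx.warnings)


@pytest.mark.parametrize("case_id", ALL_CASES)
def test_every_expected_value_reproduced(case_id):
    report = run_case(case_id)
    failures = [c for c in report.checks() if not c[3]]
    assert not failures, failures


def test_cplex6_hypothetical_joins_distal_sides():
    report = run_case("Cplex6")
    best = report.reconstruction.best
    assert best.n_hypothetical == 1
    keys = {
        frozenset({m.hypothetical[0].a.key, m.hypothetical[0].b.key})
        for m in report.reconstruction.models
        if m.n_hypothetical == 1
    }
    # the third junction connects the distal sides of the triplication and
    # the chrX duplication
    assert frozenset({("chrX", 170_000, "retains_left"),
                      ("chrX", 136_000, "retains_left")}) in keys


def test_cplex11_six_junctions_five_sequenced():
    report = run_case("Cplex11")
    best = report.reconstruction.best
    assert len(best.all_junctions()) == 6
    assert sum(1 for j in best.all_junctions() if j.support == "sequenced") == 5


def test_family3_balanced_exchange_explains_proband():
    report = run_case("Family3")
    match = report.family_results["child_matches"]["P3"]
    assert match.zero_residual
    # the child inherited the deleted chr7 (with its 815 bp chr9 insertion)
    # and an intact chr9
    assert match.outcome.transmitted == {"chr7": "derivative", "chr9": "intact"}
    dup = next(c for c in match.outcome.predicted_child_cnv if c.type == "DUP")
    assert (dup.chrom, dup.start, dup.end, dup.size_bp) \
        == ("chr9", 5_874_574, 5_875_388, 815)


def test_family12_reciprocal_recombinants():
    report = run_case("Family12")
    m_dup = report.family_results["child_matches"]["P12_dup"]
    m_del = report.family_results["child_matches"]["P12_del"]
    assert m_dup.zero_residual and m_del.zero_residual
    types = sorted(c.type for c in m_dup.outcome.predicted_child_cnv)
    assert types == ["DUP", "DUP", "TRP"]  # embedded triplication transmitted
    dele = m_del.outcome.predicted_child_cnv[0]
    assert dele.type == "DEL" and dele.size_bp == 3_352_000


def test_classifier_splits_sequenced_cases_three_and_three():
    labels = {cid: run_case(cid).classification.label
              for cid in ["Cplex4", "Cplex5", "Cplex6", "Cplex9", "Cplex11",
                          "Cplex12"]}
    basic = [c for c, l in labels.items() if l == "basic_complex_insertion"]
    chromo = [c for c, l in labels.items() if l == "chromoanasynthesis"]
    assert sorted(basic) == ["Cplex12", "Cplex4", "Cplex9"]
    assert sorted(chromo) == ["Cplex11", "Cplex5", "Cplex6"]
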