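"""Machine-readable case fixtures and the end-to-end case runner.

The nine resolved complex-insertion cases ship as structured text
(``data/cases.yaml``) on toy coordinates: copy-number calls, sequenced
junction breakends with their printed features, published derivative
models for the family cases, and the published per-case conclusions in an
``expected`` block.  ``run_case`` pushes a fixture through the pipeline
(pattern strings, breakpoint-graph reconstruction, mechanism
classification, inheritance modelling) and reports every check against
the expected values — the fixtures are the package's acceptance surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .classify import classify, extract_features
from .cnv import detect_dup_trp_inv_dup, pattern_string
from .core import (
    SUPPORT_SEQUENCED,
    BreakEnd,
    CNVCall,
    DerivativeModel,
    GenomeRef,
    Junction,
    JunctionFeature,
)
from .inheritance import (
    INTERCHROMOSOMAL,
    ParentalGenotype,
    enumerate_crossovers,
    enumerate_segregation,
    match_child,
)
from .reconstruct import ReconstructionResult, build_graph, reconstruct

__all__ = ["CaseFixture", "CaseReport", "list_cases", "load_fixture", "run_case"]


def _load_yaml() -> dict:
    with resources.files("cgr.data").joinpath("cases.yaml").open() as fh:
        return yaml.safe_load(fh)


def list_cases() -> list[str]:
    return list(_load_yaml()["cases"])


@dataclass
class CaseFixture:
    case_id: str
    description: str
    genome: GenomeRef
    calls: list[CNVCall]
    junctions: list[Junction]
    derivatives: list[DerivativeModel]
    family: Optional[dict]
    expected: dict
    warnings: list[str] = field(default_factory=list)

    def sequenced_junctions(self) -> list[Junction]:
        return [j for j in self.junctions if j.support == SUPPORT_SEQUENCED]


def _parse_breakend(d: dict) -> BreakEnd:
    return BreakEnd(d["chrom"], int(d["pos"]), d["side"], d.get("strand", "+"))


def _parse_feature(d: Optional[dict]) -> Optional[JunctionFeature]:
    if d is None:
        return None
    parts = [tuple(p) for p in d.get("template_parts", [])]
    return JunctionFeature(
        kind=d["kind"],
        mh_len=int(d.get("mh_len", 0)),
        insert_len=d.get("insert_len"),
        template_parts=parts,
    )


def load_fixture(case_id: str) -> CaseFixture:
    """Load and validate one case fixture.

    Validation: printed feature strings must match the structured
    features; junction breakends and calls must lie inside the toy
    chromosomes; calls must be non-overlapping per chromosome.  Printed
    inconsistencies that are deliberately preserved (e.g. an insertion
    length that disagrees with its printed part lengths) surface as
    warnings, not errors.
    """
    data = _load_yaml()["cases"]
    if case_id not in data:
        raise KeyError(
            f"unknown case {case_id!r}; available: {', '.join(sorted(data))}"
        )
    raw = data[case_id]
    genome = GenomeRef.from_lengths(raw["genome"]["lengths"], raw["genome"].get("ploidy"))
    warnings_: list[str] = []

    calls = []
    for c in raw.get("calls", []):
        call = CNVCall(
            c["chrom"], int(c["start"]), int(c["end"]), c["type"],
            cn=int(c.get("cn", -1)),
        )
        if call.end > genome.lengths[call.chrom]:
            raise ValueError(f"{case_id}: call {call} outside chromosome")
        calls.append(call)
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        cs = sorted(cs, key=lambda c: c.start)
        for x, y in zip(cs, cs[1:]):
            if y.start <= x.end:
                raise ValueError(f"{case_id}: overlapping calls on {chrom}")

    junctions: dict[str, Junction] = {}
    for j in raw.get("junctions", []):
        support = j.get("support", SUPPORT_SEQUENCED)
        feature = _parse_feature(j.get("feature")) if support == SUPPORT_SEQUENCED else None
        jct = Junction(
            id=j["id"],
            a=_parse_breakend(j["a"]),
            b=_parse_breakend(j["b"]),
            support=support,
            feature=feature,
        )
        for e in jct.breakends():
            if not 1 <= e.pos <= genome.lengths[e.chrom]:
                raise ValueError(f"{case_id}: breakend {e} outside chromosome")
        if feature is not None:
            printed = j.get("printed")
            if printed is not None and feature.describe() != printed:
                raise ValueError(
                    f"{case_id}/{jct.id}: structured feature "
                    f"{feature.describe()!r} != printed {printed!r}"
                )
            for w in feature.validate():
                warnings_.append(f"{jct.id}: {w}")
        junctions[jct.id] = jct

    derivatives = []
    for d in raw.get("derivatives", []):
        walk = [
            ((s["chrom"], int(s["start"]), int(s["end"])), s.get("orient", "+"))
            for s in d["walk"]
        ]
        joins = [
            None if j in (None, "ref") else junctions[j] for j in d.get("joins", [])
        ]
        derivatives.append(DerivativeModel(d["recipient"], walk, joins))

    return CaseFixture(
        case_id=case_id,
        description=raw.get("description", "").strip(),
        genome=genome,
        calls=calls,
        junctions=list(junctions.values()),
        derivatives=derivatives,
        family=raw.get("family"),
        expected=raw.get("expected", {}),
        warnings=warnings_,
    )


@dataclass
class CaseReport:
    fixture: CaseFixture
    patterns: dict[str, str]
    dup_trp_inv_dup: bool
    reconstruction: Optional[ReconstructionResult]
    classification: Optional[object]
    family_results: dict = field(default_factory=dict)

    @property
    def case_id(self) -> str:
        return self.fixture.case_id

    def checks(self) -> list[tuple[str, object, object, bool]]:
        """(name, expected, actual, ok) for every expected value the
        pipeline recomputes."""
        exp = self.fixture.expected
        out = []

        def add(name, expected, actual):
            out.append((name, expected, actual, expected == actual))

        for chrom, pat in exp.get("patterns", {}).items():
            add(f"pattern[{chrom}]", pat, self.patterns.get(chrom))
        if "dup_trp_inv_dup" in exp:
            add("dup_trp_inv_dup", exp["dup_trp_inv_dup"], self.dup_trp_inv_dup)
        if "n_cnv_calls" in exp:
            add("n_cnv_calls", exp["n_cnv_calls"], len(self.fixture.calls))
        if self.reconstruction is not None and self.reconstruction.models:
            best = self.reconstruction.best
            if "n_junctions_total" in exp:
                add("n_junctions_total", exp["n_junctions_total"],
                    len(best.all_junctions()))
            if "n_sequenced" in exp:
                add("n_sequenced", exp["n_sequenced"],
                    sum(1 for j in best.all_junctions()
                        if j.support == SUPPORT_SEQUENCED))
            if "n_hypothetical" in exp:
                add("n_hypothetical", exp["n_hypothetical"], best.n_hypothetical)
            if "hypothetical_breakends" in exp:
                want = {
                    (b["chrom"], b["pos"], b["side"])
                    for b in exp["hypothetical_breakends"]
                }
                found = any(
                    {m.hypothetical[0].a.key, m.hypothetical[0].b.key} == want
                    for m in self.reconstruction.models
                    if m.n_hypothetical == 1
                )
                add("hypothetical_junction_in_minimal_set", True, found)
        if self.classification is not None and "classification" in exp:
            add("classification", exp["classification"], self.classification.label)
        if "features" in exp:
            add(
                "features",
                exp["features"],
                [j.feature.describe() for j in self.fixture.sequenced_junctions()],
            )
        if "n_chromosomes" in exp and self.classification is not None:
            add("n_chromosomes", exp["n_chromosomes"], self._features.n_chromosomes)
        for name, res in self.family_results.get("child_matches", {}).items():
            add(f"child[{name}] explained", True, res.zero_residual)
            want_tx = (
                self.fixture.family["children"][name].get("expected_transmission")
            )
            if want_tx:
                add(f"child[{name}] transmission", dict(want_tx),
                    dict(res.outcome.transmitted))
        if "parent_profile_consistent" in self.family_results:
            add("parent_profile_consistent", True,
                self.family_results["parent_profile_consistent"])
        if "n_segregation_outcomes" in exp and "n_outcomes" in self.family_results:
            add("n_segregation_outcomes", exp["n_segregation_outcomes"],
                self.family_results["n_outcomes"])
        return out

    def ok(self) -> bool:
        return all(c[3] for c in self.checks())

    def render(self) -> str:
        lines = [f"== case {self.case_id} ==", self.fixture.description, ""]
        lines += [f"pattern {c}: {p}" for c, p in sorted(self.patterns.items())]
        lines.append(f"DUP-TRP/INV-DUP: {self.dup_trp_inv_dup}")
        if self.reconstruction is not None and self.reconstruction.models:
            best = self.reconstruction.best
            lines.append(
                f"reconstruction: {len(best.all_junctions())} junctions "
                f"({best.n_hypothetical} hypothetical); "
                f"{len(self.reconstruction.models)} minimal model(s)"
            )
            for m in best.recipient_models():
                lines.append(m.narrate())
        if self.classification is not None:
            lines.append(
                f"mechanism: {self.classification.label} "
                f"(proposed repair: {self.classification.proposed_repair})"
            )
        for name, res in self.family_results.get("child_matches", {}).items():
            lines.append(
                f"child {name}: matched {res.outcome.label or res.outcome.transmitted}"
                f" residual={len(res.residual_child)}"
            )
        lines.append("")
        for name, expv, got, okflag in self.checks():
            mark = "PASS" if okflag else "FAIL"
            lines.append(f"  [{mark}] {name}: expected {expv!r}, got {got!r}")
        return "\n".join(lines)


def run_case(case_id: str, max_hypothetical: int = 3) -> CaseReport:
    """Full pipeline on one fixture: pattern strings, reconstruction with
    hypothetical-junction inference, mechanism classification, and (for
    family cases) transmission modelling with child matching."""
    fx = load_fixture(case_id)
    patterns = {
        chrom: pattern_string(fx.calls, chrom)
        for chrom in sorted({c.chrom for c in fx.calls})
    }
    dup_trp = False
    for chrom in sorted({c.chrom for c in fx.calls}):
        ok, _ = detect_dup_trp_inv_dup(
            [c for c in fx.calls if c.chrom == chrom], fx.sequenced_junctions()
        )
        dup_trp = dup_trp or ok

    recon = None
    if "n_hypothetical" in fx.expected and fx.calls:
        graph = build_graph(fx.calls, fx.junctions, fx.genome)
        recon = reconstruct(graph, max_hypothetical=max_hypothetical)

    features = extract_features(
        None,
        fx.calls,
        fx.sequenced_junctions(),
        metadata={"de_novo": fx.expected.get("de_novo", "unknown")},
    )
    call = classify(features)

    family_results: dict = {}
    if fx.family:
        parent = ParentalGenotype(
            fx.derivatives, fx.genome, fx.family["insertion_type"]
        )
        parent_calls = parent.parent_cnv()
        family_results["parent_profile"] = parent_calls
        family_results["parent_profile_consistent"] = sorted(
            (c.chrom, c.start, c.end, c.type) for c in parent_calls
        ) == sorted((c.chrom, c.start, c.end, c.type) for c in fx.calls)
        if fx.family["insertion_type"] == INTERCHROMOSOMAL:
            outcomes = enumerate_segregation(parent)
        else:
            outcomes = enumerate_crossovers(
                parent, fx.family.get("crossover_grid_bp", 100_000)
            )
        family_results["n_outcomes"] = len(outcomes)
        family_results["outcomes"] = outcomes
        matches = {}
        for name, child in fx.family.get("children", {}).items():
            child_calls = [
                CNVCall(c["chrom"], int(c["start"]), int(c["end"]), c["type"])
                for c in child["calls"]
            ]
            matches[name] = match_child(child_calls, outcomes)
        family_results["child_matches"] = matches

    report = CaseReport(
        fixture=fx,
        patterns=patterns,
        dup_trp_inv_dup=dup_trp,
        reconstruction=recon,
        classification=call,
        family_results=family_results,
    )
    report._features = features
    return report
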