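"""Mechanistic classification of complex insertions.

The discriminating molecular signals, distilled from the junction and
copy-number signatures of resolved cases:

* multiple copy-number gains — in particular triplications — point to a
  replicative, iterative template-switching origin (chromoanasynthesis);
* so do long microhomology (>4 bp) and templated insertions at junctions;
* a single duplication inserted into a deletion with only short
  microhomology or a tiny untemplated insert is a *basic* complex
  insertion, explainable by end joining (NHEJ/MMEJ) or a single template
  switch;
* a net-balanced bidirectional exchange (allowing small flanking CNVs) is
  attributed to end joining even when some junctions carry longer
  microhomology or exchanged material — without copy-number gains there
  is no evidence of iterative replicative copying.

Blunt junctions never veto a replicative call: replicative events may
show blunt ends, small inserts or 1-2 bp microhomology at a subset of
their joints, so the rules are disjunctive on positive evidence.
Inheritance status (de novo or not) is reported as evidence but never
used by the cascade — it is pedigree metadata, not molecular signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    DUP,
    TEMPLATED,
    TRP,
    CNVCall,
    DerivativeModel,
    Junction,
)
from .cnv import detect_dup_trp_inv_dup

__all__ = [
    "CaseFeatures",
    "MechanismCall",
    "ClassifierThresholds",
    "extract_features",
    "classify",
    "annotate_repeats",
    "LABEL_BASIC",
    "LABEL_CHROMOANASYNTHESIS",
    "LABEL_BALANCED",
    "LABEL_UNCLASSIFIED",
]

LABEL_BASIC = "basic_complex_insertion"
LABEL_CHROMOANASYNTHESIS = "chromoanasynthesis"
LABEL_BALANCED = "balanced_end_joining_exchange"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass
class CaseFeatures:
    """Aggregated molecular features of one case."""

    n_gains: int = 0
    has_trp: bool = False
    has_dup_trp_inv_dup: bool = False
    max_mh: int = 0
    n_templated_insertions: int = 0
    max_templated_len: int = 0
    n_chromosomes: int = 1
    n_junctions: int = 0
    net_balanced: bool = False
    deletion_at_insertion_site: bool = False
    de_novo: str = "unknown"

    def __post_init__(self):
        for name in ("n_gains", "max_mh", "n_templated_insertions",
                     "max_templated_len", "n_junctions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} < 0")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes < 1")
        if self.de_novo not in ("yes", "no", "unknown"):
            raise ValueError("de_novo must be yes/no/unknown")


@dataclass
class ClassifierThresholds:
    """``mh_chromoanasynthesis_cutoff``: microhomology strictly above this
    counts as replicative evidence (the observed replicative cases show
    >4 bp).  ``small_cnv_max``: flanking CNVs up to this size (bp) do not
    break the 'balanced' category (the observed flanking CNVs in balanced
    carriers are a few kb)."""

    mh_chromoanasynthesis_cutoff: int = 4
    small_cnv_max: int = 10_000

    def validate(self) -> None:
        if not 0 <= self.mh_chromoanasynthesis_cutoff <= 50:
            raise ValueError("mh cutoff outside sane range 0..50")
        if not 0 <= self.small_cnv_max <= 10_000_000:
            raise ValueError("small_cnv_max outside sane range")


@dataclass
class MechanismCall:
    label: str
    evidence: list[tuple[str, object, bool]]
    proposed_repair: str
    notes: str = ""

    def __post_init__(self):
        if self.label != LABEL_UNCLASSIFIED and not any(
            ok for _, _, ok in self.evidence
        ):
            raise ValueError("a label requires at least one satisfied criterion")


def merged_gain_regions(calls: Sequence[CNVCall]) -> list[tuple[str, int, int]]:
    """Copy-number gain intervals with directly abutting gains merged — a
    triplication embedded in a duplication is one gain region."""
    gains = sorted(
        ((c.chrom, c.start, c.end) for c in calls if c.type in (DUP, TRP)),
    )
    merged: list[list] = []
    for chrom, s, e in gains:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [tuple(m) for m in merged]


def extract_features(
    model: Optional[DerivativeModel],
    calls: Sequence[CNVCall],
    junctions: Sequence[Junction],
    metadata: Optional[dict] = None,
    small_cnv_max: int = 10_000,
) -> CaseFeatures:
    """Deterministic aggregation of CNV calls and annotated junctions.

    Unresolved junctions contribute to the junction count but not to
    microhomology/insert statistics.  The chromosome count includes
    chromosomes contributing only templated-insert material.
    """
    metadata = metadata or {}
    gains = merged_gain_regions(calls)
    chroms = {c.chrom for c in calls}
    max_mh = 0
    n_templated = 0
    max_templated = 0
    for j in junctions:
        for e in j.breakends():
            chroms.add(e.chrom)
        f = j.feature
        if f is None or not j.resolved:
            continue
        max_mh = max(max_mh, f.mh_len)
        if f.kind == TEMPLATED:
            n_templated += 1
            max_templated = max(max_templated, f.insert_len)
            for part in f.template_parts:
                chroms.add(part[0])
    dup_trp = False
    for chrom in {c.chrom for c in calls}:
        ok, _ = detect_dup_trp_inv_dup(
            [c for c in calls if c.chrom == chrom], junctions
        )
        dup_trp = dup_trp or ok
    dels = [c for c in calls if c.type == "DEL"]
    del_at_site = False
    for d in dels:
        edge = {d.start - 1, d.start, d.end, d.end + 1}
        for j in junctions:
            if any(e.chrom == d.chrom and e.pos in edge for e in j.breakends()):
                del_at_site = True
    n_junctions = (
        len(model.junctions_used) if model is not None else len(junctions)
    )
    return CaseFeatures(
        n_gains=len(gains),
        has_trp=any(c.type == TRP for c in calls),
        has_dup_trp_inv_dup=dup_trp,
        max_mh=max_mh,
        n_templated_insertions=n_templated,
        max_templated_len=max_templated,
        n_chromosomes=max(len(chroms), 1),
        n_junctions=n_junctions,
        net_balanced=all(c.size_bp <= small_cnv_max for c in calls),
        deletion_at_insertion_site=del_at_site,
        de_novo=metadata.get("de_novo", "unknown"),
    )


def classify(
    features: CaseFeatures,
    thresholds: Optional[ClassifierThresholds] = None,
) -> MechanismCall:
    """Rule cascade over the aggregated features.

    1. chromoanasynthesis: copy-gain evidence (>= 2 gain regions or a
       triplication) together with replicative junction evidence
       (microhomology above the cutoff, or any templated insertion).  A
       single gain accompanied by a templated insertion — a combination
       not among the described cases — is also sent here, with a note.
    2. basic complex insertion: exactly one gain inserted at a deletion
       site, short microhomology only, no templated insertions.
    3. balanced end-joining exchange: net balanced, allowing flanking CNVs
       up to ``small_cnv_max``.
    4. otherwise unclassified.
    """
    th = thresholds or ClassifierThresholds()
    th.validate()
    f = features
    gains_ev = f.n_gains >= 2 or f.has_trp
    repl_ev = f.max_mh > th.mh_chromoanasynthesis_cutoff or f.n_templated_insertions >= 1
    evidence = [
        ("n_gains>=2 or has_trp", (f.n_gains, f.has_trp), gains_ev),
        (
            f"max_mh>{th.mh_chromoanasynthesis_cutoff} or n_templated>=1",
            (f.max_mh, f.n_templated_insertions),
            repl_ev,
        ),
        ("has_dup_trp_inv_dup", f.has_dup_trp_inv_dup, f.has_dup_trp_inv_dup),
        ("n_gains==1", f.n_gains, f.n_gains == 1),
        (
            "deletion_at_insertion_site",
            f.deletion_at_insertion_site,
            f.deletion_at_insertion_site,
        ),
        ("max_mh<=3", f.max_mh, f.max_mh <= 3),
        ("n_templated==0", f.n_templated_insertions, f.n_templated_insertions == 0),
        ("net_balanced", f.net_balanced, f.net_balanced),
        ("n_chromosomes", f.n_chromosomes, True),
        ("de_novo (metadata, not used by rules)", f.de_novo, False),
    ]
    if gains_ev and repl_ev:
        return MechanismCall(
            LABEL_CHROMOANASYNTHESIS, evidence, "FoSTeS/MMBIR-iterative"
        )
    if f.n_gains >= 1 and f.n_templated_insertions >= 1:
        return MechanismCall(
            LABEL_CHROMOANASYNTHESIS,
            evidence,
            "FoSTeS/MMBIR-iterative",
            notes=(
                "single copy-number gain with a templated insertion: a "
                "combination outside the described case classes; routed to "
                "the replicative label on the templated-insert evidence"
            ),
        )
    if (
        f.n_gains == 1
        and f.deletion_at_insertion_site
        and f.max_mh <= 3
        and f.n_templated_insertions == 0
    ):
        repair = "MMEJ" if f.max_mh >= 1 else "NHEJ"
        return MechanismCall(LABEL_BASIC, evidence, repair)
    if f.net_balanced:
        repair = "NHEJ" if f.max_mh <= 3 else "MMEJ"
        return MechanismCall(LABEL_BALANCED, evidence, repair)
    return MechanismCall(LABEL_UNCLASSIFIED, evidence, "FoSTeS/MMBIR-single")


def annotate_repeats(
    junctions: Sequence[Junction],
    repeat_intervals: Sequence[tuple],
) -> dict[str, tuple[str, str]]:
    """Label each breakend with the repeat element containing it.

    ``repeat_intervals``: (chrom, start0, end0, name) records in BED
    convention (0-based half-open).  A breakend inside no interval gets
    '-'.  Purely a lookup — repeat annotation is an input, not something
    this package computes.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s0, e0, name in repeat_intervals:
        if e0 > s0:
            trees.setdefault(chrom, IntervalTree()).addi(s0, e0, name)
    out = {}
    for j in junctions:
        labels = []
        for e in j.breakends():
            hits = trees.get(e.chrom, IntervalTree())[e.pos - 1]
            labels.append(sorted(h.data for h in hits)[0] if hits else "-")
        out[j.id] = tuple(labels)
    return out
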