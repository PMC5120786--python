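"""Meiotic transmission of parental insertions.

A parent carrying a balanced (or nearly balanced) insertion transmits, per
chromosome, either the derivative or the intact homolog.  For
interchromosomal insertions the involved chromosomes segregate
independently, producing unbalanced offspring from a balanced carrier; for
intrachromosomal insertions a single meiotic crossover between the
derivative and the intact homolog yields two reciprocal recombinant
products — one duplication-bearing, one deletion-bearing.

Child copy-number prediction assumes the other parent contributes
reference chromosomes (one copy of everything); the expected child
baseline is therefore two copies.  Junctional templated inserts carried by
a derivative are physical copies of their source loci, so parts of at
least ``MIN_INSERT_CNV_BP`` are counted in predicted profiles (an
exchanged 815 bp fragment shows up in a child at high probe density);
shorter junctional inserts sit below array resolution and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import (
    CNVCall,
    DerivativeModel,
    GenomeRef,
    SegmentCN,
    calls_from_segments,
)

__all__ = [
    "ParentalGenotype",
    "TransmissionOutcome",
    "MatchResult",
    "enumerate_segregation",
    "enumerate_crossovers",
    "match_child",
]

INTERCHROMOSOMAL = "interchromosomal"
INTRACHROMOSOMAL = "intrachromosomal"

# junctional templated inserts at least this long count as copy-number
# material in predicted profiles (roughly a few probes of high-density
# aCGH); shorter ones are invisible to the emulated assay
MIN_INSERT_CNV_BP = 500


@dataclass
class ParentalGenotype:
    """A parent's derivative chromosomes (at most one per chromosome); all
    other homologs are implied intact."""

    derivatives: list[DerivativeModel]
    genome: GenomeRef
    insertion_type: str

    def __post_init__(self):
        if self.insertion_type not in (INTERCHROMOSOMAL, INTRACHROMOSOMAL):
            raise ValueError(f"bad insertion_type {self.insertion_type!r}")
        recips = [d.recipient_chrom for d in self.derivatives]
        if len(recips) != len(set(recips)):
            raise ValueError("at most one derivative per chromosome")

    @property
    def rearranged_chroms(self) -> list[str]:
        return [d.recipient_chrom for d in self.derivatives]

    def parent_cnv(self, include_templated_inserts: bool = True) -> list[CNVCall]:
        """The parent's own copy-number profile (vs their ploidy baseline)."""
        cov = _CoverageCounter(self.genome)
        for d in self.derivatives:
            cov.add_walk(d, include_templated_inserts)
        segs = cov.segments(
            lambda chrom: self.genome.ploidy[chrom]
            - (1 if chrom in self.rearranged_chroms else 0),
            baseline_of=lambda chrom: self.genome.ploidy[chrom],
        )
        return calls_from_segments(segs)


@dataclass
class TransmissionOutcome:
    """One possible gamete (plus a reference contribution from the other
    parent) and the child copy-number profile it predicts."""

    transmitted: dict[str, str]  # chrom -> "derivative" | "intact"
    predicted_child_cnv: list[CNVCall]
    crossover_pos: Optional[int] = None
    label: str = ""


class _CoverageCounter:
    """Closed-interval coverage bookkeeping via difference maps."""

    def __init__(self, genome: GenomeRef):
        self.genome = genome
        self.deltas: dict[str, dict[int, int]] = {}

    def add_interval(self, chrom: str, start: int, end: int) -> None:
        d = self.deltas.setdefault(chrom, {})
        d[start] = d.get(start, 0) + 1
        d[end + 1] = d.get(end + 1, 0) - 1

    def add_walk(
        self,
        model: DerivativeModel,
        include_inserts: bool,
        min_insert_bp: int = MIN_INSERT_CNV_BP,
    ) -> None:
        for (chrom, s, e), _o in model.walk:
            self.add_interval(chrom, s, e)
        if include_inserts:
            for j in model.junctions_used:
                if j.feature is None:
                    continue
                for part in j.feature.template_parts:
                    if part[2] - part[1] + 1 >= min_insert_bp:
                        self.add_interval(part[0], part[1], part[2])

    def add_chromosome(self, chrom: str) -> None:
        self.add_interval(chrom, 1, self.genome.lengths[chrom])

    def segments(self, intact_of, baseline_of) -> list[SegmentCN]:
        """Non-baseline segments given per-chromosome intact-copy counts."""
        out: list[SegmentCN] = []
        for chrom, d in self.deltas.items():
            length = self.genome.lengths[chrom]
            intact = intact_of(chrom)
            baseline = baseline_of(chrom)
            bounds = sorted({1, length + 1, *(p for p in d if 1 <= p <= length + 1)})
            cum = 0
            pending = None
            for i in range(len(bounds) - 1):
                lo, hi = bounds[i], bounds[i + 1] - 1
                cum += d.get(lo, 0)
                cn = intact + cum
                if cn != baseline:
                    if pending and pending[2] == cn and pending[1] == lo - 1:
                        pending[1] = hi
                    else:
                        if pending:
                            out.append(SegmentCN(chrom, *pending, baseline))
                        pending = [lo, hi, cn]
                elif pending:
                    out.append(SegmentCN(chrom, *pending, baseline))
                    pending = None
            if pending:
                out.append(SegmentCN(chrom, *pending, baseline))
        out.sort(key=lambda s: (s.chrom, s.start))
        return out


def _child_calls(
    genome: GenomeRef,
    maternal_walks: Sequence[DerivativeModel],
    maternal_intact: Sequence[str],
    include_inserts: bool = True,
) -> list[CNVCall]:
    """Child profile: one reference copy of everything from the other
    parent, plus the transmitted maternal content; diploid baseline."""
    cov = _CoverageCounter(genome)
    for m in maternal_walks:
        cov.add_walk(m, include_inserts)
    for chrom in maternal_intact:
        cov.add_chromosome(chrom)
    segs = cov.segments(intact_of=lambda c: 1, baseline_of=lambda c: 2)
    return calls_from_segments(segs)


def enumerate_segregation(parent: ParentalGenotype) -> list[TransmissionOutcome]:
    """All 2^k independent-segregation outcomes over the k chromosomes that
    carry a derivative."""
    if parent.insertion_type != INTERCHROMOSOMAL:
        raise ValueError("independent segregation applies to interchromosomal insertions")
    chroms = parent.rearranged_chroms
    by_chrom = {d.recipient_chrom: d for d in parent.derivatives}
    outcomes = []
    for mask in range(2 ** len(chroms)):
        choice = {
            c: ("derivative" if mask & (1 << i) else "intact")
            for i, c in enumerate(chroms)
        }
        walks = [by_chrom[c] for c in chroms if choice[c] == "derivative"]
        intact = [c for c in chroms if choice[c] == "intact"]
        outcomes.append(
            TransmissionOutcome(
                transmitted=choice,
                predicted_child_cnv=_child_calls(parent.genome, walks, intact),
                label="+".join(
                    f"{'der' if choice[c] == 'derivative' else 'intact'}({c})"
                    for c in chroms
                ),
            )
        )
    return outcomes


def _split_walk(
    model: DerivativeModel, x: int
) -> Optional[tuple[list, list, list, list]]:
    """Split a walk at reference position x | x+1 on the recipient
    chromosome.  Valid only when exactly one walk element covers x, that
    element is '+' oriented, and x is strictly interior to it (a crossover
    inside a rearranged or repeated segment would create further
    complexity and is excluded)."""
    chrom = model.recipient_chrom
    covering = [
        i
        for i, ((c, s, e), o) in enumerate(model.walk)
        if c == chrom and s <= x <= e
    ]
    if len(covering) != 1:
        return None
    i = covering[0]
    (c, s, e), o = model.walk[i]
    if o != "+" or not (s <= x < e):
        return None
    left_walk = list(model.walk[:i]) + [((c, s, x), "+")]
    left_joins = list(model.joins[:i])
    right_walk = [((c, x + 1, e), "+")] + list(model.walk[i + 1 :])
    right_joins = list(model.joins[i:])
    return left_walk, left_joins, right_walk, right_joins


def enumerate_crossovers(
    parent: ParentalGenotype, interval_grid_bp: int = 100_000
) -> list[TransmissionOutcome]:
    """Reciprocal recombinant products of a single crossover between the
    intrachromosomal derivative and its intact homolog.

    Crossover positions are sampled every ``interval_grid_bp`` across the
    reference-collinear, uniquely covered region between the rearranged
    clusters (between the donor and acceptor loci).  Each position yields
    the two reciprocal products; positions inside rearranged or multiply
    used segments are excluded.
    """
    if parent.insertion_type != INTRACHROMOSOMAL:
        raise ValueError("crossover enumeration applies to intrachromosomal insertions")
    if len(parent.derivatives) != 1:
        raise ValueError("intrachromosomal parent carries exactly one derivative")
    der = parent.derivatives[0]
    chrom = der.recipient_chrom
    genome = parent.genome
    bk = [
        e.pos
        for j in der.junctions_used
        for e in j.breakends()
        if e.chrom == chrom
    ]
    if not bk:
        return []
    lo_bound, hi_bound = min(bk), max(bk)
    outcomes: list[TransmissionOutcome] = []
    x = lo_bound + interval_grid_bp
    while x < hi_bound:
        split = _split_walk(der, x)
        if split is not None:
            lw, lj, rw, rj = split
            # R1: derivative left portion + intact right arm
            r1 = DerivativeModel(
                chrom,
                lw + [((chrom, x + 1, genome.lengths[chrom]), "+")],
                lj + [None],
            )
            # R2: intact left arm + derivative right portion
            r2 = DerivativeModel(chrom, [((chrom, 1, x), "+")] + rw, [None] + rj)
            for recomb, tag in ((r1, "derivative-left"), (r2, "derivative-right")):
                outcomes.append(
                    TransmissionOutcome(
                        transmitted={chrom: f"recombinant({tag})"},
                        predicted_child_cnv=_child_calls(genome, [recomb], []),
                        crossover_pos=x,
                        label=f"crossover@{x}:{tag}",
                    )
                )
        x += interval_grid_bp
    return outcomes


@dataclass
class MatchResult:
    outcome: TransmissionOutcome
    matched: list[tuple[CNVCall, CNVCall]]
    residual_child: list[CNVCall]
    unexplained_predicted: list[CNVCall]
    score: float

    @property
    def zero_residual(self) -> bool:
        return not self.residual_child and not self.unexplained_predicted


def _reciprocal_overlap(a: CNVCall, b: CNVCall, slop: int) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end + slop) - max(a.start, b.start - slop) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.size_bp, inter / b.size_bp)


def match_child(
    child_calls: Sequence[CNVCall],
    outcomes: Sequence[TransmissionOutcome],
    slop_bp: int = 0,
    min_overlap: float = 0.5,
) -> MatchResult:
    """Score transmission outcomes against an observed child profile by
    reciprocal interval overlap; the best-scoring outcome is returned with
    the child CNVs it leaves unexplained (the 'additional complexities')."""
    if not outcomes:
        raise ValueError("no outcomes to match against")
    best: Optional[MatchResult] = None
    for oc in outcomes:
        remaining = list(oc.predicted_child_cnv)
        matched, residual = [], []
        score = 0.0
        for c in child_calls:
            hit, hit_ov = None, 0.0
            for p in remaining:
                if p.type != c.type:
                    continue
                ov = _reciprocal_overlap(c, p, slop_bp)
                if ov >= min_overlap and ov > hit_ov:
                    hit, hit_ov = p, ov
            if hit is not None:
                matched.append((c, hit))
                remaining.remove(hit)
                score += hit_ov
            else:
                residual.append(c)
        score -= 0.01 * (len(residual) + len(remaining))
        res = MatchResult(oc, matched, residual, remaining, score)
        if best is None or res.score > best.score:
            best = res
    return best
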