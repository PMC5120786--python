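"""Derivative-chromosome reconstruction from CNV calls and junctions.

The rearranged genome is modelled as a breakpoint graph: every involved
chromosome is split at each CNV boundary and junction breakend (the
common refinement), each resulting reference segment gets a required
multiplicity, and each sequenced junction contributes one novel adjacency
that must be used exactly once.  Reconstruction is an exhaustive
memoized search for one telomere-to-telomere walk per involved
chromosome jointly satisfying all multiplicities; when no such walk
exists, the minimum number of *hypothetical* junctions (the '??' joints)
is inferred to complete one.

Multiplicity encodes the assumption that one homolog of every involved
chromosome is intact (the constitutional, heterozygous situation):
``mult = max(cn - (baseline - 1), 0)`` — a deleted segment is used by no
walk, a normal segment by exactly one, a duplicated segment twice, a
triplicated segment three times (summed over all walks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    RETAINS_LEFT,
    RETAINS_RIGHT,
    SUPPORT_HYPOTHETICAL,
    SUPPORT_SEQUENCED,
    BreakEnd,
    CNVCall,
    DerivativeModel,
    GenomeRef,
    Junction,
)

__all__ = [
    "BreakpointGraph",
    "CandidateModel",
    "ReconstructionResult",
    "GraphConsistencyError",
    "build_graph",
    "reconstruct",
    "emit_derivative_sequence",
    "count_junctions",
    "snap_calls_to_junctions",
]


def snap_calls_to_junctions(
    calls: Sequence, junctions: Sequence[Junction], tol_bp: int
) -> list[CNVCall]:
    """Align segmentation-derived call edges to nearby junction breakends.

    Array segmentation places CNV boundaries midway between probes, while
    sequenced breakends are exact; a call edge within ``tol_bp`` of a
    breakend-implied boundary is moved onto it so the breakpoint-graph
    refinement does not produce spurious sliver segments.  Calls with
    exact coordinates (tol_bp=0 or no nearby breakend) pass through
    unchanged.
    """
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for j in junctions:
        if not (j.resolved and j.support == SUPPORT_SEQUENCED):
            continue
        for e in j.breakends():
            if e.side == RETAINS_RIGHT:
                starts.setdefault(e.chrom, []).append(e.pos)
                ends.setdefault(e.chrom, []).append(e.pos - 1)
            else:
                ends.setdefault(e.chrom, []).append(e.pos)
                starts.setdefault(e.chrom, []).append(e.pos + 1)

    def snap(pos: int, candidates: list[int]) -> int:
        near = [c for c in candidates if abs(c - pos) <= tol_bp]
        return min(near, key=lambda c: abs(c - pos)) if near else pos

    out = []
    for c in calls:
        s = snap(c.start, starts.get(c.chrom, []))
        e = snap(c.end, ends.get(c.chrom, []))
        if e < s:
            s, e = c.start, c.end
        out.append(
            CNVCall(c.chrom, s, e, c.type, cn=getattr(c, "cn", -1),
                    baseline=getattr(c, "baseline", 2))
        )
    return out

HYPOTHETICAL_GAP = "N" * 10  # explicit gap placeholder at '??' joints


class GraphConsistencyError(ValueError):
    pass


@dataclass
class BreakpointGraph:
    """Reference segments (common refinement of all breakpoints), their
    required derivative multiplicities, and the novel adjacencies."""

    chrom_order: list[str]
    # per chromosome: ordered segment index range [lo, hi) into `segments`
    chrom_slices: dict[str, tuple[int, int]]
    segments: list[tuple[str, int, int]]
    multiplicity: list[int]
    junctions: list[Junction]
    unresolved: list[Junction] = field(default_factory=list)
    baselines: dict[str, int] = field(default_factory=dict)

    def seg_at_start(self, chrom: str, pos: int) -> Optional[int]:
        lo, hi = self.chrom_slices[chrom]
        for i in range(lo, hi):
            if self.segments[i][1] == pos:
                return i
        return None

    def seg_at_end(self, chrom: str, pos: int) -> Optional[int]:
        lo, hi = self.chrom_slices[chrom]
        for i in range(lo, hi):
            if self.segments[i][2] == pos:
                return i
        return None


def _cn_lookup(
    calls: Sequence, chrom: str, start: int, end: int, baseline: int
) -> int:
    for c in calls:
        if c.chrom == chrom and c.start <= start and end <= c.end:
            cn = getattr(c, "cn", -1)
            if cn is None or cn < 0:
                cn = {
                    "DEL": baseline - 1,
                    "DUP": baseline + 1,
                    "TRP": baseline + 2,
                }[c.type]
            return cn
    return baseline


def build_graph(
    calls: Sequence,
    junctions: Sequence[Junction],
    genome: GenomeRef,
) -> BreakpointGraph:
    """Split every involved chromosome at all CNV boundaries and junction
    breakends; attach multiplicities and novel adjacencies.

    ``calls`` may be :class:`SegmentCN` or :class:`CNVCall` records (a call
    without an explicit cn is interpreted from its DEL/DUP/TRP type).
    Junction breakends must land on segment boundaries of the refinement —
    on these toy coordinates with zero tolerance; a breakend outside its
    chromosome is an inconsistency error.  Unresolved junctions are kept
    separately: they constrain nothing but are reported.
    """
    resolved = [j for j in junctions if j.resolved and j.support == SUPPORT_SEQUENCED]
    unresolved = [
        j for j in junctions if not (j.resolved and j.support == SUPPORT_SEQUENCED)
    ]
    involved = {c.chrom for c in calls} | {
        e.chrom for j in resolved for e in j.breakends()
    }
    missing = involved - set(genome.names)
    if missing:
        raise GraphConsistencyError(f"unknown chromosomes: {sorted(missing)}")
    # every chromosome of the reference is a node set: untouched ones
    # contribute a trivial reference walk
    boundaries: dict[str, set[int]] = {c: set() for c in genome.names}
    for c in calls:
        if c.chrom not in boundaries:
            continue
        boundaries[c.chrom].update((c.start, c.end + 1))
    for j in resolved:
        for e in j.breakends():
            if not 1 <= e.pos <= genome.lengths[e.chrom]:
                raise GraphConsistencyError(
                    f"{j.id}: breakend {e} outside chromosome"
                )
            # retains_left at p ends a segment at p; retains_right starts one at p
            boundaries[e.chrom].add(e.pos + 1 if e.side == RETAINS_LEFT else e.pos)
    segments: list[tuple[str, int, int]] = []
    multiplicity: list[int] = []
    chrom_slices: dict[str, tuple[int, int]] = {}
    baselines: dict[str, int] = {}
    for chrom in sorted(boundaries):
        length = genome.lengths[chrom]
        baseline = genome.ploidy[chrom]
        baselines[chrom] = baseline
        cuts = sorted({1, length + 1, *(b for b in boundaries[chrom] if 1 <= b <= length + 1)})
        lo = len(segments)
        for a, b in zip(cuts[:-1], cuts[1:]):
            cn = _cn_lookup(calls, chrom, a, b - 1, baseline)
            segments.append((chrom, a, b - 1))
            multiplicity.append(max(cn - (baseline - 1), 0))
        chrom_slices[chrom] = (lo, len(segments))
    graph = BreakpointGraph(
        chrom_order=sorted(boundaries),
        chrom_slices=chrom_slices,
        segments=segments,
        multiplicity=multiplicity,
        junctions=resolved,
        unresolved=unresolved,
        baselines=baselines,
    )
    for j in resolved:
        for e in j.breakends():
            ok = (
                graph.seg_at_end(e.chrom, e.pos)
                if e.side == RETAINS_LEFT
                else graph.seg_at_start(e.chrom, e.pos)
            )
            if ok is None:
                raise GraphConsistencyError(
                    f"{j.id}: breakend {e} not at any segment boundary"
                )
    return graph


@dataclass
class CandidateModel:
    """One complete reconstruction: a walk per involved chromosome."""

    walks: dict[str, DerivativeModel]
    hypothetical: list[Junction]

    @property
    def n_hypothetical(self) -> int:
        return len(self.hypothetical)

    @property
    def n_inverting(self) -> int:
        return sum(
            1
            for m in self.walks.values()
            for j in m.junctions_used
            if j.inverting
        )

    def all_junctions(self) -> list[Junction]:
        out = []
        for m in self.walks.values():
            out.extend(m.junctions_used)
        return out

    def recipient_models(self) -> list[DerivativeModel]:
        """Walks that actually use junctions (the rearranged chromosomes)."""
        return [m for m in self.walks.values() if m.junctions_used]

    def sort_key(self) -> tuple:
        coords = tuple(
            (seg, o) for m in self.walks.values() for seg, o in m.walk
        )
        return (self.n_hypothetical, self.n_inverting, coords)


@dataclass
class ReconstructionResult:
    status: str  # "ok" | "unreconstructable"
    models: list[CandidateModel]
    graph: BreakpointGraph

    @property
    def best(self) -> CandidateModel:
        if not self.models:
            raise ValueError("no model reconstructed")
        return self.models[0]


def _tail_breakend(graph, seg_idx: int, orient: str) -> tuple[str, int, str]:
    chrom, s, e = graph.segments[seg_idx]
    return (chrom, e, RETAINS_LEFT) if orient == "+" else (chrom, s, RETAINS_RIGHT)


def _head_breakend(graph, seg_idx: int, orient: str) -> tuple[str, int, str]:
    chrom, s, e = graph.segments[seg_idx]
    return (chrom, s, RETAINS_RIGHT) if orient == "+" else (chrom, e, RETAINS_LEFT)


def _head_placement(graph, key: tuple[str, int, str]) -> Optional[tuple[int, str]]:
    """Segment placement whose head matches a breakend (chrom,pos,side)."""
    chrom, pos, side = key
    if chrom not in graph.chrom_slices:
        return None
    if side == RETAINS_RIGHT:
        i = graph.seg_at_start(chrom, pos)
        return (i, "+") if i is not None else None
    i = graph.seg_at_end(chrom, pos)
    return (i, "-") if i is not None else None


def reconstruct(
    graph: BreakpointGraph,
    max_hypothetical: int = 3,
    max_models: int = 64,
) -> ReconstructionResult:
    """Search for walks satisfying every multiplicity, using every
    sequenced junction exactly once.

    Exhaustive depth-first search with memoized dead states, iteratively
    deepened over the number of hypothetical junctions allowed (0, 1, ...,
    ``max_hypothetical``).  All complete models at the minimal hypothetical
    count are collected (up to ``max_models``) and ranked: fewest inverted
    joins first, then lexicographically smallest walk coordinates — the
    full minimal set is reported rather than asserting uniqueness.  If even
    ``max_hypothetical`` extra joints cannot complete a walk the result is
    "unreconstructable".
    """
    n_seg = len(graph.segments)
    n_jct = len(graph.junctions)
    full_mask = (1 << n_jct) - 1

    # junction lookup: tail breakend key -> [(jct_idx, mate_key)]
    by_tail: dict[tuple, list[tuple[int, tuple]]] = {}
    for idx, j in enumerate(graph.junctions):
        for e, m in ((j.a, j.b), (j.b, j.a)):
            by_tail.setdefault(e.key, []).append((idx, m.key))

    chroms = graph.chrom_order
    solutions: list[tuple] = []

    def heads_with_mult(mult: tuple) -> list[tuple[int, str]]:
        out = []
        for i in range(n_seg):
            if mult[i] > 0:
                out.append((i, "+"))
                out.append((i, "-"))
        return out

    for budget in range(max_hypothetical + 1):
        dead: set = set()
        solutions = []

        def search(ci: int, seg: int, orient: str, mult: tuple, mask: int,
                   hyps: tuple, path: tuple) -> None:
            """ci: index into chroms of the walk under construction; seg/orient:
            current placement.  path: ((ci, seg, orient, jct_or_None), ...)."""
            if len(solutions) >= max_models:
                return
            key = (ci, seg, orient, mult, mask, len(hyps))
            if key in dead:
                return
            found_before = len(solutions)

            lo, hi = graph.chrom_slices[chroms[ci]]
            # 1) sequenced junctions from the current tail
            tail = _tail_breakend(graph, seg, orient)
            for jct_idx, mate in by_tail.get(tail, ()):
                if not mask & (1 << jct_idx):
                    continue
                nxt = _head_placement(graph, mate)
                if nxt is None:
                    continue
                i, o = nxt
                if mult[i] <= 0:
                    continue
                m2 = list(mult)
                m2[i] -= 1
                search(ci, i, o, tuple(m2), mask & ~(1 << jct_idx), hyps,
                       path + ((ci, i, o, jct_idx),))
            # 2) reference adjacency (within the chromosome of the *current*
            # segment, which may be inserted material from elsewhere)
            slo, shi = graph.chrom_slices[graph.segments[seg][0]]
            nxt_seg = seg + 1 if orient == "+" else seg - 1
            if slo <= nxt_seg < shi and mult[nxt_seg] > 0:
                m2 = list(mult)
                m2[nxt_seg] -= 1
                search(ci, nxt_seg, orient, tuple(m2), mask, hyps,
                       path + ((ci, nxt_seg, orient, None),))
            # 3) telomere: finish this chromosome's walk
            if orient == "+" and seg == hi - 1:
                if ci + 1 == len(chroms):
                    if mask == 0 and all(m == 0 for m in mult):
                        solutions.append((path, hyps))
                else:
                    lo2, _ = graph.chrom_slices[chroms[ci + 1]]
                    if mult[lo2] > 0:
                        m2 = list(mult)
                        m2[lo2] -= 1
                        search(ci + 1, lo2, "+", tuple(m2), mask, hyps,
                               path + ((ci + 1, lo2, "+", None),))
            # 4) hypothetical junction to any needed head
            if len(hyps) < budget:
                for i, o in heads_with_mult(mult):
                    m2 = list(mult)
                    m2[i] -= 1
                    hyp = (tail, _head_breakend(graph, i, o))
                    search(ci, i, o, tuple(m2), mask, hyps + (hyp,),
                           path + ((ci, i, o, ("hyp", len(hyps))),))
            if len(solutions) == found_before:
                dead.add(key)

        mult0 = list(graph.multiplicity)
        lo0, _ = graph.chrom_slices[chroms[0]]
        if mult0[lo0] > 0:
            mult0[lo0] -= 1
            search(0, lo0, "+", tuple(mult0), full_mask, (),
                   ((0, lo0, "+", None),))
        if solutions:
            break

    if not solutions:
        return ReconstructionResult("unreconstructable", [], graph)

    models = [_assemble(graph, chroms, path, hyps) for path, hyps in solutions]
    seen = set()
    uniq = []
    for m in sorted(models, key=CandidateModel.sort_key):
        k = m.sort_key()
        if k not in seen:
            seen.add(k)
            uniq.append(m)
    return ReconstructionResult("ok", uniq, graph)


def _assemble(graph, chroms, path, hyps) -> CandidateModel:
    hyp_junctions = []
    for n, (tail, head) in enumerate(hyps):
        a = BreakEnd(tail[0], tail[1], tail[2],
                     "+" if tail[2] == RETAINS_LEFT else "-")
        b = BreakEnd(head[0], head[1], head[2],
                     "+" if head[2] == RETAINS_RIGHT else "-")
        hyp_junctions.append(
            Junction(f"hyp{n + 1}", a, b, support=SUPPORT_HYPOTHETICAL)
        )
    walks: dict[str, DerivativeModel] = {}
    cur_ci = None
    cur_walk: list = []
    cur_joins: list = []

    def flush():
        if cur_ci is not None:
            walks[chroms[cur_ci]] = DerivativeModel(
                chroms[cur_ci], list(cur_walk), list(cur_joins)
            )

    for ci, seg_idx, orient, via in path:
        if ci != cur_ci:
            flush()
            cur_ci, cur_walk, cur_joins = ci, [], []
        else:
            if isinstance(via, tuple) and via and via[0] == "hyp":
                cur_joins.append(hyp_junctions[via[1]])
            elif via is None:
                cur_joins.append(None)
            else:
                cur_joins.append(graph.junctions[via])
        chrom, s, e = graph.segments[seg_idx]
        cur_walk.append(((chrom, s, e), orient))
    flush()
    return CandidateModel(walks, hyp_junctions)


def count_junctions(model, support: Optional[str] = None) -> int:
    """Junctions in a model (a CandidateModel or a single DerivativeModel),
    optionally filtered by support status."""
    js = (
        model.all_junctions()
        if isinstance(model, CandidateModel)
        else model.junctions_used
    )
    if support is not None:
        js = [j for j in js if j.support == support]
    return len(js)


def emit_derivative_sequence(
    model: DerivativeModel,
    genome: GenomeRef,
    features: Optional[dict] = None,
) -> str:
    """Concatenate the walk's oriented segment sequences, inserting
    junctional sequence at each novel joint.

    Breakend positions are canonical (microhomology tract assigned to one
    side), so plain concatenation is exact.  A hypothetical junction
    contributes an explicit 10-N gap placeholder; so does a sequenced
    junction whose insert sequence is unknown but of declared length
    (placeholder of that length).
    """
    features = features or {}
    parts = []
    for i, ((chrom, s, e), orient) in enumerate(model.walk):
        parts.append(genome.fetch(chrom, s, e, orient))
        if i < len(model.joins):
            j = model.joins[i]
            if j is None:
                continue
            if j.support == SUPPORT_HYPOTHETICAL:
                parts.append(HYPOTHETICAL_GAP)
                continue
            feat = features.get(j.id, j.feature)
            if feat is not None and feat.insert_len:
                parts.append(
                    feat.insert_seq if feat.insert_seq else "N" * feat.insert_len
                )
    return "".join(parts)
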