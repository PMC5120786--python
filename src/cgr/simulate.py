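"""Rearrangement simulator: ground-truth derivative chromosomes and the
assays downstream modules consume.

Two generative models are implemented, mirroring the mechanisms proposed
for complex chromosomal insertions:

* **Replicative template switching** (FoSTeS/MMBIR): a replication fork
  starting on a recipient chromosome performs an ordered chain of switches
  to other templates, each switch producing one breakpoint junction whose
  signature (microhomology, untemplated insert, or templated insert copied
  from one or more loci) is specified exactly by the chain.  Copy-number
  gains arise from re-copied templates; skipped recipient intervals become
  deletions.

* **End joining** (NHEJ/MMEJ): a donor fragment is excised and inserted at
  an acceptor locus, optionally exchanging a reciprocal fragment in the
  other direction.  Junctions are blunt or carry only short (1-3 bp)
  microhomology or untemplated inserts; no copy of anything is gained.

Microhomology is *constructed*, never sampled post hoc: the simulator
either searches near the requested landing position for flanks sharing
exactly the requested number of terminal bases, or (``plant=True``) writes
the required bases into the toy genome before copying, so the truth label
is well-defined.  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BLUNT,
    MICROHOMOLOGY,
    RETAINS_LEFT,
    RETAINS_RIGHT,
    SUPPORT_SEQUENCED,
    TEMPLATED,
    UNTEMPLATED,
    BreakEnd,
    CNVCall,
    DerivativeModel,
    GenomeRef,
    Junction,
    JunctionFeature,
    SegmentCN,
    calls_from_segments,
    closed_length,
    revcomp,
)

__all__ = [
    "SwitchEvent",
    "EventChain",
    "TruthModel",
    "JunctionRead",
    "JunctionConstructionError",
    "simulate_replicative",
    "simulate_end_joining_insertion",
    "emit_probe_table",
    "probe_table_from_segments",
    "emit_junction_reads",
    "cnv_from_walks",
    "make_replicative_case",
    "make_end_joining_case",
]

MH_SEARCH_WINDOW = 50  # bp scanned around a requested landing position


class JunctionConstructionError(ValueError):
    """Requested junction signature impossible at the chosen loci."""


@dataclass
class SwitchEvent:
    """One template switch of a replicative chain.

    The fork lands at ``target_pos`` on ``target_chrom`` and replicates
    ``copy_len`` bases in ``orientation`` before the next switch (the final
    event of a chain replicates to the chromosome end and ``copy_len`` is
    ignored).  The joint either shares ``mh_len`` terminal bases with the
    departed flank, or carries inserted sequence — never both.
    """

    target_chrom: str
    target_pos: int
    orientation: str = "+"
    copy_len: Optional[int] = None
    mh_len: int = 0
    untemplated_insert: str = ""
    templated_insert_sources: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.mh_len < 0:
            raise ValueError("mh_len < 0")
        has_insert = bool(self.untemplated_insert) or bool(
            self.templated_insert_sources
        )
        if has_insert and self.mh_len != 0:
            raise ValueError(
                "a joint shows microhomology OR inserted sequence, not both"
            )
        if self.untemplated_insert and self.templated_insert_sources:
            raise ValueError("insert is untemplated or templated, not both")


@dataclass
class EventChain:
    """An ordered chain of template switches on a recipient chromosome.

    ``start`` is where replication departs the recipient; ``resolution``
    is where it rejoins (the final event's target).  The dashed
    template-switching paths of the case figures are exactly such chains.
    """

    start: tuple[str, int]
    events: list[SwitchEvent]
    resolution: tuple[str, int]
    seed: int = 0

    def __post_init__(self):
        if not self.events:
            raise ValueError("chain needs >= 1 event")
        last = self.events[-1]
        if (last.target_chrom, last.target_pos) != tuple(self.resolution):
            raise ValueError("resolution must equal the final event's target")
        if last.orientation != "+":
            raise ValueError("resolution rejoins the recipient in + orientation")
        if self.start[0] != self.resolution[0]:
            raise ValueError(
                "start and resolution must lie on the same (recipient) chromosome"
            )

    @property
    def recipient(self) -> str:
        return self.start[0]


@dataclass
class JunctionRead:
    """A junction-spanning sequence (emulated long-range PCR + Sanger product)."""

    id: str
    seq: str
    clipped: bool = False


@dataclass
class TruthModel:
    """Ground truth for one simulated rearrangement.

    ``derivative_seq``/``derivative_model`` expose the primary (first)
    derivative; end-joining exchanges produce one derivative per involved
    chromosome, all listed in ``derivatives``.
    """

    genome: GenomeRef
    derivatives: list[DerivativeModel]
    derivative_seqs: dict[str, str]
    truth_junctions: list[Junction]
    truth_cnv: list[SegmentCN]
    rearranged_chroms: list[str]
    # junction id -> (derivative chrom, 0-based index of the last base of
    # the left flank in the derivative sequence, insert length)
    junction_layout: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @property
    def derivative_model(self) -> DerivativeModel:
        return self.derivatives[0]

    @property
    def derivative_seq(self) -> str:
        return self.derivative_seqs[self.derivatives[0].recipient_chrom]

    def truth_calls(self) -> list[CNVCall]:
        return calls_from_segments(self.truth_cnv)

    def check_invariants(self) -> None:
        """Length conservation and walk/sequence consistency."""
        for der in self.derivatives:
            seq = self.derivative_seqs[der.recipient_chrom]
            total = sum(closed_length(s, e) for (_, s, e), _o in der.walk)
            total += sum(
                (j.feature.insert_len if j.feature else 0)
                for j in der.junctions_used
            )
            if total != len(seq):
                raise AssertionError(
                    f"length conservation violated on {der.recipient_chrom}: "
                    f"{total} != {len(seq)}"
                )
        recomputed = cnv_from_walks(
            self.derivatives, self.genome, self.rearranged_chroms
        )
        if _cnv_key(recomputed) != _cnv_key(self.truth_cnv):
            raise AssertionError("truth_cnv not recomputable from walks")


def _cnv_key(segs: Sequence[SegmentCN]):
    return sorted((s.chrom, s.start, s.end, s.cn) for s in segs)


def cnv_from_walks(
    derivatives: Sequence[DerivativeModel],
    genome: GenomeRef,
    rearranged_chroms: Sequence[str],
) -> list[SegmentCN]:
    """Copy-number segments implied by segment-use counting.

    cn(x) = (# intact homologs of the chromosome) + (# derivative walks
    covering x).  A rearranged chromosome has one homolog replaced by its
    derivative, hence ploidy-1 intact copies; all other chromosomes keep
    their full ploidy intact.  Only non-baseline segments are returned.
    """
    deltas: dict[str, dict[int, int]] = {}
    for der in derivatives:
        for (chrom, s, e), _o in der.walk:
            d = deltas.setdefault(chrom, {})
            d[s] = d.get(s, 0) + 1
            d[e + 1] = d.get(e + 1, 0) - 1
    out: list[SegmentCN] = []
    for chrom, d in deltas.items():
        baseline = genome.ploidy[chrom]
        intact = baseline - (1 if chrom in rearranged_chroms else 0)
        length = genome.lengths[chrom]
        points = sorted(p for p in d if 1 <= p <= length + 1)
        bounds = sorted({1, length + 1, *points})
        cum = 0
        pending: Optional[list] = None  # [start, end, cn]
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1] - 1
            cum += d.get(lo, 0)
            cn = intact + cum
            if cn != baseline:
                if pending is not None and pending[2] == cn and pending[1] == lo - 1:
                    pending[1] = hi
                else:
                    if pending is not None:
                        out.append(
                            SegmentCN(chrom, pending[0], pending[1], pending[2], baseline)
                        )
                    pending = [lo, hi, cn]
            else:
                if pending is not None:
                    out.append(
                        SegmentCN(chrom, pending[0], pending[1], pending[2], baseline)
                    )
                    pending = None
        if pending is not None:
            out.append(SegmentCN(chrom, pending[0], pending[1], pending[2], baseline))
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# flank helpers (orientation-aware, 1-based closed coordinates)


def _flank_before(g: GenomeRef, chrom: str, pos: int, orient: str, k: int) -> str:
    """The k derivative bases that would precede ``pos`` when traversing the
    template in ``orient`` (clipped at chromosome bounds)."""
    if k <= 0:
        return ""
    if orient == "+":
        lo = max(1, pos - k)
        return g.fetch(chrom, lo, pos - 1) if pos - 1 >= lo else ""
    hi = min(g.lengths[chrom], pos + k)
    return revcomp(g.fetch(chrom, pos + 1, hi)) if pos + 1 <= hi else ""


def _base_after(g: GenomeRef, chrom: str, pos: int, orient: str) -> Optional[str]:
    """The derivative base that would follow ``pos`` in ``orient``, or None
    at a chromosome end."""
    if orient == "+":
        return g.fetch(chrom, pos + 1, pos + 1) if pos + 1 <= g.lengths[chrom] else None
    return revcomp(g.fetch(chrom, pos - 1, pos - 1)) if pos - 1 >= 1 else None


def _other_base(rng: np.random.Generator, *avoid: Optional[str]) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def _flank_after(g: GenomeRef, chrom: str, pos: int, orient: str, k: int) -> str:
    """The k derivative bases that would follow ``pos`` in ``orient``."""
    if k <= 0:
        return ""
    if orient == "+":
        hi = min(g.lengths[chrom], pos + k)
        return g.fetch(chrom, pos + 1, hi) if pos + 1 <= hi else ""
    lo = max(1, pos - k)
    return revcomp(g.fetch(chrom, lo, pos - 1)) if pos - 1 >= lo else ""


def _head_at(g: GenomeRef, chrom: str, pos: int, orient: str, k: int) -> str:
    """The first k derivative bases starting at ``pos`` in ``orient``."""
    if k <= 0:
        return ""
    if orient == "+":
        hi = min(g.lengths[chrom], pos + k - 1)
        return g.fetch(chrom, pos, hi) if hi >= pos else ""
    lo = max(1, pos - k + 1)
    return revcomp(g.fetch(chrom, lo, pos)) if pos >= lo else ""


# ---------------------------------------------------------------------------
# derivative builder


class _DerivativeBuilder:
    """Builds one derivative chromosome joint by joint.

    Shared by the replicative and end-joining simulators; handles landing
    position resolution (search or plant), canonical tract assignment, and
    sequence/segment bookkeeping.
    """

    def __init__(
        self,
        genome: GenomeRef,
        recipient: str,
        plant: bool,
        rng: np.random.Generator,
        protected: list[tuple[str, int, int]],
        id_prefix: str = "jct",
    ):
        self.g = genome
        self.recipient = recipient
        self.plant = plant
        self.rng = rng
        self.protected = protected  # intervals planting must not touch
        self.id_prefix = id_prefix
        self.der = ""
        self.segments: list[list] = []  # [chrom, lo, hi, orient]
        self.joins: list[Junction] = []
        self.layout: dict[str, tuple[str, int, int]] = {}
        self.n = 0

    # -- protection bookkeeping ------------------------------------------
    def protect(self, chrom: str, lo: int, hi: int) -> None:
        self.protected.append((chrom, lo, hi))

    def _check_plant(self, chrom: str, lo: int, hi: int, joint: str) -> None:
        for c, plo, phi in self.protected:
            if c == chrom and lo <= phi and hi >= plo:
                raise JunctionConstructionError(
                    f"{joint}: planting at {chrom}:{lo}-{hi} would overwrite "
                    f"sequence already copied or protected ({c}:{plo}-{phi})"
                )

    def _write(self, chrom: str, pos: int, bases: str, joint: str) -> None:
        self._check_plant(chrom, pos, pos + len(bases) - 1, joint)
        self.g.set_bases(chrom, pos, bases)

    # -- construction ----------------------------------------------------
    def start_prefix(self, end_pos: int) -> None:
        """Begin the derivative with the recipient's [1..end_pos] prefix."""
        if not 1 <= end_pos < self.g.lengths[self.recipient]:
            raise ValueError(f"bad start position {end_pos}")
        self.segments.append([self.recipient, 1, end_pos, "+"])
        self.der = self.g.fetch(self.recipient, 1, end_pos)
        self.protect(self.recipient, 1, end_pos)

    def _tail(self) -> tuple[str, int, str]:
        chrom, lo, hi, orient = self.segments[-1]
        return (chrom, hi if orient == "+" else lo, orient)

    def _natural_overlap(self, chrom: str, q: int, orient: str) -> tuple[int, int]:
        """Shared sequence at a joint taken as-is: (i, j) with i the bases
        preceding the landing that match the derivative tail, j the bases
        after the departure that match the landing head."""
        g = self.g
        dep_chrom, dep_pos, dep_orient = self._tail()
        i = 0
        while i < 20:
            fb = _flank_before(g, chrom, q, orient, i + 1)
            if len(fb) == i + 1 and len(self.der) > i and fb == self.der[-(i + 1) :]:
                i += 1
            else:
                break
        j = 0
        while j < 20:
            aft = _flank_after(g, dep_chrom, dep_pos, dep_orient, j + 1)
            head = _head_at(g, chrom, q, orient, j + 1)
            if len(aft) == j + 1 and len(head) == j + 1 and aft == head:
                j += 1
            else:
                break
        return i, j

    def _fit_insert(self, length: int, chrom: str, q: int, orient: str) -> str:
        """An untemplated insert whose edge bases extend neither anchor."""
        g = self.g
        dep_chrom, dep_pos, dep_orient = self._tail()
        cont = _base_after(g, dep_chrom, dep_pos, dep_orient)
        before1 = _flank_before(g, chrom, q, orient, 1)
        for _ in range(100):
            ins = "".join("ACGT"[k] for k in self.rng.integers(0, 4, size=length))
            if cont is not None and ins[0] == cont:
                continue
            if before1 and ins[-1] == before1:
                continue
            return ins
        raise JunctionConstructionError("could not fit an untemplated insert")

    def jump(
        self,
        target_chrom: str,
        target_pos: int,
        orientation: str,
        copy_end: Optional[int],
        mh_len: int = 0,
        untemplated_insert: str = "",
        templated_sources: Sequence[tuple] = (),
        jid: Optional[str] = None,
        natural: bool = False,
    ) -> Junction:
        """Switch templates: one junction, then copy up to ``copy_end``
        (inclusive, in derivative direction; None = chromosome end).

        ``natural=True`` (the end-joining mode) takes the joint exactly as
        the two flanks give it: blunt when they share nothing, otherwise a
        small boundary-fitted untemplated insert — the genome is never
        edited and the landing position is never moved.
        """
        self.n += 1
        jid = jid or f"{self.id_prefix}{self.n}"
        g = self.g
        dep_chrom, dep_pos, dep_orient = self._tail()

        insert = untemplated_insert
        parts: list[tuple] = []
        if templated_sources:
            pieces = []
            for (c, s, e, strand) in templated_sources:
                pieces.append(g.fetch(c, s, e, strand))
                parts.append((c, s, e, strand))
                self.protect(c, s, e)
            insert = "".join(pieces)

        if natural:
            if parts or mh_len:
                raise ValueError("natural joints take only blunt/untemplated features")
            q = target_pos
            if not 1 <= q <= g.lengths[target_chrom]:
                raise ValueError(f"{jid}: landing {target_chrom}:{q} outside chromosome")
            if not insert:
                i, j = self._natural_overlap(target_chrom, q, orientation)
                if i + j > 0:
                    # shared flank bases would smear the joint by a few bp;
                    # use a small insert instead so boundaries stay exact
                    insert = self._fit_insert(
                        int(self.rng.integers(1, 4)), target_chrom, q, orientation
                    )
            else:
                insert = self._fit_insert(
                    len(insert), target_chrom, q, orientation
                )
        else:
            q, insert = self._resolve_landing(
                jid, target_chrom, target_pos, orientation, mh_len, insert, parts
            )

        # copied extent on the new template (tract excluded: the derivative
        # already holds it via the departed flank)
        if orientation == "+":
            end = copy_end if copy_end is not None else g.lengths[target_chrom]
            if not q <= end <= g.lengths[target_chrom]:
                raise ValueError(f"{jid}: bad copy extent {target_chrom}:{q}-{end}")
            natural = (q, end)
        else:
            end = copy_end if copy_end is not None else 1
            if not 1 <= end <= q:
                raise ValueError(f"{jid}: bad copy extent {target_chrom}:{end}-{q}")
            natural = (end, q)

        # breakends: departure tail keeps its flank; landing head keeps the
        # opposite-handed flank
        a_side = RETAINS_LEFT if dep_orient == "+" else RETAINS_RIGHT
        b_side = RETAINS_RIGHT if orientation == "+" else RETAINS_LEFT
        a_nat, b_nat = dep_pos, q
        # canonical tract assignment: retains_left side when sides differ,
        # else the lexicographically smaller (chrom, tract-free pos)
        if mh_len and a_side != b_side:
            tract_on_a = a_side == RETAINS_LEFT
        elif mh_len:
            a_free = a_nat - mh_len if a_side == RETAINS_LEFT else a_nat + mh_len
            tract_on_a = (dep_chrom, a_free) <= (target_chrom, b_nat)
        else:
            tract_on_a = True
        if tract_on_a:
            a_pos, b_pos = a_nat, b_nat
        else:
            a_pos = a_nat - mh_len if a_side == RETAINS_LEFT else a_nat + mh_len
            b_pos = b_nat - mh_len if b_side == RETAINS_RIGHT else b_nat + mh_len
        # adjust segment extents to the canonical boundaries
        dep_seg = self.segments[-1]
        if dep_orient == "+":
            dep_seg[2] = a_pos
        else:
            dep_seg[1] = a_pos
        if orientation == "+":
            new_seg = [target_chrom, b_pos, natural[1], "+"]
        else:
            new_seg = [target_chrom, natural[0], b_pos, "-"]

        if mh_len:
            feature = JunctionFeature(MICROHOMOLOGY, mh_len=mh_len)
        elif parts:
            feature = JunctionFeature(TEMPLATED, insert_seq=insert, template_parts=parts)
        elif insert:
            feature = JunctionFeature(UNTEMPLATED, insert_seq=insert)
        else:
            feature = JunctionFeature(BLUNT)

        junction = Junction(
            id=jid,
            a=BreakEnd(dep_chrom, a_pos, a_side, "+" if a_side == RETAINS_LEFT else "-"),
            b=BreakEnd(
                target_chrom, b_pos, b_side, "+" if b_side == RETAINS_RIGHT else "-"
            ),
            support=SUPPORT_SEQUENCED,
            feature=feature,
        )
        self.joins.append(junction)
        self.layout[jid] = (self.recipient, len(self.der) - 1, len(insert))

        piece = g.fetch(target_chrom, natural[0], natural[1], orientation)
        self.der += insert + piece
        self.protect(target_chrom, natural[0], natural[1])
        self.segments.append(new_seg)
        return junction

    # -- landing resolution ----------------------------------------------
    def _landing_ok(
        self,
        q: int,
        chrom: str,
        orient: str,
        mh_len: int,
        insert: str,
    ) -> bool:
        g = self.g
        dep_chrom, dep_pos, dep_orient = self._tail()
        cont = _base_after(g, dep_chrom, dep_pos, dep_orient)
        first = _flank_before(g, chrom, q + (1 if orient == "+" else -1), orient, 1)
        # `first` is the base at q in derivative orientation
        if insert:
            if cont is not None and insert[0] == cont:
                return False
            before1 = _flank_before(g, chrom, q, orient, 1)
            if before1 and insert[-1] == before1:
                return False
            return True
        if mh_len == 0:
            before1 = _flank_before(g, chrom, q, orient, 1)
            if before1 and self.der and before1 == self.der[-1]:
                return False
            if cont is not None and first and cont == first:
                return False
            return True
        tract = self.der[-mh_len:]
        if len(tract) < mh_len:
            return False
        if _flank_before(g, chrom, q, orient, mh_len) != tract:
            return False
        deeper = _flank_before(g, chrom, q, orient, mh_len + 1)
        if len(deeper) == mh_len + 1 and len(self.der) > mh_len:
            if deeper[0] == self.der[-(mh_len + 1)]:
                return False
        if cont is not None and first and cont == first:
            return False
        return True

    def _resolve_landing(
        self,
        jid: str,
        chrom: str,
        pos: int,
        orient: str,
        mh_len: int,
        insert: str,
        parts: list[tuple],
    ) -> tuple[int, str]:
        g = self.g
        if not 1 <= pos <= g.lengths[chrom]:
            raise ValueError(f"{jid}: landing {chrom}:{pos} outside chromosome")
        if not self.plant:
            for delta in range(MH_SEARCH_WINDOW + 1):
                for q in ({pos} if delta == 0 else {pos - delta, pos + delta}):
                    if 1 <= q <= g.lengths[chrom] and self._landing_ok(
                        q, chrom, orient, mh_len, insert
                    ):
                        return q, insert
            raise JunctionConstructionError(
                f"{jid}: cannot realize mh_len={mh_len}"
                f"{' with insert' if insert else ''} near {chrom}:{pos} "
                f"(searched +/-{MH_SEARCH_WINDOW} bp; flanks disagree)"
            )

        # plant mode: force the requested position by editing reference
        # bases *outside* every copied/protected interval
        q = pos
        dep_chrom, dep_pos, dep_orient = self._tail()
        rng = self.rng

        def put_before(k_off: int, base: str) -> None:
            """Write `base` at the position k_off bases before q in derivative
            orientation (k_off >= 1)."""
            if orient == "+":
                self._write(chrom, q - k_off, base, jid)
            else:
                self._write(chrom, q + k_off, revcomp(base), jid)

        def put_cont(base: str) -> None:
            if dep_orient == "+":
                self._write(dep_chrom, dep_pos + 1, base, jid)
            else:
                self._write(dep_chrom, dep_pos - 1, revcomp(base), jid)

        cont = _base_after(g, dep_chrom, dep_pos, dep_orient)
        first = _flank_before(g, chrom, q + (1 if orient == "+" else -1), orient, 1)
        if insert and not parts:
            # untemplated: regenerate offending edge bases instead of
            # editing the genome (the insert is novel sequence anyway)
            before1 = _flank_before(g, chrom, q, orient, 1)

            def fit(ins: str) -> str:
                if len(ins) == 1:
                    if ins in (cont, before1 or None):
                        return _other_base(rng, cont, before1 or None)
                    return ins
                if cont is not None and ins[0] == cont:
                    ins = _other_base(rng, cont) + ins[1:]
                if before1 and ins[-1] == before1:
                    ins = ins[:-1] + _other_base(rng, before1)
                return ins

            insert = fit(insert)
            # an edge fix may create an accidental reference match in a
            # long novel insert; redraw until it stays untemplated
            tries = 0
            while len(insert) >= 10 and _has_template_match(insert, g, 10):
                if tries >= 100:
                    raise JunctionConstructionError(
                        f"{jid}: cannot keep a {len(insert)} bp insert untemplated"
                    )
                insert = fit(
                    "".join("ACGT"[k] for k in rng.integers(0, 4, size=len(insert)))
                )
                tries += 1
        elif insert:
            if cont is not None and insert[0] == cont:
                put_cont(_other_base(rng, insert[0]))
            before1 = _flank_before(g, chrom, q, orient, 1)
            if before1 and insert[-1] == before1:
                put_before(1, _other_base(rng, insert[-1]))
            self._plant_part_boundaries(jid, parts, first)
        elif mh_len == 0:
            before1 = _flank_before(g, chrom, q, orient, 1)
            if before1 and self.der and before1 == self.der[-1]:
                put_before(1, _other_base(rng, self.der[-1]))
            if cont is not None and first and cont == first:
                put_cont(_other_base(rng, first))
        else:
            tract = self.der[-mh_len:]
            if len(tract) < mh_len:
                raise JunctionConstructionError(
                    f"{jid}: derivative shorter than requested mh_len"
                )
            current = _flank_before(g, chrom, q, orient, mh_len)
            if current != tract:
                if orient == "+":
                    if q - mh_len < 1:
                        raise JunctionConstructionError(f"{jid}: no room for tract")
                    self._write(chrom, q - mh_len, tract, jid)
                else:
                    self._write(chrom, q + 1, revcomp(tract), jid)
            deeper = _flank_before(g, chrom, q, orient, mh_len + 1)
            if (
                len(deeper) == mh_len + 1
                and len(self.der) > mh_len
                and deeper[0] == self.der[-(mh_len + 1)]
            ):
                put_before(mh_len + 1, _other_base(rng, self.der[-(mh_len + 1)]))
            if cont is not None and first and cont == first:
                put_cont(_other_base(rng, first))
        if not self._landing_ok(q, chrom, orient, mh_len, insert):
            raise JunctionConstructionError(f"{jid}: planting failed to converge")
        return q, insert

    def _plant_part_boundaries(
        self, jid: str, parts: list[tuple], first_landing_base: str
    ) -> None:
        """Block accidental extension of each templated part's reference
        match into the next part (keeps greedy decomposition crisp)."""
        g, rng = self.g, self.rng
        for i, (c, s, e, strand) in enumerate(parts):
            nxt = (
                g.fetch(*parts[i + 1][:1], parts[i + 1][1], parts[i + 1][1])
                if False
                else None
            )
            # derivative base following this part
            if i + 1 < len(parts):
                c2, s2, e2, st2 = parts[i + 1]
                nxt = g.fetch(c2, s2, s2) if st2 == "+" else revcomp(g.fetch(c2, e2, e2))
            else:
                nxt = first_landing_base or None
            if nxt is None:
                continue
            ext = _base_after(g, c, e if strand == "+" else s, strand)
            if ext is not None and ext == nxt:
                if strand == "+":
                    self._write(c, e + 1, _other_base(rng, nxt), jid)
                else:
                    self._write(c, s - 1, revcomp(_other_base(rng, nxt)), jid)

    # -- finish -----------------------------------------------------------
    def finish_to_end(self) -> None:
        chrom, lo, hi, orient = self.segments[-1]
        if chrom != self.recipient or orient != "+" or hi != self.g.lengths[chrom]:
            raise ValueError("derivative must end at the recipient's right telomere")

    def model(self) -> DerivativeModel:
        walk = [((c, lo, hi), o) for c, lo, hi, o in self.segments]
        joins: list[Optional[Junction]] = list(self.joins)
        return DerivativeModel(self.recipient, walk, joins)


# ---------------------------------------------------------------------------
# public simulators


def simulate_replicative(
    genome: GenomeRef, chain: EventChain, plant: bool = False
) -> TruthModel:
    """Execute a template-switch chain and return the full ground truth.

    Each :class:`SwitchEvent` produces exactly one junction whose feature
    encodes the event's microhomology/insert specification.  With
    ``plant=True`` the simulator edits a copy of the genome (only at bases
    outside every copied interval) so that the requested signature is
    realizable at the requested position; with ``plant=False`` it searches
    +/-50 bp and fails loudly if the flanks cannot agree.
    """
    g = genome.copy() if plant else genome
    rng = np.random.default_rng(chain.seed)
    protected: list[tuple[str, int, int]] = []
    b = _DerivativeBuilder(g, chain.recipient, plant, rng, protected)
    b.start_prefix(chain.start[1])
    for i, ev in enumerate(chain.events):
        last = i == len(chain.events) - 1
        if last:
            copy_end = None
        else:
            if ev.copy_len is None or ev.copy_len < 1:
                raise ValueError(f"event {i + 1}: copy_len required before the last switch")
            # provisional copy extent; canonical boundary shifts handled in jump
            copy_end = (
                ev.target_pos + ev.copy_len - 1
                if ev.orientation == "+"
                else ev.target_pos - ev.copy_len + 1
            )
        b.jump(
            ev.target_chrom,
            ev.target_pos,
            ev.orientation,
            copy_end,
            mh_len=ev.mh_len,
            untemplated_insert=ev.untemplated_insert,
            templated_sources=ev.templated_insert_sources,
        )
    b.finish_to_end()
    der = b.model()
    truth_cnv = cnv_from_walks([der], g, [chain.recipient])
    tm = TruthModel(
        genome=g,
        derivatives=[der],
        derivative_seqs={chain.recipient: b.der},
        truth_junctions=list(b.joins),
        truth_cnv=truth_cnv,
        rearranged_chroms=[chain.recipient],
        junction_layout=dict(b.layout),
    )
    tm.check_invariants()
    return tm


def simulate_end_joining_insertion(
    genome: GenomeRef,
    donor: tuple[str, int, int],
    acceptor: tuple[str, int],
    reciprocal_fragment: Optional[tuple[str, int, int]] = None,
    seed: int = 0,
    orientation: str = "+",
    trim_left: int = 0,
    trim_right: int = 0,
) -> TruthModel:
    """Excise ``donor`` and insert it at ``acceptor``, end-joining style.

    Produces one derivative per involved chromosome.  With
    ``reciprocal_fragment`` the acceptor-side fragment moves into the donor
    gap (a bidirectional exchange of genetic material); ``trim_left`` /
    ``trim_right`` drop bases from the excised fragment, leaving a small
    deletion at the donor locus.  Joints are taken as the flanks give
    them — blunt, or a 1-3 bp untemplated insert — the short-signature
    repertoire of end joining; the reference is never edited.
    """
    d_chrom, d_start, d_end = donor
    a_chrom, a_pos = acceptor
    if d_end < d_start:
        raise ValueError("bad donor interval")
    if reciprocal_fragment is not None:
        r_chrom, r_start, r_end = reciprocal_fragment
        if r_chrom != a_chrom:
            raise ValueError("reciprocal fragment must lie on the acceptor chromosome")
        if r_chrom == d_chrom and not (r_end < d_start or r_start > d_end):
            raise ValueError("overlapping donor/reciprocal intervals")
        a_pos = r_start - 1
    if d_chrom == a_chrom and d_start - 1 <= a_pos <= d_end:
        raise ValueError("acceptor position inside the donor interval")
    ins_start = d_start + trim_left
    ins_end = d_end - trim_right
    if ins_end < ins_start:
        raise ValueError("trimming leaves an empty donor fragment")

    g = genome
    rng = np.random.default_rng(seed)
    protected: list[tuple[str, int, int]] = []

    def feature_draw() -> dict:
        # roughly half the joints carry a small untemplated insert; the
        # rest are taken blunt (or become inserts if the flanks happen to
        # share bases)
        if rng.random() < 0.5:
            return {"untemplated_insert": "N" * int(rng.integers(1, 4))}
        return {}

    # acceptor-chromosome derivative: prefix + donor fragment + suffix
    ba = _DerivativeBuilder(g, a_chrom, False, rng, protected, id_prefix=f"{a_chrom}_jct")
    ba.start_prefix(a_pos)
    if orientation == "+":
        ba.jump(d_chrom, ins_start, "+", ins_end, natural=True, **feature_draw())
    else:
        ba.jump(d_chrom, ins_end, "-", ins_start, natural=True, **feature_draw())
    back_pos = (r_end + 1) if reciprocal_fragment is not None else a_pos + 1
    ba.jump(a_chrom, back_pos, "+", None, natural=True, **feature_draw())
    ba.finish_to_end()

    # donor-chromosome derivative: excision (plus reciprocal fragment if any)
    bd = _DerivativeBuilder(g, d_chrom, False, rng, protected, id_prefix=f"{d_chrom}_jct")
    bd.start_prefix(d_start - 1)
    if reciprocal_fragment is not None:
        bd.jump(r_chrom, r_start, "+", r_end, natural=True, **feature_draw())
    bd.jump(d_chrom, d_end + 1, "+", None, natural=True, **feature_draw())
    bd.finish_to_end()

    ders = [ba.model(), bd.model()]
    rearranged = [a_chrom, d_chrom]
    truth_cnv = cnv_from_walks(ders, g, rearranged)
    tm = TruthModel(
        genome=g,
        derivatives=ders,
        derivative_seqs={a_chrom: ba.der, d_chrom: bd.der},
        truth_junctions=list(ba.joins) + list(bd.joins),
        truth_cnv=truth_cnv,
        rearranged_chroms=rearranged,
        junction_layout={**ba.layout, **bd.layout},
    )
    tm.check_invariants()
    return tm


# ---------------------------------------------------------------------------
# emulated assays


def probe_table_from_segments(
    genome: GenomeRef,
    segments: Sequence,
    spacing_bp: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe-level log2-ratio table emulating high-density aCGH.

    One probe every ``spacing_bp`` across every chromosome; value =
    log2(cn / baseline) + N(0, noise_sd).  ``segments`` supplies the
    non-baseline copy numbers (SegmentCN records, or DEL/DUP/TRP calls
    whose cn is interpreted from the type).  Copy number zero is floored
    at 1/32 of a copy before the log (arrays saturate, they do not report
    -inf).  Deterministic per seed.
    """
    if spacing_bp < 50:
        raise ValueError("spacing must be >= 50 bp")
    rng = np.random.default_rng(seed)
    frames = []
    by_chrom: dict[str, list] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in genome.names:
        length = genome.lengths[chrom]
        pos = np.arange(spacing_bp // 2, length + 1, spacing_bp)
        baseline = genome.ploidy[chrom]
        cn = np.full(pos.shape, float(baseline))
        for s in by_chrom.get(chrom, []):
            val = getattr(s, "cn", -1)
            if val is None or val < 0:
                val = {"DEL": baseline - 1, "DUP": baseline + 1, "TRP": baseline + 2}[
                    s.type
                ]
            cn[(pos >= s.start) & (pos <= s.end)] = val
        ratio = np.log2(np.maximum(cn, 1 / 32) / baseline)
        if noise_sd > 0:
            ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.shape)
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "log2ratio": ratio})
        )
    return pd.concat(frames, ignore_index=True)


def emit_probe_table(
    truth: TruthModel,
    spacing_bp: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe table for a simulated truth model (see
    :func:`probe_table_from_segments`)."""
    return probe_table_from_segments(
        truth.genome, truth.truth_cnv, spacing_bp, noise_sd, seed
    )


def emit_junction_reads(truth: TruthModel, flank_bp: int = 500) -> list[JunctionRead]:
    """One junction-spanning read per *sequenced* junction.

    Each read carries ``flank_bp`` derivative bases on both sides of the
    joint plus any junctional insert; reads near a derivative end are
    shortened and flagged.  Hypothetical junctions emit nothing.
    """
    max_mh = max(
        (j.feature.mh_len for j in truth.truth_junctions if j.feature), default=0
    )
    if flank_bp < 2 * max_mh:
        raise ValueError(f"flank_bp must be >= 2 * max microhomology ({2 * max_mh})")
    reads = []
    for j in truth.truth_junctions:
        if j.support != SUPPORT_SEQUENCED or j.id not in truth.junction_layout:
            continue
        chrom, joint, ins_len = truth.junction_layout[j.id]
        der = truth.derivative_seqs[chrom]
        lo = joint + 1 - flank_bp
        hi = joint + 1 + ins_len + flank_bp  # exclusive
        clipped = lo < 0 or hi > len(der)
        reads.append(JunctionRead(j.id, der[max(lo, 0) : min(hi, len(der))], clipped))
    return reads


# ---------------------------------------------------------------------------
# seeded case generators (presets mirror the observed event classes)


def _sample_locus(
    rng: np.random.Generator,
    genome: GenomeRef,
    chrom: str,
    size: int,
    used: list[tuple[str, int, int]],
    margin: int = 2_000,
    tries: int = 200,
) -> tuple[int, int]:
    """A [start, end] interval on ``chrom`` clear of all ``used`` intervals."""
    length = genome.lengths[chrom]
    for _ in range(tries):
        start = int(rng.integers(margin + 1, length - size - margin))
        end = start + size - 1
        if all(
            not (c == chrom and start - margin <= hi and end + margin >= lo)
            for c, lo, hi in used
        ):
            used.append((chrom, start, end))
            return start, end
    raise RuntimeError("could not place a locus; genome too crowded")


def _has_template_match(seq: str, genome: GenomeRef, minlen: int) -> bool:
    for i in range(len(seq) - minlen + 1):
        probe = seq[i : i + minlen]
        for chrom in genome.names:
            if probe in genome.seq(chrom) or probe in genome.rc_seq(chrom):
                return True
    return False


def _random_untemplated(
    rng: np.random.Generator, genome: GenomeRef, length: int, min_template_len: int = 10
) -> str:
    for _ in range(50):
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if length < min_template_len or not _has_template_match(
            ins, genome, min_template_len
        ):
            return ins
    # fall back to a short insert that cannot be templated
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=min(length, 9)))


def make_replicative_case(
    seed: int,
    preset: str = "basic",
    genome: Optional[GenomeRef] = None,
) -> TruthModel:
    """A seeded ground-truth case from one of three event classes.

    * ``basic``: a single template switch copies one donor fragment into a
      deleted acceptor interval (one gain, deletion at the insertion site,
      short-microhomology or small-insert joints).
    * ``chromoanasynthesis``: an iterative chain with two copied donor
      fragments (two gains), one long-microhomology joint and one joint
      with a multi-part templated insert.
    * ``mixed``: random joint signatures over 2-4 switches (round-trip
      fuzzing of the annotator).
    """
    from .genome import make_toy_genome

    rng = np.random.default_rng(seed)
    if genome is None:
        genome = make_toy_genome(
            3, [80_000, 60_000, 50_000], 0.41, seed=seed + 10_000
        )
    used: list[tuple[str, int, int]] = []
    rec = "chr1"
    start = int(rng.integers(10_000, 20_000))
    used.append((rec, 1, start))

    def small_joint() -> dict:
        if rng.random() < 0.5:
            return {"mh_len": int(rng.integers(1, 4))}
        return {
            "untemplated_insert": _random_untemplated(
                rng, genome, int(rng.integers(1, 4))
            )
        }

    if preset == "basic":
        frag = int(rng.integers(2_000, 8_000))
        ds, de = _sample_locus(rng, genome, "chr2", frag, used)
        del_len = int(rng.integers(1_000, 5_000))
        res = start + 1 + del_len
        orient = "+" if rng.random() < 0.5 else "-"
        ev1 = SwitchEvent(
            "chr2",
            ds if orient == "+" else de,
            orient,
            copy_len=frag,
            **small_joint(),
        )
        ev2 = SwitchEvent("chr1", res, "+", **small_joint())
        chain = EventChain((rec, start), [ev1, ev2], ("chr1", res), seed=seed)
        return simulate_replicative(genome, chain, plant=True)

    if preset == "chromoanasynthesis":
        frag1 = int(rng.integers(3_000, 8_000))
        frag2 = int(rng.integers(2_000, 6_000))
        s1, e1 = _sample_locus(rng, genome, "chr2", frag1, used)
        s2, e2 = _sample_locus(rng, genome, "chr3", frag2, used)
        tparts = []
        n_parts = int(rng.integers(1, 4))
        for _ in range(n_parts):
            plen = int(rng.integers(15, 60))
            ps, pe = _sample_locus(rng, genome, "chr3", plen, used)
            tparts.append(("chr3", ps, pe, "+" if rng.random() < 0.5 else "-"))
        del_len = int(rng.integers(1_000, 4_000))
        res = start + 1 + del_len
        ev1 = SwitchEvent("chr2", s1, "+", copy_len=frag1, mh_len=int(rng.integers(5, 9)))
        ev2 = SwitchEvent(
            "chr3", s2, "+", copy_len=frag2, templated_insert_sources=tparts
        )
        ev3 = SwitchEvent("chr1", res, "+", **small_joint())
        chain = EventChain((rec, start), [ev1, ev2, ev3], ("chr1", res), seed=seed)
        return simulate_replicative(genome, chain, plant=True)

    if preset == "mixed":
        n_sw = int(rng.integers(2, 5))
        events = []
        for i in range(n_sw - 1):
            chrom = ["chr2", "chr3"][i % 2]
            frag = int(rng.integers(1_500, 5_000))
            s, e = _sample_locus(rng, genome, chrom, frag, used)
            orient = "+" if rng.random() < 0.5 else "-"
            r = rng.random()
            if r < 0.35:
                joint = {"mh_len": int(rng.integers(0, 13))}
            elif r < 0.65:
                joint = {
                    "untemplated_insert": _random_untemplated(
                        rng, genome, int(rng.integers(1, 19))
                    )
                }
            else:
                parts = []
                for _ in range(int(rng.integers(1, 4))):
                    plen = int(rng.integers(12, 80))
                    ps, pe = _sample_locus(rng, genome, "chr2", plen, used)
                    parts.append(("chr2", ps, pe, "+" if rng.random() < 0.5 else "-"))
                joint = {"templated_insert_sources": parts}
            events.append(
                SwitchEvent(chrom, s if orient == "+" else e, orient, copy_len=frag, **joint)
            )
        res = start + 1 + int(rng.integers(500, 4_000))
        events.append(SwitchEvent("chr1", res, "+", **small_joint()))
        chain = EventChain((rec, start), events, ("chr1", res), seed=seed)
        return simulate_replicative(genome, chain, plant=True)

    raise ValueError(f"unknown preset {preset!r}")


def make_end_joining_case(seed: int, genome: Optional[GenomeRef] = None) -> TruthModel:
    """A seeded balanced (or near-balanced) end-joining exchange."""
    from .genome import make_toy_genome

    rng = np.random.default_rng(seed)
    if genome is None:
        genome = make_toy_genome(2, [80_000, 60_000], 0.41, seed=seed + 20_000)
    used: list[tuple[str, int, int]] = []
    frag = int(rng.integers(5_000, 20_000))
    ds, de = _sample_locus(rng, genome, "chr1", frag, used)
    a_pos = int(
        _sample_locus(rng, genome, "chr2", 2, used)[0]
    )
    reciprocal = None
    if rng.random() < 0.5:
        rlen = int(rng.integers(400, 1_200))
        rs = a_pos + 1
        reciprocal = ("chr2", rs, rs + rlen - 1)
        used.append(reciprocal)
    return simulate_end_joining_insertion(
        genome,
        ("chr1", ds, de),
        ("chr2", a_pos),
        reciprocal_fragment=reciprocal,
        seed=seed,
    )
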