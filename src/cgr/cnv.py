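"""Copy-number segmentation and per-chromosome pattern logic.

The probe tables segmented here emulate high-density aCGH (one probe every
couple of hundred bp).  Segmentation is a deliberately simple deterministic
change-point routine — greedy binary splitting on the mean log2 ratio with
a z-test against an estimated noise level, then snapping each segment to
the nearest integer copy number.  The scientific content of this package
lies downstream of segmentation, so nothing fancier (CBS etc.) is needed.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DUP,
    TRP,
    CNVCall,
    GenomeRef,
    SegmentCN,
    calls_from_segments,
)

__all__ = [
    "segment_probes",
    "call_cnvs",
    "pattern_string",
    "parse_pattern",
    "detect_dup_trp_inv_dup",
]


def _estimate_noise_sd(values: np.ndarray) -> float:
    """Robust per-probe noise estimate from first differences (MAD-based);
    insensitive to the (few) true copy-number steps."""
    if len(values) < 3:
        return 1e-6
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    sd = mad / 0.6745 / np.sqrt(2.0)
    return max(float(sd), 1e-6)


def _best_split(v: np.ndarray, lo: int, hi: int, min_probes: int) -> tuple[int, float]:
    """Best change point k in (lo, hi] splitting [lo, hi) into halves of at
    least min_probes probes; returns (k, z) with z the two-sample z score
    in units of per-probe sd (sd factored out by the caller)."""
    n = hi - lo
    if n < 2 * min_probes:
        return -1, 0.0
    seg = v[lo:hi]
    cum = np.cumsum(seg)
    total = cum[-1]
    ks = np.arange(min_probes, n - min_probes + 1)
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = cum[ks - 1] / n1
    m2 = (total - cum[ks - 1]) / n2
    z = np.abs(m1 - m2) / np.sqrt(1.0 / n1 + 1.0 / n2)
    i = int(np.argmax(z))
    return lo + int(ks[i]), float(z[i])


def segment_probes(
    probes: pd.DataFrame,
    genome: GenomeRef,
    min_probes: int = 5,
    z_thresh: float = 4.0,
    noise_sd: Optional[float] = None,
) -> list[SegmentCN]:
    """Segment a probe table (columns chrom, pos, log2ratio) into integer
    copy-number segments.

    Greedy recursive binary splitting: the best change point is accepted
    whenever its z statistic exceeds ``z_thresh``; accepted segments are
    snapped to the nearest integer CN (cn = round(baseline * 2**mean)) and
    adjacent equal-CN segments merged.  Baselines come from the genome's
    per-chromosome ploidy, never from the data.  Segment boundaries are
    placed midway between the flanking probes; the full segmentation
    (including baseline segments) is returned.

    A chromosome with fewer than ``min_probes`` probes is reported as a
    single baseline segment with a warning.
    """
    out: list[SegmentCN] = []
    for chrom, grp in probes.groupby("chrom", sort=True):
        chrom = str(chrom)
        baseline = genome.ploidy[chrom]
        length = genome.lengths[chrom]
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        v = grp["log2ratio"].to_numpy(dtype=float)
        if len(v) < min_probes:
            warnings.warn(
                f"{chrom}: only {len(v)} probes (< {min_probes}); "
                "reporting a single baseline segment"
            )
            out.append(SegmentCN(chrom, 1, length, baseline, baseline))
            continue
        sd = noise_sd if noise_sd is not None else _estimate_noise_sd(v)

        bounds: list[int] = []

        def split(lo: int, hi: int) -> None:
            k, z = _best_split(v, lo, hi, min_probes)
            if k > 0 and z / sd > z_thresh:
                split(lo, k)
                bounds.append(k)
                split(k, hi)

        split(0, len(v))
        edges = [0, *bounds, len(v)]
        # integer CN per leaf, then merge equal neighbours
        leaves = []
        for a, b in zip(edges[:-1], edges[1:]):
            cn = int(round(baseline * 2 ** float(np.mean(v[a:b]))))
            leaves.append([a, b, max(cn, 0)])
        merged = [leaves[0]]
        for a, b, cn in leaves[1:]:
            if cn == merged[-1][2]:
                merged[-1][1] = b
            else:
                merged.append([a, b, cn])
        for i, (a, b, cn) in enumerate(merged):
            start = 1 if i == 0 else (int(pos[a - 1]) + int(pos[a])) // 2 + 1
            end = length if i == len(merged) - 1 else (int(pos[b - 1]) + int(pos[b])) // 2
            out.append(SegmentCN(chrom, start, end, cn, baseline))
    return out


def call_cnvs(
    probes: pd.DataFrame,
    genome: GenomeRef,
    min_probes: int = 5,
    z_thresh: float = 4.0,
    noise_sd: Optional[float] = None,
) -> list[CNVCall]:
    """Segment and return only the non-baseline intervals as DEL/DUP/TRP calls."""
    segs = segment_probes(probes, genome, min_probes, z_thresh, noise_sd)
    return calls_from_segments(segs)


def pattern_string(calls: Sequence[CNVCall], chrom: str) -> str:
    """Hyphen-joined ordered CNV states along one chromosome.

    Gaps between non-adjacent calls appear as NML; directly abutting calls
    (e.g. the triplication embedded in a duplication) are joined without
    one.  No calls at all yields "NML".
    """
    cs = sorted((c for c in calls if c.chrom == chrom), key=lambda c: c.start)
    if not cs:
        return "NML"
    parts = [cs[0].type]
    for prev, cur in zip(cs, cs[1:]):
        if cur.start > prev.end + 1:
            parts.append("NML")
        parts.append(cur.type)
    return "-".join(parts)


def parse_pattern(pattern: str) -> list[str]:
    """Inverse of :func:`pattern_string` (state list round trip)."""
    return pattern.split("-")


def detect_dup_trp_inv_dup(
    calls: Sequence[CNVCall],
    junctions: Sequence,
    chrom: Optional[str] = None,
    slop_bp: int = 0,
) -> tuple[bool, Optional[dict]]:
    """Detect the DUP-TRP/INV-DUP signature on one chromosome.

    True iff a triplicated interval is strictly embedded in a duplication
    (DUP cover abutting it on both sides) *and* at least one junction with
    a breakend at a TRP boundary inverts orientation relative to the
    reference (both breakends retain same-handed flanks).  A triplication
    inside a duplication whose junctions are all direct does not qualify.
    """
    if chrom is not None:
        calls = [c for c in calls if c.chrom == chrom]
    chroms = {c.chrom for c in calls}
    if len(chroms) > 1:
        raise ValueError("calls span multiple chromosomes; pass chrom=")
    trps = [c for c in calls if c.type == TRP]
    dups = [c for c in calls if c.type == DUP]
    for t in trps:
        left = any(
            d.end + 1 + slop_bp >= t.start and d.start < t.start for d in dups
        )
        right = any(
            d.start - 1 - slop_bp <= t.end and d.end > t.end for d in dups
        )
        if not (left and right):
            continue
        boundary = {t.start - 1, t.start, t.end, t.end + 1}
        for j in junctions:
            if not j.inverting:
                continue
            for e in j.breakends():
                if e.chrom == t.chrom and any(
                    abs(e.pos - b) <= slop_bp for b in boundary
                ):
                    return True, {
                        "trp": t,
                        "junction": j.id,
                        "breakend": (e.chrom, e.pos, e.side),
                    }
    return False, None
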