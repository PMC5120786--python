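"""File-format export/import.

Machine-readable outputs are plain text only: VCF 4.2 with paired breakend
(BND) records for junctions, TSV probe/call/segment tables, BED for
interval exports, FASTA for sequences.  Internal coordinates are 1-based
fully closed; BED export converts to 0-based half-open (both conventions
are labelled in TSV headers).  Every writer embeds the tool version so
outputs are self-describing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .core import (
    RETAINS_LEFT,
    RETAINS_RIGHT,
    SUPPORT_SEQUENCED,
    BreakEnd,
    GenomeRef,
    Junction,
    JunctionFeature,
)

__all__ = [
    "write_junctions_vcf",
    "read_junctions_vcf",
    "write_calls_tsv",
    "write_calls_bed",
    "write_probe_tsv",
    "read_probe_tsv",
    "write_reads_fasta",
    "junction_feature_table",
]


def _bnd_alt(ref_base: str, mate: BreakEnd) -> str:
    """VCF breakend ALT for a record whose own side is retains_left
    (sequence continues after this base) — '[', ']' per the mate's side."""
    m = f"{mate.chrom}:{mate.pos}"
    if mate.side == RETAINS_RIGHT:
        return f"{ref_base}[{m}["
    return f"{ref_base}]{m}]"


def _bnd_alt_right(ref_base: str, mate: BreakEnd) -> str:
    """ALT for a record whose own side is retains_right (sequence continues
    before this base)."""
    m = f"{mate.chrom}:{mate.pos}"
    if mate.side == RETAINS_LEFT:
        return f"]{m}]{ref_base}"
    return f"[{m}[{ref_base}"


def write_junctions_vcf(
    junctions: Sequence[Junction],
    genome: GenomeRef,
    path,
    extra_header: Sequence[str] = (),
) -> None:
    """Paired BND records, one per breakend, MATEID-linked.

    INFO keys: SVTYPE=BND, MATEID, MHLEN, INSLEN, INSSEQ (when the insert
    sequence is known), TPARTS (comma-joined chrom:start-end:strand locus
    strings for templated insertions), SUPPORT, FEATURE.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=cgr-{__version__}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=MHLEN,Number=1,Type=Integer,Description="Microhomology length">',
        '##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Junctional insert length">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Junctional insert sequence">',
        '##INFO=<ID=TPARTS,Number=.,Type=String,Description="Templated insert source loci">',
        '##INFO=<ID=SUPPORT,Number=1,Type=String,Description="sequenced or hypothetical">',
        '##INFO=<ID=FEATURE,Number=1,Type=String,Description="Junction feature kind">',
        *extra_header,
    ]
    for chrom in genome.names:
        lines.append(f"##contig=<ID={chrom},length={genome.lengths[chrom]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def ref_base(e: BreakEnd) -> str:
        try:
            return genome.fetch(e.chrom, e.pos, e.pos)
        except ValueError:
            return "N"

    for j in junctions:
        f = j.feature
        info_common = [f"SVTYPE=BND", f"SUPPORT={j.support}"]
        if f is not None:
            info_common.append(f"FEATURE={f.kind}")
            if f.mh_len:
                info_common.append(f"MHLEN={f.mh_len}")
            if f.insert_len:
                info_common.append(f"INSLEN={f.insert_len}")
            if f.insert_seq:
                info_common.append(f"INSSEQ={f.insert_seq}")
            if f.template_parts:
                parts = ",".join(
                    f"{c}:{s}-{e}:{st}" for c, s, e, st in f.template_parts
                )
                info_common.append(f"TPARTS={parts}")
        for e, mate, suffix in ((j.a, j.b, "a"), (j.b, j.a, "b")):
            rid = f"{j.id}_{suffix}"
            mid = f"{j.id}_{'b' if suffix == 'a' else 'a'}"
            rb = ref_base(e)
            alt = (
                _bnd_alt(rb, mate)
                if e.side == RETAINS_LEFT
                else _bnd_alt_right(rb, mate)
            )
            info = ";".join([*info_common, f"MATEID={mid}"])
            lines.append(
                f"{e.chrom}\t{e.pos}\t{rid}\t{rb}\t{alt}\t.\tPASS\t{info}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_alt(alt: str) -> tuple[str, int, str, str]:
    """(mate_chrom, mate_pos, mate_side, own_side) from a BND ALT string."""
    if alt.endswith("[") or alt.endswith("]"):
        own = RETAINS_LEFT
        bracket = "[" if "[" in alt else "]"
        inner = alt.split(bracket)[1]
        mate_side = RETAINS_RIGHT if bracket == "[" else RETAINS_LEFT
    elif alt.startswith("[") or alt.startswith("]"):
        own = RETAINS_RIGHT
        bracket = "[" if alt[0] == "[" else "]"
        inner = alt.split(bracket)[1]
        mate_side = RETAINS_RIGHT if bracket == "[" else RETAINS_LEFT
    else:
        raise ValueError(f"not a breakend ALT: {alt!r}")
    chrom, pos = inner.rsplit(":", 1)
    return chrom, int(pos), mate_side, own


def read_junctions_vcf(path) -> list[Junction]:
    """Rebuild junctions from a BND VCF written by :func:`write_junctions_vcf`."""
    import pysam

    records = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            kv = {}
            for k in ("SUPPORT", "FEATURE", "INSSEQ"):
                if k in rec.info:
                    kv[k] = str(rec.info[k])
            for k in ("MHLEN", "INSLEN"):
                if k in rec.info:
                    kv[k] = str(int(rec.info[k]))
            if "TPARTS" in rec.info:
                v = rec.info["TPARTS"]
                kv["TPARTS"] = ",".join(v) if isinstance(v, tuple) else str(v)
            records[rec.id] = (rec.chrom, rec.pos, rec.alts[0], kv)
    junctions = {}
    for rid, (chrom, pos, alt, kv) in records.items():
        jid = rid.rsplit("_", 1)[0]
        if jid in junctions:
            continue
        m_chrom, m_pos, m_side, own_side = _parse_alt(alt)
        a = BreakEnd(chrom, pos, own_side, "+" if own_side == RETAINS_LEFT else "-")
        b = BreakEnd(m_chrom, m_pos, m_side, "+" if m_side == RETAINS_RIGHT else "-")
        support = kv.get("SUPPORT", SUPPORT_SEQUENCED)
        feature = None
        if support == SUPPORT_SEQUENCED and "FEATURE" in kv:
            parts = []
            for p in kv.get("TPARTS", "").split(","):
                if not p:
                    continue
                c, span, st = p.rsplit(":", 2)
                s, e = span.split("-")
                parts.append((c, int(s), int(e), st))
            feature = JunctionFeature(
                kind=kv["FEATURE"],
                mh_len=int(kv.get("MHLEN", 0)),
                insert_seq=kv.get("INSSEQ", ""),
                insert_len=int(kv["INSLEN"]) if "INSLEN" in kv else None,
                template_parts=parts,
            )
        junctions[jid] = Junction(jid, a, b, support=support, feature=feature)
    return list(junctions.values())


_TSV_PREAMBLE = (
    "# cgr v{version}; coordinates 1-based fully closed "
    "(BED exports are 0-based half-open)\n"
)


def write_calls_tsv(calls: Sequence, path, extra: str = "") -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "start_1based": c.start,
                "end_1based": c.end,
                "start_0based": c.start - 1,
                "end_half_open": c.end,
                "type": getattr(c, "type", None) or f"CN{c.cn}",
                "cn": getattr(c, "cn", None),
                "size_bp": c.size_bp,
            }
        )
    with open(path, "w") as fh:
        fh.write(_TSV_PREAMBLE.format(version=__version__))
        if extra:
            fh.write(f"# {extra}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_calls_bed(calls: Sequence, path) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.start)):
            name = getattr(c, "type", None) or f"CN{c.cn}"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\n")


def write_probe_tsv(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_PREAMBLE.format(version=__version__))
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_probe_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_reads_fasta(reads, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(r.seq), id=r.id,
            description="clipped" if getattr(r, "clipped", False) else "",
        )
        for r in reads
    ]
    seqio_write(records, str(path), "fasta")


def junction_feature_table(junctions: Sequence[Junction]) -> pd.DataFrame:
    """One row per junction, mirroring a published junction-feature table."""
    rows = []
    for j in junctions:
        f = j.feature
        rows.append(
            {
                "junction": j.id,
                "breakend_a": str(j.a),
                "breakend_b": str(j.b),
                "support": j.support,
                "feature": f.describe() if f else "unresolved",
                "mh_len": f.mh_len if f else None,
                "insert_len": f.insert_len if f else None,
                "template_parts": ";".join(
                    f"{c}:{s}-{e}:{st}" for c, s, e, st in (f.template_parts if f else [])
                ),
            }
        )
    return pd.DataFrame(rows)
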