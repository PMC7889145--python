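"""SAM 1.6 serialization of alignment records.

Split reads are written as a primary line (longer segment aligned, the
rest soft-clipped) plus a supplementary line, cross-referenced with
``SA`` tags.  Discordant subtype is carried in an ``XD`` tag, total
mismatch count in ``NM`` on the primary line.  Parsing goes through
pysam, so externally produced SAM with the same conventions is accepted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .align import AlignmentRecord, Segment
from .sequtil import revcomp

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SUPPLEMENTARY = 0x800


def _cigar(seg: Segment, read_len: int) -> str:
    """CIGAR in SAM (reference) orientation for one aligned segment."""
    lead, tail = seg.query_start, read_len - seg.query_end
    if seg.strand == "-":
        lead, tail = tail, lead
    parts = []
    if lead:
        parts.append(f"{lead}S")
    parts.append(f"{seg.length}M")
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def _sa_entry(seg: Segment, read_len: int, mapq: int, nm: int) -> str:
    return f"{seg.chrom},{seg.ref_start},{seg.strand},{_cigar(seg, read_len)},{mapq},{nm};"


def _base_flag(rec: AlignmentRecord) -> int:
    flag = FLAG_PAIRED | (FLAG_READ1 if rec.is_read1 else FLAG_READ2)
    if rec.proper_pair:
        flag |= FLAG_PROPER
    if not rec.mapped:
        flag |= FLAG_UNMAPPED
    if rec.mate_chrom is None:
        flag |= FLAG_MATE_UNMAPPED
    if rec.mate_strand == "-":
        flag |= FLAG_MATE_REVERSE
    return flag


def _mapq(rec: AlignmentRecord) -> int:
    return 60 if rec.mapq_class == "unique" else 0


def write_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(reference_lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{reference_lengths[chrom]}\n")
        fh.write("@PG\tID:tg-locus\tPN:tg-locus\n")
        for rec in records:
            _write_record(fh, rec)


def _write_record(fh, rec: AlignmentRecord) -> None:
    mate_rname = rec.mate_chrom if rec.mate_chrom is not None else "*"
    mate_pos = rec.mate_pos if rec.mate_pos is not None else 0
    if not rec.mapped:
        fields = [
            rec.read_id,
            str(_base_flag(rec)),
            "*",
            "0",
            "0",
            "*",
            mate_rname,
            str(mate_pos),
            "0",
            rec.seq or "*",
            "*",
        ]
        fh.write("\t".join(fields) + "\n")
        return
    segs = sorted(rec.segments, key=lambda s: -s.length)
    primary, extras = segs[0], segs[1:]
    mapq = _mapq(rec)
    for i, seg in enumerate([primary] + extras):
        flag = _base_flag(rec)
        if seg.strand == "-":
            flag |= FLAG_REVERSE
        if i > 0:
            flag |= FLAG_SUPPLEMENTARY
        seq = rec.seq if seg.strand == "+" else revcomp(rec.seq)
        nm = rec.mismatches if i == 0 else 0
        tags = [f"NM:i:{nm}"]
        if rec.discordant_subtype:
            tags.append(f"XD:Z:{rec.discordant_subtype}")
        others = [s for s in [primary] + extras if s is not seg]
        if others:
            tags.append("SA:Z:" + "".join(_sa_entry(s, rec.read_len, mapq, 0) for s in others))
        fields = [
            rec.read_id,
            str(flag),
            seg.chrom,
            str(seg.ref_start),
            str(mapq),
            _cigar(seg, rec.read_len),
            mate_rname,
            str(mate_pos),
            "0",
            seq if seq else "*",
            "*",
        ]
        fh.write("\t".join(fields) + "\t" + "\t".join(tags) + "\n")


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse SAM back into alignment records (primary + supplementary
    lines are merged into multi-segment split records)."""
    grouped: dict[tuple[str, bool], list] = {}
    order: list[tuple[str, bool]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            key = (aln.query_name, not aln.is_read2)
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(aln)
    out = []
    for key in order:
        out.append(_merge_lines(key, grouped[key]))
    return out


def _segment_from_line(aln: pysam.AlignedSegment) -> tuple[Segment, int]:
    cigar = aln.cigartuples or []
    lead = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
    tail = cigar[-1][1] if len(cigar) > 1 and cigar[-1][0] == 4 else 0
    mlen = sum(n for op, n in cigar if op == 0)
    read_len = lead + mlen + tail
    strand = "-" if aln.is_reverse else "+"
    qs = lead if strand == "+" else tail
    seg = Segment(qs, qs + mlen, aln.reference_name, aln.reference_start + 1, strand)
    return seg, read_len


def _merge_lines(key: tuple[str, bool], lines: list) -> AlignmentRecord:
    read_id, is_read1 = key
    primary = next(l for l in lines if not l.is_supplementary)
    rec = AlignmentRecord(read_id=read_id, is_read1=is_read1, read_len=0)
    if primary.has_tag("XD"):
        rec.discordant = True
        rec.discordant_subtype = primary.get_tag("XD")
    rec.proper_pair = primary.is_proper_pair
    if primary.mate_is_unmapped or primary.next_reference_name is None:
        rec.mate_chrom = None
    else:
        rec.mate_chrom = primary.next_reference_name
        rec.mate_pos = primary.next_reference_start + 1
        rec.mate_strand = "-" if primary.mate_is_reverse else "+"
    if primary.is_unmapped:
        rec.read_len = primary.query_length or 0
        rec.seq = primary.query_sequence or ""
        return rec
    segs = []
    read_len = 0
    for line in lines:
        seg, rl = _segment_from_line(line)
        segs.append(seg)
        read_len = max(read_len, rl)
    segs.sort(key=lambda s: s.query_start)
    rec.segments = segs
    rec.read_len = read_len
    rec.mismatches = int(primary.get_tag("NM")) if primary.has_tag("NM") else 0
    rec.mapq_class = "unique" if primary.mapping_quality > 0 else "ambiguous"
    seq = primary.query_sequence or ""
    rec.seq = revcomp(seq) if primary.is_reverse else seq
    return rec
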