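"""Desk-scale read mapping: k-mer seeded, ungapped, split-aware.

Maps paired-end reads to the wild-type reference and annotates each pair
as proper / discordant, and each read as unique / ambiguous / unmapped or
split.  Alignment is ungapped (the simulator introduces no indels): a
read's placement is the diagonal with the fewest substitutions.  Reads
that fail full-length placement are re-tried as two-segment split
alignments, the evidence class that pins structural-variant junctions to
base resolution.

Equal-best placements are reported as ``ambiguous`` and carry no
structural-variant evidence downstream, which keeps repeats from
spawning false junctions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequtil import revcomp
from .simreads import ReadPair


@dataclass(frozen=True)
class InsertModel:
    """Fragment-length model defining 'discordant'.

    ``max_concordant`` defaults to mean + 3 sd: pairs whose outer span
    exceeds it are distance-discordant.
    """

    mean: float = 350.0
    sd: float = 50.0
    max_concordant: float | None = None

    def __post_init__(self) -> None:
        if self.max_concordant is None:
            object.__setattr__(self, "max_concordant", self.mean + 3 * self.sd)

    @property
    def cluster_window(self) -> float:
        return self.max_concordant


@dataclass(frozen=True)
class Segment:
    """An ungapped aligned block: read[query_start:query_end] placed at
    reference ``ref_start`` (1-based leftmost base) on ``strand``."""

    query_start: int
    query_end: int
    chrom: str
    ref_start: int
    strand: str

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1


@dataclass
class AlignmentRecord:
    """One read's mapping, with pair-level flags filled by classify_pair."""

    read_id: str
    is_read1: bool
    read_len: int
    seq: str = ""
    segments: list[Segment] = field(default_factory=list)
    mismatches: int = 0
    mapq_class: str = "unmapped"  # unique | ambiguous | unmapped
    mate_chrom: str | None = None
    mate_pos: int | None = None
    mate_strand: str | None = None
    proper_pair: bool = False
    discordant: bool = False
    discordant_subtype: str | None = None

    @property
    def split(self) -> bool:
        return len(self.segments) > 1

    @property
    def mapped(self) -> bool:
        return bool(self.segments)

    @property
    def primary_segment(self) -> Segment:
        return max(self.segments, key=lambda s: s.length)

    @property
    def chrom(self) -> str | None:
        return self.primary_segment.chrom if self.segments else None

    @property
    def pos(self) -> int | None:
        return self.primary_segment.ref_start if self.segments else None

    @property
    def strand(self) -> str | None:
        return self.primary_segment.strand if self.segments else None


class KmerIndex:
    """Exact-match k-mer lookup over the reference.

    Every k-mer is retained with all of its positions (ambiguous seeds
    included); k-mers containing non-ACGT characters are masked out.
    """

    def __init__(self, reference: Mapping[str, str], k: int = 21):
        self.k = k
        self.reference = {c: reference[c].upper() for c in sorted(reference)}
        self._ref_bytes = {
            c: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for c, s in self.reference.items()
        }
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.reference.items():
            bad = {i for i, ch in enumerate(seq) if ch not in "ACGT"}
            for i in range(len(seq) - k + 1):
                if bad and any((i + j) in bad for j in range(k)):
                    continue
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self._index = index

    def get(self, kmer: str) -> Sequence[tuple[str, int]]:
        """All (chrom, 0-based position) occurrences of ``kmer``."""
        return self._index.get(kmer, ())


def _count_mismatches(a: str, b: str, cap: int) -> int:
    """Mismatches between equal-length strings, stopping past ``cap``."""
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                return n
    return n


def _full_candidates(seq: str, rc: str, index: KmerIndex) -> list[tuple[str, int, str]]:
    L, k = len(seq), index.k
    offsets = sorted({0, (L - k) // 2, L - k})
    cands: set[tuple[str, int, str]] = set()
    for oriented, strand in ((seq, "+"), (rc, "-")):
        for o in offsets:
            for chrom, i in index.get(oriented[o : o + k]):
                s = i - o
                if 0 <= s <= len(index.reference[chrom]) - L:
                    cands.add((chrom, s, strand))
    return sorted(cands)


def map_read(
    seq: str,
    index: KmerIndex,
    max_mismatch_frac: float = 0.05,
    read_id: str = "",
    is_read1: bool = True,
) -> AlignmentRecord | None:
    """Best full-length ungapped placement, or None if none qualifies.

    Returns a ``unique`` record when a single placement has strictly
    fewer mismatches than every other; equal-best placements yield an
    ``ambiguous`` record.
    """
    L = len(seq)
    if L < index.k:
        return None
    rc = revcomp(seq)
    cap = int(max_mismatch_frac * L)
    best: tuple[str, int, str] | None = None
    best_mm = cap + 1
    tie = False
    for chrom, s, strand in _full_candidates(seq, rc, index):
        target = seq if strand == "+" else rc
        mm = _count_mismatches(index.reference[chrom][s : s + L], target, best_mm)
        if mm < best_mm:
            best, best_mm, tie = (chrom, s, strand), mm, False
        elif mm == best_mm and best is not None and (chrom, s, strand) != best:
            tie = True
    if best is None or best_mm > cap:
        return None
    chrom, s, strand = best
    return AlignmentRecord(
        read_id=read_id,
        is_read1=is_read1,
        read_len=L,
        seq=seq,
        segments=[Segment(0, L, chrom, s + 1, strand)],
        mismatches=best_mm,
        mapq_class="ambiguous" if tie else "unique",
    )


def _diagonal_candidates(
    seq: str, rc: str, index: KmerIndex, step: int, max_candidates: int
) -> list[tuple[str, int, str]]:
    L, k = len(seq), index.k
    offsets = list(range(0, L - k + 1, step))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    hits: Counter = Counter()
    for oriented, strand in ((seq, "+"), (rc, "-")):
        for o in offsets:
            for chrom, i in index.get(oriented[o : o + k]):
                hits[(chrom, i - o, strand)] += 1
    ranked = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return [key for key, _ in ranked[:max_candidates]]


def _match_array(
    seq: str, rc: str, cand: tuple[str, int, str], index: KmerIndex
) -> np.ndarray:
    """Boolean per-read-position match indicator for a diagonal placement."""
    chrom, s, strand = cand
    L = len(seq)
    ref = index._ref_bytes[chrom]
    window = np.zeros(L, dtype=np.uint8)
    lo, hi = max(s, 0), min(s + L, len(ref))
    if lo < hi:
        window[lo - s : hi - s] = ref[lo:hi]
    oriented = seq if strand == "+" else rc
    m = window == np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
    return m if strand == "+" else m[::-1]


def map_split(
    seq: str,
    index: KmerIndex,
    min_segment: int = 20,
    max_mismatch_frac: float = 0.05,
    read_id: str = "",
    is_read1: bool = True,
    seed_step: int = 10,
    max_candidates: int = 6,
) -> AlignmentRecord | None:
    """Two-segment split placement for a read that failed full mapping.

    Finds the breakpoint partition maximizing total matched bases over
    ordered pairs of candidate diagonals, with both parts at least
    ``min_segment`` long.  Ties between distinct junctions are treated as
    ambiguous (no call); ties in the breakpoint position alone resolve to
    the rightmost split, matching the right-shifted junction canonical
    form.
    """
    L = len(seq)
    if L < 2 * min_segment or L < index.k:
        return None
    rc = revcomp(seq)
    cands = _diagonal_candidates(seq, rc, index, seed_step, max_candidates)
    if len(cands) < 2:
        return None
    arrays = {c: _match_array(seq, rc, c, index) for c in cands}
    lo, hi = min_segment, L - min_segment  # split point range, inclusive
    best_score = -1
    best: tuple | None = None
    ambiguous = False
    for c1 in cands:
        pre1 = np.concatenate(([0], np.cumsum(arrays[c1])))
        for c2 in cands:
            if c1 == c2:
                continue
            cum2 = np.concatenate(([0], np.cumsum(arrays[c2])))
            total2 = cum2[-1]
            bs = np.arange(lo, hi + 1)
            scores = pre1[bs] + (total2 - cum2[bs])
            j = len(scores) - 1 - int(np.argmax(scores[::-1]))  # rightmost max
            sc = int(scores[j])
            b = int(bs[j])
            if sc > best_score:
                best_score, best, ambiguous = sc, (c1, c2, b), False
            elif sc == best_score and best is not None:
                p1, p2, pb = best
                if (c1, c2) != (p1, p2):
                    ambiguous = True
    if best is None:
        return None
    mm = L - best_score
    if mm > max(2, int(max_mismatch_frac * L)):
        return None
    if ambiguous:
        return None
    c1, c2, b = best
    pre1 = np.concatenate(([0], np.cumsum(arrays[c1])))
    cum2 = np.concatenate(([0], np.cumsum(arrays[c2])))
    # each part must anchor cleanly
    if pre1[b] < b - 2 or (cum2[-1] - cum2[b]) < (L - b) - 2:
        return None

    def _segment(cand: tuple[str, int, str], qs: int, qe: int) -> Segment:
        chrom, s, strand = cand
        if strand == "+":
            ref_start = s + qs + 1
        else:
            ref_start = s + (L - qe) + 1
        return Segment(qs, qe, chrom, ref_start, strand)

    seg1, seg2 = _segment(c1, 0, b), _segment(c2, b, L)
    for seg in (seg1, seg2):
        if seg.ref_start < 1 or seg.ref_end > len(index.reference[seg.chrom]):
            return None
    return AlignmentRecord(
        read_id=read_id,
        is_read1=is_read1,
        read_len=L,
        seq=seq,
        segments=[seg1, seg2],
        mismatches=mm,
        mapq_class="unique",
    )


def align_read(
    seq: str,
    index: KmerIndex,
    read_id: str = "",
    is_read1: bool = True,
    max_mismatch_frac: float = 0.05,
    min_segment: int = 20,
) -> AlignmentRecord:
    """Full-length placement, falling back to split mapping, else unmapped."""
    rec = map_read(seq, index, max_mismatch_frac, read_id, is_read1)
    if rec is None:
        rec = map_split(seq, index, min_segment, max_mismatch_frac, read_id, is_read1)
    if rec is None:
        rec = AlignmentRecord(read_id=read_id, is_read1=is_read1, read_len=len(seq), seq=seq)
    return rec


def classify_pair(a1: AlignmentRecord, a2: AlignmentRecord, im: InsertModel) -> None:
    """Fill mate fields and proper/discordant flags on both records.

    A pair is proper iff both mates map uniquely to the same chromosome
    in forward-reverse orientation with outer span <= ``max_concordant``;
    otherwise it is discordant with subtype ``inter_chrom``,
    ``orientation`` or ``distance``.  Pairs with an unmapped or ambiguous
    mate are neither.
    """
    if a1.read_id != a2.read_id:
        raise ValueError(f"mismatched read ids: {a1.read_id} vs {a2.read_id}")
    for rec, mate in ((a1, a2), (a2, a1)):
        rec.mate_chrom = mate.chrom
        rec.mate_pos = mate.pos
        rec.mate_strand = mate.strand
        rec.proper_pair = False
        rec.discordant = False
        rec.discordant_subtype = None
    if a1.mapq_class != "unique" or a2.mapq_class != "unique":
        return
    s1, s2 = a1.primary_segment, a2.primary_segment
    if s1.chrom != s2.chrom:
        subtype = "inter_chrom"
    else:
        left, right = (s1, s2) if s1.ref_start <= s2.ref_start else (s2, s1)
        if not (left.strand == "+" and right.strand == "-"):
            subtype = "orientation"
        else:
            span = right.ref_end - left.ref_start + 1
            subtype = None if span <= im.max_concordant else "distance"
    for rec in (a1, a2):
        if subtype is None:
            rec.proper_pair = True
        else:
            rec.discordant = True
            rec.discordant_subtype = subtype


def map_pairs(
    pairs: Iterable[ReadPair],
    index: KmerIndex,
    im: InsertModel,
    max_mismatch_frac: float = 0.05,
    min_segment: int = 20,
) -> list[AlignmentRecord]:
    """Align and classify every pair; returns a flat record list."""
    out: list[AlignmentRecord] = []
    for p in pairs:
        r1 = align_read(p.seq1, index, p.read_id, True, max_mismatch_frac, min_segment)
        r2 = align_read(p.seq2, index, p.read_id, False, max_mismatch_frac, min_segment)
        classify_pair(r1, r2, im)
        out.append(r1)
        out.append(r2)
    return out
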