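"""Inter-locus adjacency (novel junction) representation and notation.

An adjacency joins two genomic loci created by a structural rearrangement,
written ``s1[chrA:p1]:s2[chrB:p2]`` where ``s1``/``s2`` are strand signs.

Orientation convention
----------------------
The sign of a side says which reference sequence is retained at the
junction:

* ``+`` -- the junction joins sequence extending to the RIGHT of ``pos``
  on the forward strand (retained interval ``[pos, ...)``);
* ``-`` -- the junction joins sequence extending to the LEFT of ``pos``
  (retained interval ``(..., pos]``).

Published breakend notations leave the sign semantics implicit; this
module documents and applies the convention above consistently for both
simulated truth and discovered calls.

Junctions are canonicalized by right-shifting through any microhomology
shared by the two sides, so that reads split anywhere inside a homology
tract resolve to a single base-exact breakpoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .sequtil import complement


class Side(NamedTuple):
    """One side of an adjacency: ``(chrom, pos, orient)``, 1-based pos."""

    chrom: str
    pos: int
    orient: str  # "+" or "-"


class SegmentEnd(NamedTuple):
    """Directed description of one junction flank.

    ``strand`` is the direction in which the derived (rearranged) sequence
    traverses the reference at this flank; ``pos`` is the junction-adjacent
    reference base (1-based).
    """

    chrom: str
    pos: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class Adjacency:
    """A junction call with its supporting evidence counts."""

    side1: Side
    side2: Side
    support_split: int = 0
    support_pairs: int = 0
    precise: bool = True

    def __post_init__(self) -> None:
        if (self.side1.chrom, self.side1.pos, self.side1.orient) > (
            self.side2.chrom,
            self.side2.pos,
            self.side2.orient,
        ):
            raise ValueError("adjacency sides must be in canonical order")

    @property
    def signature(self) -> tuple[str, str]:
        return (self.side1.orient, self.side2.orient)

    @property
    def support_total(self) -> int:
        return self.support_split + self.support_pairs

    @property
    def key(self) -> tuple:
        return (*self.side1, *self.side2)

    def is_interchromosomal(self) -> bool:
        return self.side1.chrom != self.side2.chrom


def side_from_left(end: SegmentEnd) -> Side:
    """Side notation for the flank the derived sequence arrives through."""
    return Side(end.chrom, end.pos, "-" if end.strand == "+" else "+")


def side_from_right(end: SegmentEnd) -> Side:
    """Side notation for the flank the derived sequence departs into."""
    return Side(end.chrom, end.pos, "+" if end.strand == "+" else "-")


def left_from_side(side: Side) -> SegmentEnd:
    return SegmentEnd(side.chrom, side.pos, "+" if side.orient == "-" else "-")


def right_from_side(side: Side) -> SegmentEnd:
    return SegmentEnd(side.chrom, side.pos, "+" if side.orient == "+" else "-")


def _directed_base(ref: Mapping[str, str], chrom: str, pos: int, strand: str) -> str | None:
    seq = ref.get(chrom)
    if seq is None or pos < 1 or pos > len(seq):
        return None
    base = seq[pos - 1]
    return base if strand == "+" else complement(base)


def shift_right(
    ref: Mapping[str, str],
    left: SegmentEnd,
    right: SegmentEnd,
    max_shift: int = 500,
) -> tuple[SegmentEnd, SegmentEnd]:
    """Slide a junction rightward through microhomology.

    While the next base the left flank would extend to equals the first
    base of the right flank, the junction position is ambiguous; both
    representations describe the same derived sequence.  Shifting to the
    rightmost representation makes truth and calls comparable base-exactly.
    """
    for _ in range(max_shift):
        lnext = left.pos + 1 if left.strand == "+" else left.pos - 1
        bl = _directed_base(ref, left.chrom, lnext, left.strand)
        br = _directed_base(ref, right.chrom, right.pos, right.strand)
        if bl is None or br is None or bl != br:
            break
        left = SegmentEnd(left.chrom, lnext, left.strand)
        rnext = right.pos + 1 if right.strand == "+" else right.pos - 1
        right = SegmentEnd(right.chrom, rnext, right.strand)
    return left, right


def canonical_adjacency(
    ref: Mapping[str, str],
    left: SegmentEnd,
    right: SegmentEnd,
    support_split: int = 0,
    support_pairs: int = 0,
    precise: bool = True,
) -> Adjacency:
    """Build a canonical Adjacency from two junction flank descriptors.

    The junction is first re-oriented into a deterministic frame (sorted
    sides), then right-shifted through microhomology against ``ref``.
    The same function canonicalizes simulated truth and split-read calls,
    so the two agree regardless of junction-edge homology.
    """
    sides = sorted([side_from_left(left), side_from_right(right)])
    l2, r2 = left_from_side(sides[0]), right_from_side(sides[1])
    l3, r3 = shift_right(ref, l2, r2)
    s1, s2 = sorted([side_from_left(l3), side_from_right(r3)])
    return Adjacency(s1, s2, support_split, support_pairs, precise)


def format_adjacency(adj: Adjacency, pretty: bool = True) -> str:
    """Render an adjacency in breakend notation.

    ``pretty=True`` uses comma thousands-separators
    (``+[chr16:23,118,416]:-[chr9:87,704,340]``); machine mode omits them.
    """
    fmt = "{:,}" if pretty else "{:d}"
    parts = []
    for side in (adj.side1, adj.side2):
        parts.append(f"{side.orient}[{side.chrom}:{fmt.format(side.pos)}]")
    return ":".join(parts)


_ADJ_RE = re.compile(
    r"^([+-])\[([^\[\]:]+):([0-9,]+)\]:([+-])\[([^\[\]:]+):([0-9,]+)\]$"
)


def parse_adjacency(text: str) -> Adjacency:
    """Invert :func:`format_adjacency` (either pretty or machine mode)."""
    m = _ADJ_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed adjacency string: {text!r}")
    o1, c1, p1, o2, c2, p2 = m.groups()
    return Adjacency(
        Side(c1, int(p1.replace(",", "")), o1),
        Side(c2, int(p2.replace(",", "")), o2),
    )


def match_adjacency(call: Adjacency, truth: Adjacency, tol_bp: int = 1) -> bool:
    """True if ``call`` equals ``truth`` up to ``tol_bp`` per side position."""
    return (
        call.side1.chrom == truth.side1.chrom
        and call.side2.chrom == truth.side2.chrom
        and call.signature == truth.signature
        and abs(call.side1.pos - truth.side1.pos) <= tol_bp
        and abs(call.side2.pos - truth.side2.pos) <= tol_bp
    )
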