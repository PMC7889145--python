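"""Adjacency discovery from split-read and discordant-pair evidence.

A desk-scale reimplementation of the clustering core of paired-end
structural-variant callers: split reads give base-exact junction
observations, discordant pairs give interval observations; observations
sharing a chromosome pair and orientation signature are single-linkage
clustered, and clusters with enough total support become adjacency
calls.  A region screen then retains the calls that involve the donor
locus, mirroring the investigation of variants touching the transgene
donor region with evidence on another chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .adjacency import (
    Adjacency,
    SegmentEnd,
    Side,
    canonical_adjacency,
    format_adjacency,
)
from .align import AlignmentRecord, InsertModel


@dataclass(frozen=True)
class JunctionObservation:
    """One junction observation; split observations are base-exact."""

    side1: Side
    side2: Side
    kind: str  # "split" | "pair"

    @property
    def group_key(self) -> tuple:
        return (self.side1.chrom, self.side2.chrom, self.side1.orient, self.side2.orient)


@dataclass
class EvidenceCluster:
    """Observations connecting one chromosome pair with one orientation
    signature, within the fragment-size clustering window."""

    members: list[JunctionObservation] = field(default_factory=list)

    @property
    def splits(self) -> list[JunctionObservation]:
        return [m for m in self.members if m.kind == "split"]

    @property
    def pairs(self) -> list[JunctionObservation]:
        return [m for m in self.members if m.kind == "pair"]

    @property
    def support(self) -> int:
        return len(self.members)


def _split_observation(
    rec: AlignmentRecord, ref: Mapping[str, str]
) -> JunctionObservation:
    seg_l, seg_r = sorted(rec.segments, key=lambda s: s.query_start)
    if seg_l.strand == "+":
        left = SegmentEnd(seg_l.chrom, seg_l.ref_end, "+")
    else:
        left = SegmentEnd(seg_l.chrom, seg_l.ref_start, "-")
    if seg_r.strand == "+":
        right = SegmentEnd(seg_r.chrom, seg_r.ref_start, "+")
    else:
        right = SegmentEnd(seg_r.chrom, seg_r.ref_end, "-")
    adj = canonical_adjacency(ref, left, right)
    return JunctionObservation(adj.side1, adj.side2, "split")


def _pair_observation(a1: AlignmentRecord, a2: AlignmentRecord) -> JunctionObservation:
    sides = []
    for rec in (a1, a2):
        seg = rec.primary_segment
        if seg.strand == "+":
            sides.append(Side(seg.chrom, seg.ref_end, "-"))
        else:
            sides.append(Side(seg.chrom, seg.ref_start, "+"))
    s1, s2 = sorted(sides)
    return JunctionObservation(s1, s2, "pair")


def extract_evidence(
    alignments: Sequence[AlignmentRecord],
    im: InsertModel,
    ref: Mapping[str, str],
) -> list[JunctionObservation]:
    """Turn classified alignments into junction observations.

    Each uniquely mapped split read yields a base-exact observation
    (canonicalized against the reference); each discordant template
    without a split yields an interval observation anchored at the
    mates' inner edges.  Ambiguous records carry no evidence.
    """
    observations: list[JunctionObservation] = []
    templates: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        templates.setdefault(rec.read_id, []).append(rec)
    for read_id in sorted(templates):
        recs = templates[read_id]
        splits = [r for r in recs if r.split and r.mapq_class == "unique"]
        if splits:
            for rec in splits:
                observations.append(_split_observation(rec, ref))
            continue
        if len(recs) == 2:
            a1, a2 = recs
            if (
                a1.discordant
                and a2.discordant
                and a1.mapq_class == "unique"
                and a2.mapq_class == "unique"
            ):
                observations.append(_pair_observation(a1, a2))
    return observations


def cluster(
    observations: Iterable[JunctionObservation], window: float
) -> list[EvidenceCluster]:
    """Single-linkage clustering per (chromosome pair, signature) group.

    Two observations link when both side positions differ by at most
    ``window``.  Output is independent of input order: observations are
    sorted before union-find merging.
    """
    groups: dict[tuple, list[JunctionObservation]] = {}
    for obs in observations:
        groups.setdefault(obs.group_key, []).append(obs)
    clusters: list[EvidenceCluster] = []
    for key in sorted(groups):
        obs = sorted(groups[key], key=lambda o: (o.side1.pos, o.side2.pos, o.kind))
        parent = list(range(len(obs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                if obs[j].side1.pos - obs[i].side1.pos > window:
                    break
                if abs(obs[j].side2.pos - obs[i].side2.pos) <= window:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        by_root: dict[int, EvidenceCluster] = {}
        for i, o in enumerate(obs):
            by_root.setdefault(find(i), EvidenceCluster()).members.append(o)
        clusters.extend(by_root[r] for r in sorted(by_root))
    return clusters


def call_adjacencies(
    clusters: Sequence[EvidenceCluster], min_support: int = 4
) -> list[Adjacency]:
    """Clusters with total support >= ``min_support`` become calls.

    Positions come from the median of split observations when any exist
    (``precise``), else from the median of the pair inner-edge estimates
    (imprecise); ties resolve to the lower coordinate.
    """
    calls = []
    for cl in clusters:
        if cl.support < min_support:
            continue
        source = cl.splits if cl.splits else cl.pairs
        p1 = median_low([o.side1.pos for o in source])
        p2 = median_low([o.side2.pos for o in source])
        ex = cl.members[0]
        s1 = Side(ex.side1.chrom, p1, ex.side1.orient)
        s2 = Side(ex.side2.chrom, p2, ex.side2.orient)
        if (s1.chrom, s1.pos, s1.orient) > (s2.chrom, s2.pos, s2.orient):
            s1, s2 = s2, s1
        calls.append(
            Adjacency(
                s1,
                s2,
                support_split=len(cl.splits),
                support_pairs=len(cl.pairs),
                precise=bool(cl.splits),
            )
        )
    calls.sort(key=lambda a: a.key)
    return calls


def screen_region(
    calls: Sequence[Adjacency], roi: tuple[str, int, int]
) -> list[Adjacency]:
    """Retain calls involving the donor region of interest.

    A call survives when at least one side lies inside ``roi`` and either
    the other side is on a different chromosome (candidate insertion
    flank) or both sides are inside ``roi`` (internal architecture of the
    integrated construct, e.g. an inverted segment).  Everything else --
    in particular intra-chromosomal calls elsewhere in the genome -- is
    screened out.
    """
    chrom, start, end = roi
    if start > end or start < 1:
        raise ValueError(f"malformed region of interest: {chrom}:{start}-{end}")

    def inside(side: Side) -> bool:
        return side.chrom == chrom and start <= side.pos <= end

    kept = []
    for call in calls:
        in1, in2 = inside(call.side1), inside(call.side2)
        if (in1 and in2) or (in1 and call.side2.chrom != chrom) or (
            in2 and call.side1.chrom != chrom
        ):
            kept.append(call)
    return kept


def calls_to_frame(calls: Sequence[Adjacency]) -> pd.DataFrame:
    """Tabular form of a call set, with the breakend-notation column."""
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom1": c.side1.chrom,
                "pos1": c.side1.pos,
                "orient1": c.side1.orient,
                "chrom2": c.side2.chrom,
                "pos2": c.side2.pos,
                "orient2": c.side2.orient,
                "split": c.support_split,
                "pairs": c.support_pairs,
                "precise": c.precise,
                "notation": format_adjacency(c, pretty=True),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom1", "pos1", "orient1", "chrom2", "pos2", "orient2",
            "split", "pairs", "precise", "notation",
        ],
    )


def discover(
    alignments: Sequence[AlignmentRecord],
    im: InsertModel,
    ref: Mapping[str, str],
    min_support: int = 4,
    roi: tuple[str, int, int] | None = None,
) -> list[Adjacency]:
    """Evidence extraction, clustering, calling and optional screening."""
    obs = extract_evidence(alignments, im, ref)
    calls = call_adjacencies(cluster(obs, im.cluster_window), min_support)
    if roi is not None:
        calls = screen_region(calls, roi)
    return calls
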