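"""Synthetic diploid genome carrying a BAC-style transgene insertion.

Builds a scaled toy genome that emulates the architecture of a BAC
transgenic line: a donor chromosome carries a BAC fragment containing a
promoter-swapped driver gene (its first bases replaced by a Cre-like
marker absent from the reference) plus passenger genes, and the
transgenic haplotype carries one or more tandem copies of that construct
inserted into the final exon of an acceptor gene on another chromosome.
The insertion truth (junction adjacencies and per-gene copy numbers) is
recorded so downstream discovery and quantification can be validated
against it.

The default construct integrates with its distal tail segment inverted,
which yields three distinct junctions: the two insertion flanks plus one
donor-internal inversion junction with a ``+/+`` orientation signature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pyfaidx

from .adjacency import Adjacency, SegmentEnd, canonical_adjacency
from .sequtil import revcomp

ROLES = ("driver", "passenger", "acceptor", "neutral", "reference_assay")

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with a role in the transgene model.

    Coordinates are 1-based inclusive.  ``exons``, when given, are
    1-based inclusive sub-intervals in ascending, non-overlapping order
    (only the acceptor gene needs them: the insertion site must fall in
    its final exon).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    role: str = "neutral"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"{self.gene_id}: invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.role not in ROLES:
            raise ValueError(f"{self.gene_id}: unknown role {self.role!r}")
        last = None
        for (s, e) in self.exons:
            if s < self.start or e > self.end or s > e:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} outside gene")
            if last is not None and s <= last:
                raise ValueError(f"{self.gene_id}: exons must ascend without overlap")
            last = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def final_exon(self) -> tuple[int, int]:
        if not self.exons:
            return (self.start, self.end)
        return self.exons[-1]


@dataclass(frozen=True)
class TransgeneConstruct:
    """The BAC-derived insert.

    The donor fragment ``[donor_start, donor_end]`` must cover the driver
    and all passenger genes.  ``replaced_prefix_bp`` bases starting at the
    driver gene's start are replaced by ``insert_sequence`` (the Cre-like
    marker), and the last ``inverted_tail_bp`` bases of the fragment
    integrate in reverse-complement orientation.  ``tandem_copies`` whole
    constructs integrate head-to-tail.
    """

    donor_chrom: str
    donor_start: int
    donor_end: int
    driver_gene: str
    insert_sequence: str
    replaced_prefix_bp: int = 222
    tandem_copies: int = 1
    inverted_tail_bp: int = 0

    def __post_init__(self) -> None:
        if self.donor_start < 1 or self.donor_start > self.donor_end:
            raise ValueError("invalid donor interval")
        if self.replaced_prefix_bp <= 0:
            raise ValueError("replaced_prefix_bp must be positive")
        if not self.insert_sequence:
            raise ValueError("insert_sequence must be non-empty")
        if self.tandem_copies < 1:
            raise ValueError("tandem_copies must be >= 1")
        if not 0 <= self.inverted_tail_bp < self.donor_end - self.donor_start + 1:
            raise ValueError("inverted_tail_bp out of range")

    @property
    def donor_length(self) -> int:
        return self.donor_end - self.donor_start + 1


@dataclass
class GenomeModel:
    """Two haplotypes plus annotation and planted truth.

    ``haplotypes`` maps haplotype name ("A" wild-type, "B" transgenic) to
    ``{chrom: sequence}``.  The two haplotypes are identical except at the
    insertion locus on haplotype B.
    """

    haplotypes: dict[str, dict[str, str]]
    annotation: list[GeneAnnotation]
    truth_adjacencies: list[Adjacency] = field(default_factory=list)
    truth_copy_number: dict[str, int] = field(default_factory=dict)
    truth_junctions_hapB: list[tuple[str, int]] = field(default_factory=list)
    construct: TransgeneConstruct | None = None
    insertion_site: tuple[str, int] | None = None
    deleted_span: int = 0

    @property
    def reference(self) -> dict[str, str]:
        """The wild-type reference sequences (haplotype A)."""
        return self.haplotypes["A"]

    def genes_by_role(self, role: str) -> list[GeneAnnotation]:
        return [g for g in self.annotation if g.role == role]

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.annotation:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class GenomeConfig:
    """Shape parameters of the toy genome.

    Two chromosomes of equal length: the first carries the acceptor gene
    (insertion target) and the ddPCR reference-assay gene, the second the
    BAC donor fragment.  Gene positions are laid out at fixed fractions of
    the chromosome length so the model scales; neutral genes fill a grid
    away from the acceptor/donor regions.
    """

    chrom_length: int = 200_000
    acceptor_chrom: str = "chrA"
    donor_chrom: str = "chrD"
    n_genes: int = 42
    gene_length: int = 1_200
    acceptor_exons: int = 2
    bac_fraction: tuple[float, float] = (0.30, 0.40)
    inverted_tail_fraction: float = 0.30
    cre_length: int = 1_000

    def __post_init__(self) -> None:
        if self.chrom_length < 50_000:
            raise ValueError("chromosome length must be >= 50 kb")
        if self.n_genes < 8:
            raise ValueError("need at least 8 genes (driver, 3 passengers, acceptor, assay, neutrals)")

    @property
    def bac_interval(self) -> tuple[int, int]:
        lo = int(self.bac_fraction[0] * self.chrom_length) + 1
        hi = int(self.bac_fraction[1] * self.chrom_length)
        return lo, hi

    @property
    def default_site(self) -> tuple[str, int]:
        """Default insertion site: middle of the acceptor's final exon."""
        return (self.acceptor_chrom, int(0.5125 * self.chrom_length))


def _neutral_grid(
    length: int, gene_length: int, exclusions: Sequence[tuple[int, int]], n: int, prefix: str
) -> list[tuple[str, int, int]]:
    step = max(gene_length + max(400, int(0.015 * length)), int(0.02 * length))
    out: list[tuple[str, int, int]] = []
    pos = int(0.02 * length) + 1
    i = 0
    while len(out) < n and pos + gene_length - 1 <= length - 1000:
        s, e = pos, pos + gene_length - 1
        if all(e < lo or s > hi for lo, hi in exclusions):
            i += 1
            out.append((f"{prefix}{i:02d}", s, e))
        pos += step
    if len(out) < n:
        raise ValueError(
            f"cannot place {n} neutral genes of {gene_length} bp on a "
            f"{length} bp chromosome; reduce n_genes or gene_length"
        )
    return out


def default_annotation(cfg: GenomeConfig) -> list[GeneAnnotation]:
    """Gene layout for the toy genome: driver + 3 passengers inside the
    BAC, a 2-exon acceptor, a reference-assay gene, and neutral filler."""
    L = cfg.chrom_length
    genes: list[GeneAnnotation] = []

    # Acceptor gene with >= 2 exons; the insertion disrupts the final exon.
    acc_start, acc_end = int(0.49 * L) + 1, int(0.52 * L)
    if cfg.acceptor_exons < 2:
        raise ValueError("acceptor gene must have at least 2 exons")
    first_exons_end = int(0.495 * L)
    final_start = int(0.505 * L) + 1
    # split the 5' block evenly into (acceptor_exons - 1) exons
    n5 = cfg.acceptor_exons - 1
    block = (first_exons_end - acc_start + 1) // n5
    exons = []
    for i in range(n5):
        s = acc_start + i * block
        e = first_exons_end if i == n5 - 1 else s + block - 201
        exons.append((s, e))
    exons.append((final_start, acc_end))
    genes.append(
        GeneAnnotation("ACP1", cfg.acceptor_chrom, acc_start, acc_end, "-", "acceptor", tuple(exons))
    )

    ref_start = int(0.75 * L) + 1
    genes.append(
        GeneAnnotation("REF1", cfg.acceptor_chrom, ref_start, ref_start + cfg.gene_length - 1,
                       "+", "reference_assay")
    )

    bac_lo, bac_hi = cfg.bac_interval
    B = bac_hi - bac_lo + 1

    def bac_span(f0: float, f1: float) -> tuple[int, int]:
        return bac_lo + int(f0 * B), bac_lo + int(f1 * B) - 1

    d_s, d_e = bac_span(0.10, 0.19)
    genes.append(GeneAnnotation("DRV1", cfg.donor_chrom, d_s, d_e, "+", "driver"))
    for i, (f0, f1) in enumerate([(0.225, 0.285), (0.325, 0.385), (0.425, 0.485)], 1):
        s, e = bac_span(f0, f1)
        genes.append(GeneAnnotation(f"PSG{i}", cfg.donor_chrom, s, e, "+", "passenger"))

    n_neutral = cfg.n_genes - len(genes)
    n_a = n_neutral // 2
    n_d = n_neutral - n_a
    excl_a = [(int(0.47 * L), int(0.54 * L)), (ref_start - 2000, ref_start + cfg.gene_length + 2000)]
    excl_d = [(int(0.28 * L), int(0.42 * L))]
    for gid, s, e in _neutral_grid(L, cfg.gene_length, excl_a, n_a, "NEUA"):
        genes.append(GeneAnnotation(gid, cfg.acceptor_chrom, s, e, "+", "neutral"))
    for gid, s, e in _neutral_grid(L, cfg.gene_length, excl_d, n_d, "NEUD"):
        genes.append(GeneAnnotation(gid, cfg.donor_chrom, s, e, "+", "neutral"))
    return genes


def validate_annotation(genes: Sequence[GeneAnnotation], chrom_lengths: Mapping[str, int]) -> None:
    """Reject overlapping genes, duplicate ids, and out-of-genome intervals."""
    seen: set[str] = set()
    per_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id}")
        seen.add(g.gene_id)
        if g.chrom not in chrom_lengths:
            raise ValueError(f"{g.gene_id}: chromosome {g.chrom} not in genome")
        if g.end > chrom_lengths[g.chrom]:
            raise ValueError(f"{g.gene_id}: extends past end of {g.chrom}")
        per_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in per_chrom.items():
        glist.sort(key=lambda g: g.start)
        for a, b in zip(glist, glist[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping genes on {chrom}: {a.gene_id} and {b.gene_id}"
                )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASE_CODES[rng.integers(0, 4, size=length)]).decode("ascii")


def build_reference(
    cfg: GenomeConfig,
    seed: int,
    annotation: Sequence[GeneAnnotation] | None = None,
) -> GenomeModel:
    """Build the wild-type genome: random sequences plus gene annotation.

    Deterministic for a given (config, seed).  Both haplotypes are
    identical until :func:`apply_insertion` modifies haplotype B.
    """
    rng = np.random.default_rng(seed)
    seqs = {}
    for chrom in (cfg.acceptor_chrom, cfg.donor_chrom):
        seqs[chrom] = _random_sequence(rng, cfg.chrom_length)
    genes = list(annotation) if annotation is not None else default_annotation(cfg)
    validate_annotation(genes, {c: len(s) for c, s in seqs.items()})
    acceptors = [g for g in genes if g.role == "acceptor"]
    for acc in acceptors:
        if len(acc.exons) < 2:
            raise ValueError(
                f"acceptor gene {acc.gene_id} must have >= 2 exons so the "
                "insertion can disrupt its final exon"
            )
    return GenomeModel(
        haplotypes={"A": dict(seqs), "B": dict(seqs)},
        annotation=genes,
        truth_copy_number={g.gene_id: 2 for g in genes},
    )


def synthetic_cre_sequence(length: int, seed: int) -> str:
    """A random marker sequence standing in for the Cre coding sequence.

    Drawn from an RNG stream independent of the genome so it is (with
    overwhelming probability) absent from the reference, giving the
    transgene a mappable foreign marker.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EC]))
    return _random_sequence(rng, length)


def default_construct(cfg: GenomeConfig, seed: int, tandem_copies: int = 1,
                      inverted_tail: bool = True) -> TransgeneConstruct:
    """The default scaled BAC construct for a genome built from ``cfg``."""
    bac_lo, bac_hi = cfg.bac_interval
    tail = int(cfg.inverted_tail_fraction * (bac_hi - bac_lo + 1)) if inverted_tail else 0
    return TransgeneConstruct(
        donor_chrom=cfg.donor_chrom,
        donor_start=bac_lo,
        donor_end=bac_hi,
        driver_gene="DRV1",
        insert_sequence=synthetic_cre_sequence(cfg.cre_length, seed),
        replaced_prefix_bp=222,
        tandem_copies=tandem_copies,
        inverted_tail_bp=tail,
    )


def build_construct_sequence(model: GenomeModel, construct: TransgeneConstruct) -> str:
    """Sequence of one integrated construct copy (Cre swap + inverted tail)."""
    donor = model.reference[construct.donor_chrom]
    frag = donor[construct.donor_start - 1 : construct.donor_end]
    driver = model.gene(construct.driver_gene)
    off = driver.start - construct.donor_start  # 0-based offset of driver start in fragment
    if off < 0 or off + construct.replaced_prefix_bp > len(frag):
        raise ValueError("driver replacement region outside donor fragment")
    swapped = frag[:off] + construct.insert_sequence + frag[off + construct.replaced_prefix_bp :]
    if construct.inverted_tail_bp:
        tail = construct.inverted_tail_bp
        swapped = swapped[:-tail] + revcomp(frag[-tail:])
    return swapped


def apply_insertion(
    model: GenomeModel,
    construct: TransgeneConstruct,
    site: tuple[str, int] | None = None,
    deleted_span: int = 0,
) -> GenomeModel:
    """Integrate the construct on haplotype B and record the truth.

    ``site`` is ``(chrom, pos)``: the construct is inserted between
    ``pos`` and ``pos+1`` after deleting ``deleted_span`` bases to the
    right of ``pos``.  By default the site is the midpoint of the
    acceptor gene's final exon.

    Truth adjacencies are enumerated in the orientation convention of the
    discovery module and right-shifted through junction microhomology;
    truth copy number of each passenger gene fully contained in the donor
    fragment is ``2 + tandem_copies`` (the driver stays at 2 functional
    copies: its transgenic promoter copy is Cre-swapped).
    """
    ref = model.reference
    if construct.donor_chrom not in ref:
        raise ValueError(f"donor chromosome {construct.donor_chrom} not in genome")
    if construct.donor_end > len(ref[construct.donor_chrom]):
        raise ValueError("construct interval exceeds donor chromosome")
    if site is None:
        acceptors = model.genes_by_role("acceptor")
        if not acceptors:
            raise ValueError("no acceptor gene and no explicit site given")
        fe = acceptors[0].final_exon
        site = (acceptors[0].chrom, (fe[0] + fe[1]) // 2)
    chrom, pos = site
    if chrom not in ref:
        raise ValueError(f"insertion site chromosome {chrom} not in genome")
    if deleted_span < 0 or pos < 1 or pos + deleted_span >= len(ref[chrom]):
        raise ValueError("insertion site outside chromosome")
    for role in ("driver", "passenger"):
        for g in model.genes_by_role(role):
            if g.chrom == construct.donor_chrom and not (
                construct.donor_start <= g.start and g.end <= construct.donor_end
            ):
                raise ValueError(f"donor interval must cover {role} gene {g.gene_id}")
    driver = model.gene(construct.driver_gene)
    fwd_end = construct.donor_end - construct.inverted_tail_bp
    if driver.start + construct.replaced_prefix_bp - 1 > fwd_end:
        raise ValueError("driver replacement region overlaps the inverted tail")

    unit = build_construct_sequence(model, construct)
    insert_total = unit * construct.tandem_copies
    hap_a = ref[chrom]
    hap_b_seq = hap_a[:pos] + insert_total + hap_a[pos + deleted_span :]

    ds, de, dc = construct.donor_start, construct.donor_end, construct.donor_chrom
    tail = construct.inverted_tail_bp
    m = de - tail  # last forward-orientation reference base of the construct

    ends: list[tuple[SegmentEnd, SegmentEnd]] = []
    # left flank
    ends.append((SegmentEnd(chrom, pos, "+"), SegmentEnd(dc, ds, "+")))
    # internal inversion junction
    if tail:
        ends.append((SegmentEnd(dc, m, "+"), SegmentEnd(dc, de, "-")))
        copy_end = SegmentEnd(dc, m + 1, "-")
    else:
        copy_end = SegmentEnd(dc, de, "+")
    # junction between tandem copies
    if construct.tandem_copies >= 2:
        ends.append((copy_end, SegmentEnd(dc, ds, "+")))
    # right flank
    ends.append((copy_end, SegmentEnd(chrom, pos + deleted_span + 1, "+")))

    truth: list[Adjacency] = []
    seen: set[tuple] = set()
    for left, right in ends:
        adj = canonical_adjacency(ref, left, right)
        if adj.key not in seen:
            seen.add(adj.key)
            truth.append(adj)

    # haplotype-B coordinates of the junction boundaries (first copy)
    unit_len = len(unit)
    fwd_len = unit_len - tail
    hapb_junctions = [(chrom, pos)]
    if tail:
        hapb_junctions.append((chrom, pos + fwd_len))
    hapb_junctions.append((chrom, pos + unit_len * construct.tandem_copies))

    copies = dict(model.truth_copy_number)
    for g in model.genes_by_role("passenger"):
        copies[g.gene_id] = 2 + construct.tandem_copies
    copies[construct.driver_gene] = 2

    hap_b = dict(model.haplotypes["B"])
    hap_b[chrom] = hap_b_seq
    return GenomeModel(
        haplotypes={"A": dict(model.haplotypes["A"]), "B": hap_b},
        annotation=list(model.annotation),
        truth_adjacencies=truth,
        truth_copy_number=copies,
        truth_junctions_hapB=hapb_junctions,
        construct=construct,
        insertion_site=(chrom, pos),
        deleted_span=deleted_span,
    )


# ---------------------------------------------------------------------------
# file I/O

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_annotation_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """BED6+1 (role column); BED is 0-based half-open on disk."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.role}\n"
            )


def read_annotation_bed(path: str | Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            role = f[6] if len(f) > 6 else "neutral"
            genes.append(
                GeneAnnotation(f[3], f[0], int(f[1]) + 1, int(f[2]), f[5] if len(f) > 5 else "+", role)
            )
    return genes


def write_truth_json(model: GenomeModel, path: str | Path) -> None:
    from .adjacency import format_adjacency

    payload = {
        "adjacencies": [
            {
                "side1": list(a.side1),
                "side2": list(a.side2),
                "notation": format_adjacency(a, pretty=False),
            }
            for a in model.truth_adjacencies
        ],
        "copy_number": model.truth_copy_number,
        "insertion_site": list(model.insertion_site) if model.insertion_site else None,
        "deleted_span": model.deleted_span,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
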