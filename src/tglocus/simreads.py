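"""Paired-end short-read simulation from the diploid genome model.

Emulates the whole-genome sequencing design used for insertion-site
mapping: 100-bp forward-reverse read pairs at configurable mean depth,
with fragments drawn from either haplotype (hemizygous carrier = 50:50
haplotype sampling) and iid substitution errors.  Base qualities are
emitted as a constant Q30 since nothing downstream is quality-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome import GenomeModel
from .sequtil import revcomp

_MUT = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-design parameters.

    ``haplotype_mix`` is the fraction of fragments drawn from haplotype B
    (the transgenic haplotype); 0.5 models a hemizygous carrier, 0 a
    wild-type control.
    """

    read_length: int = 100
    mean_depth: float = 40.0
    insert_mean: int = 350
    insert_sd: int = 50
    error_rate: float = 0.002
    seed: int = 0
    haplotype_mix: float = 0.5

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed 2 x read_length")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if not 0 <= self.haplotype_mix <= 1:
            raise ValueError("haplotype_mix must be in [0, 1]")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


def simulate_reads(
    model: GenomeModel, sim: SimConfig
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw read pairs from the diploid genome.

    The number of pairs is ``mean_depth * haploid_length / (2 *
    read_length)``.  Each fragment picks a haplotype (B with probability
    ``haplotype_mix``), a chromosome proportional to its length in that
    haplotype, a Normal(insert_mean, insert_sd) length, and a uniform
    start.  Read 1 is the fragment 5' end, read 2 the reverse complement
    of its 3' end (FR orientation).  Deterministic for a given seed.

    Returns the pairs plus a truth placement table with columns
    ``read_id, haplotype, chrom, frag_start, frag_end`` (1-based
    inclusive, in that haplotype's coordinates).
    """
    rl = sim.read_length
    rng = np.random.default_rng(sim.seed)
    hap_names = sorted(model.haplotypes)
    shortest = min(len(s) for h in hap_names for s in model.haplotypes[h].values())
    if sim.insert_mean > shortest:
        raise ValueError("insert_mean longer than the shortest chromosome")

    haploid_len = sum(len(s) for s in model.haplotypes["A"].values())
    n_pairs = int(round(sim.mean_depth * haploid_len / (2 * rl)))

    chrom_tables = {}
    for h in hap_names:
        chroms = sorted(model.haplotypes[h])
        lengths = np.array([len(model.haplotypes[h][c]) for c in chroms], dtype=float)
        chrom_tables[h] = (chroms, np.cumsum(lengths / lengths.sum()))

    from_b = rng.random(n_pairs) < sim.haplotype_mix
    chrom_u = rng.random(n_pairs)
    frag_lens = np.rint(rng.normal(sim.insert_mean, sim.insert_sd, n_pairs)).astype(int)
    frag_lens = np.maximum(frag_lens, rl)
    start_u = rng.random(n_pairs)
    n_err = rng.binomial(rl, sim.error_rate, size=2 * n_pairs)

    pairs: list[ReadPair] = []
    rows = []
    for i in range(n_pairs):
        hap = "B" if from_b[i] else "A"
        chroms, cum = chrom_tables[hap]
        ci = int(np.searchsorted(cum, chrom_u[i], side="right"))
        ci = min(ci, len(chroms) - 1)
        chrom = chroms[ci]
        seq = model.haplotypes[hap][chrom]
        flen = min(frag_lens[i], len(seq))
        start = 1 + int(start_u[i] * (len(seq) - flen + 1))
        frag = seq[start - 1 : start - 1 + flen]
        r1 = frag[:rl]
        r2 = revcomp(frag[-rl:])
        if n_err[2 * i]:
            r1 = _mutate(r1, n_err[2 * i], rng)
        if n_err[2 * i + 1]:
            r2 = _mutate(r2, n_err[2 * i + 1], rng)
        rid = f"frag{i:07d}"
        pairs.append(ReadPair(rid, r1, r2))
        rows.append((rid, hap, chrom, start, start + flen - 1))

    truth = pd.DataFrame(rows, columns=["read_id", "haplotype", "chrom", "frag_start", "frag_end"])
    return pairs, truth


def _mutate(read: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(read), size=min(k, len(read)), replace=False)
    chars = list(read)
    for p in positions:
        alt = _MUT.get(chars[p], "ACG")
        chars[p] = alt[rng.integers(0, len(alt))]
    return "".join(chars)


def write_fastq_pair(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path, qual_char: str = "?"
) -> None:
    """Write paired FASTQ files (constant Q30 qualities)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            q1 = qual_char * len(p.seq1)
            q2 = qual_char * len(p.seq2)
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{q2}\n")


def read_fastq_pair(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        rid1 = rec1.id.rsplit("/", 1)[0]
        rid2 = rec2.id.rsplit("/", 1)[0]
        if rid1 != rid2:
            raise ValueError(f"unpaired FASTQ records: {rec1.id} vs {rec2.id}")
        out.append(ReadPair(rid1, str(rec1.seq), str(rec2.seq)))
    return out
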