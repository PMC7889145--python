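"""Per-gene copy-number estimation from read coverage and from ddPCR.

Two independent estimators of copies per diploid genome:

* coverage: genomic-DNA reads are counted per gene, length-normalized
  with the TPM transform (count per kb, rescaled to sum to 1e6), and
  compared to a trimmed-mean genome baseline that represents the
  ordinary two-copy state;
* droplet digital PCR: the positive-droplet fraction is inverted through
  the Poisson occupancy formula ``lambda = -ln(1 - P/N)`` to a target
  concentration, then normalized to a known two-copy reference assay.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .genome import GeneAnnotation


@dataclass
class CountTable:
    """Per-gene read counts with TPM normalization.

    ``genes`` is indexed by gene_id with columns ``assigned_reads``,
    ``length_bp`` and (after :func:`tpm_normalize`) ``tpm``.
    """

    genes: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def genome_average_tpm(self) -> float:
        return float(self.genes["tpm"].mean())

    def tpm(self, gene_id: str) -> float:
        return float(self.genes.loc[gene_id, "tpm"])


@dataclass(frozen=True)
class CopyCall:
    gene_id: str
    estimated_copies: float
    baseline_copies: int = 2
    method: str = "coverage"

    def __post_init__(self) -> None:
        if self.estimated_copies < 0:
            raise ValueError("estimated_copies must be >= 0")


@dataclass(frozen=True)
class DdpcrWell:
    """Raw droplet counts for one well: P positives of N total."""

    target: str
    positive_droplets: int
    total_droplets: int
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValueError("positive droplets must satisfy 0 <= P <= N")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")


def count_reads_per_gene(
    alignments: Iterable[AlignmentRecord],
    annotation: Sequence[GeneAnnotation],
    reference_chroms: Sequence[str] | None = None,
) -> CountTable:
    """Assign uniquely mapped reads to genes by interval overlap.

    A read counts for a gene iff its placement overlaps the gene by at
    least 1 bp; a read overlapping two or more genes is assigned to
    neither.  Mates count separately (read-level coverage semantics).
    """
    if reference_chroms is not None:
        known = set(reference_chroms)
        for g in annotation:
            if g.chrom not in known:
                raise ValueError(f"annotation chromosome {g.chrom} absent from alignments")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts: dict[str, list[int]] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: g.start)
        starts[chrom] = [g.start for g in by_chrom[chrom]]
    counts = {g.gene_id: 0 for g in annotation}
    for rec in alignments:
        if rec.mapq_class != "unique":
            continue
        hits: set[str] = set()
        for seg in rec.segments:
            glist = by_chrom.get(seg.chrom)
            if not glist:
                continue
            i = bisect.bisect_right(starts[seg.chrom], seg.ref_end)
            j = max(0, i - 2)
            for g in glist[j:i]:
                if g.end >= seg.ref_start:
                    hits.add(g.gene_id)
        if len(hits) == 1:
            counts[hits.pop()] += 1
    df = pd.DataFrame(
        {
            "assigned_reads": [counts[g.gene_id] for g in annotation],
            "length_bp": [g.length for g in annotation],
        },
        index=pd.Index([g.gene_id for g in annotation], name="gene_id"),
    )
    df["tpm"] = np.nan
    return CountTable(df)


def tpm_normalize(table: CountTable) -> CountTable:
    """Fill the TPM column: rate_g = count_g/(length_g/1000), scaled so
    the TPM vector sums to one million.  Invariant to uniform count
    scaling; undefined (error) when every count is zero."""
    df = table.genes.copy()
    if (df["length_bp"] <= 0).any():
        raise ValueError("all gene lengths must be positive")
    rates = df["assigned_reads"] / (df["length_bp"] / 1000.0)
    total = rates.sum()
    if total == 0:
        raise ValueError("cannot TPM-normalize an all-zero count table")
    df["tpm"] = rates / total * 1e6
    return CountTable(df)


def estimate_copies_from_coverage(
    table: CountTable,
    gene_id: str,
    baseline_copies: int = 2,
    trim: float = 0.1,
) -> CopyCall:
    """Copies per diploid genome from length-normalized coverage.

    The genome baseline is the two-sided trimmed mean of per-gene TPM
    (default 10% per side), so a handful of transgene-amplified genes do
    not inflate the two-copy reference level the way they would in a
    plain average over a small gene set.
    """
    if table.n_genes < 10:
        raise ValueError("need >= 10 genes for a stable genome baseline")
    if table.genes["tpm"].isna().any():
        raise ValueError("run tpm_normalize first")
    if gene_id not in table.genes.index:
        raise KeyError(gene_id)
    baseline = float(stats.trim_mean(table.genes["tpm"].to_numpy(), trim))
    est = baseline_copies * table.tpm(gene_id) / baseline
    return CopyCall(gene_id, float(est), baseline_copies, method="coverage")


def copy_calls_for_all(table: CountTable, baseline_copies: int = 2) -> pd.DataFrame:
    rows = [
        estimate_copies_from_coverage(table, gid, baseline_copies)
        for gid in table.genes.index
    ]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in rows],
            "estimated_copies": [c.estimated_copies for c in rows],
            "baseline_copies": [c.baseline_copies for c in rows],
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# droplet digital PCR

def ddpcr_concentration(well: DdpcrWell) -> float:
    """Target concentration in copies per microlitre.

    Poisson occupancy: with mean ``lambda`` copies per droplet, the
    negative fraction is ``exp(-lambda)``, so ``lambda = -ln(1 - P/N)``
    and concentration = lambda / droplet volume.  Saturated wells
    (P = N) are rejected: the formula diverges.
    """
    if well.positive_droplets == well.total_droplets:
        raise ValueError("saturated well (P = N): concentration is unbounded")
    lam = -math.log1p(-well.positive_droplets / well.total_droplets)
    return lam / (well.droplet_volume_nl * 1e-3)


def pool_wells(wells: Sequence[DdpcrWell]) -> DdpcrWell:
    """Merge replicate wells by pooling droplet counts before the Poisson
    inversion (the minimum-variance merge for replicates)."""
    if not wells:
        raise ValueError("no wells to pool")
    target = wells[0].target
    vol = wells[0].droplet_volume_nl
    for w in wells:
        if w.target != target:
            raise ValueError("cannot pool wells for different targets")
        if w.droplet_volume_nl != vol:
            raise ValueError("cannot pool wells with different droplet volumes")
    return DdpcrWell(
        target,
        sum(w.positive_droplets for w in wells),
        sum(w.total_droplets for w in wells),
        vol,
    )


def copies_per_genome(
    target: DdpcrWell | Sequence[DdpcrWell],
    reference: DdpcrWell | Sequence[DdpcrWell],
    reference_copies: int = 2,
) -> CopyCall:
    """Absolute copy number normalized to a known two-copy reference assay."""
    tw = pool_wells(target) if not isinstance(target, DdpcrWell) else target
    rw = pool_wells(reference) if not isinstance(reference, DdpcrWell) else reference
    if tw.droplet_volume_nl != rw.droplet_volume_nl:
        raise ValueError("target and reference wells must share droplet volume")
    conc_r = ddpcr_concentration(rw)
    if conc_r == 0:
        raise ValueError("reference concentration is zero")
    conc_t = ddpcr_concentration(tw)
    return CopyCall(
        tw.target, reference_copies * conc_t / conc_r, reference_copies, method="ddpcr"
    )


def simulate_ddpcr_wells(
    target: str,
    lam: float,
    n_droplets: int,
    n_wells: int,
    rng: np.random.Generator,
    droplet_volume_nl: float = 0.85,
) -> list[DdpcrWell]:
    """Synthetic replicate wells with true mean occupancy ``lam``."""
    p_pos = 1.0 - math.exp(-lam)
    return [
        DdpcrWell(target, int(rng.binomial(n_droplets, p_pos)), n_droplets, droplet_volume_nl)
        for _ in range(n_wells)
    ]


def read_ddpcr_tsv(path: str | Path) -> dict[str, list[DdpcrWell]]:
    """Read wells from TSV with columns target, P, N, droplet_volume_nl."""
    df = pd.read_csv(path, sep="\t")
    wells: dict[str, list[DdpcrWell]] = {}
    for _, row in df.iterrows():
        w = DdpcrWell(
            str(row["target"]),
            int(row["P"]),
            int(row["N"]),
            float(row.get("droplet_volume_nl", 0.85)),
        )
        wells.setdefault(w.target, []).append(w)
    return wells
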