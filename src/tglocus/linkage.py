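"""Two-point linkage analysis for a transgene x floxed-locus backcross.

The informative cross segregates a dominant transgene (Cre+/Cre-) against
a floxed locus (F/F vs F/W).  With the two loci linked in repulsion-free
phase, the parental classes are Cre+;F/W and Cre-;F/F and the recombinant
classes are Cre+;F/F and Cre-;F/W; the recombination frequency theta is
the recombinant fraction, the genetic distance is 100*theta centimorgans
(two-point, no mapping function), and the LOD score compares linkage at
theta against free recombination (theta = 1/2).

Two LOD variants are provided.  ``lod_paper`` follows a published
footnote form Z = log10[(1-theta)^n / (1/2)^n], which omits the
theta^R recombinant term; ``lod_standard`` is the textbook two-point
statistic Z = log10[theta^R (1-theta)^NR / (1/2)^(R+NR)].  The two
differ whenever R > 0; both are reported so the discrepancy is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPE_CLASSES = ("Cre+;F/F", "Cre+;F/W", "Cre-;F/F", "Cre-;F/W")
DEFAULT_RECOMBINANT_CLASSES = frozenset({"Cre+;F/F", "Cre-;F/W"})
LOD_DEFINITIVE = 3.0


@dataclass
class GenotypeTable:
    """Offspring counts per two-locus genotype class."""

    counts: dict[str, int]
    recombinant_classes: frozenset[str] = DEFAULT_RECOMBINANT_CLASSES
    n_total: int | None = None

    def __post_init__(self) -> None:
        for label in self.counts:
            if label not in GENOTYPE_CLASSES:
                raise ValueError(f"unknown genotype class {label!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if not self.recombinant_classes <= set(GENOTYPE_CLASSES):
            raise ValueError("recombinant classes must be genotype classes")
        if self.n_total is None:
            self.n_total = sum(self.counts.values())
        if self.n_total < self.recombinants:
            raise ValueError("n_total smaller than recombinant count")

    @property
    def recombinants(self) -> int:
        return sum(self.counts.get(c, 0) for c in self.recombinant_classes)

    def percentage(self, label: str) -> float:
        """Observed class percentage, rounded to one decimal."""
        if self.n_total == 0:
            raise ValueError("empty table")
        return round(self.counts.get(label, 0) / self.n_total * 100, 1)


def tally_genotypes(offspring: Iterable[tuple[bool, str]]) -> GenotypeTable:
    """Count offspring records of (cre_positive, floxed genotype)."""
    counts = {c: 0 for c in GENOTYPE_CLASSES}
    for cre, flox in offspring:
        if flox not in ("F/F", "F/W"):
            raise ValueError(f"unknown floxed genotype {flox!r}")
        label = f"Cre{'+' if cre else '-'};{flox}"
        counts[label] += 1
    return GenotypeTable(counts)


def estimate_theta(table: GenotypeTable) -> float:
    """Recombination frequency: recombinant offspring / total."""
    if table.n_total == 0:
        raise ValueError("cannot estimate theta from an empty table")
    return table.recombinants / table.n_total


def genetic_distance(theta: float) -> float:
    """Genetic distance in centimorgans: 100 * theta (two-point)."""
    if not 0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    return 100.0 * theta


def lod_paper(theta: float, n: int) -> float:
    """LOD with the recombinant term dropped: Z = n*log10((1-theta)/0.5).

    This literal footnote form treats every one of the n offspring as a
    non-recombinant in the numerator; it exceeds the standard statistic
    whenever recombinants were observed.
    """
    if not 0 <= theta < 1:
        raise ValueError("theta must be in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * math.log10((1 - theta) / 0.5)


def lod_standard(recombinants: int, non_recombinants: int, theta: float) -> float:
    """Textbook two-point LOD: Z = log10[theta^R (1-theta)^NR / 0.5^n].

    Maximized over theta at theta = R/(R+NR).
    """
    if recombinants < 0 or non_recombinants < 0:
        raise ValueError("counts must be non-negative")
    n = recombinants + non_recombinants
    if n == 0:
        return 0.0
    if recombinants > 0 and theta == 0:
        raise ValueError("theta = 0 with observed recombinants gives LOD = -inf")
    if theta >= 1:
        raise ValueError("theta must be < 1")
    z = non_recombinants * math.log10(1 - theta) + n * math.log10(2.0)
    if recombinants > 0:
        z += recombinants * math.log10(theta)
    return z


def classify_linkage(lod: float) -> str:
    """LOD >= 3 is the classical definitive-linkage threshold."""
    if not math.isfinite(lod):
        raise ValueError("LOD must be finite")
    return "definitive" if lod >= LOD_DEFINITIVE else "not_definitive"


def mendelian_expectation(table: GenotypeTable) -> tuple[dict[str, float], float, int]:
    """Expected 25% per class and the Pearson chi-square statistic (3 df).

    Descriptive only -- the linkage inference is the LOD score.  Uses the
    class-count total (the four classes partition the offspring).
    """
    n = sum(table.counts.get(c, 0) for c in GENOTYPE_CLASSES)
    if n == 0:
        raise ValueError("empty table")
    expected = {c: 25.0 for c in GENOTYPE_CLASSES}
    e = n / 4.0
    chi2 = sum((table.counts.get(c, 0) - e) ** 2 / e for c in GENOTYPE_CLASSES)
    return expected, chi2, 3


@dataclass(frozen=True)
class LinkageResult:
    """Two-point linkage summary; rounded fields mirror tabular display
    conventions (theta 3 decimals, cM and LOD 1 decimal), raw values are
    retained for machine use."""

    theta_raw: float
    cm_raw: float
    lod_raw: float
    n: int
    formula: str
    classification: str

    @property
    def theta(self) -> float:
        return round(self.theta_raw, 3)

    @property
    def cm(self) -> float:
        return round(self.cm_raw, 1)

    @property
    def lod(self) -> float:
        return round(self.lod_raw, 1)

    def as_dict(self) -> dict:
        return {
            "theta": self.theta,
            "cm": self.cm,
            "lod": self.lod,
            "n": self.n,
            "formula": self.formula,
            "classification": self.classification,
            "theta_raw": self.theta_raw,
            "cm_raw": self.cm_raw,
            "lod_raw": self.lod_raw,
        }


def analyze(table: GenotypeTable, formula: str = "paper") -> LinkageResult:
    """Full two-point analysis of a genotype table.

    ``formula`` selects the reported LOD: "paper" (footnote form, default
    for fidelity to the published table) or "standard".
    """
    theta = estimate_theta(table)
    cm = genetic_distance(min(theta, 0.5))
    if formula == "paper":
        lod = lod_paper(theta, table.n_total)
    elif formula == "standard":
        r = table.recombinants
        nr = table.n_total - r
        t = theta if theta > 0 else 0.0
        lod = lod_standard(r, nr, t) if r > 0 else lod_standard(0, nr, 0.0)
    else:
        raise ValueError("formula must be 'paper' or 'standard'")
    return LinkageResult(theta, cm, lod, table.n_total, formula, classify_linkage(lod))


def simulate_backcross(
    theta: float, n: int, rng: np.random.Generator
) -> GenotypeTable:
    """Offspring of an informative backcross with true recombination
    fraction ``theta``: each gamete recombines independently with
    probability theta; non-recombinants split evenly between the two
    parental classes, recombinants between the two recombinant classes."""
    if not 0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    rec = rng.random(n) < theta
    coin = rng.random(n) < 0.5
    counts = {c: 0 for c in GENOTYPE_CLASSES}
    for r, c in zip(rec, coin):
        if r:
            counts["Cre+;F/F" if c else "Cre-;F/W"] += 1
        else:
            counts["Cre+;F/W" if c else "Cre-;F/F"] += 1
    return GenotypeTable(counts)


def read_counts_tsv(
    path: str | Path,
    n_total: int | None = None,
    recombinant_classes: frozenset[str] = DEFAULT_RECOMBINANT_CLASSES,
) -> GenotypeTable:
    """Read a genotype-class count table (columns: genotype_class, count)."""
    df = pd.read_csv(path, sep="\t")
    counts = {str(r["genotype_class"]): int(r["count"]) for _, r in df.iterrows()}
    return GenotypeTable(counts, recombinant_classes, n_total)
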