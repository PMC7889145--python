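"""Copy number: interval counting, TPM, coverage and ddPCR estimators."""

import math

import numpy as np
import pandas as pd
import pytest

from tglocus import copynum as cn
from tglocus.align import AlignmentRecord, Segment
from tglocus.copynum import (
    CountTable,
    DdpcrWell,
    copies_per_genome,
    count_reads_per_gene,
    ddpcr_concentration,
    estimate_copies_from_coverage,
    pool_wells,
    simulate_ddpcr_wells,
    tpm_normalize,
)
from tglocus.genome import GeneAnnotation


def _read(rid, chrom, pos, length=100):
    return AlignmentRecord(rid, True, length,
                           segments=[Segment(0, length, chrom, pos, "+")],
                           mapq_class="unique")


GENES3 = [
    GeneAnnotation("G1", "chr1", 1_000, 2_000),
    GeneAnnotation("G2", "chr1", 3_000, 4_500),
    GeneAnnotation("G3", "chr2", 500, 1_700),
]


def brute_force_counts(reads, genes):
    """Oracle: per-read scan over every gene interval."""
    counts = {g.gene_id: 0 for g in genes}
    for r in reads:
        seg = r.segments[0]
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == seg.chrom and seg.ref_start <= g.end and seg.ref_end >= g.start
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
    return counts


def test_counts_match_brute_force_overlap_scan():
    rng = np.random.default_rng(1)
    reads = []
    for i in range(50):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        pos = int(rng.integers(1, 4_600))
        reads.append(_read(f"r{i}", chrom, pos))
    table = count_reads_per_gene(reads, GENES3)
    oracle = brute_force_counts(reads, GENES3)
    assert dict(table.genes["assigned_reads"]) == oracle
    assert sum(oracle.values()) > 0


def test_read_inside_gene_counts_once():
    table = count_reads_per_gene([_read("r", "chr1", 1_200)], GENES3)
    assert table.genes.loc["G1", "assigned_reads"] == 1


def test_single_base_overlap_counts():
    table = count_reads_per_gene([_read("r", "chr1", 901)], GENES3)  # ends at 1000
    assert table.genes.loc["G1", "assigned_reads"] == 1
    table = count_reads_per_gene([_read("r", "chr1", 900)], GENES3)  # ends at 999
    assert table.genes.loc["G1", "assigned_reads"] == 0


def test_read_overlapping_two_genes_is_unassigned():
    genes = [GeneAnnotation("A", "chr1", 100, 200), GeneAnnotation("B", "chr1", 230, 400)]
    table = count_reads_per_gene([_read("r", "chr1", 150)], genes)  # spans 150-249
    assert table.genes["assigned_reads"].sum() == 0


def test_ambiguous_reads_are_excluded():
    rec = _read("r", "chr1", 1_200)
    rec.mapq_class = "ambiguous"
    table = count_reads_per_gene([rec], GENES3)
    assert table.genes["assigned_reads"].sum() == 0


def test_annotation_chrom_absent_from_alignments_is_an_error():
    with pytest.raises(ValueError, match="absent"):
        count_reads_per_gene([], GENES3, reference_chroms=["chr1"])


class TestTpm:
    def test_single_gene_gets_the_whole_million(self):
        t = CountTable(pd.DataFrame({"assigned_reads": [7], "length_bp": [500]},
                                    index=pd.Index(["G"], name="gene_id")))
        assert tpm_normalize(t).tpm("G") == pytest.approx(1e6)

    def test_hand_computed_two_gene_values(self):
        t = CountTable(pd.DataFrame({"assigned_reads": [100, 100],
                                     "length_bp": [1_000, 2_000]},
                                    index=pd.Index(["A", "B"], name="gene_id")))
        t = tpm_normalize(t)
        assert t.tpm("A") == pytest.approx(666_666.7, abs=0.1)
        assert t.tpm("B") == pytest.approx(333_333.3, abs=0.1)

    def test_sum_is_one_million_and_scale_invariant(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 1_000, size=20)
        lengths = rng.integers(200, 5_000, size=20)
        idx = pd.Index([f"g{i}" for i in range(20)], name="gene_id")
        t1 = tpm_normalize(CountTable(pd.DataFrame(
            {"assigned_reads": counts, "length_bp": lengths}, index=idx)))
        t2 = tpm_normalize(CountTable(pd.DataFrame(
            {"assigned_reads": counts * 2, "length_bp": lengths}, index=idx)))
        assert t1.genes["tpm"].sum() == pytest.approx(1e6, rel=1e-9)
        assert np.allclose(t1.genes["tpm"], t2.genes["tpm"])
        assert t1.genome_average_tpm == pytest.approx(t1.genes["tpm"].mean())

    def test_all_zero_counts_rejected(self):
        t = CountTable(pd.DataFrame({"assigned_reads": [0, 0], "length_bp": [100, 100]},
                                    index=pd.Index(["A", "B"], name="gene_id")))
        with pytest.raises(ValueError, match="all-zero"):
            tpm_normalize(t)


def _uniform_table(n=20, tpm_of_first=None):
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    counts = [100] * n
    if tpm_of_first is not None:
        counts[0] = tpm_of_first
    df = pd.DataFrame({"assigned_reads": counts, "length_bp": [1_000] * n}, index=idx)
    return tpm_normalize(CountTable(df))


class TestCoverageEstimator:
    def test_gene_at_baseline_is_two_copies(self):
        t = _uniform_table()
        assert estimate_copies_from_coverage(t, "g3").estimated_copies == pytest.approx(2.0)

    def test_gene_at_1_5x_baseline_is_three_copies(self):
        # 19 genes at the baseline level, one at 1.5x; 10% trim drops the
        # extremes so the baseline is the unamplified level exactly
        t = _uniform_table(tpm_of_first=150)
        assert estimate_copies_from_coverage(t, "g0").estimated_copies == pytest.approx(
            3.0, abs=1e-9
        )

    def test_too_few_genes_rejected(self):
        t = _uniform_table(n=5)
        with pytest.raises(ValueError, match="baseline"):
            estimate_copies_from_coverage(t, "g0")

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            estimate_copies_from_coverage(_uniform_table(), "nope")


def test_coverage_recovers_simulated_copy_numbers(sim40):
    """Passenger genes (3 copies) and neutral genes (2 copies) estimated
    within 0.35 at 40x; the two estimator families agree on the truth."""
    table = tpm_normalize(count_reads_per_gene(sim40.records, sim40.model.annotation))
    for g in sim40.model.genes_by_role("passenger"):
        est = estimate_copies_from_coverage(table, g.gene_id).estimated_copies
        assert est == pytest.approx(3.0, abs=0.35)
    neutral = [g.gene_id for g in sim40.model.genes_by_role("neutral")]
    ests = [estimate_copies_from_coverage(table, g).estimated_copies for g in neutral]
    assert np.mean(ests) == pytest.approx(2.0, abs=0.1)


class TestDdpcr:
    def test_no_positive_droplets_is_zero_concentration(self):
        assert ddpcr_concentration(DdpcrWell("T", 0, 10_000)) == 0.0

    def test_closed_form_inversion_at_lambda_one(self):
        """P/N = 1 - e^-1 inverts to lambda = 1, i.e. 1/0.00085 uL."""
        well = DdpcrWell("T", 6_321, 10_000, droplet_volume_nl=0.85)
        conc = ddpcr_concentration(well)
        lam = -math.log(1 - 0.6321)
        assert conc == pytest.approx(lam / 0.00085, rel=1e-6)
        assert conc == pytest.approx(1176.47, rel=1e-3)

    def test_halving_droplet_volume_doubles_concentration(self):
        a = ddpcr_concentration(DdpcrWell("T", 3_000, 10_000, 0.85))
        b = ddpcr_concentration(DdpcrWell("T", 3_000, 10_000, 0.425))
        assert b == pytest.approx(2 * a)

    def test_saturated_well_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            ddpcr_concentration(DdpcrWell("T", 100, 100))

    def test_more_positives_than_droplets_rejected(self):
        with pytest.raises(ValueError):
            DdpcrWell("T", 101, 100)

    def test_equal_concentrations_give_two_copies(self):
        w = DdpcrWell("T", 4_000, 10_000)
        r = DdpcrWell("R", 4_000, 10_000)
        assert copies_per_genome(w, r).estimated_copies == pytest.approx(2.0)

    def test_hemizygous_passenger_expectation(self):
        """Target at 1.5x the reference concentration = 3 copies/genome."""
        lam_r = 0.8
        lam_t = 1.2
        n = 10**6
        w = DdpcrWell("T", int(n * (1 - math.exp(-lam_t))), n)
        r = DdpcrWell("R", int(n * (1 - math.exp(-lam_r))), n)
        assert copies_per_genome(w, r).estimated_copies == pytest.approx(3.0, rel=1e-3)

    def test_zero_reference_concentration_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            copies_per_genome(DdpcrWell("T", 10, 100), DdpcrWell("R", 0, 100))

    def test_pooling_requires_matching_wells(self):
        w1 = DdpcrWell("T", 10, 100, 0.85)
        with pytest.raises(ValueError):
            pool_wells([w1, DdpcrWell("U", 10, 100, 0.85)])
        with pytest.raises(ValueError):
            pool_wells([w1, DdpcrWell("T", 10, 100, 0.9)])
        pooled = pool_wells([w1, DdpcrWell("T", 30, 100, 0.85)])
        assert (pooled.positive_droplets, pooled.total_droplets) == (40, 200)


def test_ddpcr_monte_carlo_triplicates_recover_truth():
    """Triplicate wells drawn from Poisson truth lambda_t/lambda_r = 1.5:
    the mean copies-per-genome estimate lands within 5% of 3.0."""
    rng = np.random.default_rng(12)
    estimates = []
    for _ in range(60):
        tw = simulate_ddpcr_wells("T", 1.2, 20_000, 3, rng)
        rw = simulate_ddpcr_wells("R", 0.8, 20_000, 3, rng)
        estimates.append(copies_per_genome(tw, rw).estimated_copies)
    assert np.mean(estimates) == pytest.approx(3.0, rel=0.05)


def test_ddpcr_estimator_is_consistent():
    """Bias shrinks as droplet count grows (N in 1e3, 1e4, 1e5)."""
    rng = np.random.default_rng(13)
    bias = []
    for n in (10**3, 10**4, 10**5):
        ests = []
        for _ in range(100):
            tw = simulate_ddpcr_wells("T", 1.2, n, 1, rng)
            rw = simulate_ddpcr_wells("R", 0.8, n, 1, rng)
            try:
                ests.append(copies_per_genome(tw, rw).estimated_copies)
            except ValueError:
                continue
        bias.append(abs(np.mean(ests) - 3.0))
    assert bias[2] < bias[0]
    assert bias[2] < 0.01


def test_coverage_and_ddpcr_estimators_agree(sim40):
    """The two estimators agree within 15% for the same truth copy
    numbers (coverage from the simulation, ddPCR from Poisson droplets)."""
    table = tpm_normalize(count_reads_per_gene(sim40.records, sim40.model.annotation))
    rng = np.random.default_rng(21)
    for g in sim40.model.genes_by_role("passenger"):
        truth = sim40.model.truth_copy_number[g.gene_id]
        cov = estimate_copies_from_coverage(table, g.gene_id).estimated_copies
        tw = simulate_ddpcr_wells(g.gene_id, 0.8 * truth / 2, 20_000, 3, rng)
        rw = simulate_ddpcr_wells("REF1", 0.8, 20_000, 3, rng)
        ddp = copies_per_genome(tw, rw).estimated_copies
        assert abs(cov - ddp) / ddp < 0.15
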