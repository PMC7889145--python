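"""Adjacency discovery: clustering, calling, screening, notation."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from tglocus.adjacency import (
    Adjacency,
    Side,
    format_adjacency,
    match_adjacency,
    parse_adjacency,
)
from tglocus.align import AlignmentRecord, InsertModel, Segment
from tglocus.svdiscover import (
    JunctionObservation,
    call_adjacencies,
    cluster,
    discover,
    extract_evidence,
    screen_region,
)


def _obs(c1, p1, o1, c2, p2, o2, kind="split"):
    return JunctionObservation(Side(c1, p1, o1), Side(c2, p2, o2), kind)


def test_no_evidence_from_concordant_alignments(small_model):
    rec1 = AlignmentRecord("r", True, 100, segments=[Segment(0, 100, "chrA", 1000, "+")],
                           mapq_class="unique", proper_pair=True)
    rec2 = AlignmentRecord("r", False, 100, segments=[Segment(0, 100, "chrA", 1250, "-")],
                           mapq_class="unique", proper_pair=True)
    assert extract_evidence([rec1, rec2], InsertModel(), small_model.reference) == []
    assert extract_evidence([], InsertModel(), small_model.reference) == []


def test_split_read_yields_exact_observation(small_model):
    """A split read over chrA:5000 / chrD:12000 pins both sides."""
    ref = small_model.reference
    rec = AlignmentRecord(
        "r", True, 100,
        segments=[Segment(0, 50, "chrA", 4951, "+"), Segment(50, 100, "chrD", 12000, "+")],
        mapq_class="unique",
    )
    (obs,) = extract_evidence([rec], InsertModel(), ref)
    assert obs.kind == "split"
    # canonical right-shift may move the junction through homology by a base or two
    assert obs.side1.chrom == "chrA" and abs(obs.side1.pos - 5000) <= 3
    assert obs.side2.chrom == "chrD" and abs(obs.side2.pos - 12000) <= 3
    assert (obs.side1.orient, obs.side2.orient) == ("-", "+")


def test_ambiguous_records_carry_no_evidence(small_model):
    rec = AlignmentRecord(
        "r", True, 100,
        segments=[Segment(0, 50, "chrA", 4951, "+"), Segment(50, 100, "chrD", 12000, "+")],
        mapq_class="ambiguous",
    )
    assert extract_evidence([rec], InsertModel(), small_model.reference) == []


class TestCluster:
    def test_nearby_same_signature_observations_merge(self):
        obs = [_obs("chrA", 100, "-", "chrD", 500, "+"),
               _obs("chrA", 110, "-", "chrD", 505, "+")]
        assert len(cluster(obs, window=500)) == 1

    def test_different_chromosome_pairs_stay_separate(self):
        obs = [_obs("chrA", 100, "-", "chrD", 500, "+"),
               _obs("chrA", 100, "-", "chrB", 500, "+")]
        assert len(cluster(obs, window=500)) == 2

    def test_opposite_signatures_never_merge(self):
        obs = [_obs("chrA", 100, "-", "chrD", 500, "+"),
               _obs("chrA", 100, "+", "chrD", 500, "+")]
        assert len(cluster(obs, window=500)) == 2

    def test_clustering_is_order_invariant(self):
        rng = random.Random(0)
        obs = [
            _obs("chrA", 100 + i, "-", "chrD", 500 + i, "+")
            for i in range(0, 5000, 250)
        ] + [_obs("chrA", 90, "-", "chrD", 480, "+", kind="pair")]
        base = cluster(obs, window=400)
        base_sets = sorted(
            tuple(sorted((o.side1.pos, o.side2.pos, o.kind) for o in c.members))
            for c in base
        )
        for _ in range(5):
            shuffled = obs[:]
            rng.shuffle(shuffled)
            got = cluster(shuffled, window=400)
            got_sets = sorted(
                tuple(sorted((o.side1.pos, o.side2.pos, o.kind) for o in c.members))
                for c in got
            )
            assert got_sets == base_sets


class TestCalling:
    def test_cluster_below_min_support_is_not_called(self):
        obs = [_obs("chrA", 100, "-", "chrD", 500, "+") for _ in range(3)]
        assert call_adjacencies(cluster(obs, 500), min_support=4) == []
        assert len(call_adjacencies(cluster(obs, 500), min_support=3)) == 1

    def test_position_is_median_of_splits_with_lower_tie(self):
        obs = [
            _obs("chrA", 100, "-", "chrD", 500, "+"),
            _obs("chrA", 102, "-", "chrD", 502, "+"),
            _obs("chrA", 104, "-", "chrD", 504, "+"),
            _obs("chrA", 106, "-", "chrD", 506, "+"),
        ]
        (call,) = call_adjacencies(cluster(obs, 500), min_support=4)
        assert (call.side1.pos, call.side2.pos) == (102, 502)
        assert call.precise

    def test_pair_only_cluster_is_imprecise(self):
        obs = [_obs("chrA", 100 + i, "-", "chrD", 500 + i, "+", kind="pair")
               for i in range(4)]
        (call,) = call_adjacencies(cluster(obs, 500), min_support=4)
        assert not call.precise
        assert call.support_pairs == 4 and call.support_split == 0


def test_raising_min_support_never_adds_calls(sim40):
    obs = extract_evidence(sim40.records, sim40.im, sim40.model.reference)
    clusters = cluster(obs, sim40.im.cluster_window)
    sizes = [len(call_adjacencies(clusters, ms)) for ms in (2, 4, 8, 16, 64)]
    assert sizes == sorted(sizes, reverse=True)


def test_default_simulation_recovers_all_truth_adjacencies(sim40):
    """Hemizygous 40x simulation: all three truth junctions called within
    1 bp with matching orientation signatures (one +/+), and nothing else
    survives the donor-region screen."""
    calls = discover(sim40.records, sim40.im, sim40.model.reference, min_support=4)
    truth = sim40.model.truth_adjacencies
    for t in truth:
        matches = [c for c in calls if match_adjacency(c, t)]
        assert matches, f"truth junction {format_adjacency(t)} not called"
        assert matches[0].precise
    screened = screen_region(calls, sim40.cfg.roi)
    assert len(screened) == len(truth)
    assert all(any(match_adjacency(c, t) for t in truth) for c in screened)
    assert sum(c.signature == ("+", "+") for c in screened) == 1


def test_wildtype_simulation_yields_zero_calls(sim_wildtype):
    calls = discover(
        sim_wildtype.records, sim_wildtype.im, sim_wildtype.model.reference, min_support=4
    )
    assert calls == []


def test_evidence_count_matches_template_recount(sim40):
    """Observation count is within 20% of the number of simulated
    templates whose fragment spans a truth junction (oracle recount from
    the truth placement table)."""
    obs = extract_evidence(sim40.records, sim40.im, sim40.model.reference)
    window = sim40.im.cluster_window
    junction_obs = [
        o
        for o in obs
        if any(
            o.side1.chrom == t.side1.chrom
            and o.side2.chrom == t.side2.chrom
            and (o.side1.orient, o.side2.orient) == t.signature
            and abs(o.side1.pos - t.side1.pos) <= window
            and abs(o.side2.pos - t.side2.pos) <= window
            for t in sim40.model.truth_adjacencies
        )
    ]
    truth = sim40.truth
    min_anchor = 20  # less than a split segment's worth of sequence on a
    # side cannot anchor any evidence class
    expected = 0
    for chrom, pos in sim40.model.truth_junctions_hapB:
        expected += (
            (truth.haplotype == "B")
            & (truth.chrom == chrom)
            & (truth.frag_start <= pos - min_anchor + 1)
            & (truth.frag_end >= pos + min_anchor)
        ).sum()
    assert abs(len(junction_obs) - expected) <= 0.2 * expected


class TestScreen:
    roi = ("chrD", 15_000, 20_000)

    def test_call_outside_roi_is_dropped(self):
        call = Adjacency(Side("chrA", 100, "-"), Side("chrA", 5_000, "+"))
        assert screen_region([call], self.roi) == []

    def test_donor_side_call_with_acceptor_mate_is_retained(self):
        call = Adjacency(Side("chrA", 100, "-"), Side("chrD", 16_000, "+"))
        assert screen_region([call], self.roi) == [call]

    def test_donor_internal_call_inside_roi_is_retained(self):
        call = Adjacency(Side("chrD", 16_000, "-"), Side("chrD", 19_000, "-"))
        assert screen_region([call], self.roi) == [call]

    def test_malformed_interval_rejected(self):
        call = Adjacency(Side("chrA", 100, "-"), Side("chrD", 16_000, "+"))
        with pytest.raises(ValueError, match="malformed"):
            screen_region([call], ("chrD", 20_000, 15_000))

    def test_decoy_intrachromosomal_calls_are_screened_out(self, sim40):
        """Simulated call set plus injected intra-chromosomal decoys: only
        the truth adjacencies survive the donor-region screen."""
        calls = discover(sim40.records, sim40.im, sim40.model.reference, min_support=4)
        decoys = [
            Adjacency(Side("chrA", 10_000, "-"), Side("chrA", 40_000, "+")),
            Adjacency(Side("chrA", 120_000, "+"), Side("chrA", 150_000, "-")),
            Adjacency(Side("chrD", 5_000, "-"), Side("chrD", 12_000, "+")),
            Adjacency(Side("chrD", 100_000, "-"), Side("chrD", 180_000, "-")),
            Adjacency(Side("chrD", 70_000, "-"), Side("chrD", 120_000, "+")),
        ]
        screened = screen_region(calls + decoys, sim40.cfg.roi)
        truth = sim40.model.truth_adjacencies
        assert len(screened) == len(truth) == 3
        for t in truth:
            assert any(match_adjacency(c, t) for c in screened)


def test_published_breakend_notation_renders_byte_identically():
    adj = Adjacency(Side("chr16", 23_118_416, "+"), Side("chr9", 87_704_340, "-"))
    assert format_adjacency(adj, pretty=True) == "+[chr16:23,118,416]:-[chr9:87,704,340]"
    assert format_adjacency(adj, pretty=False) == "+[chr16:23118416]:-[chr9:87704340]"


sides = st.tuples(
    st.sampled_from(["chr1", "chr9", "chr16", "chrX"]),
    st.integers(min_value=1, max_value=3_000_000_000),
    st.sampled_from(["+", "-"]),
).map(lambda t: Side(*t))


@given(sides, sides, st.booleans())
@settings(max_examples=100, deadline=None)
def test_notation_round_trips(s1, s2, pretty):
    a, b = sorted([s1, s2])
    adj = Adjacency(a, b)
    assert parse_adjacency(format_adjacency(adj, pretty=pretty)).key == adj.key
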