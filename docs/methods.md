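# Methods

This note documents the models and procedures implemented in
`tg-locus`, the defaults they run with, and what the synthetic-data
validation does and does not demonstrate.

## The synthetic genome and what it emulates

`tglocus.genome` builds a two-chromosome diploid toy genome
(`GenomeConfig`, default 2 × 200 kb of uniform random sequence) that
reproduces the *architecture* of a BAC transgenic line at desk scale:

* **Donor fragment** — a 20 kb interval of the donor chromosome
  (fractions 0.30–0.40 of `chrD`) standing in for a ~245 kb BAC. It
  contains a driver gene whose first 222 bp are replaced by a 1 kb
  random marker sequence absent from the reference (the "Cre" swap:
  the replacement length is the documented construct design of the
  emulated line; the marker gives the transgene a mappable foreign
  anchor), plus three passenger genes.
* **Insertion** — haplotype B receives `tandem_copies` of the construct
  between positions `pos` and `pos+1` of the acceptor chromosome,
  deleting `deleted_span` bases (default 0). The default site is the
  midpoint of the acceptor gene's final exon, modeling an insertion
  that disrupts the last exon of the gene it lands in. The acceptor
  must have ≥ 2 exons, enforced at build time.
* **Inverted tail** — by default the distal 30% (6 kb) of the construct
  integrates in reverse-complement orientation. This is the minimal
  rearrangement that yields *three* distinct junctions — left flank,
  donor-internal inversion junction, right flank — with one `+/+`
  orientation signature, matching the mixed-signature junction pattern
  reported for real BAC concatemer insertions. A simple interstitial
  insertion necessarily produces an even number of inter-chromosomal
  junctions (each boundary toggles the origin of the sequence), so a
  three-junction pattern requires a donor-internal rearrangement; the
  inverted tail is the simplest such choice.
* **Gene set** — 42 genes total (driver, 3 passengers, a 2-exon
  acceptor, a ddPCR reference-assay gene, and neutral filler at fixed
  grid positions). The count is chosen so that the 10% trimmed-mean
  coverage baseline (below) excludes all four transgene-amplified genes
  even in a small gene set.

Planted truth: each junction is recorded as a canonical adjacency (see
orientation convention below) and each gene's copies per diploid
genome (neutral 2; fully contained passengers 2 + `tandem_copies`;
driver 2, since its transgenic copy is promoter-swapped and counted as
non-functional).

**Read simulation** (`tglocus.simreads`) draws
`mean_depth × haploid_length / (2 × read_length)` forward–reverse pairs,
each from haplotype B with probability `haplotype_mix` (0.5 =
hemizygous carrier), fragment length Normal(`insert_mean` = 350,
`insert_sd` = 50) clipped below at one read length, uniform start, and
iid substitution errors (`error_rate` default 0.002, the level of a
modern short-read run after trimming). Base qualities are constant Q30
because nothing downstream is quality-aware. All stages are
deterministic given the seed.

What the simulator does **not** emulate: indels, GC and
position-dependent coverage bias, machine error profiles, chimeric
library artifacts, multiple independent insertion sites, and repetitive
reference sequence. Passing tests therefore demonstrate correctness of
the algorithms under clean mappability, not robustness to repeat-rich
real genomes — on real data the same evidence classes exist but
ambiguous mapping is the dominant complication.

## Alignment

`tglocus.align` is an ungapped, k-mer-seeded mapper adequate for the
simulator's error model (substitutions only). Defaults: k = 21, at
most 5% mismatches for a full-length placement, split segments ≥ 20 bp.
A read maps to the placement with the fewest mismatches when that
placement is *strictly* best; equal-best placements are flagged
`ambiguous` and excluded from structural-variant evidence and gene
counting, which is what keeps repeats from fabricating junctions. Reads
failing full-length placement are re-tried as two-segment splits: seed
hits at 10 bp offsets nominate candidate diagonals, and the breakpoint
partition maximizing total matched bases (each part ≥ 20 bp) is chosen,
with position ties resolved to the rightmost split so that split calls
agree with the right-shifted junction canonical form. Pairs are
classified against an insert model with `max_concordant = mean + 3·sd`
(proper = same chromosome, FR orientation, outer span within bound;
otherwise discordant with subtype inter-chromosomal / orientation /
distance).

Coordinates are 1-based inclusive everywhere, matching SAM. SAM output
writes splits as primary + supplementary lines with `SA` tags;
parsing (via pysam) reconstructs the in-memory records, so externally
produced SAM with the same conventions can enter the pipeline.

## Adjacency calling

**Orientation convention.** Published breakend notations often leave
the strand signs undefined. Here the sign of a side states which
reference sequence the junction retains: `+` joins sequence extending
to the *right* of `pos`, `-` sequence extending to the *left*. A side
list is kept in canonical (chrom, pos) order.

**Microhomology canonicalization.** When the two sides share sequence
at the junction, the breakpoint is ambiguous within the homology tract.
Both simulated truth and split-read observations are right-shifted to
the same canonical representation, so truth and calls compare
base-exactly instead of differing by the homology length.

**Clustering and calling.** Observations sharing a chromosome pair and
orientation signature are single-linkage clustered with window
`insert_mean + 3·sd` (500 bp by default); clusters reaching
`min_support = 4` total observations become calls, positioned at the
median of split observations when any exist (`precise`), else at the
median of pair inner edges. The support threshold is a conservative
choice for 40–80× data where a real junction attracts tens of
observations; no published threshold exists for the emulated study.

**Region screen.** Mirroring the investigation of variants near the
donor locus, `screen_region` keeps calls with a side inside the donor
region of interest when the other side is on a different chromosome
(candidate insertion flank) *or* also inside the region (internal
architecture of the integrated construct, such as the inversion
junction). Intra-chromosomal calls elsewhere — the usual background of
dispersed repeat artifacts — are screened out.

## Copy number

**Coverage route.** Uniquely mapped reads are assigned to genes by
≥ 1 bp interval overlap (reads touching two genes are discarded; mates
count separately, matching read-level coverage semantics). TPM applied
to genomic DNA is a length-normalized coverage measure, so for a
uniform-coverage genome TPM is proportional to copy number. The
baseline representing the two-copy state is the two-sided 10% trimmed
mean of per-gene TPM: in a compact gene set a plain average would be
inflated by the transgene-amplified genes themselves, which at genome
scale (tens of thousands of genes) is negligible but here is not.
Estimated copies = 2 × TPM_gene / baseline.

Known bias: ≥ 1 bp-overlap counting captures an effective length of
(L + read − 1) per gene, so genes much shorter than neighbours are
relatively over-counted by up to (L + read − 1)/L. All default-genome
genes are ~1.2 kb, cancelling the effect; the pipeline tests on the
50 kb mini-genome (300 bp passengers) carry tolerances that absorb it.

**ddPCR route.** With N droplets of volume v (default 0.85 µL/1000 —
an instrument-nominal droplet volume, configurable) and P positives,
the mean occupancy is λ = −ln(1 − P/N) and the concentration λ/v
copies/µL. Saturated wells (P = N) are rejected rather than clamped.
Replicate wells are pooled (P and N summed) *before* inversion — the
minimum-variance merge. Copies per genome =
2 × conc(target)/conc(reference) against a two-copy reference assay.
The estimator's bias vanishes as N grows; tests verify consistency at
N ∈ {10³, 10⁴, 10⁵} and 5% accuracy for triplicates at a 1.5× ratio.

## Linkage

θ = (recombinant offspring)/n with the recombinant classes fixed by the
cross design (transgene⁺;floxed-homozygous and
transgene⁻;floxed-heterozygous for the emulated backcross). Genetic
distance is 100·θ cM — two-point, no Haldane/Kosambi mapping, matching
how such tables are conventionally reported at short distances. Two LOD
statistics are implemented because published tables sometimes print a
footnote formula that drops the recombinant term:

* footnote form: Z = n·log₁₀((1−θ)/½) — reproduces such tables exactly
  and is the default report;
* standard form: Z = log₁₀[θ^R (1−θ)^NR / ½^(R+NR)] — the textbook
  statistic, maximized at θ = R/n, available behind a flag and asserted
  in tests to diverge from the footnote form whenever R > 0 (≈ 20.0 vs
  25.6 at the 2/43/43/2 counts).

Both classify "definitive" at Z ≥ 3. `n_total` is an explicit input
defaulting to the class-count sum, because published tables can print
an n that differs from the tallied classes by genotyping failures; the
Pearson chi-square against the uniform 25% expectation uses the class
sum. Display rounding (θ three decimals, cM and LOD one decimal)
mirrors tabular convention; raw values are retained.

## qPCR

The efficiency-corrected ratio (Pfaffl) form is implemented:
E_t^(Cq_t,control − Cq_t,case) / E_r^(Cq_r,control − Cq_r,case) with
E = 1 + efficiency/100, validated to the 50–110% range. A "2^ΔΔCq with
efficiency correction" label is ambiguous between this ratio and a
per-gene-base ΔΔCq; the two coincide at equal efficiencies, and the
ratio form is the one implemented and labeled. Technical replicates
average on the Cq scale; biological replicates summarize by geometric
mean of per-sample ratios (ratios are multiplicative). Melting-curve QC
is upstream of this package.

## Pipeline and reproducibility

`run_all` chains genome → reads → mapping → calling → screening → copy
number as idempotent plain-file stages (FASTA, FASTQ, SAM, BED, TSV,
JSON) with one run seed; per-stage seeds derive from it through a seed
sequence, and a rerun is byte-identical (checked by checksum in tests).
Default problem sizes — 400 kb genome, 40× for breakpoint work, 80× for
copy-number work (the depth class of the emulated sequencing design) —
keep a full run under a minute on one CPU while leaving every junction
with tens of supporting observations.

## Known limitations

* Ungapped alignment: indel-containing real data would need a gapped
  aligner in the `map` stage (the SAM entry point accepts external
  alignments for exactly this reason).
* No fragment-level deduplication or GC correction in coverage copy
  number; segmentation-based CNV calling is out of scope.
* The droplet classifier (rain/threshold assignment) is upstream: wells
  enter as P/N counts.
* Single insertion locus; multi-site lines would break the one-ROI
  screen and are not simulated.
* The breakend sign convention is a documented package choice; other
  tools may print the complementary convention.
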