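# tg-locus

Mapping the genomic insertion site of a BAC transgene from short-read
whole-genome sequencing, and quantifying what the insertion did.

Transgenic *Cre*-driver mouse lines are usually made by pronuclear
injection of a large BAC construct, and the construct lands somewhere
random in the genome — often inside a gene, often in several tandem
copies, and always carrying "passenger" genes that rode along on the
BAC. Most published lines have no annotated insertion site. `tg-locus`
implements the desk-scale computational core of the workflow a lab uses
to characterize such a line:

* **Two-point linkage analysis** — when a transgene refuses to segregate
  away from a nearby locus of interest, genotype tallies from an
  informative backcross give the recombination frequency
  θ = recombinants / n, the genetic distance 100·θ cM, and the LOD score
  Z comparing linkage at θ against free recombination (θ = ½); Z ≥ 3 is
  definitive.
* **Breakpoint discovery** — paired-end reads aligned to the wild-type
  reference yield split reads (one read crossing a junction, prefix and
  suffix mapping to different loci) and discordant pairs (mates with
  unexpected separation, orientation, or chromosomes). Clustering this
  evidence per chromosome pair and orientation signature produces
  adjacency calls written in breakend notation,
  `s1[chrA:p1]:s2[chrB:p2]`, with base-exact positions whenever a split
  read supports the cluster.
* **Copy-number estimation** — per-gene genomic-DNA read counts,
  TPM-normalized (count per kb, rescaled to sum to 10⁶) against a
  trimmed-mean genome baseline, estimate copies per diploid genome;
  independently, droplet digital PCR counts are inverted through the
  Poisson occupancy formula λ = −ln(1 − P/N) and normalized to a
  two-copy reference assay.
* **Efficiency-corrected qPCR** — expression fold changes by the ratio
  method, E_t^ΔCq(target) / E_r^ΔCq(reference), which reduces to the
  familiar 2^−ΔΔCq at 100% efficiency.

Because no real transgenic genome ships with known truth, the package
includes a first-class synthetic-data module: a toy diploid genome in
which one haplotype carries a scaled BAC construct (promoter-swapped
driver gene, passenger genes, optional tandem copies, and an inverted
tail segment) inserted into the final exon of an acceptor gene. The
planted truth — every junction adjacency and every gene's copy number —
lets the whole pipeline be validated end to end.

## Worked example

Simulate the default hemizygous genome (two 200 kb chromosomes, 20 kb
construct with an inverted 6 kb tail, 40× 100-bp pairs, 0.2% error) and
run discovery:

```sh
tg-locus simulate --seed 3 --out run3
```

The report ends with:

```
Called adjacencies (after region screen):
  -[chrA:102,500]:+[chrD:60,001]
  +[chrA:102,501]:+[chrD:74,001]
  -[chrD:74,000]:-[chrD:80,000]
Recovered 3/3 truth adjacencies; 0 false positive(s).
```

Reading the notation: `-[chrA:102,500]:+[chrD:60,001]` joins the
sequence left of chrA:102,500 (the acceptor gene's final exon) to the
sequence right of chrD:60,001 (the construct's first base) — the left
insertion flank. The `+/+` call is the right flank through the inverted
tail, and the donor-internal `-/-` call is the inversion junction
itself. The copy table in the same report shows the three passenger
genes near 3.0 copies (two native plus one transgenic) and background
genes near 2.0.

The linkage calculator reproduces a published-style backcross table
directly:

```sh
tg-locus linkage --counts counts.tsv --n-total 91
# theta 0.044, genetic distance 4.4 cM, LOD 25.6 -> "definitive"
```

where `counts.tsv` holds the four genotype-class counts (2, 43, 43, 2):
only 2.2% of offspring carried both the transgene and the homozygous
floxed locus against a 25% Mendelian expectation.

Other entry points: `tg-locus map` (FASTQ → SAM), `tg-locus
call-insertion` (SAM → adjacency table), `tg-locus copynum`
(SAM + BED → copy calls), `tg-locus ddpcr`, `tg-locus qpcr`.

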