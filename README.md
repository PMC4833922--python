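# ampcall

Mapping-free, primer-directed variant calling for PCR-targeted amplicon
sequencing panels with fully overlapping read pairs.

## The problem

Highly multiplexed PCR target-enrichment protocols (Hi-Plex and similar)
amplify a panel of short genomic *tiles* (~100 nt), each flanked by a pair of
gene-specific primers, and sequence them so that the two reads of every pair
cover the same insert completely from opposite ends. Two properties of such
libraries make conventional read mapping unnecessary and enable unusually
stringent error filtering:

1. **The 5′ end of every read begins with a known primer sequence**, whose
   genomic coordinates are fixed at panel design time. Hashing the first *N*
   bases of a read against the panel's primer prefixes assigns it to its tile
   in O(N) — no alignment to the genome is ever performed.
2. **Both reads of a pair observe every insert base independently.** A true
   variant appears identically in both mates; a sequencing-chemistry artefact
   almost never does. Requiring *pair concordance* therefore suppresses false
   positives far more cheaply than base-quality modelling.

`ampcall` implements this calling strategy for anyone running amplicon panels
that retain gene-specific primers in the reads (it is not suitable for
protocols that cleave primers, or for libraries without near-complete
read-pair overlap).

## The algorithm

For each sample (one pair of FASTQ files):

1. **Bin** each read pair by exact prefix lookup: both mates must hash to the
   same tile in complementary orientations, else the pair is discarded and
   counted. Primer bases are trimmed (the full primer, not just the hashed
   prefix — variants under a primer are unobservable), reads are truncated at
   the insert length to drop adapter read-through, and the reverse mate is
   reverse-complemented so both inserts are plus-strand.
2. **Filter**: each mate must cover ≥ 90 % of the tile (configurable);
   optionally, at least one mate's first 30 post-primer bases must match the
   reference exactly (the *anchor* check); optionally, bases below a Phred
   threshold are masked.
3. **Compare** each insert to the tile's reference sequence with a linear
   scan. In *thorough* mode at most one mismatch is accepted; in *fast* mode
   any number of mismatches is accepted provided consecutive mismatches are
   separated by more than `--fast-gap` bases. A mismatch pattern beyond the
   policy (the signature of an indel) triggers a global affine-gap
   (Needleman–Wunsch style) alignment, from which variants are extracted and
   indels left-normalized to VCF convention.
4. **Call**: a variant is kept only when both mates of a pair report it
   identically; per tile, a concordant variant passes when its pair count
   ≥ `--min-pairs` (default 2) **and** its fraction of surviving pairs
   ≥ `--min-proportion` (default 0.05). Failing variants are reported with
   `at`/`pt` FILTER labels rather than suppressed.
5. **Genotype** (optional, `--genotype`): for each SNV, a pileup of
   pair-consensus bases is compared against the expected base distribution of
   each candidate genotype (diploid R/R, R/A, A/A; or haploid R, A) under a
   constant-error model (error rate *e* = 1/500 by default). Expected
   distributions draw a read's base uniformly from the genotype's alleles and
   corrupt it with probability *e* to one of the three other bases. The
   genotype minimizing the G statistic

   G = 2 · Σ_b O_b · ln(O_b / (n·E_b))

   is reported in the GT field, with its G value in GS.

Outputs are a multi-sample VCF 4.2, a per-amplicon coverage TSV, and a
plain-text run log with per-sample binning/filter totals.

## Input formats

* **Primer coordinates** (`--primer-coords`): 5-column TSV, no header —
  chromosome, tile start, tile end, forward-primer name, reverse-primer
  name. **Coordinates are 1-based and inclusive at both ends.**
* **Primer sequences** (`--primer-sequences`): 2-column TSV, no header —
  primer name, oligo sequence written 5′→3′ as synthesized (the reverse
  primer is the reverse complement of the plus strand just 3′ of the tile).
* **Reference** (`--reference`): FASTA; chromosome names must match the
  coordinates file. The primers must have been designed from this reference.
* **Reads**: paired FASTQ (plain or gzip), Phred+33, given positionally as
  consecutive `r1 r2` pairs, one pair per sample.

## Worked example

The bundled simulator generates a complete panel and reads, so the example
is fully self-contained:

```python
import numpy as np
from ampcall import PanelConfig, ReadSimConfig, make_panel, random_truth
from ampcall.simulate import simulate_reads, write_fastq, write_panel

panel = make_panel(PanelConfig(n_tiles=5, seed=21))          # 5 x 100 bp tiles
rng = np.random.default_rng(21)
truth = random_truth(panel, ["sampleA"], rng,
                     snv_per_sample=2, indel_per_sample=1)
reads = simulate_reads(panel, truth,
                       ReadSimConfig(depth=50, error_rate=0.0, seed=21))
write_panel(panel, "ref.fa", "coords.tsv", "seqs.tsv")
write_fastq(reads["sampleA"][0], "sampleA_r1.fastq")
write_fastq(reads["sampleA"][1], "sampleA_r2.fastq")
```

```sh
ampcall --primer-coords coords.tsv --primer-sequences seqs.tsv \
    --reference ref.fa --out results.vcf --genotype \
    sampleA_r1.fastq sampleA_r2.fastq
```

`results.vcf` then contains exactly the three planted variants:

```
#CHROM  POS   ID  REF  ALT  QUAL  FILTER  INFO  FORMAT          sampleA
chrSim  83    .   C    G    .     PASS    .     GT:DP:PC:VP:GS  1/1:50:50:1:0.2002
chrSim  284   .   C    A    .     PASS    .     GT:DP:PC:VP:GS  0/1:50:24:0.48:0.213444
chrSim  641   .   CCA  C    .     PASS    .     DP:PC:VP        50:20:0.4
```

Reading the second record: of 50 read pairs overlapping the tile (DP), 24
carried the C→A substitution concordantly on both mates (PC), a proportion
of 0.48 (VP) — above both frequency thresholds, hence PASS — and the G-test
genotyper chose the heterozygous genotype (GT `0/1`, its G statistic in GS).
The first record is a homozygous variant planted at VAF 1.0 (all 50 pairs
carry it); the third is a left-normalized 2 bp deletion at VAF 0.5 — indels
are reported without genotypes. The coverage TSV (`results.vcf.coverage.tsv`) holds one
row per sample × tile with pair counts along the filter chain, and the run
log (`results.vcf.log`) echoes the configuration and per-sample totals
(pairs seen / matched / unassigned / filtered).

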