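# Methods

This note documents the model behind `ampcall`, the choices made where the
design was genuinely open, and what the simulator does and does not emulate.

## Library geometry assumed

Every fragment is taken to be

```
5'-[forward GSP][insert][revcomp(reverse GSP)][adapter]-3'
```

with the two reads of a pair starting at opposite ends, each beginning with
its gene-specific primer (GSP) verbatim, and overlapping the insert
completely or nearly so. Reads longer than primer + insert run into the
flank/adapter; reads shorter cover only part of the insert. The caller is
only meaningful for data with this geometry: primers retained in reads and
near-complete pair overlap.

## Tile binning

Tiles and primers come from two headerless TSVs (see README). **Tile
coordinates are interpreted as 1-based inclusive** — the convention is not
implied by the file format itself, so it is fixed here once: `start..end`
spans `end − start + 1` bases, matching VCF's coordinate convention.

The index maps the first *N* bases of each primer to its tile and
orientation. *N* defaults to the shortest primer length and must not exceed
it. Prefix matching is exact: it tolerates no mismatches, so any sequencing
or synthesis error within the first *N* bases unassigns the pair — this is a
design feature (5′ read ends are the most accurate), not a limitation to
engineer around. Two primers sharing a prefix at length *N* make binning
ambiguous, so index construction fails loudly rather than letting the last
writer win; likewise a primer with `N` inside its hashed prefix is rejected,
because an exact-match hash can never match it.

A pair is bound only when both mates hash to the same tile in complementary
orientations; mate 1 is not assumed to be the forward read. Binding at pair
level (rather than binning the two FASTQ files independently and re-pairing
within tiles) is safe because the i-th records of the two files are mates by
FASTQ convention, and it removes any re-matching ambiguity. The full primer
is trimmed — not merely the hashed prefix — since bases under a primer
reproduce the oligo, not the template, and must never support a call. Reads
are truncated at the insert length before comparison to drop adapter
read-through.

## Comparison and the gapped fallback

Most reads are identical to the reference or differ by one substitution, so
an index-by-index linear scan handles the common case in O(n):

* **thorough** mode resolves scans with ≤ 1 mismatch; ≥ 2 trigger fallback.
* **fast** mode accepts any number of mismatches as independent SNVs
  *provided every two consecutive mismatches are separated by more than
  `fast_gap` bases* (default 2); closer-spaced mismatches trigger fallback.
  The rationale: clustered mismatches are the signature of an indel shifting
  the reading frame, and only those need the expensive alignment. The
  spacing comparison direction (strictly more than `fast_gap` intervening
  bases to accept) is this package's documented choice.

The fallback is a global affine-gap alignment (Needleman–Wunsch style, via
Bio.Align.PairwiseAligner). Default scores: match +2, mismatch −1, gap open
−5, gap extend −0.5 (a gap of length L costs open + (L−1)·extend), all
configurable. These defaults are declared, not derived: they are chosen so a
single substitution (−1) is always cheaper than a gap pair (≤ −10), hence
isolated SNVs never become spurious indels. The end of the read opposite its
primer anchor gets free end gaps, so reference overhang from a short read is
truncation, not a deletion; the primer-anchored end is not free, because the
read's start position is fixed by construction.

Aligned columns convert to variants in reference coordinates: substitution
columns to SNVs, runs of adjacent gap columns to single indel events with a
1-base anchor (VCF convention). Indels are left-aligned within the tile; an
event shifted to the tile's 5′ edge anchors on the last base of the forward
primer, which is by panel design the plus-strand reference base at
`start − 1`. Normalization never reaches further left than that. Among
co-optimal alignments the aligner's canonical traceback is taken; since
equivalent indel placements collapse to the same left-normalized variant,
the output is deterministic and placement-independent.

Masked bases (below the `--qual-threshold` Phred score, replaced by `N`)
never mismatch in the linear scan, are substitution-neutral in the
alignment, and never yield variants. Masking is applied after binning —
prefix matching is exact on raw bases — and after the overlap/anchor
filters, immediately before comparison.

## Calling rules

Per tile and sample, with defaults in parentheses:

| parameter | default | meaning |
|---|---|---|
| `min_overlap_frac` | 0.90 | fraction of the tile each mate must cover |
| `anchor_enabled` / `anchor_len` | off / 30 | exact post-primer match of ≥1 mate |
| `min_abs_pairs` | 2 | minimum concordant pair count |
| `min_prop_pairs` | 0.05 | minimum fraction of surviving pairs |
| `qual_threshold` | 0 (off) | Phred masking threshold |

The anchor check passes when *either* mate's window matches, so a true
variant inside one window is still callable unless both windows are dirty.
Depth is the number of pairs surviving the overlap and anchor filters; pairs
they discard contribute to neither numerator nor denominator. Both frequency
comparisons are **inclusive (≥)** — "at the threshold" passes — a semantics
this package fixes explicitly because "above a minimum" is ambiguous.
Sub-threshold variants are written with `at`/`pt` FILTER labels rather than
dropped, so the evidence trail is complete. Concordance is exact: the same
chrom/pos/ref/alt from both mates. A locus where the mates disagree on the
allele contributes nothing, and a variant masked on one mate cannot be
concordant. The thresholds are deliberately monotone: raising either can
only demote calls, never promote them.

Defaults for `min_abs_pairs` and `min_prop_pairs` are this package's
declared values; they are the knobs a user should tune to their panel depth
and expected allele fractions.

## Genotyping model

For an SNV with reference allele R and alternate A, candidates are {R/R,
R/A, A/A} (diploid, default) or {R, A} (haploid). Under a candidate, a
read's base is drawn uniformly from the genotype's alleles, then corrupted
with constant probability *e* (default 1/500) to one of the other three
bases uniformly — so hom-R at the default expects {R: 0.998, each other:
0.002/3}. Candidates are scored against the observed pileup with the
G statistic `2·Σ O·ln(O/(n·E))` (zero-count terms contribute 0; an observed
base with zero expected probability makes the candidate infinitely distant,
which only occurs at *e* = 0). The argmin wins; exact ties prefer the
reference-heavier genotype. Non-ref/non-alt bases are not candidate alleles;
the raw G value is reported rather than a calibrated quality.

Pileups count one base per read pair, and only where both mates agree on an
unmasked base; pairs carrying an indel in the tile are excluded because
their read coordinates are shifted relative to the reference. Genotyping is
opt-in (`--genotype`) and SNV-only.

## Output

One multi-sample VCF 4.2 (samples are called independently and merged at
write time; one column per FASTQ pair). Site FILTER is PASS when the
variant passes in at least one sample, else the union of per-sample labels;
per-sample evidence lives in FORMAT fields (DP, PC, VP, and GT/GS when
genotyped); samples without the call show missing GT and zero counts. QUAL
is left missing — the method defines no site quality score. The coverage
TSV has one row per sample × tile with counts along the filter chain, and
the run log echoes configuration and per-sample totals
(seen = matched + unassigned). Timestamped header lines are the only
non-deterministic output bytes.

## Simulator

`ampcall.simulate` generates the structure the caller assumes: a random
reference chromosome with non-overlapping tiles (defaults: 10 tiles of
100 nt, 20 nt primers — typical short-amplicon geometry), primers that are
verbatim reference flanks, fully overlapping 150 nt read pairs with adapter
read-through, constant per-base substitution error (default 0.001, the
right order for modern short-read platforms), per-pair Bernoulli sampling
of planted variants at their VAF (an exact-count mode exists for threshold
boundary tests), an optional off-panel read fraction, and constant Phred-40
qualities with an optional low-quality tail to exercise masking. Everything
is deterministic per seed, and a truth VCF records the planted variants.

It does **not** model PCR duplicates or jackpotting, indel sequencing
errors, quality-dependent error profiles, primer-synthesis errors, or
cross-sample contamination. Passing tests on simulated data therefore
demonstrates algorithmic correctness under the stated read model, not
robustness to those real-data phenomena.

Default study conditions used by the test suite and the acceptance script:
panels of 10 × 100 bp tiles, 3 samples, depth 100 pairs per tile, per-base
error 0.001, variants planted at VAF 0.5 and 1.0 (3 SNVs + 2 indels of
1–3 bp per sample), evaluated over 20 independent seeds in the test suite
and 10 in the acceptance script; comparison-level checks use 1,000 random
substitution pairs and 500 planted indels of 1–5 bp on 60 nt inserts. These
sizes keep a full run in the order of seconds to a few minutes while giving
binomially tight margins on the reported rates.

## Degenerate inputs and edge behavior

* Empty panel → configuration error (nothing to call); a tile with zero
  bound pairs is reported in the coverage TSV with zeros, not omitted.
* FASTQ pairs with unequal record counts, malformed records, or mate-ID
  disagreement are fatal; unassigned pairs are data and are only counted.
* `start > end` tiles, duplicate primer names/pairs, non-ACGTN primer
  characters, missing chromosomes, and prefix collisions are all fatal at
  parse/index time with the offending line or primer named.
* Variants are confined to tile coordinates (anchor may sit at
  `start − 1`); alignment columns from read truncation yield no variants.
* Proportions at zero depth are defined as 0; zero-depth tiles produce no
  calls.

## Known limitations

* The linear scan and concordance operate per pair; there is no joint
  multi-allelic model, no strand-bias statistic beyond concordance itself,
  and no somatic (tumor/normal) mode.
* Indels are not genotyped, and genotype likelihoods (PL/GL) are not
  emitted.
* Fuzzy primer matching is intentionally absent; panels whose primers
  collide within the chosen prefix length must pick a longer prefix or
  redesign primers.
* Alignment is full Needleman–Wunsch per fallback read; for panels with
  pervasive indels this is the dominant cost (the linear scan exists
  precisely to avoid it in the common case).
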