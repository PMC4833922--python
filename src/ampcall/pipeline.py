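"""End-to-end orchestration: index once, call each sample independently.

The per-sample flow is: stream FASTQ pairs -> bin by primer prefix ->
overlap filter -> optional anchor filter -> quality masking -> per-pair
comparison and pair concordance -> per-tile frequency thresholds -> optional
G-test genotyping of SNVs. Samples never see each other's reads, so calls
for one sample are invariant to the others.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pyfaidx

from .calling import CallingThresholds, VariantCall, anchor_ok, call_tile, \
    concordant_variants, overlap_ok
from .compare import AlignScoring, CompareMode, Variant
from .errors import ConfigError
from .genotype import GenotypeModel, Pileup, genotype_call
from .outputs import CoverageRecord, write_coverage, write_run_log, write_vcf
from .panel import Tile, TileIndex, build_tile_index, parse_primer_coords, \
    parse_primer_sequences
from .reads import BoundPair, bin_pair, mask_low_quality, stream_pairs


@dataclass
class SampleStats:
    sample: str
    pairs_seen: int = 0
    pairs_bound: int = 0
    pairs_unassigned: int = 0
    pairs_overlap_failed: int = 0
    pairs_anchor_failed: int = 0
    depth_total: int = 0

    def as_dict(self) -> Dict[str, object]:
        return {
            "sample": self.sample,
            "pairs_seen": self.pairs_seen,
            "pairs_bound": self.pairs_bound,
            "pairs_unassigned": self.pairs_unassigned,
            "pairs_overlap_failed": self.pairs_overlap_failed,
            "pairs_anchor_failed": self.pairs_anchor_failed,
            "depth_total": self.depth_total,
        }


@dataclass
class SampleResult:
    sample: str
    calls: List[VariantCall]
    coverage: List[CoverageRecord]
    stats: SampleStats


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one caller invocation."""

    primer_coords: str
    primer_sequences: str
    reference: str
    fastq_pairs: Sequence[Tuple[str, str]]
    out_vcf: str
    coverage_out: Optional[str] = None
    log_out: Optional[str] = None
    prefix_len: int = 0  # 0 = use the shortest primer length
    mode: CompareMode = CompareMode()
    scoring: AlignScoring = AlignScoring()
    thresholds: CallingThresholds = CallingThresholds()
    genotype: bool = False
    ploidy: int = 2
    error_rate: float = 1 / 500
    command: Optional[str] = None


def _pileup_at(
    pairs: Sequence[Tuple[BoundPair, Sequence[Variant]]],
    tile: Tile,
    pos: int,
) -> Pileup:
    """One base per pair, counted only when both mates agree on a non-masked
    base at the position; pairs carrying an indel in this tile are skipped
    because their read coordinates are shifted relative to the reference."""
    counts = {b: 0 for b in "ACGT"}
    off = pos - tile.spec.start
    for bound, variants in pairs:
        if any(not v.is_snv for v in variants):
            continue
        fwd = bound.insert_fwd
        rev = bound.insert_rev
        rev_off = off - rev.ref_offset(tile.insert_len)
        if off >= len(fwd.bases) or rev_off < 0 or rev_off >= len(rev.bases):
            continue
        b1, b2 = fwd.bases[off], rev.bases[rev_off]
        if b1 != b2 or b1 not in counts:
            continue
        counts[b1] += 1
    return Pileup(position=pos, counts=counts)


def call_sample(
    sample: str,
    fastq1: str,
    fastq2: str,
    index: TileIndex,
    thresholds: CallingThresholds = CallingThresholds(),
    mode: CompareMode = CompareMode(),
    scoring: AlignScoring = AlignScoring(),
    genotype_model: Optional[GenotypeModel] = None,
) -> SampleResult:
    """Call variants for one sample's FASTQ pair."""
    stats = SampleStats(sample=sample)
    by_tile: Dict[str, List[BoundPair]] = {}
    tiles: Dict[str, Tile] = {t.key: t for t in index.tiles}
    for pair in stream_pairs(fastq1, fastq2):
        stats.pairs_seen += 1
        bound = bin_pair(pair, index)
        if bound is None:
            stats.pairs_unassigned += 1
            continue
        stats.pairs_bound += 1
        by_tile.setdefault(bound.tile.key, []).append(bound)

    calls: List[VariantCall] = []
    coverage: List[CoverageRecord] = []
    for key, tile in tiles.items():
        bound_pairs = by_tile.get(key, [])
        overlap_pass = [b for b in bound_pairs if overlap_ok(b, thresholds)]
        stats.pairs_overlap_failed += len(bound_pairs) - len(overlap_pass)
        if thresholds.anchor_enabled:
            anchor_pass = [b for b in overlap_pass if anchor_ok(b, thresholds)]
        else:
            anchor_pass = overlap_pass
        stats.pairs_anchor_failed += len(overlap_pass) - len(anchor_pass)
        masked = [
            mask_low_quality(b, thresholds.qual_threshold) for b in anchor_pass
        ]
        depth = len(masked)
        stats.depth_total += depth
        coverage.append(
            CoverageRecord(
                sample=sample,
                tile_key=key,
                bound_pairs=len(bound_pairs),
                overlap_pass=len(overlap_pass),
                anchor_pass=len(anchor_pass),
                depth=depth,
            )
        )
        if depth == 0:
            continue
        per_pair = [
            (b, concordant_variants(b, mode, scoring)) for b in masked
        ]
        tile_calls = call_tile(per_pair, depth, thresholds, tile=tile)
        if genotype_model is not None:
            tile_calls = [
                _genotype_snv(call, per_pair, tile, genotype_model)
                for call in tile_calls
            ]
        calls.extend(tile_calls)
    calls.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.ref,
                              c.variant.alt))
    return SampleResult(sample=sample, calls=calls, coverage=coverage, stats=stats)


def _genotype_snv(
    call: VariantCall,
    per_pair: Sequence[Tuple[BoundPair, Sequence[Variant]]],
    tile: Tile,
    model: GenotypeModel,
) -> VariantCall:
    from dataclasses import replace

    if not call.variant.is_snv:
        return call
    pileup = _pileup_at(per_pair, tile, call.variant.pos)
    if pileup.total < 1:
        return call
    result = genotype_call(pileup, call.variant.ref, call.variant.alt, model)
    return replace(call, genotype=result)


def sample_name_from_fastq(path: str) -> str:
    name = os.path.basename(path)
    for ext in (".gz", ".fastq", ".fq"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    for suffix in ("_r1", "_R1", "_1", ".r1", ".R1"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return name


def run(config: RunConfig) -> List[SampleResult]:
    """Execute a full calling run and write the VCF, coverage TSV and log."""
    for path in (config.primer_coords, config.primer_sequences, config.reference):
        if not os.path.exists(path):
            raise ConfigError(f"input file not found: {path}")
    for f1, f2 in config.fastq_pairs:
        for path in (f1, f2):
            if not os.path.exists(path):
                raise ConfigError(f"FASTQ file not found: {path}")
    if not config.fastq_pairs:
        raise ConfigError("no FASTQ pairs supplied")

    specs = parse_primer_coords(config.primer_coords)
    primers = parse_primer_sequences(config.primer_sequences)
    reference = pyfaidx.Fasta(config.reference)
    prefix_len = config.prefix_len
    if prefix_len <= 0:
        used = {
            name
            for s in specs
            for name in (s.fwd_name, s.rev_name)
            if name in primers
        }
        if not used:
            raise ConfigError("panel is empty; nothing to call")
        prefix_len = min(len(primers[n].sequence) for n in used)
    index = build_tile_index(specs, primers, reference, prefix_len)

    genotype_model = (
        GenotypeModel(ploidy=config.ploidy, error_rate=config.error_rate)
        if config.genotype
        else None
    )

    results: List[SampleResult] = []
    seen_names: Dict[str, int] = {}
    for f1, f2 in config.fastq_pairs:
        name = sample_name_from_fastq(f1)
        if name in seen_names:
            seen_names[name] += 1
            name = f"{name}.{seen_names[name]}"
        else:
            seen_names[name] = 1
        results.append(
            call_sample(
                name, f1, f2, index,
                thresholds=config.thresholds,
                mode=config.mode,
                scoring=config.scoring,
                genotype_model=genotype_model,
            )
        )

    contigs = [(name, len(reference[name])) for name in reference.keys()]
    write_vcf(
        calls_by_sample={r.sample: r.calls for r in results},
        sample_names=[r.sample for r in results],
        path=config.out_vcf,
        contigs=contigs,
        reference_path=os.path.abspath(config.reference),
        command=config.command,
    )
    if config.coverage_out:
        write_coverage(
            [rec for r in results for rec in r.coverage], config.coverage_out
        )
    if config.log_out:
        echo = {
            "primer_coords": config.primer_coords,
            "primer_sequences": config.primer_sequences,
            "reference": config.reference,
            "out_vcf": config.out_vcf,
            "prefix_len": prefix_len,
            "mode": config.mode.mode,
            "fast_gap": config.mode.fast_gap,
            "min_overlap_frac": config.thresholds.min_overlap_frac,
            "anchor_enabled": config.thresholds.anchor_enabled,
            "anchor_len": config.thresholds.anchor_len,
            "min_abs_pairs": config.thresholds.min_abs_pairs,
            "min_prop_pairs": config.thresholds.min_prop_pairs,
            "qual_threshold": config.thresholds.qual_threshold,
            "genotype": config.genotype,
            "ploidy": config.ploidy,
            "error_rate": config.error_rate,
        }
        write_run_log(config.log_out, echo, [r.stats.as_dict() for r in results])
    return results
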