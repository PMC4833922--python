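"""Result writers: multi-sample VCF, per-amplicon coverage TSV, run log.

Samples are called independently and merged at write time into one
multi-sample VCF (one column per FASTQ pair). A record's site-level FILTER is
PASS when the variant passes in at least one sample, otherwise the union of
the per-sample failure labels. Per-sample evidence travels in FORMAT fields;
samples without the call show a missing genotype and zero evidence.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pysam

from .calling import VariantCall
from .compare import Variant

VCF_FORMAT_FIELDS = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,'
    'Description="Read pairs overlapping the tile after filters">',
    '##FORMAT=<ID=PC,Number=1,Type=Integer,'
    'Description="Concordant read pairs carrying the variant">',
    '##FORMAT=<ID=VP,Number=1,Type=Float,'
    'Description="Proportion of overlapping pairs carrying the variant">',
    '##FORMAT=<ID=GS,Number=1,Type=Float,'
    'Description="G statistic of the called genotype (smaller is better)">',
)
VCF_FILTER_FIELDS = (
    '##FILTER=<ID=at,Description='
    '"Variant-pair count below the minimum absolute threshold">',
    '##FILTER=<ID=pt,Description='
    '"Variant-pair proportion below the minimum fraction of overlapping pairs">',
)


@dataclass(frozen=True)
class CoverageRecord:
    """Per (sample, tile) accounting along the filter chain."""

    sample: str
    tile_key: str
    bound_pairs: int
    overlap_pass: int
    anchor_pass: int
    depth: int


def _build_header(
    sample_names: Sequence[str],
    contigs: Sequence[Tuple[str, int]],
    reference_path: Optional[str],
    command: Optional[str],
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=ampcall")
    header.add_line(
        f"##fileDate={datetime.date.today().strftime('%Y%m%d')}"
    )
    if reference_path:
        header.add_line(f"##reference=file://{reference_path}")
    if command:
        header.add_line(f"##ampcall_command={command}")
    for name, length in contigs:
        header.contigs.add(name, length=length)
    for line in VCF_FILTER_FIELDS + VCF_FORMAT_FIELDS:
        header.add_line(line)
    for sample in sample_names:
        header.add_sample(sample)
    return header


def write_vcf(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    sample_names: Sequence[str],
    path: str,
    contigs: Sequence[Tuple[str, int]],
    reference_path: Optional[str] = None,
    command: Optional[str] = None,
) -> None:
    """Write one multi-sample VCF 4.x file of the merged calls.

    Records are sorted by (reference contig order, position, ref, alt);
    identical variants reported twice within one sample (possible only at a
    tile boundary) are merged by summing their evidence, never duplicated.
    """
    header = _build_header(sample_names, contigs, reference_path, command)
    contig_rank = {name: i for i, (name, _len) in enumerate(contigs)}

    per_sample: Dict[str, Dict[Variant, VariantCall]] = {}
    all_variants: Dict[Variant, None] = {}
    for sample in sample_names:
        merged: Dict[Variant, VariantCall] = {}
        for call in calls_by_sample.get(sample, ()):
            existing = merged.get(call.variant)
            if existing is not None:
                merged[call.variant] = VariantCall(
                    variant=call.variant,
                    pair_count=existing.pair_count + call.pair_count,
                    depth=existing.depth + call.depth,
                    filters=existing.filters | call.filters,
                    genotype=existing.genotype or call.genotype,
                    tile_key=existing.tile_key,
                )
            else:
                merged[call.variant] = call
            all_variants[call.variant] = None
        per_sample[sample] = merged

    ordered = sorted(
        all_variants,
        key=lambda v: (contig_rank.get(v.chrom, len(contig_rank)), v.pos, v.ref, v.alt),
    )
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for variant in ordered:
            rec = vcf.new_record(
                contig=variant.chrom,
                start=variant.pos - 1,
                alleles=(variant.ref, variant.alt),
            )
            rec.id = None
            site_filters: set = set()
            any_pass = False
            for sample in sample_names:
                call = per_sample[sample].get(variant)
                fmt = rec.samples[sample]
                if call is None:
                    fmt["DP"] = 0
                    fmt["PC"] = 0
                    fmt["VP"] = 0.0
                    continue
                fmt["DP"] = call.depth
                fmt["PC"] = call.pair_count
                fmt["VP"] = round(call.proportion, 6)
                if call.genotype is not None:
                    fmt["GT"] = call.genotype.gt_indices
                    fmt["GS"] = round(call.genotype.g_statistic, 6)
                if call.passed:
                    any_pass = True
                else:
                    site_filters |= call.filters
            if any_pass or not site_filters:
                rec.filter.add("PASS")
            else:
                for label in sorted(site_filters):
                    rec.filter.add(label)
            vcf.write(rec)


def write_coverage(records: Sequence[CoverageRecord], path: str) -> None:
    """Headered TSV, one row per (sample, tile), stable column order."""
    columns = (
        "sample", "tile", "bound_pairs", "overlap_pass", "anchor_pass", "depth",
    )
    with open(path, "w") as handle:
        handle.write("\t".join(columns) + "\n")
        for r in records:
            handle.write(
                f"{r.sample}\t{r.tile_key}\t{r.bound_pairs}\t"
                f"{r.overlap_pass}\t{r.anchor_pass}\t{r.depth}\n"
            )


def read_coverage(path: str) -> List[CoverageRecord]:
    records: List[CoverageRecord] = []
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            sample, tile, bound, opass, apass, depth = line.rstrip("\n").split("\t")
            records.append(
                CoverageRecord(
                    sample=sample,
                    tile_key=tile,
                    bound_pairs=int(bound),
                    overlap_pass=int(opass),
                    anchor_pass=int(apass),
                    depth=int(depth),
                )
            )
    return records


def write_run_log(
    path: str,
    config_echo: Mapping[str, object],
    sample_stats: Sequence[Mapping[str, object]],
) -> None:
    """Plain-text run log: timestamp, configuration echo, per-sample totals."""
    with open(path, "w") as handle:
        handle.write(
            f"# ampcall run log  {datetime.datetime.now().isoformat()}\n"
        )
        handle.write("[configuration]\n")
        for key, value in config_echo.items():
            handle.write(f"{key} = {value}\n")
        for stats in sample_stats:
            handle.write(f"[sample {stats['sample']}]\n")
            for key, value in stats.items():
                if key != "sample":
                    handle.write(f"{key} = {value}\n")
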