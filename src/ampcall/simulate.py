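"""Synthetic amplicon panels and reads with planted variants and truth VCFs.

The generator reproduces the statistical structure the caller assumes: a
reference chromosome carrying non-overlapping ~100 bp tiles, gene-specific
primers that are verbatim reference flanks (forward = plus-strand 5' flank,
reverse = reverse complement of the 3' flank), and fully overlapping read
pairs whose 5' ends start with the primer and whose 3' ends may read through
into a universal adapter. Sequencing noise is independent per-base
substitution at a constant rate; qualities are constant high by default with
an optional low-quality tail to exercise masking. Everything is deterministic
per seed.

What it does not emulate: PCR duplicates/jackpotting, indel sequencing
errors, platform-specific quality profiles, or primer synthesis errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .compare import Variant
from .errors import ConfigError
from .panel import PrimerSeq, Tile, TileSpec
from .reads import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"  # universal adapter read-through
HIGH_QUAL_CHAR = "I"  # Phred 40


@dataclass(frozen=True)
class PanelConfig:
    """Geometry of a synthetic panel (defaults mirror typical short-amplicon
    panels: ~100 nt tiles with 20 nt gene-specific primers)."""

    n_tiles: int = 10
    insert_len: int = 100
    primer_len: int = 20
    chrom: str = "chrSim"
    spacer_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiles < 0 or self.insert_len < 1 or self.primer_len < 1:
            raise ConfigError("panel geometry values must be positive")


@dataclass(frozen=True)
class Panel:
    """An in-memory panel: reference plus the two TSV dialects' content."""

    reference: Dict[str, str]
    specs: List[TileSpec]
    primers: Dict[str, PrimerSeq]
    config: PanelConfig

    @property
    def tiles(self) -> List[Tile]:
        out = []
        for spec in self.specs:
            seq = self.reference[spec.chrom]
            out.append(
                Tile(
                    spec=spec,
                    insert_ref=seq[spec.start - 1 : spec.end],
                    fwd_primer=self.primers[spec.fwd_name],
                    rev_primer=self.primers[spec.rev_name],
                )
            )
        return out


@dataclass(frozen=True)
class PlantedVariant:
    """A truth-set entry: a variant planted in one sample at a given VAF."""

    variant: Variant
    vaf: float
    sample: str

    def __post_init__(self) -> None:
        if not 0 < self.vaf <= 1:
            raise ConfigError(f"VAF must be in (0, 1], got {self.vaf}")


@dataclass(frozen=True)
class ReadSimConfig:
    depth: int = 100
    error_rate: float = 0.001
    read_len: int = 150
    off_panel_fraction: float = 0.0
    exact_counts: bool = False  # round(VAF*depth) carriers instead of Bernoulli
    low_qual_tail: int = 0  # length of Phred-2 tail on each read
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if not 0 <= self.off_panel_fraction < 1:
            raise ConfigError("off_panel_fraction must be in [0, 1)")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_panel(config: PanelConfig = PanelConfig()) -> Panel:
    """Generate a reference chromosome with embedded tiles and flank primers.

    Primer sequences are the true reference flanks, so reads built from the
    reference begin with them verbatim. All 2*n_tiles primer prefixes are
    unique at every length up to primer_len (enforced at full primer length
    by rejection sampling on a short prefix).
    """
    rng = np.random.default_rng(config.seed)
    check_n = min(config.primer_len, 10)
    prefixes: set = set()
    segments: List[str] = []
    specs: List[TileSpec] = []
    primers: Dict[str, PrimerSeq] = {}
    pos = 1  # next unwritten 1-based position

    def unique_flank(is_reverse: bool) -> str:
        # reject until the primer's *read-facing* prefix is unique
        for _ in range(1000):
            flank = _random_seq(rng, config.primer_len)
            oligo = revcomp(flank) if is_reverse else flank
            key = oligo[:check_n]
            if key not in prefixes:
                prefixes.add(key)
                return flank
        raise ConfigError(
            "could not generate unique primer prefixes; "
            "reduce n_tiles or increase primer_len"
        )

    for i in range(config.n_tiles):
        spacer = _random_seq(rng, config.spacer_len)
        fwd_flank = unique_flank(is_reverse=False)
        insert = _random_seq(rng, config.insert_len)
        rev_flank = unique_flank(is_reverse=True)
        segments.extend([spacer, fwd_flank, insert, rev_flank])
        pos += config.spacer_len + config.primer_len
        start, end = pos, pos + config.insert_len - 1
        pos = end + 1 + config.primer_len
        fwd_name, rev_name = f"T{i + 1}_F", f"T{i + 1}_R"
        specs.append(TileSpec(config.chrom, start, end, fwd_name, rev_name))
        primers[fwd_name] = PrimerSeq(fwd_name, fwd_flank)
        primers[rev_name] = PrimerSeq(rev_name, revcomp(rev_flank))
    segments.append(_random_seq(rng, config.spacer_len))
    reference = {config.chrom: "".join(segments)}
    return Panel(reference=reference, specs=specs, primers=primers, config=config)


def write_panel(panel: Panel, ref_path: str, coords_path: str, seqs_path: str) -> None:
    """Write the panel to FASTA + the two TSV dialects the parsers consume."""
    from .panel import write_primer_coords, write_primer_sequences

    with open(ref_path, "w") as handle:
        for chrom, seq in panel.reference.items():
            handle.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
    write_primer_coords(panel.specs, coords_path)
    write_primer_sequences(list(panel.primers.values()), seqs_path)


def random_truth(
    panel: Panel,
    samples: Sequence[str],
    rng: np.random.Generator,
    vafs: Sequence[float] = (0.5, 1.0),
    snv_per_sample: int = 3,
    indel_per_sample: int = 2,
    max_indel_len: int = 3,
    edge_margin: int = 10,
) -> List[PlantedVariant]:
    """Plant random SNVs and short indels, at most one variant per tile per
    sample, away from tile edges so overlap filters are untouched."""
    truth: List[PlantedVariant] = []
    tiles = panel.tiles
    for sample in samples:
        n_wanted = snv_per_sample + indel_per_sample
        if n_wanted > len(tiles):
            raise ConfigError("more variants requested than tiles available")
        chosen = rng.choice(len(tiles), size=n_wanted, replace=False)
        kinds = ["SNV"] * snv_per_sample + ["indel"] * indel_per_sample
        for tile_i, kind in zip(chosen, kinds):
            tile = tiles[tile_i]
            lo = tile.spec.start + edge_margin
            hi = tile.spec.end - edge_margin - max_indel_len - 1
            pos = int(rng.integers(lo, hi + 1))
            ref_base = tile.insert_ref[pos - tile.spec.start]
            vaf = float(vafs[int(rng.integers(len(vafs)))])
            if kind == "SNV":
                alt = str(
                    rng.choice([b for b in "ACGT" if b != ref_base])
                )
                var = Variant(tile.spec.chrom, pos, ref_base, alt)
            else:
                length = int(rng.integers(1, max_indel_len + 1))
                if rng.random() < 0.5:  # deletion
                    deleted = tile.insert_ref[
                        pos - tile.spec.start + 1 : pos - tile.spec.start + 1 + length
                    ]
                    var = Variant(
                        tile.spec.chrom, pos, ref_base + deleted, ref_base
                    )
                else:  # insertion
                    var = Variant(
                        tile.spec.chrom,
                        pos,
                        ref_base,
                        ref_base + _random_seq(rng, length),
                    )
            var = _normalize_in_tile(var, tile)
            truth.append(PlantedVariant(variant=var, vaf=vaf, sample=sample))
    return truth


def _normalize_in_tile(var: Variant, tile: Tile) -> Variant:
    """Left-normalize a planted indel so truth matches caller output form."""
    from .compare import left_normalize

    if var.is_snv:
        return var

    def get_base(p: int):
        if p == tile.spec.start - 1:
            return tile.fwd_primer.sequence[-1]
        if tile.spec.start <= p <= tile.spec.end:
            return tile.insert_ref[p - tile.spec.start]
        return None

    pos, ref, alt = left_normalize(
        var.pos, var.ref, var.alt, get_base, tile.spec.start - 1
    )
    return Variant(var.chrom, pos, ref, alt)


def _apply_variants(tile: Tile, variants: Sequence[Variant]) -> str:
    """Apply variants (non-overlapping, sorted) to the tile's insert."""
    seq = tile.insert_ref
    for var in sorted(variants, key=lambda v: v.pos, reverse=True):
        off = var.pos - tile.spec.start
        if off == -1:
            # anchored on the last forward-primer base just 5' of the tile
            seq = var.alt[1:] + seq[len(var.ref) - 1:]
        elif off < -1:
            raise ConfigError(f"variant {var} anchored outside its tile")
        else:
            assert seq[off : off + len(var.ref)] == tile.insert_ref[
                off : off + len(var.ref)
            ]
            seq = seq[:off] + var.alt + seq[off + len(var.ref):]
    return seq


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _qual_string(read_len: int, low_tail: int) -> str:
    if low_tail <= 0:
        return HIGH_QUAL_CHAR * read_len
    head = max(read_len - low_tail, 0)
    return HIGH_QUAL_CHAR * head + "#" * (read_len - head)  # '#' = Phred 2


def simulate_reads(
    panel: Panel,
    truth: Sequence[PlantedVariant],
    config: ReadSimConfig,
    samples: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]]]]:
    """Simulate paired reads per sample.

    Returns ``{sample: (records1, records2)}`` where each record is an
    ``(id, bases, quals)`` FASTQ triple. Per pair, each planted variant on
    the pair's tile is included with probability VAF (or for an exact
    ``round(VAF * depth)`` count of pairs in exact-counts mode); the fragment
    is ``fwd_primer + insert' + revcomp(rev_primer) + adapter``; read 1 is
    its 5' prefix and read 2 the reverse complement's 5' prefix; independent
    per-base substitution errors are applied to each read.
    """
    if samples is None:
        samples = sorted({t.sample for t in truth}) or ["sample1"]
    tiles = panel.tiles
    if tiles:
        min_read = panel.config.primer_len + 1
        if config.read_len < min_read:
            raise ConfigError(
                f"read_len {config.read_len} shorter than primer + 1 base"
            )
    rng = np.random.default_rng(config.seed)
    out: Dict[str, Tuple[list, list]] = {}
    for sample in samples:
        recs1: List[Tuple[str, str, str]] = []
        recs2: List[Tuple[str, str, str]] = []
        sample_truth = [t for t in truth if t.sample == sample]
        serial = 0
        for tile in tiles:
            tile_truth = [
                t
                for t in sample_truth
                if tile.spec.start - 1 <= t.variant.pos <= tile.spec.end
                and t.variant.chrom == tile.spec.chrom
            ]
            carrier_flags: Dict[int, np.ndarray] = {}
            for vi, t in enumerate(tile_truth):
                if config.exact_counts:
                    k = int(round(t.vaf * config.depth))
                    flags = np.zeros(config.depth, dtype=bool)
                    flags[:k] = True
                    rng.shuffle(flags)
                else:
                    flags = rng.random(config.depth) < t.vaf
                carrier_flags[vi] = flags
            for d in range(config.depth):
                serial += 1
                rid = f"{sample}:{tile.spec.fwd_name}:{serial}"
                if rng.random() < config.off_panel_fraction:
                    core = _random_seq(
                        rng, 2 * panel.config.primer_len + panel.config.insert_len
                    )
                    rid += ":offpanel"
                else:
                    carried = [
                        t.variant
                        for vi, t in enumerate(tile_truth)
                        if carrier_flags[vi][d]
                    ]
                    insert = _apply_variants(tile, carried)
                    core = (
                        tile.fwd_primer.sequence
                        + insert
                        + revcomp(tile.rev_primer.sequence)
                    )
                # each read starts at its primer end; long reads run into
                # the universal adapter beyond the fragment
                r1 = _add_errors(
                    (core + ADAPTER)[: config.read_len], config.error_rate, rng
                )
                r2 = _add_errors(
                    (revcomp(core) + ADAPTER)[: config.read_len],
                    config.error_rate, rng,
                )
                q1 = _qual_string(len(r1), config.low_qual_tail)
                q2 = _qual_string(len(r2), config.low_qual_tail)
                recs1.append((rid + "/1", r1, q1))
                recs2.append((rid + "/2", r2, q2))
        out[sample] = (recs1, recs2)
    return out


def write_fastq(records: Sequence[Tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as handle:
        for rid, bases, quals in records:
            handle.write(f"@{rid}\n{bases}\n+\n{quals}\n")


def write_truth_vcf(
    truth: Sequence[PlantedVariant], panel: Panel, path: str
) -> None:
    """Write the planted variants as a minimal multi-sample truth VCF."""
    samples = sorted({t.sample for t in truth})
    by_variant: Dict[Variant, Dict[str, float]] = {}
    for t in truth:
        by_variant.setdefault(t.variant, {})[t.sample] = t.vaf
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for chrom, seq in panel.reference.items():
            handle.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        handle.write(
            '##FORMAT=<ID=VF,Number=1,Type=Float,'
            'Description="Planted variant allele fraction">\n'
        )
        cols = "\t".join(samples)
        handle.write(
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n"
        )
        for var in sorted(by_variant):
            fields = [
                var.chrom, str(var.pos), ".", var.ref, var.alt, ".", "PASS",
                ".", "VF",
            ]
            for s in samples:
                vaf = by_variant[var].get(s)
                fields.append("." if vaf is None else f"{vaf:g}")
            handle.write("\t".join(fields) + "\n")
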