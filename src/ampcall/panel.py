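"""Primer panel metadata and the prefix hash that drives read binning.

An amplicon *tile* is a contiguous genomic interval flanked by a forward and a
reverse gene-specific primer. Because every sequencing read starts with the
primer that seeded its amplification, the first ``N`` bases of a read identify
its tile without any read mapping. This module parses the two tab-delimited
panel files, extracts each tile's reference insert from a FASTA, and builds
the hash table from length-``N`` primer prefixes to tiles.

Coordinate convention
---------------------
Tile start/end coordinates in the primer-coordinates file are **1-based,
inclusive at both ends** (the same convention VCF uses). The insert of a tile
spanning ``start..end`` therefore has length ``end - start + 1``.

File dialects
-------------
* primer coordinates: 5 tab-separated columns, no header:
  ``chrom  start  end  forward_primer_name  reverse_primer_name``
* primer sequences: 2 tab-separated columns, no header:
  ``primer_name  sequence`` (written 5'->3' as synthesized; the reverse
  primer is therefore the reverse complement of the plus strand immediately
  3' of the tile).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

from .errors import ConfigError, PanelError

FORWARD = "forward"
REVERSE = "reverse"

_VALID_PRIMER_CHARS = set("ACGTN")


@dataclass(frozen=True)
class TileSpec:
    """One line of the primer-coordinates file."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    fwd_name: str
    rev_name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PanelError(
                f"tile {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.fwd_name == self.rev_name:
            raise PanelError(
                f"tile {self.chrom}:{self.start}-{self.end}: forward and "
                f"reverse primer share the name {self.fwd_name!r}"
            )


@dataclass(frozen=True)
class PrimerSeq:
    """A named primer oligo, 5'->3' as synthesized."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PanelError(f"primer {self.name!r}: empty sequence")


@dataclass(frozen=True)
class Tile:
    """A tile spec joined with its primers and reference insert sequence."""

    spec: TileSpec
    insert_ref: str
    fwd_primer: PrimerSeq
    rev_primer: PrimerSeq

    @property
    def insert_len(self) -> int:
        return self.spec.end - self.spec.start + 1

    @property
    def key(self) -> str:
        s = self.spec
        return f"{s.chrom}:{s.start}-{s.end}({s.fwd_name}/{s.rev_name})"


@dataclass(frozen=True)
class TileIndex:
    """Hash table mapping length-``prefix_len`` primer prefixes to tiles.

    ``entries`` maps each prefix to ``(tile, orientation)`` where orientation
    is :data:`FORWARD` for forward primers and :data:`REVERSE` for reverse
    primers; the reverse entry points at the same :class:`Tile` object as its
    forward partner.
    """

    prefix_len: int
    entries: Mapping[str, Tuple[Tile, str]]

    @property
    def tiles(self) -> List[Tile]:
        seen: Dict[str, Tile] = {}
        for tile, _orient in self.entries.values():
            seen.setdefault(tile.key, tile)
        return list(seen.values())

    def lookup(self, prefix: str):
        return self.entries.get(prefix)


def parse_primer_coords(path: str) -> List[TileSpec]:
    """Parse the 5-column primer-coordinates TSV into :class:`TileSpec` records.

    Empty lines are skipped; line order is preserved. Raises
    :class:`PanelError` naming the offending line on malformed input.
    """
    specs: List[TileSpec] = []
    seen_pairs = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PanelError(
                    f"{path}:{lineno}: expected >=5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, fwd, rev = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise PanelError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            try:
                spec = TileSpec(chrom, start, end, fwd, rev)
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from None
            if (fwd, rev) in seen_pairs:
                raise PanelError(
                    f"{path}:{lineno}: duplicate primer pair ({fwd}, {rev})"
                )
            seen_pairs.add((fwd, rev))
            specs.append(spec)
    return specs


def parse_primer_sequences(path: str) -> Dict[str, PrimerSeq]:
    """Parse the 2-column primer-sequences TSV; sequences are upper-cased."""
    primers: Dict[str, PrimerSeq] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PanelError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            name, seq = fields[0], fields[1].upper()
            if name in primers:
                raise PanelError(f"{path}:{lineno}: duplicate primer name {name!r}")
            bad = set(seq) - _VALID_PRIMER_CHARS
            if bad:
                raise PanelError(
                    f"{path}:{lineno}: primer {name!r} contains invalid "
                    f"characters {sorted(bad)}"
                )
            try:
                primers[name] = PrimerSeq(name, seq)
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from None
    return primers


def write_primer_coords(specs: Iterable[TileSpec], path: str) -> None:
    with open(path, "w") as handle:
        for s in specs:
            handle.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.fwd_name}\t{s.rev_name}\n")


def write_primer_sequences(primers: Iterable[PrimerSeq], path: str) -> None:
    with open(path, "w") as handle:
        for p in primers:
            handle.write(f"{p.name}\t{p.sequence}\n")


def _fetch_insert(reference, chrom: str, start: int, end: int) -> str:
    """Extract [start, end] (1-based inclusive) from a FASTA-like object.

    Works with ``pyfaidx.Fasta`` and with a plain mapping of chromosome name
    to sequence string (used by the simulator before files hit disk).
    """
    try:
        record = reference[chrom]
    except KeyError:
        raise PanelError(f"chromosome {chrom!r} not found in reference") from None
    seq = str(record[start - 1 : end]).upper()
    if len(seq) != end - start + 1:
        raise PanelError(
            f"reference {chrom} too short for tile {start}-{end} "
            f"(got {len(seq)} bases)"
        )
    return seq


def build_tile_index(
    specs: List[TileSpec],
    primers: Mapping[str, PrimerSeq],
    reference,
    prefix_len: int,
) -> TileIndex:
    """Build the prefix hash table from panel metadata and the reference.

    ``prefix_len`` must be positive and no larger than the shortest primer in
    the panel. Each tile contributes two keys, one per primer; a prefix shared
    by two different primers is a fatal ambiguity (binning correctness depends
    on key uniqueness), reported with the colliding primer names.
    """
    if prefix_len < 1:
        raise ConfigError(f"prefix length must be >= 1, got {prefix_len}")

    used: Dict[str, PrimerSeq] = {}
    for spec in specs:
        for name in (spec.fwd_name, spec.rev_name):
            if name not in primers:
                raise PanelError(
                    f"primer {name!r} referenced by tile "
                    f"{spec.chrom}:{spec.start}-{spec.end} is missing from the "
                    f"primer-sequences file"
                )
            used[name] = primers[name]

    if used:
        shortest = min(len(p.sequence) for p in used.values())
        if prefix_len > shortest:
            raise ConfigError(
                f"prefix length {prefix_len} exceeds the shortest primer "
                f"length {shortest}"
            )

    entries: Dict[str, Tuple[Tile, str]] = {}
    key_owner: Dict[str, str] = {}
    for spec in specs:
        fwd = used[spec.fwd_name]
        rev = used[spec.rev_name]
        tile = Tile(
            spec=spec,
            insert_ref=_fetch_insert(reference, spec.chrom, spec.start, spec.end),
            fwd_primer=fwd,
            rev_primer=rev,
        )
        for primer, orient in ((fwd, FORWARD), (rev, REVERSE)):
            key = primer.sequence[:prefix_len]
            if "N" in key:
                raise PanelError(
                    f"primer {primer.name!r} has N within its first "
                    f"{prefix_len} bases; exact-prefix hashing cannot match it"
                )
            if key in key_owner and key_owner[key] != primer.name:
                raise PanelError(
                    f"prefix collision at length {prefix_len}: primers "
                    f"{key_owner[key]!r} and {primer.name!r} share prefix {key!r}"
                )
            key_owner[key] = primer.name
            entries[key] = (tile, orient)
    return TileIndex(prefix_len=prefix_len, entries=entries)
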