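"""Paired FASTQ streaming, primer-prefix binning, and base-quality masking.

The library geometry this module assumes: every fragment is
``forward_primer + insert + revcomp(reverse_primer) [+ adapter]`` and the two
reads of a pair start at opposite ends, each beginning with its gene-specific
primer, overlapping the insert completely (or nearly so). Read 1 of a pair is
not guaranteed to be the forward read; binding decides orientation from the
prefix hash.

A pair is bound to a tile only when both mates hash to the *same* tile in
complementary orientations. Primer bases (the full primer, not just the
hashed prefix) are trimmed, reads are truncated at the insert length to drop
adapter read-through, and the reverse-oriented mate is reverse-complemented so
both inserts are expressed on the plus strand. Prefix matching is exact: a
sequencing error within the first N bases leaves the pair unassigned, by
design.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from typing import Iterator, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqError
from .panel import FORWARD, REVERSE, Tile, TileIndex

MASK_BASE = "N"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    quals: Tuple[int, ...]  # Phred scores, same length as bases

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FastqError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )


@dataclass(frozen=True)
class ReadPair:
    r1: Read
    r2: Read


@dataclass(frozen=True)
class OrientedInsert:
    """A primer-trimmed read insert expressed on the plus strand.

    ``side`` records which end of the tile the read is anchored to: the
    forward read starts at the tile's 5' end (``left``), the reverse read —
    after reverse complementing — ends at the tile's 3' end (``right``). For
    a read shorter than the tile, the uncovered bases are at the opposite end.
    """

    bases: str
    quals: Tuple[int, ...]
    side: str  # "left" | "right"

    def ref_offset(self, insert_len: int) -> int:
        """0-based offset of this insert's first base within the tile."""
        if self.side == "left":
            return 0
        return max(insert_len - len(self.bases), 0)


@dataclass(frozen=True)
class BoundPair:
    """A read pair assigned to a tile, both inserts plus-strand oriented."""

    pair: ReadPair
    tile: Tile
    insert_fwd: OrientedInsert  # from the forward-primer mate, side="left"
    insert_rev: OrientedInsert  # from the reverse-primer mate, side="right"


def _open_maybe_gzip(path: str):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fragment_id(read_id: str) -> str:
    token = read_id.split()[0]
    if token.endswith(("/1", "/2")):
        token = token[:-2]
    return token


def stream_pairs(fastq1: str, fastq2: str) -> Iterator[ReadPair]:
    """Yield mate pairs from two synchronized FASTQ files (plain or gzip).

    The i-th record of file 1 is paired with the i-th record of file 2;
    fragment identifiers must agree up to the standard /1 and /2 suffixes.
    Unequal record counts or malformed records raise :class:`FastqError`.
    """
    with _open_maybe_gzip(fastq1) as h1, _open_maybe_gzip(fastq2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        index = 0
        while True:
            try:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
            except ValueError as exc:
                raise FastqError(
                    f"malformed FASTQ record near pair {index + 1} "
                    f"in {fastq1}/{fastq2}: {exc}"
                ) from None
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                longer = fastq2 if rec1 is None else fastq1
                raise FastqError(
                    f"unequal record counts: {longer} has extra records "
                    f"beyond pair {index}"
                )
            index += 1
            reads = []
            for rid, seq, qual in (rec1, rec2):
                reads.append(
                    Read(
                        id=rid,
                        bases=seq.upper(),
                        quals=tuple(ord(c) - 33 for c in qual),
                    )
                )
            if _fragment_id(reads[0].id) != _fragment_id(reads[1].id):
                raise FastqError(
                    f"pair {index}: mate identifiers disagree "
                    f"({reads[0].id!r} vs {reads[1].id!r})"
                )
            yield ReadPair(r1=reads[0], r2=reads[1])


def _trim_and_orient(read: Read, tile: Tile, orient: str) -> OrientedInsert:
    primer = tile.fwd_primer if orient == FORWARD else tile.rev_primer
    insert = read.bases[len(primer.sequence):]
    quals = read.quals[len(primer.sequence):]
    # adapter read-through: anything past the insert is off-template
    insert = insert[: tile.insert_len]
    quals = quals[: tile.insert_len]
    if orient == FORWARD:
        return OrientedInsert(bases=insert, quals=quals, side="left")
    return OrientedInsert(bases=revcomp(insert), quals=quals[::-1], side="right")


def bin_pair(pair: ReadPair, index: TileIndex) -> Optional[BoundPair]:
    """Assign a pair to a tile via the prefix hash, or return None.

    Requires both mates to hash to the same tile in complementary
    orientations (one forward, one reverse). Non-matching pairs — prefix
    sequencing errors, off-panel fragments, cross-tile chimeras — are data,
    not errors: the caller counts and discards them.
    """
    n = index.prefix_len
    hit1 = index.lookup(pair.r1.bases[:n]) if len(pair.r1.bases) >= n else None
    hit2 = index.lookup(pair.r2.bases[:n]) if len(pair.r2.bases) >= n else None
    if hit1 is None or hit2 is None:
        return None
    tile1, orient1 = hit1
    tile2, orient2 = hit2
    if tile1.key != tile2.key or orient1 == orient2:
        return None
    fwd_read, rev_read = (
        (pair.r1, pair.r2) if orient1 == FORWARD else (pair.r2, pair.r1)
    )
    return BoundPair(
        pair=pair,
        tile=tile1,
        insert_fwd=_trim_and_orient(fwd_read, tile1, FORWARD),
        insert_rev=_trim_and_orient(rev_read, tile1, REVERSE),
    )


def _mask_insert(ins: OrientedInsert, threshold: int) -> OrientedInsert:
    bases = "".join(
        MASK_BASE if q < threshold else b for b, q in zip(ins.bases, ins.quals)
    )
    return replace(ins, bases=bases)


def mask_low_quality(bound: BoundPair, qual_threshold: int) -> BoundPair:
    """Replace insert bases below ``qual_threshold`` with the mask symbol.

    Masked bases still count toward depth but can never support a variant
    call nor contradict pair concordance. Threshold 0 disables masking.
    """
    if qual_threshold <= 0:
        return bound
    return replace(
        bound,
        insert_fwd=_mask_insert(bound.insert_fwd, qual_threshold),
        insert_rev=_mask_insert(bound.insert_rev, qual_threshold),
    )
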