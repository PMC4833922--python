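"""Read-insert vs reference-insert comparison.

Most reads are identical to the reference or carry a single substitution, so
a linear index-by-index scan resolves them in O(n). Only when the scan sees a
mismatch pattern suggestive of an indel does the module fall back to a global
(Needleman-Wunsch style) affine-gap alignment, from which variants are
extracted and indels left-normalized to the VCF convention.

Two scan policies exist:

* ``thorough`` — at most one mismatch is accepted; two or more trigger the
  gapped fallback.
* ``fast`` — any number of mismatches is accepted as independent SNVs
  provided every two consecutive mismatches are separated by more than
  ``fast_gap`` bases; clustered mismatches (the signature of an indel
  shifting the frame) trigger the fallback.

Masked bases (``N``) never mismatch and never yield variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AmpcallError, ConfigError
from .panel import Tile
from .reads import OrientedInsert

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

RESOLVED = "resolved"
FALLBACK = "fallback"


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized variant in 1-based reference coordinates.

    SNVs have single-base ref and alt; indels carry a 1-base anchor (VCF
    convention) and are left-aligned within their tile.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.alt) > len(self.ref):
            return INSERTION
        return DELETION

    @property
    def is_snv(self) -> bool:
        return self.vclass == SNV

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CompareMode:
    """Linear-scan acceptance policy: ``thorough`` or ``fast``."""

    mode: str = "thorough"
    fast_gap: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("thorough", "fast"):
            raise ConfigError(f"unknown compare mode {self.mode!r}")
        if self.fast_gap < 1:
            raise ConfigError(f"fast_gap must be >= 1, got {self.fast_gap}")


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scores for the fallback alignment.

    Defaults penalize gaps more heavily than mismatches so an isolated
    substitution is never rendered as a gap pair. A gap of length L scores
    ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class CompareResult:
    status: str  # RESOLVED | FALLBACK
    variants: Tuple[Variant, ...] = field(default_factory=tuple)


def linear_compare(
    read_insert: str,
    ref_insert: str,
    tile: Tile,
    mode: CompareMode,
    ref_offset: int = 0,
) -> CompareResult:
    """Index-by-index scan of a plus-strand read insert against the reference.

    ``ref_offset`` is the 0-based tile offset of the read's first base (zero
    for forward reads; positive for reverse reads shorter than the tile).
    Returns RESOLVED with the SNVs found, or FALLBACK when the mismatch
    pattern exceeds the mode's policy and a gapped alignment is required.
    """
    span = min(len(read_insert), len(ref_insert) - ref_offset)
    mismatches: List[int] = []
    for i in range(span):
        rb = read_insert[i]
        xb = ref_insert[ref_offset + i]
        if rb != xb and rb != "N" and xb != "N":
            mismatches.append(i)
            if mode.mode == "thorough" and len(mismatches) > 1:
                return CompareResult(status=FALLBACK)
    if mode.mode == "fast" and len(mismatches) > 1:
        for prev, cur in zip(mismatches, mismatches[1:]):
            if cur - prev - 1 <= mode.fast_gap:
                return CompareResult(status=FALLBACK)
    variants = tuple(
        Variant(
            chrom=tile.spec.chrom,
            pos=tile.spec.start + ref_offset + i,
            ref=ref_insert[ref_offset + i],
            alt=read_insert[i],
        )
        for i in mismatches
    )
    return CompareResult(status=RESOLVED, variants=variants)


def _make_aligner(scoring: AlignScoring, side: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    alphabet = "ACGTN"
    matrix = np.full((5, 5), scoring.mismatch, dtype=float)
    np.fill_diagonal(matrix, scoring.match)
    # N is uninformative: never a mismatch, never worth opening a gap over
    matrix[4, :] = scoring.match
    matrix[:, 4] = scoring.match
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=alphabet, dims=2, data=matrix
    )
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # The read is anchored at the primer end of the tile; the opposite end
    # may be truncated, so reference overhang there is free, not a deletion.
    # side="global" disables free ends (strict Needleman-Wunsch).
    if side == "global":
        return aligner
    end = "right" if side == "left" else "left"
    names = [
        (f"open_{end}_deletion_score", f"query_{end}_open_gap_score"),
        (f"extend_{end}_deletion_score", f"query_{end}_extend_gap_score"),
    ]
    for new, legacy in names:
        setattr(aligner, new if hasattr(aligner, new) else legacy, 0.0)
    return aligner


def gapped_align(
    read_insert: str,
    ref_insert: str,
    scoring: AlignScoring = AlignScoring(),
    side: str = "left",
) -> Align.Alignment:
    """One optimal global alignment of read (query) against reference (target).

    ``side`` selects which read end may be truncated ("left"-anchored reads
    get free reference overhang on the right and vice versa); "global"
    disables free end gaps entirely. Deterministic: of the co-optimal
    alignments the aligner's canonical first traceback is taken, and
    downstream left-normalization makes equivalent indel placements collapse
    to the same variant.
    """
    if not read_insert or not ref_insert:
        raise AmpcallError("cannot align empty sequences")
    aligner = _make_aligner(scoring, side)
    return next(iter(aligner.align(ref_insert, read_insert)))


def left_normalize(
    pos: int,
    ref: str,
    alt: str,
    get_base: Callable[[int], Optional[str]],
    min_pos: int,
) -> Tuple[int, str, str]:
    """Left-align an indel to the VCF parsimonious representation.

    ``get_base(p)`` returns the plus-strand reference base at 1-based
    position ``p`` (or None when unavailable); shifting stops at ``min_pos``.
    Idempotent on already-normalized variants.
    """
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > min_pos:
            prev = get_base(pos - 1)
            if prev is None:
                break
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _tile_base(tile: Tile, pos: int) -> Optional[str]:
    """Plus-strand reference base at 1-based genomic ``pos`` within reach of
    the tile: the insert itself, or the last forward-primer base just 5' of it
    (primers are reference flanks by design)."""
    start = tile.spec.start
    if pos == start - 1:
        return tile.fwd_primer.sequence[-1]
    if start <= pos <= tile.spec.end:
        return tile.insert_ref[pos - start]
    return None


def variants_from_alignment(alignment: Align.Alignment, tile: Tile) -> List[Variant]:
    """Convert aligned columns to left-normalized variants in tile coordinates.

    Runs of adjacent gap columns merge into single indel events; columns in
    the read's truncated end regions (leading/trailing query gaps) produce no
    variants; columns containing a masked base produce no variants.
    """
    ref_gapped = str(alignment[0])
    read_gapped = str(alignment[1])
    if ref_gapped.replace("-", "") != tile.insert_ref:
        raise AmpcallError(
            "alignment reference side does not match the tile's insert"
        )

    core = [i for i, b in enumerate(read_gapped) if b != "-"]
    if not core:
        return []
    first, last = core[0], core[-1]

    chrom = tile.spec.chrom
    start = tile.spec.start
    min_pos = start - 1

    variants: List[Variant] = []
    run_type: Optional[str] = None  # DELETION | INSERTION
    run_ref_start = 0  # 0-based insert offset of first deleted base / insertion point
    run_bases: List[str] = []

    def flush() -> None:
        nonlocal run_type, run_bases
        if run_type is None:
            return
        if run_type == DELETION:
            i = run_ref_start
            pos = start + i - 1
            anchor = _tile_base(tile, pos)
            ref = anchor + "".join(run_bases)
            alt = anchor
        else:
            if "N" in run_bases:  # masked insertion content: unreportable
                run_type, run_bases = None, []
                return
            i = run_ref_start
            pos = start + i - 1
            anchor = _tile_base(tile, pos)
            ref = anchor
            alt = anchor + "".join(run_bases)
        pos, ref, alt = left_normalize(
            pos, ref, alt, lambda p: _tile_base(tile, p), min_pos
        )
        variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alt=alt))
        run_type, run_bases = None, []

    ref_idx = 0
    for col, (xb, rb) in enumerate(zip(ref_gapped, read_gapped)):
        in_core = first <= col <= last
        if xb != "-" and rb != "-":
            flush()
            if in_core and xb != rb and rb != "N" and xb != "N":
                variants.append(
                    Variant(chrom=chrom, pos=start + ref_idx, ref=xb, alt=rb)
                )
            ref_idx += 1
        elif rb == "-":  # gap in read
            if in_core:
                if run_type != DELETION:
                    flush()
                    run_type = DELETION
                    run_ref_start = ref_idx
                run_bases.append(xb)
            else:
                flush()
            ref_idx += 1
        else:  # gap in reference: insertion in read
            if in_core:
                if run_type != INSERTION:
                    flush()
                    run_type = INSERTION
                    run_ref_start = ref_idx
                run_bases.append(rb)
            else:
                flush()
    flush()
    variants.sort()
    return variants


def compare_insert(
    insert: OrientedInsert,
    tile: Tile,
    mode: CompareMode,
    scoring: AlignScoring = AlignScoring(),
) -> List[Variant]:
    """Full per-read comparison: linear scan, gapped fallback if required."""
    offset = insert.ref_offset(tile.insert_len)
    result = linear_compare(insert.bases, tile.insert_ref, tile, mode, offset)
    if result.status == RESOLVED:
        return list(result.variants)
    alignment = gapped_align(
        insert.bases, tile.insert_ref, scoring=scoring, side=insert.side
    )
    return variants_from_alignment(alignment, tile)
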