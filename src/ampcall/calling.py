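"""Stringency filters and per-tile variant calling.

The calling rules, applied per tile:

1. *Overlap*: each read of a pair must cover at least ``min_overlap_frac`` of
   the tile (default 90%); failing pairs are discarded from depth and
   evidence.
2. *Anchor* (optional): at least one mate's post-primer sequence must exactly
   match the reference for ``anchor_len`` bases at its end of the tile.
3. *Concordance*: a variant is kept only when it is reported identically
   (chrom/pos/ref/alt) by both reads of a pair — sequencing artefacts are
   almost never pair-concordant, which is what makes the caller stringent.
4. *Frequency*: a concordant variant passes only with pair count >=
   ``min_abs_pairs`` AND proportion of surviving pairs >= ``min_prop_pairs``
   (both comparisons inclusive); variants failing a threshold are still
   reported, labeled ``at`` (absolute) and/or ``pt`` (proportion).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Tuple

from .compare import AlignScoring, CompareMode, Variant, compare_insert
from .errors import ConfigError
from .genotype import GenotypeResult
from .panel import Tile
from .reads import BoundPair

FILTER_ABS = "at"  # below minimum absolute pair count
FILTER_PROP = "pt"  # below minimum proportion of overlapping pairs


@dataclass(frozen=True)
class CallingThresholds:
    """User-adjustable stringency knobs."""

    min_overlap_frac: float = 0.9
    anchor_enabled: bool = False
    anchor_len: int = 30
    min_abs_pairs: int = 2
    min_prop_pairs: float = 0.05
    qual_threshold: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_frac <= 1:
            raise ConfigError("min_overlap_frac must be in (0, 1]")
        if not 0 <= self.min_prop_pairs <= 1:
            raise ConfigError("min_prop_pairs must be in [0, 1]")
        if self.min_abs_pairs < 0:
            raise ConfigError("min_abs_pairs must be >= 0")
        if self.anchor_len < 1:
            raise ConfigError("anchor_len must be >= 1")


@dataclass(frozen=True)
class VariantCall:
    """A variant with its per-sample evidence and filter status."""

    variant: Variant
    pair_count: int
    depth: int
    filters: FrozenSet[str] = frozenset()
    genotype: Optional[GenotypeResult] = None
    tile_key: str = ""

    @property
    def proportion(self) -> float:
        return self.pair_count / self.depth if self.depth else 0.0

    @property
    def passed(self) -> bool:
        return not self.filters


def overlap_ok(bound: BoundPair, thresholds: CallingThresholds) -> bool:
    """True iff BOTH inserts cover >= min_overlap_frac of the tile (inclusive)."""
    need = thresholds.min_overlap_frac * bound.tile.insert_len
    eps = 1e-9
    return (
        len(bound.insert_fwd.bases) + eps >= need
        and len(bound.insert_rev.bases) + eps >= need
    )


def anchor_ok(bound: BoundPair, thresholds: CallingThresholds) -> bool:
    """True iff at least one mate's post-primer window matches the reference.

    The forward mate is checked against the first ``anchor_len`` bases of the
    tile, the reverse mate against the last ``anchor_len`` (its post-primer
    sequence before orientation). Masked bases fail the exact match.
    """
    k = thresholds.anchor_len
    ref = bound.tile.insert_ref
    fwd = bound.insert_fwd.bases
    rev = bound.insert_rev.bases
    fwd_match = len(fwd) >= k and fwd[:k] == ref[:k]
    rev_match = len(rev) >= k and rev[-k:] == ref[-k:]
    return fwd_match or rev_match


def concordant_variants(
    bound: BoundPair,
    mode: CompareMode,
    scoring: AlignScoring = AlignScoring(),
) -> List[Variant]:
    """Variants reported identically by both plus-strand inserts of a pair.

    A locus where the mates disagree on the allele contributes nothing; a
    variant seen by only one mate (artefact, or masked on the other mate) is
    dropped.
    """
    v_fwd = compare_insert(bound.insert_fwd, bound.tile, mode, scoring)
    if not v_fwd:
        return []
    v_rev = compare_insert(bound.insert_rev, bound.tile, mode, scoring)
    shared = set(v_fwd) & set(v_rev)
    return sorted(shared)


def call_tile(
    per_pair_variants: Sequence[Tuple[BoundPair, Sequence[Variant]]],
    depth: int,
    thresholds: CallingThresholds,
    tile: Optional[Tile] = None,
) -> List[VariantCall]:
    """Aggregate concordant per-pair variants into per-tile calls.

    ``depth`` is the number of pairs surviving the overlap/anchor filters.
    Every distinct concordant variant is reported; those below the absolute
    or proportional thresholds carry the ``at``/``pt`` filter labels instead
    of being suppressed. Zero depth yields no calls.
    """
    if depth <= 0:
        return []
    tally: Counter = Counter()
    for _pair, variants in per_pair_variants:
        tally.update(variants)
    calls: List[VariantCall] = []
    for variant, count in sorted(tally.items()):
        failed = set()
        if count < thresholds.min_abs_pairs:
            failed.add(FILTER_ABS)
        if count / depth < thresholds.min_prop_pairs:
            failed.add(FILTER_PROP)
        calls.append(
            VariantCall(
                variant=variant,
                pair_count=count,
                depth=depth,
                filters=frozenset(failed),
                tile_key=tile.key if tile is not None else "",
            )
        )
    return calls
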