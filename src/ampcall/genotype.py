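"""SNV genotyping by G-test goodness of fit against a constant-error model.

For an SNV with reference allele R and alternate allele A, the candidate
genotypes are R/R, R/A, A/A (diploid) or R, A (haploid). Under a candidate
genotype, a read's base at the position is drawn uniformly from the
genotype's alleles and then corrupted with a constant probability ``e``
(default 1/500) to one of the three other bases, uniformly. The observed
base pileup is compared to each candidate's expected distribution with the
G statistic

    G = 2 * sum_b O_b * ln(O_b / (n * E_b))    over bases with O_b > 0,

and the genotype with the smallest G is reported (ties broken toward the
genotype with more reference alleles). G is non-negative and zero exactly
when the observed proportions match the expected distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

from .errors import ConfigError

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Pileup:
    """Base counts observed at one reference position (one count per pair)."""

    position: int
    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GenotypeModel:
    ploidy: int = 2
    error_rate: float = 1 / 500

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ConfigError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class GenotypeResult:
    """The winning genotype with the G statistics of every candidate."""

    genotype: Tuple[str, ...]  # allele multiset, e.g. ("A", "C")
    g_statistic: float
    candidates: Mapping[Tuple[str, ...], float]
    ref_allele: str
    alt_allele: str

    @property
    def gt_indices(self) -> Tuple[int, ...]:
        """VCF GT allele indices (0 = ref, 1 = alt) for the called genotype."""
        return tuple(0 if a == self.ref_allele else 1 for a in self.genotype)


def expected_distribution(
    genotype: Tuple[str, ...], model: GenotypeModel
) -> Dict[str, float]:
    """Expected base distribution for a genotype under the error model."""
    if len(genotype) != model.ploidy:
        raise ConfigError(
            f"genotype {genotype} does not match ploidy {model.ploidy}"
        )
    e = model.error_rate
    dist = {b: 0.0 for b in BASES}
    w = 1.0 / len(genotype)
    for allele in genotype:
        if allele not in BASES:
            raise ConfigError(f"invalid allele {allele!r}")
        for b in BASES:
            dist[b] += w * ((1.0 - e) if b == allele else e / 3.0)
    return dist


def g_statistic(observed: Mapping[str, int], expected: Mapping[str, float]) -> float:
    """G-test statistic 2*sum O*ln(O/(n*E)); zero-count terms contribute 0.

    An observed base with zero expected probability makes the candidate
    maximally disfavored (returns +inf rather than faulting).
    """
    n = sum(observed.values())
    if n < 1:
        raise ConfigError("cannot compute G statistic on an empty pileup")
    g = 0.0
    for b, o in observed.items():
        if o <= 0:
            continue
        e = expected.get(b, 0.0)
        if e <= 0.0:
            return math.inf
        g += o * math.log(o / (n * e))
    return max(2.0 * g, 0.0)


def genotype_call(
    pileup: Pileup, ref_base: str, alt_base: str, model: GenotypeModel
) -> GenotypeResult:
    """Pick the candidate genotype minimizing the G statistic.

    Candidate order lists reference-heavier genotypes first, and the strict
    minimum scan therefore breaks ties conservatively toward the reference.
    """
    if ref_base == alt_base:
        raise ConfigError("ref and alt alleles must differ")
    if model.ploidy == 2:
        candidates = [
            (ref_base, ref_base),
            (ref_base, alt_base),
            (alt_base, alt_base),
        ]
    else:
        candidates = [(ref_base,), (alt_base,)]
    scores: Dict[Tuple[str, ...], float] = {}
    best = None
    for genotype in candidates:
        g = g_statistic(pileup.counts, expected_distribution(genotype, model))
        scores[genotype] = g
        if best is None or g < scores[best]:
            best = genotype
    return GenotypeResult(
        genotype=best,
        g_statistic=scores[best],
        candidates=scores,
        ref_allele=ref_base,
        alt_allele=alt_base,
    )
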