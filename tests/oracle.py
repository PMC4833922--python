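"""Independent brute-force oracles for alignment and indel normalization.

Everything here is deliberately written from first principles — exhaustive
enumeration and plain Gotoh dynamic programming — and shares no code with
the package's alignment path, so it can serve as an independent check.

Scoring convention mirrors the package's declared semantics: a gap of length
L costs ``gap_open + (L - 1) * gap_extend``; ``free_left``/``free_right``
make leading/trailing gap runs in the *read* free (reference overhang from
read truncation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -0.5


def score_alignment(
    ref_g: str,
    read_g: str,
    sc: Scoring = Scoring(),
    free_left: bool = False,
    free_right: bool = False,
) -> float:
    """Score a gapped alignment column by column."""
    assert len(ref_g) == len(read_g)
    n = len(ref_g)
    # leading/trailing read-gap runs that may be free
    lead = 0
    while lead < n and read_g[lead] == "-":
        lead += 1
    trail = 0
    while trail < n - lead and read_g[n - 1 - trail] == "-":
        trail += 1
    total = 0.0
    in_ref_gap = in_read_gap = False
    for col in range(n):
        a, b = ref_g[col], read_g[col]
        assert not (a == "-" and b == "-")
        if b == "-":
            free = (free_left and col < lead) or (
                free_right and col >= n - trail
            )
            if not free:
                total += sc.gap_extend if in_read_gap else sc.gap_open
            in_read_gap, in_ref_gap = True, False
        elif a == "-":
            total += sc.gap_extend if in_ref_gap else sc.gap_open
            in_ref_gap, in_read_gap = True, False
        else:
            total += sc.match if a == b else sc.mismatch
            in_ref_gap = in_read_gap = False
    return total


def enumerate_alignments(ref: str, read: str) -> Iterator[Tuple[str, str]]:
    """All global alignments (no gap-gap columns) of two short strings."""
    if not ref and not read:
        yield "", ""
        return
    if ref:
        for rg, dg in enumerate_alignments(ref[1:], read):
            yield ref[0] + rg, "-" + dg
    if read:
        for rg, dg in enumerate_alignments(ref, read[1:]):
            yield "-" + rg, read[0] + dg
    if ref and read:
        for rg, dg in enumerate_alignments(ref[1:], read[1:]):
            yield ref[0] + rg, read[0] + dg


def best_alignments_bruteforce(
    ref: str,
    read: str,
    sc: Scoring = Scoring(),
    free_left: bool = False,
    free_right: bool = False,
) -> Tuple[float, List[Tuple[str, str]]]:
    """Optimal score and ALL optimal alignments, by exhaustive enumeration."""
    best = NEG_INF
    winners: List[Tuple[str, str]] = []
    for rg, dg in enumerate_alignments(ref, read):
        s = score_alignment(rg, dg, sc, free_left, free_right)
        if s > best + 1e-9:
            best, winners = s, [(rg, dg)]
        elif abs(s - best) <= 1e-9:
            winners.append((rg, dg))
    return best, winners


def dp_align(
    ref: str,
    read: str,
    sc: Scoring = Scoring(),
    free_left: bool = False,
    free_right: bool = False,
) -> Tuple[float, str, str]:
    """Affine-gap global alignment (Gotoh) with optional free read-end gaps.

    Returns (score, gapped_ref, gapped_read). Traceback preference is
    diagonal > read-gap > ref-gap; co-optimal solutions differ only in indel
    placement, which downstream left-shifting collapses.
    """
    m, n = len(ref), len(read)
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    RG = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in read
    FG = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in ref
    M[0][0] = 0.0
    for i in range(1, m + 1):
        if free_left:
            RG[i][0] = 0.0
        else:
            RG[i][0] = sc.gap_open + (i - 1) * sc.gap_extend
    for j in range(1, n + 1):
        FG[0][j] = sc.gap_open + (j - 1) * sc.gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = sc.match if ref[i - 1] == read[j - 1] else sc.mismatch
            M[i][j] = max(M[i - 1][j - 1], RG[i - 1][j - 1], FG[i - 1][j - 1]) + sub
            RG[i][j] = max(
                max(M[i - 1][j], FG[i - 1][j]) + sc.gap_open,
                RG[i - 1][j] + sc.gap_extend,
            )
            FG[i][j] = max(
                max(M[i][j - 1], RG[i][j - 1]) + sc.gap_open,
                FG[i][j - 1] + sc.gap_extend,
            )

    # terminal cell: free_right lets trailing reference bases go unaligned
    end_i, end_state, best = m, None, NEG_INF
    candidates = []
    if free_right:
        for i in range(m + 1):
            for state, mat in (("M", M), ("FG", FG)):
                candidates.append((mat[i][n], i, state))
        candidates.append((RG[m][n], m, "RG"))
    else:
        candidates = [(M[m][n], m, "M"), (RG[m][n], m, "RG"), (FG[m][n], m, "FG")]
    for s, i, state in candidates:
        if s > best + 1e-9:
            best, end_i, end_state = s, i, state

    ref_g: List[str] = []
    read_g: List[str] = []
    for i in range(m, end_i, -1):  # free trailing reference overhang
        ref_g.append(ref[i - 1])
        read_g.append("-")
    i, j, state = end_i, n, end_state
    while i > 0 or j > 0:
        if state == "M":
            sub = sc.match if ref[i - 1] == read[j - 1] else sc.mismatch
            ref_g.append(ref[i - 1])
            read_g.append(read[j - 1])
            prev = M[i - 1][j - 1]
            target = M[i][j] - sub
            if abs(M[i - 1][j - 1] - target) <= 1e-9:
                state = "M"
            elif abs(RG[i - 1][j - 1] - target) <= 1e-9:
                state = "RG"
            else:
                state = "FG"
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if j == 0:
                state = "RG"
            elif i == 0:
                state = "FG"
        elif state == "RG":
            ref_g.append(ref[i - 1])
            read_g.append("-")
            here = RG[i][j]
            if j == 0 and free_left:
                state = "RG"  # stays in the free leading run
            elif abs(RG[i - 1][j] + sc.gap_extend - here) <= 1e-9 and i > 1:
                state = "RG"
            elif abs(M[i - 1][j] + sc.gap_open - here) <= 1e-9:
                state = "M"
            elif abs(FG[i - 1][j] + sc.gap_open - here) <= 1e-9:
                state = "FG"
            else:
                state = "RG"
            i -= 1
            if i == 0 and j > 0:
                state = "FG"
        else:  # FG
            ref_g.append("-")
            read_g.append(read[j - 1])
            here = FG[i][j]
            if abs(FG[i][j - 1] + sc.gap_extend - here) <= 1e-9 and j > 1:
                state = "FG"
            elif abs(M[i][j - 1] + sc.gap_open - here) <= 1e-9:
                state = "M"
            elif abs(RG[i][j - 1] + sc.gap_open - here) <= 1e-9:
                state = "RG"
            else:
                state = "FG"
            j -= 1
            if j == 0 and i > 0:
                state = "RG"
    return best, "".join(reversed(ref_g)), "".join(reversed(read_g))


def simple_variants(
    ref_g: str, read_g: str, ref_start: int = 1
) -> List[Tuple[int, str, str, str]]:
    """Naive variant extraction: (1-based pos, kind, ref seg, alt seg).

    Leading/trailing read-gap runs are treated as truncation and skipped.
    Kind is 'sub', 'del' or 'ins'; positions are of the first affected
    reference base ('ins' = insertion before that reference position).
    """
    n = len(ref_g)
    core = [c for c in range(n) if read_g[c] != "-"]
    if not core:
        return []
    first, last = core[0], core[-1]
    out: List[Tuple[int, str, str, str]] = []
    ref_pos = ref_start
    col = 0
    while col < n:
        a, b = ref_g[col], read_g[col]
        if col < first or col > last:
            if a != "-":
                ref_pos += 1
            col += 1
            continue
        if a != "-" and b != "-":
            if a != b:
                out.append((ref_pos, "sub", a, b))
            ref_pos += 1
            col += 1
        elif b == "-":
            start = ref_pos
            seg = []
            while col < n and first <= col <= last and read_g[col] == "-" and ref_g[col] != "-":
                seg.append(ref_g[col])
                ref_pos += 1
                col += 1
            out.append((start, "del", "".join(seg), ""))
        else:
            start = ref_pos
            seg = []
            while col < n and ref_g[col] == "-":
                seg.append(read_g[col])
                col += 1
            out.append((start, "ins", "", "".join(seg)))
    return out


def leftmost_equivalent_indel(
    ref: str, pos0: int, kind: str, seg: str, ref_start: int = 1
) -> Tuple[int, str, str]:
    """Brute-force left-shift of an indel to its leftmost equivalent placement.

    ``pos0`` is the 0-based offset into ``ref`` of the first deleted base
    (deletion) or of the reference base the insertion precedes. Tries every
    smaller offset and keeps the leftmost that produces the same edited
    sequence, then returns the VCF-style anchored (1-based pos, REF, ALT)
    using the base at offset anchor-1 (caller guarantees it exists or
    supplies ref with a 5' flank base prepended).
    """
    length = len(seg)
    if kind == "del":
        edited = ref[:pos0] + ref[pos0 + length:]
        best = pos0
        for j in range(1, pos0):  # offset 0 is the 5' flank anchor, not shiftable past
            if ref[:j] + ref[j + length:] == edited:
                best = j
                break
        anchor = best - 1
        return (
            ref_start + anchor,
            ref[anchor : anchor + 1] + ref[best : best + length],
            ref[anchor : anchor + 1],
        )
    if kind == "ins":
        edited = ref[:pos0] + seg + ref[pos0:]
        best = pos0
        for j in range(1, pos0):
            if ref[:j] + edited[j : j + length] + ref[j:] == edited:
                best = j
                break
        anchor = best - 1
        return (
            ref_start + anchor,
            ref[anchor : anchor + 1],
            ref[anchor : anchor + 1] + edited[best : best + length],
        )
    raise ValueError(kind)
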