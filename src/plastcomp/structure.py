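"""Quadripartite structure detection for circular plastomes.

Plastomes carry two identical inverted-repeat copies (IRa/IRb) separated by
a large and a small single-copy region (LSC/SSC).  This module finds that
architecture from sequence alone: it locates the maximal-length *exact*
inverted repeat pair whose copies do not overlap on the circle, and labels
the two gaps between the copies LSC (longer) and SSC (shorter).

The search is seed-and-extend on the doubled sequence (circularity) against
the doubled reverse complement: exact k-mer seed hits are grouped by
diagonal, merged into runs, and extended to maximal exact matches.  Exact
matching is appropriate here because plastid IR copies are typically
identical; it also makes the maximality property checkable base by base.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from ._genetics import revcomp
from .genome_io import GenomeRecord


class NoInvertedRepeatError(ValueError):
    """No inverted repeat of the required minimum length exists."""


@dataclass(frozen=True)
class Region:
    """A (possibly origin-wrapping) arc of a circular genome.

    ``start`` is in [0, genome length); ``end = start + length`` may exceed
    the genome length, meaning the arc wraps past the origin.
    """

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def positions(self, n: int) -> range:
        return range(self.start, self.start + self.length)


@dataclass(frozen=True)
class QuadripartiteStructure:
    lsc: Region
    ssc: Region
    ira: Region
    irb: Region
    genome_length: int

    def __post_init__(self) -> None:
        total = (self.lsc.length + self.ssc.length
                 + self.ira.length + self.irb.length)
        if total != self.genome_length:
            raise ValueError(
                f"region lengths sum to {total}, genome is {self.genome_length}"
            )
        if self.ira.length != self.irb.length:
            raise ValueError("IR copies differ in length")
        if self.lsc.length < self.ssc.length:
            raise ValueError("LSC shorter than SSC")

    @property
    def ir_length(self) -> int:
        return self.ira.length


def _arc_seq(s: str, start: int, length: int) -> str:
    n = len(s)
    start %= n
    if start + length <= n:
        return s[start : start + length]
    return s[start:] + s[: (start + length) - n]


def _candidate_runs(s: str, min_ir_bp: int) -> list[tuple[int, int, int]]:
    """Maximal exact match runs between S+S and revcomp(S)+revcomp(S).

    Returns (i, j, length) triples: D[i:i+length] == E[j:j+length], where
    D = S+S and E = revcomp(S)+revcomp(S).
    """
    n = len(s)
    d = s + s
    e = revcomp(s) * 2
    k = min(31, min_ir_bp)
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(e) - k + 1):
        index[e[j : j + k]].append(j)
    # seed hits grouped by diagonal i - j
    diagonals: dict[int, set[int]] = defaultdict(set)
    for i in range(len(d) - k + 1):
        for j in index.get(d[i : i + k], ()):
            diagonals[i - j].add(i)
    runs: list[tuple[int, int, int]] = []
    for diag, starts in diagonals.items():
        ordered = sorted(starts)
        block_start = ordered[0]
        prev = ordered[0]
        blocks = []
        for i in ordered[1:]:
            if i == prev + 1:
                prev = i
            else:
                blocks.append((block_start, prev))
                block_start = prev = i
        blocks.append((block_start, prev))
        for first, last in blocks:
            i0, j0 = first, first - diag
            i1 = last + k  # one past the matched span
            j1 = last + k - diag
            # extend left/right by direct comparison
            while i0 > 0 and j0 > 0 and d[i0 - 1] == e[j0 - 1]:
                i0 -= 1
                j0 -= 1
            while i1 < len(d) and j1 < len(e) and d[i1] == e[j1]:
                i1 += 1
                j1 += 1
            length = i1 - i0
            if length >= min_ir_bp:
                runs.append((i0, j0, length))
    return sorted(set(runs))


def _arcs_disjoint(a: int, b: int, length: int, n: int) -> bool:
    return (b - a) % n >= length and (a - b) % n >= length


def detect_quadripartite(record: GenomeRecord,
                         min_ir_bp: int = 1000) -> QuadripartiteStructure:
    """Detect LSC/SSC/IRa/IRb on a circular genome.

    Parameters
    ----------
    record : the genome; must be circular and at least ``4 * min_ir_bp`` long.
    min_ir_bp : minimum acceptable IR copy length.  The 1 kb default admits
        every real plastid IR (tens of kb) while rejecting small dispersed
        repeats.

    Returns the maximal-length exact inverted-repeat pair with
    non-overlapping copies; ties are broken by smallest start coordinate.

    Raises
    ------
    NoInvertedRepeatError
        If no qualifying repeat exists (the caller may lower ``min_ir_bp``).
    """
    if not record.circular:
        raise ValueError("quadripartite detection requires a circular genome")
    s = record.sequence
    n = len(s)
    if n < 4 * min_ir_bp:
        raise ValueError(
            f"genome of {n} bp is shorter than 4 * min_ir_bp = {4 * min_ir_bp}"
        )
    best: tuple[int, int, int] | None = None  # (length, arc_a, arc_b)
    for i, j, length in _candidate_runs(s, min_ir_bp):
        length = min(length, n)
        a = i % n
        # E[j:j+L] is revcomp of the S arc starting at (n - j - L) mod n
        for sub in range(length, min_ir_bp - 1, -1):
            if 2 * sub > n:
                continue
            b = (n - j - sub) % n
            if a != b and _arcs_disjoint(a, b, sub, n):
                lo, hi = sorted(((a, b)))
                cand = (sub, lo, hi)
                if best is None or (cand[0], -cand[1], -cand[2]) > (
                    best[0], -best[1], -best[2]
                ):
                    best = cand
                break  # shorter truncations of this run cannot beat `sub`
    if best is None:
        raise NoInvertedRepeatError(
            f"no inverted repeat of >= {min_ir_bp} bp found in {record.id}"
        )
    length, a, b = best
    assert _arc_seq(s, b, length) == revcomp(_arc_seq(s, a, length))
    gap_ab = (b - (a + length)) % n  # gap after arc a, before arc b
    gap_ba = (a - (b + length)) % n
    if gap_ab >= gap_ba:
        lsc = Region((a + length) % n, gap_ab)
        ssc = Region((b + length) % n, gap_ba)
        irb, ira = Region(b, length), Region(a, length)
    else:
        lsc = Region((b + length) % n, gap_ba)
        ssc = Region((a + length) % n, gap_ab)
        irb, ira = Region(a, length), Region(b, length)
    # convention: traversal order LSC -> IRb -> SSC -> IRa
    if (irb.start - lsc.end) % n != 0:
        ira, irb = irb, ira
    return QuadripartiteStructure(
        lsc=lsc, ssc=ssc, ira=ira, irb=irb, genome_length=n
    )


def structure_table(results: dict[str, QuadripartiteStructure]):
    """Tabulate detections (1-based starts, as printed in genome reports)."""
    import pandas as pd

    rows = []
    for genome_id, q in results.items():
        rows.append(
            {
                "genome_id": genome_id,
                "lsc_len": q.lsc.length,
                "ssc_len": q.ssc.length,
                "ir_len": q.ir_length,
                "lsc_start": q.lsc.start % q.genome_length + 1,
                "ssc_start": q.ssc.start % q.genome_length + 1,
                "ira_start": q.ira.start % q.genome_length + 1,
                "irb_start": q.irb.start % q.genome_length + 1,
            }
        )
    return pd.DataFrame(rows)
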