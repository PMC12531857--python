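"""Perfect microsatellite (SSR) detection and classification.

Finds maximal perfect tandem repeats with unit-length-specific minimum copy
numbers, reports primitive motifs only, and classifies each locus by unit
length (MonoSSR .. DecaSSR, ExtendedSSR), genomic location (CDS / intron /
IGS) and base richness (AT-rich / GC-rich / balanced).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, classify_position

#: minimum copy numbers per unit length: 10 for mononucleotides, 5 for
#: dinucleotides, 4 for trinucleotides, 3 for tetra- through
#: decanucleotides.
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4,
                                      **{u: 3 for u in range(4, 11)}}

#: primitive units of 11-50 bp with >= 3 copies form the ExtendedSSR class
EXTENDED_MAX_UNIT = 50
EXTENDED_MIN_REPEATS = 3

_CATEGORY_NAMES = {
    1: "MonoSSR", 2: "DiSSR", 3: "TriSSR", 4: "TetraSSR", 5: "PentaSSR",
    6: "HexaSSR", 7: "HeptaSSR", 8: "OctaSSR", 9: "NonaSSR", 10: "DecaSSR",
}

CATEGORY_ORDER = tuple(_CATEGORY_NAMES[u] for u in range(1, 11)) + ("ExtendedSSR",)


@dataclass(frozen=True)
class SSRLocus:
    genome_id: str
    motif: str          # primitive unit as read on the plus strand
    unit_len: int
    n_repeats: int
    start: int          # 0-based half-open span
    end: int
    category: str
    location: str | None = None  # CDS / intron / IGS, set against a record
    richness: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def classify_richness(motif: str) -> str:
    """AT-rich (AT fraction > 0.5), GC-rich (< 0.5), or balanced (= 0.5)."""
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be non-empty ACGT, got {motif!r}")
    at = sum(motif.count(b) for b in "AT") / len(motif)
    if at > 0.5:
        return "AT-rich"
    if at < 0.5:
        return "GC-rich"
    return "balanced"


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation — stable key for motif grouping."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def _category(unit_len: int) -> str:
    return _CATEGORY_NAMES.get(unit_len, "ExtendedSSR")


def find_ssrs(sequence: str,
              thresholds: Mapping[int, int] | None = None,
              genome_id: str = "",
              max_unit: int = EXTENDED_MAX_UNIT) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting their unit threshold.

    Runs containing N (or any non-ACGT symbol) are broken at that symbol.
    Motifs are reported primitive; a locus is suppressed when its span lies
    inside a locus of a shorter unit (it would re-describe the same
    repetition).  Output is sorted by start, then unit length.
    """
    seq = sequence.upper()
    if not seq:
        return []
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C"))
        | (arr == ord("G")) | (arr == ord("T"))
    )
    units = sorted(set(thresholds) | set(range(11, max_unit + 1)))
    loci: list[SSRLocus] = []
    for u in units:
        if u <= 0 or u >= len(seq):
            continue
        min_rep = thresholds.get(u, EXTENDED_MIN_REPEATS if u > 10 else None)
        if min_rep is None:
            continue
        match = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.view(np.int8)))
        for a, e in zip(edges[0::2], edges[1::2]):
            span_len = (e - a) + u  # s[a : a+span_len] has period u
            n_rep = span_len // u
            if n_rep < min_rep:
                continue
            motif = seq[a : a + u]
            if not _is_primitive(motif):
                continue
            loci.append(
                SSRLocus(
                    genome_id=genome_id,
                    motif=motif,
                    unit_len=u,
                    n_repeats=n_rep,
                    start=int(a),
                    end=int(a + n_rep * u),
                    category=_category(u),
                    richness=classify_richness(motif),
                )
            )
    # containment suppression: a longer-unit locus inside a shorter-unit
    # locus restates the same repetition and is dropped
    kept: list[SSRLocus] = []
    for locus in loci:
        contained = any(
            other.unit_len < locus.unit_len
            and other.start <= locus.start
            and other.end >= locus.end
            for other in loci
        )
        if not contained:
            kept.append(locus)
    kept.sort(key=lambda l: (l.start, l.unit_len))
    return kept


def find_genome_ssrs(record: GenomeRecord,
                     thresholds: Mapping[int, int] | None = None
                     ) -> list[SSRLocus]:
    """SSR scan of a whole genome with location classes attached.

    Detection runs on the full plus strand, so loci inside the inverted
    repeats appear once per IR copy.
    """
    loci = find_ssrs(record.sequence, thresholds, genome_id=record.id)
    return [
        replace(l, location=classify_position(record, l.span)) for l in loci
    ]


def locus_table(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Per-locus table (1-based inclusive coordinates, as published)."""
    rows = []
    for l in loci:
        rows.append(
            {
                "genome_id": l.genome_id,
                "start": l.start + 1,
                "end": l.end,
                "motif": l.motif,
                "canonical_motif": canonical_motif(l.motif),
                "unit_len": l.unit_len,
                "n_repeats": l.n_repeats,
                "category": l.category,
                "location": l.location,
                "richness": l.richness,
            }
        )
    return pd.DataFrame(rows)


def _grouped_summary(df: pd.DataFrame, column: str,
                     order: Sequence[str]) -> pd.DataFrame:
    rows = []
    groups = [("ALL", df)] + [
        (gid, sub) for gid, sub in df.groupby("genome_id")
    ]
    for gid, sub in groups:
        total = len(sub)
        for value in order:
            count = int((sub[column] == value).sum())
            rows.append(
                {
                    "genome_id": gid,
                    column: value,
                    "count": count,
                    "percent": round(100.0 * count / total, 2) if total else None,
                }
            )
    return pd.DataFrame(rows)


def summarize_ssrs(loci: Sequence[SSRLocus],
                   records: Sequence[GenomeRecord] | None = None
                   ) -> dict[str, pd.DataFrame]:
    """Counts and percentages by category, location and richness.

    Returns per-genome rows plus a pooled "ALL" row per grouping; with no
    loci all counts are 0 and percentages are blank.  ``records`` is used
    to fill in location classes for loci that do not carry one yet.
    """
    if records is not None:
        by_id = {r.id: r for r in records}
        loci = [
            l if l.location is not None or l.genome_id not in by_id
            else replace(l, location=classify_position(by_id[l.genome_id], l.span))
            for l in loci
        ]
    df = locus_table(loci)
    if df.empty:
        df = pd.DataFrame(
            columns=["genome_id", "category", "location", "richness"]
        )
    return {
        "category": _grouped_summary(df, "category", CATEGORY_ORDER),
        "location": _grouped_summary(df, "location", ("CDS", "intron", "IGS")),
        "richness": _grouped_summary(
            df, "richness", ("AT-rich", "GC-rich", "balanced")
        ),
    }
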