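"""Annotated plastome I/O and position bookkeeping.

This module carries the annotated genome through the pipeline: it reads and
writes GenBank flat files, extracts spliced, strand-corrected coding
sequences, and classifies genomic positions into coding (CDS), intron, or
intergenic-spacer (IGS) space — the three location classes used by the SSR
census.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)``.  GenBank
files use 1-based inclusive coordinates; the conversion happens only at the
file boundary.  Features of circular genomes that span the origin are
normalized at load time by rotating the sequence so that no feature wraps;
the applied rotation is recorded on the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._genetics import revcomp

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA")

_VALID_BASES = frozenset("ACGTN")


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted."""


@dataclass(frozen=True)
class Feature:
    """One annotated feature.

    Parameters
    ----------
    kind : {'gene', 'CDS', 'tRNA', 'rRNA'}
    name : gene symbol (or a stable fallback label)
    strand : '+' or '-'
    parts : ordered exon intervals, 0-based half-open, always sorted by
        start coordinate regardless of strand.  Strand correction happens
        at extraction time, not in the coordinates.
    """

    kind: str
    name: str
    strand: str
    parts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no parts")
        for s, e in self.parts:
            if s >= e:
                raise ValueError(
                    f"feature {self.name!r} has an empty interval [{s}, {e})"
                )

    @property
    def footprint(self) -> tuple[int, int]:
        """The [min start, max end) span of the whole feature."""
        return (min(s for s, _ in self.parts), max(e for _, e in self.parts))

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.parts)


@dataclass
class GenomeRecord:
    """A circular annotated nucleotide sequence.

    ``rotation_offset`` records how far the original sequence origin was
    shifted left during origin-wrap normalization (0 when no feature
    spanned the origin).
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    rotation_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if set(self.sequence) - _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"record {self.id!r} contains non-ACGTN symbols {bad}")
        n = len(self.sequence)
        for f in self.features:
            lo, hi = f.footprint
            if lo < 0 or hi > n:
                raise ValueError(
                    f"feature {f.name!r} interval [{lo}, {hi}) outside genome "
                    f"of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        return 100.0 * (s.count("G") + s.count("C")) / acgt


@dataclass(frozen=True)
class CodingSequence:
    """A spliced, strand-corrected protein-coding sequence.

    ``complete`` is True when the length is a positive multiple of three of
    at least 6 bp; incomplete CDSs are carried along but excluded from
    codon statistics by default.
    """

    gene: str
    genome_id: str
    seq: str
    complete: bool

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# GenBank parsing / writing
# ---------------------------------------------------------------------------


def _feature_name(feat: SeqFeature, index: int) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"{feat.type}_{index}"


def _convert_feature(feat: SeqFeature, index: int) -> tuple[Feature, bool]:
    """Return (feature, wraps_origin) for a Biopython feature."""
    name = _feature_name(feat, index)
    if feat.location is None:
        raise GenBankParseError(f"feature {name!r} has an unparseable location")
    raw_parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
    strand = "-" if feat.location.strand == -1 else "+"
    # A feature split across the origin appears as consecutive parts
    # (x, genome_end) then (0, y) (order reversed on the minus strand).
    wraps = False
    for (s1, e1), (s2, e2) in zip(raw_parts, raw_parts[1:]):
        if (s2 == 0 and s1 > e2) or (s1 == 0 and s2 > e1):
            wraps = True
    parts = tuple(sorted(raw_parts))
    return Feature(kind=feat.type, name=name, strand=strand, parts=parts), wraps


def _rotate_record(rec_id, seq, feats_raw, offset):
    """Rotate sequence left by ``offset`` and remap feature coordinates."""
    n = len(seq)
    seq = seq[offset:] + seq[:offset]
    rotated = []
    for feat in feats_raw:
        parts = sorted(((s - offset) % n, ((e - 1 - offset) % n) + 1)
                       for s, e in feat.parts)
        # merge the artificial split at the old origin
        merged: list[list[int]] = []
        for s, e in parts:
            if merged and merged[-1][1] == s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        rotated.append(
            Feature(feat.kind, feat.name, feat.strand,
                    tuple((s, e) for s, e in merged))
        )
    return seq, rotated


def parse_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read a GenBank flat file into :class:`GenomeRecord` objects.

    join()/complement() locations are resolved into sorted exon parts and a
    strand flag; coordinates become 0-based half-open.  Records annotated
    with circular topology whose features span the origin are rotated so
    every feature is contiguous.

    Raises
    ------
    GenBankParseError
        If a record has no sequence or a feature location cannot be parsed.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if not seq or set(seq) == {"N"} and len(rec.seq) == 0:
            raise GenBankParseError(f"record {rec.id!r} has an empty ORIGIN")
        circular = rec.annotations.get("topology", "linear") == "circular"
        feats: list[Feature] = []
        wrap_offsets: list[int] = []
        for i, f in enumerate(rec.features):
            if f.type not in FEATURE_KINDS:
                continue
            feature, wraps = _convert_feature(f, i)
            feats.append(feature)
            if wraps:
                if not circular:
                    raise GenBankParseError(
                        f"feature {feature.name!r} spans the origin of a "
                        f"linear record"
                    )
                # rotate so this feature starts at 0: its true start is the
                # first part that touches the old sequence end
                start = min(s for s, e in feature.parts if e == len(seq))
                wrap_offsets.append(start)
        offset = 0
        if wrap_offsets:
            offset = min(wrap_offsets)
            seq, feats = _rotate_record(rec.id, seq, feats, offset)
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence=seq,
                circular=circular,
                features=feats,
                rotation_offset=offset,
            )
        )
    if not records:
        raise GenBankParseError(f"no GenBank records found in {path}")
    return records


def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as GenBank flat files (1-based inclusive coordinates)."""
    out = []
    for rec in records:
        seqrec = SeqRecord(
            Seq(rec.sequence),
            id=rec.id,
            name=rec.id[:16],
            description="",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if rec.circular else "linear",
            },
        )
        for f in rec.features:
            strand = -1 if f.strand == "-" else 1
            locs = [SimpleLocation(s, e, strand=strand) for s, e in f.parts]
            location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            seqrec.features.append(
                SeqFeature(location, type=f.kind, qualifiers={"gene": [f.name]})
            )
        out.append(seqrec)
    SeqIO.write(out, str(path), "genbank")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def spliced_sequence(record: GenomeRecord, feature: Feature) -> str:
    """Concatenate a feature's parts and strand-correct the result."""
    n = len(record)
    chunks = []
    for s, e in feature.parts:
        if s < 0 or e > n:
            raise ValueError(
                f"CDS {feature.name!r} part [{s}, {e}) outside genome of "
                f"length {n}"
            )
        chunks.append(record.sequence[s:e])
    seq = "".join(chunks)
    return revcomp(seq) if feature.strand == "-" else seq


def extract_cds(record: GenomeRecord, dedupe: bool = True) -> list[CodingSequence]:
    """Extract one :class:`CodingSequence` per CDS feature.

    Inverted-repeat-resident genes are annotated twice per genome; with
    ``dedupe`` (the default) copies identical in both name and sequence are
    reported once so codon statistics do not double-weight them.
    """
    seen: set[tuple[str, str]] = set()
    out: list[CodingSequence] = []
    for f in record.features:
        if f.kind != "CDS":
            continue
        seq = spliced_sequence(record, f)
        key = (f.name, seq)
        if dedupe and key in seen:
            continue
        seen.add(key)
        complete = len(seq) >= 6 and len(seq) % 3 == 0
        out.append(
            CodingSequence(gene=f.name, genome_id=record.id, seq=seq,
                           complete=complete)
        )
    return out


# ---------------------------------------------------------------------------
# Position classification
# ---------------------------------------------------------------------------

LOCATION_CLASSES = ("CDS", "intron", "IGS")


def classify_genome(record: GenomeRecord) -> np.ndarray:
    """Label every genome position as CDS (0), intron (1) or IGS (2).

    A position is CDS when it lies inside a CDS exon; intron when it lies
    inside a gene/tRNA/rRNA footprint but inside no exon part; IGS
    otherwise.  The three classes partition the genome.
    """
    n = len(record)
    in_cds_exon = np.zeros(n, dtype=bool)
    in_any_exon = np.zeros(n, dtype=bool)
    in_footprint = np.zeros(n, dtype=bool)
    for f in record.features:
        if f.kind == "CDS":
            for s, e in f.parts:
                in_cds_exon[s:e] = True
        if f.kind in ("CDS", "tRNA", "rRNA"):
            for s, e in f.parts:
                in_any_exon[s:e] = True
        if f.kind in ("gene", "tRNA", "rRNA"):
            lo, hi = f.footprint
            in_footprint[lo:hi] = True
    labels = np.full(n, 2, dtype=np.uint8)  # IGS
    labels[in_footprint & ~in_any_exon] = 1  # intron
    labels[in_cds_exon] = 0  # CDS
    return labels


def classify_position(record: GenomeRecord,
                      interval: tuple[int, int]) -> str:
    """Classify an interval by its start coordinate (total over the genome).

    Intervals straddling a class boundary take the class of their start,
    which keeps the assignment single-valued and deterministic.
    """
    start, end = interval
    if not (0 <= start < len(record)) or end > len(record) or start >= end:
        raise ValueError(f"interval [{start}, {end}) outside genome")
    for f in record.features:
        if f.kind != "CDS":
            continue
        for s, e in f.parts:
            if s <= start < e:
                return "CDS"
    in_exon = False
    in_fp = False
    for f in record.features:
        if f.kind in ("CDS", "tRNA", "rRNA"):
            for s, e in f.parts:
                if s <= start < e:
                    in_exon = True
        if f.kind in ("gene", "tRNA", "rRNA"):
            lo, hi = f.footprint
            if lo <= start < hi:
                in_fp = True
    if in_fp and not in_exon:
        return "intron"
    return "IGS"


# ---------------------------------------------------------------------------
# Per-genome summary (mirrors the family-wide genome-feature table)
# ---------------------------------------------------------------------------


def summarize_genomes(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Per-genome feature summary.

    Counts are raw annotation counts (IR-duplicated genes count twice,
    matching how published plastome tables report totals).
    """
    rows = []
    for rec in records:
        n_protein = sum(1 for f in rec.features if f.kind == "CDS")
        n_rrna = sum(1 for f in rec.features if f.kind == "rRNA")
        n_trna = sum(1 for f in rec.features if f.kind == "tRNA")
        rows.append(
            {
                "genome_id": rec.id,
                "length_bp": len(rec),
                "gc_percent": round(rec.gc_percent, 2),
                "n_protein": n_protein,
                "n_rRNA": n_rrna,
                "n_tRNA": n_trna,
                "n_total": n_protein + n_rrna + n_trna,
            }
        )
    return pd.DataFrame(rows)
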