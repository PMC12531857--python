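"""Pairwise Ka/Ks estimation by the Nei–Gojobori (1986) counting method.

For a codon-aligned homolog pair the method counts synonymous (S) and
nonsynonymous (N) *sites* by enumerating the nine single-nucleotide
neighbors of each codon, counts synonymous (Sd) and nonsynonymous (Nd)
*differences* by averaging over all minimal mutational pathways between
aligned codons, converts the proportions pS = Sd/S and pN = Nd/N to rates
with the Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3), and reports
omega = Ka/Ks.  Mutational paths through stop codons are excluded
throughout, following standard NG86 practice.

Protein-guided codon alignment is provided for homolog pairs of unequal
length; gap-containing codon columns are removed before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log
from typing import Sequence

import pandas as pd

from ._genetics import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate
from .genome_io import CodingSequence

_BASES = "ACGT"

#: omega bin edges: < 0.5 strong purifying, [0.5, 1.0] relaxed purifying,
#: > 1.0 positive; the boundary 0.5 falls in the relaxed bin.
REGIMES = ("strong_purifying", "relaxed_purifying", "positive", "undefined")


@dataclass(frozen=True)
class KaKsResult:
    gene: str
    pair: tuple[str, str]
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    Ks: float | None
    Ka: float | None
    omega: float | None
    regime: str


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes ``(number of synonymous changes) / (number of
    non-stop changes)`` synonymous sites; every codon contributes exactly
    three sites in total, so n = 3 - s.

    Raises
    ------
    ValueError
        If the codon is a stop codon or contains non-ACGT symbols.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor in STOP_CODONS:
                continue
            non_stop += 1
            if CODON_TO_AA[neighbor] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon
    pair.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are discarded.  If every pathway is blocked
    by stops (possible only for some 2- and 3-substitution pairs), the
    average falls back to all pathways so the pair still contributes.
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[int, int] | None:
        syn = nonsyn = 0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        result = walk(order)
        if result is not None:
            valid.append(result)
        else:
            # rebuild ignoring the stop rule for the fallback average
            syn = nonsyn = 0
            current = c1
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                aa_from = CODON_TO_AA.get(current, "*")
                aa_to = CODON_TO_AA.get(nxt, "*")
                if aa_from == aa_to:
                    syn += 1
                else:
                    nonsyn += 1
                current = nxt
            blocked.append((syn, nonsyn))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * log(1 - 4 * p / 3)


def classify_omega(omega: float | None) -> str:
    """Bin omega into the selection regimes used for cohort summaries."""
    if omega is None:
        return "undefined"
    if omega < 0.5:
        return "strong_purifying"
    if omega <= 1.0:
        return "relaxed_purifying"
    return "positive"


def ng86_kaks(seq1: str, seq2: str, gene: str = "",
              pair: tuple[str, str] = ("", "")) -> KaKsResult:
    """NG86 Ka/Ks of two codon-aligned, equal-length sequences.

    Columns in which either codon is a stop or contains a non-ACGT symbol
    are skipped.  At least 10 usable codon columns are required.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be codon-aligned and equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in CODON_TO_AA or c2 not in CODON_TO_AA:
            continue
        n_codons += 1
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons < 10:
        raise ValueError(
            f"only {n_codons} comparable codon columns; at least 10 required"
        )
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = _jukes_cantor(pS) if pS is not None else None
    Ka = _jukes_cantor(pN) if pN is not None else None
    omega = None
    if Ka is not None and Ks is not None and Ks > 0:
        omega = Ka / Ks
    return KaKsResult(
        gene=gene, pair=pair, n_codons=n_codons,
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        omega=omega, regime=classify_omega(omega),
    )


# ---------------------------------------------------------------------------
# Protein-guided codon alignment
# ---------------------------------------------------------------------------

#: fixed alignment scoring, declared for reproducibility
ALIGN_MATCH = 1.0
ALIGN_MISMATCH = -1.0
ALIGN_GAP_OPEN = -5.0
ALIGN_GAP_EXTEND = -1.0


def _strip_stop(seq: str) -> str:
    if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        return seq[:-3]
    return seq


def codon_align(cds1: CodingSequence, cds2: CodingSequence) -> tuple[str, str]:
    """Globally align two CDSs via their translations; return the gap-free
    codon columns as two equal-length nucleotide strings.

    The proteins are aligned with fixed match/mismatch/affine-gap scores
    (match +1, mismatch -1, gap open -5, extend -1) and the alignment is
    threaded back onto codons; columns containing a gap are dropped.
    """
    from Bio.Align import PairwiseAligner

    s1 = _strip_stop(cds1.seq.upper())
    s2 = _strip_stop(cds2.seq.upper())
    p1, p2 = translate(s1), translate(s2)
    if not p1 or not p2:
        raise ValueError("cannot align an empty translation")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_gap_score = ALIGN_GAP_OPEN
    aligner.extend_gap_score = ALIGN_GAP_EXTEND
    alignment = aligner.align(p1, p2)[0]
    blocks1, blocks2 = alignment.aligned
    out1: list[str] = []
    out2: list[str] = []
    for (a0, a1), (b0, b1) in zip(blocks1, blocks2):
        out1.append(s1[3 * a0 : 3 * a1])
        out2.append(s2[3 * b0 : 3 * b1])
    return "".join(out1), "".join(out2)


def kaks(cds1: CodingSequence, cds2: CodingSequence) -> KaKsResult:
    """Align two homologous CDSs and estimate Ka/Ks (NG86 + JC)."""
    a1, a2 = codon_align(cds1, cds2)
    return ng86_kaks(
        a1, a2, gene=cds1.gene, pair=(cds1.genome_id, cds2.genome_id)
    )


# ---------------------------------------------------------------------------
# Cohort profiling
# ---------------------------------------------------------------------------


def reference_pair_kaks(cds_by_genome: dict[str, list[CodingSequence]],
                        reference_id: str) -> list[KaKsResult]:
    """Compare each gene of every genome against one reference genome.

    The reference scheme (rather than all-vs-all) keeps the number of
    comparisons linear in the cohort size and makes the pairing
    deterministic and documentable.  Genes are matched by name; incomplete
    CDSs and failed estimates are skipped.
    """
    if reference_id not in cds_by_genome:
        raise ValueError(f"reference genome {reference_id!r} not in cohort")
    ref = {c.gene: c for c in cds_by_genome[reference_id] if c.complete}
    results: list[KaKsResult] = []
    for genome_id, cds_list in sorted(cds_by_genome.items()):
        if genome_id == reference_id:
            continue
        for cds in cds_list:
            if not cds.complete or cds.gene not in ref:
                continue
            try:
                results.append(kaks(ref[cds.gene], cds))
            except ValueError:
                continue
    return results


def kaks_table(results: Sequence[KaKsResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "genome_1": r.pair[0],
                "genome_2": r.pair[1],
                "n_codons": r.n_codons,
                "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                "Ka": r.Ka, "Ks": r.Ks, "omega": r.omega,
                "regime": r.regime,
            }
        )
    return pd.DataFrame(rows)


def regime_fractions(results: Sequence[KaKsResult]) -> pd.DataFrame:
    """Fraction of comparisons per selection regime (sums to 1)."""
    counts = {regime: 0 for regime in REGIMES}
    for r in results:
        counts[r.regime] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        [
            {
                "regime": regime,
                "count": count,
                "fraction": count / total if total else None,
            }
            for regime, count in counts.items()
        ]
    )


def category_means(results: Sequence[KaKsResult],
                   categories: dict[str, str]) -> pd.DataFrame:
    """Mean Ka, Ks and omega per functional gene category."""
    df = kaks_table(results)
    if df.empty:
        return df
    df["category"] = df["gene"].map(categories).fillna("unassigned")
    return (
        df.groupby("category")[["Ka", "Ks", "omega"]]
        .mean()
        .reset_index()
    )
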