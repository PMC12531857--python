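"""Codon usage bias statistics: RSCU, ENC, positional GC, PR2, neutrality
regression, and ordination of RSCU vectors.

The per-gene pipeline is: count codons -> relative synonymous codon usage
(RSCU) -> Wright's effective number of codons (ENC) and the GC3s null
curve -> positional GC content -> Parity-Rule-2 coordinates.  Cohort-level
analyses (neutrality regression of GC12 on GC3, principal-component
ordination of the 59-dimensional RSCU vectors) operate on collections of
per-gene results.

ENC follows Wright (1990): for each amino acid with synonymous family size
k > 1 and total count n >= 2, the codon homozygosity is

    F-hat = (n * sum(p_i^2) - 1) / (n - 1)

with p_i the within-family codon proportions and n the *total codon count*
for that amino acid.  Family-size means F2, F3, F4, F6 average F-hat over
the observed amino acids of each degeneracy class, and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

clipped to the theoretical [20, 61] range.  When isoleucine (the only
threefold family) is unobserved, F3 is imputed as (F2 + F4)/2; amino acids
with fewer than two counted codons, or with non-positive F-hat, are left
out of the family means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    RSCU_CODONS,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    STOP_CODONS,
)
from .genome_io import CodingSequence

_GC = frozenset("GC")

#: codons of amino acids with degeneracy > 1 — the "synonymous" universe
#: used for GC3s and the PR2 all-degenerate mode
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

#: codons of strictly fourfold-degenerate families — the classical PR2 set
FOURFOLD_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] == 4
)


@dataclass
class CodonCountTable:
    """Per-gene counts of the 61 sense codons."""

    gene: str
    genome_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in count table: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")
        self.counts = {c: int(v) for c, v in self.counts.items() if v}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in AA_TO_CODONS[aa]}


def count_codons(cds: CodingSequence) -> CodonCountTable:
    """Frame-0 codon census of a complete CDS.

    The terminal stop codon and any codon containing a non-ACGT symbol are
    dropped; stop codons are never counted.
    """
    if len(cds.seq) < 6:
        raise ValueError(f"CDS {cds.gene!r} shorter than 6 bp")
    if not cds.complete:
        raise ValueError(f"CDS {cds.gene!r} is not complete")
    counts: dict[str, int] = {}
    seq = cds.seq
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            continue
        if codon not in CODON_TO_AA:
            continue  # ambiguous symbols drop the whole codon
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(gene=cds.gene, genome_id=cds.genome_id, counts=counts)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def rscu(table: CodonCountTable) -> dict[str, float | None]:
    """Relative synonymous codon usage for every sense codon.

    RSCU(c) = count(c) / mean count over c's synonymous family.  Families
    with zero total count are undefined (None), not zero.  The single-codon
    amino acids (Met, Trp) are reported as 1.0 by convention; they carry no
    synonymous signal and are excluded from RSCU feature vectors.
    """
    out: dict[str, float | None] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in SINGLE_CODON_AAS:
            out[codons[0]] = 1.0
            continue
        family_total = sum(table.counts.get(c, 0) for c in codons)
        if family_total == 0:
            for c in codons:
                out[c] = None
            continue
        expected = family_total / len(codons)
        for c in codons:
            out[c] = table.counts.get(c, 0) / expected
    return out


def rscu_vector(table: CodonCountTable,
                impute: float = 0.0) -> np.ndarray:
    """The 59-dimensional RSCU feature vector (undefined entries imputed)."""
    values = rscu(table)
    return np.array(
        [values[c] if values[c] is not None else impute for c in RSCU_CODONS]
    )


def rscu_matrix(tables: Sequence[CodonCountTable]) -> pd.DataFrame:
    """Genes x 59 RSCU matrix (rows indexed gene@genome)."""
    rows = {f"{t.gene}@{t.genome_id}": rscu_vector(t) for t in tables}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(RSCU_CODONS))


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------


def _family_homozygosity(counts: Mapping[str, int]) -> float | None:
    n = sum(counts.values())
    if n < 2:
        return None
    sum_p2 = sum((v / n) ** 2 for v in counts.values())
    f_hat = (n * sum_p2 - 1) / (n - 1)
    if f_hat <= 0:
        return None
    return f_hat


def enc(table: CodonCountTable) -> float | None:
    """Wright's effective number of codons, clipped to [20, 61].

    Returns None when a whole degeneracy class (other than the threefold
    one, which is imputed) has no usable amino acid.
    """
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, k in DEGENERACY.items():
        if k == 1:
            continue
        f_hat = _family_homozygosity(table.family_counts(aa))
        if f_hat is not None:
            by_class[k].append(f_hat)
    means = {k: (sum(v) / len(v) if v else None) for k, v in by_class.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2
    if any(means[k] is None for k in (2, 3, 4, 6)):
        return None
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return float(min(61.0, max(20.0, value)))


def enc_expected(gc3s: float) -> float:
    """Wright's null ENC as a function of GC3s: 2 + s + 29/(s^2 + (1-s)^2).

    This is the expected ENC when codon usage is dictated solely by the
    G+C composition at synonymous third positions.  The curve is finite at
    the boundaries (31.0 at s = 0, 32.0 at s = 1) and peaks at s = 0.5.
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must lie in [0, 1], got {gc3s}")
    s = gc3s
    return 2 + s + 29 / (s * s + (1 - s) * (1 - s))


# ---------------------------------------------------------------------------
# Positional GC and PR2
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionalGC:
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float | None
    a3: int
    t3: int
    g3: int
    c3: int


def positional_gc(table: CodonCountTable) -> PositionalGC:
    """GC content by codon position.

    gc1/gc2/gc3 use every counted codon; gc3s and the a3/t3/g3/c3 tallies
    use only third positions of codons whose amino acid has degeneracy > 1
    (Met and Trp excluded, stops never counted) — the synonymous universe.
    """
    if table.total == 0:
        raise ValueError("no analyzed codons")
    pos_gc = [0, 0, 0]
    for codon, count in table.counts.items():
        for p in range(3):
            if codon[p] in _GC:
                pos_gc[p] += count
    gc1, gc2, gc3 = (g / table.total for g in pos_gc)
    tallies = {"A": 0, "T": 0, "G": 0, "C": 0}
    for codon in DEGENERATE_CODONS:
        count = table.counts.get(codon, 0)
        if count:
            tallies[codon[2]] += count
    syn_total = sum(tallies.values())
    gc3s = (tallies["G"] + tallies["C"]) / syn_total if syn_total else None
    return PositionalGC(
        gc1=gc1, gc2=gc2, gc3=gc3, gc12=(gc1 + gc2) / 2, gc3s=gc3s,
        a3=tallies["A"], t3=tallies["T"], g3=tallies["G"], c3=tallies["C"],
    )


def pr2(table: CodonCountTable,
        codon_set: str = "fourfold") -> tuple[float | None, float | None]:
    """Parity-Rule-2 coordinates (x = G3/(G3+C3), y = A3/(A3+T3)).

    ``codon_set`` selects the third-position universe: ``"fourfold"`` (the
    classical PR2 definition, default) or ``"all_degenerate"`` (every amino
    acid with more than one codon).  A coordinate with a zero denominator
    is None and the gene is excluded from plots and means.
    """
    if codon_set == "fourfold":
        universe: Iterable[str] = FOURFOLD_CODONS
    elif codon_set == "all_degenerate":
        universe = DEGENERATE_CODONS
    else:
        raise ValueError(f"unknown codon_set {codon_set!r}")
    tallies = {"A": 0, "T": 0, "G": 0, "C": 0}
    for codon in universe:
        count = table.counts.get(codon, 0)
        if count:
            tallies[codon[2]] += count
    gc = tallies["G"] + tallies["C"]
    at = tallies["A"] + tallies["T"]
    x = tallies["G"] / gc if gc else None
    y = tallies["A"] / at if at else None
    return x, y


# ---------------------------------------------------------------------------
# Neutrality regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def neutrality_fit(points: Sequence[tuple[float, float]]) -> RegressionFit:
    """Ordinary least squares of GC12 on GC3 over (gc3, gc12) gene points.

    A slope near 1 indicates GC content driven by a shared mutational
    pressure acting on all codon positions; a slope near 0 indicates
    selection decoupling the (mostly synonymous) third position from the
    first two.
    """
    if len(points) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    gc3 = np.array([p[0] for p in points], dtype=float)
    gc12 = np.array([p[1] for p in points], dtype=float)
    if np.ptp(gc3) == 0:
        raise ValueError("GC3 is constant; the fit is undefined")
    if np.ptp(gc12) == 0:
        # constant response: zero slope with no explained variance
        return RegressionFit(slope=0.0, intercept=float(gc12[0]),
                             r_squared=0.0, n_points=len(points))
    fit = stats.linregress(gc3, gc12)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(points),
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray  # genes x axes
    explained: tuple[float, ...]  # per-axis fraction of total variance
    axes: int


def ordinate_rscu(matrix: np.ndarray | pd.DataFrame,
                  axes: int = 2,
                  mode: str = "pca") -> OrdinationResult:
    """Ordination of genes in RSCU space.

    ``mode="pca"`` (default) is column-centered principal-component
    analysis of the genes x 59 RSCU matrix.  ``mode="coa"`` is classical
    correspondence analysis (chi-square distances on the same matrix),
    offered for comparability with codon-usage studies that use COA.
    Undefined RSCU entries must already be imputed (0 by convention).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("ordination needs at least 3 genes")
    if mode == "pca":
        centered = x - x.mean(axis=0)
        total_var = float((centered**2).sum())
        if total_var <= 1e-12 * x.size:
            k = min(axes, *x.shape)
            return OrdinationResult(
                coordinates=np.zeros((x.shape[0], k)),
                explained=tuple(0.0 for _ in range(k)),
                axes=k,
            )
        from sklearn.decomposition import PCA

        k = min(axes, min(x.shape[0] - 1, x.shape[1]))
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(centered)
        explained = tuple(float(v) for v in pca.explained_variance_ratio_)
        return OrdinationResult(coordinates=coords, explained=explained, axes=k)
    if mode == "coa":
        grand = x.sum()
        if grand <= 0:
            raise ValueError("COA requires a non-negative matrix with mass")
        p = x / grand
        r = p.sum(axis=1)
        c = p.sum(axis=0)
        if np.any(r == 0) or np.any(c == 0):
            raise ValueError("COA requires strictly positive margins")
        s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        u, sv, _ = np.linalg.svd(s, full_matrices=False)
        inertia = sv**2
        total = inertia.sum()
        k = min(axes, len(sv))
        coords = (u[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
        explained = tuple(
            float(inertia[i] / total) if total > 0 else 0.0 for i in range(k)
        )
        return OrdinationResult(coordinates=coords, explained=explained, axes=k)
    raise ValueError(f"unknown ordination mode {mode!r}")


# ---------------------------------------------------------------------------
# Assembled per-gene profile and cohort tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CUBProfile:
    """The full per-gene codon-usage-bias profile."""

    gene: str
    genome_id: str
    n_codons: int
    rscu: dict[str, float | None]
    enc: float | None
    gc: PositionalGC
    pr2_x: float | None
    pr2_y: float | None


def cub_profile(table: CodonCountTable,
                pr2_mode: str = "fourfold") -> CUBProfile:
    gc = positional_gc(table)
    x, y = pr2(table, codon_set=pr2_mode)
    return CUBProfile(
        gene=table.gene,
        genome_id=table.genome_id,
        n_codons=table.total,
        rscu=rscu(table),
        enc=enc(table),
        gc=gc,
        pr2_x=x,
        pr2_y=y,
    )


def cub_table(profiles: Sequence[CUBProfile]) -> pd.DataFrame:
    """Tidy per-gene table of the scalar CUB statistics."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "gene": p.gene,
                "genome_id": p.genome_id,
                "n_codons": p.n_codons,
                "enc": p.enc,
                "gc1": p.gc.gc1,
                "gc2": p.gc.gc2,
                "gc3": p.gc.gc3,
                "gc12": p.gc.gc12,
                "gc3s": p.gc.gc3s,
                "pr2_x": p.pr2_x,
                "pr2_y": p.pr2_y,
            }
        )
    return pd.DataFrame(rows)


def species_means(profiles: Sequence[CUBProfile]) -> pd.DataFrame:
    """Unweighted per-genome means of ENC, GC3s and PR2 coordinates.

    Genes with undefined values are excluded from the respective mean.
    """
    df = cub_table(profiles)
    if df.empty:
        return df
    return (
        df.groupby("genome_id")[["enc", "gc3s", "pr2_x", "pr2_y"]]
        .mean()
        .reset_index()
    )
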