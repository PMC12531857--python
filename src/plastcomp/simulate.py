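"""Synthetic plastome generator with machine-readable ground truth.

Every analysis stage in this package is validated against constructions
whose answers are known by design: circular quadripartite genomes with an
exact inverted-repeat pair, gene models with spliced CDSs emitted from
controllable codon-usage distributions, perfect SSRs planted at recorded
spans, and homolog pairs diverged at a controlled dN/dS.

Ground-truth closure: every generator output returns truth tables (feature
coordinates, planted SSR spans, per-gene codon tallies, realized
substitution counts) so detection stages can be checked span- and
byte-exactly.  Background sequence is i.i.d. bases at a configurable GC,
iteratively re-randomized until it contains no tandem repeat meeting the
default SSR thresholds, so any repeat the scanner reports is a planted one.

Default genome dimensions, gene complement and composition follow the
plastome this package was built around: an LSC of 87,592 bp, an SSC of
18,599 bp, IRs of 26,994 bp (160,179 bp in total), 86 protein-coding + 37
tRNA + 8 rRNA genes, ~300-codon genes (the mean plastid CDS is ~900 bp),
and non-coding GC of 0.35.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from ._genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    revcomp,
)
from .genome_io import CodingSequence, Feature, GenomeRecord
from .ssr import DEFAULT_THRESHOLDS, find_ssrs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class CapacityError(ValueError):
    """Requested genome content exceeds a region's capacity."""


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    n_repeats: int
    region_class: str  # CDS / intron / IGS


@dataclass
class SimulationSpec:
    """Parameters of one synthetic plastome (defaults = study conditions)."""

    seed: int = 0
    lsc_len: int = 87_592
    ssc_len: int = 18_599
    ir_len: int = 26_994
    n_genes: int = 86
    n_trna: int = 37
    n_rrna: int = 8
    gene_len_codons: int = 300
    intron_frac: float = 0.3
    intron_len: int = 500
    trna_len: int = 75
    rrna_len: int = 120
    background_gc: float = 0.35
    codon_weights: dict[str, dict[str, float]] | None = None
    concentration: float | None = None
    gc3_target: float | None = None
    ssr_plant_list: list[PlantedSSR] = field(default_factory=list)
    omega_target: float = 0.5
    divergence: float = 0.05
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("lsc_len", "ssc_len", "ir_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0, 1)")
        if self.divergence < 0 or self.omega_target < 0:
            raise ValueError("divergence and omega_target must be >= 0")
        self.ssr_plant_list = [
            p if isinstance(p, PlantedSSR) else PlantedSSR(*p)
            for p in self.ssr_plant_list
        ]
        for p in self.ssr_plant_list:
            if p.region_class not in ("CDS", "intron", "IGS"):
                raise ValueError(f"unknown region class {p.region_class!r}")


_FLOAT_KEYS = {"intron_frac", "background_gc", "gc3_target",
               "concentration", "omega_target", "divergence"}


def spec_to_text(spec: SimulationSpec) -> str:
    """Serialize a spec as ``key = value`` lines (provenance record)."""
    lines = []
    for key, value in vars(spec).items():
        if key == "codon_weights":
            continue  # not representable as a flat key=value line
        if key == "ssr_plant_list":
            value = ";".join(
                f"{p.motif},{p.n_repeats},{p.region_class}" for p in value
            )
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def spec_from_text(text: str) -> SimulationSpec:
    kwargs: dict = {}
    known = set(SimulationSpec.__dataclass_fields__)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValueError(f"unknown simulation key {key!r}")
        if key == "ssr_plant_list":
            plants = []
            if raw:
                for item in raw.split(";"):
                    motif, n, cls = item.split(",")
                    plants.append(PlantedSSR(motif, int(n), cls))
            kwargs[key] = plants
        elif key == "genome_id":
            kwargs[key] = raw
        elif raw == "None":
            kwargs[key] = None
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(raw)
        else:
            kwargs[key] = int(raw)
    return SimulationSpec(**kwargs)


# ---------------------------------------------------------------------------
# Codon emission
# ---------------------------------------------------------------------------


def _family_distribution(aa, weights, gc3, rng, concentration):
    codons = AA_TO_CODONS[aa]
    if weights is not None:
        w = np.array([max(0.0, weights.get(c, 0.0)) for c in codons])
        if w.sum() <= 0:
            w = np.ones(len(codons))
    elif concentration is not None and len(codons) > 1:
        w = rng.dirichlet(np.full(len(codons), concentration))
    else:
        w = np.ones(len(codons), dtype=float)
    w = w / w.sum()
    if gc3 is not None and len(codons) > 1:
        gc_idx = [i for i, c in enumerate(codons) if c[2] in "GC"]
        at_idx = [i for i, c in enumerate(codons) if c[2] in "AT"]
        if gc_idx and at_idx:
            out = np.zeros(len(codons))
            wg, wa = w[gc_idx], w[at_idx]
            out[gc_idx] = gc3 * (wg / wg.sum() if wg.sum() > 0
                                 else 1.0 / len(gc_idx))
            out[at_idx] = (1 - gc3) * (wa / wa.sum() if wa.sum() > 0
                                       else 1.0 / len(at_idx))
            w = out
    return dict(zip(codons, w))


def build_codon_distribution(weights: dict[str, dict[str, float]] | None = None,
                             gc3_target: float | None = None,
                             concentration: float | None = None,
                             rng: np.random.Generator | None = None
                             ) -> dict[str, float]:
    """A probability distribution over the 61 sense codons.

    Amino-acid marginals are proportional to family size, so with no
    weights, concentration or GC3 target the distribution is uniform over
    all 61 sense codons.  Within-family weights can be supplied per amino
    acid, drawn from a symmetric Dirichlet with the given concentration
    (small values concentrate usage on few codons per family), and/or
    reshaped so the third base of every degenerate family is G or C with
    probability exactly ``gc3_target``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    dist: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        fam = _family_distribution(
            aa, None if weights is None else weights.get(aa),
            gc3_target, rng, concentration,
        )
        aa_mass = len(codons) / len(SENSE_CODONS)
        for codon, p in fam.items():
            dist[codon] = aa_mass * p
    return dist


def simulate_cds(weights: dict[str, dict[str, float]] | None = None,
                 n_codons: int = 300,
                 seed: int | np.random.Generator = 0,
                 gc3_target: float | None = None,
                 concentration: float | None = None,
                 gene: str = "simgene",
                 genome_id: str = "synthetic"
                 ) -> tuple[CodingSequence, dict[str, int]]:
    """Emit a CDS of ``n_codons`` sense codons plus a terminal stop.

    The first codon is ATG; the rest are drawn i.i.d. from
    :func:`build_codon_distribution`.  Returns the CDS and the exact
    emission tally (ATG included, terminal stop excluded), which by
    construction equals the codon census of the emitted sequence.
    """
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dist = build_codon_distribution(weights, gc3_target, concentration, rng)
    codons = list(dist)
    probs = np.array([dist[c] for c in codons])
    probs = probs / probs.sum()
    draws = rng.choice(len(codons), size=n_codons - 1, p=probs)
    body = ["ATG"] + [codons[i] for i in draws]
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    tally: dict[str, int] = {}
    for c in body:
        tally[c] = tally.get(c, 0) + 1
    return (
        CodingSequence(gene=gene, genome_id=genome_id,
                       seq="".join(body) + stop, complete=True),
        tally,
    )


# ---------------------------------------------------------------------------
# Neutrality-plot cohorts
# ---------------------------------------------------------------------------


def simulate_neutrality_cohort(n_genes: int,
                               seed: int = 0,
                               n_codons: int = 2000,
                               mode: str = "neutral"
                               ) -> list[tuple[float, float]]:
    """Per-gene (GC3, GC12) points under controlled compositional regimes.

    ``mode="neutral"``: each gene draws a GC pressure g ~ Uniform(0.2, 0.8)
    applied identically at all three codon positions — the mutational
    regime, whose GC12-on-GC3 regression slope tends to 1.
    ``mode="selection"``: positions 1-2 follow g, but the third position is
    governed by an *independent* per-gene pressure h ~ Uniform(0.2, 0.8) —
    GC3 then carries no information about GC12 and the slope tends to 0.
    (Pinning GC3 at a constant instead would leave the predictor with
    binomial noise only and make the slope estimator statistically
    uninformative.)  ``mode="constant"``: every gene sits exactly at the
    expected composition (0.5, 0.5) with no sampling — a degenerate
    constant predictor for which the regression is undefined.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    if mode == "constant":
        return [(0.5, 0.5)] * n_genes
    if mode in ("neutral", "selection"):
        g = rng.uniform(0.2, 0.8, size=n_genes)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    gc_prob = np.repeat(g[:, None], 3, axis=1)
    if mode == "selection":
        gc_prob[:, 2] = rng.uniform(0.2, 0.8, size=n_genes)
    draws = rng.random((n_genes, 3, n_codons)) < gc_prob[:, :, None]
    gc_by_pos = draws.mean(axis=2)
    return [
        (float(gc_by_pos[i, 2]),
         float((gc_by_pos[i, 0] + gc_by_pos[i, 1]) / 2))
        for i in range(n_genes)
    ]


# ---------------------------------------------------------------------------
# Homolog-pair evolution at a controlled dN/dS
# ---------------------------------------------------------------------------


def evolve_pair(cds: CodingSequence,
                omega_target: float,
                divergence: float,
                seed: int = 0) -> tuple[CodingSequence, dict[str, int]]:
    """Derive a diverged copy of a CDS with dN/dS held at ``omega_target``.

    Substitutions are proposed uniformly over sites (terminal stop codon
    excluded) and alternative bases; proposals creating stop codons are
    rejected outright.  For omega <= 1, synonymous proposals are accepted
    with probability 1 and nonsynonymous ones with probability omega; for
    omega > 1 the roles flip (nonsynonymous always accepted, synonymous
    accepted with probability 1/omega).  The process stops after
    ``round(divergence * L)`` accepted substitutions, L being the number
    of mutable sites; multiple hits at one site are allowed.

    Returns the mutated copy and the realized substitution tally
    ``{"synonymous": ..., "nonsynonymous": ...}``.
    """
    if omega_target < 0 or divergence < 0:
        raise ValueError("omega_target and divergence must be >= 0")
    rng = np.random.default_rng(seed)
    seq = list(cds.seq.upper())
    n_mutable = len(seq) - 3  # the terminal stop codon is immutable
    if n_mutable <= 0:
        raise ValueError("CDS too short to evolve")
    counts = {"synonymous": 0, "nonsynonymous": 0}
    n_target = int(round(divergence * n_mutable))
    if n_target == 0:
        return dc_replace(cds, genome_id=cds.genome_id + "_derived"), counts
    p_syn = 1.0 if omega_target <= 1 else 1.0 / omega_target
    p_non = omega_target if omega_target <= 1 else 1.0
    accepted = proposals = 0
    limit = 10_000 + 2_000 * n_target
    while accepted < n_target:
        proposals += 1
        if proposals > limit:
            raise RuntimeError("mutation acceptance stalled")
        pos = int(rng.integers(n_mutable))
        old_base = seq[pos]
        new_base = [b for b in "ACGT" if b != old_base][int(rng.integers(3))]
        cstart = 3 * (pos // 3)
        old_codon = "".join(seq[cstart : cstart + 3])
        k = pos - cstart
        new_codon = old_codon[:k] + new_base + old_codon[k + 1 :]
        if new_codon in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA.get(new_codon) == CODON_TO_AA.get(old_codon)
        if rng.random() >= (p_syn if synonymous else p_non):
            continue
        seq[pos] = new_base
        counts["synonymous" if synonymous else "nonsynonymous"] += 1
        accepted += 1
    return (
        CodingSequence(gene=cds.gene, genome_id=cds.genome_id + "_derived",
                       seq="".join(seq), complete=cds.complete),
        counts,
    )


# ---------------------------------------------------------------------------
# Whole-genome construction
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _clean_background(rng: np.random.Generator, length: int,
                      gc: float, max_iter: int = 300) -> str:
    """Background bases containing no tandem repeat meeting thresholds."""
    if length <= 0:
        return ""
    arr = list(_random_bases(rng, length, gc))
    for _ in range(max_iter):
        loci = find_ssrs("".join(arr), DEFAULT_THRESHOLDS)
        if not loci:
            return "".join(arr)
        for locus in loci:
            arr[locus.start : locus.end] = list(
                _random_bases(rng, locus.end - locus.start, gc)
            )
    raise RuntimeError("background scrubbing did not converge")


def _overwrite_plant(segment: str, at: int, motif: str,
                     n_repeats: int) -> tuple[str, int]:
    """Overwrite ``segment[at : at+len]`` with motif^n plus guard bases.

    The guard bases directly before and after the repeat are chosen so the
    run cannot extend by one unit in either direction; segment length is
    preserved.  Returns (new segment, repeat start within segment).
    """
    repeat = motif * n_repeats
    u = len(motif)
    if at < 1 or at + len(repeat) + 1 > len(segment):
        raise CapacityError("segment too small for planted SSR")
    left_guard = next(b for b in "ACGT" if b != motif[u - 1])
    right_guard = next(b for b in "ACGT" if b != motif[0])
    out = (segment[: at - 1] + left_guard + repeat + right_guard
           + segment[at + len(repeat) + 1 :])
    return out, at


def _clean_cds(rng, n_codons, spec, gene):
    """A CDS free of qualifying SSRs (whole-sequence rejection sampling)."""
    for _ in range(300):
        cds, tally = simulate_cds(
            weights=spec.codon_weights, n_codons=n_codons, seed=rng,
            gc3_target=spec.gc3_target, concentration=spec.concentration,
            gene=gene, genome_id=spec.genome_id,
        )
        if not find_ssrs(cds.seq, DEFAULT_THRESHOLDS):
            return cds, tally
    raise RuntimeError("could not draw an SSR-free CDS")


def _embed_repeat_in_cds(cds_seq: str, motif: str, n_repeats: int,
                         rng: np.random.Generator) -> tuple[str, int]:
    """Insert motif^n into a CDS at a codon boundary, padded to a whole
    number of stop-free codons, with the run maximal in the result.

    Raises :class:`CapacityError` if no stop-free, maximal embedding can
    be found for this motif.
    """
    u = len(motif)
    repeat = motif * n_repeats
    n_codons_body = (len(cds_seq) - 6) // 3
    if n_codons_body < 4:
        raise CapacityError("CDS too short for SSR embedding")
    for _ in range(30):
        insert_at = 3 + 3 * int(rng.integers(1, n_codons_body - 1))
        for left_len in (0, 1, 2):
            right_len = (3 - (left_len + len(repeat)) % 3) % 3
            for left in _pads(left_len):
                if left_len and left[-1] == motif[u - 1]:
                    continue  # would extend the run leftward
                for right in _pads(right_len):
                    if right_len and right[0] == motif[0]:
                        continue  # would extend the run rightward
                    block = left + repeat + right
                    codons = [block[i : i + 3]
                              for i in range(0, len(block), 3)]
                    if any(c in STOP_CODONS for c in codons):
                        continue
                    candidate = (cds_seq[:insert_at] + block
                                 + cds_seq[insert_at:])
                    start = insert_at + left_len
                    if candidate[start - 1] == motif[u - 1]:
                        continue
                    after = start + len(repeat)
                    if (after < len(candidate)
                            and candidate[after] == motif[0]):
                        continue
                    found = find_ssrs(candidate, DEFAULT_THRESHOLDS)
                    if (len(found) == 1
                            and found[0].span == (start, start + len(repeat))):
                        return candidate, start
    raise CapacityError(
        f"cannot embed SSR {motif}x{n_repeats} into a CDS without stops"
    )


def _pads(length: int):
    if length == 0:
        yield ""
        return
    bases = "ACGT"
    if length == 1:
        yield from bases
        return
    for a in bases:
        for b in bases:
            yield a + b


@dataclass
class _Element:
    kind: str  # CDS / tRNA / rRNA
    name: str
    block: str
    exons: list[tuple[int, int]]  # within-block exon intervals
    strand: str
    cds: CodingSequence | None = None
    planted: list[dict] = field(default_factory=list)  # block-local entries


def _build_cds_element(rng, spec, name, plants) -> _Element:
    cds, _tally = _clean_cds(rng, spec.gene_len_codons, spec, name)
    seq = cds.seq
    entries: list[dict] = []
    for plant in (p for p in plants if p.region_class == "CDS"):
        seq, start = _embed_repeat_in_cds(seq, plant.motif,
                                          plant.n_repeats, rng)
        entries.append({"motif": plant.motif, "n_repeats": plant.n_repeats,
                        "unit_len": len(plant.motif), "local_start": start,
                        "region_class": "CDS"})
    intron_plants = [p for p in plants if p.region_class == "intron"]
    has_intron = bool(intron_plants) or rng.random() < spec.intron_frac
    if has_intron:
        blocked = [(e["local_start"] - 1,
                    e["local_start"] + e["unit_len"] * e["n_repeats"] + 1)
                   for e in entries]
        for _ in range(200):
            split = int(rng.integers(3, len(seq) - 3))
            if all(not (s < split < e) for s, e in blocked):
                break
        else:
            raise CapacityError("cannot split CDS around planted repeats")
        intron = _clean_background(rng, spec.intron_len, spec.background_gc)
        for plant in intron_plants:
            repeat_len = len(plant.motif) * plant.n_repeats
            at = (len(intron) - repeat_len) // 2
            intron, at = _overwrite_plant(intron, at, plant.motif,
                                          plant.n_repeats)
            entries.append({"motif": plant.motif,
                            "n_repeats": plant.n_repeats,
                            "unit_len": len(plant.motif),
                            "local_start": split + at,
                            "region_class": "intron"})
        block = seq[:split] + intron + seq[split:]
        exons = [(0, split), (split + len(intron), len(block))]
        for e in entries:
            if e["region_class"] == "CDS" and e["local_start"] >= split:
                e["local_start"] += len(intron)
    else:
        block = seq
        exons = [(0, len(seq))]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        m = len(block)
        block = revcomp(block)
        exons = sorted((m - e, m - s) for s, e in exons)
        for e in entries:
            length = e["unit_len"] * e["n_repeats"]
            e["local_start"] = m - e["local_start"] - length
            e["motif"] = revcomp(e["motif"])
    final_cds = CodingSequence(gene=name, genome_id=spec.genome_id, seq=seq,
                               complete=len(seq) % 3 == 0 and len(seq) >= 6)
    return _Element(kind="CDS", name=name, block=block, exons=exons,
                    strand=strand, cds=final_cds, planted=entries)


@dataclass
class GroundTruth:
    """Machine-readable truth tables accompanying a simulated genome."""

    spec: SimulationSpec
    features: list[Feature]
    cds: list[CodingSequence]
    codon_tallies: dict[str, dict[str, int]]
    ssrs: list[dict]  # motif, n_repeats, unit_len, start, end, region_class
    regions: dict[str, tuple[int, int]]  # lsc / irb / ssc / ira -> [start, end)


def simulate_genome(spec: SimulationSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Construct a circular quadripartite genome per the specification.

    Layout is LSC + IRb + SSC + IRa with IRa the exact reverse complement
    of IRb.  Genes fill the single-copy regions (LSC first) separated by
    intergenic gaps; planted SSRs go into gaps, introns or CDSs per their
    requested region class.  Junction bases are fixed so the IR pair
    cannot be extended by a single base, and the whole genome is scrubbed
    until the SSR scan reports exactly the planted loci.

    Raises :class:`CapacityError` when the requested content cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.background_gc

    gene_plants: list[list[PlantedSSR]] = [[] for _ in range(spec.n_genes)]
    feature_plants = [p for p in spec.ssr_plant_list
                      if p.region_class in ("CDS", "intron")]
    if feature_plants and spec.n_genes == 0:
        raise CapacityError("CDS/intron SSR planting requires genes")
    for i, plant in enumerate(feature_plants):
        gene_plants[i % spec.n_genes].append(plant)
    igs_plants = [p for p in spec.ssr_plant_list if p.region_class == "IGS"]

    elements: list[_Element] = []
    for i in range(spec.n_genes):
        elements.append(
            _build_cds_element(rng, spec, f"gene{i + 1:03d}", gene_plants[i])
        )
    for i in range(spec.n_trna):
        elements.append(
            _Element(kind="tRNA", name=f"trn{i + 1:02d}",
                     block=_clean_background(rng, spec.trna_len, gc),
                     exons=[(0, spec.trna_len)],
                     strand="+" if rng.random() < 0.5 else "-")
        )
    for i in range(spec.n_rrna):
        elements.append(
            _Element(kind="rRNA", name=f"rrn{i + 1:02d}",
                     block=_clean_background(rng, spec.rrna_len, gc),
                     exons=[(0, spec.rrna_len)],
                     strand="+" if rng.random() < 0.5 else "-")
        )
    order = rng.permutation(len(elements)) if elements else []
    elements = [elements[i] for i in order]

    # pack elements into LSC first, then SSC
    min_gap = 2
    assignment: dict[str, list[_Element]] = {"LSC": [], "SSC": []}
    used = {"LSC": min_gap, "SSC": min_gap}
    sizes = {"LSC": spec.lsc_len, "SSC": spec.ssc_len}
    for el in elements:
        need = len(el.block) + min_gap
        if used["LSC"] + need <= sizes["LSC"]:
            assignment["LSC"].append(el)
            used["LSC"] += need
        elif used["SSC"] + need <= sizes["SSC"]:
            assignment["SSC"].append(el)
            used["SSC"] += need
        else:
            raise CapacityError("gene content exceeds single-copy capacity")

    igs_assignment: dict[str, list[PlantedSSR]] = {"LSC": [], "SSC": []}
    for i, plant in enumerate(igs_plants):
        region = "SSC" if (i % 4 == 3 and spec.ssc_len >= 2000) else "LSC"
        igs_assignment[region].append(plant)

    region_start = {"LSC": 0,
                    "SSC": spec.lsc_len + spec.ir_len}
    planted_records: list[dict] = []
    features: list[Feature] = []
    region_seqs: dict[str, str] = {}

    for region in ("LSC", "SSC"):
        els = assignment[region]
        plants = igs_assignment[region]
        blocks_total = sum(len(e.block) for e in els)
        filler = sizes[region] - blocks_total
        n_gaps = len(els) + 1
        if filler < n_gaps * min_gap:
            raise CapacityError(f"{region} too small for requested content")
        base_gap, extra = divmod(filler, n_gaps)
        gap_lengths = [base_gap + (1 if i < extra else 0)
                       for i in range(n_gaps)]
        plant_by_gap: dict[int, list[PlantedSSR]] = {}
        for i, plant in enumerate(plants):
            plant_by_gap.setdefault(i % n_gaps, []).append(plant)
        pieces: list[str] = []
        pos = region_start[region]
        for gi in range(n_gaps):
            gap_seq = _clean_background(rng, gap_lengths[gi], gc)
            gplants = plant_by_gap.get(gi, [])
            if gplants:
                need = sum(len(p.motif) * p.n_repeats + 2 for p in gplants)
                if need + len(gplants) >= len(gap_seq):
                    raise CapacityError("IGS gap too small for planted SSRs")
                spacing = (len(gap_seq) - need) // (len(gplants) + 1)
                cursor = max(1, spacing)
                for plant in gplants:
                    gap_seq, at = _overwrite_plant(
                        gap_seq, cursor, plant.motif, plant.n_repeats
                    )
                    rep_len = len(plant.motif) * plant.n_repeats
                    planted_records.append(
                        {"motif": plant.motif, "n_repeats": plant.n_repeats,
                         "unit_len": len(plant.motif), "start": pos + at,
                         "end": pos + at + rep_len, "region_class": "IGS"}
                    )
                    cursor = at + rep_len + 1 + max(1, spacing)
            pieces.append(gap_seq)
            pos += len(gap_seq)
            if gi < len(els):
                el = els[gi]
                block_start = pos
                parts = tuple((block_start + s, block_start + e)
                              for s, e in el.exons)
                if el.kind == "CDS":
                    features.append(
                        Feature(kind="gene", name=el.name, strand=el.strand,
                                parts=((block_start,
                                        block_start + len(el.block)),))
                    )
                    features.append(
                        Feature(kind="CDS", name=el.name, strand=el.strand,
                                parts=parts)
                    )
                else:
                    features.append(
                        Feature(kind=el.kind, name=el.name, strand=el.strand,
                                parts=parts)
                    )
                for entry in el.planted:
                    rep_len = entry["unit_len"] * entry["n_repeats"]
                    planted_records.append(
                        {"motif": entry["motif"],
                         "n_repeats": entry["n_repeats"],
                         "unit_len": entry["unit_len"],
                         "start": block_start + entry["local_start"],
                         "end": block_start + entry["local_start"] + rep_len,
                         "region_class": entry["region_class"]}
                    )
                pieces.append(el.block)
                pos += len(el.block)
        region_seqs[region] = "".join(pieces)
        if len(region_seqs[region]) != sizes[region]:
            raise RuntimeError("region assembly length mismatch")

    irb = _clean_background(rng, spec.ir_len, gc)
    genome = region_seqs["LSC"] + irb + region_seqs["SSC"] + revcomp(irb)
    genome = _finalize_genome(genome, spec, planted_records, features, rng)

    record = GenomeRecord(id=spec.genome_id, sequence=genome, circular=True,
                          features=features)
    from .codon_stats import count_codons

    cds_truth = [el.cds for el in elements if el.kind == "CDS"]
    tallies = {c.gene: count_codons(c).counts for c in cds_truth}
    n = len(genome)
    regions = {
        "lsc": (0, spec.lsc_len),
        "irb": (spec.lsc_len, spec.lsc_len + spec.ir_len),
        "ssc": (spec.lsc_len + spec.ir_len,
                spec.lsc_len + spec.ir_len + spec.ssc_len),
        "ira": (spec.lsc_len + spec.ir_len + spec.ssc_len, n),
    }
    truth = GroundTruth(
        spec=spec, features=features, cds=cds_truth, codon_tallies=tallies,
        ssrs=sorted(planted_records, key=lambda d: d["start"]),
        regions=regions,
    )
    return record, truth


def _finalize_genome(genome, spec, planted, features, rng):
    """Enforce IR junction guards and scrub unplanned SSRs genome-wide."""
    n = len(genome)
    arr = list(genome)
    lsc_end = spec.lsc_len
    irb_end = spec.lsc_len + spec.ir_len
    ssc_end = irb_end + spec.ssc_len
    protected = np.zeros(n, dtype=bool)
    for entry in planted:
        protected[max(0, entry["start"] - 1) : min(n, entry["end"] + 1)] = True
    for f in features:
        if f.kind == "CDS":
            for s, e in f.parts:
                protected[s:e] = True
    guards = (0, lsc_end - 1, irb_end, ssc_end - 1)
    planted_spans = {(e["start"], e["end"]) for e in planted}

    def rebuild_ira():
        arr[ssc_end:n] = list(revcomp("".join(arr[lsc_end:irb_end])))

    for _ in range(500):
        changed = False
        # the IR pair must not be extendable by one base at either junction
        if arr[lsc_end - 1] == _COMP[arr[0]]:
            arr[lsc_end - 1] = next(
                b for b in "ACGT" if b != _COMP[arr[0]] and b != arr[lsc_end - 1]
            )
            changed = True
        if arr[irb_end] == _COMP[arr[ssc_end - 1]]:
            arr[ssc_end - 1] = next(
                b for b in "ACGT"
                if _COMP[b] != arr[irb_end] and b != arr[ssc_end - 1]
            )
            changed = True
        loci = find_ssrs("".join(arr), DEFAULT_THRESHOLDS)
        spans = {(l.start, l.end) for l in loci}
        extras = [l for l in loci if (l.start, l.end) not in planted_spans]
        if not extras and not changed and planted_spans <= spans:
            return "".join(arr)
        for locus in extras:
            editable = [p for p in range(locus.start, locus.end)
                        if not protected[p] and p not in guards]
            if not editable:
                raise RuntimeError(
                    f"unremovable spurious SSR at {locus.span}"
                )
            pos = editable[len(editable) // 2]
            if pos >= ssc_end:  # inside IRa: edit the IRb mirror instead
                pos = irb_end - 1 - (pos - ssc_end)
            arr[pos] = "ACGT"[(("ACGT".index(arr[pos]))
                               + 1 + int(rng.integers(3))) % 4]
        rebuild_ira()
    raise RuntimeError("genome finalization did not converge")
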