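# Methods

This note documents the statistical procedures implemented in plastcomp,
the conventions adopted where the underlying methods literature leaves a
choice open, and what the synthetic-data generator does and does not
emulate.

## Genome model and coordinates

A genome is a circular sequence over {A, C, G, T, N} with typed features
(gene, CDS, tRNA, rRNA).  All internal coordinates are 0-based half-open;
GenBank's 1-based inclusive coordinates are converted only at the file
boundary.  Features spanning the circular origin are normalized at load
time by rotating the sequence so no feature wraps; the rotation offset is
kept on the record so positions can be mapped back.

Coding sequences are the concatenation of a CDS feature's exon parts in
ascending genome order, reverse-complemented for minus-strand features.  A
CDS is *complete* when its spliced length is a multiple of three and at
least 6 bp; incomplete CDSs are retained but excluded from codon
statistics.  Genes duplicated by the inverted repeat are de-duplicated by
(name, sequence) identity for codon statistics, while per-genome gene
counts report raw annotation counts (the convention of published plastome
feature tables; the two numbers differ exactly by the IR-resident
duplicates).

Position classes partition the genome: CDS (inside a CDS exon), intron
(inside a gene/tRNA/rRNA footprint but in no exon part), IGS (everything
else).  An interval straddling a boundary takes the class of its start
coordinate — a deterministic single-label rule needed for location
percentages.  Note that under this rule tRNA/rRNA gene bodies fall into
IGS, not CDS; only protein-coding exons count as coding.

## Quadripartite structure

The detector finds the maximal-length *exact* inverted-repeat pair with
non-overlapping copies on the circle, via 31-mer seed matches between the
doubled sequence and its doubled reverse complement, merged along
diagonals and extended to maximal runs.  The two gaps between the copies
are labeled LSC (longer) and SSC (shorter).  Exact matching is
appropriate because plastid IR copies are typically identical; it also
makes maximality checkable base-by-base and the result invariant under
rotation of the circular sequence.  Ties among equally long candidates
break toward the smallest start coordinate.  `min_ir_bp` defaults to
1,000 bp: real plastid IRs are tens of kb, and 1 kb excludes dispersed
small repeats while remaining permissive.  On real accessions an
exact-match IR may differ by a few bases from annotation-derived
boundaries, which are sometimes curated rather than computed.

## SSR census

Perfect tandem repeats only, with unit-length thresholds
{1: 10, 2: 5, 3: 4, 4–10: 3} copies (configurable); primitive units of
11–50 bp with ≥ 3 copies form the ExtendedSSR class (50 bp is a declared
cap; the upper bound of the ">10 bp" class is otherwise open).  For each
unit length the scanner marks positions where `s[i] == s[i+u]`, extracts
maximal periodic runs, trims them to whole units anchored at the run
start, and reports only primitive motifs (a motif that is itself a
repetition of a shorter unit is a re-description, e.g. "AA" inside a
poly-A run).  A locus whose span lies inside a locus of shorter unit is
suppressed for the same reason.  Runs containing N break at the N.
Motifs are recorded as read on the plus strand; a `canonical_motif`
column (lexicographically minimal rotation) supports motif-level grouping
across genomes.  Because detection runs on the full genome, loci inside
the inverted repeats appear once per IR copy; users who want
single-copy counts can intersect loci with the detected IR intervals.
Richness is the AT fraction of the motif: > 0.5 AT-rich, < 0.5 GC-rich,
exactly 0.5 balanced.

## Codon usage statistics

Codon counts are a frame-0 scan of complete CDSs; the terminal stop codon
and any codon containing a non-ACGT symbol are dropped, and stop codons
are never counted.

*RSCU* is the observed count divided by the family mean.  Families with
zero total count are flagged undefined rather than zero (a structurally
missing value, not an observed avoidance).  Met and Trp are reported as
1.0 by convention and excluded from feature vectors, giving the standard
59-dimensional RSCU vector; undefined entries are imputed as 0 when a
vector is required.

*ENC* follows Wright (1990).  F̂ = (nΣp̂² − 1)/(n − 1) uses the amino
acid's total codon count n; amino acids with n < 2 or non-positive F̂ are
excluded from the degeneracy-class means; a missing threefold mean (Ile
unobserved) is imputed as (F₂ + F₄)/2; if any other class has no usable
amino acid, ENC is undefined.  The final value is clipped to the
theoretical [20, 61] range — the clip matters in practice, because for
near-uniform usage the reciprocal form of the estimator overshoots 61
slightly at finite counts.  At small gene sizes (~100 codons) the
estimator is noticeably noisy and biased downward of the ceiling; ENC
comparisons should be made at comparable gene lengths.

*GC3s* uses third positions of codons whose amino acid has degeneracy
> 1 (Met, Trp and stops excluded) — the synonymous-site universe.  GC12
is the mean of GC1 and GC2 over all counted codons.

*PR2* coordinates are (G3/(G3+C3), A3/(A3+T3)).  The default universe is
the fourfold-degenerate families — the classical Parity-Rule-2 setting,
where every third-position change is synonymous and mutation–selection
balance predicts A=T and G=C — with an `all_degenerate` mode for the
broader definition some studies use.  A coordinate whose denominator is
zero is undefined and the gene is excluded from plots and means.

*Neutrality fit* is ordinary least squares of GC12 on GC3 (scipy); it
requires ≥ 3 genes and a non-constant predictor.  A constant response is
returned as slope 0 with R² = 0.

*Ordination* is column-centered PCA (scikit-learn) of the genes × 59
RSCU matrix; explained-variance fractions are relative to total variance,
so they sum to ≤ 1 and are invariant to gene order.  A classical
correspondence-analysis mode (chi-square scaling, SVD) is provided for
comparability with codon-usage studies that use COA, but PCA is the
default because the centered-RSCU formulation is what the 59-vector
construction describes.

Per-genome aggregate statistics (species means of ENC, GC3s, PR2) are
unweighted means over genes with defined values.

## Ka/Ks (NG86)

Sites: each codon contributes exactly three sites split by the fraction
of synonymous changes among its nine single-nucleotide neighbors;
mutations to stop codons are excluded from the per-position denominator.
Differences: per aligned codon pair, all orderings of the differing
positions are enumerated and averaged with equal weight; pathways through
stop codons are discarded.  In the rare case where every minimal pathway
is blocked by a stop codon, the average falls back to all pathways so the
pair still contributes (the alternative — dropping the column — would
bias divergent pairs downward).  S and N are averaged over the two
sequences; pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), undefined at saturation (p ≥ 3/4); ω = Ka/Ks is
undefined when Ks = 0.

Homolog pairs of unequal length are aligned through their translations
(global alignment, match +1, mismatch −1, gap open −5, extend −1 — fixed
so results are reproducible) and threaded back to codons; gap-containing
columns are removed.  NG86 with JC correction is a deliberately
self-contained counting estimator: it is exactly checkable against
exhaustive pathway enumeration, at the cost of ignoring
transition/transversion and codon-frequency effects that model-based
estimators absorb, so absolute ω values on real data can differ slightly
from model-averaged tools.

Regime bins: ω < 0.5 strong purifying; 0.5 ≤ ω ≤ 1.0 relaxed purifying
(the 0.5 boundary is assigned to the relaxed bin — half-open bins,
declared explicitly); ω > 1.0 positive; undefined otherwise.

Cohort profiling compares each gene of every genome against a single
declared reference genome (default: the first genome).  A reference
scheme keeps the number of comparisons linear and the pairing
deterministic; all-vs-all averaging is a different estimand and is not
provided.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
plastome biology in detail:

- **Layout**: LSC + IRb + SSC + IRa, IRa an exact reverse complement of
  IRb.  Junction bases are set so the IR pair cannot be extended by one
  base, making the detector's maximality property hold by construction.
  Defaults are the dimensions of the reference genome this package was
  built around (87,592 / 18,599 / 26,994 bp; 160,179 bp total) with its
  gene complement (86 CDS + 37 tRNA + 8 rRNA), ~300-codon genes (mean
  plastid CDS ≈ 900 bp) and non-coding GC of 0.35.
- **Background** is i.i.d. bases at a configurable GC, iteratively
  re-randomized until the SSR scan finds nothing, so planted signal and
  noise are cleanly separated.  The whole assembled genome is scrubbed
  the same way (edits mirrored into the IR copy) until the scan reports
  exactly the planted loci.
- **CDS emission** draws codons i.i.d. with amino-acid marginals
  proportional to family size (so the default is uniform over the 61
  sense codons), within-family weights either supplied, or drawn from a
  symmetric Dirichlet (small concentration → strong bias), and an
  optional exact third-position GC target per degenerate family.  The
  emission tally is returned and equals the codon census of the emitted
  sequence.
- **Neutrality cohorts**: per-gene GC pressure g ~ Uniform(0.2, 0.8)
  applied at all three positions (mutational regime, slope → 1).  The
  selection variant gives the third position an *independent* pressure
  h ~ Uniform(0.2, 0.8): GC3 then carries no information about GC12 and
  the fitted slope converges to 0 with standard error ≈ 0.045 at 500
  genes.  Pinning GC3 at a constant would instead leave only binomial
  noise in the predictor and make the slope estimator uninformative
  (standard error ≈ 0.8), so the decoupled-pressure construction is the
  one that actually tests the claim.  The constant mode returns exact
  (0.5, 0.5) points — a degenerate predictor for which the fit is
  undefined.
- **dN/dS control**: substitutions are proposed uniformly over sites and
  alternative bases, stop-creating proposals rejected; nonsynonymous
  proposals are accepted with probability ω (ω ≤ 1) or synonymous ones
  with probability 1/ω (ω > 1), stopping after round(divergence × L)
  accepted substitutions.  At low divergence the NG86 estimate of ω is
  centered on the target (the acceptance ratio matches the site-count
  ratio up to small stop-adjacency effects).  This is an acceptance
  filter, not a continuous-time codon model: it has no
  transition/transversion structure and divergence is a fixed count
  rather than Poisson.

What the generator does not emulate: real plastome gene order and operon
structure, genes inside the IR, intron biology (introns are plain
background), phylogenetic correlation among genomes, imperfect repeats,
sequencing error.  Tests passing on synthetic data therefore validate
the *estimators and detectors*, not robustness to annotation noise or to
evolutionary model misspecification on real accessions.

## Problem sizes and numerics

The test suite validates the analytic limits exactly (ENC 61/20, RSCU 1,
PR2 center), detection on constructed genomes up to full plastome size
(160 kb), SSR recovery of 50 planted loci in a 100 kb genome,
neutrality-slope recovery on 500 genes × 2,000 codons, and ω recovery at
targets 0.1 / 0.5 / 2.0 over 100 replicates of 300-codon pairs at
divergence 0.05 — sizes chosen so each check is statistically meaningful
while the whole suite runs in seconds.  ENC agreement with an
independently written brute-force implementation is asserted to 1e-9;
pathway-difference agreement with exhaustive enumeration to 1e-12;
stochastic recoveries use the simulation tolerances stated above.

## Known limitations

- Exact-match IR detection can disagree with curated annotation
  boundaries by a few bases on real accessions.
- The SSR scanner has no imperfect-repeat mode; published censuses from
  tools with mismatch tolerance will differ.
- NG86 assumes equal mutation rates among nucleotides; ω on real genes
  shifts slightly relative to model-averaged estimators.
- Published cohort-level values for a given family additionally depend on
  unstated tool settings (repeat-scanner mode, gene inclusion filters,
  PR2 codon universe, Ka/Ks pairing scheme); this package makes each such
  choice explicit and configurable instead of trying to reverse-engineer
  any one publication's pipeline.
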