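"""NG86 Ka/Ks: site counting, pathway averaging, alignment, regimes."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from plastcomp._genetics import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from plastcomp.genome_io import CodingSequence
from plastcomp.selection import (
    classify_omega,
    codon_align,
    kaks,
    ng86_kaks,
    ng86_sites,
    pathway_differences,
    regime_fractions,
)
from plastcomp.simulate import evolve_pair, simulate_cds


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_pathways(c1: str, c2: str) -> tuple[float, float]:
    """Recursive exhaustive pathway enumeration, written independently of
    the implementation's permutation walk."""

    def expand(current: str, remaining: frozenset[int]):
        if not remaining:
            yield (0, 0, True)
            return
        for pos in remaining:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            through_stop = nxt in STOP_CODONS
            syn = (not through_stop
                   and CODON_TO_AA.get(nxt) == CODON_TO_AA.get(current))
            aa_cur = CODON_TO_AA.get(current, "*")
            aa_nxt = CODON_TO_AA.get(nxt, "*")
            step_syn = 1 if aa_cur == aa_nxt else 0
            for s, n, ok in expand(nxt, remaining - {pos}):
                yield (s + step_syn, n + (1 - step_syn),
                       ok and not through_stop)

    diff = frozenset(i for i in range(3) if c1[i] != c2[i])
    if not diff:
        return 0.0, 0.0
    paths = list(expand(c1, diff))
    usable = [(s, n) for s, n, ok in paths if ok]
    if not usable:
        usable = [(s, n) for s, n, _ in paths]
    return (sum(p[0] for p in usable) / len(usable),
            sum(p[1] for p in usable) / len(usable))


def oracle_protein_alignment(p1: str, p2: str) -> float:
    """Plain Needleman–Wunsch with affine gaps approximated as linear open
    cost per gap column (matches the aligner settings used for scoring
    comparisons on gap-free optimal alignments)."""
    inf = float("inf")
    m, n = len(p1), len(p2)
    score = [[-inf] * (n + 1) for _ in range(m + 1)]
    score[0][0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i < m and j < n:
                s = 1.0 if p1[i] == p2[j] else -1.0
                score[i + 1][j + 1] = max(score[i + 1][j + 1],
                                          score[i][j] + s)
            if i < m:
                score[i + 1][j] = max(score[i + 1][j], score[i][j] - 5.0)
            if j < n:
                score[i][j + 1] = max(score[i][j + 1], score[i][j] - 5.0)
    return score[m][n]


class TestSites:
    def test_glycine_third_position_fully_synonymous(self):
        assert ng86_sites("GGG") == (pytest.approx(1.0), pytest.approx(2.0))

    def test_methionine_has_no_synonymous_sites(self):
        s, n = ng86_sites("ATG")
        assert s == 0.0 and n == 3.0

    def test_tryptophan_stop_neighbors_excluded(self):
        # TGG: position 2 has neighbor TAG (stop), position 3 has TGA (stop)
        s, n = ng86_sites("TGG")
        assert s == 0.0 and n == 3.0

    def test_neighbor_enumeration_oracle_over_all_codons(self):
        for codon in SENSE_CODONS:
            syn_fraction_sum = 0.0
            for pos in range(3):
                changes = [
                    codon[:pos] + b + codon[pos + 1 :]
                    for b in "ACGT" if b != codon[pos]
                ]
                sense = [c for c in changes if c not in STOP_CODONS]
                if sense:
                    syn = sum(
                        1 for c in sense
                        if CODON_TO_AA[c] == CODON_TO_AA[codon]
                    )
                    syn_fraction_sum += syn / len(sense)
            s, n = ng86_sites(codon)
            assert s == pytest.approx(syn_fraction_sum, abs=1e-12)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPathways:
    def test_two_substitution_toy_pair_matches_enumeration(self):
        # 5-codon pair with one 2-substitution codon (CCT -> CAG)
        sd, nd = pathway_differences("CCT", "CAG")
        osd, ond = oracle_pathways("CCT", "CAG")
        assert sd == pytest.approx(osd, abs=1e-12)
        assert nd == pytest.approx(ond, abs=1e-12)
        assert sd + nd == pytest.approx(2.0)

    def test_seeded_panel_matches_oracle(self):
        rng = np.random.default_rng(606)
        codons = list(SENSE_CODONS)
        for _ in range(200):
            c1, c2 = rng.choice(codons, size=2)
            sd, nd = pathway_differences(c1, c2)
            osd, ond = oracle_pathways(c1, c2)
            assert sd == pytest.approx(osd, abs=1e-12)
            assert nd == pytest.approx(ond, abs=1e-12)


class TestKaKs:
    def _pair(self, seed=1, n=100):
        cds, _ = simulate_cds(n_codons=n, seed=seed)
        return cds

    def test_identical_pair_has_zero_rates(self):
        cds = self._pair()
        r = ng86_kaks(cds.seq, cds.seq)
        assert r.Sd == 0 and r.Nd == 0
        assert r.Ka == 0 and r.Ks == 0
        assert r.omega is None and r.regime == "undefined"

    def test_single_synonymous_change_sign_structure(self):
        cds = self._pair(seed=2)
        seq = cds.seq[:9] + "GAA" + cds.seq[12:]
        other = seq[:9] + "GAG" + seq[12:]
        r = ng86_kaks(seq, other)
        assert r.Nd == 0 and r.Sd == pytest.approx(1.0)
        assert r.Ka == 0 and r.Ks > 0
        assert r.omega == pytest.approx(0.0)

    def test_symmetry(self):
        a = self._pair(seed=3)
        b, _ = evolve_pair(a, 0.8, 0.05, seed=4)
        r1 = ng86_kaks(a.seq, b.seq)
        r2 = ng86_kaks(b.seq, a.seq)
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)

    def test_site_conservation(self):
        a = self._pair(seed=5)
        b, _ = evolve_pair(a, 1.0, 0.08, seed=6)
        r = ng86_kaks(a.seq, b.seq)
        assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_too_few_codons_rejected(self):
        with pytest.raises(ValueError):
            ng86_kaks("ATGGCT", "ATGGCT")


class TestClassify:
    @pytest.mark.parametrize("omega,regime", [
        (0.05, "strong_purifying"),
        (0.49999, "strong_purifying"),
        (0.5, "relaxed_purifying"),
        (1.0, "relaxed_purifying"),
        (1.51, "positive"),
        (None, "undefined"),
    ])
    def test_bins(self, omega, regime):
        assert classify_omega(omega) == regime

    def test_regime_fractions_sum_to_one(self):
        results = []
        for seed, omega in enumerate((0.1, 0.4, 0.8, 2.0)):
            cds, _ = simulate_cds(n_codons=200, seed=900 + seed)
            mut, _ = evolve_pair(cds, omega, 0.05, seed=950 + seed)
            results.append(ng86_kaks(cds.seq, mut.seq))
        df = regime_fractions(results)
        assert df["fraction"].sum() == pytest.approx(1.0)


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        cds, _ = simulate_cds(n_codons=40, seed=10)
        a1, a2 = codon_align(cds, cds)
        assert a1 == a2 == cds.seq[:-3]

    def test_internal_codon_deletion_removed(self):
        cds, _ = simulate_cds(n_codons=50, seed=11)
        s = cds.seq
        deleted = CodingSequence("g", "s2", s[:30] + s[33:], True)
        a1, a2 = codon_align(cds, deleted)
        assert len(a1) == len(a2) == len(s) - 3 - 3
        assert a2 == deleted.seq[:-3]

    def test_alignment_score_matches_dp_oracle(self):
        from Bio.Align import PairwiseAligner

        from plastcomp._genetics import translate
        from plastcomp.selection import (
            ALIGN_GAP_OPEN,
            ALIGN_MATCH,
            ALIGN_MISMATCH,
        )

        rng = np.random.default_rng(12)
        cds, _ = simulate_cds(n_codons=50, seed=12)
        seq = list(cds.seq[:-3])
        for _ in range(3):  # three random substitutions
            pos = int(rng.integers(len(seq)))
            seq[pos] = "ACGT"[int(rng.integers(4))]
        p1 = translate(cds.seq[:-3])
        p2 = translate("".join(seq))
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = ALIGN_MATCH
        aligner.mismatch_score = ALIGN_MISMATCH
        aligner.open_gap_score = ALIGN_GAP_OPEN
        aligner.extend_gap_score = -1.0
        assert aligner.score(p1, p2) == oracle_protein_alignment(p1, p2)
        # with substitutions only, the optimal alignment keeps every column
        mutated = CodingSequence("g", "s2", "".join(seq) + cds.seq[-3:], True)
        a1, a2 = codon_align(cds, mutated)
        assert a1 == cds.seq[:-3]
        assert a2 == "".join(seq)

    def test_kaks_convenience_runs_end_to_end(self):
        cds, _ = simulate_cds(n_codons=60, seed=13)
        mut, _ = evolve_pair(cds, 0.5, 0.05, seed=14)
        r = kaks(cds, mut)
        assert r.n_codons == 60
        assert r.omega is None or r.omega >= 0
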