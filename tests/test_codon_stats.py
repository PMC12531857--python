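"""Codon usage statistics: counts, RSCU, ENC, positional GC, PR2,
neutrality regression and ordination."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp._genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    RSCU_CODONS,
    SENSE_CODONS,
)
from plastcomp.codon_stats import (
    CodonCountTable,
    count_codons,
    enc,
    enc_expected,
    neutrality_fit,
    ordinate_rscu,
    positional_gc,
    pr2,
    rscu,
    rscu_vector,
)
from plastcomp.genome_io import CodingSequence
from plastcomp.simulate import simulate_cds


def _table(counts: dict[str, int]) -> CodonCountTable:
    return CodonCountTable(gene="g", genome_id="s", counts=counts)


def _cds(seq: str) -> CodingSequence:
    return CodingSequence("g", "s", seq, len(seq) % 3 == 0 and len(seq) >= 6)


# ---------------------------------------------------------------------------
# Independent oracle: a deliberately naive re-derivation of Wright's ENC
# ---------------------------------------------------------------------------


def brute_force_enc(counts: dict[str, int]) -> float | None:
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if k == 1:
            continue
        xs = [counts.get(c, 0) for c in codons]
        n = sum(xs)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in xs) - 1) / (n - 1)
        if f > 0:
            per_class[k].append(f)
    f_bar = {k: (sum(v) / len(v) if v else None) for k, v in per_class.items()}
    if f_bar[3] is None and f_bar[2] is not None and f_bar[4] is not None:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
    if any(f_bar[k] is None for k in (2, 3, 4, 6)):
        return None
    value = 2 + 9 / f_bar[2] + 1 / f_bar[3] + 5 / f_bar[4] + 3 / f_bar[6]
    return min(61.0, max(20.0, value))


class TestCountCodons:
    def test_simple_census_excludes_stop(self):
        table = count_codons(_cds("ATGGCTGCTTAA"))
        assert table.counts == {"ATG": 1, "GCT": 2}

    def test_ambiguous_codon_dropped(self):
        table = count_codons(_cds("ATGNNNGCTTAA"))
        assert table.counts == {"ATG": 1, "GCT": 1}

    def test_emission_tally_identity(self):
        cds, tally = simulate_cds(n_codons=1000, seed=3)
        assert count_codons(cds).counts == tally

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            count_codons(CodingSequence("g", "s", "ATG", False))


class TestRSCU:
    def test_uniform_family_usage_gives_one(self):
        table = _table({c: 4 for c in SENSE_CODONS})
        values = rscu(table)
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_single_codon_concentration_forces_family_size(self):
        leu = AA_TO_CODONS["L"]
        table = _table({"TTA": 12})
        values = rscu(table)
        assert values["TTA"] == pytest.approx(6.0)
        for codon in leu:
            if codon != "TTA":
                assert values[codon] == pytest.approx(0.0)

    def test_hand_computed_two_fold(self):
        values = rscu(_table({"GAA": 3, "GAG": 1}))
        assert values["GAA"] == pytest.approx(1.5)
        assert values["GAG"] == pytest.approx(0.5)

    def test_unobserved_family_flagged_not_zero(self):
        values = rscu(_table({"GAA": 1}))
        assert values["TGT"] is None and values["TGC"] is None

    def test_vector_has_59_dimensions_without_met_trp(self):
        assert len(RSCU_CODONS) == 59
        assert "ATG" not in RSCU_CODONS and "TGG" not in RSCU_CODONS
        vec = rscu_vector(_table({"GAA": 2, "GAG": 2}))
        assert vec.shape == (59,)

    @given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                           st.integers(min_value=0, max_value=50),
                           max_size=61))
    @settings(max_examples=100, deadline=None)
    def test_family_sums_equal_family_size(self, counts):
        values = rscu(_table(counts))
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) == 1:
                continue
            family = [values[c] for c in codons]
            total = sum(counts.get(c, 0) for c in codons)
            if total == 0:
                assert all(v is None for v in family)
            else:
                assert sum(family) == pytest.approx(len(codons))


class TestENC:
    def test_equal_usage_caps_at_61(self):
        assert enc(_table({c: 100 for c in SENSE_CODONS})) == 61.0

    def test_one_codon_per_amino_acid_gives_20(self):
        table = _table({cs[0]: 100 for cs in AA_TO_CODONS.values()})
        assert enc(table) == pytest.approx(20.0)

    def test_two_fold_homozygosity_hand_value(self):
        # counts (3, 1): n = 4, sum p^2 = 0.625, F = (4*0.625 - 1)/3 = 0.5
        from plastcomp.codon_stats import _family_homozygosity

        assert _family_homozygosity({"GAA": 3, "GAG": 1}) == pytest.approx(0.5)

    def test_empty_table_undefined(self):
        assert enc(_table({})) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_genes(self, seed):
        cds, _ = simulate_cds(n_codons=200, seed=seed,
                              concentration=[5.0, 1.0, 0.2][seed % 3])
        table = count_codons(cds)
        expected = brute_force_enc(table.counts)
        got = enc(table)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_concentration(self):
        means = []
        for conc in (10.0, 1.0, 0.1):
            values = []
            for s in range(15):
                cds, _ = simulate_cds(n_codons=500, seed=700 + s,
                                      concentration=conc)
                values.append(enc(count_codons(cds)))
            means.append(np.mean(values))
        assert means[0] > means[1] > means[2]

    def test_uniform_emission_approaches_61(self):
        cds, _ = simulate_cds(n_codons=6100, seed=13)
        assert enc(count_codons(cds)) > 59.5


class TestENCExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0),
                                            (1.0, 32.0)])
    def test_closed_form_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_maximum_at_one_half(self):
        grid = np.linspace(0.01, 0.99, 199)
        values = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5, abs=0.01)


class TestPositionalGC:
    def test_met_plus_gcg_counts_ala_only(self):
        table = count_codons(_cds("ATGGCGTAA"))
        gc = positional_gc(table)
        assert gc.g3 == 1 and gc.a3 == gc.t3 == gc.c3 == 0
        assert gc.gc3s == pytest.approx(1.0)

    def test_positionwise_tally_single_codon(self):
        # GAA: G, A, A -> only the first position contributes G+C
        table = _table({"GAA": 10})
        gc = positional_gc(table)
        assert gc.gc1 == 1.0 and gc.gc2 == 0.0 and gc.gc3 == 0.0
        assert gc.gc12 == pytest.approx(0.5)
        # GCA: G, C, A -> positions 1 and 2 are both G/C
        gc2 = positional_gc(_table({"GCA": 10}))
        assert gc2.gc1 == 1.0 and gc2.gc2 == 1.0 and gc2.gc3 == 0.0
        assert gc2.gc12 == pytest.approx(1.0)

    def test_gc3_target_recovered_within_sampling_error(self):
        n = 30_000
        cds, _ = simulate_cds(n_codons=n, seed=4, gc3_target=0.30)
        gc = positional_gc(count_codons(cds))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(gc.gc3s - 0.30) < 3 * se


class TestPR2:
    def test_balanced_composition_maps_to_center(self):
        table = _table({"GCA": 5, "GCT": 5, "GCG": 5, "GCC": 5})
        assert pr2(table) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_all_g_third_positions(self):
        table = _table({"GCG": 8, "GGG": 2})
        x, y = pr2(table)
        assert x == pytest.approx(1.0)
        assert y is None  # no A/T third positions observed

    def test_fourfold_vs_all_degenerate_hand_tally(self):
        # Glu (GAA/GAG, twofold) only enters the all-degenerate universe.
        # Fourfold (Ala only): A3=2, G3=2, T3=2, C3=1 -> x=2/3, y=1/2.
        # All-degenerate adds GAA (A3+=4) and GAG (G3+=1)
        #   -> A3=6, G3=3, T3=2, C3=1 -> x=3/4, y=3/4.
        table = _table({"GCA": 2, "GCG": 2, "GCT": 2, "GCC": 1,
                        "GAA": 4, "GAG": 1})
        assert pr2(table, codon_set="fourfold") == (
            pytest.approx(2 / 3), pytest.approx(1 / 2)
        )
        assert pr2(table, codon_set="all_degenerate") == (
            pytest.approx(3 / 4), pytest.approx(3 / 4)
        )

    def test_zero_denominator_excluded(self):
        x, y = pr2(_table({"GAA": 3}))
        assert x is None and y is None


class TestNeutralityFit:
    def test_identity_line(self):
        pts = [(x, x) for x in (0.2, 0.3, 0.4, 0.5)]
        fit = neutrality_fit(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        pts = [(x, 0.4) for x in (0.2, 0.3, 0.4, 0.5)]
        fit = neutrality_fit(pts)
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_constant_predictor_undefined(self):
        with pytest.raises(ValueError):
            neutrality_fit([(0.3, 0.1), (0.3, 0.2), (0.3, 0.3)])


class TestOrdination:
    def test_identical_rows_have_zero_variance(self):
        x = np.tile(np.linspace(0, 2, 59), (5, 1))
        res = ordinate_rscu(x)
        assert all(e == 0.0 for e in res.explained)
        assert np.allclose(res.coordinates, 0.0)

    def test_rank_one_structure_explained_by_axis_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(59), rng.random(59)
        x = np.vstack([a] * 5 + [b] * 5)
        res = ordinate_rscu(x)
        assert res.explained[0] == pytest.approx(1.0)
        assert res.explained[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.random((20, 59))
        res = ordinate_rscu(x)
        cov = np.cov(x, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fractions = eig / eig.sum()
        assert res.explained[0] == pytest.approx(fractions[0], abs=1e-9)
        assert res.explained[1] == pytest.approx(fractions[1], abs=1e-9)

    def test_permutation_invariant_explained_variance(self):
        rng = np.random.default_rng(2)
        x = rng.random((15, 59))
        res1 = ordinate_rscu(x)
        perm = rng.permutation(15)
        res2 = ordinate_rscu(x[perm])
        assert res1.explained == pytest.approx(res2.explained)
        assert sum(res1.explained) <= 1.0 + 1e-9

    def test_needs_three_genes(self):
        with pytest.raises(ValueError):
            ordinate_rscu(np.zeros((2, 59)))
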