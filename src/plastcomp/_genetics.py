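"""Standard genetic code tables shared across the package.

All sequences are plus-strand DNA over {A, C, G, T, N}; codons are DNA
triplets (the tabular outputs render them with U for display, matching the
convention of codon-usage literature).
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the standard code; plastid CDSs use it

#: codon (DNA) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in sorted({CODON_TO_AA[c] for c in SENSE_CODONS})
}

#: amino acid -> synonymous family size (1, 2, 3, 4 or 6)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: single-codon amino acids (Met, Trp) -- excluded from RSCU feature vectors
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, n in DEGENERACY.items() if n == 1
)

#: the 59 codons used as RSCU feature vectors (sense minus ATG and TGG)
RSCU_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a frame-0 DNA string; stops become '*', ambiguous codons 'X'."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in CODON_TO_AA:
            aas.append(CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append("X")
    return "".join(aas)


def to_rna(codon: str) -> str:
    """Render a DNA codon with U, the display convention for codon tables."""
    return codon.replace("T", "U")
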