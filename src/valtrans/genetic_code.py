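"""Standard genetic code tables used throughout the package.

Derived from Biopython's standard codon table (NCBI table 1) so the
codon/amino-acid mapping is never hand-typed.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: the three stop codons (TAA, TAG, TGA)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: 61 sense codons in alphabetical order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: all 64 codons
ALL_CODONS: tuple[str, ...] = tuple(sorted(SENSE_CODONS + STOP_CODONS))

#: 20 amino acids, one-letter, alphabetical
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of its codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (strict Watson-Crick, ACGT only)."""
    return seq.translate(_COMPLEMENT)[::-1]


def codon_to_anticodon(codon: str) -> str:
    """Anticodon read 5'->3' that decodes ``codon`` by exact pairing.

    Wobble decoding is deliberately not modelled: GTG maps to CAC and
    nothing else.
    """
    return reverse_complement(codon)
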