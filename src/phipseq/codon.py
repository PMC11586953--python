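"""Deterministic codon usage for reverse-translating peptide tiles.

The display library encodes each peptide with a fixed, deterministic codon
per residue (the most frequently used codon in highly expressed E. coli
genes). A deterministic table keeps library construction reproducible and
makes reverse translation an exact left inverse of translation.

The ambiguity residue ``X`` maps to ``NNN``, which the standard translation
table reads back as ``X``.
"""

from __future__ import annotations

from Bio.Seq import Seq

#: Most-used codon per amino acid in highly expressed E. coli genes.
ECOLI_PREFERRED_CODONS: dict[str, str] = {
    "A": "GCG",
    "R": "CGC",
    "N": "AAC",
    "D": "GAT",
    "C": "TGC",
    "Q": "CAG",
    "E": "GAA",
    "G": "GGC",
    "H": "CAT",
    "I": "ATT",
    "L": "CTG",
    "K": "AAA",
    "M": "ATG",
    "F": "TTT",
    "P": "CCG",
    "S": "AGC",
    "T": "ACC",
    "W": "TGG",
    "Y": "TAT",
    "V": "GTG",
    "X": "NNN",
}

#: Nucleotide sequence encoding the FLAG tag (DYKDDDDK), used as the
#: 5' flank of every insert.
FLAG_TAG_NT = "".join(ECOLI_PREFERRED_CODONS[aa] for aa in "DYKDDDDK")

#: Nucleotide sequence encoding the STREP tag (WSHPQFEK), used as the
#: 3' flank of every insert.
STREP_TAG_NT = "".join(ECOLI_PREFERRED_CODONS[aa] for aa in "WSHPQFEK")


def translate_nt(nt: str) -> str:
    """Translate a nucleotide sequence to protein (standard table)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"nucleotide length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())
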