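"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STOP_CODONS = {"TAA", "TAG", "TGA"}
#: the 61 sense codons, used when synthesising stop-free reading frames
SENSE_CODONS = tuple(
    a + b + c
    for a in DNA_ALPHABET
    for b in DNA_ALPHABET
    for c in DNA_ALPHABET
    if a + b + c not in STOP_CODONS
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string codon by codon; trailing partial codon is dropped."""
    return "".join(_CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def is_dna(seq: str) -> bool:
    return bool(seq) and not set(seq) - set(DNA_ALPHABET)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=n))


def random_orf(rng: np.random.Generator, n_nt: int, start_atg: bool = False) -> str:
    """Random stop-free reading frame of ``n_nt`` nucleotides (multiple of 3)."""
    if n_nt % 3:
        raise ValueError("ORF length must be a multiple of 3")
    n_codons = n_nt // 3
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    if start_atg and codons:
        codons[0] = "ATG"
    return "".join(codons)
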