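"""Synthetic germline locus and cloning-element generator.

Real murine TRA/TRB germline sequences are not bundled with the package;
instead this module synthesises a length-calibrated stand-in locus on the
fly (the package ships no data files).  The locus is:

* 20 TRAV / 10 TRAJ / 1 TRAC   (alpha chain)
* 26 TRBV / 12 TRBJ / 1 TRBC   (beta chain)
* 13 alpha leader peptides (SSA-F01..F13), one per Vα family, mirroring the
  13-vector expression library; a single beta leader (SSB)
* the porcine teschovirus-1 P2A linker (real 66 nt sequence)
* a synthetic vector-backbone core carrying the colony-screen control-primer
  sites

Segment lengths are calibrated so that

* second-PCR amplicons (8 nt tag + 22 nt universal linker + V + junction
  N-region + J + 80 nt constant-region stub + 8 nt tag) fall inside the
  accepted 480-560 nt merged-read window for every V/J/N combination, and
* the colony-screen product between the control primers on an assembled
  expression construct falls inside the expected 1600-1700 bp window.

All sequences are drawn from a seeded RNG; reading frames that end up inside
the expression ORF are synthesised stop-free, V segments end on a TGT/TGC
cysteine codon and J segments carry an in-frame TTT/TTC...GGN-NNN-GGN FGxG
motif, so junction arithmetic behaves like the real loci.
"""

from __future__ import annotations

import numpy as np

from ._dna import SENSE_CODONS, random_dna, random_orf
from .reference import GeneSegment, ReferenceSet

#: universal forward-primer linker (5' of every first-PCR V primer)
UNIVERSAL_LINKER = "GCAGTGGTATCAACGCAGAGTA"  # 22 nt
#: porcine teschovirus-1 2A peptide (GSG-ATNFSLLKQAGDVEENPGP), 66 nt
P2A_NT = (
    "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
)
#: colony-screen control primers (forward primes the backbone upstream of
#: the SSα cassette; reverse primes downstream of the Cβ stop)
CONTROL_FW = "TCGATCCTCCCTTTATCCAG"
CONTROL_REV = "CCATGGAACTGCACTTG"

N_V_ALPHA, N_J_ALPHA = 20, 10
N_V_BETA, N_J_BETA = 26, 12
N_FAMILIES_ALPHA = 13

LEN_SS_ALPHA = 60
LEN_SS_BETA = 57
LEN_C_ALPHA = 300
LEN_C_BETA = 270  # includes the terminal TAA stop
C_STUB_LEN = 80   # constant-region bases captured on the sequencing amplicon

_V_ALPHA_LENGTHS = (324, 327, 330, 333, 336)
_V_BETA_LENGTHS = (330, 333, 336, 339, 342)
_J_ALPHA_LENGTHS = (57, 60)
_J_BETA_LENGTHS = (54, 57, 60)

_REVCOMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def _make_v(rng: np.random.Generator, name: str, chain: str, family: str,
            length: int, functional: bool) -> GeneSegment:
    # stop-free frame ending on the conserved cysteine codon
    body = random_orf(rng, length - 3)
    cys = "TGT" if rng.random() < 0.5 else "TGC"
    return GeneSegment(
        id=name, chain=chain, seg_class="V", family=family,
        sequence=body + cys, functional=functional,
        cys_codon_start=length - 3,
    )


def _make_j(rng: np.random.Generator, name: str, chain: str, length: int) -> GeneSegment:
    # phe codon placed on a codon boundary, >= 12 nt of J left for the FGxG motif
    max_phe = length - 12
    phe_start = int(rng.choice(np.arange(0, max_phe + 1, 3)[2:]))  # keep >=6 nt 5' context
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=length // 3)]
    k = phe_start // 3
    codons[k] = "TTT" if rng.random() < 0.5 else "TTC"
    codons[k + 1] = "GG" + "TCAG"[rng.integers(0, 4)]   # G of FGxG
    codons[k + 3] = "GG" + "TCAG"[rng.integers(0, 4)]   # second G
    return GeneSegment(
        id=name, chain=chain, seg_class="J", family=name,
        sequence="".join(codons), functional=True, phe_codon_start=phe_start,
    )


def make_reference(seed: int = 0, n_nonfunctional_v: int = 0) -> ReferenceSet:
    """Build the calibrated synthetic reference locus.

    Parameters
    ----------
    seed
        Seeds every sequence draw; the same seed reproduces the locus.
    n_nonfunctional_v
        Number of additional pseudogene (non-functional) Vα segments to
        append, for exercising functionality bookkeeping.
    """
    rng = np.random.default_rng(seed)
    segments: list[GeneSegment] = []

    for i in range(N_V_ALPHA):
        fam = f"F{(i % N_FAMILIES_ALPHA) + 1:02d}"
        segments.append(_make_v(
            rng, f"TRAV{i + 1}", "alpha", fam,
            int(rng.choice(_V_ALPHA_LENGTHS)), functional=True))
    for i in range(n_nonfunctional_v):
        fam = f"F{(i % N_FAMILIES_ALPHA) + 1:02d}"
        segments.append(_make_v(
            rng, f"TRAV{N_V_ALPHA + i + 1}P", "alpha", fam,
            int(rng.choice(_V_ALPHA_LENGTHS)), functional=False))
    for i in range(N_J_ALPHA):
        segments.append(_make_j(rng, f"TRAJ{i + 1}", "alpha",
                                int(rng.choice(_J_ALPHA_LENGTHS))))
    for i in range(N_V_BETA):
        segments.append(_make_v(
            rng, f"TRBV{i + 1}", "beta", f"TRBV{i + 1}",
            int(rng.choice(_V_BETA_LENGTHS)), functional=True))
    for i in range(N_J_BETA):
        segments.append(_make_j(rng, f"TRBJ{i + 1}", "beta",
                                int(rng.choice(_J_BETA_LENGTHS))))

    segments.append(GeneSegment(
        id="TRAC", chain="alpha", seg_class="C", family="TRAC",
        sequence=random_orf(rng, LEN_C_ALPHA), functional=True))
    segments.append(GeneSegment(
        id="TRBC", chain="beta", seg_class="C", family="TRBC",
        sequence=random_orf(rng, LEN_C_BETA - 3) + "TAA", functional=True))

    for i in range(N_FAMILIES_ALPHA):
        fam = f"F{i + 1:02d}"
        segments.append(GeneSegment(
            id=f"SSA-{fam}", chain="alpha", seg_class="SS", family=fam,
            sequence=random_orf(rng, LEN_SS_ALPHA, start_atg=True), functional=True))
    segments.append(GeneSegment(
        id="SSB", chain="beta", seg_class="SS", family="SSB",
        sequence=random_orf(rng, LEN_SS_BETA, start_atg=True), functional=True))

    segments.append(GeneSegment(
        id="P2A", chain=None, seg_class="2A", family="P2A",
        sequence=P2A_NT, functional=True))

    # Backbone core (between Cβ end and SSα start on the sense strand):
    # pad / reverse-primer site (as its sense-strand reverse complement) /
    # pad / pad / forward-primer site / pad.
    core = (
        random_dna(rng, 20)
        + _rc(CONTROL_REV)
        + random_dna(rng, 150)
        + random_dna(rng, 120)
        + CONTROL_FW
        + random_dna(rng, 30)
    )
    segments.append(GeneSegment(
        id="VEC-CORE", chain=None, seg_class="backbone", family="VEC",
        sequence=core, functional=True))

    return ReferenceSet(segments)
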