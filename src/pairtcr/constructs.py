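"""In-silico Gibson assembly of single-vector TCRα-2A-TCRβ expression constructs.

From a paired, productive clonotype the module designs three homology-tailed
fragments (the TCRα gene, the Cα-2A-SSβ linker, the TCRβ gene), picks the
family-matched vector from a 13-member library whose backbones carry the
TCRα leader (SSα) and the TCRβ constant region (Cβ), merges everything into
a circular plasmid by exact overlap joining, validates the single
SSα→...→Cβ open reading frame, and predicts the colony-screen PCR product
of the printed control primer pair (expected 1600-1700 bp).

Fragment design is germline-reverting: outside the observed junction the
chain is rebuilt from the assigned germline V and J segments, mirroring how
the gene-specific cloning PCR reverts errors introduced by the degenerate
first-PCR primers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._dna import revcomp, translate
from .fixture import CONTROL_FW, CONTROL_REV
from .reference import ReferenceSet
from .repertoire import PairedTCR


class AssemblyError(ValueError):
    """A Gibson junction failed (missing or duplicated homology match)."""

    def __init__(self, junction: str, message: str):
        self.junction = junction
        super().__init__(f"assembly_error({junction}): {message}")


@dataclass(frozen=True)
class ConstructConfig:
    homology_len: int = 20
    screen_window: tuple[int, int] = (1600, 1700)
    control_fw: str = CONTROL_FW
    control_rev: str = CONTROL_REV

    def __post_init__(self) -> None:
        if self.screen_window[0] > self.screen_window[1]:
            raise ValueError("screen window lower bound exceeds upper bound")
        if self.homology_len < 10:
            raise ValueError("homology_len must be >= 10")


@dataclass(frozen=True)
class GibsonFragment:
    """A linear dsDNA fragment whose terminal homology regions are literal
    prefix/suffix of ``sequence``."""

    name: str
    sequence: str
    left_homology: str
    right_homology: str

    def __post_init__(self) -> None:
        if not self.sequence.startswith(self.left_homology):
            raise ValueError(f"{self.name}: left homology is not a prefix")
        if not self.sequence.endswith(self.right_homology):
            raise ValueError(f"{self.name}: right homology is not a suffix")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VectorEntry:
    """One member of the SSα vector library.

    ``linearized`` starts at the single cut site, running
    Cβ -> backbone core -> SSα, so the vector's two Gibson ends are the SSα
    3' end (right) and the Cβ 5' end (left).
    """

    family: str
    linearized: str
    ss_alpha_len: int
    c_beta_len: int

    def __len__(self) -> int:
        return len(self.linearized)


def make_vector_library(ref: ReferenceSet) -> dict[str, VectorEntry]:
    """Build the family-keyed vector library from the reference's SSα
    leaders, Cβ and backbone core."""
    core = next(s for s in ref if s.seg_class == "backbone").sequence
    c_beta = next(s for s in ref if s.seg_class == "C" and s.chain == "beta").sequence
    library = {}
    for seg in ref:
        if seg.seg_class == "SS" and seg.chain == "alpha":
            library[seg.family] = VectorEntry(
                family=seg.family,
                linearized=c_beta + core + seg.sequence,
                ss_alpha_len=len(seg.sequence),
                c_beta_len=len(c_beta),
            )
    if not library:
        raise ValueError("reference carries no alpha leader (SS) segments")
    return library


def select_vector(v_alpha_id: str, library: dict[str, VectorEntry],
                  ref: ReferenceSet) -> VectorEntry:
    """The library entry whose SSα matches the Vα gene's family."""
    family = ref[v_alpha_id].family
    if family not in library:
        raise KeyError(
            f"no vector for Vα family {family!r}; covered families: "
            f"{sorted(library)}"
        )
    return library[family]


def _rebuild_chain(ref: ReferenceSet, v_id: str, j_id: str, cdr3_nt: str) -> str:
    """Germline V + observed junction + germline J (primer-error reversion)."""
    v, j = ref[v_id], ref[j_id]
    return v.sequence[: v.cys_codon_start] + cdr3_nt + j.sequence[j.phe_codon_start + 3 :]


def design_fragments(pair: PairedTCR, ref: ReferenceSet,
                     cfg: ConstructConfig = ConstructConfig()
                     ) -> tuple[GibsonFragment, GibsonFragment, GibsonFragment]:
    """Design the three Gibson fragments for one productive pair.

    The Vα fragment is tailed with homology to the SSα 3' end (left, family
    matched) and the Cα 5' end (right); the linker fragment is the full
    Cα-2A-SSβ cassette; the Vβ fragment is tailed to SSβ (left) and Cβ
    (right).
    """
    for chain, rec in (("alpha", pair.alpha), ("beta", pair.beta)):
        if rec is None:
            raise ValueError(f"missing {chain} chain record")
        if not rec.productive:
            raise ValueError(f"{chain} chain is not productive; cloning requires "
                             "an in-frame, stop-free rearrangement")
    h = cfg.homology_len
    v_alpha = pair.alpha.v_hit.segment_id
    ss_alpha = next(s for s in ref if s.seg_class == "SS" and s.chain == "alpha"
                    and s.family == ref[v_alpha].family)
    ss_beta = next(s for s in ref if s.seg_class == "SS" and s.chain == "beta")
    c_alpha = next(s for s in ref if s.seg_class == "C" and s.chain == "alpha")
    c_beta = next(s for s in ref if s.seg_class == "C" and s.chain == "beta")
    p2a = next(s for s in ref if s.seg_class == "2A")

    chain_a = _rebuild_chain(ref, v_alpha, pair.alpha.j_hit.segment_id, pair.alpha.cdr3_nt)
    chain_b = _rebuild_chain(ref, pair.beta.v_hit.segment_id,
                             pair.beta.j_hit.segment_id, pair.beta.cdr3_nt)

    frag_va = GibsonFragment(
        name="TCRa",
        sequence=ss_alpha.sequence[-h:] + chain_a + c_alpha.sequence[:h],
        left_homology=ss_alpha.sequence[-h:],
        right_homology=c_alpha.sequence[:h],
    )
    linker_seq = c_alpha.sequence + p2a.sequence + ss_beta.sequence
    frag_linker = GibsonFragment(
        name="Ca-2A-SSb",
        sequence=linker_seq,
        left_homology=linker_seq[:h],
        right_homology=linker_seq[-h:],
    )
    frag_vb = GibsonFragment(
        name="TCRb",
        sequence=ss_beta.sequence[-h:] + chain_b + c_beta.sequence[:h],
        left_homology=ss_beta.sequence[-h:],
        right_homology=c_beta.sequence[:h],
    )
    return frag_va, frag_linker, frag_vb


@dataclass
class ValidationReport:
    in_frame: bool
    premature_stops: list[int]          # codon start offsets from SSα ATG
    junctions_seamless: bool
    has_2a_in_frame: bool = False
    note: str = ""


@dataclass
class ExpressionConstruct:
    """Assembled circular plasmid; serialised with origin at the SSα ATG so
    the SSα-Vα-Cα-2A-SSβ-Vβ-Cβ reading frame is contiguous."""

    sequence: str                        # circular, origin = SSα start
    features: dict[str, tuple[int, int]]  # 0-based half-open spans
    vector_family: str
    validation: Optional[ValidationReport] = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def orf(self) -> str:
        return self.sequence[: self.features["Cbeta"][1]]


_JUNCTION_NAMES = ("SSalpha-Valpha", "Valpha-Calpha", "SSbeta-Vbeta", "Vbeta-Cbeta")


def assemble(fragments: tuple[GibsonFragment, GibsonFragment, GibsonFragment],
             vector: VectorEntry, cfg: ConstructConfig = ConstructConfig(),
             ref: Optional[ReferenceSet] = None) -> ExpressionConstruct:
    """Join vector + fragments into a circular plasmid by exact homology
    overlap.

    Seams are verified in order (vector->Vα, Vα->linker, linker->Vβ,
    Vβ->vector closure); a missing or non-unique homology match raises
    :class:`AssemblyError` naming the junction.
    """
    frag_va, frag_linker, frag_vb = fragments
    h = cfg.homology_len
    pieces = [vector.linearized, frag_va.sequence, frag_linker.sequence, frag_vb.sequence]
    # seam i joins pieces[i] -> pieces[(i+1) % 4]; closure wraps to the vector
    assembled = pieces[0]
    for i, name in enumerate(_JUNCTION_NAMES[:3]):
        left, right = assembled, pieces[i + 1]
        if left[-h:] != right[:h]:
            raise AssemblyError(name, "terminal homology regions do not match")
        assembled = left + right[h:]
    if assembled[-h:] != pieces[0][:h]:
        raise AssemblyError(_JUNCTION_NAMES[3], "closure homology does not match vector end")
    circular = assembled[:-h]

    # each seam's homology string must appear exactly once on the plasmid
    seams = [frag_va.left_homology, frag_va.right_homology,
             frag_linker.right_homology, frag_vb.right_homology]
    for name, seam in zip(_JUNCTION_NAMES, seams):
        count = _circular_count(circular, seam)
        if count != 1:
            raise AssemblyError(name, f"homology region occurs {count} times on the plasmid")

    # feature map; rotate the serialisation origin to the SSα ATG
    if ref is None:
        raise ValueError("assemble requires the reference set for the feature map")
    len_vec = len(vector.linearized)
    ss_start = len_vec - vector.ss_alpha_len
    rotated = circular[ss_start:] + circular[:ss_start]
    la = len(frag_va) - 2 * h
    c_alpha_len = len(next(s for s in ref if s.seg_class == "C" and s.chain == "alpha"))
    p2a_len = len(next(s for s in ref if s.seg_class == "2A"))
    ssb_len = len(next(s for s in ref if s.seg_class == "SS" and s.chain == "beta"))
    lb = len(frag_vb) - 2 * h
    pos = 0
    features: dict[str, tuple[int, int]] = {}
    for name, span in (
        ("SSalpha", vector.ss_alpha_len), ("Valpha", la), ("Calpha", c_alpha_len),
        ("P2A", p2a_len), ("SSbeta", ssb_len), ("Vbeta", lb),
        ("Cbeta", vector.c_beta_len),
    ):
        features[name] = (pos, pos + span)
        pos += span
    features["backbone"] = (pos, len(rotated))
    return ExpressionConstruct(
        sequence=rotated,
        features=features,
        vector_family=vector.family,
    )


def _circular_count(circular: str, motif: str) -> int:
    doubled = circular + circular[: len(motif) - 1]
    count = start = 0
    while True:
        i = doubled.find(motif, start)
        if i == -1 or i >= len(circular):
            return count
        count += 1
        start = i + 1


def validate_orf(construct: ExpressionConstruct) -> ValidationReport:
    """Translate from the SSα ATG and check one continuous, stop-free frame
    through the Cβ stop, with the 2A peptide read through in frame."""
    seq = construct.sequence
    feats = construct.features
    orf_end = feats["Cbeta"][1]
    seamless = all(
        feats[a][1] == feats[b][0]
        for a, b in zip(("SSalpha", "Valpha", "Calpha", "P2A", "SSbeta", "Vbeta"),
                        ("Valpha", "Calpha", "P2A", "SSbeta", "Vbeta", "Cbeta"))
    )
    if not seq.startswith("ATG"):
        report = ValidationReport(False, [], seamless, note="no ATG at SSα start")
        construct.validation = report
        return report
    aa = translate(seq[:orf_end])
    stops = [3 * i for i, c in enumerate(aa) if c == "*"]
    # the terminal Cβ stop codon is expected; everything earlier is premature
    premature = [p for p in stops if p < orf_end - 3]
    frame_ok = orf_end % 3 == 0 and seq[orf_end - 3 : orf_end] in ("TAA", "TAG", "TGA")
    p2a_aa = translate(seq[slice(*feats["P2A"])])
    has_2a = feats["P2A"][0] % 3 == 0 and p2a_aa in aa
    report = ValidationReport(
        in_frame=frame_ok and not premature and has_2a and seamless,
        premature_stops=premature,
        junctions_seamless=seamless,
        has_2a_in_frame=has_2a,
        note="" if frame_ok else "ORF end out of frame or missing terminal stop",
    )
    construct.validation = report
    return report


def predict_screen_amplicon(construct: ExpressionConstruct,
                            cfg: ConstructConfig = ConstructConfig()) -> int:
    """Length (bp) of the colony-screen PCR product of the control primer
    pair, including both primer footprints.

    Requires exactly one site per primer (forward on the sense strand,
    reverse priming the sense strand via its reverse complement).
    """
    seq = construct.sequence
    n_fw = _circular_count(seq, cfg.control_fw)
    rev_site = revcomp(cfg.control_rev)
    n_rev = _circular_count(seq, rev_site)
    if n_fw != 1 or n_rev != 1:
        raise ValueError(
            f"control primer site count must be exactly 1 (fw: {n_fw}, rev: {n_rev})"
        )
    doubled = seq + seq
    fw_start = doubled.find(cfg.control_fw)
    rev_end = doubled.find(rev_site, fw_start) + len(rev_site)
    return rev_end - fw_start


def to_genbank(construct: ExpressionConstruct, path, name: str = "pairtcr_construct") -> None:
    """Write the construct as a circular GenBank flat file with features."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    record = SeqRecord(Seq(construct.sequence), id=name[:16], name=name[:16],
                       description=f"TCRa-2A-TCRb expression construct "
                                   f"(SSα family {construct.vector_family})")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    for feat_name, (start, end) in construct.features.items():
        record.features.append(SeqFeature(
            FeatureLocation(start, end), type="misc_feature",
            qualifiers={"label": [feat_name]},
        ))
    SeqIO.write(record, str(path), "genbank")
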