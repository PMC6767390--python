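"""Germline gene-segment references.

A :class:`ReferenceSet` holds the V/J/C gene segments of the TCRα and TCRβ
loci together with the auxiliary sequences needed for expression cloning
(leader/signal sequences, the 2A linker, and the vector backbone core).
Segments are read from a FASTA file plus a tab-delimited metadata sidecar
(one row per record) rather than from FASTA description lines, because
germline-database header dialects vary.

V segments are stored 5'->3' on the coding strand, from FWR1 through the end
of the conserved junction cysteine codon; J segments carry the position of
the FGxG-motif phenylalanine codon.  Anchor coordinates are 0-based
nucleotide offsets of the codon start within the segment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import is_dna

CHAINS = ("alpha", "beta")
#: recognised segment classes: germline V/J/C, leader ("SS"), 2A linker,
#: and the vector backbone core used by construct design.
SEG_CLASSES = ("V", "J", "C", "SS", "2A", "backbone")
#: classes that are not tied to one TCR chain
_CHAINLESS = frozenset({"2A", "backbone"})

METADATA_COLUMNS = (
    "id", "chain", "class", "family", "functional",
    "cys_codon_start", "phe_codon_start",
)


@dataclass(frozen=True)
class GeneSegment:
    """One germline segment (or cloning element) of the reference.

    ``cys_codon_start`` (V) / ``phe_codon_start`` (J) are the 0-based start
    positions of the conserved junction-cysteine / FGxG-phenylalanine codon.
    """

    id: str
    chain: Optional[str]  # "alpha" | "beta"; None for 2A/backbone
    seg_class: str
    family: str
    sequence: str
    functional: bool = True
    cys_codon_start: Optional[int] = None
    phe_codon_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("segment id must be non-empty")
        if self.seg_class not in SEG_CLASSES:
            raise ValueError(f"{self.id}: unknown segment class {self.seg_class!r}")
        if self.seg_class in _CHAINLESS:
            if self.chain is not None:
                raise ValueError(f"{self.id}: class {self.seg_class} is chain-neutral")
        elif self.chain not in CHAINS:
            raise ValueError(f"{self.id}: chain must be one of {CHAINS}")
        if not is_dna(self.sequence):
            raise ValueError(f"{self.id}: sequence must be non-empty uppercase ACGT")
        if self.seg_class == "V":
            if self.cys_codon_start is None:
                raise ValueError(f"{self.id}: V segment needs cys_codon_start")
            if not 0 <= self.cys_codon_start <= len(self.sequence) - 3:
                raise ValueError(f"{self.id}: cys_codon_start outside sequence")
        if self.seg_class == "J":
            if self.phe_codon_start is None:
                raise ValueError(f"{self.id}: J segment needs phe_codon_start")
            if not 0 <= self.phe_codon_start <= len(self.sequence) - 3:
                raise ValueError(f"{self.id}: phe_codon_start outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """A validated, id-keyed collection of :class:`GeneSegment`."""

    def __init__(self, segments: Iterable[GeneSegment]):
        self._segments: dict[str, GeneSegment] = {}
        for seg in segments:
            if seg.id in self._segments:
                raise ValueError(f"duplicate segment id {seg.id!r}")
            self._segments[seg.id] = seg

    def __len__(self) -> int:
        return len(self._segments)

    def __iter__(self):
        return iter(self._segments.values())

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._segments

    def __getitem__(self, seg_id: str) -> GeneSegment:
        try:
            return self._segments[seg_id]
        except KeyError:
            raise KeyError(f"unknown segment id {seg_id!r}") from None

    @property
    def locus_counts(self) -> dict[str, dict[str, int]]:
        """Functional-segment counts per (chain, class), recomputed on access."""
        counts: dict[str, dict[str, int]] = {}
        for seg in self:
            if seg.chain is None or not seg.functional:
                continue
            counts.setdefault(seg.chain, {})
            counts[seg.chain][seg.seg_class] = counts[seg.chain].get(seg.seg_class, 0) + 1
        return counts

    def require_complete(self, chain: str) -> None:
        """Check that ``chain`` has at least one functional V, J and C segment."""
        counts = self.locus_counts.get(chain, {})
        missing = [c for c in ("V", "J", "C") if counts.get(c, 0) < 1]
        if missing:
            raise ValueError(
                f"reference lacks functional {'/'.join(missing)} segment(s) for chain {chain}"
            )


def functional_segments(ref: ReferenceSet, chain: str, seg_class: str) -> list[GeneSegment]:
    """All functional segments of one chain and class, in stable id order."""
    if seg_class not in SEG_CLASSES:
        raise ValueError(f"unknown segment class {seg_class!r}")
    if seg_class in _CHAINLESS:
        want_chain = None
    elif chain in CHAINS:
        want_chain = chain
    else:
        raise ValueError(f"unknown chain {chain!r}")
    return sorted(
        (s for s in ref if s.chain == want_chain and s.seg_class == seg_class and s.functional),
        key=lambda s: s.id,
    )


def _parse_anchor(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in ("", ".", "NA", "nan"):
        return None
    return int(float(text))


def load_reference(fasta_path, metadata_path) -> ReferenceSet:
    """Load and validate a reference from FASTA + tab-delimited metadata.

    Every FASTA record must have exactly one metadata row (matched on ``id``)
    and vice versa; any record failing a segment invariant aborts the load
    with the offending identifier in the error message.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata table missing columns: {sorted(missing_cols)}")
    if meta["id"].duplicated().any():
        dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata rows for: {dups}")
    rows = {row["id"]: row for row in meta.to_dict("records")}

    segments = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in rows:
            raise ValueError(f"FASTA record {rec.id!r} has no metadata row")
        row = rows[rec.id]
        seen.add(rec.id)
        chain = None if row["chain"] in (".", "", None) else str(row["chain"])
        segments.append(
            GeneSegment(
                id=rec.id,
                chain=chain,
                seg_class=str(row["class"]),
                family=str(row["family"]),
                sequence=str(rec.seq).upper(),
                functional=str(row["functional"]).strip().lower() in ("1", "true", "t", "yes"),
                cys_codon_start=_parse_anchor(row["cys_codon_start"]),
                phe_codon_start=_parse_anchor(row["phe_codon_start"]),
            )
        )
    orphans = set(rows) - seen
    if orphans:
        raise ValueError(f"metadata rows without FASTA record: {sorted(orphans)}")
    return ReferenceSet(segments)


def write_reference(ref: ReferenceSet, fasta_path, metadata_path) -> None:
    """Serialise a ReferenceSet back to FASTA + metadata (round-trip safe)."""
    records = [SeqRecord(Seq(seg.sequence), id=seg.id, description="") for seg in ref]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "id": seg.id,
            "chain": seg.chain if seg.chain is not None else ".",
            "class": seg.seg_class,
            "family": seg.family,
            "functional": str(seg.functional).lower(),
            "cys_codon_start": "." if seg.cys_codon_start is None else seg.cys_codon_start,
            "phe_codon_start": "." if seg.phe_codon_start is None else seg.phe_codon_start,
        }
        for seg in ref
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def reference_to_strings(ref: ReferenceSet) -> tuple[str, str]:
    """In-memory FASTA/metadata serialisation (handy for tests)."""
    fasta = io.StringIO()
    records = [SeqRecord(Seq(seg.sequence), id=seg.id, description="") for seg in ref]
    SeqIO.write(records, fasta, "fasta")
    meta = io.StringIO()
    write_reference_meta = pd.DataFrame(
        [
            {
                "id": s.id,
                "chain": s.chain if s.chain is not None else ".",
                "class": s.seg_class,
                "family": s.family,
                "functional": str(s.functional).lower(),
                "cys_codon_start": "." if s.cys_codon_start is None else s.cys_codon_start,
                "phe_codon_start": "." if s.phe_codon_start is None else s.phe_codon_start,
            }
            for s in ref
        ],
        columns=METADATA_COLUMNS,
    )
    write_reference_meta.to_csv(meta, sep="\t", index=False)
    return fasta.getvalue(), meta.getvalue()
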