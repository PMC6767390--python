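"""Barcode matrix, plate geometry, and amplicon structure.

The second PCR tags every well's product with a column-specific forward
barcode and a row-specific reverse barcode; the (forward, reverse) tag pair
addresses one well across a stack of 384-well plates, so a single pooled
sequencing run can be demultiplexed back to wells.  This module owns that
two-dimensional code: barcode generation, the well map, tag decoding with
bounded error correction, and the structural model of the assembled
amplicon shared by the simulator and the demultiplexer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from ._dna import hamming, random_dna, revcomp
from .fixture import C_STUB_LEN, UNIVERSAL_LINKER
from .reference import ReferenceSet

ROWS_PER_PLATE = 16
COLS_PER_PLATE = 24
ROW_LABELS = "ABCDEFGHIJKLMNOP"

LAYOUT_FORMAT_VERSION = 1


class WellAddress(NamedTuple):
    plate: int      # 0-based
    row: str        # "A".."P"
    column: int     # 1..24


@dataclass(frozen=True)
class BarcodeSet:
    """An error-correcting set of equal-length DNA tags."""

    tags: tuple[str, ...]
    min_pairwise_hamming: int

    def __post_init__(self) -> None:
        if not self.tags:
            raise ValueError("empty barcode set")
        length = len(self.tags[0])
        if any(len(t) != length for t in self.tags):
            raise ValueError("all tags must have the same length")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("duplicate tags")
        for i, a in enumerate(self.tags):
            for b in self.tags[i + 1 :]:
                if hamming(a, b) < self.min_pairwise_hamming:
                    raise ValueError(
                        f"tags {a}/{b} violate min pairwise Hamming "
                        f"{self.min_pairwise_hamming}"
                    )
                if a == revcomp(b):
                    raise ValueError(f"tag {a} is the reverse complement of {b}")

    @property
    def tag_length(self) -> int:
        return len(self.tags[0])

    def __len__(self) -> int:
        return len(self.tags)


def generate_barcodes(n: int, length: int = 8, min_dist: int = 3,
                      seed: int = 0, max_tries: Optional[int] = None) -> BarcodeSet:
    """Greedy seeded search for ``n`` tags with pairwise Hamming >= ``min_dist``.

    Deterministic for a given seed.  Raises if the bounded search cannot
    reach ``n`` codes, reporting the largest set found.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_dist > length:
        raise ValueError("min_dist cannot exceed tag length")
    if n > 4 ** length:
        raise ValueError(f"only {4 ** length} tags of length {length} exist; {n} requested")
    rng = np.random.default_rng(seed)
    tries = max_tries if max_tries is not None else max(20_000, 2_000 * n)
    accepted: list[str] = []
    for _ in range(tries):
        cand = random_dna(rng, length)
        if any(hamming(cand, t) < min_dist for t in accepted):
            continue
        if any(cand == revcomp(t) for t in accepted) or cand == revcomp(cand):
            continue
        accepted.append(cand)
        if len(accepted) == n:
            return BarcodeSet(tags=tuple(accepted), min_pairwise_hamming=min_dist)
    raise ValueError(
        f"could not find {n} tags (length {length}, min_dist {min_dist}); "
        f"largest set found: {len(accepted)}"
    )


@dataclass(frozen=True)
class PlateLayout:
    """Bijection between (fwd tag, rev tag) pairs and plate wells.

    Plates are tiled into a virtual super-grid of ``tiling`` (rows, cols) of
    plates; columns of the super-grid consume forward tags, rows consume
    reverse tags, so each well of each plate receives a unique tag pair.
    """

    n_plates: int
    fwd_tags: BarcodeSet
    rev_tags: BarcodeSet
    tiling: tuple[int, int]

    def __post_init__(self) -> None:
        pr, pc = self.tiling
        if pr * pc < self.n_plates:
            raise ValueError(f"tiling {self.tiling} holds fewer than {self.n_plates} plates")
        need_fwd = pc * COLS_PER_PLATE
        need_rev = pr * ROWS_PER_PLATE
        if len(self.fwd_tags) < need_fwd or len(self.rev_tags) < need_rev:
            raise ValueError(
                f"insufficient tags for {self.n_plates} plates: need "
                f"{need_fwd} fwd x {need_rev} rev (= {need_fwd * need_rev} combinations "
                f">= {self.n_plates * ROWS_PER_PLATE * COLS_PER_PLATE} wells), "
                f"have {len(self.fwd_tags)} x {len(self.rev_tags)}"
            )

    @property
    def n_wells(self) -> int:
        return self.n_plates * ROWS_PER_PLATE * COLS_PER_PLATE

    def wells(self):
        for plate in range(self.n_plates):
            for row in ROW_LABELS:
                for col in range(1, COLS_PER_PLATE + 1):
                    yield WellAddress(plate, row, col)

    def tag_indices(self, well: WellAddress) -> tuple[int, int]:
        if not (0 <= well.plate < self.n_plates):
            raise ValueError(f"plate {well.plate} outside layout")
        gr, gc = divmod(well.plate, self.tiling[1])
        fi = gc * COLS_PER_PLATE + (well.column - 1)
        ri = gr * ROWS_PER_PLATE + ROW_LABELS.index(well.row)
        return fi, ri

    def encode(self, well: WellAddress) -> tuple[str, str]:
        fi, ri = self.tag_indices(well)
        return self.fwd_tags.tags[fi], self.rev_tags.tags[ri]

    def well_for_indices(self, fi: int, ri: int) -> Optional[WellAddress]:
        gc, col0 = divmod(fi, COLS_PER_PLATE)
        gr, row0 = divmod(ri, ROWS_PER_PLATE)
        plate = gr * self.tiling[1] + gc
        if gc >= self.tiling[1] or plate >= self.n_plates:
            return None
        return WellAddress(plate, ROW_LABELS[row0], col0 + 1)

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": LAYOUT_FORMAT_VERSION,
                "n_plates": self.n_plates,
                "tiling": list(self.tiling),
                "fwd_tags": list(self.fwd_tags.tags),
                "rev_tags": list(self.rev_tags.tags),
                "min_pairwise_hamming": [
                    self.fwd_tags.min_pairwise_hamming,
                    self.rev_tags.min_pairwise_hamming,
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlateLayout":
        doc = json.loads(text)
        if doc.get("format_version") != LAYOUT_FORMAT_VERSION:
            raise ValueError(f"unsupported layout format version {doc.get('format_version')}")
        mf, mr = doc["min_pairwise_hamming"]
        return cls(
            n_plates=doc["n_plates"],
            fwd_tags=BarcodeSet(tuple(doc["fwd_tags"]), mf),
            rev_tags=BarcodeSet(tuple(doc["rev_tags"]), mr),
            tiling=tuple(doc["tiling"]),
        )


def default_tiling(n_plates: int) -> tuple[int, int]:
    """Near-square plate super-grid; 12 plates tile as 3 rows x 4 columns."""
    pc = math.ceil(math.sqrt(n_plates))
    pr = math.ceil(n_plates / pc)
    return pr, pc


def build_layout(n_plates: int, fwd_tags: BarcodeSet, rev_tags: BarcodeSet,
                 tiling: Optional[tuple[int, int]] = None) -> PlateLayout:
    """Lay ``n_plates`` 384-well plates out over the barcode matrix."""
    n_wells = n_plates * ROWS_PER_PLATE * COLS_PER_PLATE
    if len(fwd_tags) * len(rev_tags) < n_wells:
        raise ValueError(
            f"need {n_wells} tag combinations for {n_plates} plates, "
            f"have {len(fwd_tags)} x {len(rev_tags)} = {len(fwd_tags) * len(rev_tags)}"
        )
    if tiling is None:
        tiling = default_tiling(n_plates)
    return PlateLayout(n_plates=n_plates, fwd_tags=fwd_tags, rev_tags=rev_tags, tiling=tiling)


class DecodeReject(NamedTuple):
    reason: str  # unknown_fwd | unknown_rev | ambiguous | unmapped


def _match_tag(observed: str, tags: tuple[str, ...], max_mismatch: int):
    """Index of the unique nearest tag within ``max_mismatch``.

    Returns (index, None) on success, (None, reason) otherwise; a distance
    tie at the minimum is ambiguous.
    """
    best, best_d, tie = None, max_mismatch + 1, False
    for i, tag in enumerate(tags):
        d = hamming(observed, tag)
        if d < best_d:
            best, best_d, tie = i, d, False
        elif d == best_d:
            tie = True
    if best is None:
        return None, "unknown"
    if tie:
        return None, "ambiguous"
    return best, None


def decode_tags(fwd_observed: str, rev_observed: str, layout: PlateLayout,
                max_mismatch: int = 1):
    """Map an observed tag pair to its well, correcting up to ``max_mismatch``
    substitutions per tag.  Returns a WellAddress or a :class:`DecodeReject`."""
    if len(fwd_observed) != layout.fwd_tags.tag_length:
        return DecodeReject("unknown_fwd")
    if len(rev_observed) != layout.rev_tags.tag_length:
        return DecodeReject("unknown_rev")
    fi, err = _match_tag(fwd_observed, layout.fwd_tags.tags, max_mismatch)
    if fi is None:
        return DecodeReject("ambiguous" if err == "ambiguous" else "unknown_fwd")
    ri, err = _match_tag(rev_observed, layout.rev_tags.tags, max_mismatch)
    if ri is None:
        return DecodeReject("ambiguous" if err == "ambiguous" else "unknown_rev")
    well = layout.well_for_indices(fi, ri)
    if well is None:
        return DecodeReject("unmapped")
    return well


@dataclass(frozen=True)
class AmpliconSchema:
    """Structure of the assembled second-PCR amplicon (sense strand):

    ``fwd_tag + universal_linker + V...J chain insert + C stub + revcomp(rev_tag)``

    The same schema is used by the simulator (to build amplicons) and the
    demultiplexer (to locate tags, trim, and call the chain from the
    constant-region stub).
    """

    universal_linker: str
    tag_length: int
    c_stubs: dict[str, str]              # chain -> constant-region stub
    expected_insert_length_range: tuple[int, int]

    def amplicon(self, fwd_tag: str, rev_tag: str, chain_seq: str, chain: str) -> str:
        return (
            fwd_tag + self.universal_linker + chain_seq
            + self.c_stubs[chain] + revcomp(rev_tag)
        )

    def insert(self, assembled: str) -> str:
        """Strip tags and linker from an assembled read (C stub retained)."""
        return assembled[self.tag_length + len(self.universal_linker) : -self.tag_length]


def schema_from_reference(ref: ReferenceSet, tag_length: int = 8,
                          linker: str = UNIVERSAL_LINKER,
                          c_stub_len: int = C_STUB_LEN,
                          max_n_region: int = 10) -> AmpliconSchema:
    """Derive the amplicon schema (stubs and exact length range) from a
    reference set."""
    stubs = {}
    lo, hi = math.inf, 0
    for chain, c_id in (("alpha", None), ("beta", None)):
        c_segs = [s for s in ref if s.chain == chain and s.seg_class == "C"]
        if not c_segs:
            raise ValueError(f"reference has no constant segment for chain {chain}")
        stubs[chain] = c_segs[0].sequence[:c_stub_len]
        v_lens = [len(s) for s in ref if s.chain == chain and s.seg_class == "V"]
        j_lens = [len(s) for s in ref if s.chain == chain and s.seg_class == "J"]
        fixed = 2 * tag_length + len(linker) + len(stubs[chain])
        lo = min(lo, fixed + min(v_lens) + min(j_lens))
        hi = max(hi, fixed + max(v_lens) + max(j_lens) + max_n_region)
    return AmpliconSchema(
        universal_linker=linker,
        tag_length=tag_length,
        c_stubs=stubs,
        expected_insert_length_range=(int(lo), int(hi)),
    )
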