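"""Read merging, quality/length filtering, subsampling and demultiplexing.

The pooled 2 x 300 bp run is turned back into per-well, per-chain read bins:

1. :func:`merge_pairs` overlaps each mate pair into one assembled amplicon
   (best ungapped overlap, quality-aware disagreement resolution, and a
   PandaSeq-like read-level quality score in [0, 1]);
2. :func:`subsample_plate` randomly thins the pool (the platform sequences
   far deeper than needed);
3. :func:`filter_reads` keeps assembled reads with quality strictly above
   0.8 and length inside the inclusive 480-560 nt window;
4. :func:`demux` decodes the forward/reverse tag pair to a well, trims tags
   and linker, and calls the chain from the constant-region stub.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from ._dna import revcomp
from .amplicon import AmpliconSchema, DecodeReject, PlateLayout, WellAddress, decode_tags


@dataclass
class AssembledRead:
    """A merged read pair.

    ``assembly_quality`` is the geometric mean over bases of the posterior
    base-correctness probability (1 - Phred error probability), a read-level
    score in [0, 1].
    """

    sequence: str
    quality: np.ndarray          # per-base Phred scores
    assembly_quality: float
    read_id: str = ""

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int64)
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality length differ")
        if not 0.0 <= self.assembly_quality <= 1.0:
            raise ValueError("assembly_quality must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterConfig:
    """Read filters: quality strictly above ``q_min``, length inside the
    inclusive ``[len_min, len_max]`` window, and per-plate subsampling."""

    q_min: float = 0.8
    len_min: int = 480
    len_max: int = 560
    subsample_per_plate: int = 75_000
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_min <= 1.0:
            raise ValueError("q_min must be in [0, 1]")
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")


_MAX_Q = 60


def _geo_mean_correct(quality: np.ndarray) -> float:
    p_err = 10.0 ** (-np.asarray(quality, dtype=float) / 10.0)
    return float(np.exp(np.mean(np.log1p(-p_err))))


def merge_pairs(r1: tuple[str, Sequence[int]], r2: tuple[str, Sequence[int]],
                min_overlap: int = 30, min_identity: float = 0.75,
                read_id: str = "") -> Optional[AssembledRead]:
    """Assemble one mate pair by its best ungapped overlap.

    ``r2`` is reverse-complemented; every overlap length ``>= min_overlap``
    is scored (+1 match / -1 mismatch) and the maximal-score overlap wins.
    Disagreeing bases take the higher-quality mate's call with quality
    ``|q1 - q2|``; agreeing bases get the summed quality (capped).  Returns
    ``None`` when no overlap reaches ``min_overlap`` at ``min_identity``.
    """
    s1, q1 = r1
    s2, q2 = r2
    if not s1 or not s2:
        return None
    s2 = revcomp(s2)
    q2 = np.asarray(q2, dtype=np.int64)[::-1]
    q1 = np.asarray(q1, dtype=np.int64)
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)

    best_o, best_score, best_matches = 0, -(10 ** 9), 0
    max_o = min(len(s1), len(s2))
    for o in range(min_overlap, max_o + 1):
        matches = int(np.count_nonzero(a1[len(s1) - o :] == a2[:o]))
        score = 2 * matches - o  # matches - mismatches
        if score > best_score:
            best_o, best_score, best_matches = o, score, matches
    if best_o == 0 or best_matches / best_o < min_identity:
        return None

    o = best_o
    left_s, left_q = s1[: len(s1) - o], q1[: len(q1) - o]
    right_s, right_q = s2[o:], q2[o:]
    ov1, ov2 = a1[len(s1) - o :], a2[:o]
    ovq1, ovq2 = q1[len(q1) - o :], q2[:o]
    agree = ov1 == ov2
    merged = np.where((ovq1 >= ovq2) | agree, ov1, ov2)
    merged_q = np.where(agree, np.minimum(ovq1 + ovq2, _MAX_Q),
                        np.maximum(np.abs(ovq1 - ovq2), 2))
    sequence = left_s + merged.tobytes().decode() + right_s
    quality = np.concatenate([left_q, merged_q, right_q])
    return AssembledRead(
        sequence=sequence,
        quality=quality,
        assembly_quality=_geo_mean_correct(quality),
        read_id=read_id,
    )


def filter_reads(reads: Iterable[AssembledRead], cfg: FilterConfig = FilterConfig()
                 ) -> tuple[list[AssembledRead], list[tuple[AssembledRead, str]]]:
    """Split reads into (kept, dropped-with-reason).

    Kept iff ``assembly_quality > q_min`` (strict) and
    ``len_min <= length <= len_max`` (inclusive).
    """
    kept, dropped = [], []
    for read in reads:
        if not cfg.len_min <= len(read) <= cfg.len_max:
            dropped.append((read, "length"))
        elif not read.assembly_quality > cfg.q_min:
            dropped.append((read, "quality"))
        else:
            kept.append(read)
    return kept, dropped


def subsample_plate(reads: Sequence, n: int, seed: int = 0) -> list:
    """Uniform subsample without replacement (all reads if ``n >= len``),
    deterministic per seed; input order is preserved."""
    if n < 0:
        raise ValueError("n must be >= 0")
    reads = list(reads)
    if n >= len(reads):
        return reads
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


@dataclass
class WellBin:
    """Reads demultiplexed to one (well, chain) bin; stored sequences have
    tags and linker trimmed (constant-region stub retained)."""

    well: WellAddress
    chain: str
    members: list[AssembledRead] = field(default_factory=list)


def _chain_caller(schema: AmpliconSchema):
    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-3,
        open_gap_score=-5, extend_gap_score=-2,
    )
    stub_len = max(len(s) for s in schema.c_stubs.values())

    def call(insert: str, margin: int = 5) -> Optional[str]:
        tail = insert[-(stub_len + 40) :]
        scores = {c: aligner.score(tail, stub) for c, stub in schema.c_stubs.items()}
        ranked = sorted(scores, key=lambda c: (-scores[c], c))
        if len(ranked) > 1 and scores[ranked[0]] - scores[ranked[1]] < margin:
            return None
        return ranked[0]

    return call


def demux(reads: Iterable[AssembledRead], layout: PlateLayout, schema: AmpliconSchema,
          max_mismatch: int = 1, chain_margin: int = 5
          ) -> tuple[dict[tuple[WellAddress, str], WellBin], dict[str, int]]:
    """Assign assembled reads to (well, chain) bins via the tag matrix.

    Returns the bins plus a conserved stats counter: ``assigned`` plus every
    reject category sums to the input read count.
    """
    call_chain = _chain_caller(schema)
    bins: dict[tuple[WellAddress, str], WellBin] = {}
    stats = {"assigned": 0, "unknown_fwd": 0, "unknown_rev": 0,
             "ambiguous": 0, "unmapped": 0, "ambiguous_chain": 0, "too_short": 0}
    tag_len = schema.tag_length
    min_len = 2 * tag_len + len(schema.universal_linker) + 1
    for read in reads:
        if len(read) < min_len:
            stats["too_short"] += 1
            continue
        fwd_obs = read.sequence[:tag_len]
        rev_obs = revcomp(read.sequence[-tag_len:])
        hit = decode_tags(fwd_obs, rev_obs, layout, max_mismatch)
        if isinstance(hit, DecodeReject):
            stats[hit.reason] += 1
            continue
        insert = schema.insert(read.sequence)
        chain = call_chain(insert, chain_margin)
        if chain is None:
            stats["ambiguous_chain"] += 1
            continue
        trim_lo = tag_len + len(schema.universal_linker)
        trimmed = AssembledRead(
            sequence=insert,
            quality=read.quality[trim_lo : len(read) - tag_len],
            assembly_quality=read.assembly_quality,
            read_id=read.read_id,
        )
        key = (hit, chain)
        bins.setdefault(key, WellBin(well=hit, chain=chain)).members.append(trimmed)
        stats["assigned"] += 1
    return bins, stats


def read_fastq_pairs(r1_path, r2_path):
    """Iterate (id, (seq, qual), (seq, qual)) over two synchronised FASTQ files."""
    from Bio import SeqIO

    for rec1, rec2 in zip(SeqIO.parse(str(r1_path), "fastq"),
                          SeqIO.parse(str(r2_path), "fastq"), strict=True):
        yield (
            rec1.id.rsplit("/", 1)[0],
            (str(rec1.seq), rec1.letter_annotations["phred_quality"]),
            (str(rec2.seq), rec2.letter_annotations["phred_quality"]),
        )


def preprocess_run(r1_path, r2_path, layout: PlateLayout, schema: AmpliconSchema,
                   cfg: FilterConfig = FilterConfig(), min_overlap: int = 30,
                   max_mismatch: int = 1):
    """Full front end: merge -> subsample -> filter -> demux.

    Subsampling is applied to the pooled run with budget
    ``subsample_per_plate x n_plates`` (plate identity is only known after
    tag decoding).  Returns (bins, stats); stats counts are conserved.
    """
    merged, n_pairs, n_unmerged = [], 0, 0
    for rid, r1, r2 in read_fastq_pairs(r1_path, r2_path):
        n_pairs += 1
        m = merge_pairs(r1, r2, min_overlap=min_overlap, read_id=rid)
        if m is None:
            n_unmerged += 1
        else:
            merged.append(m)
    budget = cfg.subsample_per_plate * layout.n_plates
    sampled = subsample_plate(merged, budget, seed=cfg.subsample_seed)
    n_subsampled_out = len(merged) - len(sampled)
    kept, dropped = filter_reads(sampled, cfg)
    bins, stats = demux(kept, layout, schema, max_mismatch=max_mismatch)
    stats.update(
        input_pairs=n_pairs, unmerged=n_unmerged,
        subsampled_out=n_subsampled_out, filtered=len(dropped),
    )
    return bins, stats
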