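import numpy as np
import pytest

import pairtcr as pt
from pairtcr._dna import random_dna, translate
from pairtcr.amplicon import WellAddress
from pairtcr.annotate import annotate_read, records_to_table
from pairtcr.preprocess import AssembledRead, WellBin
from pairtcr.reference import functional_segments

from oracles import majority_consensus, smith_waterman_score


class TestAssignSegment:
    def test_verbatim_segment_is_identity_hit(self, ref):
        seg = functional_segments(ref, "alpha", "V")[3]
        hit = pt.assign_segment(seg.sequence, functional_segments(ref, "alpha", "V"))
        assert hit.segment_id == seg.id
        assert hit.identity == 1.0
        assert hit.score == 2 * len(seg)

    def test_two_substitutions_cost_exactly_ten(self, ref, rng):
        seg = functional_segments(ref, "beta", "V")[0]
        seq = list(seg.sequence)
        for pos in (50, 120):  # interior positions
            seq[pos] = next(b for b in "ACGT" if b != seq[pos])
        read = "".join(seq)
        hit = pt.assign_segment(read, functional_segments(ref, "beta", "V"))
        assert hit.segment_id == seg.id
        assert hit.score == 2 * len(seg) - 2 * (2 + 3)
        assert hit.score == smith_waterman_score(read, seg.sequence)

    def test_random_sequence_is_no_hit(self, ref, rng):
        read = random_dna(rng, 60)
        candidates = functional_segments(ref, "alpha", "V")
        best = max(smith_waterman_score(read, c.sequence) for c in candidates)
        assert best < 50  # brute-force confirms the floor applies
        assert pt.assign_segment(read, candidates) is None

    def test_matches_exhaustive_dp_oracle_on_random_instances(self, ref, rng):
        segments = (functional_segments(ref, "alpha", "J")
                    + functional_segments(ref, "beta", "J")
                    + functional_segments(ref, "alpha", "V")[:3])
        for _ in range(60):
            read = random_dna(rng, int(rng.integers(40, 601)))
            seg = segments[int(rng.integers(0, len(segments)))]
            expected = smith_waterman_score(read, seg.sequence)
            hit = pt.assign_segment(read, [seg], score_floor=-1)
            assert hit.score == expected

    def test_tie_break_is_lexicographic(self, ref):
        # two identical candidate sequences under different ids
        seg = functional_segments(ref, "alpha", "V")[0]
        twin_b = pt.GeneSegment("ZZZ-TWIN", "alpha", "V", "F01", seg.sequence,
                                cys_codon_start=seg.cys_codon_start)
        hit = pt.assign_segment(seg.sequence, [twin_b, seg])
        assert hit.segment_id == min(seg.id, "ZZZ-TWIN")


class TestExtractCdr3:
    def test_recovers_ground_truth_junction(self, ref, rng):
        for _ in range(20):
            clone = pt.sample_clonotype(ref, rng, force_productive=False)
            chain_nt = pt.chain_sequence(ref, clone.v_alpha, clone.j_alpha,
                                         clone.junction_alpha)
            ann = annotate_read(chain_nt, ref, "alpha")
            assert ann is not None
            v_hit, j_hit, cdr3_nt, cdr3_aa, productive = ann
            assert (v_hit.segment_id, j_hit.segment_id) == (clone.v_alpha,
                                                            clone.j_alpha)
            assert cdr3_nt == clone.junction_alpha
            assert productive == clone.productive_alpha

    def test_out_of_frame_junction_is_unproductive(self, ref, rng):
        # force a junction with 14 inserted nucleotides minus trimming -> 1 mod 3
        while True:
            clone = pt.sample_clonotype(ref, rng, force_productive=False)
            if len(clone.junction_beta) % 3:
                break
        chain_nt = pt.chain_sequence(ref, clone.v_beta, clone.j_beta,
                                     clone.junction_beta)
        ann = annotate_read(chain_nt, ref, "beta")
        assert ann is not None and ann[4] is False

    def test_in_frame_stop_is_unproductive(self, ref):
        v = functional_segments(ref, "alpha", "V")[0]
        j = functional_segments(ref, "alpha", "J")[0]
        insert_len = 3 - (3 + j.phe_codon_start + 3) % 3 + 3
        insert = "TAA" + "G" * (insert_len - 3)
        junction = (v.sequence[v.cys_codon_start:] + insert
                    + j.sequence[: j.phe_codon_start + 3])
        assert len(junction) % 3 == 0
        assert not pt.is_productive(ref, v.id, j.id, junction)
        ann = annotate_read(pt.chain_sequence(ref, v.id, j.id, junction), ref, "alpha")
        assert ann is not None and ann[4] is False

    def test_productivity_agrees_with_independent_translation(self, ref, rng):
        for _ in range(50):
            clone = pt.sample_clonotype(ref, rng, force_productive=False)
            chain_nt = pt.chain_sequence(ref, clone.v_beta, clone.j_beta,
                                         clone.junction_beta)
            trimmed = chain_nt[: len(chain_nt) - len(chain_nt) % 3]
            independent = (len(clone.junction_beta) % 3 == 0
                           and "*" not in translate(trimmed))
            assert pt.is_productive(ref, clone.v_beta, clone.j_beta,
                                    clone.junction_beta) == independent


def _bin_of(seqs, well=WellAddress(0, "A", 1), chain="alpha"):
    return WellBin(well, chain, [
        AssembledRead(s, np.full(len(s), 37), 0.99, read_id=str(i))
        for i, s in enumerate(seqs)
    ])


class TestWellConsensus:
    def test_identical_reads_give_full_support_no_doublet(self, ref, rng):
        clone = pt.sample_clonotype(ref, rng)
        seq = pt.chain_sequence(ref, clone.v_alpha, clone.j_alpha,
                                clone.junction_alpha)
        rec = pt.well_consensus(_bin_of([seq] * 5), ref)
        assert rec.n_reads_support == 5 and not rec.doublet_flag
        assert rec.cdr3_nt == clone.junction_alpha

    def test_minority_clone_sets_doublet_flag(self, ref, rng):
        a = pt.sample_clonotype(ref, rng)
        b = pt.sample_clonotype(ref, rng)
        seq_a = pt.chain_sequence(ref, a.v_alpha, a.j_alpha, a.junction_alpha)
        seq_b = pt.chain_sequence(ref, b.v_alpha, b.j_alpha, b.junction_alpha)
        rec = pt.well_consensus(_bin_of([seq_a] * 6 + [seq_b] * 3), ref)
        assert rec.cdr3_nt == a.junction_alpha
        assert rec.doublet_flag  # 3/9 = 33% >= 20% and >= 2 reads
        rec2 = pt.well_consensus(_bin_of([seq_a] * 9 + [seq_b]), ref)
        assert not rec2.doublet_flag  # single read never flags

    def test_consensus_equals_majority_vote_oracle(self, ref, rng):
        clone = pt.sample_clonotype(ref, rng)
        seq = pt.chain_sequence(ref, clone.v_alpha, clone.j_alpha,
                                clone.junction_alpha)
        reads = []
        for _ in range(10):
            pos = int(rng.integers(0, len(seq)))
            sub = "ACGT"[int(rng.integers(0, 4))]
            reads.append(seq[:pos] + sub + seq[pos + 1 :])
        rec = pt.well_consensus(_bin_of(reads), ref)
        grouped = [r for r in reads
                   if annotate_read(r, ref, "alpha") is not None
                   and annotate_read(r, ref, "alpha")[2] == rec.cdr3_nt]
        assert rec.consensus_sequence == majority_consensus(grouped)

    def test_all_no_hit_bin_returns_none(self, ref, rng):
        junk = [random_dna(rng, 500) for _ in range(3)]
        assert pt.well_consensus(_bin_of(junk), ref) is None

    def test_records_table_columns(self, clean_records):
        table = records_to_table(clean_records)
        assert len(table) == len(clean_records)
        assert {"v_gene", "j_gene", "cdr3_nt", "productive"} <= set(table.columns)


class TestRoundTripRecovery:
    def test_error_free_run_recovers_every_well_annotation(self, clean_run,
                                                           clean_records):
        truth = clean_run.ground_truth.set_index(["plate", "row", "column"])
        assert len(clean_records) == 2 * len(truth)
        for rec in clean_records:
            row = truth.loc[(rec.well.plate, rec.well.row, rec.well.column)]
            sfx = "alpha" if rec.chain == "alpha" else "beta"
            assert rec.v_hit.segment_id == row[f"v_{sfx}"]
            assert rec.j_hit.segment_id == row[f"j_{sfx}"]
            assert rec.cdr3_nt == row[f"junction_{sfx}"]
            assert rec.productive == row[f"productive_{sfx}"]
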