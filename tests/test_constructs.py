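import numpy as np
import pytest

import pairtcr as pt
from pairtcr._dna import revcomp, translate
from pairtcr.amplicon import WellAddress
from pairtcr.annotate import ChainRecord, SegmentHit
from pairtcr.constructs import AssemblyError, ConstructConfig, GibsonFragment
from pairtcr.repertoire import PairedTCR


@pytest.fixture(scope="module")
def library(ref):
    return pt.make_vector_library(ref)


def pair_from_clonotype(clone, well=WellAddress(0, "A", 1)):
    def rec(chain):
        hit = lambda sid: SegmentHit(sid, 0.0, 0, 0, 0, 0, 1.0)
        return ChainRecord(well, chain, hit(clone.v(chain)), hit(clone.j(chain)),
                           clone.junction(chain), None, clone.productive(chain),
                           5, False, "")
    return PairedTCR(well=well, alpha=rec("alpha"), beta=rec("beta"))


@pytest.fixture(scope="module")
def productive_pair(ref):
    rng = np.random.default_rng(21)
    return pair_from_clonotype(pt.sample_clonotype(ref, rng, force_productive=True))


def build(ref, library, pair, cfg=ConstructConfig()):
    frags = pt.design_fragments(pair, ref, cfg)
    vec = pt.select_vector(pair.alpha.v_hit.segment_id, library, ref)
    return frags, vec, pt.assemble(frags, vec, cfg, ref=ref)


class TestDesignFragments:
    def test_homology_tails_have_configured_length(self, ref, productive_pair):
        frags = pt.design_fragments(productive_pair, ref)
        for f in frags:
            assert len(f.left_homology) == len(f.right_homology) == 20
            assert f.sequence.startswith(f.left_homology)
            assert f.sequence.endswith(f.right_homology)

    def test_germline_reversion_outside_junction(self, ref, productive_pair):
        # simulate primer-region substitutions: they never reach the fragment
        frag_va, _, _ = pt.design_fragments(productive_pair, ref)
        v = ref[productive_pair.alpha.v_hit.segment_id]
        germline_5p = v.sequence[: v.cys_codon_start]
        assert frag_va.sequence[20 : 20 + len(germline_5p)] == germline_5p
        j = ref[productive_pair.alpha.j_hit.segment_id]
        germline_3p = j.sequence[j.phe_codon_start + 3 :]
        assert germline_3p in frag_va.sequence

    def test_missing_or_unproductive_chain_errors(self, ref, productive_pair):
        alpha_only = PairedTCR(well=productive_pair.well,
                               alpha=productive_pair.alpha, beta=None)
        with pytest.raises(ValueError, match="beta"):
            pt.design_fragments(alpha_only, ref)
        import dataclasses
        bad_beta = dataclasses.replace(productive_pair.beta, productive=False)
        with pytest.raises(ValueError, match="productive"):
            pt.design_fragments(PairedTCR(well=productive_pair.well,
                                          alpha=productive_pair.alpha,
                                          beta=bad_beta), ref)


class TestSelectVector:
    def test_family_keyed_lookup(self, ref, library, productive_pair):
        v_id = productive_pair.alpha.v_hit.segment_id
        vec = pt.select_vector(v_id, library, ref)
        assert vec.family == ref[v_id].family

    def test_uncovered_family_errors_with_coverage_list(self, ref, library):
        missing = {k: v for k, v in library.items() if k != "F03"}
        v3 = next(s.id for s in ref if s.seg_class == "V" and s.chain == "alpha"
                  and s.family == "F03")
        with pytest.raises(KeyError, match="F03"):
            pt.select_vector(v3, missing, ref)

    def test_thirteen_distinct_backbones(self, library):
        assert len(library) == 13
        assert len({v.linearized for v in library.values()}) == 13


class TestAssemble:
    def test_feature_order_and_disjoint_spans(self, ref, library, productive_pair):
        _, _, construct = build(ref, library, productive_pair)
        order = ["SSalpha", "Valpha", "Calpha", "P2A", "SSbeta", "Vbeta", "Cbeta"]
        spans = [construct.features[n] for n in order]
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 == s1 and s0 < e0
        assert spans[0][0] == 0

    def test_seamless_length_arithmetic(self, ref, library, productive_pair):
        frags, vec, construct = build(ref, library, productive_pair)
        total = len(vec.linearized) + sum(len(f) for f in frags)
        assert len(construct) == total - 4 * 20

    def test_corrupted_tail_names_failing_junction(self, ref, library,
                                                   productive_pair):
        frags = list(pt.design_fragments(productive_pair, ref))
        bad = frags[2].sequence
        bad = revcomp(bad[:20]) + bad[20:]
        frags[2] = GibsonFragment(frags[2].name, bad, bad[:20], frags[2].right_homology)
        vec = pt.select_vector(productive_pair.alpha.v_hit.segment_id, library, ref)
        with pytest.raises(AssemblyError, match="SSbeta-Vbeta"):
            pt.assemble(tuple(frags), vec, ref=ref)

    def test_assembly_is_deterministic(self, ref, library, productive_pair):
        _, _, c1 = build(ref, library, productive_pair)
        _, _, c2 = build(ref, library, productive_pair)
        assert c1.sequence == c2.sequence


class TestValidateOrf:
    def test_productive_pair_is_in_frame(self, ref, library, productive_pair):
        _, _, construct = build(ref, library, productive_pair)
        report = pt.validate_orf(construct)
        assert report.in_frame and not report.premature_stops
        assert report.junctions_seamless and report.has_2a_in_frame
        # independent translate-and-scan of the ORF
        orf = construct.orf
        aa = translate(orf)
        assert aa.count("*") == 1 and aa.endswith("*")

    def test_cdr3_peptides_appear_in_translation(self, ref, library, productive_pair):
        _, _, construct = build(ref, library, productive_pair)
        aa = translate(construct.orf)
        for rec in (productive_pair.alpha, productive_pair.beta):
            assert translate(rec.cdr3_nt) in aa

    def test_single_nt_deletion_flips_validation(self, ref, library,
                                                 productive_pair):
        _, _, construct = build(ref, library, productive_pair)
        cut = construct.features["Valpha"][1]  # Vα-Cα junction
        mutated = construct.sequence[: cut - 1] + construct.sequence[cut:]
        import dataclasses
        broken = dataclasses.replace(construct, sequence=mutated)
        report = pt.validate_orf(broken)
        assert not report.in_frame
        if report.premature_stops:
            assert min(report.premature_stops) >= cut - 1 - 60  # downstream-ish

    def test_missing_start_codon_reported_not_raised(self, ref, library,
                                                     productive_pair):
        _, _, construct = build(ref, library, productive_pair)
        import dataclasses
        broken = dataclasses.replace(construct,
                                     sequence="TTG" + construct.sequence[3:])
        report = pt.validate_orf(broken)
        assert not report.in_frame and "ATG" in report.note


class TestScreenAmplicon:
    def test_fixture_constructs_land_in_printed_window(self, ref, library, rng):
        for _ in range(10):
            pair = pair_from_clonotype(pt.sample_clonotype(ref, rng))
            _, _, construct = build(ref, library, pair)
            length = pt.predict_screen_amplicon(construct)
            assert 1600 <= length <= 1700

    def test_toy_template_exact_arithmetic(self):
        cfg = ConstructConfig()
        # place primers at hand-counted offsets on a 100 bp toy circle
        fw, rev = cfg.control_fw, cfg.control_rev
        seq = "A" * 10 + fw + "C" * 20 + revcomp(rev) + "G" * (100 - 10 - len(fw)
                                                               - 20 - len(rev))
        construct = pt.ExpressionConstruct(sequence=seq, features={},
                                           vector_family="F01")
        # product: fw(20) + spacer(20) + rev site(17) = 57
        assert pt.predict_screen_amplicon(construct, cfg) == 57

    def test_absent_primer_site_errors_with_count(self, ref, library,
                                                  productive_pair):
        _, _, construct = build(ref, library, productive_pair)
        import dataclasses
        cfg = ConstructConfig()
        corrupted = construct.sequence.replace(cfg.control_fw, "A" * 20)
        broken = dataclasses.replace(construct, sequence=corrupted)
        with pytest.raises(ValueError, match="fw: 0"):
            pt.predict_screen_amplicon(broken, cfg)


class TestEndToEnd:
    def test_any_productive_pair_clones_in_frame(self, ref, library, rng):
        for _ in range(10):
            pair = pair_from_clonotype(pt.sample_clonotype(ref, rng))
            _, _, construct = build(ref, library, pair)
            report = pt.validate_orf(construct)
            assert report.in_frame
            aa = translate(construct.orf)
            assert translate(pair.alpha.cdr3_nt) in aa
            assert translate(pair.beta.cdr3_nt) in aa

    def test_genbank_round_trip(self, ref, library, productive_pair, tmp_path):
        from Bio import SeqIO
        _, _, construct = build(ref, library, productive_pair)
        pt.to_genbank(construct, tmp_path / "c.gb", name="test")
        rec = SeqIO.read(tmp_path / "c.gb", "genbank")
        assert str(rec.seq) == construct.sequence
        assert rec.annotations["topology"] == "circular"
        labels = {f.qualifiers["label"][0] for f in rec.features}
        assert {"SSalpha", "P2A", "Cbeta"} <= labels
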