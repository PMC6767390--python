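"""Design and validate a TCRα-2A-TCRβ expression construct in silico.

Takes one productive paired clonotype, designs the three homology-tailed
Gibson fragments, picks the family-matched vector from the 13-member SSα
library, assembles the circular plasmid, validates the single open reading
frame, and predicts the colony-screen PCR product of the control primers.
"""

import numpy as np

import pairtcr as pt
from pairtcr._dna import translate
from pairtcr.amplicon import WellAddress
from pairtcr.annotate import ChainRecord, SegmentHit
from pairtcr.repertoire import PairedTCR

ref = pt.make_reference(seed=0)
library = pt.make_vector_library(ref)
clone = pt.sample_clonotype(ref, np.random.default_rng(3), force_productive=True)

well = WellAddress(0, "A", 1)
hit = lambda sid: SegmentHit(sid, 0.0, 0, 0, 0, 0, 1.0)
pair = PairedTCR(
    well=well,
    alpha=ChainRecord(well, "alpha", hit(clone.v_alpha), hit(clone.j_alpha),
                      clone.junction_alpha, None, True, 5, False, ""),
    beta=ChainRecord(well, "beta", hit(clone.v_beta), hit(clone.j_beta),
                     clone.junction_beta, None, True, 5, False, ""),
)

fragments = pt.design_fragments(pair, ref)
vector = pt.select_vector(clone.v_alpha, library, ref)
construct = pt.assemble(fragments, vector, ref=ref)
report = pt.validate_orf(construct)
screen_bp = pt.predict_screen_amplicon(construct)

print(f"clonotype: {clone.v_alpha}/{clone.j_alpha} + {clone.v_beta}/{clone.j_beta}")
print(f"vector family: {vector.family} (of {len(library)} in the SSα library)")
print(f"plasmid size: {len(construct)} bp")
print(f"in frame: {report.in_frame}; premature stops: {report.premature_stops}")
print(f"CDR3α peptide {translate(pair.alpha.cdr3_nt)} in ORF: "
      f"{translate(pair.alpha.cdr3_nt) in translate(construct.orf)}")
print(f"colony-screen product: {screen_bp} bp (expected window 1600-1700)")
# A product inside the window plus in-frame validation is what a passing
# colony screen + Sanger confirmation would show at the bench.
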