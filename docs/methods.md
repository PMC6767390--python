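# Methods

This note documents the models, conventions and parameter choices behind
`pairtcr`, in the order data flows through the pipeline.

## Synthetic reference locus (`pairtcr.fixture`)

No germline sequences ship with the package; `make_reference(seed)`
synthesises a stand-in locus with the real loci's bookkeeping structure:
20 TRAV (in 13 families) / 10 TRAJ / 1 TRAC, 26 TRBV / 12 TRBJ / 1 TRBC,
13 family-specific α leaders (mirroring the 13-vector expression library),
one β leader, the real 66 nt porcine teschovirus-1 P2A sequence, and a
synthetic vector-backbone core carrying the colony-screen control-primer
sites. V segments end on a TGT/TGC cysteine codon; J segments carry an
in-frame TTY-GGN-NNN-GGN (FGxG) motif; all frames that end up inside the
expression ORF are generated stop-free so that frame arithmetic behaves
like real, functional germline genes.

Lengths are the load-bearing calibration:

* V 324–336 nt (α) / 330–342 nt (β), J 54–60 nt, C stub 80 nt, tags 8 nt,
  universal linker 22 nt → every merged amplicon (with tags) lies in
  499–530 nt, inside the accepted 480–560 window. Note the underlying gel
  estimate of the wet assay (~450/480 bp *without* barcode/linker bases)
  sits below that window; the filter is interpreted as applying to the
  full assembled read including tags, which is the only reading that is
  self-consistent, and this tension is deliberately surfaced here.
* SSα 60, Cα 300, 2A 66, SSβ 57, Cβ 270 nt plus fixed backbone pads put
  the control-primer screen product at 1605–1658 bp for any V/J/N-region
  combination, inside the expected 1600–1700 bp window.

Real references can be dropped in through the FASTA + tab-delimited
metadata format (`id, chain, class, family, functional, cys_codon_start,
phe_codon_start`; anchors are 0-based codon-start offsets). Metadata is a
sidecar table rather than parsed FASTA headers because header dialects
vary between databases.

## Barcode matrix and decoding (`pairtcr.amplicon`)

Defaults: tag length 8 nt, minimum pairwise Hamming distance 3, one
correctable mismatch per tag — `d_min ≥ 2·e_max + 1` makes the correction
provably unique. Tag sets also exclude reverse-complement collisions.
Plates tile into a near-square super-grid (12 plates → 3 × 4); columns of
the super-grid consume forward tags, rows consume reverse tags, giving a
bijection between tag pairs and wells that is serialised as a versioned
JSON layout. Decoding picks the unique nearest tag within the mismatch
budget; distance ties are rejected as `ambiguous`, and structurally valid
but unused tag pairs as `unmapped`.

## Simulator (`pairtcr.simulate`)

What it emulates: one clonotype per filled well (V and J uniform over
functional segments; 0–10 random N nucleotides at the junction; by default
resampled until productive, as sorted cells express in-frame receptors),
independent per-chain dropout (one knob standing in for RT failure, PCR
dropout and annotation loss combined), a fixed number of read pairs per
well and chain, i.i.d. per-base substitution error, and an index-sort
table (population label + 6 lognormal fluorescence channels). Optional
doublet wells mix a second clonotype at 30% of reads.

Defaults: 90% wells filled, 5 read pairs/well/chain, dropout 0.1/chain,
substitution rate 0.003, 2 × 300 nt reads, doublet rate 0.

Quality model: two states, Q37 and Q12; the low-state fraction is chosen
so the configured error rate equals the rate implied by the qualities, but
error placement is drawn independently of the state, keeping the emitted
substitution frequency exactly Bernoulli(rate) (and exactly zero at rate
0). Qualities therefore carry realistic structure for quality-aware
merging without base-level truth leakage being required for correctness.

What it does **not** model: indels, PCR chimeras, primer-efficiency bias
across V families, cross-well contamination, and quality degradation along
the read. Passing tests therefore demonstrate correctness of the decoding,
annotation and bookkeeping logic under substitution noise — not robustness
to structural artefacts of real libraries.

## Preprocessing (`pairtcr.preprocess`)

* **Merging** scans every ungapped overlap ≥ 30 nt between read 1 and the
  reverse complement of read 2, scoring +1/−1, and requires ≥ 75% identity
  in the best overlap. Disagreements take the higher-quality base with
  quality |q₁ − q₂| (floored at 2); agreements get the summed quality
  capped at Q60. The read-level score is the geometric mean over bases of
  (1 − error probability) — a PandaSeq-like statistic in [0, 1], since the
  original statistic is not formally defined anywhere.
* **Filtering**: quality strictly `> 0.8`; length inclusive in
  `[480, 560]` — the literal reading of "higher than 0.8" and "480–560".
* **Subsampling** (uniform, without replacement, seeded) happens after
  merging and before filtering, matching the stated order of operations.
  It is applied to the pooled run with budget `subsample_per_plate ×
  n_plates` (default 75 000/plate, the middle of the 50–100 k range),
  because plate identity is only known after tag decoding.
* **Demultiplexing** decodes both tags, trims tags + linker, and calls the
  chain by local-alignment score against the Cα vs Cβ stubs with a minimum
  margin of 5 score points (ties → `ambiguous_chain`). All reject
  categories are counted and conserve the input read count.

## Annotation (`pairtcr.annotate`)

Scoring: match +2, mismatch −3, gap open −5, gap extend −2, where a gap of
length k costs 5 + 2(k − 1); best segment by score, ties broken by
lexicographic id; hits below a floor of 50 (~25 matched bases) are
discarded. Alignment is delegated to Biopython's `PairwiseAligner`; the
test suite checks it against an independent exhaustive affine-gap DP on
hundreds of random instances.

CDR3 convention: the junction **includes** both the V cysteine codon and
the J phenylalanine codon. This is explicit and testable; IMGT-style
trimmed junctions are a 3 nt slice on each side. Productivity = junction
length ≡ 0 (mod 3), anchors fully aligned, and no stop codon in the chain
frame anchored at the V segment start.

Consensus: reads grouped by (V, J, CDR3); the largest group wins (ties by
lexicographic key); base calls by per-column majority within the dominant
group (ties to the lexicographically smallest base). Doublet flag when the
runner-up group holds ≥ 20% of reads and ≥ 2 reads — conservative, since
the sorter deposits one cell per well and no contamination rule is
otherwise defined. All thresholds are keyword-configurable.

## Pairing statistics (`pairtcr.repertoire`)

Denominators are sorted input cells (the manifest), not reads, matching
the "% of input cells" framing of plate-based efficiency reporting.
Clonotype identity, where needed, is the (V gene, J gene, CDR3 nucleotide)
triple per chain. Under independent per-chain dropout d the expected
paired fraction is (1 − d)²; the acceptance suite verifies the full
pipeline reproduces this within 3 binomial σ at 1 000 wells.

## Construct design (`pairtcr.constructs`)

Fragments carry 20 nt homology tails (configurable; no published tail
lengths exist to adopt). Fragment sequences are rebuilt as germline V +
observed junction + germline J, which models the error-reverting
gene-specific PCR: any simulated substitution outside the junction never
reaches the construct. The Cα/linker boundary is fixed at the Cα 5' end:
the linker fragment is the full Cα–2A–SSβ cassette and the Vα fragment
ends at the Cα 5' junction, recorded in the feature map.

Assembly is exact overlap merging (vector → Vα → linker → Vβ → closure);
each seam's homology string must occur exactly once on the finished
plasmid, so total length = Σ fragments − 4 × 20. The circular sequence is
serialised with origin at the SSα ATG, making the ORF contiguous for
validation; GenBank output is circular with the full feature map.
Validation translates SSα→Cβ and requires: no premature stop, a terminal
stop, seamless feature adjacency, and the 2A peptide in frame. The screen
product length is the distance from the forward-primer 5' end to the
reverse-primer site 3' end on the circle (both footprints included),
erroring unless each site occurs exactly once.

## Reactivity (`pairtcr.reactivity`)

AUC integrates the mean replicate response over the linear concentration
axis (trapezoids, baseline 0, negative readings clamped) in
(ng/mL)·(mg/mL) units; the 0.5 threshold is strict, equal to 50× the
negative-control mean of 0.01. A log₁₀-dose mode exists because
plate-reader software is ambiguous on the axis; linear is the default as
the threshold's published fold-over-control interpretation only holds
there. The panel generator plants a chosen number of responders with
saturating curves whose top-dose responses are log-uniform in 0.5–80
ng/mL (the observed spread among responsive receptors) and non-responders
at control level.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeds; simulated
  FASTQ output is byte-identical per seed.
* Problem sizes in the test and acceptance suites (100-well round trips,
  1 000-well dropout propagation at 2 reads/well, 200 alignment-oracle
  instances, 50 validated constructs) were chosen as the smallest runs at
  which the binomial/exactness checks are meaningful.
* Known limitations: no indel-tolerant tag decoding; no allele-level gene
  resolution; no D-segment resolution for TCRβ (subsumed in the junction);
  chain inference assumes the constant stub survives at the read 3' end;
  efficiency tables mirror real-data reporting only in form — their values
  on synthetic runs are properties of the simulator's dropout settings,
  not of any biological dataset.
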