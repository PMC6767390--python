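"""Synthetic sorted-plate simulator.

Emulates the wet-lab front end of the platform: single T cells index-sorted
into 384-well plates, per-well V(D)J clonotypes with random N-region
junctions, matrix-barcoded second-PCR amplicons, and 2 x 300 bp paired-end
reads with per-base substitution error.  Every run returns its ground truth
(one row per filled well), so each downstream stage can be scored exactly.

The error model is substitution-only and i.i.d. per base at the configured
rate.  Phred qualities follow a two-state model (high ~= Q37, low ~= Q12);
the fraction of low-quality bases is set so the configured error rate is
consistent with the qualities, but error placement is drawn independently,
which keeps the emitted error frequency exactly Bernoulli(rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._dna import random_dna, revcomp, translate
from .amplicon import AmpliconSchema, PlateLayout
from .reference import ReferenceSet, functional_segments

POPULATIONS = ("CD4_spleen", "actCD4_spleen", "Tfh_LN", "Treg_LN", "actCD8_liver")
FLUOR_CHANNELS = ("FSC", "SSC", "CD4", "CD44", "CXCR5", "PD1")

_Q_HIGH, _Q_LOW = 37, 12
_ERR_HIGH = 10.0 ** (-_Q_HIGH / 10)
_ERR_LOW = 10.0 ** (-_Q_LOW / 10)


@dataclass(frozen=True)
class Clonotype:
    """Ground-truth paired rearrangement of one cell.

    Junctions run from the V conserved-cysteine codon through the J
    FGxG-phenylalanine codon, both inclusive.
    """

    v_alpha: str
    j_alpha: str
    v_beta: str
    j_beta: str
    junction_alpha: str
    junction_beta: str
    productive_alpha: bool
    productive_beta: bool
    population_label: str = "CD4_spleen"

    def junction(self, chain: str) -> str:
        return self.junction_alpha if chain == "alpha" else self.junction_beta

    def v(self, chain: str) -> str:
        return self.v_alpha if chain == "alpha" else self.v_beta

    def j(self, chain: str) -> str:
        return self.j_alpha if chain == "alpha" else self.j_beta

    def productive(self, chain: str) -> bool:
        return self.productive_alpha if chain == "alpha" else self.productive_beta


def chain_sequence(ref: ReferenceSet, v_id: str, j_id: str, junction: str) -> str:
    """Full V...J chain nucleotide sequence implied by a junction string."""
    v, j = ref[v_id], ref[j_id]
    return v.sequence[: v.cys_codon_start] + junction + j.sequence[j.phe_codon_start + 3 :]


def is_productive(ref: ReferenceSet, v_id: str, j_id: str, junction: str) -> bool:
    """Frame-preserving junction with a stop-free chain reading frame."""
    if len(junction) % 3:
        return False
    chain = chain_sequence(ref, v_id, j_id, junction)
    return "*" not in translate(chain[: len(chain) - len(chain) % 3])


def _sample_chain(ref: ReferenceSet, rng: np.random.Generator, chain: str,
                  max_n_region: int = 10) -> tuple[str, str, str, bool]:
    vs = functional_segments(ref, chain, "V")
    js = functional_segments(ref, chain, "J")
    v = vs[rng.integers(0, len(vs))]
    j = js[rng.integers(0, len(js))]
    n = int(rng.integers(0, max_n_region + 1))
    junction = (
        v.sequence[v.cys_codon_start :]
        + random_dna(rng, n)
        + j.sequence[: j.phe_codon_start + 3]
    )
    return v.id, j.id, junction, is_productive(ref, v.id, j.id, junction)


def sample_clonotype(ref: ReferenceSet, rng: np.random.Generator,
                     force_productive: bool = True,
                     population_label: Optional[str] = None,
                     max_n_region: int = 10) -> Clonotype:
    """Draw a random paired clonotype: uniform functional V and J per chain,
    0-10 random N nucleotides at the junction.

    With ``force_productive`` each chain is resampled until productive,
    mimicking that sorted cells express in-frame receptors.
    """
    ref.require_complete("alpha")
    ref.require_complete("beta")
    chains = {}
    for chain in ("alpha", "beta"):
        for _ in range(1000):
            drawn = _sample_chain(ref, rng, chain, max_n_region)
            if not force_productive or drawn[3]:
                chains[chain] = drawn
                break
        else:  # pragma: no cover - fixture loci always admit productive draws
            raise RuntimeError(f"no productive {chain} rearrangement found in 1000 draws")
    if population_label is None:
        population_label = POPULATIONS[rng.integers(0, len(POPULATIONS))]
    va, ja, jxa, pa = chains["alpha"]
    vb, jb, jxb, pb = chains["beta"]
    return Clonotype(va, ja, vb, jb, jxa, jxb, pa, pb, population_label)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated run.

    Defaults mirror the platform's setup: 384-well plates, 2 x 300 bp reads,
    modest per-chain dropout (RT/PCR failure folded into a single knob) and
    a low substitution error rate.
    """

    n_plates: int = 1
    wells_filled: float | int = 0.9      # fraction, or exact well count
    reads_per_well: int = 5              # read pairs per well and chain
    chain_dropout_alpha: float = 0.1
    chain_dropout_beta: float = 0.1
    substitution_error_rate: float = 0.003
    read_length: int = 300
    doublet_rate: float = 0.0
    force_productive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chain_dropout_alpha", "chain_dropout_beta", "doublet_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.substitution_error_rate <= 0.05:
            raise ValueError("substitution_error_rate must be in [0, 0.05]")
        if self.reads_per_well < 0:
            raise ValueError("reads_per_well must be >= 0")
        if isinstance(self.wells_filled, float) and not 0.0 <= self.wells_filled <= 1.0:
            raise ValueError("wells_filled fraction must be in [0, 1]")


@dataclass
class SimulatedRun:
    """Outputs of :func:`simulate_run`."""

    fastq_r1: Path
    fastq_r2: Path
    index_sort: pd.DataFrame
    ground_truth: pd.DataFrame
    index_sort_path: Optional[Path] = None
    ground_truth_path: Optional[Path] = None


def _low_state_fraction(rate: float) -> float:
    return float(np.clip((rate - _ERR_HIGH) / (_ERR_LOW - _ERR_HIGH), 0.0, 1.0))


def _noisy_read(rng: np.random.Generator, template: str, rate: float,
                p_low: float) -> tuple[str, str]:
    """Apply substitution errors and draw the two-state quality string."""
    n = len(template)
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    if rate > 0:
        hits = np.nonzero(rng.random(n) < rate)[0]
        if hits.size:
            lut = np.frombuffer(b"ACGT", dtype=np.uint8)
            for i in hits:
                choices = lut[lut != arr[i]]
                arr[i] = choices[rng.integers(0, 3)]
    low = rng.random(n) < p_low
    qual = np.where(low, _Q_LOW, _Q_HIGH) + 33
    return arr.tobytes().decode(), qual.astype(np.uint8).tobytes().decode()


def _fluorescence(rng: np.random.Generator, population: str) -> list[float]:
    # population index shifts a couple of channels so phenotype joins are
    # non-trivial; absolute values are arbitrary "MFI-like" intensities
    k = POPULATIONS.index(population) if population in POPULATIONS else 0
    base = rng.lognormal(mean=7.0, sigma=0.4, size=len(FLUOR_CHANNELS))
    base[2 + (k % 4)] *= 3.0
    return [round(float(x), 2) for x in base]


def simulate_run(ref: ReferenceSet, layout: PlateLayout, schema: AmpliconSchema,
                 config: SimulationConfig, out_dir) -> SimulatedRun:
    """Simulate a full sorted-and-sequenced run.

    Writes ``reads_R1.fastq`` / ``reads_R2.fastq``, ``index_sort.tsv`` and
    ``ground_truth.tsv`` under ``out_dir``; byte-identical for a given
    config (the seed fixes everything).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    all_wells = list(layout.wells())
    if config.n_plates > layout.n_plates:
        raise ValueError(f"config asks {config.n_plates} plates, layout holds {layout.n_plates}")
    wells = [w for w in all_wells if w.plate < config.n_plates]
    if isinstance(config.wells_filled, int) and not isinstance(config.wells_filled, bool):
        n_fill = config.wells_filled
    else:
        n_fill = int(round(config.wells_filled * len(wells)))
    if n_fill > len(wells):
        raise ValueError(f"config asks {n_fill} filled wells, layout holds {len(wells)}")
    filled_idx = sorted(rng.choice(len(wells), size=n_fill, replace=False))
    filled = [wells[i] for i in filled_idx]

    p_low = _low_state_fraction(config.substitution_error_rate)
    truth_rows, index_rows = [], []
    serial = 0
    r1_path, r2_path = out_dir / "reads_R1.fastq", out_dir / "reads_R2.fastq"
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for well in filled:
            clone = sample_clonotype(ref, rng, force_productive=config.force_productive)
            doublet = rng.random() < config.doublet_rate
            second = (
                sample_clonotype(ref, rng, force_productive=config.force_productive,
                                 population_label=clone.population_label)
                if doublet else None
            )
            dropped = {
                "alpha": rng.random() < config.chain_dropout_alpha,
                "beta": rng.random() < config.chain_dropout_beta,
            }
            truth_rows.append({
                "plate": well.plate, "row": well.row, "column": well.column,
                "population_label": clone.population_label,
                "v_alpha": clone.v_alpha, "j_alpha": clone.j_alpha,
                "junction_alpha": clone.junction_alpha,
                "productive_alpha": clone.productive_alpha,
                "v_beta": clone.v_beta, "j_beta": clone.j_beta,
                "junction_beta": clone.junction_beta,
                "productive_beta": clone.productive_beta,
                "alpha_dropped": dropped["alpha"], "beta_dropped": dropped["beta"],
                "doublet": doublet,
            })
            index_rows.append({
                "plate": well.plate, "row": well.row, "column": well.column,
                "population_label": clone.population_label,
                **dict(zip(FLUOR_CHANNELS, _fluorescence(rng, clone.population_label))),
            })
            fwd_tag, rev_tag = layout.encode(well)
            for chain in ("alpha", "beta"):
                if dropped[chain]:
                    continue
                k = config.reads_per_well
                plan = [(clone, k)]
                if second is not None and k > 1:
                    k_minor = max(1, int(round(0.3 * k)))
                    plan = [(clone, k - k_minor), (second, k_minor)]
                for c, n_reads in plan:
                    template = schema.amplicon(
                        fwd_tag, rev_tag,
                        chain_sequence(ref, c.v(chain), c.j(chain), c.junction(chain)),
                        chain,
                    )
                    t_rc = revcomp(template)
                    for _ in range(n_reads):
                        rid = (f"sim:{serial}:{well.plate}:{well.row}:{well.column}:{chain}")
                        serial += 1
                        s1, q1 = _noisy_read(rng, template[: config.read_length],
                                             config.substitution_error_rate, p_low)
                        s2, q2 = _noisy_read(rng, t_rc[: config.read_length],
                                             config.substitution_error_rate, p_low)
                        f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                        f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")

    ground_truth = pd.DataFrame(truth_rows)
    index_sort = pd.DataFrame(index_rows)
    gt_path = out_dir / "ground_truth.tsv"
    ix_path = out_dir / "index_sort.tsv"
    ground_truth.to_csv(gt_path, sep="\t", index=False)
    index_sort.to_csv(ix_path, sep="\t", index=False)
    return SimulatedRun(r1_path, r2_path, index_sort, ground_truth, ix_path, gt_path)


# ---------------------------------------------------------------------------
# dose-response panel generator (for the reactivity module)

def simulate_reactivity_panel(n_total: int = 30, n_reactive: int = 12, seed: int = 0,
                              concentrations=(0.0, 0.0625, 0.25, 1.0, 2.0),
                              n_replicates: int = 2):
    """Synthetic IL-2 dose-response panel with a planted number of reactive
    clones.

    Reactive clones secrete IL-2 dose-dependently with plateau responses
    log-uniform in 0.5-80 ng/mL at the top antigen dose (the observed
    spread among responsive receptors); non-reactive clones sit at
    negative-control level (~0.01 ng/mL).  Returns a list of
    :class:`pairtcr.reactivity.DoseResponse`.
    """
    from .reactivity import DoseResponse

    if n_reactive > n_total:
        raise ValueError("n_reactive cannot exceed n_total")
    rng = np.random.default_rng(seed)
    reactive_flags = np.zeros(n_total, dtype=bool)
    reactive_flags[rng.choice(n_total, size=n_reactive, replace=False)] = True
    top = max(concentrations)
    curves = []
    for i, is_reactive in enumerate(reactive_flags):
        if is_reactive:
            top_response = float(np.exp(rng.uniform(np.log(0.5), np.log(80.0))))
            ec50 = float(rng.uniform(0.05, 0.5))
            plateau = top_response * (top + ec50) / top
            mean = [plateau * c / (c + ec50) for c in concentrations]
        else:
            mean = [0.01 for _ in concentrations]
        points = []
        for c, m in zip(concentrations, mean):
            reps = np.maximum(rng.normal(m, 0.05 * m + 0.003, size=n_replicates), 0.0)
            points.append((float(c), [float(x) for x in reps]))
        curves.append(DoseResponse(clone_id=f"TCR{i + 1:03d}", antigen="OVA", points=points))
    return curves
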