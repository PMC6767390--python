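import numpy as np
import pytest

import pairtcr as pt


@pytest.fixture(scope="session")
def ref():
    return pt.make_reference(seed=0)


@pytest.fixture(scope="session")
def schema(ref):
    return pt.schema_from_reference(ref)


@pytest.fixture(scope="session")
def layout1():
    """Single-plate layout: 24 forward (column) x 16 reverse (row) tags."""
    fwd = pt.generate_barcodes(24, length=8, min_dist=3, seed=101)
    rev = pt.generate_barcodes(16, length=8, min_dist=3, seed=102)
    return pt.build_layout(1, fwd, rev)


@pytest.fixture(scope="session")
def layout12():
    """Full 12-plate stack (3 x 4 super-grid): 96 x 48 tags."""
    fwd = pt.generate_barcodes(96, length=8, min_dist=3, seed=103)
    rev = pt.generate_barcodes(48, length=8, min_dist=3, seed=104)
    return pt.build_layout(12, fwd, rev)


@pytest.fixture(scope="session")
def clean_run(ref, schema, layout1, tmp_path_factory):
    """Error-free, dropout-free run: 1 plate x 100 wells, 5 reads/well/chain."""
    cfg = pt.SimulationConfig(
        n_plates=1, wells_filled=100, reads_per_well=5,
        chain_dropout_alpha=0.0, chain_dropout_beta=0.0,
        substitution_error_rate=0.0, seed=11,
    )
    out = tmp_path_factory.mktemp("clean_run")
    return pt.simulate_run(ref, layout1, schema, cfg, out)


@pytest.fixture(scope="session")
def clean_bins(clean_run, layout1, schema):
    bins, stats = pt.preprocess_run(clean_run.fastq_r1, clean_run.fastq_r2,
                                    layout1, schema)
    return bins, stats


@pytest.fixture(scope="session")
def clean_records(clean_bins, ref):
    bins, _ = clean_bins
    return pt.annotate_run(bins, ref)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
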