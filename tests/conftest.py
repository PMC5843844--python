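import numpy as np
import pytest

from igpipe import (
    PipelineConfig,
    PrimerScheme,
    RepertoireSimParams,
    SequencingRead,
    make_toy_references,
    process_read_pairs,
    simulate_reads,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def toy():
    """Toy germline reference set + the default primer scheme."""
    refs, scheme = make_toy_references(1)
    return refs, scheme


@pytest.fixture(scope="session")
def clean_run(toy):
    """A small zero-error simulation processed through the full cascade."""
    refs, scheme = toy
    params = RepertoireSimParams(
        seed=11, n_clones=15, molecules_per_clone=3, reads_per_molecule=3
    )
    molecules, truth = simulate_repertoire(params, refs, scheme)
    pairs, read_truth = simulate_reads(molecules, params)
    records, ledger, counts = process_read_pairs(pairs, scheme, refs.constants)
    return {
        "params": params, "molecules": molecules, "truth": truth,
        "pairs": pairs, "records": records, "ledger": ledger, "counts": counts,
    }


def make_read(bases: str, qual: int = 40, rid: str = "r") -> SequencingRead:
    return SequencingRead(rid, bases, np.full(len(bases), qual, dtype=np.int16))


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def scheme():
    return PrimerScheme()
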