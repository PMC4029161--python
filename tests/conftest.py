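"""Shared fixtures: a moderately sized simulated landscape reused across tests."""
import numpy as np
import pytest

from repeatdim import annotate, simkit
from repeatdim.models import GERMLINE, SOMA


@pytest.fixture(scope="session")
def landscape():
    """Desk-scale paired landscape: default family table at reduced copy number."""
    return simkit.simulate_landscape(
        simkit.default_landscape(copy_scale=0.3),
        n_reads={GERMLINE: 2500, SOMA: 1000},
        seed=7,
    )


@pytest.fixture(scope="session")
def oracle_alignments(landscape):
    """Truth-derived gapless alignments for both genomes, post filters."""
    alns = []
    for label in (GERMLINE, SOMA):
        rt = landscape.truth.reads
        rt = rt[rt.genome_label == label]
        alns.extend(simkit.oracle_alignments(landscape.readsets[label], rt,
                                             landscape.pools))
    return annotate.filter_alignments(alns)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
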