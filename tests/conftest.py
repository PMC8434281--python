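"""Shared fixtures.

The expensive artefacts (the full synthetic benchmark population and the
four dimer reconstructions) are built once per session and shared between
the unit tests and the acceptance tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

from zincturn import refdata
from zincturn.reconstruct import reconstruct_dimer_entry
from zincturn.synthetic import MotifSpec, build_motif_structure, make_benchmark_set

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """Full-size synthetic population: 129 motifs in the survey's cluster
    proportions (86, 16, 13, 11, 1, 1, 1) plus 6 decoys; returns
    (directory, truth table DataFrame)."""
    out = tmp_path_factory.mktemp("benchmark")
    truth = make_benchmark_set(out, decoys=6, noise_sd=0.05, seed=BENCHMARK_SEED)
    return out, pd.DataFrame(truth)


@pytest.fixture(scope="session")
def dimer_reconstructions():
    """The four observed pseudo-symmetric dimers rebuilt from published
    torsions: {entry: (structure, motif, DimerModel)}."""
    return {
        e.entry: reconstruct_dimer_entry(e)
        for e in refdata.DIMER_ENTRIES
    }


@pytest.fixture(scope="session")
def cluster1_structure():
    """A noiseless motif at the dominant cluster's mean torsions."""
    spec = MotifSpec(sequence="CPFHP",
                     backbone=(-59.0, -37.0, -65.0, -47.0, -79.0, -21.0),
                     chi1_cys=72.0, chi1_his=-75.0, zn="ideal")
    return spec, build_motif_structure(spec)
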