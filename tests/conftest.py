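import numpy as np
import pandas as pd
import pytest

from canedet.det import ComparisonSpec
from canedet.io import CountMatrix, Genotype, canonical_design
from canedet.simulate import SimulationConfig, simulate_experiment


def make_matrix(counts, lengths=None, totals=None, libraries=None):
    """Build a CountMatrix from a plain nested list of counts."""
    counts = np.asarray(counts, dtype=np.int64)
    n, m = counts.shape
    ids = [f"T{i:05d}" for i in range(n)]
    libraries = libraries or [f"L{j}" for j in range(m)]
    frame = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"), columns=libraries)
    lengths = pd.Series(lengths if lengths is not None else [1000] * n, index=frame.index)
    if totals is None:
        totals = frame.sum(axis=0)
    else:
        totals = pd.Series(totals, index=libraries)
    return CountMatrix(counts=frame, lengths=lengths, library_totals=totals)


@pytest.fixture
def design16():
    return canonical_design()


@pytest.fixture
def simulated():
    """One canonical simulated experiment shared across tests."""
    return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture
def genotype_spec(design16):
    return ComparisonSpec(
        label="high_vs_low",
        group_a=tuple(d.library_id for d in design16 if d.genotype is Genotype.HIGH_BNF),
        group_b=tuple(d.library_id for d in design16 if d.genotype is Genotype.LOW_BNF),
    )
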