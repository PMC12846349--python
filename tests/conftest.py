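import numpy as np
import pytest

from charkit import synthetic_data as sd
from charkit.genome_io import GenomeRecord
from charkit.seq_align import ScoringScheme


@pytest.fixture
def unit_scheme() -> ScoringScheme:
    """match=1, mismatch=-1, gap=-1: convenient for hand-derived examples."""
    return ScoringScheme(match=1, mismatch=-1, gap=-1)


@pytest.fixture
def prf_genome_set():
    """20 positive genomes plus 3 scrambled-motif negatives, mildly diverged."""
    spec = sd.PrfGenomeSpec(
        n_genomes=23,
        negatives={3: "scramble_motif", 11: "scramble_motif", 17: "scramble_motif"},
        divergence=0.05,
        seed=42,
    )
    return sd.make_prf_genomes(spec)


@pytest.fixture
def onestep_times() -> np.ndarray:
    return np.arange(0.0, 70.1, 10.0)


@pytest.fixture
def simple_record() -> GenomeRecord:
    return GenomeRecord(id="toy", sequence="ATGAAATAA")
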