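import numpy as np
import pytest

from umicall import aligner, simdata
from umicall.preprocess import FastqRead


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_library():
    return aligner.ReferenceLibrary(
        [aligner.ReferenceRecord(name, seq)
         for name, seq in simdata.TOY_PANEL.items()])


@pytest.fixture(scope="session")
def toy_index(toy_library):
    return aligner.KmerIndex.build(toy_library, k=11)


@pytest.fixture(scope="session")
def small_sim():
    """A small end-to-end dataset: 300 molecules, one 5% variant."""
    cfg = simdata.SimConfig(
        seed=42, molecules_per_locus=100,
        variants=(simdata.Variant("EX1", 62, "A", "G", 0.05),))
    reads, truth = simdata.simulate_dataset(cfg)
    return cfg, reads, truth


def make_read(seq, qual=30, rid="r"):
    return FastqRead(rid, seq, np.full(len(seq), qual, dtype=np.int32))
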