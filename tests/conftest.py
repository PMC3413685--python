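import numpy as np
import pytest

from btdpipe import simdata


@pytest.fixture(scope="session")
def small_transcriptome():
    cfg = simdata.SimConfig(n_genes=10, isoform_probability=0.0, seed=42)
    return simdata.generate_transcriptome(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_read(rng, length=90, q_low=2, q_high=41):
    bases = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24] * 4 + [0.04]))
    quals = [int(q) for q in rng.integers(q_low, q_high, size=length)]
    return bases, quals
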