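import numpy as np
import pytest

import genetexture as gt

BASES = "ACTG"


def random_sequence(rng: np.random.Generator, length: int, rec_id: str = "r") -> gt.NucleotideSequence:
    return gt.NucleotideSequence(
        id=rec_id, bases="".join(rng.choice(list(BASES), size=length))
    )


@pytest.fixture(scope="session")
def benchmark_data():
    """Default 3-class synthetic benchmark, featurized once per session."""
    specs = gt.default_benchmark_specs()
    seqs, labels = gt.generate_sequences(specs, seed=1)
    return gt.assemble_features(seqs, labels)
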