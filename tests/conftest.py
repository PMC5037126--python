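import random

import pytest

from desatnet import synth
from desatnet.seqio import AMINO_ACIDS, DomainRange, ProteinRecord


def random_protein(rng: random.Random, length: int, rec_id: str = "P") -> ProteinRecord:
    seq = "".join(rng.choices(AMINO_ACIDS, k=length))
    return ProteinRecord(id=rec_id, sequence=seq)


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted superfamily fast enough for unit tests:
    2 families x 2 subfamilies x 6 tips of 150 aa, 12 background."""
    config = synth.SynthConfig(
        seed=7,
        n_families=2,
        subfamilies_per_family=2,
        seqs_per_subfamily=6,
        seq_len=150,
        n_background=12,
        frac_fused=0.5,
        frac_characterized=0.34,
        b5_len=60,
    )
    return config, *synth.generate(config)


@pytest.fixture(scope="session")
def small_build(small_corpus):
    config, records, truth = small_corpus
    return synth.build_pipeline(records, length_bounds=(50, 550))


@pytest.fixture(scope="session")
def default_recovery():
    """The full-scale planted-recovery experiment at the study conditions
    (4 families x 3 subfamilies x 25 tips, 50 background, seed 0).
    Session-scoped: several acceptance checks read the same run."""
    return synth.recovery_experiment(synth.SynthConfig(seed=0))
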