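import numpy as np
import pytest

from modpore import errprof, refseq, simdata


@pytest.fixture(scope="session")
def clone():
    """The bundled 1908-nt IVT template transcript."""
    return refseq.bundled_reference()


@pytest.fixture(scope="session")
def random_transcript():
    """Factory for random ACGU transcripts (seeded)."""

    def make(length: int, seed: int = 0, name: str = "rand") -> refseq.ReferenceTranscript:
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), size=length))
        return refseq.ReferenceTranscript(name=name, sequence=seq)

    return make


@pytest.fixture(scope="session")
def canonical_600(clone):
    """A deeply covered canonical-only sample shared across tests."""
    cfg = simdata.preset_config("canonical", n_reads=600, seed=11)
    sample, _ = simdata.simulate_sample(cfg, clone)
    profile = errprof.pileup_sample(sample, clone)
    events = simdata.events_frame(sample, clone)
    return sample, profile, events
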