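import numpy as np
import pytest

import erpdecode as ed
from erpdecode.channels import DECODING_27


@pytest.fixture(scope="session")
def paper_sequence():
    """One full six-block session with the default design."""
    return ed.generate_sequence(ed.SequenceSpec(), seed=7)


@pytest.fixture(scope="session")
def two_block_spec():
    return ed.SequenceSpec(n_blocks=2)


@pytest.fixture(scope="session")
def small_simconfig(two_block_spec):
    """Reduced montage / short session used by the decoding tests."""
    return ed.SimConfig(
        channel_names=tuple(DECODING_27),
        noise_sd=10.0,
        sequence_spec=two_block_spec,
    )


@pytest.fixture(scope="session")
def noiseless_epochs():
    """Noise-free full-montage subject: class means are exact ground truth."""
    cfg = ed.SimConfig(noise_sd=0.0)
    seq = ed.generate_sequence(cfg.sequence_spec, seed=11)
    return ed.simulate_subject_epochs(
        cfg, "noiseless", {"age": "younger", "creativity": "creative"},
        seq=seq, seed=0,
    ), cfg


@pytest.fixture(scope="session")
def null_subject_accuracy(small_simconfig):
    """Decoded accuracy for one subject with no condition difference."""
    seq = ed.generate_sequence(small_simconfig.sequence_spec, seed=21)
    ep = ed.simulate_subject_epochs(
        small_simconfig, "null0", {"age": "younger", "creativity": "creative"},
        seq=seq, seed=22,
    )
    return ed.run_decoding(ep, ed.DecodingConfig(n_iterations=10), seed=23)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
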