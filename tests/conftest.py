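import numpy as np
import pytest

import oriforge as of

MONO = of.ZSpaceConfig(include_mono=True, include_di=False, include_tri=False)

TINY_CCONFIG = of.ClassifierConfig(
    n_blocks=2,
    block=of.BlockConfig(conv_channels=4),
    mlp_hidden=(16, 8),
    input_dim=12,
)


def tiny_tconfig(seed: int = 0, max_epochs: int = 12) -> of.TrainConfig:
    return of.TrainConfig(seed=seed, max_epochs=max_epochs, patience=4, batch_size=32)


@pytest.fixture(scope="session")
def small_dataset():
    """300 origin-like vs genome-like sequences, mono-encoded (12-dim)."""
    seqs, labels, _ = of.make_labeled_dataset(
        of.FixtureSpec(n_pos=150, n_neg=150, length_range=(300, 1200), seed=7)
    )
    X = of.encode_batch(seqs, MONO)
    return seqs, X, labels


@pytest.fixture(scope="session")
def trained_tiny(small_dataset):
    """A small trained model plus its held-out split, shared across tests."""
    _, X, y = small_dataset
    model = of.train((X[:200], y[:200]), (X[200:], y[200:]), TINY_CCONFIG, tiny_tconfig())
    return model, X[200:], y[200:]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
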