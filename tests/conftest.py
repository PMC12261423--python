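import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from dnaclr import (
    Encoder,
    EncoderConfig,
    PairBatch,
    SequenceRecord,
    make_training_pairs,
    sample_species_models,
    tokenize,
)


@pytest.fixture(scope="session")
def tiny_encoder() -> Encoder:
    """2-layer, 16-dim encoder for loss-oracle and identity checks."""
    cfg = EncoderConfig(max_tokens=16, n_layers=2, hidden_dim=16, n_heads=2,
                        dropout_rate=0.1)
    return Encoder(cfg, seed=0)


@pytest.fixture(scope="session")
def small_pairs() -> PairBatch:
    """Fragment pairs from 4 strongly divergent synthetic species."""
    models = sample_species_models(4, order=1, concentration=0.15,
                                   genome_length=8_000, seed=11)
    return make_training_pairs(models, pairs_per_species=12,
                               fragment_length=200, seed=12)


def random_records(n: int, length: int, seed: int) -> list[SequenceRecord]:
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(
            seq_id=f"r{i}",
            sequence="".join(rng.choice(list("ACGT"), size=length)),
        )
        for i in range(n)
    ]


@pytest.fixture
def random_batch(tiny_encoder):
    recs = random_records(6, 12, seed=3)
    return tokenize(recs, tiny_encoder.config.max_tokens)
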