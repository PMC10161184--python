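import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from semdrift import (
    EmbeddingModel,
    TrainingConfig,
    YearEnsemble,
    align_all,
    train_year_ensemble,
)
from semdrift.synthetic import SyntheticSpec, generate_corpus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_random_model(
    rng: np.random.Generator,
    n_tokens: int = 30,
    dim: int = 8,
    year: int = 2000,
    replicate: int = 0,
    prefix: str = "t",
) -> EmbeddingModel:
    """A synthetic embedding model with Gaussian random vectors."""
    vocab = [f"{prefix}{i:04d}" for i in range(n_tokens)]
    vectors = rng.normal(size=(n_tokens, dim)).astype(np.float32)
    counts = {t: 10 + i for i, t in enumerate(vocab)}
    return EmbeddingModel(
        year=year,
        replicate=replicate,
        vocab=vocab,
        vectors=vectors,
        token_counts=counts,
        total_tokens=sum(counts.values()) + 50,
    )


def make_random_ensemble(
    rng: np.random.Generator, year: int, replicates: int = 3, **kw
) -> YearEnsemble:
    models = [
        make_random_model(rng, year=year, replicate=r, **kw)
        for r in range(replicates)
    ]
    return YearEnsemble(year=year, models=models)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def micro_slices():
    """A small 3-year null corpus shared by training-dependent tests."""
    slices = {}
    for y in (2000, 2001, 2002):
        spec = SyntheticSpec(
            vocab_size=120,
            years=(y, y + 1),
            sentences_per_year=800,
            sentence_length=6,
            seed=50 + y,
            n_topics=6,
        )
        s, _ = generate_corpus(spec)
        slices[y] = s[y]
    return slices


@pytest.fixture(scope="session")
def micro_cfg():
    return TrainingConfig(
        dim=16, epochs=2, min_count=5, window=8, replicates=3, base_seed=9
    )


@pytest.fixture(scope="session")
def micro_ensembles(micro_slices, micro_cfg):
    return {
        y: train_year_ensemble(s, micro_cfg) for y, s in micro_slices.items()
    }


@pytest.fixture(scope="session")
def micro_aligned(micro_ensembles):
    return align_all(micro_ensembles, anchor=(2002, 0))
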