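"""Replicate CBOW embedding ensembles per year.

For every year's corpus slice, ``R`` continuous-bag-of-words word2vec models
are trained that differ only in their random seed (``base_seed + replicate``).
Training stochasticity makes any single embedding model unstable; the
replicate ensemble is what lets the change statistic separate genuine
semantic drift from run-to-run noise.

Training is single-threaded and deterministic: retraining a replicate with
the same seed reproduces identical vectors.  Models round-trip through the
word2vec text format with a TSV token-count sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._cbow import _train_epochs
from .preprocessing import CorpusSlice

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "EmbeddingModel",
    "YearEnsemble",
    "train_year_ensemble",
    "relative_frequency",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    """CBOW hyperparameters.

    Defaults mirror the reference analysis: 300-dimensional vectors, 10
    epochs, minimum token frequency 5, context window 16, ten replicate
    models per year.  ``negative``/``subsample``/learning-rate values are
    standard word2vec defaults.
    """

    dim: int = 300
    epochs: int = 10
    min_count: int = 5
    window: int = 16
    replicates: int = 10
    base_seed: int = 42
    negative: int = 5
    subsample: float = 1e-3
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (intra-year distance needs pairs)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.window < 1 or self.epochs < 1:
            raise ValueError("window and epochs must be >= 1")


@dataclass
class EmbeddingModel:
    """One trained replicate for one year.

    ``vectors`` row ``i`` is the vector of ``vocab[i]``.  ``token_counts``
    covers the vocabulary (tokens at or above ``min_count``);
    ``total_tokens`` is the full corpus size including below-cutoff mass, so
    relative frequencies are corpus-size-normalized.
    """

    year: int
    replicate: int
    vocab: list[str]
    vectors: np.ndarray
    token_counts: dict[str, int]
    total_tokens: int
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.vocab) != self.vectors.shape[0]:
            raise ValueError("vocab / vectors row mismatch")
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]

    def index(self, token: str) -> int:
        return self._index[token]

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy of the vector matrix."""
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        return self.vectors / norms


@dataclass
class YearEnsemble:
    year: int
    models: list[EmbeddingModel]

    def __post_init__(self) -> None:
        if any(m.year != self.year for m in self.models):
            raise ValueError("ensemble members must share the year")
        dims = {m.dim for m in self.models}
        if len(dims) > 1:
            raise ValueError(f"ensemble members have mixed dims {dims}")

    @property
    def replicates(self) -> int:
        return len(self.models)

    @property
    def vocab(self) -> list[str]:
        return self.models[0].vocab


def _build_vocab(
    slice_: CorpusSlice, min_count: int
) -> tuple[list[str], dict[str, int]]:
    # deterministic order: count descending, then lexicographic
    items = [(t, c) for t, c in slice_.token_counts.items() if c >= min_count]
    items.sort(key=lambda tc: (-tc[1], tc[0]))
    vocab = [t for t, _ in items]
    return vocab, {t: i for i, t in enumerate(vocab)}


def train_year_ensemble(slice_: CorpusSlice, cfg: TrainingConfig) -> YearEnsemble:
    """Train ``cfg.replicates`` CBOW models on one year's sentences.

    Replicate ``r`` uses seed ``cfg.base_seed + r`` for both vector
    initialization and the sampling stream, so ensembles are reproducible
    and replicates share an identical vocabulary.
    """
    vocab, index = _build_vocab(slice_, cfg.min_count)
    if not vocab:
        raise ValueError(
            f"year {slice_.year}: vocabulary empty after min_count={cfg.min_count} filter"
        )
    counts = np.array([slice_.token_counts[t] for t in vocab], dtype=np.int64)

    # encode sentences, dropping below-cutoff tokens (word2vec convention)
    ids: list[int] = []
    offsets = [0]
    for sent in slice_.sentences:
        n0 = len(ids)
        ids.extend(index[t] for t in sent if t in index)
        if len(ids) > n0:
            offsets.append(len(ids))
    tokens = np.array(ids, dtype=np.int32)
    offs = np.array(offsets, dtype=np.int64)
    if tokens.size == 0:
        raise ValueError(f"year {slice_.year}: no trainable sentences after vocab filter")

    # subsampling keep probabilities (word2vec.c formula)
    total_in_vocab = counts.sum()
    keep = np.ones(len(vocab), dtype=np.float64)
    if cfg.subsample > 0:
        ratio = cfg.subsample * total_in_vocab / counts
        keep = np.minimum(1.0, np.sqrt(ratio) + ratio)

    # negative-sampling distribution: unigram^0.75
    pow_counts = counts.astype(np.float64) ** 0.75
    neg_cum = np.cumsum(pow_counts)
    neg_cum /= neg_cum[-1]

    models = []
    for r in range(cfg.replicates):
        seed = cfg.base_seed + r
        rng = np.random.default_rng(seed)
        syn0 = (
            (rng.random((len(vocab), cfg.dim), dtype=np.float32) - 0.5) / cfg.dim
        ).astype(np.float32)
        syn1 = np.zeros((len(vocab), cfg.dim), dtype=np.float32)
        _train_epochs(
            tokens,
            offs,
            syn0,
            syn1,
            keep,
            neg_cum,
            cfg.window,
            cfg.negative,
            cfg.epochs,
            cfg.alpha,
            cfg.min_alpha,
            seed,
        )
        models.append(
            EmbeddingModel(
                year=slice_.year,
                replicate=r,
                vocab=list(vocab),
                vectors=syn0,
                token_counts={t: int(c) for t, c in zip(vocab, counts)},
                total_tokens=slice_.total_tokens,
            )
        )
    return YearEnsemble(year=slice_.year, models=models)


def relative_frequency(model_or_slice, token: str) -> float | None:
    """Corpus-size-normalized token frequency: count / total_tokens.

    Returns ``None`` (a distinguished missing value, not zero) for tokens
    absent from the counts.
    """
    counts = model_or_slice.token_counts
    if token not in counts:
        return None
    total = model_or_slice.total_tokens
    return counts[token] / total if total else None


def save_model(model: EmbeddingModel, path: str | Path) -> Path:
    """Write vectors in word2vec text format plus a ``.counts.tsv`` sidecar.

    Format: header line ``V dim``, then one ``token v1 ... v_dim`` line per
    vocabulary entry.  Tokens containing whitespace cannot be represented and
    are rejected.  The sidecar stores (token, count) rows and the corpus
    total under the ``__total_tokens__`` key.
    """
    path = Path(path)
    for t in model.vocab:
        if any(ch.isspace() for ch in t):
            raise ValueError(f"token {t!r} contains whitespace; not representable")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vocab)} {model.dim}\n")
        for t, row in zip(model.vocab, model.vectors):
            fh.write(t + " " + " ".join(f"{x:.8e}" for x in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".counts.tsv")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write(f"__total_tokens__\t{model.total_tokens}\n")
        for t in model.vocab:
            fh.write(f"{t}\t{model.token_counts[t]}\n")
    return path


def load_model(
    path: str | Path, year: int | None = None, replicate: int = 0
) -> EmbeddingModel:
    """Read a word2vec text-format model written by :func:`save_model`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: malformed word2vec header {header!r}")
        try:
            n, dim = int(header[0]), int(header[1])
        except ValueError:
            raise ValueError(f"{path}:1: malformed word2vec header {header!r}")
        vocab: list[str] = []
        vectors = np.empty((n, dim), dtype=np.float32)
        for i in range(n):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}:{i + 2}: expected {n} rows, file truncated")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{i + 2}: expected {dim + 1} fields, got {len(parts)}"
                )
            vocab.append(parts[0])
            vectors[i] = np.array(parts[1:], dtype=np.float32)

    token_counts: dict[str, int] = {}
    total = 0
    sidecar = path.with_suffix(path.suffix + ".counts.tsv")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            for line in fh:
                tok, cnt = line.rstrip("\n").split("\t")
                if tok == "__total_tokens__":
                    total = int(cnt)
                else:
                    token_counts[tok] = int(cnt)
    if year is None:
        # conventional file name: <year>_<replicate>.w2v
        stem = path.stem.split("_")
        year = int(stem[0])
        if len(stem) > 1 and stem[1].isdigit():
            replicate = int(stem[1])
    return EmbeddingModel(
        year=year,
        replicate=replicate,
        vocab=vocab,
        vectors=vectors,
        token_counts=token_counts,
        total_tokens=total or sum(token_counts.values()),
    )
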