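"""Synthetic year-binned corpora with planted semantic shifts.

Real semantic-change analyses have no ground truth, so the pipeline is
validated on corpora where the truth is planted by construction.  Background
sentences come from a topic-mixture unigram process that is identical in
every year: each background token belongs to one topic, a sentence picks a
topic and draws most of its tokens from that topic's members.  CBOW encodes
context distributions, so topics give every token a stable, learnable
neighborhood.

A planted target token appears in its own sentences with a per-sentence
occurrence probability.  Before its change year the target's context tokens
are drawn from ``context_set_a``; from the change year onward each context
token comes from ``context_set_b`` with probability ``mixing_after`` (else
still from A).  The mixture weight is therefore the effect size of the
semantic shift, and the occurrence probabilities control the frequency
component independently — the two ingredients of the change metric can be
stressed in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .changepoint import ChangepointCall
from .preprocessing import CorpusSlice

__all__ = [
    "TargetShift",
    "SyntheticSpec",
    "generate_corpus",
    "evaluate_calls",
    "EvalResult",
    "reference_spec",
    "null_spec",
]


@dataclass(frozen=True)
class TargetShift:
    """One planted semantic shift with optional frequency change."""

    token: str
    change_year: int
    context_set_a: tuple[str, ...]
    context_set_b: tuple[str, ...]
    mixing_after: float = 1.0
    freq_before: float = 0.01
    freq_after: float = 0.01

    def __post_init__(self) -> None:
        if set(self.context_set_a) & set(self.context_set_b):
            raise ValueError(f"{self.token}: context sets must be disjoint")
        if not (0.0 < self.mixing_after <= 1.0):
            raise ValueError("mixing_after must lie in (0, 1]")
        if not (0.0 < self.freq_before <= 1.0 and 0.0 < self.freq_after <= 1.0):
            raise ValueError("occurrence probabilities must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    vocab_size: int = 500
    years: tuple[int, int] = (2000, 2007)  # inclusive
    sentences_per_year: int = 20_000
    sentence_length: int = 8
    targets: tuple[TargetShift, ...] = ()
    seed: int = 0
    n_topics: int | None = None
    topic_purity: float = 0.8

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError("year range must span at least 2 years")
        for t in self.targets:
            if not (y0 < t.change_year < y1):
                raise ValueError(
                    f"{t.token}: change_year {t.change_year} must lie strictly "
                    f"inside the year range {self.years}"
                )
        if self.vocab_size < 10 or self.sentence_length < 3:
            raise ValueError("vocab_size >= 10 and sentence_length >= 3 required")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _background_vocab(vocab_size: int) -> list[str]:
    width = len(str(vocab_size - 1))
    return [f"w{i:0{width}d}" for i in range(vocab_size)]


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[dict[int, CorpusSlice], dict[str, TargetShift]]:
    """Generate per-year corpus slices plus the planted ground truth.

    Fully deterministic given ``spec.seed``: the same spec yields
    byte-identical slices.  Target tokens may not appear inside any context
    set (that would blur the planted contexts).
    """
    vocab = _background_vocab(spec.vocab_size)
    target_names = {t.token for t in spec.targets}
    for t in spec.targets:
        ctx = set(t.context_set_a) | set(t.context_set_b)
        if ctx & target_names:
            raise ValueError(
                f"{t.token}: context sets collide with target tokens {ctx & target_names}"
            )
    if target_names & set(vocab):
        raise ValueError("target tokens collide with background vocabulary")

    n_topics = spec.n_topics or max(1, spec.vocab_size // 25)
    topic_of = np.arange(spec.vocab_size) % n_topics
    topic_members = [np.flatnonzero(topic_of == k) for k in range(n_topics)]
    vocab_arr = np.array(vocab)

    rng = np.random.default_rng(spec.seed)
    slices: dict[int, CorpusSlice] = {}
    L = spec.sentence_length
    for year in spec.year_list:
        n = spec.sentences_per_year
        topics = rng.integers(0, n_topics, size=n)
        # vectorized background sampling: per-token coin for topic vs global
        from_topic = rng.random((n, L)) < spec.topic_purity
        global_ids = rng.integers(0, spec.vocab_size, size=(n, L))
        ids = np.empty((n, L), dtype=np.int64)
        for k in range(n_topics):
            rows = topics == k
            m = int(rows.sum())
            if m == 0:
                continue
            members = topic_members[k]
            ids[rows] = members[rng.integers(0, len(members), size=(m, L))]
        ids[~from_topic] = global_ids[~from_topic]
        sentences = vocab_arr[ids].tolist()

        for t in spec.targets:
            p = t.freq_before if year < t.change_year else t.freq_after
            n_occ = int(rng.binomial(spec.sentences_per_year, p))
            if n_occ == 0:
                continue
            ctx_a = np.array(t.context_set_a)
            ctx_b = np.array(t.context_set_b)
            use_b = (
                (rng.random((n_occ, L - 1)) < t.mixing_after)
                if year >= t.change_year
                else np.zeros((n_occ, L - 1), dtype=bool)
            )
            ctx = np.where(
                use_b,
                ctx_b[rng.integers(0, len(ctx_b), size=(n_occ, L - 1))],
                ctx_a[rng.integers(0, len(ctx_a), size=(n_occ, L - 1))],
            )
            pos = rng.integers(0, L, size=n_occ)
            for i in range(n_occ):
                sent = ctx[i].tolist()
                sent.insert(int(pos[i]), t.token)
                sentences.append(sent)

        s = CorpusSlice(year=year)
        s.add_sentences(sentences)
        slices[year] = s
    truth = {t.token: t for t in spec.targets}
    return slices, truth


@dataclass(frozen=True)
class EvalResult:
    precision: float | None  # None when there are no calls at all
    recall: float
    localization_error: float | None  # mean |transitions off|, recovered targets
    n_true_positive_calls: int
    n_false_positive_calls: int
    n_targets_recovered: int
    n_targets: int


def evaluate_calls(
    calls: Sequence[ChangepointCall],
    ground_truth: Mapping[str, TargetShift],
    tolerance_transitions: int = 1,
) -> EvalResult:
    """Score changepoint calls against planted shifts.

    A planted shift at change year c corresponds to the transition
    (c−1, c); a call on that token within ``tolerance_transitions`` of it is
    a true positive.  Calls on stable (unplanted) tokens, or far from the
    planted year, are false positives.
    """
    tp = fp = 0
    best_err: dict[str, int] = {}
    for call in calls:
        shift = ground_truth.get(call.token)
        if shift is None:
            fp += 1
            continue
        err = abs(call.year_pair[1] - shift.change_year)
        if err <= tolerance_transitions:
            tp += 1
            if call.token not in best_err or err < best_err[call.token]:
                best_err[call.token] = err
        else:
            fp += 1
    n_targets = len(ground_truth)
    recovered = len(best_err)
    return EvalResult(
        precision=(tp / (tp + fp)) if (tp + fp) else None,
        recall=recovered / n_targets if n_targets else float("nan"),
        localization_error=(
            float(np.mean(list(best_err.values()))) if best_err else None
        ),
        n_true_positive_calls=tp,
        n_false_positive_calls=fp,
        n_targets_recovered=recovered,
        n_targets=n_targets,
    )


def reference_spec(seed: int = 0) -> SyntheticSpec:
    """The canonical recovery benchmark: 500 background tokens over 8 years,
    20,000 sentences/year, one target with a full context shift (mixing 1.0)
    and a 3x frequency rise at the midpoint year."""
    vocab = _background_vocab(500)
    n_topics = 20
    topic0 = tuple(vocab[i] for i in range(0, 500) if i % n_topics == 0)[:15]
    topic1 = tuple(vocab[i] for i in range(0, 500) if i % n_topics == 7)[:15]
    target = TargetShift(
        token="target_shift",
        change_year=2004,
        context_set_a=topic0,
        context_set_b=topic1,
        mixing_after=1.0,
        freq_before=0.01,
        freq_after=0.03,
    )
    return SyntheticSpec(
        vocab_size=500,
        years=(2000, 2007),
        sentences_per_year=20_000,
        sentence_length=8,
        targets=(target,),
        seed=seed,
        n_topics=n_topics,
    )


def null_spec(
    seed: int = 0, sentences_per_year: int = 5_000, years: tuple[int, int] = (2000, 2007)
) -> SyntheticSpec:
    """A no-shift corpus: all years statistically exchangeable."""
    return SyntheticSpec(
        vocab_size=500,
        years=years,
        sentences_per_year=sentences_per_year,
        sentence_length=8,
        targets=(),
        seed=seed,
        n_topics=20,
    )
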