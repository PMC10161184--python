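"""Numba kernels for CBOW training with negative sampling.

Single-threaded, fully deterministic given the seed: the update order follows
the corpus order and an internal xorshift64* generator drives window
shrinking, frequency subsampling, and negative-sample draws.  Conventions
follow the original word2vec.c CBOW path: the hidden state is the mean of the
context vectors, negatives are drawn from the unigram^0.75 table, and the
learning rate decays linearly over the total number of training words.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True)
def _rng_step(state):
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state, state * _MULT


@njit(cache=True)
def _rng_uniform(state):
    state, out = _rng_step(state)
    return state, (out >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _train_epochs(
    tokens,       # int32[:] concatenated token ids
    offsets,      # int64[:] sentence boundaries, len n_sent+1
    syn0,         # float32[V, d] input vectors (updated in place)
    syn1,         # float32[V, d] output vectors (updated in place)
    keep_prob,    # float64[V] subsampling keep probability
    neg_cum,      # float64[V] cumulative negative-sampling distribution
    window,
    negative,
    epochs,
    alpha0,
    min_alpha,
    seed,
):
    dim = syn0.shape[1]
    n_sent = offsets.shape[0] - 1
    total_words = np.float64(epochs) * np.float64(tokens.shape[0]) + 1.0
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    state, _ = _rng_step(state)  # warm up

    max_len = 0
    for s in range(n_sent):
        ln = offsets[s + 1] - offsets[s]
        if ln > max_len:
            max_len = int(ln)
    kept = np.empty(max_len, dtype=np.int32)
    h = np.empty(dim, dtype=np.float32)
    neu1e = np.empty(dim, dtype=np.float32)

    word_count = 0.0
    for _epoch in range(epochs):
        for s in range(n_sent):
            start, stop = offsets[s], offsets[s + 1]
            word_count += stop - start
            alpha = alpha0 * (1.0 - word_count / total_words)
            if alpha < min_alpha:
                alpha = min_alpha
            # frequency subsampling
            n_kept = 0
            for i in range(start, stop):
                w = tokens[i]
                if keep_prob[w] >= 1.0:
                    kept[n_kept] = w
                    n_kept += 1
                else:
                    state, u = _rng_uniform(state)
                    if u < keep_prob[w]:
                        kept[n_kept] = w
                        n_kept += 1
            for i in range(n_kept):
                center = kept[i]
                state, out = _rng_step(state)
                b = int(out % np.uint64(window))
                lo = i - window + b
                hi = i + window - b
                if lo < 0:
                    lo = 0
                if hi >= n_kept:
                    hi = n_kept - 1
                cw = 0
                for k in range(dim):
                    h[k] = 0.0
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    c = kept[j]
                    for k in range(dim):
                        h[k] += syn0[c, k]
                    cw += 1
                if cw == 0:
                    continue
                inv = np.float32(1.0 / cw)
                for k in range(dim):
                    h[k] *= inv
                    neu1e[k] = 0.0
                for neg in range(negative + 1):
                    if neg == 0:
                        target = center
                        label = np.float32(1.0)
                    else:
                        state, u = _rng_uniform(state)
                        target = np.int32(np.searchsorted(neg_cum, u))
                        if target == center:
                            continue
                        label = np.float32(0.0)
                    f = np.float32(0.0)
                    for k in range(dim):
                        f += h[k] * syn1[target, k]
                    if f > 8.0:
                        sig = np.float32(1.0)
                    elif f < -8.0:
                        sig = np.float32(0.0)
                    else:
                        sig = np.float32(1.0 / (1.0 + np.exp(-f)))
                    g = np.float32((label - sig) * alpha)
                    for k in range(dim):
                        neu1e[k] += g * syn1[target, k]
                    for k in range(dim):
                        syn1[target, k] += g * h[k]
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    c = kept[j]
                    for k in range(dim):
                        syn0[c, k] += neu1e[k]
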