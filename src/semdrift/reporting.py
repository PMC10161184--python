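"""Nearest-neighbor tables, frequency series, and stability diagnostics.

Neighbor distances are averaged across the replicate ensemble rather than
taken from a single model, consistent with the multi-model design of the
pipeline; ranks are invariant under alignment because rotations preserve
cosine distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import YearEnsemble
from .metrics import intra_year_distance, cosine_distance

__all__ = [
    "NeighborTable",
    "nearest_neighbors",
    "frequency_series",
    "neighbor_overlap",
    "stability_report",
]


@dataclass(frozen=True)
class NeighborTable:
    token: str
    year: int
    neighbors: tuple[tuple[str, float], ...]  # ascending mean distance


def nearest_neighbors(ens: YearEnsemble, token: str, k: int = 15) -> NeighborTable:
    """Top-k neighbors by replicate-averaged cosine distance.

    Ties broken lexicographically; the query token is excluded.  Unknown
    tokens raise (exact match only).
    """
    if token not in ens.models[0]:
        raise KeyError(f"token {token!r} not in year {ens.year} vocabulary")
    vocab = np.array(ens.vocab)
    dists = np.zeros(len(vocab))
    for m in ens.models:
        units = m.unit_vectors()
        q = units[m.index(token)]
        dists += np.clip(1.0 - units @ q, 0.0, 2.0)
    dists /= len(ens.models)
    order = np.lexsort((vocab, dists))
    order = order[vocab[order] != token][:k]
    return NeighborTable(
        token=token,
        year=ens.year,
        neighbors=tuple((str(vocab[i]), float(dists[i])) for i in order),
    )


def frequency_series(
    slices: Mapping[int, object], token: str, normalized: bool = True
) -> dict[int, float]:
    """Per-year usage of a token: raw count or corpus-size-adjusted fraction.

    Years where the token is absent report zero (a zero count is meaningful
    here, unlike in ratio computations).
    """
    out: dict[int, float] = {}
    for year in sorted(slices):
        s = slices[year]
        count = s.token_counts.get(token, 0)
        if normalized:
            total = s.total_tokens
            out[year] = count / total if total else 0.0
        else:
            out[year] = float(count)
    return out


def neighbor_overlap(
    table_a: NeighborTable, table_b: NeighborTable
) -> tuple[set[str], set[str], set[str]]:
    """Partition two neighbor tables' tokens into (shared, only_a, only_b)."""
    if table_a.token != table_b.token:
        raise ValueError(
            f"mismatched query tokens {table_a.token!r} vs {table_b.token!r}"
        )
    a = {t for t, _ in table_a.neighbors}
    b = {t for t, _ in table_b.neighbors}
    return a & b, a - b, b - a


def stability_report(
    aligned: Mapping[int, YearEnsemble],
    ref_year: int,
    tokens: Sequence[str] | None = None,
    single_replicate: int = 0,
) -> pd.DataFrame:
    """Single-model vs multi-model distances of each year to a reference year.

    For every token present in all years, compute (a) the single-model cosine
    distance between one fixed replicate's vectors in year y and in the
    reference year, and (b) the integrated multi-model statistic: the mean
    inter-year distance over all replicate pairs divided by the mean of the
    two years' intra-year distances.  Years trained on smaller corpora show
    inflated, more dispersed single-model distances; the integrated statistic
    corrects for that instability.
    """
    years = sorted(aligned)
    if ref_year not in aligned:
        raise ValueError(f"reference year {ref_year} not in ensembles")
    if tokens is None:
        common = set(aligned[years[0]].vocab)
        for y in years[1:]:
            common &= set(aligned[y].vocab)
        tokens = sorted(common)

    ref = aligned[ref_year]
    ref_single = ref.models[single_replicate]
    intra_ref = {t: intra_year_distance(ref, t) for t in tokens}

    rows = []
    for y in years:
        if y == ref_year:
            continue
        ens = aligned[y]
        single = ens.models[single_replicate]
        for t in tokens:
            d_single = cosine_distance(single.vector(t), ref_single.vector(t))
            inter = float(
                np.mean(
                    [
                        cosine_distance(a.vector(t), b.vector(t))
                        for a in ens.models
                        for b in ref.models
                    ]
                )
            )
            intra = 0.5 * (intra_year_distance(ens, t) + intra_ref[t])
            rows.append(
                {
                    "year": y,
                    "token": t,
                    "single_model": d_single,
                    "multi_model": inter / max(intra, 1e-8),
                }
            )
    return pd.DataFrame(rows, columns=["year", "token", "single_model", "multi_model"])
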