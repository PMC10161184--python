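"""Per-token change time series from distances and frequency ratios.

For each consecutive year pair (y, y+1) and each token present in both years,
three ingredients are combined:

* **intra-year distance** — mean cosine distance between the token's vectors
  across all R(R−1)/2 unordered replicate pairs within one year; a direct
  measure of training instability for that token.
* **inter-year distance** — mean cosine distance over the full R² Cartesian
  product of models from the two years; the raw change signal.
* **frequency ratio** — relative (corpus-size-normalized) frequency in the
  more recent year over the previous year.

The distance ratio inter / mean(intra_y, intra_{y+1}) penalizes tokens whose
replicates disagree even within a year and rewards stable tokens; a perfectly
stable token with unchanged frequency sits at a baseline metric of 1.  The
frequency ratio is folded in multiplicatively — by default symmetrized as
max(f, 1/f) so that usage drops also raise the signal; the directional
product is available as a configuration switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedEnsemble
from .embedding import YearEnsemble, relative_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceStats",
    "SeriesPoint",
    "TokenTimeSeries",
    "cosine_distance",
    "intra_year_distance",
    "inter_year_distance",
    "frequency_ratio",
    "change_metric",
    "build_series",
    "series_to_frame",
    "frame_to_series",
]

EPS = 1e-8


@dataclass(frozen=True)
class DistanceStats:
    """Distance summary for one token over one consecutive-year transition."""

    token: str
    year_pair: tuple[int, int]
    intra_mean_prev: float
    intra_mean_next: float
    inter_mean: float
    n_intra_pairs: int
    n_inter_pairs: int


@dataclass(frozen=True)
class SeriesPoint:
    year_pair: tuple[int, int]
    intra_prev: float
    intra_next: float
    inter: float
    distance_ratio: float
    freq_ratio: float
    metric: float


@dataclass
class TokenTimeSeries:
    """Ordered change-metric points for one token.

    ``year_pairs`` may be gappy when the token drops out of some years'
    vocabularies; downstream changepoint detection must reset across gaps.
    """

    token: str
    points: list[SeriesPoint]

    def __post_init__(self) -> None:
        pairs = [p.year_pair for p in self.points]
        if any(b <= a for a, b in zip(pairs, pairs[1:])):
            raise ValueError(f"{self.token}: year pairs not strictly increasing")

    @property
    def metrics(self) -> np.ndarray:
        return np.array([p.metric for p in self.points])


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − cos(u, v), clipped to [0, 2].

    0 means the vectors point the same way; 2 means they are antipodal.
    Zero-norm inputs have no direction and are rejected.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for zero-norm vectors")
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 2.0))


def intra_year_distance(ens: YearEnsemble, token: str) -> float:
    """Mean cosine distance of a token to itself across replicate pairs.

    Replicates of one year share a vocabulary, so a missing token signals
    corruption and raises.
    """
    vecs = [m.vector(token) for m in ens.models]
    return float(
        np.mean([cosine_distance(a, b) for a, b in combinations(vecs, 2)])
    )


def inter_year_distance(
    prev: YearEnsemble, next_: YearEnsemble, token: str
) -> float:
    """Mean cosine distance over the R² cross-year model pairs."""
    if not all(token in m for m in prev.models) or not all(
        token in m for m in next_.models
    ):
        raise KeyError(f"token {token!r} absent from one year's vocabulary")
    dists = [
        cosine_distance(a.vector(token), b.vector(token))
        for a in prev.models
        for b in next_.models
    ]
    return float(np.mean(dists))


def frequency_ratio(prev_slice, next_slice, token: str) -> float | None:
    """Relative frequency in the later year over the earlier year.

    ``None`` when the token is uncounted (or zero) in the earlier year — the
    point is omitted from the series rather than forced to a sentinel.
    """
    f_prev = relative_frequency(prev_slice, token)
    f_next = relative_frequency(next_slice, token)
    if f_prev is None or f_next is None or f_prev == 0.0:
        return None
    return f_next / f_prev


def change_metric(
    stats: DistanceStats,
    freq_ratio: float,
    combiner: str = "symmetric",
    eps: float = EPS,
) -> float:
    """Combine distance ratio and frequency ratio into the change metric.

    distance_ratio = inter / max(mean(intra_prev, intra_next), eps);
    metric = distance_ratio × max(f, 1/f)   ("symmetric", default)
           = distance_ratio × f             ("directional")
    """
    intra = 0.5 * (stats.intra_mean_prev + stats.intra_mean_next)
    if intra < eps:
        logger.warning(
            "%s %s: vanishing intra-year distance; eps floor applied",
            stats.token,
            stats.year_pair,
        )
        intra = eps
    distance_ratio = stats.inter_mean / intra
    if combiner == "symmetric":
        f = max(freq_ratio, 1.0 / freq_ratio)
    elif combiner == "directional":
        f = freq_ratio
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return distance_ratio * f


def _unit_matrices(ens: YearEnsemble) -> list[np.ndarray]:
    return [m.unit_vectors() for m in ens.models]


def _intra_means(units: list[np.ndarray]) -> np.ndarray:
    """Vectorized per-token intra-year mean distance over replicate pairs."""
    sims = [
        np.einsum("ij,ij->i", a, b)
        for a, b in combinations(units, 2)
    ]
    return np.clip(1.0 - np.mean(sims, axis=0), 0.0, 2.0)


def build_series(
    aligned: Mapping[int, AlignedEnsemble],
    slices: Mapping[int, object],
    tokens: Iterable[str] | None = None,
    combiner: str = "symmetric",
) -> dict[str, TokenTimeSeries]:
    """Build every token's change time series over consecutive year pairs.

    ``slices`` supplies frequencies (anything with ``token_counts`` /
    ``total_tokens``, i.e. a CorpusSlice).  A point is emitted for a year
    pair only when the token is in both years' vocabularies and has nonzero
    frequency in the earlier year; tokens can therefore have gappy series.
    Output ordering is deterministic (lexicographic tokens, ordered points).
    """
    years = sorted(aligned)
    if len(years) < 2:
        raise ValueError("need at least 2 years to build a series")
    wanted = set(tokens) if tokens is not None else None

    units = {y: _unit_matrices(aligned[y]) for y in years}
    intra = {
        y: dict(zip(aligned[y].vocab, _intra_means(units[y]))) for y in years
    }
    vocab_index = {
        y: {t: i for i, t in enumerate(aligned[y].vocab)} for y in years
    }

    out: dict[str, list[SeriesPoint]] = {}
    for y0, y1 in zip(years, years[1:]):
        if y1 != y0 + 1:
            logger.info("non-consecutive years %d -> %d; series will gap", y0, y1)
        idx0, idx1 = vocab_index[y0], vocab_index[y1]
        shared = sorted(set(idx0) & set(idx1))
        if wanted is not None:
            shared = [t for t in shared if t in wanted]
        if not shared:
            continue
        rows0 = np.array([idx0[t] for t in shared])
        rows1 = np.array([idx1[t] for t in shared])
        sims = [
            np.einsum("ij,ij->i", a[rows0], b[rows1])
            for a in units[y0]
            for b in units[y1]
        ]
        inter = np.clip(1.0 - np.mean(sims, axis=0), 0.0, 2.0)
        n_inter = len(units[y0]) * len(units[y1])
        r = len(units[y0])
        n_intra = r * (r - 1) // 2
        for t, d_inter in zip(shared, inter):
            f = frequency_ratio(slices[y0], slices[y1], t)
            if f is None:
                logger.debug("%s (%d,%d): no frequency; point omitted", t, y0, y1)
                continue
            stats = DistanceStats(
                token=t,
                year_pair=(y0, y1),
                intra_mean_prev=float(intra[y0][t]),
                intra_mean_next=float(intra[y1][t]),
                inter_mean=float(d_inter),
                n_intra_pairs=n_intra,
                n_inter_pairs=n_inter,
            )
            m = change_metric(stats, f, combiner=combiner)
            ratio = m / (max(f, 1.0 / f) if combiner == "symmetric" else f)
            out.setdefault(t, []).append(
                SeriesPoint(
                    year_pair=(y0, y1),
                    intra_prev=stats.intra_mean_prev,
                    intra_next=stats.intra_mean_next,
                    inter=stats.inter_mean,
                    distance_ratio=ratio,
                    freq_ratio=f,
                    metric=m,
                )
            )
    return {
        t: TokenTimeSeries(token=t, points=pts) for t, pts in sorted(out.items())
    }


def series_to_frame(series: Mapping[str, TokenTimeSeries]) -> pd.DataFrame:
    """Flatten a series map to the TSV-ready table."""
    rows = [
        {
            "token": s.token,
            "year_prev": p.year_pair[0],
            "year_next": p.year_pair[1],
            "intra_prev": p.intra_prev,
            "intra_next": p.intra_next,
            "inter": p.inter,
            "distance_ratio": p.distance_ratio,
            "freq_ratio": p.freq_ratio,
            "metric": p.metric,
        }
        for s in series.values()
        for p in s.points
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "token",
            "year_prev",
            "year_next",
            "intra_prev",
            "intra_next",
            "inter",
            "distance_ratio",
            "freq_ratio",
            "metric",
        ],
    )


def frame_to_series(df: pd.DataFrame) -> dict[str, TokenTimeSeries]:
    """Inverse of :func:`series_to_frame` (used by the CLI detect step)."""
    out: dict[str, TokenTimeSeries] = {}
    for token, grp in df.groupby("token", sort=True):
        grp = grp.sort_values("year_prev")
        pts = [
            SeriesPoint(
                year_pair=(int(r.year_prev), int(r.year_next)),
                intra_prev=float(r.intra_prev),
                intra_next=float(r.intra_next),
                inter=float(r.inter),
                distance_ratio=float(r.distance_ratio),
                freq_ratio=float(r.freq_ratio),
                metric=float(r.metric),
            )
            for r in grp.itertuples()
        ]
        out[str(token)] = TokenTimeSeries(token=str(token), points=pts)
    return out
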