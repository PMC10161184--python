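"""CUSUM changepoint calling on per-token change-metric series.

The detector keeps two one-sided cumulative sums of the differences between
consecutive timepoints,

    gp_t = max(0, gp_{t-1} + (x_t − x_{t-1}) − drift)
    gn_t = max(0, gn_{t-1} − (x_t − x_{t-1}) − drift)

and fires an alarm (rise / fall) whenever an accumulator exceeds the
threshold; both accumulators reset after an alarm.  The default threshold is
the 99th percentile of every metric value pooled across all tokens and
transitions — a single global cutoff rather than a per-token one.  Gappy
series (tokens absent from some years) reset the accumulators at each gap so
differences are never taken across missing years.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .metrics import TokenTimeSeries

__all__ = [
    "CusumConfig",
    "ChangepointCall",
    "DetectionSummary",
    "global_threshold",
    "cusum_detect",
    "detect_all",
]


@dataclass(frozen=True)
class CusumConfig:
    """CUSUM parameters: drift 0 and a pooled-99th-percentile threshold by
    default.  Exactly one of ``threshold`` / ``percentile`` may be set."""

    drift: float = 0.0
    threshold: float | None = None
    percentile: float | None = 99.0
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.drift < 0:
            raise ValueError("drift must be non-negative")
        if (self.threshold is None) == (self.percentile is None):
            raise ValueError("set exactly one of threshold / percentile")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.percentile is not None and not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")


@dataclass(frozen=True)
class ChangepointCall:
    token: str
    year_pair: tuple[int, int]
    cusum_value: float
    metric_at_call: float
    direction: str  # "rise" | "fall"


@dataclass(frozen=True)
class DetectionSummary:
    threshold: float
    total_calls: int
    n_tokens_tested: int
    n_tokens_called: int
    n_tokens_single_call: int
    calls_per_transition: dict[tuple[int, int], int]


def global_threshold(
    all_series: Mapping[str, TokenTimeSeries] | Iterable[TokenTimeSeries],
    percentile: float = 99.0,
) -> float:
    """Empirical percentile (linear interpolation) of ALL pooled metric values."""
    series = (
        all_series.values() if isinstance(all_series, Mapping) else all_series
    )
    pool = np.concatenate([s.metrics for s in series if s.points] or [np.array([])])
    if pool.size == 0:
        raise ValueError("no metric values pooled; cannot derive threshold")
    return float(np.percentile(pool, percentile))


def _segments(series: TokenTimeSeries) -> list[list]:
    """Split a gappy series into runs of consecutive transitions."""
    segs: list[list] = []
    for p in series.points:
        if segs and p.year_pair[0] == segs[-1][-1].year_pair[1]:
            segs[-1].append(p)
        else:
            segs.append([p])
    return segs


def cusum_detect(series: TokenTimeSeries, cfg: CusumConfig) -> list[ChangepointCall]:
    """Run the two-sided CUSUM recursion over one token's series.

    Requires a resolved ``cfg.threshold``.  Accumulators reset at series gaps
    and after every alarm; calls are reported in time order, localized to the
    transition at which the alarm fired.
    """
    if cfg.threshold is None:
        raise ValueError("cusum_detect needs a resolved threshold "
                         "(use global_threshold / detect_all)")
    calls: list[ChangepointCall] = []
    for seg in _segments(series):
        gp = gn = 0.0
        for prev, cur in zip(seg, seg[1:]):
            diff = cur.metric - prev.metric
            gp = max(0.0, gp + diff - cfg.drift)
            gn = max(0.0, gn - diff - cfg.drift)
            fired = None
            if gp > cfg.threshold:
                fired = ("rise", gp)
            elif cfg.two_sided and gn > cfg.threshold:
                fired = ("fall", gn)
            if fired is not None:
                calls.append(
                    ChangepointCall(
                        token=series.token,
                        year_pair=cur.year_pair,
                        cusum_value=fired[1],
                        metric_at_call=cur.metric,
                        direction=fired[0],
                    )
                )
                gp = gn = 0.0
    return calls


def detect_all(
    series_map: Mapping[str, TokenTimeSeries], cfg: CusumConfig = CusumConfig()
) -> tuple[list[ChangepointCall], DetectionSummary]:
    """Call changepoints for every token and summarize.

    When configured with a percentile, the threshold is resolved once from
    the pooled metric distribution of ``series_map``.  The summary reports
    the per-transition call histogram and how many tokens have exactly one
    call (single-event changepoints dominate in practice).
    """
    if cfg.threshold is None:
        thr = global_threshold(series_map, cfg.percentile)
        cfg = replace(cfg, threshold=thr, percentile=None)
    calls: list[ChangepointCall] = []
    per_token: Counter = Counter()
    n_tested = 0
    for token in sorted(series_map):
        s = series_map[token]
        if len(s.points) < 2:
            continue
        n_tested += 1
        token_calls = cusum_detect(s, cfg)
        calls.extend(token_calls)
        if token_calls:
            per_token[token] = len(token_calls)
    histogram = Counter(c.year_pair for c in calls)
    summary = DetectionSummary(
        threshold=float(cfg.threshold),
        total_calls=len(calls),
        n_tokens_tested=n_tested,
        n_tokens_called=len(per_token),
        n_tokens_single_call=sum(1 for n in per_token.values() if n == 1),
        calls_per_transition=dict(sorted(histogram.items())),
    )
    return calls, summary
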