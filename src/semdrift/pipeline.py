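"""End-to-end convenience driver: slices → ensembles → alignment → series → calls."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .alignment import AlignedEnsemble, align_all
from .changepoint import ChangepointCall, CusumConfig, DetectionSummary, detect_all
from .embedding import TrainingConfig, YearEnsemble, train_year_ensemble
from .metrics import TokenTimeSeries, build_series
from .preprocessing import CorpusSlice

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    aligned: dict[int, AlignedEnsemble]
    series: dict[str, TokenTimeSeries]
    calls: list[ChangepointCall]
    summary: DetectionSummary


def run_pipeline(
    slices: Mapping[int, CorpusSlice],
    train_cfg: TrainingConfig,
    cusum_cfg: CusumConfig = CusumConfig(),
    anchor: tuple[int, int] | None = None,
    combiner: str = "symmetric",
) -> PipelineResult:
    """Run the full detection pipeline on preprocessed year slices.

    Trains the replicate ensemble for every year, aligns all models onto the
    anchor (default: replicate 0 of the latest year), builds every token's
    change series, and calls changepoints with the pooled-percentile CUSUM.
    """
    ensembles: dict[int, YearEnsemble] = {
        year: train_year_ensemble(slices[year], train_cfg) for year in sorted(slices)
    }
    aligned = align_all(ensembles, anchor=anchor)
    series = build_series(aligned, slices, combiner=combiner)
    calls, summary = detect_all(series, cusum_cfg)
    return PipelineResult(aligned=aligned, series=series, calls=calls, summary=summary)
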