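"""Cosine distance, intra/inter-year distances, and the combined change metric."""

import copy
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from semdrift import (
    DistanceStats,
    build_series,
    change_metric,
    cosine_distance,
    frequency_ratio,
    inter_year_distance,
    intra_year_distance,
)
from semdrift.metrics import series_to_frame
from semdrift.preprocessing import CorpusSlice

from conftest import make_random_ensemble


def _stats(intra_prev, intra_next, inter, token="t", pair=(2000, 2001)):
    return DistanceStats(
        token=token,
        year_pair=pair,
        intra_mean_prev=intra_prev,
        intra_mean_next=intra_next,
        inter_mean=inter,
        n_intra_pairs=3,
        n_inter_pairs=9,
    )


class TestCosineDistance:
    def test_identical_vectors_zero(self, rng):
        v = rng.normal(size=300)
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_vectors_two(self, rng):
        v = rng.normal(size=300)
        assert cosine_distance(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_unit_vectors_one(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    @given(st.integers(0, 2**32 - 1))
    def test_bounded_on_random_pairs(self, seed):
        r = np.random.default_rng(seed)
        d = cosine_distance(r.normal(size=8), r.normal(size=8))
        assert 0.0 <= d <= 2.0


class TestIntraYearDistance:
    def test_identical_replicates_zero(self, rng):
        ens = make_random_ensemble(rng, 2000, replicates=3, n_tokens=10, dim=4)
        for m in ens.models[1:]:
            m.vectors = ens.models[0].vectors.copy()
        assert intra_year_distance(ens, ens.vocab[0]) == pytest.approx(0.0, abs=1e-7)

    def test_two_replicates_single_pair(self, rng):
        ens = make_random_ensemble(rng, 2000, replicates=2, n_tokens=10, dim=4)
        t = ens.vocab[3]
        expected = cosine_distance(ens.models[0].vector(t), ens.models[1].vector(t))
        assert intra_year_distance(ens, t) == pytest.approx(expected)

    def test_four_replicates_match_pair_enumeration(self, rng):
        ens = make_random_ensemble(rng, 2000, replicates=4, n_tokens=10, dim=4)
        t = ens.vocab[0]
        pairs = [
            cosine_distance(a.vector(t), b.vector(t))
            for a, b in combinations(ens.models, 2)
        ]
        assert len(pairs) == 6
        assert intra_year_distance(ens, t) == pytest.approx(np.mean(pairs))


class TestInterYearDistance:
    def test_copied_year_structured_case(self, rng):
        prev = make_random_ensemble(rng, 2000, replicates=2, n_tokens=8, dim=4)
        nxt = copy.deepcopy(prev)
        for m in nxt.models:
            m.year = 2001
        t = prev.vocab[0]
        # product includes the two zero-distance self pairs
        d01 = cosine_distance(prev.models[0].vector(t), prev.models[1].vector(t))
        assert inter_year_distance(prev, nxt, t) == pytest.approx(2 * d01 / 4)

    def test_two_by_two_matches_manual_product(self, rng):
        prev = make_random_ensemble(rng, 2000, replicates=2, n_tokens=8, dim=4)
        nxt = make_random_ensemble(rng, 2001, replicates=2, n_tokens=8, dim=4)
        t = prev.vocab[2]
        manual = np.mean(
            [
                cosine_distance(a.vector(t), b.vector(t))
                for a in prev.models
                for b in nxt.models
            ]
        )
        assert inter_year_distance(prev, nxt, t) == pytest.approx(manual)

    def test_mean_within_pair_bounds(self, rng):
        prev = make_random_ensemble(rng, 2000, replicates=3, n_tokens=8, dim=4)
        nxt = make_random_ensemble(rng, 2001, replicates=3, n_tokens=8, dim=4)
        t = prev.vocab[1]
        pairs = [
            cosine_distance(a.vector(t), b.vector(t))
            for a in prev.models
            for b in nxt.models
        ]
        d = inter_year_distance(prev, nxt, t)
        assert min(pairs) <= d <= max(pairs)


class TestFrequencyRatio:
    @staticmethod
    def _slice(year, counts, extra=0):
        s = CorpusSlice(year=year)
        s.token_counts.update(counts)
        if extra:
            s.token_counts["__filler__"] = extra
        return s

    def test_equal_relative_frequencies_one(self):
        a = self._slice(2000, {"t": 10}, extra=90)
        b = self._slice(2001, {"t": 20}, extra=180)
        assert frequency_ratio(a, b, "t") == pytest.approx(1.0)

    def test_doubling(self):
        a = self._slice(2000, {"t": 1}, extra=99)
        b = self._slice(2001, {"t": 2}, extra=98)
        assert frequency_ratio(a, b, "t") == pytest.approx(2.0)

    def test_missing_in_prev_is_none(self):
        a = self._slice(2000, {"other": 5})
        b = self._slice(2001, {"t": 5})
        assert frequency_ratio(a, b, "t") is None

    def test_random_counts_match_recount(self, rng):
        ca = {f"t{i}": int(c) for i, c in enumerate(rng.integers(1, 50, size=20))}
        cb = {f"t{i}": int(c) for i, c in enumerate(rng.integers(1, 50, size=20))}
        a, b = self._slice(2000, ca), self._slice(2001, cb)
        ta, tb = sum(ca.values()), sum(cb.values())
        for t in ca:
            assert frequency_ratio(a, b, t) == pytest.approx(
                (cb[t] / tb) / (ca[t] / ta)
            )


class TestChangeMetric:
    def test_stable_token_null_is_one(self):
        assert change_metric(_stats(0.2, 0.2, 0.2), 1.0) == pytest.approx(1.0)

    def test_directional_hand_arithmetic(self):
        # inter 0.4 over mean intra 0.2, times frequency ratio 2 -> 4.0
        m = change_metric(_stats(0.1, 0.3, 0.4), 2.0, combiner="directional")
        assert m == pytest.approx(4.0)

    def test_symmetric_combiner_inverts_drops(self):
        up = change_metric(_stats(0.1, 0.1, 0.1), 2.0)
        down = change_metric(_stats(0.1, 0.1, 0.1), 0.5)
        assert up == pytest.approx(down)
        assert up == pytest.approx(2.0)

    def test_doubling_intra_halves_ratio(self):
        m1 = change_metric(_stats(0.1, 0.3, 0.4), 1.0)
        m2 = change_metric(_stats(0.2, 0.6, 0.4), 1.0)
        assert m2 == pytest.approx(m1 / 2)

    def test_strictly_decreasing_in_intra_year_instability(self):
        # the metric penalizes intra-year instability at fixed inter and freq
        intras = np.linspace(0.05, 1.0, 25)
        ms = [change_metric(_stats(i, i, 0.5), 1.3) for i in intras]
        assert all(a > b for a, b in zip(ms, ms[1:]))

    def test_eps_floor_on_vanishing_intra(self):
        m = change_metric(_stats(0.0, 0.0, 1e-3), 1.0)
        assert np.isfinite(m) and m > 0

    def test_unknown_combiner_rejected(self):
        with pytest.raises(ValueError):
            change_metric(_stats(0.1, 0.1, 0.1), 1.0, combiner="nope")


class TestBuildSeries:
    def test_three_years_two_points(self, micro_aligned, micro_slices):
        series = build_series(micro_aligned, micro_slices)
        tok = micro_aligned[2000].vocab[0]
        assert tok in series
        assert [p.year_pair for p in series[tok].points] == [
            (2000, 2001),
            (2001, 2002),
        ]

    def test_points_match_scalar_recomputation(self, micro_aligned, micro_slices):
        series = build_series(micro_aligned, micro_slices)
        tok = sorted(series)[5]
        p = series[tok].points[0]
        assert p.intra_prev == pytest.approx(
            intra_year_distance(micro_aligned[2000], tok), abs=1e-6
        )
        assert p.intra_next == pytest.approx(
            intra_year_distance(micro_aligned[2001], tok), abs=1e-6
        )
        assert p.inter == pytest.approx(
            inter_year_distance(micro_aligned[2000], micro_aligned[2001], tok),
            abs=1e-6,
        )
        assert p.freq_ratio == pytest.approx(
            frequency_ratio(micro_slices[2000], micro_slices[2001], tok)
        )
        expected = (
            p.inter / max(0.5 * (p.intra_prev + p.intra_next), 1e-8)
        ) * max(p.freq_ratio, 1 / p.freq_ratio)
        assert p.metric == pytest.approx(expected)

    def test_duplicated_year_gives_unit_frequency_ratio(self, micro_aligned,
                                                        micro_slices):
        # identical corpus content in both years -> frequency ratio exactly 1
        twin = copy.deepcopy(micro_slices[2000])
        twin.year = 2001
        series = build_series(
            {2000: micro_aligned[2000], 2001: micro_aligned[2001]},
            {2000: micro_slices[2000], 2001: twin},
        )
        for tok in list(series)[:10]:
            if tok in micro_slices[2000].token_counts:
                assert series[tok].points[0].freq_ratio == 1.0

    def test_token_filter(self, micro_aligned, micro_slices):
        tok = micro_aligned[2000].vocab[1]
        series = build_series(micro_aligned, micro_slices, tokens=[tok])
        assert set(series) == {tok}

    def test_series_frame_columns(self, micro_aligned, micro_slices):
        df = series_to_frame(build_series(micro_aligned, micro_slices))
        assert list(df.columns) == [
            "token", "year_prev", "year_next", "intra_prev", "intra_next",
            "inter", "distance_ratio", "freq_ratio", "metric",
        ]
        assert (df["metric"] > 0).all()

    def test_single_year_rejected(self, micro_aligned, micro_slices):
        with pytest.raises(ValueError, match="2 years"):
            build_series({2000: micro_aligned[2000]}, micro_slices)
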