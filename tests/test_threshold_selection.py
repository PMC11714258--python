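"""Sweeps, similarity trends, range selection and trend agreement."""

import itertools

import numpy as np
import pytest

from scanpathselect import (
    DomainError,
    ScanPathSequence,
    benchmark_compare,
    between_trend,
    default_grid,
    ideal_trend,
    select_range,
    similarity,
    threshold_sweep,
    trend_correlation,
    within_trend,
)
from scanpathselect.threshold_selection import SimilarityTrend, SweepResult

ALPHABET = [f"{k:02d}" for k in range(10)]


def random_sweep(t, p, seed, max_len=8):
    """A SweepResult filled with random token sequences."""
    rng = np.random.default_rng(seed)
    seqs = tuple(
        tuple(
            ScanPathSequence(rng.choice(ALPHABET, rng.integers(0, max_len + 1)))
            for _ in range(p)
        )
        for _ in range(t)
    )
    return SweepResult(
        grid=np.arange(10.0, 10.0 * t + 1, 10.0),
        participant_ids=tuple(f"P{j}" for j in range(p)),
        sequences=seqs,
    )


def constant_sweep(t, p, tokens):
    seq = ScanPathSequence(tokens)
    return SweepResult(
        grid=np.arange(10.0, 10.0 * t + 1, 10.0),
        participant_ids=tuple(f"P{j}" for j in range(p)),
        sequences=tuple(tuple(seq for _ in range(p)) for _ in range(t)),
    )


class TestThresholdSweep:
    def test_shape_one_participant_three_thresholds(self, small_cohort):
        rec = small_cohort[0].recording
        sweep = threshold_sweep([rec], np.array([50.0, 100.0, 150.0]))
        assert sweep.t == 3 and sweep.p == 1
        assert all(len(row) == 1 for row in sweep.sequences)

    def test_rerun_is_bit_identical(self, small_cohort):
        recs = [o.recording for o in small_cohort[:2]]
        grid = np.array([100.0, 200.0])
        a = threshold_sweep(recs, grid)
        b = threshold_sweep(recs, grid)
        assert a.sequences == b.sequences

    def test_recording_without_schedule_is_rejected(self, make_recording):
        rec = make_recording(np.zeros(100), np.zeros(100))
        with pytest.raises(Exception, match="schedule"):
            threshold_sweep([rec], np.array([100.0]))


class TestBetweenTrend:
    def test_identical_sequences_give_unit_similarity(self):
        sweep = constant_sweep(t=2, p=3, tokens=["00", "01"])
        trend = between_trend(sweep)
        np.testing.assert_allclose(trend.values, 1.0)

    def test_two_participants_equals_single_pair_similarity(self):
        sweep = random_sweep(t=3, p=2, seed=1)
        trend = between_trend(sweep)
        for i in range(3):
            a, b = sweep.sequences[i]
            assert trend.values[i] == pytest.approx(similarity(a, b))

    def test_matches_double_loop_recount(self):
        sweep = random_sweep(t=4, p=4, seed=2)
        trend = between_trend(sweep)
        for i in range(4):
            sims = [
                similarity(sweep.sequences[i][j], sweep.sequences[i][k])
                for j, k in itertools.combinations(range(4), 2)
            ]
            assert len(sims) == 6
            assert trend.values[i] == pytest.approx(np.mean(sims))

    def test_invariant_under_participant_permutation(self):
        sweep = random_sweep(t=3, p=5, seed=3)
        perm = [3, 0, 4, 1, 2]
        permuted = SweepResult(
            grid=sweep.grid,
            participant_ids=tuple(sweep.participant_ids[j] for j in perm),
            sequences=tuple(tuple(row[j] for j in perm) for row in sweep.sequences),
        )
        np.testing.assert_allclose(
            between_trend(sweep).values, between_trend(permuted).values
        )

    def test_single_participant_is_domain_error(self):
        with pytest.raises(DomainError, match="2 participants"):
            between_trend(random_sweep(t=2, p=1, seed=0))

    def test_pair_subsample_is_seeded_and_averages_fewer_pairs(self):
        sweep = random_sweep(t=2, p=6, seed=4)
        a = between_trend(sweep, max_pairs=5, seed=0)
        b = between_trend(sweep, max_pairs=5, seed=0)
        np.testing.assert_array_equal(a.values, b.values)


class TestWithinTrend:
    def test_identical_sequences_across_thresholds_give_unit_v(self):
        sweep = constant_sweep(t=5, p=2, tokens=["03", "03", "07"])
        trend = within_trend(sweep)
        np.testing.assert_allclose(trend.values, 1.0)
        np.testing.assert_allclose(trend.per_participant, 1.0)

    def test_two_thresholds_symmetry(self):
        sweep = random_sweep(t=2, p=1, seed=5)
        trend = within_trend(sweep)
        s = similarity(sweep.sequences[0][0], sweep.sequences[1][0])
        np.testing.assert_allclose(trend.values, [s, s])

    def test_matches_double_loop_recount(self):
        t, p = 4, 3
        sweep = random_sweep(t=t, p=p, seed=6)
        trend = within_trend(sweep)
        v = np.zeros((t, p))
        for j in range(p):
            for i in range(t):
                v[i, j] = np.mean(
                    [
                        similarity(sweep.sequences[i][j], sweep.sequences[l][j])
                        for l in range(t)
                        if l != i
                    ]
                )
        np.testing.assert_allclose(trend.per_participant, v)
        np.testing.assert_allclose(trend.values, v.mean(axis=1))

    def test_single_threshold_is_domain_error(self):
        with pytest.raises(DomainError):
            within_trend(random_sweep(t=1, p=2, seed=0))


class TestIdealTrend:
    def test_all_equal_to_ideal_gives_one(self):
        ideal = ScanPathSequence(["00", "01", "02"])
        sweep = constant_sweep(t=3, p=2, tokens=list(ideal))
        np.testing.assert_allclose(ideal_trend(sweep, ideal).values, 1.0)

    def test_single_participant_equals_per_threshold_similarity(self):
        sweep = random_sweep(t=4, p=1, seed=7)
        ideal = ScanPathSequence(ALPHABET[:5])
        trend = ideal_trend(sweep, ideal)
        for i in range(4):
            assert trend.values[i] == pytest.approx(
                similarity(sweep.sequences[i][0], ideal)
            )

    def test_matches_recount(self):
        sweep = random_sweep(t=3, p=4, seed=8)
        ideal = ScanPathSequence(ALPHABET[:6])
        trend = ideal_trend(sweep, ideal)
        for i in range(3):
            expected = np.mean(
                [similarity(seq, ideal) for seq in sweep.sequences[i]]
            )
            assert trend.values[i] == pytest.approx(expected)

    def test_empty_ideal_is_domain_error(self):
        with pytest.raises(DomainError):
            ideal_trend(random_sweep(t=2, p=2, seed=0), ScanPathSequence(()))


def trend_from(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = (
        np.arange(10.0, 10.0 * values.size + 1, 10.0) if grid is None else grid
    )
    return SimilarityTrend(grid=grid, values=values, kind="ideal")


class TestSelectRange:
    def test_unimodal_trend(self):
        # Rises to 0.9 at 200 deg/s then falls; delta 0.05 keeps >= 0.85.
        grid = np.arange(10.0, 401.0, 10.0)
        values = 0.9 - 0.9 * ((grid - 200.0) / 400.0) ** 2
        sel = select_range(trend_from(values, grid), delta=0.05)
        assert sel.argmax_threshold == 200.0
        inside = (grid >= sel.lower) & (grid <= sel.upper)
        assert (values[inside] >= 0.9 - 0.05 - 1e-12).all()
        # Direct-scan oracle for the contiguous band around the argmax.
        ok = values >= values.max() - 0.05
        lo = hi = int(np.argmax(values))
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < values.size - 1 and ok[hi + 1]:
            hi += 1
        assert (sel.lower, sel.upper) == (grid[lo], grid[hi])

    def test_constant_trend_selects_full_grid_lowest_argmax(self):
        sel = select_range(trend_from([0.7] * 6))
        assert sel.argmax_threshold == 10.0
        assert (sel.lower, sel.upper) == (10.0, 60.0)

    def test_two_equal_maxima_pick_the_lower_threshold(self):
        sel = select_range(trend_from([0.1, 0.9, 0.1, 0.9, 0.1]), delta=0.0)
        assert sel.argmax_threshold == 20.0
        assert (sel.lower, sel.upper) == (20.0, 20.0)

    def test_floor_restricts_the_range(self):
        sel = select_range(trend_from([0.69, 0.72, 0.74, 0.71, 0.69]), floor=0.70)
        assert sel.lower == 20.0 and sel.upper == 40.0


class TestTrendCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        a = trend_from(np.linspace(0.1, 0.9, 10))
        b = trend_from(np.sqrt(a.values))
        rho, p = trend_correlation(a, b)
        assert rho == pytest.approx(1.0)
        assert p < 0.001

    def test_reversal_gives_rho_minus_one(self):
        a = trend_from(np.linspace(0.1, 0.9, 8))
        b = trend_from(a.values[::-1])
        assert trend_correlation(a, b)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        a = trend_from(rng.uniform(0, 1, 40))
        b = trend_from(rng.uniform(0, 1, 40))
        rho, _ = trend_correlation(a, b)
        from scipy.stats import rankdata

        ra, rb = rankdata(a.values), rankdata(b.values)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expected)

    def test_zero_variance_trend_reports_undefined(self):
        a = trend_from([0.5] * 5)
        b = trend_from(np.linspace(0, 1, 5))
        rho, p = trend_correlation(a, b)
        assert np.isnan(rho) and np.isnan(p)

    def test_mismatched_grids_rejected(self):
        a = trend_from([0.1, 0.2, 0.3])
        b = SimilarityTrend(
            grid=np.array([5.0, 10.0, 15.0]), values=a.values, kind="ideal"
        )
        with pytest.raises(DomainError):
            trend_correlation(a, b)


class TestBenchmarkCompare:
    def test_report_values_equal_direct_lookups(self):
        rng = np.random.default_rng(10)
        trend = trend_from(rng.uniform(0.2, 0.9, 40))
        report = benchmark_compare(trend, [200.0, 350.0], benchmark=30.0)
        lookup = dict(zip(trend.grid, trend.values))
        for _, row in report.iterrows():
            assert row.ideal_similarity == pytest.approx(
                lookup[row.threshold_dva_s]
            )
            assert row.difference_vs_benchmark == pytest.approx(
                lookup[row.threshold_dva_s] - lookup[30.0]
            )

    def test_argmax_candidate_beats_or_ties_benchmark(self):
        rng = np.random.default_rng(11)
        trend = trend_from(rng.uniform(0.2, 0.9, 40))
        best = float(trend.grid[np.argmax(trend.values)])
        report = benchmark_compare(trend, [best])
        cand = report[report.role == "candidate"].iloc[0]
        assert cand.difference_vs_benchmark >= 0.0

    def test_benchmark_equal_to_candidate_has_zero_difference(self):
        trend = trend_from(np.linspace(0.2, 0.9, 10))
        report = benchmark_compare(trend, [30.0], benchmark=30.0)
        assert (report.difference_vs_benchmark == 0.0).all()

    def test_off_grid_threshold_is_domain_error(self):
        trend = trend_from([0.5, 0.6, 0.7])
        with pytest.raises(DomainError, match="not on the sweep grid"):
            benchmark_compare(trend, [25.0], benchmark=30.0)


def test_default_grid_is_10_to_400_step_10():
    grid = default_grid()
    assert grid[0] == 10.0 and grid[-1] == 400.0 and grid.size == 40
    assert np.unique(np.diff(grid)).tolist() == [10.0]
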