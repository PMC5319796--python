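"""Static-interval detection, dwell statistics, false-positive model and
heat maps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriturn import residence
from oriturn.exceptions import InvalidModelError
from oriturn.io import TrackSet, Trajectory
from oriturn.simulate import (
    DiffusionModel,
    SimulationConfig,
    TrackLengthLaw,
    simulate_brownian_tracks,
)

from conftest import DT, make_track

CFG = residence.ResidenceConfig(frame_interval=DT)


class TestFindStaticIntervals:
    def test_fully_static_track_is_one_interval(self):
        t = make_track("s", np.zeros((12, 2)))
        intervals = residence.find_static_intervals(t, CFG)
        assert len(intervals) == 1
        iv = intervals[0]
        assert (iv.start_frame, iv.end_frame) == (0, 11)
        assert iv.duration == pytest.approx(12 * DT)  # 0.492 s

    def test_large_alternating_jumps_give_no_interval(self):
        coords = [(0, 0) if i % 2 == 0 else (1.0, 0) for i in range(10)]
        t = make_track("alt", coords)
        assert residence.find_static_intervals(t, CFG) == []

    def test_hand_crafted_partial_trapping(self):
        # frames 0-5 within 0.1 um of the origin, frames 6-9 far from
        # everything else -> exactly one interval covering frames 0-5
        rng = np.random.default_rng(0)
        near = rng.uniform(-0.07, 0.07, size=(6, 2))
        far = np.array([[5.0, 0], [10.0, 0], [15.0, 0], [20.0, 0]])
        t = make_track("h", np.vstack([near, far]))
        intervals = residence.find_static_intervals(t, CFG)
        assert len(intervals) == 1
        assert (intervals[0].start_frame, intervals[0].end_frame) == (0, 5)
        assert intervals[0].duration == pytest.approx(6 * DT)

    def test_gap_breaks_an_interval(self):
        t = make_track("g", np.zeros((8, 2)),
                       frames=[0, 1, 2, 3, 10, 11, 12, 13])
        intervals = residence.find_static_intervals(t, CFG)
        assert [(iv.start_frame, iv.end_frame) for iv in intervals] == \
            [(0, 3), (10, 13)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_selected_intervals_validate_their_predicate(self, seed):
        """Non-overlap, gap-freeness and the within-radius predicate hold for
        every interval on random two-state tracks."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 25)
        sd = rng.choice([0.02, 0.1, 0.25])
        pos = np.cumsum(rng.normal(0, sd, size=(n, 2)), axis=0)
        frames = np.sort(rng.choice(np.arange(2 * n), size=n, replace=False))
        t = Trajectory("r", frames, pos[:, 0], pos[:, 1], DT)
        intervals = residence.find_static_intervals(t, CFG)
        claimed = set()
        idx = {f: i for i, f in enumerate(frames)}
        for iv in intervals:
            span = set(range(iv.start_frame, iv.end_frame + 1))
            assert not (span & claimed)  # non-overlapping
            claimed |= span
            members = [idx[f] for f in span]
            assert len(members) == len(span)  # no frame gap inside
            ax, ay = iv.anchor
            for i in members:
                assert np.hypot(t.x[i] - ax, t.y[i] - ay) <= CFG.radius + 1e-12
            assert iv.n_frames >= CFG.min_frames


class TestResidenceSummary:
    def test_fixed_length_static_tracks(self):
        tracks = TrackSet([make_track(f"s{i}", np.zeros((5, 2)))
                           for i in range(10)], frame_interval=DT)
        summary = residence.residence_summary(tracks, CFG)
        assert summary.n_intervals == 10
        assert summary.mean_residence == pytest.approx(5 * 41.0)  # 205 ms
        cdf_p = [p for _, p in summary.cdf]
        assert cdf_p[0] >= 0 and cdf_p[-1] == 1.0
        assert np.all(np.diff(cdf_p) >= 0)

    def test_empty_summary_is_flagged_not_raised(self):
        coords = [(i * 1.0, 0) for i in range(6)]
        tracks = TrackSet([make_track("m", coords)], frame_interval=DT)
        summary = residence.residence_summary(tracks, CFG)
        assert summary.n_intervals == 0 and np.isnan(summary.mean_residence)

    def test_two_state_dwell_recovered_after_truncation_correction(self):
        model = DiffusionModel(components=[(0.027, 0.5), (0.51, 0.5)],
                               switching=(0.200, 0.200))
        cfg = SimulationConfig(seed=17, frame_interval=DT,
                               track_length_law=TrackLengthLaw("fixed", 30, 2))
        tracks = simulate_brownian_tracks(model, 1200, cfg)
        summary = residence.residence_summary(tracks, CFG)
        corrected = residence.truncation_corrected_mean_ms(summary, CFG)
        assert abs(corrected - 200.0) / 200.0 <= 0.15

    def test_long_track_restriction_shifts_mean_upward(self):
        model = DiffusionModel(components=[(0.027, 0.5), (0.51, 0.5)],
                               switching=(0.200, 0.200))
        cfg = SimulationConfig(seed=19, frame_interval=DT,
                               track_length_law=TrackLengthLaw("geometric", 8, 3))
        tracks = simulate_brownian_tracks(model, 3000, cfg)
        all_mean = residence.residence_summary(tracks, CFG).mean_residence
        long_mean = residence.residence_summary(
            tracks, CFG, min_track_frames=10).mean_residence
        assert long_mean > all_mean


class TestKsComparison:
    def _durations_pool(self, seed):
        model = DiffusionModel(components=[(0.027, 0.5), (0.51, 0.5)],
                               switching=(0.200, 0.200))
        cfg = SimulationConfig(seed=seed, frame_interval=DT,
                               track_length_law=TrackLengthLaw("fixed", 30, 2))
        tracks = simulate_brownian_tracks(model, 1200, cfg)
        return residence.residence_summary(tracks, CFG)

    @staticmethod
    def _summary_from(durations):
        ivs = [residence.StaticInterval("x", (0, 0), 0, max(2, int(d / DT) - 1), d)
               for d in durations]
        return residence.ResidenceSummary(
            intervals=ivs, mean_residence=float(np.mean(durations) * 1000),
            n_intervals=len(ivs), cdf=[])

    def test_identical_samples_are_not_rejected(self):
        s = self._durations_pool(23)
        stat, p = residence.residence_cdf_compare(s, s)
        assert stat == 0.0 and p == 1.0

    def test_null_rejection_rate_at_or_below_nominal(self):
        """Random splits of one pooled dwell sample reject at most at the
        nominal 5% level.  Dwell durations are frame-quantized (heavily
        tied), which makes the KS p-values conservative: the observed rate
        sits below 5% but the test never becomes anti-conservative."""
        pool = self._durations_pool(29).durations()
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            perm = rng.permutation(pool)
            half = len(perm) // 2
            a = self._summary_from(perm[:half])
            b = self._summary_from(perm[half:])
            if residence.residence_cdf_compare(a, b)[1] < 0.05:
                rejections += 1
        assert 0.0 < rejections / n_rep <= 0.07

    def test_different_dwells_are_detected(self):
        def summary(dwell, seed):
            model = DiffusionModel(components=[(0.027, 0.5), (0.51, 0.5)],
                                   switching=(dwell, 0.200))
            cfg = SimulationConfig(seed=seed, frame_interval=DT,
                                   track_length_law=TrackLengthLaw("fixed", 30, 2))
            return residence.residence_summary(
                simulate_brownian_tracks(model, 600, cfg), CFG)
        _, p = residence.residence_cdf_compare(summary(0.200, 37),
                                               summary(0.300, 38))
        assert p < 0.05


class TestStopProbability:
    def test_limits(self):
        assert residence.stop_probability(0.0, DT, 0.23) == 1.0
        assert residence.stop_probability(0.51, DT, 0.0) == 0.0

    def test_headline_evaluation(self):
        p = residence.stop_probability(0.51, 0.041, 0.23)
        assert p == pytest.approx(1 - np.exp(-0.23 ** 2 / (4 * 0.51 * 0.041)),
                                  abs=1e-12)
        assert p == pytest.approx(0.469, abs=0.002)

    def test_matches_monte_carlo_step_fraction(self):
        d, dt, r = 0.68, 0.041, 0.23
        rng = np.random.default_rng(5)
        steps = rng.normal(0, np.sqrt(2 * d * dt), size=(200_000, 2))
        frac = np.mean(np.hypot(steps[:, 0], steps[:, 1]) < r)
        se = np.sqrt(frac * (1 - frac) / len(steps))
        assert abs(residence.stop_probability(d, dt, r) - frac) < 3 * se


def exact_run_probability(n, p, min_run=3):
    """Exhaustive-enumeration oracle: probability that a string of n
    Bernoulli(p) trials contains a success run of >= min_run."""
    total = 0.0
    for bits in itertools.product((0, 1), repeat=n):
        run = best = 0
        for b in bits:
            run = run + 1 if b else 0
            best = max(best, run)
        if best >= min_run:
            k = sum(bits)
            total += p ** k * (1 - p) ** (n - k)
    return total


class TestRunProbability:
    def test_collapsed_sum_at_n_equals_min_run(self):
        assert residence.run_probability(3, 0.4) == pytest.approx(0.4 ** 3)

    @pytest.mark.parametrize("n,expected", [(4, 0.1875), (5, 0.21875)])
    def test_term_by_term_hand_expansion(self, n, expected):
        assert residence.run_probability(n, 0.5) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_closed_form_oracle(self):
        # independently derived: P = p^(m-1) * (1 - (1-p)^(n-m+1))
        for n in (3, 7, 20, 150):
            for p in (0.1, 0.469, 0.9):
                closed = p ** 2 * (1 - (1 - p) ** (n - 2))
                assert residence.run_probability(n, p) == pytest.approx(
                    closed, rel=1e-10)

    def test_exact_for_short_tracks_undercount_beyond(self):
        """Against 2^n enumeration: the combinatorial grouping is exact for
        n <= 4 and undercounts (never overcounts) for n >= 5."""
        for p in (0.3, 0.5, 0.7):
            for n in range(3, 13):
                exact = exact_run_probability(n, p)
                approx = residence.run_probability(n, p)
                if n <= 4:
                    assert approx == pytest.approx(exact, abs=1e-12)
                else:
                    assert approx < exact + 1e-12

    def test_monotone_in_n_and_p_and_bounded(self):
        grid = np.linspace(0.0, 1.0, 11)
        for p in grid:
            vals = [residence.run_probability(n, p) for n in range(3, 201, 9)]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        for n in (5, 50):
            vals = [residence.run_probability(n, p) for p in grid]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert residence.run_probability(10, 1.0) == 1.0

    def test_short_track_returns_zero(self):
        assert residence.run_probability(2, 0.9) == 0.0

    def test_generalized_min_run_matches_printed_form_at_3(self):
        for n in (4, 9):
            assert residence.run_probability(n, 0.42, min_run=3) == \
                pytest.approx(residence.run_probability(n, 0.42))

    def test_stable_at_large_n(self):
        v = residence.run_probability(10_000, 0.469)
        assert 0.0 <= v <= 1.0 and np.isfinite(v)


class TestFalsePositiveRate:
    def test_short_tracks_contribute_zero(self):
        model = residence.false_positive_rate([2, 2, 2], 0.5, CFG)
        assert model.rate == 0.0

    def test_immobile_limit_counts_long_tracks(self):
        model = residence.false_positive_rate([2, 3, 5, 5], 0.0, CFG)
        assert model.p == 1.0
        assert model.rate == pytest.approx(0.75)

    def test_worked_example_n5(self):
        model = residence.false_positive_rate([5], 0.68, CFG)
        assert model.p == pytest.approx(0.3777, abs=1e-3)
        assert model.rate == pytest.approx(0.108, abs=1e-3)

    def test_monte_carlo_decreases_with_d_and_converges(self):
        rates = [residence.monte_carlo_false_positive_rate(
            [5], d, CFG, n_tracks=20_000, seed=1) for d in (0.3, 0.68, 1.5)]
        assert rates[0] > rates[1] > rates[2]
        a = residence.monte_carlo_false_positive_rate([5], 0.68, CFG,
                                                      n_tracks=100_000, seed=2)
        b = residence.monte_carlo_false_positive_rate([5], 0.68, CFG,
                                                      n_tracks=100_000, seed=3)
        assert abs(a - b) < 0.01

    def test_anchored_detector_flags_more_than_the_analytic_model(self):
        """The real fixed-anchor detector unions over candidate anchors and
        is far more permissive than the combinatorial model."""
        analytic = residence.false_positive_rate([5], 0.68, CFG).rate
        anchored = residence.monte_carlo_false_positive_rate(
            [5], 0.68, CFG, n_tracks=5_000, seed=4, detector="anchored")
        assert anchored > analytic


class TestHeatMap:
    @pytest.mark.parametrize("k", [2, 5, 12])
    def test_static_run_peak_matches_geometric_series(self, k):
        t = make_track("s", np.full((k, 2), 0.37))
        hm = residence.heat_map(t, damping=0.8)
        expected = (1 - 0.8 ** k) / (1 - 0.8)
        assert hm.peak == pytest.approx(expected, abs=1e-9)

    def test_fast_crossing_track_stays_cold(self):
        coords = [(i * 1.0, 0.0) for i in range(6)]  # steps >> mask sd
        hm = residence.heat_map(make_track("f", coords))
        assert hm.peak == pytest.approx(1.0, abs=1e-6)

    def test_field_nonnegative_and_covers_padding(self):
        t = make_track("t", [(0, 0), (0.1, 0.2), (0.3, 0.1)])
        hm = residence.heat_map(t, grid_spacing=0.02, mask_sd=0.08)
        assert np.all(hm.temperatures >= 0)
        assert hm.origin[0] <= 0 - 3 * 0.08 + 0.02 + 1e-9

    def test_oversized_grid_rejected(self):
        t = make_track("big", [(0, 0), (500.0, 500.0)])
        with pytest.raises(InvalidModelError, match="coarser"):
            residence.heat_map(t, grid_spacing=0.001)
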