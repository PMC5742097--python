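import numpy as np
import pytest

import cinemetrics as cm
from cinemetrics.io_formats import GazeTrace, ValidationError
from cinemetrics.gaze_asynchrony import (
    DIVERGENT,
    NON_DIVERGENT,
    UNCLASSIFIABLE,
    classify_window,
    estimate_null_distribution,
    pairwise_gaze_distances,
    segment_windows,
)
from conftest import make_traces


class TestSegmentWindows:
    def test_600_samples_give_196_windows(self, rng):
        traces = make_traces(rng.random((3, 600, 2)) * 500)
        wins = segment_windows(traces)
        assert len(wins) == 196  # floor((600 - 15) / 3) + 1
        assert wins[1].start_ms - wins[0].start_ms == 50.0

    def test_short_trace_gives_zero_windows(self, rng):
        traces = make_traces(rng.random((2, 10, 2)))
        assert segment_windows(traces) == []

    def test_overlap_is_80_percent(self):
        cfg = cm.Config()
        m = cfg.win_ms * cfg.gaze_rate / 1000
        h = cfg.hop_ms * cfg.gaze_rate / 1000
        assert 1 - h / m == pytest.approx(0.80)

    def test_window_content_matches_direct_slice(self, rng):
        pos = rng.random((2, 100, 2)) * 100
        wins = segment_windows(make_traces(pos))
        k = 7
        np.testing.assert_array_equal(wins[k].positions, pos[:, 3 * k : 3 * k + 15])

    def test_inconsistent_grids_rejected(self, rng):
        traces = make_traces(rng.random((2, 120, 2)))
        traces[1].time_ms = traces[1].time_ms * 2.0
        with pytest.raises(ValidationError, match="grid"):
            segment_windows(traces)
        bad_len = make_traces(rng.random((2, 120, 2)))
        bad_len[1] = make_traces(rng.random((1, 60, 2)))[0]
        with pytest.raises(ValidationError, match="inconsistent"):
            segment_windows(bad_len)


class TestPairwiseDistances:
    def test_identical_traces_give_zero(self, rng):
        pos = rng.random((1, 60, 2)) * 100
        wins = segment_windows(make_traces(np.repeat(pos, 2, axis=0)))
        d = pairwise_gaze_distances(wins[0])
        np.testing.assert_array_equal(d, np.zeros(15))

    def test_3_4_5_triangle(self):
        pos = np.zeros((2, 15, 2))
        pos[1, :, 0] = 3.0
        pos[1, :, 1] = 4.0
        wins = segment_windows(make_traces(pos))
        np.testing.assert_allclose(pairwise_gaze_distances(wins[0]), 5.0)

    def test_distance_count_four_traces(self, rng):
        wins = segment_windows(make_traces(rng.random((4, 60, 2))))
        assert len(pairwise_gaze_distances(wins[0])) == 6 * 15  # C(4,2) * m

    def test_fewer_than_two_usable_traces_unclassifiable(self, rng):
        pos = rng.random((2, 15, 2))
        traces = make_traces(pos)
        traces[1].valid[:] = False  # 0% valid, below the 50% rule
        win = segment_windows(traces)[0]
        assert pairwise_gaze_distances(win) is None
        null = cm.NullDistribution(q_lo=1, q_hi=2, n_draws=10, seed=0)
        assert classify_window(None, null) == UNCLASSIFIABLE

    def test_invalid_samples_skipped_pairwise(self):
        pos = np.zeros((2, 15, 2))
        pos[1, :, 0] = 1.0
        traces = make_traces(pos)
        traces[0].valid[:5] = False  # 10/15 valid, above threshold
        d = pairwise_gaze_distances(segment_windows(traces)[0])
        assert len(d) == 10


class TestNullDistribution:
    def test_constant_traces_give_degenerate_null(self):
        pos = np.full((3, 120, 2), 7.0)
        null = estimate_null_distribution(make_traces(pos), n_draws=20, seed=1)
        assert null.degenerate and null.q_lo == null.q_hi == 0.0

    def test_same_seed_reproduces_quantiles(self, uniform_traces):
        cfg = cm.Config(n_draws=30)
        a = estimate_null_distribution(uniform_traces, seed=9, config=cfg)
        b = estimate_null_distribution(uniform_traces, seed=9, config=cfg)
        assert (a.q_lo, a.q_hi) == (b.q_lo, b.q_hi)
        c = estimate_null_distribution(uniform_traces, seed=10, config=cfg)
        assert (a.q_lo, a.q_hi) != (c.q_lo, c.q_hi)

    def test_uniform_gaze_null_matches_monte_carlo_oracle(self, uniform_traces):
        cfg = cm.Config(n_draws=60)
        null = estimate_null_distribution(uniform_traces, seed=2, config=cfg)
        rng = np.random.default_rng(99)
        a = rng.uniform([0, 0], [1024, 768], size=(400_000, 2))
        b = rng.uniform([0, 0], [1024, 768], size=(400_000, 2))
        d = np.hypot(*(a - b).T)
        q_lo, q_hi = np.percentile(d, [5, 95])
        assert null.q_lo == pytest.approx(q_lo, rel=0.05)
        assert null.q_hi == pytest.approx(q_hi, rel=0.05)


class TestClassifyWindow:
    null = cm.NullDistribution(q_lo=10.0, q_hi=100.0, n_draws=100, seed=0)

    def test_all_inside_is_divergent(self):
        assert classify_window(np.full(20, 50.0), self.null) == DIVERGENT

    def test_all_below_is_non_divergent(self):
        assert classify_window(np.full(20, 2.0), self.null) == NON_DIVERGENT

    def test_share_exactly_at_threshold_counts_divergent(self):
        d = np.array([50.0] * 3 + [1.0] * 7)  # share inside = 0.30
        assert classify_window(d, self.null, frac=0.30) == DIVERGENT
        d = np.array([50.0] * 2 + [1.0] * 8)  # share inside = 0.20
        assert classify_window(d, self.null, frac=0.30) == NON_DIVERGENT

    def test_degenerate_null_forces_non_divergent(self):
        null = cm.NullDistribution(q_lo=0.0, q_hi=0.0, n_draws=10, seed=0, degenerate=True)
        assert classify_window(np.zeros(5), null) == NON_DIVERGENT

    def test_empty_distances_unclassifiable(self):
        assert classify_window(np.array([]), self.null) == UNCLASSIFIABLE

    def test_outside_rule_inverts_region(self):
        d = np.full(10, 500.0)  # all outside
        assert classify_window(d, self.null, rule="outside") == DIVERGENT
        assert classify_window(d, self.null, rule="inside") == NON_DIVERGENT


class TestAttentionalAsynchrony:
    def test_score_in_unit_interval(self, uniform_traces):
        res = cm.attentional_asynchrony(uniform_traces, cm.Config(n_draws=25), seed=4)
        assert 0.0 <= res.score <= 1.0
        assert res.n_classifiable <= res.n_windows == len(res.labels)

    def test_relabeling_participants_and_viewings_preserves_score(self, uniform_traces):
        cfg = cm.Config(n_draws=25)
        base = cm.attentional_asynchrony(uniform_traces, cfg, seed=4)
        renamed = [
            GazeTrace(f"Q{i}", 2 if tr.viewing == 1 else 1, tr.trailer_id,
                      tr.time_ms, tr.xy, tr.valid)
            for i, tr in enumerate(uniform_traces)
        ]
        again = cm.attentional_asynchrony(renamed, cfg, seed=4)
        assert again.score == base.score
        assert again.labels == base.labels

    def test_appended_invalid_samples_do_not_move_score(self, uniform_traces):
        cfg = cm.Config(n_draws=25)
        null = estimate_null_distribution(uniform_traces, seed=4, config=cfg)
        base = cm.attentional_asynchrony(uniform_traces, cfg, null=null)
        extended = []
        for tr in uniform_traces:
            pad = 30
            extra_t = tr.time_ms[-1] + (np.arange(1, pad + 1)) * (1000 / 60)
            extended.append(
                GazeTrace(tr.participant_id, tr.viewing, tr.trailer_id,
                          np.concatenate([tr.time_ms, extra_t]),
                          np.vstack([tr.xy, np.zeros((pad, 2))]),
                          np.concatenate([tr.valid, np.zeros(pad, dtype=bool)]))
            )
        res = cm.attentional_asynchrony(extended, cfg, null=null)
        assert res.score == base.score

    def test_viewing_restriction_filters_traces(self, gaze_df):
        table = cm.GazeTable(gaze_df)
        cfg = cm.Config(n_draws=20)
        res = cm.attentional_asynchrony(table.traces(), cfg, viewing=1, seed=0)
        assert 0.0 <= res.score <= 1.0
        only_one = [t for t in table.traces() if t.viewing == 1]
        assert len(only_one) == 2

    def test_needs_two_traces(self, uniform_traces):
        with pytest.raises(ValidationError, match="2 traces"):
            cm.attentional_asynchrony(uniform_traces[:1], cm.Config(n_draws=5))
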