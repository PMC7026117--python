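import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mesomotif import motifs, synthetic
from mesomotif.io_core import Movie
from mesomotif.motifs import CorrelationTrace


def brute_force_events(values, threshold, min_run=5):
    """Independent run-length oracle: frame-by-frame scan."""
    events = []
    start = None
    for i, v in enumerate(list(values) + [-np.inf]):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            if i - start >= min_run:
                events.append((start, i - start))
            start = None
    return events


def trace_from(values):
    values = np.asarray(values, dtype=float)
    return CorrelationTrace(values=values, mu=float(values.mean()),
                            sigma=float(values.std()), template_id="forelimb")


class TestCorrelationTrace:
    def test_embedded_template_window_gives_unity(self, template_16):
        data = np.zeros((40, 16, 16))
        data[20:25] = template_16.frames
        trace = motifs.correlation_trace(Movie(data, is_dff=True), template_16)
        assert trace.values[20] == pytest.approx(1.0, abs=1e-9)

    def test_negated_window_gives_minus_one(self, template_16):
        data = np.zeros((40, 16, 16))
        data[20:25] = -template_16.frames
        trace = motifs.correlation_trace(Movie(data, is_dff=True), template_16)
        assert trace.values[20] == pytest.approx(-1.0, abs=1e-9)

    def test_length_and_bounds(self, template_16, white_dff_movie):
        trace = motifs.correlation_trace(white_dff_movie(n_frames=300), template_16)
        assert len(trace.values) == 300 - 4
        assert np.all(trace.values >= -1.0) and np.all(trace.values <= 1.0)

    def test_white_noise_trace_centred_and_symmetric(self, template_16,
                                                     white_dff_movie):
        from scipy import stats
        for seed in range(5):
            trace = motifs.correlation_trace(
                white_dff_movie(n_frames=10_000, seed=seed), template_16)
            assert abs(trace.mu) < 0.01
            assert abs(stats.skew(trace.values)) < 0.1

    def test_zero_variance_window_warns_and_zeroes(self, template_16):
        data = np.zeros((20, 16, 16))
        with pytest.warns(UserWarning, match="zero-variance"):
            trace = motifs.correlation_trace(Movie(data, is_dff=True), template_16)
        assert np.all(trace.values == 0)

    def test_shape_mismatch_rejected(self, template_16, white_dff_movie):
        with pytest.raises(ValueError, match="shape"):
            motifs.correlation_trace(white_dff_movie(field=(8, 8)), template_16)


class TestBinarize:
    def test_fraction_threshold_inclusive(self):
        frame = np.array([[0.0, 0.2], [0.5, 1.0]])
        out = motifs.binarize_frame(frame, 0.4)
        assert out.tolist() == [[False, False], [True, True]]

    def test_fraction_one_keeps_only_argmax(self):
        frame = np.array([[0.1, 0.5], [0.9, 1.0]])
        assert motifs.binarize_frame(frame, 1.0).sum() == 1

    def test_fraction_zero_keeps_all_positive(self):
        frame = np.array([[-1.0, 0.0], [0.3, 1.0]])
        assert motifs.binarize_frame(frame, 0.0).sum() == 3

    def test_nonpositive_frame_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            motifs.binarize_frame(np.zeros((3, 3)), 0.4)


class TestConcordance:
    def test_identical_binary_frames_score_one(self):
        frame = np.zeros((10, 10))
        frame[2:5, 2:5] = 1.0
        assert motifs.concordance(frame, frame, "forelimb") == 1.0

    def test_disjoint_blobs_score_zero(self):
        a = np.zeros((10, 10)); a[0:3, 0:3] = 1.0
        b = np.zeros((10, 10)); b[6:9, 6:9] = 1.0
        assert motifs.concordance(a, b, "whisker") == 0.0

    def test_half_overlap_gives_one_third(self):
        a = np.zeros((10, 10)); a[0:2, 0:4] = 1.0   # 8 px
        b = np.zeros((10, 10)); b[0:2, 2:6] = 1.0   # 8 px, 4 shared
        assert motifs.concordance(a, b, "hindlimb") == pytest.approx(1 / 3)

    def test_dice_variant(self):
        a = np.zeros((10, 10)); a[0:2, 0:4] = 1.0
        b = np.zeros((10, 10)); b[0:2, 2:6] = 1.0
        assert motifs.concordance(a, b, "hindlimb", metric="dice") == pytest.approx(0.5)


class TestDetectEvents:
    def test_all_subthreshold_yields_nothing(self):
        assert motifs.detect_events(trace_from(np.zeros(50)), 0.5) == []

    def test_single_run_of_six(self):
        values = np.zeros(30); values[10:16] = 1.0
        events = motifs.detect_events(trace_from(values), 0.5)
        assert len(events) == 1
        assert events[0].onset_frame == 10
        assert events[0].duration_frames == 6

    def test_run_of_four_discarded(self):
        values = np.zeros(30); values[10:14] = 1.0
        assert motifs.detect_events(trace_from(values), 0.5) == []

    def test_runs_not_merged_across_gap(self):
        values = np.zeros(30)
        values[5:10] = 1.0
        values[11:16] = 1.0
        events = motifs.detect_events(trace_from(values), 0.5)
        assert [e.onset_frame for e in events] == [5, 11]

    def test_threshold_is_strict(self):
        values = np.full(10, 0.5)
        assert motifs.detect_events(trace_from(values), 0.5) == []

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 200))
            values = rng.normal(0, 1, n)
            thr = float(rng.normal(0, 1))
            got = [(e.onset_frame, e.duration_frames)
                   for e in motifs.detect_events(trace_from(values), thr)]
            assert got == brute_force_events(values, thr)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=5, max_size=60),
           st.floats(-1, 1, allow_nan=False),
           st.integers(min_value=1, max_value=8))
    def test_brute_force_equivalence_property(self, values, thr, min_run):
        got = [(e.onset_frame, e.duration_frames)
               for e in motifs.detect_events(trace_from(values), thr, min_run=min_run)]
        assert got == brute_force_events(values, thr, min_run)

    def test_event_count_nonincreasing_in_threshold(self, rng):
        values = rng.normal(0, 1, 2000)
        trace = trace_from(values)
        counts = [len(motifs.detect_events(trace, trace.mu + k * trace.sigma))
                  for k in np.arange(0, 3, 0.25)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestCalibrateThreshold:
    def _planted(self, seed=0):
        movie, _ = synthetic.simulate_spontaneous(
            n_frames=2000, field=(32, 32), event_rate_per_modality=4e-3,
            modalities=("forelimb",), seed=seed)
        from mesomotif.preprocess import dff
        return dff(movie)

    def test_single_k_grid(self, template_32):
        d = self._planted()
        trace = motifs.correlation_trace(d, template_32)
        curve, threshold = motifs.calibrate_threshold(
            trace, d, template_32, k_grid=np.array([2.0]))
        assert len(curve.concordance) == 1
        assert threshold == pytest.approx(trace.mu + 2.0 * trace.sigma)

    def test_planted_events_give_rising_concordance(self, template_32):
        # amplitude >> noise and no bleach drift: raising the threshold moves
        # matches onto genuine events, so concordance rises to a plateau
        for seed in range(5):
            movie, _ = synthetic.simulate_spontaneous(
                n_frames=2000, field=(32, 32), event_rate_per_modality=4e-3,
                amplitude_pct=2.0, noise_sd_pct=0.02, bleach_tau_frames=1e12,
                modalities=("forelimb",), seed=seed)
            from mesomotif.preprocess import dff
            d = dff(movie)
            trace = motifs.correlation_trace(d, template_32)
            curve, _ = motifs.calibrate_threshold(
                trace, d, template_32, k_grid=np.arange(0.0, 2.51, 0.25))
            c = curve.concordance
            assert all(b >= a - 0.01 for a, b in zip(c, c[1:]))  # non-decreasing
            assert c[-1] > c[0] + 0.05                           # and genuinely rising

    def test_noise_movie_falls_back_to_default_threshold(self, template_16,
                                                         white_dff_movie):
        d = white_dff_movie(n_frames=2000, seed=3)
        trace = motifs.correlation_trace(d, template_16)
        _, threshold = motifs.calibrate_threshold(trace, d, template_16)
        assert threshold >= trace.mu + 1.5 * trace.sigma - 1e-12


class TestFrequencySummaries:
    def test_frequency_units(self):
        events = [None] * 10  # only the count matters
        assert motifs.motif_frequency(events, 50_005) == pytest.approx(
            10 / 50_001 * 10_000)

    def test_zero_events(self):
        assert motifs.motif_frequency([], 10_001) == 0.0

    def test_concatenating_movie_doubles_count(self, template_16):
        movie, _ = synthetic.simulate_spontaneous(
            n_frames=2000, field=(16, 16), event_rate_per_modality=4e-3,
            modalities=("forelimb",), noise_sd_pct=0.02, seed=5)
        from mesomotif.preprocess import dff
        d = dff(movie)
        doubled = Movie(np.concatenate([d.data, d.data]), is_dff=True)
        t1 = motifs.correlation_trace(d, template_16)
        t2 = motifs.correlation_trace(doubled, template_16)
        thr = t1.threshold()
        n1 = len(motifs.detect_events(t1, thr))
        n2 = len(motifs.detect_events(t2, thr))
        assert abs(n2 - 2 * n1) <= 1  # boundary effects only
        f1 = motifs.motif_frequency(motifs.detect_events(t1, thr), d.n_frames)
        f2 = motifs.motif_frequency(motifs.detect_events(t2, thr), doubled.n_frames)
        assert f2 == pytest.approx(f1, rel=0.15)

    def test_most_represented_motif(self):
        assert motifs.most_represented_motif(
            {"forelimb": 2.0, "hindlimb": 1.0, "whisker": 3.0}) == ("whisker", 3.0)

    def test_tie_breaks_in_canonical_order(self):
        assert motifs.most_represented_motif(
            {"whisker": 2.0, "hindlimb": 2.0, "forelimb": 2.0})[0] == "forelimb"

    def test_single_modality(self):
        assert motifs.most_represented_motif({"hindlimb": 0.5}) == ("hindlimb", 0.5)


class TestModalityICC:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["forelimb", "hindlimb", "whisker"])

    def test_consistent_subjects_give_high_icc(self, rng):
        base = np.array([1.0, 4.0, 7.0, 10.0, 13.0])
        table = self._table(np.column_stack([base + rng.normal(0, 0.05, 5)
                                             for _ in range(3)]))
        icc, _ = motifs.modality_icc(table)
        assert icc > 0.9

    def test_permuted_columns_give_low_icc(self, rng):
        iccs = []
        for _ in range(20):
            cols = [rng.permutation(rng.normal(0, 1, 8)) for _ in range(3)]
            icc, _ = motifs.modality_icc(self._table(np.column_stack(cols)))
            iccs.append(icc)
        assert abs(np.mean(iccs)) < 0.2

    def test_icc_increases_with_shared_subject_shift(self, rng):
        means = []
        for shift_sd in (0.0, 1.0, 3.0):
            vals = []
            for rep in range(10):
                shift = rng.normal(0, shift_sd, (8, 1))
                table = self._table(rng.normal(0, 1, (8, 3)) + shift)
                vals.append(motifs.modality_icc(table)[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            motifs.modality_icc(self._table(np.ones((2, 3))))
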