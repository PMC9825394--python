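"""Calcium-trace processing chain: smoothing, bleach correction, dF/F,
peaks, normalization and response drops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipitune.stimuli import DEFAULT_IPIS_MS, StimulusSpec, default_pulse_stimuli
from ipitune.synthetic import SpeciesProfile, _normalized_tuning, simulate_trace
from ipitune.traces import (
    FluorescenceTrace,
    aggregate_trials,
    bleach_correct,
    compute_dff,
    delta_responses,
    moving_average,
    normalize_peaks,
    peak_response,
    process_trace,
)
from ipitune.tuning import tuning_value

PULSE_25 = StimulusSpec(kind="pulse_song", ipi_ms=25.0)


def make_trace(values, stim=PULSE_25):
    return FluorescenceTrace(
        values=np.asarray(values, dtype=float),
        stim=stim,
        individual_id="t",
        species="melanogaster",
    )


class TestMovingAverage:
    def test_hand_computed_shrunken_edges(self):
        out = moving_average([0, 3, 0, 3, 0], window=3)
        assert np.allclose(out, [1.5, 1, 2, 1, 1.5])

    def test_constant_series_invariant(self):
        assert np.allclose(moving_average(np.full(20, 7.0)), 7.0)

    def test_window_one_is_identity(self, rng):
        v = rng.standard_normal(30)
        assert np.array_equal(moving_average(v, window=1), v)

    def test_rejects_bad_windows(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], window=3)
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0, 3.0], window=2)


class TestBleachCorrect:
    def test_linear_trace_becomes_baseline_constant(self):
        t = np.arange(60) / 10.0
        trace = make_trace(50.0 - 2.0 * t)
        out = bleach_correct(trace)
        base = (50.0 - 2.0 * t)[(t >= 0.0) & (t < 1.0)].mean()
        assert np.allclose(out, base)

    def test_zero_slope_is_identity(self):
        trace = make_trace(np.full(60, 42.0))
        assert np.allclose(bleach_correct(trace), 42.0)

    def test_transient_outside_windows_preserved_vs_manual_ols(self):
        t = np.arange(60) / 10.0
        transient = np.where((t >= 1.5) & (t < 3.0), 5.0, 0.0)
        raw = 80.0 - 1.2 * t + transient
        trace = make_trace(raw)
        out = bleach_correct(trace)
        # manual OLS on the frames in [0,1) u [4,5): transient is zero there
        mask = ((t >= 0) & (t < 1)) | ((t >= 4) & (t < 5))
        slope, intercept = np.polyfit(t[mask], raw[mask], 1)
        line = intercept + slope * t
        expected = raw - (line - line[(t >= 0) & (t < 1)].mean())
        assert np.allclose(out, expected)
        # transient retained at full amplitude on top of a flat baseline
        assert out[(t >= 1.5) & (t < 3.0)].mean() - out[t < 1].mean() == pytest.approx(5.0)

    def test_fit_residuals_sum_to_zero_in_windows(self):
        rng = np.random.default_rng(5)
        t = np.arange(60) / 10.0
        raw = 90 - 0.7 * t + 0.3 * rng.standard_normal(60)
        trace = make_trace(raw)
        mask = ((t >= 0) & (t < 1)) | ((t >= 4) & (t < 5))
        slope, intercept = np.polyfit(t[mask], raw[mask], 1)
        assert np.sum(raw[mask] - (intercept + slope * t[mask])) == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        raw = 100 - 0.5 * np.arange(60) / 10 + 0.4 * rng.standard_normal(60)
        trace = make_trace(raw)
        once = bleach_correct(trace)
        twice = bleach_correct(trace, values=once)
        assert np.allclose(once, twice, rtol=1e-9, atol=1e-9)

    def test_degenerate_windows_rejected(self):
        trace = make_trace(np.full(60, 1.0))
        with pytest.raises(ValueError):
            bleach_correct(trace, windows=[(0.0, 0.1)])  # single frame


class TestComputeDff:
    def test_constant_series_gives_zero(self):
        trace = make_trace(np.full(60, 33.0))
        proc = compute_dff(np.full(60, 33.0), trace)
        assert np.allclose(proc.dff, 0.0)
        assert proc.f_base == pytest.approx(33.0)

    def test_doubling_gives_one(self):
        trace = make_trace(np.full(60, 10.0))
        corrected = np.full(60, 10.0)
        corrected[12:20] = 20.0
        proc = compute_dff(corrected, trace)
        assert np.allclose(proc.dff[12:20], 1.0)

    def test_baseline_mean_dff_is_zero(self):
        rng = np.random.default_rng(7)
        raw = 100 + rng.standard_normal(60)
        trace = make_trace(raw)
        proc = compute_dff(bleach_correct(trace), trace)
        assert abs(proc.dff[:10].mean()) < 1e-12

    def test_nonpositive_baseline_rejected(self):
        trace = make_trace(np.full(60, 1.0))
        with pytest.raises(ValueError, match="non-positive baseline"):
            compute_dff(np.full(60, -3.0), trace)

    @given(k=st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(8)
        raw = 100 - 0.4 * np.arange(60) / 10 + rng.standard_normal(60)
        raw[15:25] += 20
        t1 = make_trace(raw)
        t2 = make_trace(k * raw)
        d1 = process_trace(t1).dff
        d2 = process_trace(t2).dff
        assert np.allclose(d1, d2, rtol=1e-9, atol=1e-12)


class TestPeakResponse:
    def test_zero_everywhere(self):
        trace = make_trace(np.full(60, 5.0))
        proc = compute_dff(np.full(60, 5.0), trace)
        assert peak_response(proc) == 0.0

    def test_spike_inside_window(self):
        trace = make_trace(np.full(60, 5.0))
        corrected = np.full(60, 5.0)
        corrected[14] = 6.0  # t=1.4s, inside stimulus period
        assert peak_response(compute_dff(corrected, trace)) == pytest.approx(0.2)

    def test_late_spike_excluded(self):
        # 25 ms x 20 pulses: period [1.0, 1.0+0.5+0.5) s; spike at 3.0 s
        trace = make_trace(np.full(60, 5.0))
        corrected = np.full(60, 5.0)
        corrected[30] = 50.0
        corrected[12] = 5.5
        assert peak_response(compute_dff(corrected, trace)) == pytest.approx(0.1)


class TestAggregateAndNormalize:
    def test_single_trial_identity(self):
        assert aggregate_trials({25.0: [0.4]}) == {25.0: 0.4}

    def test_mean_and_order_invariance(self):
        assert aggregate_trials({25.0: [0.1, 0.2, 0.3]})[25.0] == pytest.approx(0.2)
        assert aggregate_trials({25.0: [0.3, 0.1, 0.2]})[25.0] == pytest.approx(0.2)

    def test_missing_trials_fail(self):
        with pytest.raises(ValueError, match="no trials"):
            aggregate_trials({25.0: []})

    def test_uniform_peaks(self):
        curve = normalize_peaks(np.ones(10), DEFAULT_IPIS_MS)
        assert np.allclose(curve.normalized_peaks, 0.1)

    def test_scale_invariance(self, rng):
        raw = rng.uniform(0.05, 1.0, 10)
        c1 = normalize_peaks(raw, DEFAULT_IPIS_MS)
        c2 = normalize_peaks(2 * raw, DEFAULT_IPIS_MS)
        assert np.allclose(c1.normalized_peaks, c2.normalized_peaks)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError):
            normalize_peaks(np.zeros(10), DEFAULT_IPIS_MS)

    def test_reference_shape_peaks_at_25ms(self, mel_average_params):
        raw = tuning_value(mel_average_params, np.array(DEFAULT_IPIS_MS))
        curve = normalize_peaks(raw, DEFAULT_IPIS_MS)
        assert curve.normalized_peaks.sum() == pytest.approx(1.0, abs=1e-12)
        assert curve.ipis_ms[np.argmax(curve.normalized_peaks)] == 25.0


class TestDeltaResponses:
    def test_direct_subtraction(self):
        peaks = np.full(10, 0.1)
        peaks[0], peaks[1] = 0.10, 0.15  # 15 and 25 ms
        peaks[2] = 0.05
        curve = normalize_peaks(peaks, DEFAULT_IPIS_MS)
        d = delta_responses(curve).set_index("ipi_ms")["delta_response"]
        norm = peaks / peaks.sum()
        assert d[15.0] == pytest.approx(norm[1] - norm[0])
        assert d[35.0] == pytest.approx(norm[1] - norm[2])
        assert 25.0 not in d.index

    def test_equal_reference_gives_zero(self):
        peaks = np.full(10, 0.1)
        curve = normalize_peaks(peaks, DEFAULT_IPIS_MS)
        assert np.allclose(delta_responses(curve)["delta_response"], 0.0)

    def test_missing_reference_fails(self):
        curve = normalize_peaks(np.ones(9), [15, 35, 45, 55, 65, 75, 85, 95, 105])
        with pytest.raises(ValueError, match="reference IPI"):
            delta_responses(curve)

    def test_simulans_drop_at_15ms_exceeds_melanogaster(
        self, mel_average_params, sim_average_params
    ):
        """The stronger fast inhibition in D. simulans deepens the 15-ms drop."""
        x = np.array(DEFAULT_IPIS_MS)
        d = {}
        for label, p in (("mel", mel_average_params), ("sim", sim_average_params)):
            curve = normalize_peaks(tuning_value(p, x), x)
            d[label] = delta_responses(curve).set_index("ipi_ms")["delta_response"][15.0]
        assert d["sim"] > d["mel"]


def test_end_to_end_round_trip_zero_noise():
    """Noiseless synthetic traces reproduce the generating normalized tuning
    to well within 2% per IPI after the full processing chain."""
    prof = SpeciesProfile(
        species_label="melanogaster",
        param_means=(0.2017, 83.9797, 1.8644, 3.8980),
        trace_noise_sd=0.0,
        bleach_slope_range=(-0.35, -0.35),
    )
    params = prof.mean_params
    raw = []
    for stim in default_pulse_stimuli():
        tr = simulate_trace(params, stim, prof, seed=1)
        raw.append(peak_response(process_trace(tr)))
    curve = normalize_peaks(raw, list(DEFAULT_IPIS_MS))
    truth = _normalized_tuning(params)
    assert np.all(np.abs(curve.normalized_peaks - truth) / truth < 0.02)


def test_trace_rejects_non_finite_values():
    values = np.ones(60)
    values[3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        make_trace(values)
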