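import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from septaquant import (
    aggregate_ring_stats,
    detect_rings,
    fwhm,
    mean_trace,
    movie_midline_trace,
    preset,
    ring_spacings,
    ring_time_trace,
    simulate_movie,
)
from septaquant.imgio import TimeLapseStack
from septaquant.kymo import LineProfile
from septaquant.rings import RingPeak, RingTrace
from conftest import make_profile_array
from oracles import oracle_detect_indices, oracle_gaussian_fwhm


def profile_from(y, spacing_um=0.1):
    y = np.asarray(y, dtype=float)
    return LineProfile(np.arange(y.size) * spacing_um, y)


def gaussian_bump(n, centre, sigma, amplitude, baseline=0.0):
    x = np.arange(n, dtype=float)
    return baseline + amplitude * np.exp(-0.5 * ((x - centre) / sigma) ** 2)


# ---------------------------------------------------------------------------
# detection


def test_intensity_filter_keeps_only_bright_peak():
    """Two bumps at 150 and 80 AU with the 100 AU filter: only the bright
    one survives as a ring."""
    y = gaussian_bump(80, 20, 3, 150.0) + gaussian_bump(80, 60, 3, 80.0)
    peaks = detect_rings(profile_from(y), min_intensity=100.0)
    assert len(peaks) == 1
    assert peaks[0].position == pytest.approx(2.0, abs=0.051)


def test_constant_profile_has_no_rings():
    assert detect_rings(profile_from(np.full(50, 200.0))) == []


def test_five_equal_bumps_at_construction_positions():
    y = np.zeros(120)
    centres = [20, 40, 60, 80, 100]
    for c in centres:
        y += gaussian_bump(120, c, 2.5, 200.0)
    peaks = detect_rings(profile_from(y), min_intensity=100.0)
    assert len(peaks) == 5
    for peak, c in zip(peaks, centres):
        assert peak.position == pytest.approx(c * 0.1, abs=0.051)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 10**6), st.integers(8, 64))
def test_detection_matches_bruteforce_oracle(seed, n):
    """detect_rings agrees index-for-index with a literal enumeration of
    the local-maximum, threshold and separation rules."""
    rng = np.random.default_rng(seed)
    y = make_profile_array(n, rng)
    peaks = detect_rings(profile_from(y), min_intensity=100.0, min_separation_px=3)
    got = [int(round(p.position / 0.1)) for p in peaks]
    assert got == oracle_detect_indices(y, 100.0, 3)


def test_raising_threshold_never_adds_rings():
    rng = np.random.default_rng(42)
    for _ in range(20):
        y = make_profile_array(64, rng)
        counts = [
            len(detect_rings(profile_from(y), min_intensity=t))
            for t in (50.0, 100.0, 150.0, 250.0)
        ]
        assert counts == sorted(counts, reverse=True)


def test_prominence_option_filters_on_height_above_baseline():
    y = gaussian_bump(60, 30, 3, 80.0, baseline=100.0)  # apex 180, prominence 80
    assert len(detect_rings(profile_from(y), min_intensity=100.0)) == 1
    assert (
        detect_rings(profile_from(y), min_intensity=100.0, use_prominence=True) == []
    )


# ---------------------------------------------------------------------------
# FWHM


@pytest.mark.parametrize("sigma", [2.0, 3.0, 5.0])
def test_fwhm_matches_analytic_gaussian_width(sigma):
    y = gaussian_bump(80, 40, sigma, 300.0)
    profile = profile_from(y, spacing_um=1.0)  # report width in px
    width, left, right, baseline, censored = fwhm(profile, 40)
    assert not censored
    expected = oracle_gaussian_fwhm(sigma)
    assert expected == pytest.approx(2.0 * np.sqrt(2 * np.log(2)) * sigma, rel=1e-9)
    assert width == pytest.approx(expected, abs=0.1)


def test_fwhm_triangular_peak_is_exact():
    y = np.zeros(20)
    y[6:13] = [0, 100, 200, 400, 200, 100, 0]  # apex at 9, zero at 9±3... scaled
    y = np.zeros(20)
    apex = 10
    for i in range(20):
        y[i] = max(0.0, 1.0 - abs(i - apex) / 4.0) * 400.0
    width, left, right, baseline, censored = fwhm(profile_from(y, 1.0), apex)
    assert (width, censored) == (pytest.approx(4.0), False)
    assert left == pytest.approx(8.0) and right == pytest.approx(12.0)


def test_fwhm_rectangular_pulse():
    y = np.zeros(20)
    y[7:13] = 200.0  # plateau of 6 samples
    profile = profile_from(y, 1.0)
    peaks = detect_rings(profile, min_intensity=100.0)
    assert len(peaks) == 1
    width, left, right, baseline, censored = fwhm(profile, int(peaks[0].position))
    assert width == pytest.approx(6.0)


def test_edge_peak_is_censored():
    y = np.linspace(0, 300, 30)  # monotone ramp: apex at the right edge
    y[-2] = 310.0  # local max adjacent to the edge, half level never crossed
    width, left, right, baseline, censored = fwhm(profile_from(y, 1.0), 28)
    assert censored and np.isnan(width)


# ---------------------------------------------------------------------------
# spacings


def _peak_at(pos, hid="h0"):
    return RingPeak(hid, pos, 200.0, 50.0, 0.4, pos - 0.2, pos + 0.2, False)


def test_ring_spacings_order_invariant():
    sorted_peaks = [_peak_at(p) for p in (5.0, 15.0, 25.0)]
    np.testing.assert_allclose(ring_spacings(sorted_peaks), [10.0, 10.0])
    shuffled = [_peak_at(p) for p in (25.0, 5.0, 15.0)]
    np.testing.assert_allclose(ring_spacings(shuffled), [10.0, 10.0])
    assert ring_spacings([_peak_at(7.0)]).size == 0


# ---------------------------------------------------------------------------
# ROI traces


def test_constant_stack_gives_constant_trace():
    frames = np.full((6, 40, 80), 33.0)
    stack = TimeLapseStack(frames, 10.0, 0.1)
    from septaquant.imgio import MidlineTrace

    midline = MidlineTrace("h", [[10.0, 20.0], [70.0, 20.0]], 0.1)
    trace = ring_time_trace(stack, midline, ring_position=3.0)
    np.testing.assert_allclose(trace.mean_roi_intensity, 33.0)
    np.testing.assert_allclose(trace.times, np.arange(6) * 10.0)
    with pytest.raises(ValueError, match="outside"):
        ring_time_trace(stack, midline, ring_position=9.0)


def test_noiseless_ring_trace_peaks_at_truth_frame(tiny_config):
    """Trace argmax lands on the true peak frame and the maximum matches
    the render-model expectation of the ROI mean within 5%."""
    cfg = tiny_config.replace(
        shot_noise_scale=0.0, read_noise_sigma=0.0, cyto_mod_cv=0.0,
        ring_amplitude_cv=0.0, ring_onset_jitter_frames=0,
    )
    stack, truth = simulate_movie(cfg)
    midline = movie_midline_trace(truth, cfg)
    # a ring inside the initial hyphal extent, so the pre-onset ROI already
    # holds the full cytoplasmic signal and max - min isolates the ring
    ring = truth.rings[0]
    assert ring.arc_position < cfg.initial_length
    trace = ring_time_trace(stack, midline, ring.arc_position)
    assert int(np.argmax(trace.mean_roi_intensity)) == ring.peak_frame

    # model-implied expected ROI mean at the peak: background + the mean over
    # the 10x20 ROI of (cyto + sum of ring Gaussians) * transverse ridge
    px = cfg.pixel_size
    along = (np.arange(10) - 5) * px + ring.arc_position
    across = np.arange(-10, 10, dtype=float)
    axial = np.full(along.size, cfg.cyto_level)
    for other in truth.rings:
        axial += other.amplitude * np.exp(
            -0.5 * ((along - other.arc_position) / other.axial_sigma) ** 2
        )
    ridge = np.exp(-0.5 * (across / ((cfg.hypha_width / 2.3548) / px)) ** 2)
    expected_signal = np.outer(ridge, axial).mean()
    measured = trace.mean_roi_intensity.max() - trace.mean_roi_intensity.min()
    assert measured == pytest.approx(
        expected_signal - cfg.cyto_level * ridge.mean(), rel=0.05
    )


def test_background_roi_trace_stays_at_background(tiny_config):
    cfg = tiny_config.replace(shot_noise_scale=0.0, read_noise_sigma=0.0)
    stack, truth = simulate_movie(cfg)
    midline = movie_midline_trace(truth, cfg)
    # far from any ring: a position in the old, ring-free part of the hypha
    trace = ring_time_trace(stack, midline, ring_position=3.0)
    spread = trace.mean_roi_intensity.max() - trace.mean_roi_intensity.min()
    assert spread < 2.0  # only growth/bleach-free constant content


# ---------------------------------------------------------------------------
# trace averaging


def _const_trace(value, n=6, hid="h0"):
    return RingTrace(hid, 0, np.arange(n) * 10.0, np.full(n, float(value)))


def test_mean_trace_identical_traces():
    t, m, sem, n = mean_trace([_const_trace(40.0)] * 5)
    np.testing.assert_allclose(m, 40.0)
    np.testing.assert_allclose(sem, 0.0)
    assert np.all(n == 5)


def test_mean_trace_two_constants():
    t, m, sem, n = mean_trace([_const_trace(10.0), _const_trace(20.0)])
    np.testing.assert_allclose(m, 15.0)
    np.testing.assert_allclose(sem, 5.0)  # |a-b|/2


def test_mean_trace_mixed_intervals_rejected():
    a = _const_trace(10.0)
    b = RingTrace("h1", 0, np.arange(6) * 5.0, np.full(6, 10.0))
    with pytest.raises(ValueError, match="interval"):
        mean_trace([a, b])


def test_onset_alignment_registers_shifted_kinetics():
    """Two copies of one kinetic profile, one delayed by 2 frames, align
    onto each other in onset mode (s.e.m. 0 where both contribute)."""
    kinetic = np.array([0, 0, 0, 50, 100, 150, 100, 50, 0, 0], dtype=float)
    a = RingTrace("h0", 0, np.arange(10) * 10.0, kinetic)
    b = RingTrace("h1", 0, np.arange(10) * 10.0, np.roll(kinetic, 2))
    t, m, sem, n = mean_trace([a, b], align="onset")
    np.testing.assert_allclose(sem[n == 2], 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# replicate aggregation


def test_identical_widths_have_zero_ci():
    peaks = {f"h{i}": [_peak_at(1.0 + j, f"h{i}") for j in range(3)] for i in range(2)}
    summary = aggregate_ring_stats(peaks)
    rep = summary.replicates[0]
    assert rep.ci_width == pytest.approx(0.0)
    assert rep.n_rings == 6


def test_two_width_ci_matches_t_quantile():
    peaks = {
        "h0": [
            RingPeak("h0", 1.0, 200.0, 50.0, 4.0, 0.0, 4.0, False),
            RingPeak("h0", 9.0, 200.0, 50.0, 6.0, 7.0, 13.0, False),
        ]
    }
    summary = aggregate_ring_stats(peaks)
    rep = summary.replicates[0]
    assert rep.mean_width == pytest.approx(5.0)
    se = np.std([4.0, 6.0], ddof=1) / np.sqrt(2)
    assert rep.ci_width == pytest.approx(stats.t.ppf(0.975, 1) * se)


def test_censored_rings_excluded_but_counted():
    peaks = {
        "h0": [
            RingPeak("h0", 1.0, 200.0, 50.0, 4.0, 0.0, 4.0, False),
            RingPeak("h0", 5.0, 120.0, 50.0, float("nan"), float("nan"), float("nan"), True),
        ]
    }
    summary = aggregate_ring_stats(peaks)
    rep = summary.replicates[0]
    assert rep.mean_width == pytest.approx(4.0)
    assert rep.n_censored == 1 and rep.n_rings == 2


def test_no_usable_rings_raises():
    with pytest.raises(ValueError, match="no usable rings"):
        aggregate_ring_stats({"h0": []})
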