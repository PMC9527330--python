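import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergpheno import signal
from ergpheno.config import RunConfig
from ergpheno.errors import ValidationError
from ergpheno.signal import (
    STD_GRID,
    ComponentMeasure,
    RawTrace,
    StdTrace,
    baseline_correct,
    detect_components,
    flicker_signal_magnitude,
    resample,
    select_traces_flicker,
    select_traces_mse,
    standardize,
)

from conftest import flash_wave, make_key, make_std


# ---------------------------------------------------------------- baseline

def test_baseline_hand_arithmetic():
    # five post-zero samples 1..5 -> mean 3 subtracted everywhere
    t = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
    v = np.array([10.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    out = baseline_correct(RawTrace(make_key(), t, v))
    np.testing.assert_allclose(out.voltage_uV, v - 3.0)


def test_baseline_constant_trace_becomes_zero():
    t = np.arange(0, 81, 0.5)
    out = baseline_correct(RawTrace(make_key(), t, np.full(t.size, 7.0)))
    np.testing.assert_allclose(out.voltage_uV, 0.0)


def test_baseline_idempotent():
    rng = np.random.default_rng(0)
    t = np.arange(0, 81, 0.5)
    tr = baseline_correct(RawTrace(make_key(), t, rng.normal(0, 50, t.size)))
    again = baseline_correct(tr)
    np.testing.assert_allclose(again.voltage_uV, tr.voltage_uV, atol=1e-12)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_baseline_postcondition_property(seed):
    rng = np.random.default_rng(seed)
    t = np.arange(0, 81, 0.5)
    out = baseline_correct(RawTrace(make_key(), t, rng.normal(0, 100, t.size)))
    post = out.voltage_uV[np.flatnonzero(t > 0)[:5]]
    assert abs(post.mean()) < 1e-9


def test_baseline_too_few_post_zero_samples():
    with pytest.raises(ValidationError):
        baseline_correct(RawTrace(make_key(), np.array([0.0, 1.0, 2.0]), np.zeros(3)))


# ---------------------------------------------------------------- resample

def test_resample_identity_on_grid():
    v = np.sin(STD_GRID / 7.0)
    out = resample(RawTrace(make_key(), STD_GRID, v))
    np.testing.assert_allclose(out.voltage_uV, v)


def test_resample_preserves_linear_function():
    t = np.arange(0.0, 83.0, 0.37)
    out = resample(RawTrace(make_key(), t, 2.0 * t))
    np.testing.assert_allclose(out.voltage_uV, 2.0 * STD_GRID, atol=1e-9)


def test_resample_refuses_short_span():
    t = np.arange(0.0, 60.0, 0.5)
    with pytest.raises(ValidationError):
        resample(RawTrace(make_key(), t, np.zeros(t.size)))


# ---------------------------------------------------------------- selection

def _oracle_min_mse_triple(voltages):
    """Independent exhaustive search over all triples."""
    n = len(voltages)
    best, best_score = None, np.inf
    for idx in itertools.combinations(range(n), 3):
        score = 0.0
        for i, j in itertools.combinations(idx, 2):
            score += np.mean((voltages[i] - voltages[j]) ** 2)
        if score < best_score:
            best, best_score = idx, score
    return best


def _repeats(voltages):
    return [make_std(v, repeat=i + 1) for i, v in enumerate(voltages)]


def test_select_mse_n3_returns_all():
    reps = _repeats(np.random.default_rng(0).normal(size=(3, 161)))
    sel = select_traces_mse(reps)
    assert sel.repeats == [1, 2, 3] and not sel.flagged


def test_select_mse_rejects_blink_contaminated():
    rng = np.random.default_rng(1)
    base = flash_wave()
    voltages = np.stack([base + rng.normal(0, 3, 161) for _ in range(5)])
    blink = 300.0 * np.exp(-((STD_GRID - 40.0) ** 2) / (2 * 8.5**2))
    voltages[1] += blink
    voltages[3] += blink * 0.8
    sel = select_traces_mse(_repeats(voltages))
    assert sel.repeats == [1, 3, 5]
    oracle = _oracle_min_mse_triple(voltages)
    assert tuple(r - 1 for r in sel.repeats) == oracle


def test_select_mse_tie_break_first_indices():
    reps = _repeats(np.tile(flash_wave(), (6, 1)))
    assert select_traces_mse(reps).repeats == [1, 2, 3]


def test_select_mse_two_repeats_flagged():
    sel = select_traces_mse(_repeats(np.zeros((2, 161))))
    assert sel.repeats == [1, 2] and sel.flagged


def test_select_mse_single_repeat_errors():
    with pytest.raises(ValidationError):
        select_traces_mse(_repeats(np.zeros((1, 161))))


@given(st.integers(0, 2**32 - 1), st.integers(4, 8))
@settings(max_examples=40, deadline=None)
def test_select_mse_matches_oracle_property(seed, n):
    rng = np.random.default_rng(seed)
    voltages = rng.normal(0, 50, size=(n, 161))
    sel = select_traces_mse(_repeats(voltages))
    assert tuple(r - 1 for r in sel.repeats) == _oracle_min_mse_triple(voltages)


def test_select_flicker_ordering():
    t = STD_GRID
    voltages = [a * np.sin(2 * np.pi * 30 * t / 1000.0) for a in (1.0, 2.0, 3.0, 4.0)]
    sel = select_traces_flicker([make_std(v, stimulus="LA30Hz", repeat=i + 1)
                                 for i, v in enumerate(voltages)])
    assert sel.repeats == [2, 3, 4]


def test_select_flicker_n3_returns_all():
    reps = [make_std(np.zeros(161), stimulus="LA30Hz", repeat=i + 1) for i in range(3)]
    assert select_traces_flicker(reps).repeats == [1, 2, 3]


def test_flicker_magnitude_matches_quadrature_oracle():
    rng = np.random.default_rng(3)
    v = rng.normal(0, 10, 161)
    # oracle: correlation with sine and cosine in quadrature
    w = 2 * np.pi * 30 * STD_GRID / 1000.0
    oracle = np.hypot(np.sum(v * np.cos(w)), np.sum(v * np.sin(w)))
    assert flicker_signal_magnitude(v) == pytest.approx(oracle, rel=1e-9)


# ---------------------------------------------------------------- detection

def _noiseless_oracle_flash(v, a_start=8.0, b_cut=20.0):
    """Argmin/argmax oracle on the noiseless model trace."""
    mask_a = STD_GRID >= a_start
    ia = np.argmin(np.where(mask_a, v, np.inf))
    after = STD_GRID > STD_GRID[ia]
    mask_b = after & (STD_GRID >= b_cut)
    ib = np.argmax(np.where(mask_b, v, -np.inf))
    return STD_GRID[ia], STD_GRID[ib]


@pytest.mark.parametrize("stim,a_time,b_time,a_amp,b_amp,sa,sb", [
    ("DA10", 15.0, 45.0, 250.0, 400.0, 4.0, 12.0),
    ("DA10", 18.0, 52.0, 120.0, 200.0, 3.0, 10.0),
    ("LA3", 15.0, 30.0, 40.0, 120.0, 3.0, 6.0),
    ("LA3", 20.0, 36.0, 25.0, 90.0, 2.0, 5.0),
])
def test_detect_flash_matches_noiseless_oracle(run_config, stim, a_time, b_time,
                                               a_amp, b_amp, sa, sb):
    v = flash_wave(a_amp, a_time, b_amp, b_time, sa, sb)
    m = detect_components(make_std(v, stimulus=stim), stim, run_config)
    ta, tb = _noiseless_oracle_flash(v)
    assert m.quality_ok
    assert abs(m.a_time_ms - ta) <= 0.5
    assert abs(m.b_time_ms - tb) <= 0.5


@pytest.mark.parametrize("sa,sb,a_time,b_time,stim", [
    (2.0, 4.0, 16.0, 30.0, "LA3"),
    (3.0, 6.0, 15.0, 32.0, "LA3"),
    (4.0, 12.0, 16.0, 46.0, "DA10"),
])
def test_detect_amplitudes_within_2pct(run_config, sa, sb, a_time, b_time, stim):
    # narrow lobes paired with their physiologic (overlapping) spacing
    v = flash_wave(200.0, a_time, 350.0, b_time, sa, sb)
    m = detect_components(make_std(v), stim, run_config)
    true_a = abs(v[0] - v.min())
    true_b = v.max() - v.min()
    assert m.a_amp_uV == pytest.approx(true_a, rel=0.02)
    assert m.b_amp_uV == pytest.approx(true_b, rel=0.02)


def test_detect_flat_trace_flagged(run_config):
    m = detect_components(make_std(np.zeros(161)), "DA10", run_config)
    assert not m.quality_ok and np.isnan(m.a_time_ms)


def test_detect_measurement_convention(run_config):
    # trough -100 then peak +200 -> a_amp 100, b_amp 300
    v = flash_wave(100.0, 20.0, 200.0, 45.0, 4.0, 6.0)
    m = detect_components(make_std(v), "DA10", run_config)
    assert m.a_amp_uV == pytest.approx(100.0, rel=0.02)
    assert m.b_amp_uV == pytest.approx(300.0, rel=0.02)
    assert m.b_time_ms > m.a_time_ms


def test_detect_flicker(run_config):
    amp, phase = 90.0, 8.0
    arg = 2 * np.pi * (STD_GRID - phase) / 1000.0
    v = amp * np.sin(30 * arg) + 0.2 * amp * np.sin(60 * arg)
    m = detect_components(make_std(v, stimulus="LA30Hz"), "LA30Hz", run_config)
    assert m.quality_ok
    # oracle: first local minimum after the cutoff, then the following maximum
    interior = np.arange(1, 160)
    minima = interior[(v[interior] <= v[interior - 1])
                      & (v[interior] <= v[interior + 1])
                      & (STD_GRID[interior] >= 5.0)]
    lo = minima[0]
    maxima = interior[(v[interior] >= v[interior - 1])
                      & (v[interior] >= v[interior + 1]) & (interior > lo)]
    hi = maxima[0]
    assert abs(m.peak_time_ms - STD_GRID[hi]) <= 0.5
    assert m.peak_amp_uV == pytest.approx(v[hi] - v[lo], rel=0.02)


def test_peak_times_unbiased_under_noise(run_config):
    rng = np.random.default_rng(11)
    errors = []
    clean = flash_wave(250.0, 15.0, 400.0, 48.0)
    truth_a, _ = _noiseless_oracle_flash(clean)
    for _ in range(500):
        v = clean + rng.normal(0, 5.0, 161)
        m = detect_components(make_std(v), "DA10", run_config)
        if m.quality_ok:
            errors.append(m.a_time_ms - truth_a)
    assert len(errors) > 450
    assert abs(np.mean(errors)) <= 0.5


# ---------------------------------------------------------------- summarizing

def test_measure_selected_identical_eyes(run_config):
    v = flash_wave()
    sel = [
        signal.SelectedTraces("P0", eye, "DA10", [1, 2, 3], np.tile(v, (3, 1)))
        for eye in ("L", "R")
    ]
    eye_df, pat_df = signal.measure_selected(sel, run_config)
    assert len(eye_df) == 2 and len(pat_df) == 1
    assert pat_df["b_amp_uV"].iloc[0] == pytest.approx(eye_df["b_amp_uV"].iloc[0])


def test_measure_selected_eye_mean(run_config):
    v1 = flash_wave(b_amp=300.0)
    v2 = flash_wave(b_amp=330.0)
    sel = [
        signal.SelectedTraces("P0", "L", "DA10", [1], v1[None, :]),
        signal.SelectedTraces("P0", "R", "DA10", [1], v2[None, :]),
    ]
    eye_df, pat_df = signal.measure_selected(sel, run_config)
    expected = eye_df["b_amp_uV"].mean()
    assert pat_df["b_amp_uV"].iloc[0] == pytest.approx(expected)


def test_measure_unmeasurable_flagged_missing(run_config):
    sel = [signal.SelectedTraces("P0", "L", "DA10", [1], np.zeros((1, 161)))]
    eye_df, pat_df = signal.measure_selected(sel, run_config)
    assert not pat_df["quality_ok"].iloc[0]
    assert np.isnan(pat_df["a_amp_uV"].iloc[0])


def test_b_time_after_a_time_on_cohort(small_cohort, run_config):
    sel = signal.preprocess_and_select(small_cohort.traces, run_config)
    eye_df, _ = signal.measure_selected(sel, run_config)
    flash = eye_df[eye_df["stimulus"].isin(["DA10", "LA3"])].dropna(
        subset=["a_time_ms", "b_time_ms"]
    )
    assert (flash["b_time_ms"] > flash["a_time_ms"]).all()


def test_cohort_eye_and_patient_counts(small_cohort, run_config):
    sel = signal.preprocess_and_select(small_cohort.traces, run_config)
    eye_df, pat_df = signal.measure_selected(sel, run_config)
    # 58 bilateral + 2 unilateral patients, 3 stimuli each
    assert len(eye_df) == (58 * 2 + 2) * 3
    assert len(pat_df) == 60 * 3


def test_trace_table_round_trip(small_cohort):
    df = signal.raw_to_trace_table(small_cohort.traces[:10])
    back = signal.trace_table_to_raw(df)
    orig = sorted(small_cohort.traces[:10], key=lambda t: (
        t.key.patient_id, t.key.eye, t.key.stimulus, t.key.repeat))
    for a, b in zip(orig, back):
        assert a.key == b.key
        np.testing.assert_array_equal(a.voltage_uV, b.voltage_uV)
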