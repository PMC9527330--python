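"""Preprocessing, automated trace selection, and ERG component measurement.

The measurement chain per (patient, eye, stimulus):

1. resample each repeat onto the standard 0-80 ms grid (0.5 ms steps),
2. baseline-correct (subtract the mean of the five samples directly after
   time zero),
3. select up to three repeats — by minimum summed pairwise mean squared
   error for flash stimuli, by maximum 30 Hz Fourier magnitude for flicker,
4. low-pass filter (zero-phase order-5 Butterworth) and locate components
   via the first qualifying zero crossing of the first derivative,
5. average component values over selected traces, then over eyes.

Amplitude conventions: a-wave amplitude is measured from the value at time
zero down to the trough; b-wave amplitude from the a-trough up to the
b-peak; the flicker peak amplitude from the preceding trough up to the
peak. Times are reported at the grid sample of the derivative crossing;
amplitudes are read from the unfiltered trace.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import nan

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from ergpheno.config import FLASH_STIMULI, FLICKER_STIMULUS, STIMULI, RunConfig
from ergpheno.errors import ValidationError

STD_STEP_MS = 0.5
STD_STOP_MS = 80.0
STD_GRID = STD_STEP_MS * np.arange(161)
N_STD_SAMPLES = 161

#: Wide-format component column names used across the package.
COMPONENT_COLUMNS = ("DA10_a", "DA10_b", "LA3_a", "LA3_b", "LA30Hz_peak")


@dataclass(frozen=True)
class TraceKey:
    patient_id: str
    eye: str
    stimulus: str
    repeat: int


@dataclass
class RawTrace:
    """One repeat's voltage-versus-time series for one eye and stimulus."""

    key: TraceKey
    time_ms: np.ndarray
    voltage_uV: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uV = np.asarray(self.voltage_uV, dtype=float)
        if self.time_ms.size < 2:
            raise ValidationError(f"trace {self.key} needs >= 2 samples")
        if self.time_ms.size != self.voltage_uV.size:
            raise ValidationError(f"trace {self.key}: time/voltage length mismatch")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValidationError(f"trace {self.key}: time not strictly increasing")


@dataclass
class StdTrace:
    """Voltages on the standard 161-sample grid."""

    key: TraceKey
    voltage_uV: np.ndarray

    def __post_init__(self) -> None:
        self.voltage_uV = np.asarray(self.voltage_uV, dtype=float)
        if self.voltage_uV.size != N_STD_SAMPLES:
            raise ValidationError(
                f"standard trace must have {N_STD_SAMPLES} samples, "
                f"got {self.voltage_uV.size}"
            )


@dataclass
class SelectedTraces:
    """The repeats retained for one (patient, eye, stimulus)."""

    patient_id: str
    eye: str
    stimulus: str
    repeats: list[int]
    voltages: np.ndarray  # shape (k, 161)
    flagged: bool = False


@dataclass
class ComponentMeasure:
    """Component measurements for a single trace (flash or flicker)."""

    stimulus: str
    a_amp_uV: float = nan
    a_time_ms: float = nan
    b_amp_uV: float = nan
    b_time_ms: float = nan
    peak_amp_uV: float = nan
    peak_time_ms: float = nan
    quality_ok: bool = True


def baseline_correct(trace: RawTrace) -> RawTrace:
    """Shift a trace so the mean of the five samples directly after t=0 is zero."""
    post = np.flatnonzero(trace.time_ms > 0)
    if post.size < 5:
        raise ValidationError(
            f"trace {trace.key}: need >= 5 samples after t=0, got {post.size}"
        )
    shift = trace.voltage_uV[post[:5]].mean()
    return RawTrace(trace.key, trace.time_ms, trace.voltage_uV - shift)


def _baseline_std(voltage: np.ndarray) -> np.ndarray:
    # samples 1..5 are the 0.5-2.5 ms grid points
    return voltage - voltage[1:6].mean()


def resample(trace: RawTrace) -> StdTrace:
    """Linearly interpolate a trace onto the standard 0-80 ms grid."""
    t = trace.time_ms
    if t[0] > 1e-9 or t[-1] < STD_STOP_MS - 1e-9:
        raise ValidationError(
            f"trace {trace.key}: samples must span [0, {STD_STOP_MS}] ms, "
            f"got [{t[0]}, {t[-1]}]"
        )
    return StdTrace(trace.key, np.interp(STD_GRID, t, trace.voltage_uV))


def standardize(trace: RawTrace) -> StdTrace:
    """Resample onto the standard grid, then baseline-correct."""
    std = resample(trace)
    return StdTrace(std.key, _baseline_std(std.voltage_uV))


def _pairwise_mse_score(voltages: np.ndarray, idx: tuple[int, ...]) -> float:
    total = 0.0
    for i, j in itertools.combinations(idx, 2):
        d = voltages[i] - voltages[j]
        total += float(np.mean(d * d))
    return total


def select_traces_mse(repeats: list[StdTrace], k: int = 3) -> SelectedTraces:
    """Select the ``k`` mutually most consistent repeats of a flash stimulus.

    Exhaustive search over all C(n, k) subsets for the one minimizing the
    summed pairwise mean squared difference among its members; ties go to
    the earliest repeat indices. With exactly two repeats both are returned
    and the selection is flagged.
    """
    n = len(repeats)
    if n < 2:
        raise ValidationError("trace selection requires >= 2 repeats")
    first = repeats[0]
    voltages = np.stack([r.voltage_uV for r in repeats])
    if n <= k:
        return SelectedTraces(
            first.key.patient_id,
            first.key.eye,
            first.key.stimulus,
            [r.key.repeat for r in repeats],
            voltages,
            flagged=n == 2,
        )
    best_idx: tuple[int, ...] | None = None
    best_score = np.inf
    for idx in itertools.combinations(range(n), k):
        score = _pairwise_mse_score(voltages, idx)
        if score < best_score:
            best_score = score
            best_idx = idx
    assert best_idx is not None
    return SelectedTraces(
        first.key.patient_id,
        first.key.eye,
        first.key.stimulus,
        [repeats[i].key.repeat for i in best_idx],
        voltages[list(best_idx)],
        flagged=False,
    )


def flicker_signal_magnitude(voltage: np.ndarray, freq_hz: float = 30.0) -> float:
    """Magnitude of the discrete Fourier component at ``freq_hz`` over 0-80 ms."""
    phase = 2.0 * np.pi * freq_hz * STD_GRID / 1000.0
    return float(np.abs(np.sum(voltage * np.exp(-1j * phase))))


def select_traces_flicker(repeats: list[StdTrace], k: int = 3) -> SelectedTraces:
    """Select the ``k`` flicker repeats with the largest 30 Hz signal."""
    n = len(repeats)
    if n < 2:
        raise ValidationError("trace selection requires >= 2 repeats")
    first = repeats[0]
    voltages = np.stack([r.voltage_uV for r in repeats])
    if n <= k:
        return SelectedTraces(
            first.key.patient_id,
            first.key.eye,
            first.key.stimulus,
            [r.key.repeat for r in repeats],
            voltages,
            flagged=n == 2,
        )
    mags = np.array([flicker_signal_magnitude(v) for v in voltages])
    order = np.argsort(-mags, kind="stable")[:k]
    order = np.sort(order)  # keep repeat order within the selection
    return SelectedTraces(
        first.key.patient_id,
        first.key.eye,
        first.key.stimulus,
        [repeats[i].key.repeat for i in order],
        voltages[order],
        flagged=False,
    )


def select_traces(repeats: list[StdTrace], k: int = 3) -> SelectedTraces:
    stim = repeats[0].key.stimulus
    if stim == FLICKER_STIMULUS:
        return select_traces_flicker(repeats, k)
    return select_traces_mse(repeats, k)


def lowpass_filter(voltage: np.ndarray, cutoff_hz: float, order: int = 5) -> np.ndarray:
    """Zero-phase order-``order`` Butterworth low-pass on the standard grid."""
    fs = 1000.0 / STD_STEP_MS
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, voltage)


def _first_crossing(
    deriv: np.ndarray, start: int, kind: str, tol: float = 0.0
) -> int | None:
    """First derivative zero crossing at or after ``start``.

    ``kind="trough"`` looks for negative-to-positive crossings (local
    minima of the trace), ``kind="peak"`` for positive-to-negative ones.
    Sign changes where both derivative samples sit below ``tol`` are
    numerical noise in flat trace regions and are skipped. Returns the
    grid index nearer the zero, or None.
    """
    for i in range(start, deriv.size - 1):
        if kind == "trough":
            hit = deriv[i] <= 0.0 < deriv[i + 1]
        else:
            hit = deriv[i] >= 0.0 > deriv[i + 1]
        if hit and max(abs(deriv[i]), abs(deriv[i + 1])) > tol:
            return i if abs(deriv[i]) < abs(deriv[i + 1]) else i + 1
    return None


def _grid_index(time_ms: float) -> int:
    return int(np.ceil(time_ms / STD_STEP_MS - 1e-9))


def detect_components(
    trace: StdTrace, stimulus: str, config: RunConfig
) -> ComponentMeasure:
    """Locate and measure the a-/b-wave (flash) or trough/peak (flicker).

    A missing qualifying crossing yields NaN fields and ``quality_ok=False``
    rather than an exception.
    """
    if stimulus not in STIMULI:
        raise ValidationError(f"unknown stimulus {stimulus!r}")
    v = trace.voltage_uV
    filtered = lowpass_filter(
        v, config.filter_cutoff_hz[stimulus], config.butterworth_order
    )
    deriv = np.gradient(filtered, STD_STEP_MS)
    tol = 1e-6 * float(np.max(np.abs(deriv)))  # numerical noise floor
    out = ComponentMeasure(stimulus=stimulus)
    cutoffs = config.min_time_ms[stimulus]

    if stimulus in FLASH_STIMULI:
        ia = _first_crossing(deriv, _grid_index(cutoffs["a"]), "trough", tol)
        if ia is None:
            out.quality_ok = False
            return out
        out.a_time_ms = float(STD_GRID[ia])
        out.a_amp_uV = abs(float(v[0] - v[ia]))
        ib = _first_crossing(deriv, max(ia + 1, _grid_index(cutoffs["b"])), "peak", tol)
        if ib is None:
            out.quality_ok = False
            return out
        out.b_time_ms = float(STD_GRID[ib])
        out.b_amp_uV = max(float(v[ib] - v[ia]), 0.0)
    else:
        it = _first_crossing(deriv, _grid_index(cutoffs["trough"]), "trough", tol)
        if it is None:
            out.quality_ok = False
            return out
        ip = _first_crossing(deriv, it + 1, "peak", tol)
        if ip is None:
            out.quality_ok = False
            return out
        out.peak_time_ms = float(STD_GRID[ip])
        out.peak_amp_uV = max(float(v[ip] - v[it]), 0.0)
    return out


def preprocess_and_select(
    traces: list[RawTrace] | pd.DataFrame, config: RunConfig, k: int = 3
) -> list[SelectedTraces]:
    """Standardize every repeat and run trace selection per (patient, eye, stimulus).

    Accepts either a list of :class:`RawTrace` or a long-format trace table.
    """
    if isinstance(traces, pd.DataFrame):
        traces = trace_table_to_raw(traces)
    groups: dict[tuple[str, str, str], list[StdTrace]] = {}
    for tr in traces:
        key = (tr.key.patient_id, tr.key.eye, tr.key.stimulus)
        groups.setdefault(key, []).append(standardize(tr))
    out = []
    for key in sorted(groups):
        reps = sorted(groups[key], key=lambda s: s.key.repeat)
        out.append(select_traces(reps, k))
    return out


def measure_selected(
    selected: list[SelectedTraces], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure components on selected traces; average per eye, then per patient.

    Returns ``(eye_df, patient_df)``. Component columns hold NaN and the
    quality flag is cleared where nothing was measurable.
    """
    value_cols = [
        "a_amp_uV",
        "a_time_ms",
        "b_amp_uV",
        "b_time_ms",
        "peak_amp_uV",
        "peak_time_ms",
    ]
    eye_rows = []
    for sel in selected:
        measures = [
            detect_components(
                StdTrace(TraceKey(sel.patient_id, sel.eye, sel.stimulus, rep), v),
                sel.stimulus,
                config,
            )
            for rep, v in zip(sel.repeats, sel.voltages)
        ]
        row: dict[str, object] = {
            "patient_id": sel.patient_id,
            "eye": sel.eye,
            "stimulus": sel.stimulus,
            "n_traces": len(measures),
        }
        ok = not sel.flagged
        for col in value_cols:
            vals = [getattr(m, col) for m in measures if np.isfinite(getattr(m, col))]
            row[col] = float(np.mean(vals)) if vals else nan
        ok = ok and all(m.quality_ok for m in measures)
        row["quality_ok"] = ok
        eye_rows.append(row)
    eye_df = pd.DataFrame(eye_rows)

    patient_rows = []
    for (pid, stim), grp in eye_df.groupby(["patient_id", "stimulus"], sort=True):
        row = {"patient_id": pid, "stimulus": stim, "n_eyes": len(grp)}
        for col in value_cols:
            vals = grp[col].dropna()
            row[col] = float(vals.mean()) if len(vals) else nan
        row["quality_ok"] = bool(grp["quality_ok"].all()) and any(
            np.isfinite(row[c]) for c in value_cols
        )
        patient_rows.append(row)
    patient_df = pd.DataFrame(patient_rows)
    return eye_df, patient_df


def component_matrix(df: pd.DataFrame, by_eye: bool = False) -> pd.DataFrame:
    """Pivot a measurement table into wide component columns.

    ``DA10_a``/``DA10_b``/``LA3_a``/``LA3_b`` are flash amplitudes and
    ``LA30Hz_peak`` the flicker peak amplitude, indexed by patient (or by
    (patient, eye) when ``by_eye``).
    """
    index = ["patient_id", "eye"] if by_eye else ["patient_id"]
    out = {}
    for stim, col, name in [
        ("DA10", "a_amp_uV", "DA10_a"),
        ("DA10", "b_amp_uV", "DA10_b"),
        ("LA3", "a_amp_uV", "LA3_a"),
        ("LA3", "b_amp_uV", "LA3_b"),
        ("LA30Hz", "peak_amp_uV", "LA30Hz_peak"),
    ]:
        sub = df[df["stimulus"] == stim].set_index(index)[col]
        out[name] = sub
    return pd.DataFrame(out)


def trace_table_to_raw(df: pd.DataFrame) -> list[RawTrace]:
    """Split a long-format trace table into per-repeat :class:`RawTrace` objects."""
    out = []
    for (pid, eye, stim, rep), grp in df.groupby(
        ["patient_id", "eye", "stimulus", "repeat"], sort=True
    ):
        out.append(
            RawTrace(
                TraceKey(str(pid), str(eye), str(stim), int(rep)),
                grp["time_ms"].to_numpy(),
                grp["voltage_uV"].to_numpy(),
            )
        )
    return out


def raw_to_trace_table(traces: list[RawTrace]) -> pd.DataFrame:
    """Concatenate :class:`RawTrace` objects into a long-format trace table."""
    frames = []
    for tr in traces:
        n = tr.time_ms.size
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(tr.key.patient_id, n),
                    "eye": np.repeat(tr.key.eye, n),
                    "stimulus": np.repeat(tr.key.stimulus, n),
                    "repeat": np.repeat(tr.key.repeat, n),
                    "time_ms": tr.time_ms,
                    "voltage_uV": tr.voltage_uV,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
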