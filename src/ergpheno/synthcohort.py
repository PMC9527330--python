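"""Synthetic ERG cohort generator.

Produces cohorts with the structure the downstream pipeline assumes: flash
waveforms modelled as a negative plus a positive Gaussian lobe, flicker as a
30 Hz fundamental with a small 60 Hz harmonic, repeat-to-repeat noise with
slow drift and occasional blink transients, high interocular symmetry, and
a biallelic variant model in which the milder allele limits disease
severity (combined multiplier ``1 - 0.9 * s1 * s2`` on full-field
amplitudes, so one benign allele leaves full-field responses intact).

Phenotype group labels follow a deterministic rule: group 1 when every true
amplitude clears its normative limit (the 5th percentile of the group-1
generative distribution), group 2 when only light-adapted amplitudes fall
below, group 3 when any dark-adapted amplitude falls below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ergpheno.errors import ValidationError
from ergpheno.signal import RawTrace, TraceKey, raw_to_trace_table

NATIVE_STEP_MS = 0.25
NATIVE_GRID = NATIVE_STEP_MS * np.arange(337)  # 0 .. 84 ms

LA_COMPONENTS = ("LA3_a", "LA3_b", "LA30Hz_peak")
DA_COMPONENTS = ("DA10_a", "DA10_b")
ALL_COMPONENTS = DA_COMPONENTS + LA_COMPONENTS


@dataclass
class FlashShape:
    """Two-lobe flash waveform: trough depth/time and peak height/time."""

    a_amp: float
    a_time: float
    b_amp: float
    b_time: float
    sigma_a: float
    sigma_b: float

    def __post_init__(self) -> None:
        if self.a_amp < 0 or self.b_amp < 0:
            raise ValidationError("flash amplitudes must be >= 0")
        if self.a_time >= self.b_time:
            raise ValidationError("a-trough time must precede b-peak time")


@dataclass
class FlickerShape:
    amp: float
    phase_ms: float

    def __post_init__(self) -> None:
        if self.amp < 0:
            raise ValidationError("flicker amplitude must be >= 0")


@dataclass
class WaveParams:
    """Generative waveform parameters for one eye."""

    flash: dict[str, FlashShape]  # keys DA10, LA3
    flicker: FlickerShape
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    blink_prob: float = 0.0
    n_repeats: int = 3

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValidationError("n_repeats must be >= 2")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ValidationError("noise/drift must be >= 0")
        if not 0.0 <= self.blink_prob <= 1.0:
            raise ValidationError("blink_prob must lie in [0, 1]")


@dataclass(frozen=True)
class Variant:
    """Panel entry: HGVS-style id, allele severity in [0, 1], population frequency."""

    variant_id: str
    severity: float
    frequency: float


BLINK_AMP_UV = 300.0
BLINK_WIDTH_MS = 20.0


def _default_amp_means() -> dict[str, float]:
    return {
        "DA10_a": 250.0,
        "DA10_b": 400.0,
        "LA3_a": 40.0,
        "LA3_b": 120.0,
        "LA30Hz_peak": 90.0,
    }


def _default_peak_times() -> dict[str, float]:
    return {"DA10_a": 15.0, "DA10_b": 48.0, "LA3_a": 15.0, "LA3_b": 30.0}


def _default_age_rates() -> dict[str, float]:
    # µV/y decline applied to group-1 baseline amplitudes
    return {
        "DA10_b": -1.72,
        "LA3_b": -0.75,
        "LA30Hz_peak": -0.41,
        "DA10_a": -1.46,
        "LA3_a": -0.20,
    }


def default_variant_panel(
    n_variants: int = 30, seed: int | None = None
) -> list[Variant]:
    """Panel with severities spread over [0, 1] and Zipf-like frequencies."""
    sev = np.linspace(0.0, 1.0, n_variants)
    if seed is not None:
        sev = np.random.default_rng(seed).permutation(sev)
    freq = 1.0 / (np.arange(n_variants) + 2.0)
    freq /= freq.sum()
    return [
        Variant(f"c.{101 + 7 * i}A>G", float(sev[i]), float(freq[i]))
        for i in range(n_variants)
    ]


@dataclass
class SimConfig:
    """Settings of the cohort generator; defaults give a plausible ISCEV-range cohort."""

    n_patients: int = 100
    mode: Literal["groups", "genotype"] = "groups"
    group_mix: tuple[float, float, float] = (0.58, 0.07, 0.35)
    panel: list[Variant] | None = None
    rho: float = 0.96
    n_unilateral: int = 0
    age_range: tuple[float, float] = (10.0, 70.0)
    age_ref: float = 20.0
    amp_means: dict[str, float] = field(default_factory=_default_amp_means)
    peak_times: dict[str, float] = field(default_factory=_default_peak_times)
    age_rates: dict[str, float] = field(default_factory=_default_age_rates)
    # lobe widths (ms) per flash stimulus; LA3 lobes are narrower so the
    # small a-trough is not swallowed by the b-lobe
    lobe_widths: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"DA10": (4.0, 12.0), "LA3": (3.0, 6.0)}
    )
    flicker_phase_ms: float = 8.0
    between_sd: float = 0.2  # log-sd of the shared per-patient factor
    jitter_sd: float = 0.04  # log-sd of per-component jitter
    time_jitter_sd: float = 0.4
    noise_sd: float = 2.0
    drift_amp: float = 4.0
    blink_prob: float = 0.01
    repeats_range: tuple[int, int] = (3, 8)
    la_scale: float = 0.35
    da_scale: float = 0.35
    la_delay_ms: float = 6.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not 0.0 < self.rho <= 1.0:
            raise ValidationError("rho must lie in (0, 1]")
        if self.mode == "genotype" and self.panel is not None and not self.panel:
            raise ValidationError("variant panel must not be empty")
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValidationError("group_mix must sum to 1")
        lo, hi = self.repeats_range
        if lo < 2 or hi < lo:
            raise ValidationError("repeats_range must satisfy 2 <= lo <= hi")


@dataclass
class SyntheticCohort:
    traces: list[RawTrace]
    cohort: pd.DataFrame
    truth: pd.DataFrame
    limits: dict[str, float]

    def trace_table(self) -> pd.DataFrame:
        return raw_to_trace_table(self.traces)


def closed_form(params: WaveParams, stimulus: str, t: np.ndarray) -> np.ndarray:
    """Noise-free waveform model at times ``t`` (ms)."""
    if stimulus == "LA30Hz":
        f = params.flicker
        arg = 2.0 * np.pi * (t - f.phase_ms) / 1000.0
        return f.amp * np.sin(30.0 * arg) + 0.2 * f.amp * np.sin(60.0 * arg)
    sh = params.flash[stimulus]
    return -sh.a_amp * np.exp(
        -((t - sh.a_time) ** 2) / (2.0 * sh.sigma_a**2)
    ) + sh.b_amp * np.exp(-((t - sh.b_time) ** 2) / (2.0 * sh.sigma_b**2))


def generate_trace(
    params: WaveParams,
    stimulus: str,
    rng: np.random.Generator,
    time_ms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One repeat: closed-form model plus noise, drift, and a possible blink."""
    t = NATIVE_GRID if time_ms is None else np.asarray(time_ms, dtype=float)
    v = closed_form(params, stimulus, t)
    if params.drift_amp > 0:
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        v = v + params.drift_amp * np.sin(2.0 * np.pi * freq * t / 1000.0 + phase)
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, t.size)
    if params.blink_prob > 0 and rng.random() < params.blink_prob:
        center = rng.uniform(10.0, 70.0)
        sigma = BLINK_WIDTH_MS / 2.355  # FWHM -> sd
        v = v + BLINK_AMP_UV * np.exp(-((t - center) ** 2) / (2.0 * sigma**2))
    return t, v


def assign_group(amplitudes: dict[str, float], limits: dict[str, float]) -> int:
    """Deterministic phenotype rule from true amplitudes and normative limits."""
    if any(amplitudes[c] < limits[c] for c in DA_COMPONENTS):
        return 3
    if any(amplitudes[c] < limits[c] for c in LA_COMPONENTS):
        return 2
    return 1


def _baseline_amp(config: SimConfig, comp: str, age: float) -> float:
    base = config.amp_means[comp] + config.age_rates[comp] * (age - config.age_ref)
    return max(base, 0.2 * config.amp_means[comp])


def _patient_amplitudes(
    config: SimConfig, rng: np.random.Generator, age: float
) -> dict[str, float]:
    shared = np.exp(rng.normal(0.0, config.between_sd))
    return {
        comp: _baseline_amp(config, comp, age)
        * shared
        * np.exp(rng.normal(0.0, config.jitter_sd))
        for comp in ALL_COMPONENTS
    }


def normative_limits(
    config: SimConfig, seed: int = 0, n_mc: int = 4000
) -> dict[str, float]:
    """5th percentile of the group-1 generative amplitude distributions."""
    rng = np.random.default_rng([seed, 571])
    draws = {comp: np.empty(n_mc) for comp in ALL_COMPONENTS}
    for i in range(n_mc):
        age = rng.uniform(*config.age_range)
        amps = _patient_amplitudes(config, rng, age)
        for comp in ALL_COMPONENTS:
            draws[comp][i] = amps[comp]
    return {comp: float(np.percentile(draws[comp], 5)) for comp in ALL_COMPONENTS}


def _eye_waveparams(
    config: SimConfig,
    amps: dict[str, float],
    times: dict[str, float],
    flicker_phase: float,
    n_repeats: int,
) -> WaveParams:
    flash = {
        stim: FlashShape(
            amps[f"{stim}_a"],
            times[f"{stim}_a"],
            amps[f"{stim}_b"],
            times[f"{stim}_b"],
            *config.lobe_widths[stim],
        )
        for stim in ("DA10", "LA3")
    }
    return WaveParams(
        flash=flash,
        flicker=FlickerShape(amps["LA30Hz_peak"], flicker_phase),
        noise_sd=config.noise_sd,
        drift_amp=config.drift_amp,
        blink_prob=config.blink_prob,
        n_repeats=n_repeats,
    )


def generate_cohort(config: SimConfig, seed: int = 0) -> SyntheticCohort:
    """Simulate a cohort: traces, metadata, and per-patient ground truth.

    In ``genotype`` mode two alleles are drawn per patient from the variant
    panel; the combined multiplier ``m = 1 - 0.9*s1*s2`` scales dark-adapted
    amplitudes and ``m**2`` the light-adapted ones, so generalized cone
    dysfunction precedes rod involvement as severity grows. In ``groups``
    mode the phenotype mix is sampled directly and fixed scalings applied.
    Group labels are always re-derived from the realized true amplitudes.
    """
    rng = np.random.default_rng(seed)
    limits = normative_limits(config, seed=seed)
    panel = config.panel
    if config.mode == "genotype" and panel is None:
        panel = default_variant_panel()
    n = config.n_patients

    ages = rng.uniform(*config.age_range, n)
    sexes = rng.choice(["M", "F"], n)
    pupils = rng.choice([">=7mm", "<7mm"], n, p=[0.85, 0.15])
    compliance = rng.choice([1, 2, 3, 4, 5], n, p=[0.02, 0.08, 0.2, 0.35, 0.35])
    unilateral = set(rng.choice(n, size=config.n_unilateral, replace=False))

    cohort_rows, truth_rows = [], []
    patient_data = []
    for i in range(n):
        pid = f"P{i:04d}"
        if config.mode == "genotype":
            freqs = np.array([v.frequency for v in panel])
            freqs = freqs / freqs.sum()
            ia, ib = rng.choice(len(panel), size=2, p=freqs)
            s1, s2 = panel[ia].severity, panel[ib].severity
            m = 1.0 - 0.9 * min(s1, s2) * max(s1, s2)
            mult_da, mult_la = m, m * m
            la_delay = config.la_delay_ms * (1.0 - m)
            variant_a, variant_b = panel[ia].variant_id, panel[ib].variant_id
        else:
            g = int(rng.choice([1, 2, 3], p=config.group_mix))
            mult_la = config.la_scale if g >= 2 else 1.0
            mult_da = config.da_scale if g == 3 else 1.0
            la_delay = config.la_delay_ms if g >= 2 else 0.0
            s1 = s2 = np.nan
            variant_a = variant_b = ""

        amps = _patient_amplitudes(config, rng, ages[i])
        for comp in LA_COMPONENTS:
            amps[comp] *= mult_la
        for comp in DA_COMPONENTS:
            amps[comp] *= mult_da
        times = dict(config.peak_times)
        times["LA3_a"] += la_delay
        times["LA3_b"] += la_delay
        flicker_phase = config.flicker_phase_ms + 0.2 * la_delay
        group = assign_group(amps, limits)

        patient_data.append((pid, amps, times, flicker_phase))
        cohort_rows.append(
            {
                "patient_id": pid,
                "age_years": float(ages[i]),
                "sex": sexes[i],
                "pupil_class": pupils[i],
                "compliance": int(compliance[i]),
                "group_label": group,
                "variant_a": variant_a,
                "variant_b": variant_b,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "group": group,
                "severity_a": s1,
                "severity_b": s2,
                "mult_da": mult_da,
                "mult_la": mult_la,
                **{f"true_{c}": amps[c] for c in ALL_COMPONENTS},
            }
        )

    # Eye-level perturbation calibrated so interocular correlation ~= rho:
    # r = var_between / (var_between + var_within).
    truth = pd.DataFrame(truth_rows)
    eye_sd = {}
    for comp in ALL_COMPONENTS:
        var_b = float(np.var(truth[f"true_{comp}"], ddof=1)) if n > 1 else 0.0
        eye_sd[comp] = np.sqrt(max(var_b * (1.0 - config.rho) / config.rho, 0.0))
    t_jit = config.time_jitter_sd * np.sqrt(1.0 - config.rho)

    traces: list[RawTrace] = []
    for i, (pid, amps, times, flicker_phase) in enumerate(patient_data):
        eyes = ["R"] if i in unilateral else ["L", "R"]
        for eye in eyes:
            eye_amps = {
                comp: max(amps[comp] + rng.normal(0.0, eye_sd[comp]), 0.0)
                for comp in ALL_COMPONENTS
            }
            eye_times = {k: v + rng.normal(0.0, t_jit) for k, v in times.items()}
            for comp in ALL_COMPONENTS:
                truth.loc[i, f"true_{comp}_{eye}"] = eye_amps[comp]
            n_rep = int(rng.integers(config.repeats_range[0], config.repeats_range[1] + 1))
            params = _eye_waveparams(config, eye_amps, eye_times, flicker_phase, n_rep)
            for stim in ("DA10", "LA3", "LA30Hz"):
                for rep in range(1, n_rep + 1):
                    t, v = generate_trace(params, stim, rng)
                    traces.append(RawTrace(TraceKey(pid, eye, stim, rep), t, v))

    cohort = pd.DataFrame(cohort_rows)
    return SyntheticCohort(traces=traces, cohort=cohort, truth=truth, limits=limits)


def truth_component_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """True patient-level amplitudes as a wide component matrix."""
    out = truth.set_index("patient_id")[[f"true_{c}" for c in ALL_COMPONENTS]].copy()
    out.columns = list(ALL_COMPONENTS)
    return out
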