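"""Run configuration: filter cutoffs, detection thresholds, CV and model settings."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from ergpheno.errors import ValidationError

STIMULI = ("DA10", "LA3", "LA30Hz")
FLASH_STIMULI = ("DA10", "LA3")
FLICKER_STIMULUS = "LA30Hz"


def _default_filter_cutoffs() -> dict[str, float]:
    return {"DA10": 90.0, "LA3": 90.0, "LA30Hz": 100.0}


def _default_min_times() -> dict[str, dict[str, float]]:
    return {
        "DA10": {"a": 8.0, "b": 20.0},
        "LA3": {"a": 8.0, "b": 20.0},
        "LA30Hz": {"trough": 5.0},
    }


def _default_svm_grid() -> list[dict[str, Any]]:
    return [{"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01)]


def _default_ada_grid() -> list[dict[str, Any]]:
    return [
        {"max_depth": d, "n_estimators": n} for d in (1, 2) for n in (50, 200)
    ]


def _default_lr_grid() -> list[dict[str, Any]]:
    return [{"C": c} for c in (0.1, 1.0, 10.0)]


@dataclass
class RunConfig:
    """All tunable settings of the analysis pipeline.

    Attributes
    ----------
    filter_cutoff_hz
        Low-pass Butterworth cutoff per stimulus, in Hz.
    min_time_ms
        Minimum-time detection cutoffs per stimulus/component, in ms,
        guarding against artifactual early troughs and peaks.
    grid_start_ms, grid_stop_ms, grid_step_ms
        Standard resampling grid; defaults give 161 samples on 0-80 ms.
    cv_folds, cv_repeats, inner_val_fraction
        Outer folds, number of repeats, and inner validation split of the
        nested cross-validation (0.2 of the outer training set yields a
        global 64:16:20 train/validation/test partition).
    svm_grid, ada_grid, lr_grid, final_svm_c_grid
        Hyperparameter candidates for the three base learners and the
        patient-level SVM.
    enet_l1_ratio, enet_alpha, enet_n_alphas, enet_cv_folds
        Elastic-net settings; ``enet_alpha=None`` selects the penalty
        strength by internal cross-validation.
    class_weighted
        Use inverse-frequency class weights in the base learners.
    seed
        Master random seed for every stochastic step.
    """

    filter_cutoff_hz: dict[str, float] = field(default_factory=_default_filter_cutoffs)
    min_time_ms: dict[str, dict[str, float]] = field(default_factory=_default_min_times)
    grid_start_ms: float = 0.0
    grid_stop_ms: float = 80.0
    grid_step_ms: float = 0.5
    butterworth_order: int = 5

    cv_folds: int = 5
    cv_repeats: int = 5
    inner_val_fraction: float = 0.2
    svm_grid: list[dict[str, Any]] = field(default_factory=_default_svm_grid)
    ada_grid: list[dict[str, Any]] = field(default_factory=_default_ada_grid)
    lr_grid: list[dict[str, Any]] = field(default_factory=_default_lr_grid)
    final_svm_c_grid: list[float] = field(default_factory=lambda: [0.1, 1.0, 10.0])
    class_weighted: bool = False

    enet_l1_ratio: float = 0.5
    enet_alpha: float | None = None
    enet_n_alphas: int = 50
    enet_cv_folds: int = 5
    min_variant_count: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for stim, cut in self.filter_cutoff_hz.items():
            if cut <= 0:
                raise ValidationError(f"filter cutoff for {stim} must be > 0, got {cut}")
        for stim, cuts in self.min_time_ms.items():
            for comp, cut in cuts.items():
                if cut <= 0:
                    raise ValidationError(
                        f"minimum-time cutoff {stim}/{comp} must be > 0, got {cut}"
                    )
        if self.grid_start_ms > 0.0 or self.grid_stop_ms < 80.0:
            raise ValidationError("resampling grid must cover 0-80 ms")
        if self.grid_step_ms <= 0:
            raise ValidationError("grid step must be > 0")
        if not 0.0 < self.inner_val_fraction < 1.0:
            raise ValidationError("inner_val_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    @property
    def grid_ms(self):
        import numpy as np

        n = int(round((self.grid_stop_ms - self.grid_start_ms) / self.grid_step_ms)) + 1
        return self.grid_start_ms + self.grid_step_ms * np.arange(n)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
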