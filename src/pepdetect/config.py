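"""Nested pipeline configuration with strict JSON round-tripping.

Defaults throughout are the study conditions the package targets: 60-channel
EEG at 1000 Hz, 50 trials with 5-15 s rests, a 0.1-10 Hz zero-phase
bandpass, 50 Hz decimation, -2/+4 s epochs, 500 ms windows with 20 + 20
augmentation per trial, one xDAWN component, BLDA with a median-output
threshold, and 45/5 splits over 10 folds at a 90 % detection criterion.
Unknown keys are rejected so that a stored configuration always reproduces
the run that wrote it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict

from .simulate import SimulationConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Section):
    n_trials: int = 50
    sampling_rate: float = 1000.0
    rest_duration_range: tuple[float, float] = (5.0, 15.0)
    n1_amplitude: float = -14.75
    n1_latency: float = 62.0
    p2_amplitude: float = 5.0
    p2_latency: float = 167.0
    sustained_ratio: float = 0.3
    noise_rms: float = 12.0
    noise_spectral_exponent: float = 1.0
    side_sequence: Literal["random"] | tuple[Literal["left", "right"], ...] = "random"
    force_drop: float = 130.0
    force_drop_window: float = 300.0
    amplitude_jitter_sd: float = 0.0
    asymmetry: float = 0.0
    seed: int = 0

    def to_simulation_config(self, seed: int | None = None) -> SimulationConfig:
        kw = self.model_dump()
        if seed is not None:
            kw["seed"] = seed
        return SimulationConfig(**kw).validate()


class PreprocessSection(_Section):
    band_low: float = 0.1
    band_high: float = 10.0
    filter_order: int = 4
    target_rate: float = 50.0
    epoch_pre: float = 2.0
    epoch_post: float = 4.0
    window_ms: float = 500.0
    n_rest: int = 20
    slide_start: float = -300.0
    slide_stop: float = 100.0
    slide_step: float = 20.0
    rest_start_range: tuple[float, float] = (-2000.0, -500.0)
    test_start: float = -500.0
    test_stop: float = 500.0
    test_step: float = 20.0


class ModelSection(_Section):
    n_components: int = 1
    blda_max_iter: int = 100
    blda_tol: float = 1e-4
    balanced_targets: bool = True


class EvaluationSection(_Section):
    criterion: float = 90.0
    n_test: int = 5
    n_folds: int = 10
    seed: int = 0


class PipelineConfig(_Section):
    """Full run configuration: simulation, preprocessing, model, evaluation."""

    simulation: SimulationSection = SimulationSection()
    preprocessing: PreprocessSection = PreprocessSection()
    model: ModelSection = ModelSection()
    evaluation: EvaluationSection = EvaluationSection()

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = self.model_dump_json(indent=indent)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))
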