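"""Pipeline configuration: YAML-backed, schema-validated, defaults filled.

Unknown keys are rejected; validation errors name the offending path
(e.g. ``preprocess.smooth_fwhm_mm``).
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Block):
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_networks: int = Field(6, ge=2)
    rois_per_network: int = Field(4, ge=2)
    n_subjects: int = Field(12, ge=1)
    snr: float = Field(5.0, ge=0)
    drift_amplitude: float = Field(0.3, ge=0)
    spikes_per_run: int = Field(2, ge=0)
    tr: float = Field(2.2, gt=0)
    rest_frames_per_run: int = Field(160, ge=1)
    rest_runs: int = Field(2, ge=1)
    task_frames: int = Field(100, ge=1)
    voxel_size_mm: float = Field(3.0, gt=0)
    parcel_radius: float = Field(2.0, gt=0)


class PreprocessBlock(_Block):
    detrend: bool = True
    lowpass_hz: float | None = Field(0.1, gt=0)
    smooth_fwhm_mm: float | None = Field(6.0, ge=0)
    nuisance_regression: bool = True
    global_signal: bool = True
    censor_threshold_percent: float = Field(0.5, ge=0)


class FeaturesConfig(_Block):
    min_frames: int = Field(30, ge=3)
    batch_size: int = Field(256, ge=1)


class ClassifierConfig(_Block):
    n_dense_blocks: int = Field(2, ge=1)
    layers_per_block: tuple[int, ...] = (1, 2)
    kernel_edges: tuple[int, ...] = (3, 5)
    growth_rate: int = Field(6, ge=1)
    stem_channels: int = Field(8, ge=1)
    compression: float = Field(0.5, gt=0, le=1)
    use_batch_norm: bool = True
    pooling: Literal["average"] = "average"
    patience_validations: int = Field(3, ge=1)
    split_fractions: tuple[float, float] = (0.7, 0.3)
    learning_rate: float = Field(3e-3, gt=0)
    batch_size: int = Field(16, ge=1)
    max_epochs: int = Field(80, ge=1)
    validate_every: int = Field(2, ge=1)
    mode_window: int = Field(3, ge=1)
    box_length: int = Field(3, ge=1)


class TaskConfig(_Block):
    n_blocks: int = Field(5, ge=0)
    block_frames: int = Field(10, ge=1)
    amplitude: float = 1.0
    #: the expressive task drives the posterior (Wernicke-analog) parcel weakly
    wernicke_amplitude_scale: float = Field(0.4, ge=0)
    #: task-general networks co-activated by the task (ids beyond the language
    #: network), emulating non-specific task responses
    coactivate_networks: tuple[int, ...] = (2, 3)
    hrf_shape: float = Field(6.0, gt=0)
    hrf_scale_s: float = Field(1.0, gt=0)
    smooth_fwhm_mm: float = Field(10.0, ge=0)


class MetaRoiConfig(_Block):
    z_threshold: float = Field(3.7, gt=0)
    smooth1_fwhm_mm: float = Field(1.0, ge=0)
    smooth2_fwhm_mm: float = Field(3.0, ge=0)
    connectivity: Literal[6, 26] = 26
    peak_z: float = Field(8.0, gt=0)
    blob_fwhm_mm: float = Field(9.0, gt=0)
    distractor_peak_z: float | None = 5.0
    distractor_fwhm_mm: float = Field(4.5, gt=0)


class EvaluateConfig(_Block):
    n_grid: int = Field(101, ge=3)
    n_boot: int = Field(10_000, ge=10)
    alpha: float = Field(0.05, gt=0, le=1)
    negative_set: Literal["exclude-other-roi", "whole-mask"] = "exclude-other-roi"


class PipelineConfig(_Block):
    seed: int = 0
    out_dir: str = "langmap_out"
    frames_mode: Literal["100", "all", "both"] = "both"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessBlock = Field(default_factory=PreprocessBlock)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    task: TaskConfig = Field(default_factory=TaskConfig)
    metaroi: MetaRoiConfig = Field(default_factory=MetaRoiConfig)
    evaluate: EvaluateConfig = Field(default_factory=EvaluateConfig)


def validate_config(raw: dict | None) -> PipelineConfig:
    """Schema-check a raw mapping; fills defaults, rejects unknown keys.

    Raises :class:`ConfigurationError` whose message lists one line per
    problem, each naming the path into the document.
    """
    try:
        return PipelineConfig.model_validate(raw or {})
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{path}: {err['msg']}")
        raise ConfigurationError("invalid configuration:\n  " +
                                 "\n  ".join(lines)) from None


def load_config(path: str | None) -> PipelineConfig:
    """Read and validate a YAML config file (``None`` -> all defaults)."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return validate_config(raw)
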