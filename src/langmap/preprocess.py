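"""BOLD denoising chain: detrend, low-pass, smooth, nuisance regression, censor.

The chain is applied identically to resting-state and task runs. Frame
censoring is computed from the raw intensities (percent change relative to the
whole-brain mean is only meaningful before detrending removes the mean) and the
resulting mask is handed to every downstream correlation/GLM computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import (InsufficientDataError, MaskError, ParameterError,
                     SingularityError)
from .phantom import BoldRun

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CensorMask:
    """Per-frame keep/exclude decisions from the frame-to-frame RMS criterion.

    ``rms_trace[f]`` is the RMS over brain voxels of the intensity change from
    frame f-1 to f, in percent of the whole-brain mean intensity; frame 0 has
    no predecessor and is always kept.
    """

    keep: np.ndarray
    threshold_percent: float
    rms_trace: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.shape != self.rms_trace.shape:
            raise ParameterError("keep and rms_trace must have equal length")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def excluded_frames(self) -> set[int]:
        return set(np.flatnonzero(~self.keep).tolist())

    def to_text(self) -> str:
        return "\n".join("1" if k else "0" for k in self.keep) + "\n"

    @classmethod
    def all_kept(cls, n_frames: int, threshold_percent: float = 0.5) -> "CensorMask":
        return cls(np.ones(n_frames, bool), threshold_percent, np.zeros(n_frames))


@dataclass
class NuisanceSet:
    """Nuisance regressor matrix (frames x columns) with column names."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.names):
            raise ParameterError("one name per nuisance column required")
        if self.matrix.shape[1] < 1:
            raise ParameterError("at least one nuisance column required")


@dataclass
class PreprocessConfig:
    """Stage toggles and parameters for the denoising chain."""

    detrend: bool = True
    lowpass_hz: float | None = 0.1
    smooth_fwhm_mm: float | None = 6.0
    nuisance_regression: bool = True
    global_signal: bool = True
    censor_threshold_percent: float = 0.5
    extra_nuisance: NuisanceSet | None = field(default=None, repr=False)


def detrend_run(run: BoldRun) -> BoldRun:
    """Remove the per-voxel least-squares line (mean and linear trend)."""
    if run.n_frames < 3:
        raise InsufficientDataError(
            f"detrending needs >= 3 frames, got {run.n_frames}")
    out = signal.detrend(run.data, axis=-1, type="linear")
    return run.with_data(out)


def lowpass_filter(run: BoldRun, cutoff_hz: float = 0.1) -> BoldRun:
    """Zero-phase low-pass below ``cutoff_hz`` (second-order Butterworth,
    applied forward-backward)."""
    nyquist = 0.5 / run.protocol.tr
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz not in (0, Nyquist={nyquist:.4f}) for "
            f"TR={run.protocol.tr}")
    b, a = signal.butter(2, cutoff_hz / nyquist, btype="low")
    out = signal.filtfilt(b, a, run.data, axis=-1)
    return run.with_data(out)


def spatial_smooth(volume: np.ndarray, fwhm_mm: float,
                   voxel_size_mm: float = 3.0) -> np.ndarray:
    """Separable Gaussian blur with the stated FWHM per axis (mm).

    sigma = FWHM / (2 * sqrt(2 * ln 2)) converted to voxels; reflective
    boundary, so total intensity is conserved. ``fwhm_mm = 0`` is the identity.
    Works on 3D volumes and framewise on 4D runs.
    """
    if fwhm_mm < 0:
        raise ParameterError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return np.asarray(volume).copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    vol = np.asarray(volume, dtype=float)
    sigmas = (sigma, sigma, sigma) + ((0.0,) if vol.ndim == 4 else ())
    return ndimage.gaussian_filter(vol, sigma=sigmas, mode="reflect")


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    out = spatial_smooth(run.data, fwhm_mm, run.protocol.voxel_size_mm)
    return run.with_data(out)


def build_nuisance_set(run: BoldRun, wm_mask: np.ndarray | None = None,
                       csf_mask: np.ndarray | None = None,
                       include_global: bool = True) -> NuisanceSet:
    """Assemble nuisance waveforms from a run.

    Columns: white-matter mean, CSF mean, global (whole-brain) mean, and — as
    the stand-in for motion realignment parameters on phantom data — the
    injected spike indicator and its temporal derivative.
    """
    cols, names = [], []

    def add(series, name):
        # constant waveforms carry no variance beyond the intercept
        if np.std(series) > 1e-12:
            cols.append(series)
            names.append(name)

    if wm_mask is not None and wm_mask.any():
        add(run.data[wm_mask].mean(axis=0), "wm_mean")
    if csf_mask is not None and csf_mask.any():
        add(run.data[csf_mask].mean(axis=0), "csf_mean")
    if include_global:
        if not run.brain_mask.any():
            raise MaskError("empty brain mask")
        add(run.data[run.brain_mask].mean(axis=0), "global_mean")
    if run.motion_spike_frames:
        ind = np.zeros(run.n_frames)
        ind[sorted(run.motion_spike_frames)] = 1.0
        cols.append(ind); names.append("spike_indicator")
        cols.append(np.gradient(ind)); names.append("spike_derivative")
    if not cols:
        cols.append(np.zeros(run.n_frames)); names.append("null")
    return NuisanceSet(np.column_stack(cols), names)


def regress_nuisance(run: BoldRun, nuisance: NuisanceSet) -> BoldRun:
    """Per-voxel least-squares removal of the nuisance waveforms (+ intercept).

    Residuals are orthogonal to every regressor. A rank-deficient design
    raises :class:`SingularityError` naming the collinear columns.
    """
    X = np.column_stack([np.ones(run.n_frames), nuisance.matrix])
    names = ["intercept"] + list(nuisance.names)
    if nuisance.matrix.shape[0] != run.n_frames:
        raise ParameterError("nuisance rows must equal run frame count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        _, r_diag, piv = _qr_pivots(X)
        bad = [names[p] for p, d in zip(piv, r_diag) if abs(d) < 1e-10 * max(abs(r_diag[0]), 1)]
        raise SingularityError(f"collinear nuisance columns: {bad or names}")
    shape = run.data.shape
    Y = run.data.reshape(-1, shape[-1]).T  # frames x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return run.with_data(resid.T.reshape(shape))


def _qr_pivots(X):
    import scipy.linalg as sla
    q, r, piv = sla.qr(X, pivoting=True, mode="economic")
    return q, np.diag(r), piv


def censor_frames(run: BoldRun, threshold_percent: float = 0.5) -> CensorMask:
    """Flag frames by whole-brain RMS frame-to-frame intensity change.

    A frame is excluded when the RMS (over brain voxels) of its change from
    the previous frame exceeds ``threshold_percent`` of the whole-brain mean
    intensity. An isolated spike therefore flags the spike frame and its
    successor (both transitions exceed the threshold). Frame 0 is always kept.
    """
    if not run.brain_mask.any():
        raise MaskError("empty brain mask")
    series = run.data[run.brain_mask]  # voxels x frames
    whole_brain_mean = series.mean()
    if whole_brain_mean == 0:
        raise MaskError("whole-brain mean intensity is zero")
    diffs = np.diff(series, axis=1)
    rms = np.sqrt((diffs ** 2).mean(axis=0))
    trace = np.concatenate([[0.0], rms / abs(whole_brain_mean) * 100.0])
    keep = trace <= threshold_percent
    keep[0] = True
    return CensorMask(keep, threshold_percent, trace)


def preprocess_run(run: BoldRun, config: PreprocessConfig | None = None,
                   wm_mask: np.ndarray | None = None,
                   csf_mask: np.ndarray | None = None) -> tuple[BoldRun, CensorMask]:
    """Full chain: detrend -> low-pass -> spatial smooth -> nuisance regression,
    with frame censoring evaluated on the raw input intensities.

    Identical code path for resting-state and task runs. Returns the denoised
    run and the censor mask; censored frames are *not* removed from the data
    array — downstream computations drop them via the mask.
    """
    config = config or PreprocessConfig()
    censor = censor_frames(run, config.censor_threshold_percent)
    out = run
    if config.detrend:
        out = detrend_run(out)
    if config.lowpass_hz is not None:
        out = lowpass_filter(out, config.lowpass_hz)
    if config.smooth_fwhm_mm is not None and config.smooth_fwhm_mm > 0:
        out = smooth_run(out, config.smooth_fwhm_mm)
    if config.nuisance_regression:
        nuis = build_nuisance_set(out, wm_mask=wm_mask, csf_mask=csf_mask,
                                  include_global=config.global_signal)
        if config.extra_nuisance is not None:
            nuis = NuisanceSet(
                np.column_stack([nuis.matrix, config.extra_nuisance.matrix]),
                nuis.names + config.extra_nuisance.names)
        out = regress_nuisance(out, nuis)
    return out, censor


def pool_runs(runs_and_censors: list[tuple[BoldRun, CensorMask]]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate preprocessed runs along time; returns (data, keep)."""
    if not runs_and_censors:
        raise InsufficientDataError("no runs to pool")
    datas = [rc[0].data for rc in runs_and_censors]
    keeps = [rc[1].keep for rc in runs_and_censors]
    shapes = {d.shape[:3] for d in datas}
    if len(shapes) != 1:
        raise ParameterError("runs on different grids cannot be pooled")
    return np.concatenate(datas, axis=-1), np.concatenate(keeps)


def select_contiguous_frames(keep: np.ndarray, n_frames: int = 100) -> np.ndarray:
    """Restrict a keep mask to its first ``n_frames`` kept frames.

    Used to match resting-state data quantity to the task acquisition: of the
    pooled kept frames, the earliest contiguous block of ``n_frames`` is
    retained.
    """
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) < n_frames:
        raise InsufficientDataError(
            f"only {len(kept_idx)} kept frames, need {n_frames}")
    out = np.zeros_like(keep, dtype=bool)
    out[kept_idx[:n_frames]] = True
    return out
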