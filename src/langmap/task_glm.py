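"""Block-design GLM activation mapping — the task-fMRI comparator.

Voxelwise least squares against [intercept, boxcar (x) hemodynamic kernel];
the activation map carries both the task beta and its t statistic. Post-
processing is a 10 mm Gaussian smooth and extra-cranial masking — no response
clustering and no thresholding, so the downstream ROC sees the full map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import GlmDesign
from .errors import InsufficientDataError, MaskError, SingularityError
from .phantom import AcquisitionProtocol, BoldRun
from .preprocess import CensorMask, spatial_smooth


@dataclass
class ActivationMap:
    """Task beta and t-statistic volumes from a GLM fit."""

    beta: np.ndarray
    tstat: np.ndarray
    design_used: GlmDesign
    smoothing_fwhm_mm: float = 0.0
    dof: int = 0


def build_design_matrix(design: GlmDesign, protocol: AcquisitionProtocol
                        ) -> np.ndarray:
    """(frames x 2) matrix: intercept and the hemodynamic task regressor.

    A design with no blocks yields the intercept-only matrix.
    """
    n = protocol.n_frames_per_run
    if not design.block_onsets:
        return np.ones((n, 1))
    reg = design.regressor(n, protocol.tr)
    return np.column_stack([np.ones(n), reg])


def fit_glm(run: BoldRun, design_matrix: np.ndarray,
            censor: CensorMask | None = None,
            design: GlmDesign | None = None) -> ActivationMap:
    """Per-voxel least squares on kept frames.

    beta is the task-column coefficient; t = beta / SE with residual degrees
    of freedom = kept frames - columns.
    """
    keep = censor.keep if censor is not None else np.ones(run.n_frames, bool)
    X = design_matrix[keep]
    n, p = X.shape
    if n <= p + 2:
        raise InsufficientDataError(
            f"{n} kept frames insufficient for {p} columns")
    if np.linalg.matrix_rank(X) < p:
        raise SingularityError("design matrix is rank deficient")
    mask = run.brain_mask
    if not mask.any():
        raise MaskError("empty brain mask")
    Y = run.data[mask][:, keep].T  # frames x voxels
    beta_all, *_ = np.linalg.lstsq(X, Y, rcond=None)
    dof = n - p
    beta_vol = np.zeros(mask.shape)
    t_vol = np.zeros(mask.shape)
    if p > 1:  # intercept-only designs carry no task effect
        resid = Y - X @ beta_all
        sigma2 = (resid ** 2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
        beta_vol[mask] = beta_all[1]
        t_vol[mask] = beta_all[1] / se
    return ActivationMap(beta=beta_vol, tstat=t_vol,
                         design_used=design, dof=dof)


def postprocess_activation(amap: ActivationMap, fwhm_mm: float = 10.0,
                           mask: np.ndarray | None = None,
                           voxel_size_mm: float = 3.0) -> ActivationMap:
    """Gaussian smooth (default 10 mm) and mask out extra-cranial voxels.

    Neither clustering nor thresholding is applied.
    """
    beta = spatial_smooth(amap.beta, fwhm_mm, voxel_size_mm)
    tstat = spatial_smooth(amap.tstat, fwhm_mm, voxel_size_mm)
    if mask is not None:
        if not mask.any():
            raise MaskError("empty mask")
        beta = beta * mask
        tstat = tstat * mask
    return ActivationMap(beta=beta, tstat=tstat, design_used=amap.design_used,
                         smoothing_fwhm_mm=fwhm_mm, dof=amap.dof)
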