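"""Block-design timing and the hemodynamic response kernel.

Shared between the phantom generator (which injects task responses) and the
GLM module (which fits them), so both use the identical regressor: a block
boxcar convolved with a gamma-variate hemodynamic kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DesignError


@dataclass(frozen=True)
class HrfParams:
    """Gamma-variate hemodynamic kernel, peaking at ``(shape - 1) * scale_s`` seconds.

    Defaults put the peak near 5 s, the conventional BOLD response latency.
    """

    shape: float = 6.0
    scale_s: float = 1.0
    duration_s: float = 30.0

    def kernel(self, tr: float) -> np.ndarray:
        """Discrete kernel sampled at the repetition time, normalized to unit sum."""
        t = np.arange(0.0, self.duration_s, tr)
        h = stats.gamma.pdf(t, a=self.shape, scale=self.scale_s)
        s = h.sum()
        if s <= 0:
            raise DesignError("hemodynamic kernel integrates to zero at this TR")
        return h / s


@dataclass(frozen=True)
class GlmDesign:
    """Task block timing in frame units.

    ``block_onsets`` are 0-based frame indices of block starts; each block lasts
    ``block_duration_frames``. Blocks must lie within the run and not overlap.
    """

    block_onsets: tuple[int, ...]
    block_duration_frames: int
    hrf_params: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self):
        if self.block_duration_frames < 1:
            raise DesignError("block duration must be >= 1 frame")
        onsets = sorted(self.block_onsets)
        for a, b in zip(onsets, onsets[1:]):
            if a + self.block_duration_frames > b:
                raise DesignError(f"blocks at frames {a} and {b} overlap")

    def validate_for(self, n_frames: int) -> None:
        for onset in self.block_onsets:
            if onset < 0 or onset + self.block_duration_frames > n_frames:
                raise DesignError(
                    f"block at frame {onset} (length {self.block_duration_frames}) "
                    f"exceeds the {n_frames}-frame run")

    def boxcar(self, n_frames: int) -> np.ndarray:
        """0/1 task indicator per frame (before hemodynamic convolution)."""
        self.validate_for(n_frames)
        box = np.zeros(n_frames)
        for onset in self.block_onsets:
            box[onset:onset + self.block_duration_frames] = 1.0
        return box

    def regressor(self, n_frames: int, tr: float) -> np.ndarray:
        """Boxcar convolved with the hemodynamic kernel, truncated to the run."""
        box = self.boxcar(n_frames)
        h = self.hrf_params.kernel(tr)
        return np.convolve(box, h)[:n_frames]


def five_block_design(n_frames: int = 100, block_frames: int = 10,
                      hrf: HrfParams | None = None) -> GlmDesign:
    """The acquisition's word-generation layout: five task/rest cycles.

    Task blocks of ``block_frames`` alternate with equal rest blocks, task
    first, e.g. frames 0-9 task, 10-19 rest, ... for the 100-frame default.
    """
    onsets = tuple(range(0, 2 * 5 * block_frames, 2 * block_frames))
    design = GlmDesign(onsets, block_frames, hrf or HrfParams())
    design.validate_for(n_frames)
    return design
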