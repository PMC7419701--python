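"""Ground-truth language ROIs from a meta-analytic Z-map.

Five steps turn a Z-score association map into disjoint Broca-like and
Wernicke-like masks:

1. Gaussian smooth, 1 mm FWHM per cardinal direction.
2. Map positive Z-scores to probabilities via tanh; threshold at Z > 3.7.
   (3.7 is a Z-score, so the threshold is applied in Z units; tanh is
   order-preserving, so cluster membership is identical either way — the tanh
   map is kept as the probability annotation.)
3. Retain the two largest connected clusters (left hemisphere).
4. Gaussian smooth each cluster indicator, 3 mm FWHM; re-binarize at 0.5.
5. Assign voxels claimed by both smoothed clusters to the cluster with the
   nearer center of mass (Euclidean, mm).

The anterior (higher-y centroid) ROI is named Broca-like, the posterior
Wernicke-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InsufficientClusterError, MaskError, ParameterError
from .phantom import MetaMap
from .preprocess import spatial_smooth

Z_THRESHOLD = 3.7


@dataclass
class LanguageRois:
    """Disjoint Broca-like and Wernicke-like ground-truth masks."""

    broca_mask: np.ndarray
    wernicke_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.broca_mask & self.wernicke_mask).any():
            raise ParameterError("language ROIs must be disjoint")
        if not self.broca_mask.any() or not self.wernicke_mask.any():
            raise ParameterError("language ROIs must be non-empty")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ParameterError(f"connectivity must be 6 or 26, got {connectivity}")


def connected_components(mask: np.ndarray, connectivity: int = 26
                         ) -> tuple[np.ndarray, list[int]]:
    """Label maximal connected regions; returns (labels, sizes by label)."""
    labeled, n = ndimage.label(np.asarray(mask, bool), structure=_structure(connectivity))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=range(1, n + 1)).astype(int).tolist()
    return labeled, sizes


def center_of_mass(volume: np.ndarray, voxel_size_mm: float = 1.0) -> np.ndarray:
    """Intensity-weighted mean position in mm (uniform scaling affine)."""
    vol = np.asarray(volume, dtype=float)
    if vol.sum() == 0:
        raise MaskError("empty support: center of mass undefined")
    return np.asarray(ndimage.center_of_mass(vol)) * voxel_size_mm


def build_language_rois(meta: MetaMap, z_threshold: float = Z_THRESHOLD,
                        smooth1_fwhm_mm: float = 1.0,
                        smooth2_fwhm_mm: float = 3.0,
                        connectivity: int = 26,
                        rebinarize_at: float = 0.5) -> LanguageRois:
    """Execute the five construction steps; see the module docstring."""
    vox = meta.voxel_size_mm
    z = spatial_smooth(meta.zvolume, smooth1_fwhm_mm, vox)            # step 1
    prob = np.where(z > 0, np.tanh(z), 0.0)                           # step 2
    supra = z > z_threshold
    mid_x = meta.zvolume.shape[0] // 2
    left = np.zeros_like(supra)
    left[:mid_x] = True
    supra &= left
    labeled, sizes = connected_components(supra, connectivity)        # step 3
    if len(sizes) < 2:
        raise InsufficientClusterError(
            f"need >= 2 supra-{z_threshold} clusters, found {len(sizes)} "
            f"(census: {sizes})")
    order = sorted(range(1, len(sizes) + 1),
                   key=lambda lab: (sizes[lab - 1],
                                    float(z[labeled == lab].max())),
                   reverse=True)  # size first; peak z breaks ties
    keep_labels = order[:2]
    masks = []
    for lab in keep_labels:
        ind = (labeled == lab).astype(float)
        sm = spatial_smooth(ind, smooth2_fwhm_mm, vox)                # step 4
        masks.append(sm >= rebinarize_at)
    coms = [center_of_mass(m, vox) for m in masks]
    overlap = masks[0] & masks[1]                                     # step 5
    if overlap.any():
        pts = np.argwhere(overlap) * vox
        d0 = np.linalg.norm(pts - coms[0], axis=1)
        d1 = np.linalg.norm(pts - coms[1], axis=1)
        to_first = d0 <= d1
        for i, (p, first) in enumerate(zip(np.argwhere(overlap), to_first)):
            (masks[1] if first else masks[0])[tuple(p)] = False
    # anterior (higher y centroid) = Broca-like
    coms = [center_of_mass(m, vox) for m in masks]
    if coms[0][1] >= coms[1][1]:
        broca, wernicke = masks
    else:
        wernicke, broca = masks
        coms = coms[::-1]
    provenance = {
        "z_threshold": z_threshold, "smooth1_fwhm_mm": smooth1_fwhm_mm,
        "smooth2_fwhm_mm": smooth2_fwhm_mm, "connectivity": connectivity,
        "rebinarize_at": rebinarize_at, "cluster_census": sizes,
        "kept_cluster_sizes": [sizes[lab - 1] for lab in keep_labels],
        "broca_com_mm": [float(v) for v in coms[0]],
        "wernicke_com_mm": [float(v) for v in coms[1]],
        "space_tag": meta.space_tag,
    }
    return LanguageRois(broca_mask=broca, wernicke_mask=wernicke,
                        provenance=provenance)
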