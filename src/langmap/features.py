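"""Seed-correlation feature volumes and classifier example sets.

A training example is the whole-brain Fisher-z correlation volume of one seed
(the mean series of a parcel), labeled with the parcel's network. At inference
time the same representation is computed per voxel, so classification reduces
to voxelwise network-membership scoring. The Fisher transform z = atanh(r)
stabilizes the sampling variance of the correlations before they enter the
network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import h5py
import numpy as np

from .errors import CoverageError, DegenerateSeedError, InsufficientDataError
from .phantom import RoiSet

#: correlations are clamped to |r| <= 1 - R_CLAMP before atanh
R_CLAMP = 1e-7
#: fewer kept frames than this makes a correlation estimate unreliable
MIN_FRAMES = 30


@dataclass
class CorrelationVolume:
    """Fisher-z correlation of every voxel with one seed series."""

    values: np.ndarray
    seed_id: int
    frames_used: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise DegenerateSeedError("non-finite correlation values")


def _kept(data: np.ndarray, keep: np.ndarray | None) -> np.ndarray:
    """(voxels..., frames) -> same with censored frames dropped."""
    if keep is None:
        return data
    return data[..., np.asarray(keep, dtype=bool)]


def extract_roi_timeseries(data: np.ndarray, roi_set: RoiSet,
                           keep: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Mean time series per parcel, restricted to kept frames."""
    out = {}
    for roi_id in roi_set.roi_ids:
        m = roi_set.labels == roi_id
        m &= roi_set.brain_mask
        if not m.any():
            raise CoverageError(f"parcel {roi_id} has no in-mask voxels")
        out[roi_id] = _kept(data[m], keep).mean(axis=0)
    return out


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with the documented clamp |r| <= 1 - 1e-7."""
    return np.arctanh(np.clip(r, -1.0 + R_CLAMP, 1.0 - R_CLAMP))


def _standardize_columns(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each column (voxel series); returns (z, zero_variance_mask)."""
    mu = ts.mean(axis=0, keepdims=True)
    sd = ts.std(axis=0, keepdims=True)
    degenerate = sd[0] == 0
    sd[:, degenerate] = 1.0
    return (ts - mu) / sd, degenerate


def seed_correlation_volume(data: np.ndarray, seed_series: np.ndarray,
                            brain_mask: np.ndarray,
                            keep: np.ndarray | None = None,
                            seed_id: int = -1) -> CorrelationVolume:
    """Voxelwise Pearson correlation with a seed, Fisher-z transformed.

    Censored frames are dropped before the correlation; voxels outside the
    brain mask (and zero-variance voxels) get z = 0.
    """
    ts = _kept(data[brain_mask], keep).T.astype(float)  # frames x voxels
    n = ts.shape[0]
    seed = np.asarray(seed_series, dtype=float)
    if len(seed) == data.shape[-1] and keep is not None:
        seed = seed[np.asarray(keep, dtype=bool)]
    if len(seed) != n:
        raise InsufficientDataError(
            f"seed length {len(seed)} != kept frame count {n}")
    if n < 3:
        raise InsufficientDataError("need >= 3 kept frames for a correlation")
    if seed.std() == 0:
        raise DegenerateSeedError("seed series has zero variance")
    zs = (seed - seed.mean()) / seed.std()
    zv, degenerate = _standardize_columns(ts)
    r = zv.T @ zs / n
    r[degenerate] = 0.0
    vol = np.zeros(brain_mask.shape)
    vol[brain_mask] = fisher_z(r)
    return CorrelationVolume(values=vol, seed_id=seed_id, frames_used=n)


# ---------------------------------------------------------------------------
# example sets
# ---------------------------------------------------------------------------

@dataclass
class ExampleSet:
    """Labeled correlation volumes partitioned into train/validation."""

    volumes: np.ndarray            # (N, x, y, z) float32
    labels: np.ndarray             # (N,) network ids 1..K
    train_idx: np.ndarray
    val_idx: np.ndarray
    n_networks: int

    def __post_init__(self):
        n = len(self.volumes)
        if len(self.labels) != n:
            raise CoverageError("one label per volume required")
        if len(self.train_idx) + len(self.val_idx) != n:
            raise CoverageError("partition does not conserve the example count")

    @property
    def n_examples(self) -> int:
        return len(self.volumes)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("volumes", data=self.volumes, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("train_idx", data=self.train_idx)
            f.create_dataset("val_idx", data=self.val_idx)
            f.attrs["n_networks"] = self.n_networks

    @classmethod
    def load(cls, path: str) -> "ExampleSet":
        with h5py.File(path, "r") as f:
            return cls(volumes=f["volumes"][...], labels=f["labels"][...],
                       train_idx=f["train_idx"][...], val_idx=f["val_idx"][...],
                       n_networks=int(f.attrs["n_networks"]))


def split_example_ids(n_examples: int, split_fractions=(0.7, 0.3),
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle ``n_examples`` ids and partition by the split fractions.

    The validation count is ``round(n * validation_fraction)`` — for 268,000
    examples at the default 70/30 split this is 80,400 validation and 187,600
    training ids.
    """
    if not np.isclose(sum(split_fractions), 1.0):
        raise InsufficientDataError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ids = rng.permutation(n_examples)
    n_val = int(round(n_examples * split_fractions[1]))
    return np.sort(ids[n_val:]), np.sort(ids[:n_val])


def build_training_examples(subject_runs: list[tuple[np.ndarray, np.ndarray | None]],
                            roi_set: RoiSet, split_fractions=(0.7, 0.3),
                            seed: int = 0) -> ExampleSet:
    """One example per (subject, seed parcel): the parcel-seed correlation
    volume labeled with the parcel's network.

    ``subject_runs`` holds per-subject (preprocessed 4D data, keep mask).
    Degenerate seeds are skipped with a recorded warning rather than failing
    the cohort.
    """
    if not subject_runs:
        raise InsufficientDataError("need at least one subject")
    vols, labels, skipped = [], [], []
    for s, (data, keep) in enumerate(subject_runs):
        roi_series = extract_roi_timeseries(data, roi_set, keep)
        for roi_id, series in roi_series.items():
            try:
                cv = seed_correlation_volume(data, series, roi_set.brain_mask,
                                             keep, seed_id=roi_id)
            except DegenerateSeedError:
                skipped.append((s, roi_id))
                continue
            vols.append(cv.values.astype(np.float32))
            labels.append(roi_set.network_of_roi[roi_id])
    if skipped:
        import warnings
        warnings.warn(f"skipped degenerate seeds: {skipped}", stacklevel=2)
    volumes = np.stack(vols)
    labels = np.asarray(labels, dtype=np.int64)
    train_idx, val_idx = split_example_ids(len(volumes), split_fractions, seed)
    return ExampleSet(volumes=volumes, labels=labels, train_idx=train_idx,
                      val_idx=val_idx, n_networks=roi_set.n_networks)


def iter_inference_examples(data: np.ndarray, brain_mask: np.ndarray,
                            keep: np.ndarray | None = None,
                            batch_size: int = 256,
                            dtype=np.float32,
                            ) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stream per-voxel whole-brain correlation volumes in raster order.

    For every in-mask voxel (C-order raster over the grid), the voxel's own
    series is the seed. Yields ``(flat_positions, volumes, degenerate)`` where
    ``flat_positions`` indexes the in-mask raster order, ``volumes`` is a
    float32 batch of Fisher-z volumes and ``degenerate`` flags zero-variance
    seeds (their volumes are all-zero; the classifier assigns them uniform
    probabilities).
    """
    ts = _kept(data[brain_mask], keep).T.astype(float)  # frames x voxels
    n = ts.shape[0]
    if n < 3:
        raise InsufficientDataError("need >= 3 kept frames")
    z, degenerate = _standardize_columns(ts)
    z = z.astype(dtype)
    n_vox = z.shape[1]
    shape = brain_mask.shape
    for start in range(0, n_vox, batch_size):
        stop = min(start + batch_size, n_vox)
        r = (z[:, start:stop].T @ z) / np.float32(n)
        zz = fisher_z(r)
        deg = degenerate[start:stop]
        zz[deg] = 0.0
        zz[:, degenerate] = 0.0
        vols = np.zeros((stop - start,) + shape, dtype=dtype)
        vols[:, brain_mask] = zz
        yield np.arange(start, stop), vols, deg
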