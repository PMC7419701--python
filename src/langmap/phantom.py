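"""Synthetic phantom cohorts with known resting-state network topography.

The downstream analysis (seed-correlation features, 3D CNN network
classification, block-design GLM, meta-analytic ROI construction) assumes BOLD
data in which voxels of the same network share a latent low-frequency signal.
This module generates such data on a small isotropic grid, in register across
modalities, together with meta-analytic Z-maps containing two left-hemisphere
supra-threshold clusters and the packaged patient cohort table.

Conventions: axis 0 is x; the left hemisphere is the lower-x half of the grid.
"Anterior" is the higher-y direction, so the Broca-analog parcel sits left and
anterior, the Wernicke-analog left and posterior.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .design import GlmDesign
from .errors import (CapacityError, CohortParseError, MaskError,
                     ParameterError, RoiLookupError)

BASELINE_INTENSITY = 1000.0
#: whole-volume intensity offset injected at motion-spike frames, in percent of
#: the whole-brain mean: 5x the default 0.5 % censoring threshold.
SPIKE_OFFSET_PERCENT = 2.5


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition timing and geometry for one scanning protocol.

    Defaults mirror the patient protocol: 3 mm cubic voxels, TR = 2.2 s,
    resting state acquired as two 160-frame runs (320 frames total), the task
    as a single 100-frame run.
    """

    tr: float = 2.2
    n_frames_per_run: int = 160
    n_runs: int = 2
    voxel_size_mm: float = 3.0
    grid_shape: tuple[int, int, int] = (24, 24, 24)

    def __post_init__(self):
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.n_frames_per_run < 1 or self.n_runs < 1:
            raise ParameterError("frame and run counts must be >= 1")
        if self.voxel_size_mm <= 0:
            raise ParameterError("voxel size must be positive")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ParameterError("grid_shape must be 3 axes, each >= 8 voxels")

    @classmethod
    def patient_rest(cls, grid_shape=(24, 24, 24)) -> "AcquisitionProtocol":
        return cls(tr=2.2, n_frames_per_run=160, n_runs=2, grid_shape=grid_shape)

    @classmethod
    def patient_task(cls, grid_shape=(24, 24, 24)) -> "AcquisitionProtocol":
        return cls(tr=2.2, n_frames_per_run=100, n_runs=1, grid_shape=grid_shape)

    @classmethod
    def training_cohort(cls, grid_shape=(24, 24, 24)) -> "AcquisitionProtocol":
        """Normal-cohort protocol (TR = 3.0 s, single longer run)."""
        return cls(tr=3.0, n_frames_per_run=248, n_runs=1, grid_shape=grid_shape)


@dataclass
class RoiSet:
    """Labeled parcels, each assigned to one of K resting-state networks.

    ``labels`` holds 0 for background and parcel ids 1..R. The designated
    language-analog network owns the Broca-like and Wernicke-like parcels
    (both in the left hemisphere). Background compartments standing in for
    white matter and CSF are provided for nuisance extraction.
    """

    labels: np.ndarray
    network_of_roi: dict[int, int]
    centers: dict[int, tuple[float, float, float]]
    n_networks: int
    voxel_size_mm: float
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    language_network: int = 1
    broca_roi: int = 1
    wernicke_roi: int = 2

    def __post_init__(self):
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.network_of_roi)
        if missing:
            raise ParameterError(f"parcels {sorted(missing)} lack a network assignment")
        if self.n_networks < 2:
            raise ParameterError("need at least 2 networks")

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.network_of_roi)

    def roi_mask(self, roi_id: int) -> np.ndarray:
        if roi_id not in self.network_of_roi:
            raise RoiLookupError(f"unknown parcel id {roi_id}")
        return self.labels == roi_id

    def network_rois(self, network_id: int) -> list[int]:
        return [r for r, k in self.network_of_roi.items() if k == network_id]

    @property
    def language_rois(self) -> list[int]:
        return self.network_rois(self.language_network)


@dataclass
class BoldRun:
    """One 4D acquisition (x, y, z, frame) with timing and motion metadata."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    brain_mask: np.ndarray
    motion_spike_frames: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.data.shape[-1] != self.protocol.n_frames_per_run:
            raise ParameterError(
                f"run has {self.data.shape[-1]} frames, protocol says "
                f"{self.protocol.n_frames_per_run}")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise MaskError("brain mask grid does not match data grid")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data, self.protocol, self.brain_mask, self.motion_spike_frames)


@dataclass
class MetaMap:
    """Meta-analytic Z-score volume on the phantom grid."""

    zvolume: np.ndarray
    space_tag: str
    voxel_size_mm: float
    planted_centers: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.zvolume)):
            raise ParameterError("meta map contains non-finite values")


def _candidate_centers(grid_shape, parcel_radius, spacing):
    """Lattice of admissible blob centers inside the spherical brain."""
    center = (np.array(grid_shape) - 1) / 2.0
    brain_radius = min(grid_shape) / 2.0 - 1.0
    # blob centers stay 1 voxel inside the brain; blobs may be clipped at the
    # brain edge (they are intersected with the mask when rasterized)
    reach = brain_radius - 1.0
    axes = []
    for n in grid_shape:
        k = max(1, int((n - 2 * (spacing // 2)) // spacing))
        coords = np.arange(k) * spacing
        coords = coords + (n - 1 - coords[-1]) / 2.0  # center the lattice
        axes.append(coords)
    pts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    dist = np.linalg.norm(pts - center, axis=1)
    return [tuple(p) for p in pts[dist <= reach]], center, brain_radius


def _ball_mask(grid_shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def make_phantom_atlas(grid_shape=(24, 24, 24), n_networks: int = 6,
                       rois_per_network: int = 4, seed: int = 0,
                       voxel_size_mm: float = 3.0,
                       parcel_radius: float = 2.0) -> RoiSet:
    """Place ``n_networks * rois_per_network`` disjoint spherical parcels.

    Parcels sit on a lattice (spacing > 2 * radius, so disjointness holds by
    construction) inside a spherical brain mask. Network 1 is the designated
    language analog: its first parcel (Broca-like) is left-anterior, its second
    (Wernicke-like) left-posterior; any further language parcels prefer the
    right hemisphere (homolog analogs). Two leftover lattice sites become the
    white-matter and CSF stand-in compartments.

    Raises :class:`CapacityError` when the grid cannot host the request.
    """
    if n_networks < 2 or rois_per_network < 2:
        raise ParameterError("need n_networks >= 2 and rois_per_network >= 2")
    n_parcels = n_networks * rois_per_network
    spacing = int(2 * parcel_radius + 1)
    candidates, center, brain_radius = _candidate_centers(
        grid_shape, parcel_radius, spacing)
    # capacity: parcels + 2 nuisance compartments must fit on the lattice
    if n_parcels + 2 > len(candidates):
        raise CapacityError(
            f"grid {grid_shape} offers {len(candidates)} non-overlapping sites "
            f"for parcels of radius {parcel_radius}; "
            f"{n_parcels} parcels + 2 compartments requested")
    mid_x = (grid_shape[0] - 1) / 2.0
    left = [c for c in candidates if c[0] < mid_x]
    if len(left) < 2:
        raise CapacityError("fewer than two left-hemisphere sites available")

    # Broca-analog: left hemisphere, most anterior (largest y); Wernicke-analog:
    # left hemisphere, most posterior. Deterministic lexicographic tie-breaks.
    broca = max(left, key=lambda c: (c[1], -c[0], -c[2]))
    wernicke = min(left, key=lambda c: (c[1], c[0], c[2]))
    if broca == wernicke:
        raise CapacityError("cannot separate anterior and posterior language sites")

    rng = np.random.default_rng(seed)
    remaining = [c for c in candidates if c not in (broca, wernicke)]
    order = rng.permutation(len(remaining))
    remaining = [remaining[i] for i in order]

    placements: dict[int, tuple[float, float, float]] = {1: broca, 2: wernicke}
    network_of_roi: dict[int, int] = {1: 1, 2: 1}
    # remaining language parcels prefer right-hemisphere sites
    rid = 3
    right_pool = [c for c in remaining if c[0] > mid_x]
    other_pool = [c for c in remaining if c[0] <= mid_x]
    for _ in range(rois_per_network - 2):
        pool = right_pool if right_pool else other_pool
        placements[rid] = pool.pop(0)
        network_of_roi[rid] = 1
        rid += 1
    pool = right_pool + other_pool
    for net in range(2, n_networks + 1):
        for _ in range(rois_per_network):
            placements[rid] = pool.pop(0)
            network_of_roi[rid] = net
            rid += 1

    if len(pool) < 2:
        raise CapacityError("no lattice sites left for white-matter/CSF compartments")
    wm_center, csf_center = pool[0], pool[1]

    brain_mask = _ball_mask(grid_shape, center, brain_radius)
    labels = np.zeros(grid_shape, dtype=np.int32)
    for roi_id, c in placements.items():
        labels[_ball_mask(grid_shape, c, parcel_radius) & brain_mask] = roi_id
    wm_mask = _ball_mask(grid_shape, wm_center, 1.5) & brain_mask & (labels == 0)
    csf_mask = _ball_mask(grid_shape, csf_center, 1.5) & brain_mask & (labels == 0)
    if not (labels[brain_mask] >= 0).all() or not brain_mask[labels > 0].all():
        raise MaskError("parcel voxels escaped the brain mask")  # pragma: no cover
    return RoiSet(labels=labels, network_of_roi=network_of_roi,
                  centers={k: tuple(map(float, v)) for k, v in placements.items()},
                  n_networks=n_networks, voxel_size_mm=voxel_size_mm,
                  brain_mask=brain_mask, wm_mask=wm_mask, csf_mask=csf_mask)


def _lowpass_latent(white: np.ndarray, tr: float, cutoff_hz: float = 0.1) -> np.ndarray:
    """Low-pass filter white noise below the retained BOLD band and standardize."""
    nyq = 0.5 / tr
    b, a = signal.butter(2, min(cutoff_hz / nyq, 0.99), btype="low")
    lat = signal.filtfilt(b, a, white, axis=-1)
    sd = lat.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (lat - lat.mean(axis=-1, keepdims=True)) / sd


def _mix_coefficients(snr: float) -> tuple[float, float]:
    """Unit-variance mixing of latent and noise: var ratio latent/noise = snr."""
    if snr < 0:
        raise ParameterError("snr must be >= 0")
    if math.isinf(snr):
        return 1.0, 0.0
    return math.sqrt(snr / (snr + 1.0)), math.sqrt(1.0 / (snr + 1.0))


def simulate_rest_run(roi_set: RoiSet, protocol: AcquisitionProtocol,
                      snr: float = 5.0, drift_amplitude: float = 0.3,
                      spike_frames=(), seed: int = 0,
                      latent_scale: float = 1.0) -> BoldRun:
    """Simulate one resting-state run on the phantom atlas.

    Each network carries one latent Gaussian signal low-pass filtered below
    0.1 Hz. A parcel voxel's series mixes its network latent and white noise
    with variance ratio ``snr`` (unit total fluctuation variance), plus a
    per-voxel linear drift of scale ``drift_amplitude``; background brain
    voxels carry noise and drift only. Frames listed in ``spike_frames``
    receive a whole-brain intensity offset of ``SPIKE_OFFSET_PERCENT`` of the
    baseline, large enough to trip the default censoring threshold.
    """
    T = protocol.n_frames_per_run
    spikes = frozenset(int(f) for f in spike_frames)
    for f in spikes:
        if f < 0 or f >= T:
            raise IndexError(f"spike frame {f} outside run of {T} frames")
    rng = np.random.default_rng(seed)
    latents = _lowpass_latent(rng.standard_normal((roi_set.n_networks, T)),
                              protocol.tr)
    a_sig, a_noise = _mix_coefficients(snr)

    mask = roi_set.brain_mask
    n_vox = int(mask.sum())
    data = np.zeros(roi_set.labels.shape + (T,))
    noise = rng.standard_normal((n_vox, T))
    labels_in = roi_set.labels[mask]
    series = a_noise * noise  # background: white noise only, no latent
    for roi_id, net in roi_set.network_of_roi.items():
        sel = labels_in == roi_id
        if sel.any():
            series[sel] = (latent_scale * a_sig * latents[net - 1]
                           + a_noise * noise[sel])
    if drift_amplitude > 0:
        slopes = drift_amplitude * rng.standard_normal(n_vox)
        series += slopes[:, None] * np.linspace(-1.0, 1.0, T)
    series += BASELINE_INTENSITY
    if spikes:
        offset = SPIKE_OFFSET_PERCENT / 100.0 * BASELINE_INTENSITY
        series[:, sorted(spikes)] += offset
    data[mask] = series
    return BoldRun(data=data, protocol=protocol, brain_mask=mask,
                   motion_spike_frames=spikes)


def simulate_task_run(roi_set: RoiSet, protocol: AcquisitionProtocol,
                      design: GlmDesign, responsive_parcels,
                      amplitude: float = 1.0, snr: float = 5.0,
                      drift_amplitude: float = 0.3, spike_frames=(),
                      seed: int = 0, include_spontaneous: bool = True) -> BoldRun:
    """Rest-like run plus a block-design response in the responsive parcels.

    The added response is ``amplitude`` times the design regressor (boxcar
    convolved with the hemodynamic kernel), so a noiseless GLM fit recovers
    ``amplitude`` exactly. ``amplitude`` may also be a mapping
    ``parcel id -> amplitude`` to drive parcels unequally (e.g. an expressive
    task driving an anterior region harder than a posterior one). With
    ``amplitude = 0`` the run is identical to :func:`simulate_rest_run` with
    the same seed.

    ``include_spontaneous=False`` suppresses the latent network signals
    (parcels then carry noise only), so that with zero noise the GLM recovers
    the planted amplitude exactly — spontaneous activity is otherwise a
    legitimate confound that biases the estimate.
    """
    design.validate_for(protocol.n_frames_per_run)
    run = simulate_rest_run(roi_set, protocol, snr=snr,
                            drift_amplitude=drift_amplitude,
                            spike_frames=spike_frames, seed=seed,
                            latent_scale=1.0 if include_spontaneous else 0.0)
    reg = None
    for pid in responsive_parcels:
        amp = amplitude.get(int(pid), 0.0) if isinstance(amplitude, dict) \
            else amplitude
        m = roi_set.roi_mask(int(pid))  # unknown parcel -> lookup error
        if amp == 0.0:
            continue
        if reg is None:
            reg = design.regressor(protocol.n_frames_per_run, protocol.tr)
        run.data[m] += amp * reg
    return run


def simulate_meta_map(roi_set: RoiSet, peak_z: float = 8.0,
                      blob_fwhm_mm: float = 9.0,
                      distractor_peak_z: float | None = None,
                      distractor_fwhm_mm: float = 4.5,
                      noise_sd: float = 0.2, seed: int = 0,
                      space_tag: str = "phantom") -> MetaMap:
    """Z-score map with Gaussian blobs on the language-analog parcel centers.

    Two blobs of height ``peak_z`` sit on the Broca- and Wernicke-analog
    centers. An optional distractor blob (smaller spatial extent) can be
    planted in the left hemisphere to exercise cluster-size ranking; background
    voxels carry small Gaussian noise.
    """
    if peak_z <= 3.7:
        raise ParameterError("peak_z must exceed the 3.7 cluster threshold")
    shape = roi_set.labels.shape
    rng = np.random.default_rng(seed)
    z = noise_sd * rng.standard_normal(shape)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]

    def add_blob(center, peak, fwhm_mm):
        sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / roi_set.voxel_size_mm
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        z[...] += peak * np.exp(-d2 / (2.0 * sigma_vox ** 2))

    broca_c = roi_set.centers[roi_set.broca_roi]
    wern_c = roi_set.centers[roi_set.wernicke_roi]
    add_blob(broca_c, peak_z, blob_fwhm_mm)
    add_blob(wern_c, peak_z, blob_fwhm_mm)
    planted = {"broca": broca_c, "wernicke": wern_c}
    if distractor_peak_z is not None:
        mid_x = (shape[0] - 1) / 2.0
        pool = [c for rid, c in roi_set.centers.items()
                if c[0] < mid_x and rid not in (roi_set.broca_roi, roi_set.wernicke_roi)]
        if pool:
            dc = max(pool, key=lambda c: min(
                np.linalg.norm(np.subtract(c, broca_c)),
                np.linalg.norm(np.subtract(c, wern_c))))
        else:
            dc = (shape[0] / 4.0, (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0)
        add_blob(dc, distractor_peak_z, distractor_fwhm_mm)
        planted["distractor"] = tuple(map(float, dc))
    return MetaMap(zvolume=z, space_tag=space_tag,
                   voxel_size_mm=roi_set.voxel_size_mm, planted_centers=planted)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age_bin: str
    handedness: str
    laterality_index: float
    lesions: tuple[tuple[str, float], ...]  # (location, volume mL)
    pathology: str

    @property
    def total_volume_ml(self) -> float:
        return float(sum(v for _, v in self.lesions))


@dataclass
class CohortTable:
    """Patient metadata mirroring the clinical/demographic table."""

    patients: tuple[PatientRecord, ...]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for loc, vol in p.lesions:
                rows.append({"patient_id": p.patient_id, "age_bin": p.age_bin,
                             "handedness": p.handedness,
                             "laterality_index": p.laterality_index,
                             "tumor_location": loc, "tumor_volume_ml": vol,
                             "pathology": p.pathology})
        return pd.DataFrame(rows)


_COHORT_COLUMNS = ["patient_id", "age_bin", "handedness", "laterality_index",
                   "tumor_location", "tumor_volume_ml", "pathology"]


def packaged_cohort_path() -> str:
    """Path of the packaged 35-patient cohort fixture."""
    return str(importlib.resources.files("langmap").joinpath("data/cohort_table1.tsv"))


def load_cohort_table(path: str) -> CohortTable:
    """Parse a tab-separated cohort table (one row per lesion).

    Multi-lesion patients appear on consecutive rows sharing a patient id.
    Malformed rows raise :class:`CohortParseError` naming the line.
    """
    patients: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file") from None
        if header != _COHORT_COLUMNS:
            raise CohortParseError(
                f"{path}: line 1: expected columns {_COHORT_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_COHORT_COLUMNS):
                raise CohortParseError(
                    f"{path}: line {lineno}: expected {len(_COHORT_COLUMNS)} "
                    f"fields, got {len(row)}")
            pid, age, hand, li, loc, vol, path_ = row
            try:
                li_val = float(li)
                vol_val = float(vol)
            except ValueError as exc:
                raise CohortParseError(f"{path}: line {lineno}: {exc}") from None
            if vol_val <= 0:
                raise CohortParseError(
                    f"{path}: line {lineno}: lesion volume must be > 0, got {vol_val}")
            if pid not in patients:
                patients[pid] = {"age_bin": age, "handedness": hand,
                                 "laterality_index": li_val, "lesions": [],
                                 "pathology": path_}
                order.append(pid)
            patients[pid]["lesions"].append((loc, vol_val))
    if not patients:
        raise CohortParseError(f"{path}: no data rows")
    records = tuple(
        PatientRecord(pid, d["age_bin"], d["handedness"], d["laterality_index"],
                      tuple(d["lesions"]), d["pathology"])
        for pid, d in ((p, patients[p]) for p in order))
    return CohortTable(patients=records)
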