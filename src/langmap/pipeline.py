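"""End-to-end phantom experiment: simulate -> preprocess -> features -> train
-> predict (100 and all frames) -> task GLM -> meta ROIs -> ROC evaluation.

Per-subject probability/activation maps are produced first, then arithmetically
averaged, and a single group-level ROC is computed per (ROI, method) — six
curves for the default two-ROI, three-method grid, plus the matched-data
comparison (all-frame vs 100-frame classifier AUC confidence intervals).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .classifier import (DenseNet3D, DenseNet3DConfig, ProbabilityVolume,
                         TrainingHistory, build_model, smooth_probability,
                         train)
from .config import PipelineConfig, validate_config
from .design import GlmDesign, HrfParams, five_block_design
from .features import build_training_examples, iter_inference_examples
from .group_eval import (GroupMap, MethodComparison, RocResult, compare_methods,
                         group_average, normalize_map, plot_roc,
                         roc_curve_vertical)
from .io import save_volume
from .meta_roi import LanguageRois, build_language_rois
from .phantom import (AcquisitionProtocol, MetaMap, RoiSet,
                      make_phantom_atlas, simulate_meta_map, simulate_rest_run,
                      simulate_task_run)
from .preprocess import (PreprocessConfig, pool_runs, preprocess_run,
                         select_contiguous_frames)
from .task_glm import build_design_matrix, fit_glm, postprocess_activation

log = logging.getLogger("langmap")


@dataclass
class ResultsBundle:
    """Everything the experiment produced, plus where it was written."""

    config: PipelineConfig
    atlas: RoiSet
    meta_map: MetaMap
    language_rois: LanguageRois
    group_maps: dict[str, GroupMap]
    roc_results: dict[tuple[str, str], RocResult]   # (roi, source) -> result
    comparisons: dict[str, MethodComparison]
    history: TrainingHistory
    provenance: dict
    out_dir: str | None = None
    subject_prob_maps: dict[str, list[ProbabilityVolume]] = field(default_factory=dict)


def _stage_seeds(global_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from the global seed."""
    ss = np.random.SeedSequence(global_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _preprocess_config(cfg: PipelineConfig) -> PreprocessConfig:
    p = cfg.preprocess
    return PreprocessConfig(detrend=p.detrend, lowpass_hz=p.lowpass_hz,
                            smooth_fwhm_mm=p.smooth_fwhm_mm,
                            nuisance_regression=p.nuisance_regression,
                            global_signal=p.global_signal,
                            censor_threshold_percent=p.censor_threshold_percent)


def _classifier_config(cfg: PipelineConfig, n_classes: int) -> DenseNet3DConfig:
    c = cfg.classifier
    return DenseNet3DConfig(
        n_dense_blocks=c.n_dense_blocks, layers_per_block=c.layers_per_block,
        kernel_edges=c.kernel_edges, growth_rate=c.growth_rate,
        stem_channels=c.stem_channels, compression=c.compression,
        use_batch_norm=c.use_batch_norm, pooling=c.pooling, n_classes=n_classes,
        patience_validations=c.patience_validations,
        split_fractions=c.split_fractions, learning_rate=c.learning_rate,
        batch_size=c.batch_size, max_epochs=c.max_epochs,
        validate_every=c.validate_every)


def _predict_subject(model: DenseNet3D, data: np.ndarray, keep: np.ndarray,
                     atlas: RoiSet, cfg: PipelineConfig,
                     class_names: list[str]) -> ProbabilityVolume:
    from .classifier import predict_volume
    stream = iter_inference_examples(data, atlas.brain_mask, keep,
                                     batch_size=cfg.features.batch_size)
    prob = predict_volume(model, stream, atlas.brain_mask, class_names)
    return smooth_probability(prob, cfg.classifier.mode_window,
                              cfg.classifier.box_length)


def run_experiment(config: PipelineConfig | dict | None = None,
                   out_dir: str | None = None,
                   write_outputs: bool = True) -> ResultsBundle:
    """Run the full phantom experiment described in the module docstring."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config
    sim = cfg.simulate
    out_dir = out_dir or cfg.out_dir
    seeds = _stage_seeds(cfg.seed, 6 + 3 * sim.n_subjects)
    seed_atlas, seed_meta, seed_split, seed_init, seed_train, seed_spike = seeds[:6]
    subject_seeds = seeds[6:]

    log.info("stage=simulate seed=%d subjects=%d grid=%s", cfg.seed,
             sim.n_subjects, sim.grid_shape)
    atlas = make_phantom_atlas(sim.grid_shape, sim.n_networks,
                               sim.rois_per_network, seed=seed_atlas,
                               voxel_size_mm=sim.voxel_size_mm,
                               parcel_radius=sim.parcel_radius)
    rest_protocol = AcquisitionProtocol(
        tr=sim.tr, n_frames_per_run=sim.rest_frames_per_run,
        n_runs=sim.rest_runs, voxel_size_mm=sim.voxel_size_mm,
        grid_shape=sim.grid_shape)
    task_protocol = AcquisitionProtocol(
        tr=sim.tr, n_frames_per_run=sim.task_frames, n_runs=1,
        voxel_size_mm=sim.voxel_size_mm, grid_shape=sim.grid_shape)
    hrf = HrfParams(shape=cfg.task.hrf_shape, scale_s=cfg.task.hrf_scale_s)
    design = five_block_design(sim.task_frames, cfg.task.block_frames, hrf) \
        if cfg.task.n_blocks == 5 else GlmDesign(
            tuple(range(0, 2 * cfg.task.n_blocks * cfg.task.block_frames,
                        2 * cfg.task.block_frames)), cfg.task.block_frames, hrf)
    meta = simulate_meta_map(atlas, peak_z=cfg.metaroi.peak_z,
                             blob_fwhm_mm=cfg.metaroi.blob_fwhm_mm,
                             distractor_peak_z=cfg.metaroi.distractor_peak_z,
                             distractor_fwhm_mm=cfg.metaroi.distractor_fwhm_mm,
                             seed=seed_meta)
    rois = build_language_rois(meta, z_threshold=cfg.metaroi.z_threshold,
                               smooth1_fwhm_mm=cfg.metaroi.smooth1_fwhm_mm,
                               smooth2_fwhm_mm=cfg.metaroi.smooth2_fwhm_mm,
                               connectivity=cfg.metaroi.connectivity)

    pre_cfg = _preprocess_config(cfg)
    spike_rng = np.random.default_rng(seed_spike)
    rest_data: list[tuple[np.ndarray, np.ndarray]] = []
    task_maps: list[np.ndarray] = []
    # the word-generation analog drives all language parcels (the posterior
    # one weakly) and co-activates the configured task-general networks
    responsive = list(atlas.language_rois)
    amplitudes = {pid: cfg.task.amplitude for pid in responsive}
    amplitudes[atlas.wernicke_roi] = (cfg.task.amplitude
                                      * cfg.task.wernicke_amplitude_scale)
    for net in cfg.task.coactivate_networks:
        if 1 <= net <= atlas.n_networks and net != atlas.language_network:
            for pid in atlas.network_rois(net):
                responsive.append(pid)
                amplitudes[pid] = cfg.task.amplitude
    log.info("stage=preprocess censor_threshold=%.3f%%",
             pre_cfg.censor_threshold_percent)
    for s in range(sim.n_subjects):
        runs = []
        for r in range(sim.rest_runs):
            spikes = spike_rng.choice(
                np.arange(1, sim.rest_frames_per_run), size=sim.spikes_per_run,
                replace=False) if sim.spikes_per_run else []
            run = simulate_rest_run(atlas, rest_protocol, snr=sim.snr,
                                    drift_amplitude=sim.drift_amplitude,
                                    spike_frames=spikes,
                                    seed=subject_seeds[3 * s] + r)
            runs.append(preprocess_run(run, pre_cfg, wm_mask=atlas.wm_mask,
                                       csf_mask=atlas.csf_mask))
        data, keep = pool_runs(runs)
        rest_data.append((data.astype(np.float32), keep))

        task_run = simulate_task_run(atlas, task_protocol, design, responsive,
                                     amplitude=amplitudes, snr=sim.snr,
                                     drift_amplitude=sim.drift_amplitude,
                                     seed=subject_seeds[3 * s + 1])
        task_pre, task_censor = preprocess_run(task_run, pre_cfg,
                                               wm_mask=atlas.wm_mask,
                                               csf_mask=atlas.csf_mask)
        X = build_design_matrix(design, task_protocol)
        amap = fit_glm(task_pre, X, task_censor, design)
        amap = postprocess_activation(amap, cfg.task.smooth_fwhm_mm,
                                      atlas.brain_mask, sim.voxel_size_mm)
        task_maps.append(amap.tstat)

    log.info("stage=features examples_per_subject=%d", len(atlas.roi_ids))
    examples = build_training_examples(rest_data, atlas,
                                       cfg.classifier.split_fractions,
                                       seed=seed_split)
    clf_cfg = _classifier_config(cfg, atlas.n_networks)
    model, manifest = build_model(clf_cfg, sim.grid_shape, seed=seed_init)
    log.info("stage=train layers=%d examples=%d", len(manifest),
             examples.n_examples)
    history = train(model, examples, clf_cfg, seed=seed_train)
    log.info("stage=train done epochs=%d best_val_acc=%.4f reason=%s",
             history.n_epochs, history.best_accuracy, history.stop_reason)

    class_names = ["language" if k + 1 == atlas.language_network
                   else f"network-{k + 1}" for k in range(atlas.n_networks)]
    modes = {"both": ["all", "100"], "all": ["all"], "100": ["100"]}[cfg.frames_mode]
    subject_probs: dict[str, list[ProbabilityVolume]] = {m: [] for m in modes}
    total_rest_frames = sim.rest_frames_per_run * sim.rest_runs
    for s, (data, keep) in enumerate(rest_data):
        for m in modes:
            k = keep if m == "all" else select_contiguous_frames(keep, 100)
            prob = _predict_subject(model, data, k, atlas, cfg, class_names)
            subject_probs[m].append(prob)
        log.info("stage=predict subject=%d kept=%d", s, int(keep.sum()))

    group_maps: dict[str, GroupMap] = {}
    mode_tag = {"all": f"cnn-{total_rest_frames}", "100": "cnn-100"}
    for m in modes:
        lang = [p.class_map("language") for p in subject_probs[m]]
        gm = group_average(lang, source_tag=mode_tag[m])
        gm.volume = normalize_map(gm.volume, atlas.brain_mask)
        group_maps[mode_tag[m]] = gm
    gm_task = group_average(task_maps, source_tag="task")
    gm_task.volume = normalize_map(gm_task.volume, atlas.brain_mask)
    group_maps["task"] = gm_task

    # evaluation: left-hemisphere brain voxels; negatives exclude the other ROI
    mid_x = sim.grid_shape[0] // 2
    left = np.zeros(sim.grid_shape, dtype=bool)
    left[:mid_x] = True
    base_mask = atlas.brain_mask & left
    truths = {"broca": rois.broca_mask, "wernicke": rois.wernicke_mask}
    roc_results: dict[tuple[str, str], RocResult] = {}
    ev = cfg.evaluate
    for roi_name, truth in truths.items():
        other = truths["wernicke" if roi_name == "broca" else "broca"]
        eval_mask = base_mask.copy()
        if ev.negative_set == "exclude-other-roi":
            eval_mask &= ~(other & ~truth)
        for tag, gm in group_maps.items():
            roc_results[(roi_name, tag)] = roc_curve_vertical(
                gm.volume, truth, eval_mask, n_grid=ev.n_grid,
                n_boot=ev.n_boot, alpha=ev.alpha, seed=cfg.seed,
                truth_tag=roi_name, source_tag=tag)
    comparisons = {}
    if len(modes) == 2:
        for roi_name in truths:
            comparisons[roi_name] = compare_methods(
                roc_results[(roi_name, mode_tag["all"])],
                roc_results[(roi_name, "cnn-100")])

    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed, "langmap_version": __version__,
        "numpy_version": np.__version__,
        "layer_manifest": manifest,
        "layer_accounting": clf_cfg.accounting(),
        "train_stop_reason": history.stop_reason,
        "best_validation_accuracy": history.best_accuracy,
        "meta_roi_provenance": rois.provenance,
    }
    bundle = ResultsBundle(config=cfg, atlas=atlas, meta_map=meta,
                           language_rois=rois, group_maps=group_maps,
                           roc_results=roc_results, comparisons=comparisons,
                           history=history, provenance=provenance,
                           out_dir=out_dir if write_outputs else None,
                           subject_prob_maps=subject_probs)
    if write_outputs:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: ResultsBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    vox = bundle.config.simulate.voxel_size_mm
    save_volume(os.path.join(out_dir, "atlas_labels.nii.gz"),
                bundle.atlas.labels.astype(np.int16), vox)
    save_volume(os.path.join(out_dir, "meta_zmap.nii.gz"),
                bundle.meta_map.zvolume, vox)
    save_volume(os.path.join(out_dir, "roi_broca.nii.gz"),
                bundle.language_rois.broca_mask.astype(np.uint8), vox)
    save_volume(os.path.join(out_dir, "roi_wernicke.nii.gz"),
                bundle.language_rois.wernicke_mask.astype(np.uint8), vox)
    for tag, gm in bundle.group_maps.items():
        save_volume(os.path.join(out_dir, f"group_{tag}.nii.gz"), gm.volume, vox)
    for (roi, tag), res in bundle.roc_results.items():
        res.to_json(os.path.join(out_dir, f"roc_{roi}_{tag}.json"))
    for roi in ("broca", "wernicke"):
        subset = {tag: r for (rn, tag), r in bundle.roc_results.items()
                  if rn == roi}
        if subset:
            plot_roc(subset, os.path.join(out_dir, f"roc_{roi}.png"),
                     title=f"{roi} ROI")
    comp = {roi: vars(c) for roi, c in bundle.comparisons.items()}
    with open(os.path.join(out_dir, "comparison.json"), "w") as fh:
        json.dump(comp, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(_report_markdown(bundle))


def _report_markdown(bundle: ResultsBundle) -> str:
    lines = ["# Language-network mapping: phantom experiment report", ""]
    lines.append(f"- subjects: {bundle.config.simulate.n_subjects}")
    lines.append(f"- grid: {bundle.config.simulate.grid_shape}, "
                 f"networks: {bundle.config.simulate.n_networks}")
    lines.append(f"- training: {bundle.history.n_epochs} epochs, "
                 f"best validation accuracy "
                 f"{bundle.history.best_accuracy:.4f} "
                 f"({bundle.history.stop_reason})")
    lines.append("")
    lines.append("| ROI | method | AUC | 95% CI |")
    lines.append("|-----|--------|-----|--------|")
    for (roi, tag), res in sorted(bundle.roc_results.items()):
        lines.append(f"| {roi} | {tag} | {res.auc:.4f} | "
                     f"[{res.auc_ci[0]:.4f}, {res.auc_ci[1]:.4f}] |")
    for roi, comp in bundle.comparisons.items():
        lines.append("")
        lines.append(f"Matched-data check ({roi}): AUC difference "
                     f"{comp.auc_difference:+.4f}, CI overlap: {comp.ci_overlap}")
    return "\n".join(lines) + "\n"
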