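"""Group averaging and ROC/AUC evaluation against the ground-truth ROIs.

Group maps are arithmetic averages of per-patient maps; localization is
quantified with ROC curves whose true-positive rates are vertically averaged
over a 101-point false-positive-rate grid across bootstrap replicates
(voxelwise case resampling), with percentile confidence bands and an AUC
confidence interval from the replicate distribution. AUC equals the
concordant-pair fraction with ties counted 1/2, so it is invariant under
strictly monotone transforms of the scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import ComparisonError, DegeneracyError, ParameterError, ShapeError
from .phantom import CohortTable


@dataclass
class GroupMap:
    """Voxelwise arithmetic mean over subjects."""

    volume: np.ndarray
    n_subjects: int
    source_tag: str = ""

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError("need at least one subject")


def group_average(maps: list[np.ndarray], source_tag: str = "") -> GroupMap:
    """Voxelwise arithmetic mean of per-subject maps (identical grids)."""
    shapes = {np.asarray(m).shape for m in maps}
    if len(shapes) != 1:
        raise ShapeError(f"maps on mismatched grids: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    return GroupMap(volume=stack.mean(axis=0), n_subjects=len(maps),
                    source_tag=source_tag)


def normalize_map(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max normalize within the mask to [0, 1] (order-preserving, so ROC
    and AUC are unchanged); zero outside."""
    out = np.zeros_like(np.asarray(volume, dtype=float))
    vals = volume[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        out[mask] = (vals - lo) / (hi - lo)
    return out


def _extract(scores, truth, eval_mask):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if eval_mask is not None:
        s = scores[eval_mask]
        t = truth[eval_mask]
    else:
        s = scores.ravel()
        t = truth.ravel()
    if t.all() or not t.any():
        raise DegeneracyError("truth must contain both classes in the mask")
    return s, t


def roc_auc(scores: np.ndarray, truth: np.ndarray,
            eval_mask: np.ndarray | None = None) -> float:
    """Concordant-pair AUC (ties 1/2) via the rank formula."""
    s, t = _extract(scores, truth, eval_mask)
    ranks = stats.rankdata(s)
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _roc_points(scores: np.ndarray, truth: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """ROC vertices from a threshold sweep over unique score values.

    Returns (fpr, tpr), both ascending, anchored at (0,0) and (1,1). Tied
    scores collapse to a single vertex, which makes the trapezoidal area equal
    to the ties-1/2 rank AUC.
    """
    order = np.argsort(-scores, kind="stable")
    t_sorted = truth[order]
    s_sorted = scores[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(t_sorted)[distinct]
    fp = np.cumsum(~t_sorted)[distinct]
    tpr = np.r_[0.0, tp / tp[-1]]
    fpr = np.r_[0.0, fp / fp[-1]]
    return fpr, tpr


@dataclass
class RocResult:
    """Vertically averaged ROC with bootstrap confidence bands."""

    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_ci: tuple[np.ndarray, np.ndarray]
    auc: float
    auc_ci: tuple[float, float]
    n_boot: int
    alpha: float
    truth_tag: str = ""
    source_tag: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fpr_grid"] = self.fpr_grid.tolist()
        d["tpr_mean"] = self.tpr_mean.tolist()
        d["tpr_ci"] = [np.asarray(c).tolist() for c in self.tpr_ci]
        d["auc_ci"] = [float(c) for c in self.auc_ci]
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RocResult":
        return cls(fpr_grid=np.asarray(d["fpr_grid"]),
                   tpr_mean=np.asarray(d["tpr_mean"]),
                   tpr_ci=(np.asarray(d["tpr_ci"][0]), np.asarray(d["tpr_ci"][1])),
                   auc=d["auc"], auc_ci=tuple(d["auc_ci"]), n_boot=d["n_boot"],
                   alpha=d["alpha"], truth_tag=d.get("truth_tag", ""),
                   source_tag=d.get("source_tag", ""))


def roc_curve_vertical(scores: np.ndarray, truth: np.ndarray,
                       eval_mask: np.ndarray | None = None,
                       n_grid: int = 101, n_boot: int = 10_000,
                       alpha: float = 0.05, seed: int = 0,
                       truth_tag: str = "", source_tag: str = "") -> RocResult:
    """Bootstrap ROC with vertical averaging on an ``n_grid``-point FPR grid.

    Voxels are resampled with replacement; each replicate's ROC is linearly
    interpolated onto the grid. ``tpr_mean`` is the replicate mean, the band
    the (alpha/2, 1-alpha/2) percentiles, and the AUC interval comes from the
    replicate AUC distribution (trapezoidal areas).
    """
    if n_boot < 10:
        raise ParameterError(f"n_boot must be >= 10, got {n_boot}")
    s, t = _extract(scores, truth, eval_mask)
    n = len(s)
    grid = np.linspace(0.0, 1.0, n_grid)
    rng = np.random.default_rng(seed)
    tprs = np.empty((n_boot, n_grid))
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ti = t[idx]
        if ti.all() or not ti.any():      # degenerate resample: redraw
            idx = rng.integers(0, n, n)
            ti = t[idx]
            if ti.all() or not ti.any():
                tprs[i] = grid
                aucs[i] = 0.5
                continue
        fpr, tpr = _roc_points(s[idx], ti)
        tprs[i] = np.interp(grid, fpr, tpr)
        aucs[i] = np.trapezoid(tpr, fpr)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    band = (np.percentile(tprs, lo_q, axis=0), np.percentile(tprs, hi_q, axis=0))
    return RocResult(fpr_grid=grid, tpr_mean=tprs.mean(axis=0), tpr_ci=band,
                     auc=roc_auc(s, t), auc_ci=(float(np.percentile(aucs, lo_q)),
                                                float(np.percentile(aucs, hi_q))),
                     n_boot=n_boot, alpha=alpha, truth_tag=truth_tag,
                     source_tag=source_tag)


@dataclass
class MethodComparison:
    auc_difference: float
    ci_overlap: bool
    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def compare_methods(result_a: RocResult, result_b: RocResult) -> MethodComparison:
    """AUC difference and whether the two AUC confidence intervals overlap."""
    if result_a.truth_tag != result_b.truth_tag:
        raise ComparisonError(
            f"truth tags differ: {result_a.truth_tag!r} vs {result_b.truth_tag!r}")
    a_lo, a_hi = result_a.auc_ci
    b_lo, b_hi = result_b.auc_ci
    overlap = (a_lo <= b_hi) and (b_lo <= a_hi)
    return MethodComparison(auc_difference=result_a.auc - result_b.auc,
                            ci_overlap=bool(overlap), auc_a=result_a.auc,
                            auc_b=result_b.auc, ci_a=(a_lo, a_hi),
                            ci_b=(b_lo, b_hi))


def summarize_cohort(table: CohortTable) -> dict:
    """Per-patient total lesion volumes and cohort descriptives."""
    totals = {p.patient_id: p.total_volume_ml for p in table.patients}
    vols = np.array(list(totals.values()))
    pathology: dict[str, int] = {}
    hemisphere: dict[str, int] = {}
    for p in table.patients:
        pathology[p.pathology] = pathology.get(p.pathology, 0) + 1
        loc = p.lesions[0][0].lower()
        side = loc.split()[0]
        if side == "bilateral":
            # dominant side, e.g. "bilateral frontal lobes (left>right)"
            side = "left" if "left>" in loc else (
                "right" if "right>" in loc else "bilateral")
        if side not in ("left", "right", "bilateral"):
            side = "other"
        hemisphere[side] = hemisphere.get(side, 0) + 1
    return {"n_patients": table.n_patients,
            "total_volume_ml": totals,
            "mean_volume_ml": float(vols.mean()),
            "min_volume_ml": float(vols.min()),
            "max_volume_ml": float(vols.max()),
            "pathology_counts": pathology,
            "hemisphere_counts": hemisphere}


def plot_roc(results: dict[str, RocResult], path: str, title: str = "") -> None:
    """Write a ROC figure (mean curves with confidence bands)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        ax.plot(res.fpr_grid, res.tpr_mean,
                label=f"{name} (AUC {res.auc:.3f})")
        ax.fill_between(res.fpr_grid, res.tpr_ci[0], res.tpr_ci[1], alpha=0.2)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
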