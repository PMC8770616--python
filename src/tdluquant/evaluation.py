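"""Segmentation and agreement metrics.

Per-class and pixel-weighted Dice scores with bootstrap confidence
intervals, row-normalized confusion matrices, Cohen's kappa (linear-
weighted and unweighted) for ordinal rater agreement, and a generic
percentile bootstrap. Dice is evaluated on the six tissue classes after
the derived border class has been merged back into intralobular stroma in
both maps; background (unannotated) pixels are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classes as C
from .annotations import LabelMap
from .features import merge_border

__all__ = [
    "dice",
    "DiceReport",
    "dice_report",
    "confusion_matrix",
    "KappaReport",
    "cohens_kappa",
    "bootstrap_ci",
]


def dice(seg: LabelMap, truth: LabelMap, class_code: int) -> float:
    """Dice overlap 2|S∩G| / (|S|+|G|) for one class.

    1.0 when the class is absent from both maps (correctly predicted
    absent), 0.0 when present in exactly one.
    """
    if seg.shape != truth.shape:
        raise ValueError(f"extent mismatch: {seg.shape} vs {truth.shape}")
    s = seg.codes == class_code
    g = truth.codes == class_code
    denom = int(s.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(s & g)) / denom


@dataclass
class DiceReport:
    per_class: dict[str, float]
    weighted_mean: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    weighted_mean_ci95: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": name,
                "dice": score,
                "ci_low": self.ci95.get(name, (np.nan, np.nan))[0],
                "ci_high": self.ci95.get(name, (np.nan, np.nan))[1],
            }
            for name, score in self.per_class.items()
        ]
        rows.append(
            {
                "class": "all (weighted mean)",
                "dice": self.weighted_mean,
                "ci_low": (self.weighted_mean_ci95 or (np.nan, np.nan))[0],
                "ci_high": (self.weighted_mean_ci95 or (np.nan, np.nan))[1],
            }
        )
        return pd.DataFrame(rows)


def _pair_stats(pairs, classes) -> np.ndarray:
    """Per-pair, per-class (intersection, |S|+|G|, |G|) pixel counts."""
    stats = np.zeros((len(pairs), len(classes), 3), dtype=np.int64)
    for i, (seg, truth) in enumerate(pairs):
        for j, c in enumerate(classes):
            s = seg.codes == c
            g = truth.codes == c
            stats[i, j] = (
                int(np.count_nonzero(s & g)),
                int(s.sum()) + int(g.sum()),
                int(g.sum()),
            )
    return stats


def _pooled_dice(stats: np.ndarray) -> tuple[np.ndarray, float]:
    """Pooled (micro) per-class Dice and ground-truth-pixel-weighted mean."""
    totals = stats.sum(axis=0)  # (n_classes, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(
            totals[:, 1] > 0, 2.0 * totals[:, 0] / totals[:, 1], np.nan
        )
    g_count = totals[:, 2]
    present = g_count > 0
    weighted = (
        float((per_class[present] * g_count[present]).sum() / g_count[present].sum())
        if present.any()
        else np.nan
    )
    return per_class, weighted


def dice_report(
    pairs: list[tuple[LabelMap, LabelMap]],
    n_boot: int = 2000,
    seed: int = 0,
    merge_border_first: bool = True,
) -> DiceReport:
    """Pooled Dice over (segmentation, ground truth) pairs with bootstrap CIs.

    Intersections and mask sizes are summed over all pairs before the ratio
    (micro pooling); the overall score weights each class by its
    ground-truth pixel count. Confidence intervals resample the pairs
    (annotated regions) with replacement, n=2000 by default. Classes absent
    from every ground truth are reported as NaN.
    """
    if not pairs:
        raise ValueError("need at least one (segmentation, truth) pair")
    if merge_border_first:
        pairs = [(merge_border(s), merge_border(g)) for s, g in pairs]
    classes = list(C.EVALUATED)
    stats = _pair_stats(pairs, classes)
    per_class, weighted = _pooled_dice(stats)

    rng = np.random.default_rng(seed)
    n = len(pairs)
    boot_pc = np.empty((n_boot, len(classes)))
    boot_w = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot_pc[b], boot_w[b] = _pooled_dice(stats[idx])
    ci95 = {}
    for j, c in enumerate(classes):
        vals = boot_pc[:, j]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            ci95[C.CLASS_NAMES[c]] = (
                float(np.percentile(vals, 2.5)),
                float(np.percentile(vals, 97.5)),
            )
    w = boot_w[~np.isnan(boot_w)]
    weighted_ci = (
        (float(np.percentile(w, 2.5)), float(np.percentile(w, 97.5))) if len(w) else None
    )
    return DiceReport(
        per_class={
            C.CLASS_NAMES[c]: float(per_class[j]) for j, c in enumerate(classes)
        },
        weighted_mean=float(weighted),
        ci95=ci95,
        weighted_mean_ci95=weighted_ci,
    )


def confusion_matrix(
    seg: LabelMap, truth: LabelMap, classes=None, normalize: str = "rows"
) -> pd.DataFrame:
    """Row-normalized confusion matrix (rows: ground truth, cols: predicted).

    Each row sums to 1 for classes present in the ground truth and is all
    zeros otherwise.
    """
    if seg.shape != truth.shape:
        raise ValueError(f"extent mismatch: {seg.shape} vs {truth.shape}")
    classes = list(classes) if classes is not None else list(C.EVALUATED)
    k = len(classes)
    code_to_idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=np.int64)
    g = truth.codes.ravel()
    s = seg.codes.ravel()
    keep = np.isin(g, classes) & np.isin(s, classes)
    g_idx = np.vectorize(code_to_idx.get)(g[keep]) if keep.any() else np.array([], int)
    s_idx = np.vectorize(code_to_idx.get)(s[keep]) if keep.any() else np.array([], int)
    np.add.at(counts, (g_idx, s_idx), 1)
    mat = counts.astype(float)
    if normalize == "rows":
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sums > 0, mat / sums, 0.0)
    names = [C.CLASS_NAMES[c] for c in classes]
    return pd.DataFrame(mat, index=names, columns=names)


def plot_confusion_heatmap(matrix: pd.DataFrame, path=None):
    """Render a row-normalized confusion matrix as a heat map.

    Rows are ground truth, columns predictions; cell text is the
    row-normalized fraction as a percentage.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1.2 * len(matrix.columns) + 2, 1.0 * len(matrix) + 2))
    im = ax.imshow(values, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("ground truth")
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            ax.text(
                j,
                i,
                f"{100 * values[i, j]:.0f}%",
                ha="center",
                va="center",
                fontsize=8,
                color="black" if values[i, j] < 0.6 else "white",
            )
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass
class KappaReport:
    kappa: float
    weighting: str  # "linear" | "unweighted"
    n_items: int
    ci95: tuple[float, float] | None = None


def cohens_kappa(a, b, weighting: str = "linear", categories=None) -> KappaReport:
    """Cohen's kappa between two raters on an ordinal 0-5 scale.

    kappa = 1 - (sum w_ij O_ij) / (sum w_ij E_ij), with disagreement
    weights w_ij = |i - j| (linear) or 1[i != j] (unweighted); E is the
    outer product of the marginals. Agreement bands: <0 none, 0-0.20
    slight, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial,
    0.81-1 almost perfect.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("rating vectors differ in length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 rated items")
    cats = (
        np.asarray(sorted(categories))
        if categories is not None
        else np.arange(min(a.min(), b.min()), max(a.max(), b.max()) + 1)
    )
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    observed = np.zeros((k, k), dtype=float)
    for ai, bi in zip(a, b):
        observed[idx[ai], idx[bi]] += 1
    observed /= n
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weighting == "linear":
        w = np.abs(ii - jj).astype(float)
    elif weighting == "unweighted":
        w = (ii != jj).astype(float)
    else:
        raise ValueError("weighting must be 'linear' or 'unweighted'")
    denom = float((w * expected).sum())
    if denom == 0.0:
        return KappaReport(kappa=1.0, weighting=weighting, n_items=n)
    kappa = 1.0 - float((w * observed).sum()) / denom
    return KappaReport(kappa=kappa, weighting=weighting, n_items=n)


def bootstrap_ci(
    items, statistic, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """95% percentile bootstrap CI of ``statistic`` over resampled items.

    The resampling unit is the item a rating or an image pair belongs to
    (TDLU for kappa, annotated region for Dice). Deterministic given seed;
    a constant statistic yields a zero-width interval.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to bootstrap")
    rng = np.random.default_rng(seed)
    n = len(items)
    stats = np.empty(n_boot, dtype=float)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[i] = statistic([items[j] for j in idx])
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))
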