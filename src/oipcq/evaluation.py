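"""Scoring inferred skeletons against gold standards, ROC/AUC sweeps, and
the robustness studies (gene-order permutations, threshold sweeps,
subsample stability).

All comparisons are undirected: a directed gold standard collapses each
regulator→target pair to a single undirected edge before counting, because
the inferred object is a skeleton without orientations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .baseline import pca_cmi
from .inference import InferenceConfig, infer
from .io_formats import ExpressionMatrix
from .skeleton import Skeleton

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc_auc",
    "permutation_study",
    "threshold_sd_study",
    "subsample_stability",
    "PermutationStudyResult",
    "make_method",
]

InferFn = Callable[[ExpressionMatrix, float], Skeleton]


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-level confusion counts over all unordered gene pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The standard benchmark metric block.

    TPR = TP/(TP+FN), PPV = TP/(TP+FP), FPR = FP/(FP+TN), FDR = FP/(FP+TP),
    ACC = (TP+TN)/total, F = 2·PPV·TPR/(PPV+TPR), and MCC with the
    square-rooted denominator √((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Every 0/0
    ratio is reported as 0 (the empty-prediction limit).
    """

    tpr: float
    ppv: float
    fpr: float
    fdr: float
    acc: float
    f_measure: float
    mcc: float


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), fpr non-decreasing
    auc: float
    thresholds: tuple[float, ...]


def confusion(pred: Skeleton, gold: Skeleton) -> ConfusionCounts:
    """Count TP/FP/TN/FN over all unordered pairs of the shared gene set."""
    if set(pred.gene_ids) != set(gold.gene_ids):
        raise ValueError("prediction and gold standard cover different gene sets")
    n = pred.n_genes
    total = n * (n - 1) // 2
    tp = len(pred.edges & gold.edges)
    fp = len(pred.edges - gold.edges)
    fn = len(gold.edges - pred.edges)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(c: ConfusionCounts) -> MetricSet:
    """Derive the full metric set from confusion counts; degenerate counts
    follow the 0-conventions documented on :class:`MetricSet`."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    tpr = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    fpr = _ratio(fp, fp + tn)
    fdr = _ratio(fp, fp + tp)
    acc = _ratio(tp + tn, c.total)
    f = _ratio(2 * ppv * tpr, ppv + tpr)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return MetricSet(tpr=tpr, ppv=ppv, fpr=fpr, fdr=fdr, acc=acc, f_measure=f, mcc=mcc)


def f_measure(pred: Skeleton, gold: Skeleton) -> float:
    return metrics(confusion(pred, gold)).f_measure


# ---------------------------------------------------------------------------
# method adapters
# ---------------------------------------------------------------------------


def make_method(
    name: Literal["oipcq", "oipcq2", "pca-cmi", "cmi2ni"],
    quantile_k: float = 70.0,
    max_order: int = 2,
    gene_order: Sequence[str] | None = None,
) -> InferFn:
    """Build a ``(expr, theta) -> Skeleton`` adapter for sweeps.

    For OIPCQ/OIPCQ2 the single swept θ sets both θ1 and θ2 (k held fixed);
    for the baselines θ is their single threshold. ``cmi2ni`` is the
    CMI2NI-style baseline: the PCA-CMI loop with the CMI2 estimator.
    """
    if name in ("oipcq", "oipcq2"):
        est = "cmi2" if name == "oipcq2" else "cmi"

        def run(expr: ExpressionMatrix, theta: float) -> Skeleton:
            cfg = InferenceConfig(
                theta1=theta, theta2=theta, quantile_k=quantile_k,
                max_order=max_order, estimator=est,
            )
            return infer(expr, cfg)[0]

    elif name in ("pca-cmi", "cmi2ni"):
        est = "cmi2" if name == "cmi2ni" else "cmi"

        def run(expr: ExpressionMatrix, theta: float) -> Skeleton:
            return pca_cmi(
                expr, theta, gene_order=gene_order, max_order=max_order,
                estimator=est,
            )

    else:
        raise ValueError(f"unknown method {name!r}")
    return run


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(
    expr: ExpressionMatrix,
    gold: Skeleton,
    method: InferFn,
    theta_grid: Sequence[float],
) -> ROCCurve:
    """Sweep the threshold grid, collect (FPR, TPR) points, anchor with
    (0,0) and (1,1), and integrate by the trapezoid rule over the
    fpr-sorted points. Duplicate points are collapsed."""
    if len(theta_grid) == 0:
        raise ValueError("theta_grid must be non-empty")
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for theta in theta_grid:
        m = metrics(confusion(method(expr, theta), gold))
        pts.add((m.fpr, m.tpr))
    ordered = sorted(pts)
    fprs = np.array([p[0] for p in ordered])
    tprs = np.array([p[1] for p in ordered])
    auc = float(np.trapezoid(tprs, fprs))
    return ROCCurve(points=tuple(ordered), auc=auc, thresholds=tuple(theta_grid))


# ---------------------------------------------------------------------------
# robustness studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationStudyResult:
    tp_fp: tuple[tuple[int, int], ...]
    f_values: tuple[float, ...]
    sd_tp: float
    sd_fp: float

    @property
    def n_distinct(self) -> int:
        return len(set(self.tp_fp))


def permutation_study(
    expr: ExpressionMatrix,
    gold: Skeleton,
    method: Literal["pca-cmi", "cmi2ni", "oipcq", "oipcq2"],
    n_perms: int,
    theta: float,
    seed: int,
    max_order: int = 2,
    quantile_k: float = 70.0,
    permutations: Sequence[Sequence[str]] | None = None,
) -> PermutationStudyResult:
    """Rerun a method under ``n_perms`` random gene-order permutations and
    record the (TP, FP) scatter — the order-dependency experiment.

    Order-dependent baselines receive each permutation as their visitation
    order; OIPCQ/OIPCQ2 (the controls) receive the data with columns
    physically permuted, which must not change their output. Explicit
    ``permutations`` override the seeded draw (used for exhaustive studies).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be at least 1")
    rng = np.random.default_rng(seed)
    ids = list(expr.gene_ids)
    if permutations is None:
        permutations = [
            [ids[i] for i in rng.permutation(len(ids))] for _ in range(n_perms)
        ]
    tp_fp: list[tuple[int, int]] = []
    fs: list[float] = []
    for perm in permutations:
        if method in ("pca-cmi", "cmi2ni"):
            pred = make_method(method, max_order=max_order, gene_order=list(perm))(
                expr, theta
            )
        else:
            shuffled = expr.reorder_genes(perm)
            pred = make_method(method, quantile_k=quantile_k, max_order=max_order)(
                shuffled, theta
            )
        m = metrics(confusion(pred, gold))
        c = confusion(pred, gold)
        tp_fp.append((c.tp, c.fp))
        fs.append(m.f_measure)
    tps = np.array([t for t, _ in tp_fp], dtype=float)
    fps = np.array([f for _, f in tp_fp], dtype=float)
    return PermutationStudyResult(
        tp_fp=tuple(tp_fp),
        f_values=tuple(fs),
        sd_tp=float(tps.std(ddof=0)),
        sd_fp=float(fps.std(ddof=0)),
    )


def threshold_sd_study(
    expr: ExpressionMatrix,
    gold: Skeleton,
    method: InferFn,
    grid: Sequence[float] | None = None,
    sweep: Literal["theta", "quantile"] = "theta",
    sd_divisor: Literal["population", "sample"] = "population",
) -> tuple[float, float, tuple[tuple[int, int], ...]]:
    """Standard deviation of TP and FP across a threshold (or quantile) grid.

    Default grids follow the benchmark protocol: θ ∈ (0,1) in steps of 0.001
    for ``sweep="theta"`` (with k fixed inside ``method``), and k ∈ [50,90]
    percent in steps of 0.1 for ``sweep="quantile"`` (with θ fixed inside
    ``method``; the callable then receives k as its second argument).
    Returns (sd_tp, sd_fp, recorded (tp, fp) sequence).
    """
    if grid is None:
        grid = (
            np.arange(0.001, 1.0, 0.001)
            if sweep == "theta"
            else np.arange(50.0, 90.0 + 1e-9, 0.1)
        )
    tp_fp: list[tuple[int, int]] = []
    for value in grid:
        c = confusion(method(expr, float(value)), gold)
        tp_fp.append((c.tp, c.fp))
    ddof = 0 if sd_divisor == "population" else 1
    tps = np.array([t for t, _ in tp_fp], dtype=float)
    fps = np.array([f for _, f in tp_fp], dtype=float)
    return float(tps.std(ddof=ddof)), float(fps.std(ddof=ddof)), tuple(tp_fp)


def subsample_stability(
    expr: ExpressionMatrix,
    gold: Skeleton,
    method: Callable[[ExpressionMatrix], Skeleton],
    drop_fraction: float = 0.1,
    reps: int = 200,
    seed: int = 0,
    sd_divisor: Literal["sample", "population"] = "sample",
) -> tuple[float, tuple[float, ...]]:
    """Stability of the F-measure under random sample removal.

    Each replicate removes ``floor(drop_fraction·m)`` samples uniformly
    without replacement, reruns ``method`` at fixed configuration and
    records the F-measure; returns (sd, per-replicate F values).
    """
    if not (0 < drop_fraction < 1):
        raise ValueError("drop_fraction must lie in (0, 1)")
    m = expr.n_samples
    n_drop = int(drop_fraction * m)
    if m - n_drop < 5:
        raise ValueError("too few samples would remain after dropping")
    rng = np.random.default_rng(seed)
    fs: list[float] = []
    for _ in range(reps):
        keep = np.sort(rng.choice(m, size=m - n_drop, replace=False))
        pred = method(expr.subset_samples(keep))
        fs.append(metrics(confusion(pred, gold)).f_measure)
    if reps == 1:
        warnings.warn("standard deviation undefined for a single replicate; reporting 0")
        return 0.0, tuple(fs)
    ddof = 1 if sd_divisor == "sample" else 0
    return float(np.array(fs).std(ddof=ddof)), tuple(fs)
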