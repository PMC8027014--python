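"""OIPCQ: order-independent, quantile-thresholded PC-style skeleton inference.

The algorithm starts from the complete graph and prunes it in at most three
rounds of conditional-independence tests of increasing order:

* order 0 — remove every edge whose mutual information is below θ1;
* order 1 — for each surviving edge X–Y, condition on each single gene of
  ``V_XY`` (common neighbors); the edge's statistic is the k-th percentile
  of its CMI values, and it is removed when that statistic is below θ2;
* order 2 — condition on each unordered pair drawn from ``U_XY`` (union of
  neighborhoods, covering paths of length 3); same percentile rule.

Two design points give order independence, i.e. an inferred edge set that
does not depend on how the input genes are ordered:

1. the separator pools of an order are computed on the *previous* order's
   skeleton and frozen before any test of the current order runs;
2. removals are applied in a single batch at the end of each order.

Edges with an empty separator pool at an order are kept untested — PC-family
convention: edges are removed only on positive evidence of independence.
Percentiles over pools that contain saturated (collinearity-capped)
estimator values include the cap itself, so collinear conditioners count as
strong dependence and never cause a removal.

OIPCQ2 is the same procedure with the CMI2 estimator substituted at orders
1 and 2; order 0 uses plain MI in both variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .info_measures import (
    EstimatorValue,
    GaussianStats,
    cmi2_from_stats,
    cmi_gaussian_from_stats,
    mi_gaussian_from_stats,
)
from .skeleton import Skeleton, complete_skeleton

__all__ = [
    "InferenceConfig",
    "EdgeStats",
    "EdgeStatistics",
    "percentile",
    "run_order0",
    "run_order1",
    "run_order2",
    "infer",
]

logger = logging.getLogger("oipcq")

Edge = tuple[str, str]
EstimatorName = Literal["cmi", "cmi2"]


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable parameters of a run.

    θ1 is the MI threshold (order 0), θ2 the CMI threshold (orders 1–2),
    both strict and in nats; ``quantile_k`` is the percentile of the
    per-edge CMI distribution that is compared against θ2 (k = 100 recovers
    the classical CMI_max rule); ``estimator`` selects OIPCQ (``cmi``) or
    OIPCQ2 (``cmi2``).
    """

    theta1: float = 0.05
    theta2: float = 0.05
    quantile_k: float = 70.0
    max_order: int = 2
    estimator: EstimatorName = "cmi"

    def __post_init__(self) -> None:
        if self.theta1 < 0 or self.theta2 < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 < self.quantile_k <= 100):
            raise ValueError("quantile_k must lie in (0, 100]")
        if self.max_order not in (0, 1, 2):
            raise ValueError("max_order must be 0, 1 or 2")
        if self.estimator not in ("cmi", "cmi2"):
            raise ValueError("estimator must be 'cmi' or 'cmi2'")


@dataclass
class EdgeStats:
    """Per-pair audit trail across all orders."""

    mi: float = float("nan")
    order1_values: list[float] = field(default_factory=list)
    order1_quantile: float | None = None
    order2_values: list[float] = field(default_factory=list)
    order2_quantile: float | None = None
    removed_at_order: int | str = "kept"
    v_set: frozenset[str] = frozenset()
    u_set: frozenset[str] = frozenset()


class EdgeStatistics(dict):
    """Mapping from canonical (a, b) pairs (a < b) to :class:`EdgeStats`."""

    def get_pair(self, x: str, y: str) -> EdgeStats:
        return self[(x, y) if x < y else (y, x)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (a, b), st in sorted(self.items()):
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "mi": st.mi,
                    "order1_quantile": st.order1_quantile,
                    "order2_quantile": st.order2_quantile,
                    "removed_at_order": st.removed_at_order,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_a",
                "gene_b",
                "mi",
                "order1_quantile",
                "order2_quantile",
                "removed_at_order",
            ],
        )


def percentile(values: Iterable[float], k: float) -> float:
    """k-th percentile with linear interpolation between order statistics
    (position (n−1)·k/100). k = 100 gives the maximum; a singleton list
    returns its single value."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("percentile of an empty list is undefined")
    if not (0 < k <= 100):
        raise ValueError("k must lie in (0, 100]")
    return float(np.percentile(vals, k))


def _estimator(
    config: InferenceConfig, stats: GaussianStats
) -> Callable[[str, str, Iterable[str]], EstimatorValue]:
    if config.estimator == "cmi2":
        return lambda x, y, cond: cmi2_from_stats(stats, x, y, cond)
    return lambda x, y, cond: cmi_gaussian_from_stats(stats, x, y, cond)


def run_order0(
    expr: ExpressionMatrix,
    config: InferenceConfig,
    stats: EdgeStatistics | None = None,
    gauss: GaussianStats | None = None,
) -> tuple[Skeleton, EdgeStatistics]:
    """Order-0 round: MI relevance filtering on the complete graph.

    Both variants use plain MI here. All removals are simultaneous (the
    per-pair tests are independent, so batching matters only for symmetry
    with later orders).
    """
    gauss = gauss or GaussianStats.from_expression(expr)
    stats = stats if stats is not None else EdgeStatistics()
    s_start = complete_skeleton(expr.gene_ids)
    drop: list[Edge] = []
    for a, b in sorted(s_start.edges):
        mi = mi_gaussian_from_stats(gauss, a, b).value
        st = stats.setdefault((a, b), EdgeStats())
        st.mi = mi
        if mi < config.theta1:
            st.removed_at_order = 0
            drop.append((a, b))
    s0 = s_start.remove_edges(drop)
    logger.info(
        "order 0: removed %d of %d edges (MI < %g), %d kept",
        len(drop), s_start.n_edges, config.theta1, s0.n_edges,
    )
    return s0, stats


def _run_conditional_order(
    skeleton: Skeleton,
    config: InferenceConfig,
    estimator: Callable[[str, str, Iterable[str]], EstimatorValue],
    stats: EdgeStatistics,
    order: int,
) -> Skeleton:
    """Shared machinery of orders 1 and 2: freeze pools, test, batch-remove."""
    drop: list[Edge] = []
    for a, b in sorted(skeleton.edges):
        st = stats.setdefault((a, b), EdgeStats())
        if order == 1:
            pool = skeleton.v_set(a, b)
            st.v_set = pool
            cond_sets: list[tuple[str, ...]] = [(z,) for z in sorted(pool)]
        else:
            pool = skeleton.u_set(a, b)
            st.u_set = pool
            cond_sets = list(combinations(sorted(pool), 2))
        if not cond_sets:
            continue  # untestable at this order: keep the edge
        values = [estimator(a, b, cond).value for cond in cond_sets]
        q = percentile(values, config.quantile_k)
        if order == 1:
            st.order1_values, st.order1_quantile = values, q
        else:
            st.order2_values, st.order2_quantile = values, q
        if q < config.theta2:
            st.removed_at_order = order
            drop.append((a, b))
    result = skeleton.remove_edges(drop)
    logger.info(
        "order %d: removed %d of %d edges (CMI_%g < %g), %d kept",
        order, len(drop), skeleton.n_edges, config.quantile_k,
        config.theta2, result.n_edges,
    )
    return result


def run_order1(
    s0: Skeleton,
    expr: ExpressionMatrix,
    config: InferenceConfig,
    stats: EdgeStatistics | None = None,
    gauss: GaussianStats | None = None,
) -> tuple[Skeleton, EdgeStatistics]:
    """Order-1 round: percentile of CMI(X,Y|Z) over Z ∈ V_XY, pools frozen
    on ``s0``, removals batched at order end."""
    gauss = gauss or GaussianStats.from_expression(expr)
    stats = stats if stats is not None else EdgeStatistics()
    s1 = _run_conditional_order(s0, config, _estimator(config, gauss), stats, order=1)
    return s1, stats


def run_order2(
    s1: Skeleton,
    expr: ExpressionMatrix,
    config: InferenceConfig,
    stats: EdgeStatistics | None = None,
    gauss: GaussianStats | None = None,
) -> tuple[Skeleton, EdgeStatistics]:
    """Order-2 round: percentile of CMI(X,Y|Z,W) over unordered pairs
    {Z,W} ⊆ U_XY, pools frozen on ``s1``, removals batched at order end.

    Requires at least 5 samples so the 4×4 covariance can be full rank.
    """
    if expr.n_samples < 5:
        raise ValueError("order-2 inference requires at least 5 samples")
    gauss = gauss or GaussianStats.from_expression(expr)
    stats = stats if stats is not None else EdgeStatistics()
    s2 = _run_conditional_order(s1, config, _estimator(config, gauss), stats, order=2)
    return s2, stats


def infer(
    expr: ExpressionMatrix, config: InferenceConfig | None = None
) -> tuple[Skeleton, EdgeStatistics]:
    """Run OIPCQ (or OIPCQ2 when ``config.estimator == "cmi2"``) end to end.

    Orders 0..max_order are applied in sequence; the returned edge set is
    invariant to any permutation of the input gene columns, and the audit
    trail records every per-edge statistic and the order of each removal.
    """
    config = config or InferenceConfig()
    gauss = GaussianStats.from_expression(expr)
    stats = EdgeStatistics()
    skeleton, _ = run_order0(expr, config, stats, gauss)
    if config.max_order >= 1:
        skeleton, _ = run_order1(skeleton, expr, config, stats, gauss)
    if config.max_order >= 2:
        skeleton, _ = run_order2(skeleton, expr, config, stats, gauss)
    return skeleton, stats
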