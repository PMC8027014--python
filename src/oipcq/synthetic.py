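"""Seeded linear-Gaussian network simulator.

Generates ground-truth DAGs and expression data from a linear structural
equation model: each gene is a weighted sum of its parents plus independent
Gaussian noise. In this family the Gaussian MI/CMI estimators are exact, so
skeleton-recovery properties of the inference algorithms are meaningful and
every experiment in the package can run without external downloads. The
simulator emulates steady-state (single-snapshot) expression compendia; it
does not model time courses, knockouts, or non-Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import ExpressionMatrix
from .skeleton import Skeleton

__all__ = ["SyntheticModel", "random_model", "sample", "gold_skeleton"]


@dataclass(frozen=True)
class SyntheticModel:
    """A ground-truth causal model: DAG + edge weights + per-gene noise."""

    gene_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # directed (parent, child)
    weights: tuple[float, ...]  # aligned with edges
    noise_sd: float
    topo_order: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("model graph must be acyclic")
        if len(self.weights) != len(self.edges):
            raise ValueError("one weight per directed edge required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _gene_ids(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"G{i + 1:0{width}d}" for i in range(n))


def random_model(
    n_genes: int,
    expected_degree: float = 2.0,
    weight_range: tuple[float, float] = (0.6, 1.0),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticModel:
    """Erdős–Rényi-style random DAG with uniform ± weights.

    A random topological order is drawn; each forward pair becomes an edge
    with probability ``expected_degree/(n_genes−1)``, giving mean total
    degree ``expected_degree``. Weights are uniform on ±[lo, hi] (bounded
    away from zero so every true edge is detectable in principle). Fully
    deterministic given the seed.
    """
    lo, hi = weight_range
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not (0 < lo < hi):
        raise ValueError("weight_range must satisfy 0 < lo < hi")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    p = expected_degree / (n_genes - 1)
    if not (0 <= p <= 1):
        raise ValueError(
            f"expected_degree {expected_degree} infeasible for {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    ids = _gene_ids(n_genes)
    topo = tuple(ids[i] for i in rng.permutation(n_genes))
    edges: list[tuple[str, str]] = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                edges.append((topo[i], topo[j]))
    magnitudes = rng.uniform(lo, hi, size=len(edges))
    signs = rng.choice([-1.0, 1.0], size=len(edges))
    return SyntheticModel(
        gene_ids=ids,
        edges=tuple(edges),
        weights=tuple(float(w) for w in magnitudes * signs),
        noise_sd=float(noise_sd),
        topo_order=topo,
        seed=seed,
    )


def sample(model: SyntheticModel, n_samples: int, seed: int = 0) -> ExpressionMatrix:
    """Draw expression samples by ancestral sampling of the linear SEM.

    ``X_child = Σ w·X_parent + ε``, ε ~ N(0, noise_sd²) i.i.d. Columns of
    the result are ordered by gene id — not topological order — so nothing
    downstream can accidentally exploit a causal ordering. Bit-identical
    for identical (model, seed).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    parents: dict[str, list[tuple[str, float]]] = {g: [] for g in model.gene_ids}
    for (a, b), w in zip(model.edges, model.weights):
        parents[b].append((a, w))
    values: dict[str, np.ndarray] = {}
    for g in model.topo_order:
        x = rng.normal(0.0, model.noise_sd, size=n_samples)
        for parent, w in parents[g]:
            x = x + w * values[parent]
        values[g] = x
    matrix = np.column_stack([values[g] for g in model.gene_ids])
    return ExpressionMatrix(model.gene_ids, matrix)


def gold_skeleton(model: SyntheticModel) -> Skeleton:
    """The undirected version of the model's DAG — the recovery target."""
    return Skeleton(model.gene_ids, model.edges)
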