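"""Shared fixtures: small hand-built matrices, seeded synthetic data sets,
and the frozen parameters of the two calibrated study fixtures."""

from __future__ import annotations

import numpy as np
import pytest

import oipcq

# ---------------------------------------------------------------------------
# Frozen fixture parameters
# ---------------------------------------------------------------------------

#: 4-gene dataset on which the order-dependent baseline provably disagrees
#: with itself across visitation orders (verified by the exhaustive 24-order
#: oracle in the baseline tests). Found by a pilot search over simulator
#: seeds; frozen here.
ORDER_SENSITIVE = dict(model_seed=0, sample_seed=1000, n_samples=40, theta=0.08)

#: Recovery-suite conditions: 20-gene random DAGs, expected degree 2,
#: |weights| in [0.6, 1.0], noise sd 0.5, 500 samples, thresholds
#: θ1 = θ2 = 0.05, k = 70.
RECOVERY = dict(
    n_genes=20, expected_degree=2.0, weight_range=(0.6, 1.0),
    noise_sd=0.5, n_samples=500, theta=0.05, quantile_k=70.0, n_seeds=20,
)

#: Median-F floor for the recovery suite, calibrated by a pilot run under
#: exactly the conditions above (pilot median F over the 20 seeds: 0.885).
#: The floor is set well below the pilot point so that it tests gross
#: regressions, not run-to-run noise.
RECOVERY_MEDIAN_F_FLOOR = 0.75


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def tiny_expr() -> oipcq.ExpressionMatrix:
    """4-sample, 2-gene matrix with known covariance (off-diag 4/3)."""
    return oipcq.ExpressionMatrix(
        ("x", "y"), np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0], [4.0, 4.0]])
    )


@pytest.fixture(scope="session")
def order_sensitive_data():
    """The crafted 4-gene dataset plus its threshold."""
    p = ORDER_SENSITIVE
    model = oipcq.random_model(4, expected_degree=2.0, noise_sd=0.5,
                               seed=p["model_seed"])
    expr = oipcq.sample(model, p["n_samples"], seed=p["sample_seed"])
    return expr, p["theta"]


def _recovery_run(seed: int):
    p = RECOVERY
    model = oipcq.random_model(
        p["n_genes"], p["expected_degree"], p["weight_range"],
        p["noise_sd"], seed=seed,
    )
    expr = oipcq.sample(model, p["n_samples"], seed=seed + 10_000)
    gold = oipcq.gold_skeleton(model)
    cfg = oipcq.InferenceConfig(
        theta1=p["theta"], theta2=p["theta"], quantile_k=p["quantile_k"]
    )
    s0, stats = oipcq.run_order0(expr, cfg)
    s1, _ = oipcq.run_order1(s0, expr, cfg, stats)
    s2, _ = oipcq.run_order2(s1, expr, cfg, stats)
    return dict(expr=expr, gold=gold, cfg=cfg, s0=s0, s1=s1, s2=s2)


@pytest.fixture(scope="session")
def recovery_suite():
    """Per-seed inference runs of the full recovery study (all orders kept)."""
    return [_recovery_run(seed) for seed in range(RECOVERY["n_seeds"])]


@pytest.fixture(scope="session")
def chain_data():
    """Strong chain A→B→C: the canonical conditional-independence example."""
    rng = np.random.default_rng(42)
    a = rng.normal(0, 1, 600)
    b = 0.9 * a + rng.normal(0, 0.5, 600)
    c = 0.9 * b + rng.normal(0, 0.5, 600)
    return oipcq.ExpressionMatrix(("A", "B", "C"), np.column_stack([a, b, c]))
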