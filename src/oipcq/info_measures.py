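"""Gaussian dependency estimators: mutual information (MI), conditional
mutual information (CMI) and conditional mutual inclusive information (CMI2).

Under a joint-Gaussian model the estimators reduce to covariance
determinants:

* ``MI(X,Y)   = ½ ln( σ²_X σ²_Y / |C(X,Y)| ) = −½ ln(1 − ρ²_XY)``
* ``CMI(X,Y|Z) = ½ ln( |C(X,Z)| |C(Y,Z)| / (|C(Z)| |C(X,Y,Z)|) )``

CMI2 is the symmetrized Kullback–Leibler divergence between the observed
joint distribution P(X,Y,Z) and the two interventional distributions that
sever the X→Y (resp. Y→X) dependence:

    CMI2(X,Y|Z) = ( DKL(P ‖ P_{X→Y}) + DKL(P ‖ P_{Y→X}) ) / 2

with ``P_{X→Y}(x,y,z) = p(x,z) · ∫ p(y|z,x') p(x') dx'``. Under Gaussianity
the interventional distribution is itself Gaussian with the same mean, so
both KL terms have closed forms; see :func:`cmi2`.

All values are in nats. Degenerate (collinear) configurations are never
propagated as infinities: any determinant below a relative floor marks the
value *saturated* and the estimator returns a large finite cap, treating a
perfectly collinear pair as maximally dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .io_formats import ExpressionMatrix

__all__ = [
    "DET_FLOOR",
    "SATURATION_CAP",
    "GaussianStats",
    "covariance",
    "mi_gaussian",
    "cmi_gaussian",
    "cmi2",
    "EstimatorValue",
]

#: Relative determinant floor: a determinant below DET_FLOOR times the
#: product of the diagonal entries is treated as numerically singular.
DET_FLOOR = 1e-12

#: Value returned for saturated (collinear) configurations: ½·ln(1/DET_FLOOR).
SATURATION_CAP = 0.5 * math.log(1.0 / DET_FLOOR)


class EstimatorValue(NamedTuple):
    """An estimator result together with its saturation flag."""

    value: float
    saturated: bool


@dataclass(frozen=True)
class GaussianStats:
    """Sample covariance over a selected gene subset (divisor n−1)."""

    covariance: np.ndarray
    variable_ids: tuple[str, ...]
    sample_count: int

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", c)
        if c.shape != (len(self.variable_ids), len(self.variable_ids)):
            raise ValueError("covariance shape does not match variable ids")
        if not np.allclose(c, c.T, rtol=0, atol=1e-10 * (1 + np.abs(c).max())):
            raise ValueError("covariance matrix is not symmetric")

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix) -> "GaussianStats":
        """Full-gene covariance, computed once; entries are identical (to the
        bit) under any permutation of the input columns."""
        c = np.cov(expr.values, rowvar=False, ddof=1)
        c = np.atleast_2d(np.asarray(c, dtype=float))
        return cls(c, expr.gene_ids, expr.n_samples)

    def index(self, gene: str) -> int:
        try:
            return self.variable_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


def covariance(expr: ExpressionMatrix, genes: Sequence[str]) -> GaussianStats:
    """Unbiased sample covariance of the selected genes, in the given order.

    Duplicate selections are allowed (they yield a rank-deficient matrix,
    which downstream estimators report as saturated).
    """
    cols = [expr.column_index(g) for g in genes]
    sub = expr.values[:, cols]
    c = np.atleast_2d(np.cov(sub, rowvar=False, ddof=1))
    return GaussianStats(c, tuple(genes), expr.n_samples)


# ---------------------------------------------------------------------------
# determinant bookkeeping
# ---------------------------------------------------------------------------


def _logdet(c: np.ndarray) -> tuple[float, bool]:
    """(log-determinant, saturated). The empty matrix has determinant 1.

    Saturation is judged relative to the product of the diagonal (the
    determinant of the independent model with the same variances).
    """
    if c.size == 0:
        return 0.0, False
    diag = np.diag(c)
    if np.any(diag <= 0.0):
        return -math.inf, True
    sign, logdet = np.linalg.slogdet(c)
    ref = float(np.sum(np.log(diag)))
    if sign <= 0 or logdet < ref + math.log(DET_FLOOR):
        return -math.inf, True
    return float(logdet), False


def _cmi_from_cov(cov: np.ndarray, ix: int, iy: int, iz: Sequence[int]) -> EstimatorValue:
    """CMI(X,Y|Z) from a joint covariance by the four-determinant formula.

    With an empty conditioning set this reduces to Gaussian MI.
    """
    iz = list(iz)
    xz = [ix, *iz]
    yz = [iy, *iz]
    xyz = [ix, iy, *iz]
    ld_xz, s1 = _logdet(cov[np.ix_(xz, xz)])
    ld_yz, s2 = _logdet(cov[np.ix_(yz, yz)])
    ld_z, s3 = _logdet(cov[np.ix_(iz, iz)])
    ld_xyz, s4 = _logdet(cov[np.ix_(xyz, xyz)])
    if s1 or s2 or s3 or s4:
        return EstimatorValue(SATURATION_CAP, True)
    value = 0.5 * (ld_xz + ld_yz - ld_z - ld_xyz)
    return EstimatorValue(max(value, 0.0), False)


def _select(stats: GaussianStats, x: str, y: str, cond: Iterable[str]):
    """Canonically ordered index selection: (x, y) sorted, then sorted cond.

    Fixing the within-submatrix ordering by gene id makes every determinant
    bit-identical under any permutation of the input columns — the numerical
    half of the order-independence guarantee.
    """
    cond = sorted(set(cond))
    if x == y:
        raise ValueError("x and y must be distinct genes")
    if x in cond or y in cond:
        raise ValueError("conditioning set must not contain x or y")
    a, b = (x, y) if x < y else (y, x)
    return stats.index(a), stats.index(b), [stats.index(z) for z in cond]


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------


def mi_gaussian_from_stats(stats: GaussianStats, x: str, y: str) -> EstimatorValue:
    ix, iy, _ = _select(stats, x, y, ())
    return _cmi_from_cov(stats.covariance, ix, iy, [])


def cmi_gaussian_from_stats(
    stats: GaussianStats, x: str, y: str, cond: Iterable[str]
) -> EstimatorValue:
    ix, iy, iz = _select(stats, x, y, cond)
    return _cmi_from_cov(stats.covariance, ix, iy, iz)


def cmi2_from_stats(
    stats: GaussianStats, x: str, y: str, cond: Iterable[str]
) -> EstimatorValue:
    """Gaussian CMI2 via explicit interventional covariances.

    For the direction X→Y, regress Y on (X, Z): coefficients (a, b) and
    residual variance v. The interventional law replaces Y by
    ``a·X' + b·Z + ε`` with X' an independent copy of the X marginal, so its
    covariance keeps the (X, Z) block and substitutes

        Var(Y)    = a²·Var(X) + bᵀ C_ZZ b + v
        Cov(Y, Z) = bᵀ C_ZZ
        Cov(Y, X) = bᵀ C_ZX .

    Means coincide with the observed law, so each KL term is
    ``½ [ tr(Σq⁻¹ Σ) − d + ln|Σq| − ln|Σ| ]``. The two directions are
    averaged. If the empirical partial correlation of (X,Y) given Z is zero,
    a = 0 and the interventional law equals P, giving CMI2 = 0.
    """
    ix, iy, iz = _select(stats, x, y, cond)
    idx = [ix, iy, *iz]
    sigma = stats.covariance[np.ix_(idx, idx)]
    d = sigma.shape[0]
    ld_sigma, sat = _logdet(sigma)
    if sat:
        return EstimatorValue(SATURATION_CAP, True)

    z_pos = list(range(2, d))

    def one_direction(target: int, source: int) -> tuple[float, bool]:
        sz = [source, *z_pos]
        c_sz = sigma[np.ix_(sz, sz)]
        _, sat_sz = _logdet(c_sz)
        if sat_sz:
            return 0.0, True
        coef = np.linalg.solve(c_sz, sigma[sz, target])
        a, b = coef[0], coef[1:]
        v = sigma[target, target] - float(coef @ sigma[sz, target])
        sq = sigma.copy()
        czz = sigma[np.ix_(z_pos, z_pos)]
        sq[target, target] = (
            a * a * sigma[source, source] + float(b @ czz @ b) + max(v, 0.0)
        )
        byz = b @ sigma[np.ix_(z_pos, [source] + z_pos)]
        sq[target, source] = sq[source, target] = byz[0]
        for k, zp in enumerate(z_pos):
            sq[target, zp] = sq[zp, target] = byz[k + 1]
        ld_q, sat_q = _logdet(sq)
        if sat_q:
            return 0.0, True
        kl = 0.5 * (float(np.trace(np.linalg.solve(sq, sigma))) - d + ld_q - ld_sigma)
        return kl, False

    kl_xy, sat1 = one_direction(target=1, source=0)  # sever X→Y
    kl_yx, sat2 = one_direction(target=0, source=1)  # sever Y→X
    if sat1 or sat2:
        return EstimatorValue(SATURATION_CAP, True)
    return EstimatorValue(max(0.5 * (kl_xy + kl_yx), 0.0), False)


def mi_gaussian(expr: ExpressionMatrix, x: str, y: str) -> float:
    """Gaussian mutual information of two genes, in nats (≥ 0)."""
    return mi_gaussian_from_stats(GaussianStats.from_expression(expr), x, y).value


def cmi_gaussian(
    expr: ExpressionMatrix, x: str, y: str, cond: Iterable[str] = ()
) -> float:
    """Gaussian conditional mutual information CMI(x, y | cond), in nats.

    With an empty conditioning set this equals :func:`mi_gaussian`.
    """
    return cmi_gaussian_from_stats(
        GaussianStats.from_expression(expr), x, y, cond
    ).value


def cmi2(expr: ExpressionMatrix, x: str, y: str, cond: Iterable[str] = ()) -> float:
    """Conditional mutual inclusive information CMI2(x, y | cond), in nats."""
    return cmi2_from_stats(GaussianStats.from_expression(expr), x, y, cond).value
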