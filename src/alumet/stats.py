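"""Exact and multiple-testing statistics shared by every pipeline stage.

These primitives are implemented here rather than delegated so that the
pipeline's inferential core is fully auditable: a two-sided Fisher exact
test using the minimum-likelihood rule, Benjamini-Hochberg and Bonferroni
adjustment, and the product-moment correlation coefficient.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable2x2",
    "ZeroVarianceError",
    "fisher_exact_two_sided",
    "hypergeom_log_pmf",
    "bh_adjust",
    "bonferroni_adjust",
    "pearson_r",
]

# Tables whose point probability is within this relative tolerance of the
# observed table's are counted as "at least as extreme" (guards against
# float round-off splitting exactly tied tables).
_REL_TOL = 1e-7


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested for a constant vector."""


class ContingencyTable2x2(NamedTuple):
    """2x2 cross-tabulation of DEG status against Alu-insertion status.

    a: DEGs with Alu insertion, b: DEGs without, c: non-DEGs with,
    d: non-DEGs without.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def validate(self) -> "ContingencyTable2x2":
        for v in self:
            if v < 0 or int(v) != v:
                raise ValueError(f"counts must be non-negative integers, got {tuple(self)}")
        if self.n == 0:
            raise ValueError("contingency table is empty (N = 0)")
        return self


def hypergeom_log_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """Log hypergeometric pmf for k successes in the first row, given
    margins (row totals r1, r2; first-column total c1)."""
    k = np.asarray(k)
    n = r1 + r2
    return (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the minimum-likelihood rule: sum the hypergeometric probabilities
    of every table with the same margins whose point probability does not
    exceed that of the observed table. Any zero margin means no association
    is testable and returns p = 1. Log-space factorials keep the
    computation stable for totals well beyond 1e5.
    """
    t = ContingencyTable2x2(*table).validate()
    a, b, c, d = (int(v) for v in t)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = np.exp(hypergeom_log_pmf(ks, r1, r2, c1))
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


def _as_pvector(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending order
    statistics; ties are broken by stable sort so equal p-values share an
    adjusted value.
    """
    p = _as_pvector(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q
    return out


def bonferroni_adjust(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p * m); m defaults to len(p)."""
    p = _as_pvector(p)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Raises ZeroVarianceError when either vector is constant, since the
    coefficient is undefined rather than zero in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlation requires finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float(np.dot(xc, yc) / (sx * sy))
    return max(-1.0, min(1.0, r))
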