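"""Shared ordinary-least-squares engine.

A thin QR-based OLS with explicit rank diagnostics.  Kept minimal so the
permutation module can reuse the same partialled-out (Frisch-Waugh-Lovell)
algebra in vectorised form over thousands of genotype permutations; the
scalar path here is the reference the vectorised path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass
class OLSFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    rss: float
    fitted: np.ndarray
    resid: np.ndarray

    def term(self, name: str) -> tuple[float, float, float, float]:
        """(beta, se, t, p) for one named term."""
        i = self.names.index(name)
        return self.beta[i], self.se[i], self.t[i], self.p[i]


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise :class:`CollinearityError` naming dependent columns."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name each column that adds no rank over the columns before it,
        # so the later-entered (offending) term is reported, not the base
        offenders = []
        r = 0
        for j in range(p):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                offenders.append(names[j])
            r = rj
        raise CollinearityError(
            f"design matrix rank {rank} < {p}; collinear or constant terms: {offenders}"
        )
    if n <= p:
        raise CollinearityError(
            f"no residual degrees of freedom: n={n} observations, p={p} parameters"
        )


def ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """Fit y = X b by OLS with two-tailed t tests on ``n - p`` df."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    check_full_rank(X, names)
    Q, R = np.linalg.qr(X)
    beta = scipy.linalg.solve_triangular(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    Rinv = scipy.linalg.solve_triangular(R, np.eye(p))
    var = sigma2 * np.sum(Rinv**2, axis=1)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(list(names), beta, se, t, pvals, df, rss, fitted, resid)


def residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or columns) after OLS projection on Z."""
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ coef
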