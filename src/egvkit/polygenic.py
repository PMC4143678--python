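"""Variance-component polygenic model: y ~ N(X beta, sigma_g^2 R + sigma_e^2 I).

Fitting uses the spectral trick: one eigendecomposition R = U D U' turns
the covariance into sigma_p^2 diag(h^2 d_i + 1 - h^2) in the rotated
basis, so beta and sigma_p^2 profile out analytically and the likelihood
is maximized over the single parameter h^2 in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .pedigree import RelatednessMatrix

__all__ = ["KinshipEigen", "PolygenicFit", "fit_polygenic", "residualize"]

_RIDGE = 1e-8  # diagonal ridge applied to R before decomposition


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a relatedness matrix R (plus ridge).

    Reused across replicates: the decomposition depends only on R, while
    each phenotype replicate re-optimizes h^2 in the rotated basis.
    """

    ids: list[str]
    U: np.ndarray
    d: np.ndarray
    source: str = "ped"

    @classmethod
    def from_matrix(cls, R: RelatednessMatrix, ridge: float = _RIDGE) -> "KinshipEigen":
        vals = R.values + ridge * np.eye(len(R.ids))
        d, U = eigh(vals)
        if d.min() < -1e-6:
            raise ValueError(
                f"R is not PSD (min eigenvalue {d.min():.3e}); repair it first"
            )
        return cls(list(R.ids), U, np.clip(d, 0.0, None), R.source)

    @property
    def n(self) -> int:
        return len(self.d)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.U.T @ a


@dataclass
class PolygenicFit:
    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    method: str = "ML"
    boundary: bool = False
    flat: bool = False
    names: list[str] = field(default_factory=list)

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    @property
    def lam(self) -> float:
        """Variance ratio lambda = sigma_e^2 / sigma_g^2 used by the BLUP."""
        if self.sigma_g2 <= 0:
            raise ZeroDivisionError("sigma_g2 = 0; lambda undefined")
        return self.sigma_e2 / self.sigma_g2


def _profile_negloglik(h2, yt, Xt, d, reml):
    n, p = Xt.shape
    k = h2 * d + (1.0 - h2)
    if k.min() <= 0:  # h2 = 1 with a singular R: likelihood undefined
        return np.inf, np.full(p, np.nan), np.nan
    w = 1.0 / k
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    dof = n - p if reml else n
    sigma_p2 = max(rss / dof, np.finfo(float).tiny)  # guard exact-fit degeneracy
    ll = -0.5 * (dof * np.log(2 * np.pi * sigma_p2) + np.sum(np.log(k)) + dof)
    if reml:
        sign, logdet = np.linalg.slogdet(A)
        ll -= 0.5 * logdet
    return -ll, beta, sigma_p2


def fit_polygenic(
    y: np.ndarray,
    X: np.ndarray,
    R: RelatednessMatrix | KinshipEigen,
    method: str = "ML",
    names: list[str] | None = None,
    xtol: float = 1e-8,
) -> PolygenicFit:
    """Maximum-likelihood fit of the polygenic model.

    Parameters
    ----------
    y, X : phenotype vector and fixed-effect design (include the intercept).
    R : relatedness matrix (will be eigendecomposed) or a cached
        :class:`KinshipEigen`.
    method : "ML" (default) or "REML".

    Returns the fixed-effect estimates, the additive genetic and
    environmental variance components, narrow-sense heritability
    h^2 = sigma_g^2 / sigma_p^2, and the maximized log-likelihood.
    Degenerate kinship (R proportional to I) leaves h^2 unidentified;
    the fit returns the h^2 = 0 boundary with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X row counts differ")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in y or X")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("X is rank deficient")
    reml = method.upper() == "REML"

    eig = R if isinstance(R, KinshipEigen) else KinshipEigen.from_matrix(R)
    if eig.n != y.size:
        raise ValueError("R dimension does not match y")
    yt = eig.rotate(y)
    Xt = eig.rotate(X)
    d = eig.d

    flat = float(d.max() - d.min()) < 1e-9
    if flat:
        warnings.warn(
            "kinship is proportional to identity; h2 unidentifiable, "
            "returning the h2=0 boundary",
            stacklevel=2,
        )
        h2_hat = 0.0
    else:
        res = minimize_scalar(
            lambda h: _profile_negloglik(h, yt, Xt, d, reml)[0],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": xtol},
        )
        h2_hat = float(res.x)
        # snap to the boundary when it is at least as good
        for edge in (0.0, 1.0):
            if _profile_negloglik(edge, yt, Xt, d, reml)[0] <= res.fun + 1e-10:
                h2_hat = edge
                break

    nll, beta, sigma_p2 = _profile_negloglik(h2_hat, yt, Xt, d, reml)
    boundary = h2_hat in (0.0, 1.0)
    return PolygenicFit(
        beta=beta,
        sigma_g2=h2_hat * sigma_p2,
        sigma_e2=(1.0 - h2_hat) * sigma_p2,
        h2=h2_hat,
        loglik=-nll,
        method="REML" if reml else "ML",
        boundary=boundary,
        flat=flat,
        names=list(names) if names else [],
    )


def residualize(y: np.ndarray, X: np.ndarray, fit: PolygenicFit) -> np.ndarray:
    """Fixed-effect residuals y - X beta_hat from a polygenic fit."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape != (y.size, len(fit.beta)):
        raise ValueError(
            f"dimension mismatch: X {X.shape}, y {y.size}, beta {len(fit.beta)}"
        )
    return y - X @ fit.beta
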