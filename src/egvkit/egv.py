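"""Estimated genetic values: BLUP shrinkage of residual phenotypes.

The EGV — the human analogue of an estimated breeding value — is the
random-effect solution of the mixed model with covariance
sigma_g^2 R + sigma_e^2 I:

    EGV = (I + R^{-1} lambda)^{-1} (y - X beta),   lambda = sigma_e^2 / sigma_g^2

computed here as R (R + lambda I)^{-1} resid via the eigendecomposition
of R (algebraically identical, and avoids forming R^{-1}).  The
prediction-error variance (PEV) of the BLUP,

    E = Var(EGV - g) = sigma_g^2 R - sigma_g^2 R (R + lambda I)^{-1} R,

serves as the error-variance matrix that the association model can
absorb as an extra covariance component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import RelatednessMatrix
from .polygenic import KinshipEigen, PolygenicFit, fit_polygenic, residualize

__all__ = ["EGVResult", "compute_egv", "egv_error_variance", "egv_pipeline"]


@dataclass
class EGVResult:
    """Per-individual estimated genetic values plus their error variance."""

    ids: list[str]
    egv: np.ndarray
    lam: float
    source: str
    E: np.ndarray | None = None  # PEV matrix, phenotype-units squared

    def to_frame(self, replicate: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "egv": self.egv, "source": self.source})
        if replicate is not None:
            df.insert(1, "replicate", replicate)
        return df


def _as_eigen(R: RelatednessMatrix | KinshipEigen) -> KinshipEigen:
    return R if isinstance(R, KinshipEigen) else KinshipEigen.from_matrix(R)


def compute_egv(
    resid: np.ndarray,
    R: RelatednessMatrix | KinshipEigen,
    sigma_g2: float,
    sigma_e2: float,
    with_error_variance: bool = True,
) -> EGVResult:
    """BLUP genetic values from residualized phenotypes.

    Solves (I + lambda R^{-1}) EGV = resid through the spectral form
    EGV = U diag(d / (d + lambda)) U' resid; sigma_g2 must be positive.
    """
    if sigma_g2 <= 0:
        raise ValueError("no additive variance (sigma_g2 <= 0); EGV undefined")
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be >= 0")
    resid = np.asarray(resid, dtype=float).ravel()
    eig = _as_eigen(R)
    if eig.n != resid.size:
        raise ValueError("residual length does not match R")
    lam = sigma_e2 / sigma_g2
    shrink = eig.d / (eig.d + lam)
    egv = eig.U @ (shrink * (eig.U.T @ resid))
    E = _pev(eig, sigma_g2, lam) if with_error_variance else None
    return EGVResult(list(eig.ids), egv, lam, eig.source, E)


def _pev(eig: KinshipEigen, sigma_g2: float, lam: float) -> np.ndarray:
    # sigma_g^2 (d - d^2/(d+lambda)) = sigma_g^2 d lambda / (d + lambda)
    pev_eigs = sigma_g2 * eig.d * lam / (eig.d + lam)
    E = (eig.U * pev_eigs) @ eig.U.T
    return 0.5 * (E + E.T)


def egv_error_variance(
    R: RelatednessMatrix | KinshipEigen, sigma_g2: float, sigma_e2: float
) -> np.ndarray:
    """Prediction-error variance matrix E = Var(EGV - g) of the BLUP."""
    if sigma_g2 <= 0:
        raise ValueError("no additive variance (sigma_g2 <= 0); EGV undefined")
    eig = _as_eigen(R)
    return _pev(eig, sigma_g2, sigma_e2 / sigma_g2)


def egv_pipeline(
    pheno: pd.DataFrame,
    X: np.ndarray,
    R: RelatednessMatrix | KinshipEigen,
    ids: list[str] | None = None,
    method: str = "ML",
) -> tuple[dict[int, EGVResult], dict[int, PolygenicFit], list[int]]:
    """Fit, residualize and BLUP every phenotype replicate.

    ``pheno`` is long-format with columns (id, replicate, y); covariate
    effects are re-estimated per replicate while covariate values stay
    fixed.  Replicates whose heritability estimate hits the h^2 = 0
    boundary are skipped (the EGV is undefined without additive
    variance) and reported in the third return value.

    Returns (egvs by replicate, polygenic fits by replicate, skipped).
    """
    eig = _as_eigen(R)
    order = ids if ids is not None else eig.ids
    if list(eig.ids) != list(order):
        raise ValueError("id order mismatch between phenotypes and R")
    results: dict[int, EGVResult] = {}
    fits: dict[int, PolygenicFit] = {}
    skipped: list[int] = []
    for rep, grp in pheno.groupby("replicate", sort=True):
        y = grp.set_index("id")["y"].reindex(order).to_numpy()
        fit = fit_polygenic(y, X, eig, method=method)
        fits[int(rep)] = fit
        if fit.sigma_g2 <= 0:
            skipped.append(int(rep))
            continue
        resid = residualize(y, X, fit)
        results[int(rep)] = compute_egv(resid, eig, fit.sigma_g2, fit.sigma_e2)
    return results, fits, skipped
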