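"""Measured-genotype association (MGA) under a family covariance.

Each SNP enters as one additive fixed effect; the null (no SNP) and
alternative (SNP) models are both fit by maximum likelihood under

    Omega = sigma_p^2 (2*Phi*h2 + I*e2 + En*eps),   h2 + e2 + eps = 1,

where Phi is the *expected* (pedigree) kinship for every trait, En is
the BLUP prediction-error variance matrix normalised to unit mean
diagonal (so eps is a variance proportion), and the likelihood-ratio
statistic 2*(ll_alt - ll_null) is referred to chi-square with 1 df.
With eps constrained to zero this is the standard polygenic MGA model.

Internally everything is rotated into the eigenbasis of 2*Phi; when En
is a function of the same matrix (the pedigree-sourced EGV case) it is
diagonal there too and each likelihood evaluation costs O(n p^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .genotypes import GenotypeMatrix
from .pedigree import RelatednessMatrix
from .polygenic import KinshipEigen

__all__ = ["AssocModelSpec", "AssocResult", "mga_test", "genome_scan", "FamilyCovariance"]


@dataclass
class AssocModelSpec:
    """Configuration of the MGA covariance model.

    ``phi2`` is the expected relatedness 2*Phi from the pedigree (used
    for all traits, raw phenotype and EGVs alike).  ``E`` is the EGV
    error-variance matrix; it is only used when ``include_E`` is true,
    the convention being true for EGV traits and false for the raw
    phenotype.
    """

    phi2: RelatednessMatrix | KinshipEigen
    E: np.ndarray | None = None
    include_E: bool = False
    significance_threshold: float = 5e-8


@dataclass
class AssocResult:
    snp: str
    chrom: str
    pos: int
    maf: float
    beta_snp: float
    lrt: float
    p: float
    significant: bool
    status: str = "ok"  # ok | skipped_monomorphic | nonconverged
    h2: float = np.nan
    eps: float = np.nan

    _FIELDS = ("snp", "chrom", "pos", "maf", "beta_snp", "lrt", "p",
               "significant", "status", "h2", "eps")


class FamilyCovariance:
    """Prepared covariance components in the eigenbasis of 2*Phi."""

    def __init__(self, spec: AssocModelSpec):
        phi2 = spec.phi2
        self.eig = phi2 if isinstance(phi2, KinshipEigen) else KinshipEigen.from_matrix(phi2)
        self.include_E = spec.include_E and spec.E is not None
        self.e_diag: np.ndarray | None = None
        self.E_rot: np.ndarray | None = None
        if self.include_E:
            E = np.asarray(spec.E, dtype=float)
            scale = float(np.mean(np.diag(E)))
            if scale <= 0:
                self.include_E = False
            else:
                En = E / scale
                Er = self.eig.U.T @ En @ self.eig.U
                off = Er - np.diag(np.diag(Er))
                if np.max(np.abs(off)) < 1e-8:
                    self.e_diag = np.clip(np.diag(Er), 0.0, None)
                else:
                    self.E_rot = 0.5 * (Er + Er.T)

    @property
    def n(self) -> int:
        return self.eig.n

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.eig.U.T @ a

    # -- profile likelihood -------------------------------------------------

    def _negloglik(self, h2: float, eps: float, yt: np.ndarray, Xt: np.ndarray):
        n, p = Xt.shape
        e2 = 1.0 - h2 - eps
        if h2 < 0 or eps < 0 or e2 < -1e-12:
            return np.inf, None, None
        e2 = max(e2, 0.0)
        if self.E_rot is None:
            k = h2 * self.eig.d + e2
            if self.e_diag is not None:
                k = k + eps * self.e_diag
            if k.min() <= 1e-12:
                return np.inf, None, None
            w = 1.0 / k
            XtW = Xt * w[:, None]
            A = XtW.T @ Xt
            b = XtW.T @ yt
            try:
                beta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            r = yt - Xt @ beta
            rss = float(r @ (w * r))
            logdet = float(np.sum(np.log(k)))
        else:
            K = h2 * np.diag(self.eig.d) + eps * self.E_rot + e2 * np.eye(n)
            try:
                cf = cho_factor(K, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            Ky = cho_solve(cf, yt, check_finite=False)
            KX = cho_solve(cf, Xt, check_finite=False)
            A = Xt.T @ KX
            beta = np.linalg.solve(A, Xt.T @ Ky)
            r = yt - Xt @ beta
            rss = float(r @ cho_solve(cf, r, check_finite=False))
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        if rss <= 0:
            return np.inf, None, None
        sigma_p2 = rss / n
        nll = 0.5 * (n * np.log(2 * np.pi * sigma_p2) + logdet + n)
        return nll, beta, sigma_p2

    def fit(self, yt: np.ndarray, Xt: np.ndarray, warm: tuple[float, float] | None = None):
        """Maximize the likelihood over the variance proportions.

        ``warm`` optionally seeds the optimizer (e.g. with the null
        model's estimates when refitting with one extra column).
        Returns (loglik, beta, sigma_p2, h2, eps).
        """
        if not self.include_E:
            res = minimize_scalar(
                lambda h: self._negloglik(h, 0.0, yt, Xt)[0],
                bounds=(0.0, 1.0 - 1e-9),
                method="bounded",
                options={"xatol": 1e-8},
            )
            h2 = float(res.x)
            for edge in (0.0,):
                if self._negloglik(edge, 0.0, yt, Xt)[0] <= res.fun + 1e-10:
                    h2 = edge
            nll, beta, sp2 = self._negloglik(h2, 0.0, yt, Xt)
            return -nll, beta, sp2, h2, 0.0

        # two free proportions: parameterize the simplex by u, v in [0,1]^2
        # with h2 = u, eps = v * (1 - h2)
        def obj(x):
            u, v = np.clip(x, 0.0, 1.0)
            h2 = u * (1.0 - 1e-9)
            eps = v * (1.0 - h2) * (1.0 - 1e-9)
            return self._negloglik(h2, eps, yt, Xt)[0]

        starts = [(0.3, 0.2), (0.7, 0.5)]
        if warm is not None:
            h2w, epsw = warm
            vw = epsw / (1.0 - h2w) if h2w < 1 else 0.0
            starts.insert(0, (float(np.clip(h2w, 0.0, 1.0)), float(np.clip(vw, 0.0, 1.0))))
        best = None
        for x0 in starts:
            r = minimize(obj, x0, method="L-BFGS-B",
                         bounds=[(0.0, 1.0), (0.0, 1.0)],
                         options={"maxiter": 60, "ftol": 1e-12, "gtol": 1e-9})
            if best is None or r.fun < best.fun:
                best = r
        u, v = np.clip(best.x, 0.0, 1.0)
        h2 = float(u * (1.0 - 1e-9))
        eps = float(v * (1.0 - h2) * (1.0 - 1e-9))
        nll, beta, sp2 = self._negloglik(h2, eps, yt, Xt)
        return -nll, beta, sp2, h2, eps


def _prepare_snp(g: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Mean-impute missing dosages; None if the SNP is monomorphic."""
    g = np.asarray(g, dtype=float).copy()
    ok = ~np.isnan(g)
    if not ok.any():
        return None
    mean = g[ok].mean()
    g[~ok] = mean
    if g.std() == 0:
        return None
    p = mean / 2.0
    return g, float(min(p, 1.0 - p))


def mga_test(
    trait: np.ndarray,
    snp_dosages: np.ndarray,
    X: np.ndarray,
    spec: AssocModelSpec,
    snp_meta: tuple[str, str, int] = ("snp", "0", 0),
    cov: FamilyCovariance | None = None,
    null_fit: tuple | None = None,
) -> AssocResult:
    """Likelihood-ratio test of one SNP's additive effect on a trait.

    The null model regresses the trait on X alone; the alternative adds
    the (mean-imputed) dosage column.  Variance proportions are
    re-optimized in both models.  Monomorphic SNPs yield a skip record.
    """
    name, chrom, pos = snp_meta
    cov = cov or FamilyCovariance(spec)
    prep = _prepare_snp(snp_dosages)
    if prep is None:
        return AssocResult(name, chrom, pos, np.nan, np.nan, np.nan, np.nan,
                           False, status="skipped_monomorphic")
    g, maf = prep
    y = np.asarray(trait, dtype=float).ravel()
    yt = cov.rotate(y)
    Xt = cov.rotate(np.atleast_2d(np.asarray(X, dtype=float)))
    if null_fit is None:
        null_fit = cov.fit(yt, Xt)
    ll0 = null_fit[0]
    gt = cov.rotate(g)
    Xt_alt = np.column_stack([Xt, gt])
    try:
        ll1, beta, _, h2, eps = cov.fit(yt, Xt_alt, warm=(null_fit[3], null_fit[4]))
    except (np.linalg.LinAlgError, ValueError):
        return AssocResult(name, chrom, pos, maf, np.nan, np.nan, np.nan,
                           False, status="nonconverged")
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(chi2.sf(lrt, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AssocResult(
        name, chrom, pos, maf, float(beta[-1]), lrt, p,
        p < spec.significance_threshold, status="ok", h2=h2, eps=eps,
    )


def genome_scan(
    trait: np.ndarray,
    G: GenotypeMatrix,
    X: np.ndarray,
    spec: AssocModelSpec,
) -> pd.DataFrame:
    """Run mga_test over every SNP of ``G``; never aborts on a bad SNP.

    The null model is fit once and reused; only the alternative model is
    re-fit per SNP.  Returns a DataFrame with one row per SNP (columns
    snp, chrom, pos, maf, beta_snp, lrt, p, significant, status).
    """
    cov = FamilyCovariance(spec)
    y = np.asarray(trait, dtype=float).ravel()
    yt = cov.rotate(y)
    Xt = cov.rotate(np.atleast_2d(np.asarray(X, dtype=float)))
    null_fit = cov.fit(yt, Xt)
    ll0 = null_fit[0]

    # mean-impute and rotate every dosage column in one pass
    D = G.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    nan = np.isnan(D)
    D[nan] = np.take(col_mean, np.where(nan)[1])
    poly = D.std(axis=0) > 0
    p_alt = col_mean / 2.0
    mafs = np.minimum(p_alt, 1.0 - p_alt)
    Dt = cov.rotate(D)

    names = G.snps["snp"].astype(str).to_numpy()
    chroms = G.snps["chrom"].astype(str).to_numpy()
    poss = G.snps["pos"].to_numpy()
    rows = []
    for k in range(G.n_snps):
        if not poly[k]:
            res = AssocResult(names[k], chroms[k], int(poss[k]), np.nan, np.nan,
                              np.nan, np.nan, False, status="skipped_monomorphic")
        else:
            Xt_alt = np.column_stack([Xt, Dt[:, k]])
            try:
                ll1, beta, _, h2, eps = cov.fit(yt, Xt_alt, warm=(null_fit[3], null_fit[4]))
                lrt = max(0.0, 2.0 * (ll1 - ll0))
                p = float(chi2.sf(lrt, df=1))
                p = min(max(p, np.nextafter(0, 1)), 1.0)
                res = AssocResult(
                    names[k], chroms[k], int(poss[k]), float(mafs[k]),
                    float(beta[-1]), lrt, p, p < spec.significance_threshold,
                    status="ok", h2=h2, eps=eps,
                )
            except (np.linalg.LinAlgError, ValueError):
                res = AssocResult(names[k], chroms[k], int(poss[k]), float(mafs[k]),
                                  np.nan, np.nan, np.nan, False, status="nonconverged")
        rows.append({f: getattr(res, f) for f in AssocResult._FIELDS})
    return pd.DataFrame(rows)
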