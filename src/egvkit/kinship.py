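"""Marker-based relatedness (KING-robust) and nearest-correlation repair.

The KING-robust kinship estimator for a sample pair (i, j), over the
SNPs where both genotypes are observed, is

    phi_hat = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))

with N_Aa,Aa the number of SNPs where both are heterozygous, N_AA,aa the
number with opposite homozygotes, and N_Aa(i) the heterozygote count of
sample i.  It is robust to allele-frequency misspecification and hence
to population substructure, which is why family studies favour it.

Marker-based matrices are generally indefinite; before they can serve as
a covariance they are repaired to the nearest correlation matrix by
Higham's alternating-projections algorithm with Dykstra's correction.
"""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, RelatednessMatrix

__all__ = [
    "KinshipUndefinedError",
    "king_robust_pair",
    "empirical_relatedness_matrix",
    "nearest_correlation",
    "NearestCorrelationError",
]


class KinshipUndefinedError(ValueError):
    """KING denominator is zero: the pair shares no heterozygous sites."""


class NearestCorrelationError(RuntimeError):
    """Alternating projections failed to converge; carries last residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"nearest-correlation did not converge in {max_iter} iterations "
            f"(last max-norm change {residual:.3e})"
        )


def king_robust_pair(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """KING-robust kinship estimate for one sample pair.

    Missing dosages (NaN) are dropped pairwise-complete.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    if g_i.shape != g_j.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~np.isnan(g_i) & ~np.isnan(g_j)
    gi, gj = g_i[ok], g_j[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_hethet = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        raise KinshipUndefinedError(
            "no heterozygous sites in either sample over pairwise-complete SNPs"
        )
    return (n_hethet - 2.0 * n_opp) / denom


def _king_matrix(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs KING-robust kinship via indicator matrix products.

    Returns (phi, defined) where ``defined`` flags pairs with a nonzero
    denominator.  Missing dosages contribute to no indicator, so counts
    are automatically pairwise-complete.
    """
    het = (dos == 1).astype(float)
    aa = (dos == 0).astype(float)
    bb = (dos == 2).astype(float)
    obs = het + aa + bb  # 1 where genotype observed
    n_hethet = het @ het.T
    n_opp = aa @ bb.T
    n_opp = n_opp + n_opp.T
    het_i = het @ obs.T  # het count of i over sites also observed in j
    denom = het_i + het_i.T
    defined = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(defined, (n_hethet - 2.0 * n_opp) / np.where(defined, denom, 1.0), np.nan)
    return phi, defined


def empirical_relatedness_matrix(
    G: GenotypeMatrix,
    ped: Pedigree | None = None,
    variant_set: str = "common",
    maf_cut: float = 0.05,
    max_missing: float = 0.10,
) -> RelatednessMatrix:
    """Marker-based relatedness R = 2*phi_hat for all sample pairs.

    variant_set="common" keeps SNPs with MAF >= ``maf_cut`` (source tag
    "snp"); variant_set="all" keeps every polymorphic site (source tag
    "seq").  SNPs missing in more than ``max_missing`` of samples are
    dropped first.  The diagonal is fixed at 1.
    """
    if variant_set not in ("common", "all"):
        raise ValueError(f"variant_set must be 'common' or 'all', got {variant_set!r}")
    if ped is not None:
        missing = set(G.sample_ids) - set(ped.ids)
        if missing:
            raise ValueError(f"samples not in pedigree: {sorted(missing)[:5]}")
    maf = G.maf()
    keep = (G.missing_rate() <= max_missing) & (maf > 0)
    if variant_set == "common":
        keep &= maf >= maf_cut
    if not keep.any():
        raise ValueError("no informative SNPs after filtering")
    phi, defined = _king_matrix(G.dosages[:, keep])
    bad = np.argwhere(~defined & ~np.eye(G.n_samples, dtype=bool))
    if len(bad):
        i, j = bad[0]
        raise KinshipUndefinedError(
            f"kinship undefined for {len(bad) // 2} pair(s), e.g. "
            f"({G.sample_ids[i]}, {G.sample_ids[j]}): no heterozygous sites"
        )
    R = 2.0 * phi
    np.fill_diagonal(R, 1.0)
    R = 0.5 * (R + R.T)
    return RelatednessMatrix(
        list(G.sample_ids), R, source="snp" if variant_set == "common" else "seq"
    )


def nearest_correlation(
    M: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> np.ndarray:
    """Nearest correlation matrix by alternating projections (Higham).

    Alternates projection onto the PSD cone (eigenvalue clipping) and the
    unit-diagonal affine set, with Dykstra's correction so the iteration
    converges to the Frobenius-nearest correlation matrix.  Stops when the
    max-norm change between successive iterates falls below ``tol``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    Y = 0.5 * (M + M.T)
    ds = np.zeros_like(Y)
    for _ in range(max_iter):
        R_k = Y - ds
        # project onto PSD cone
        w, V = np.linalg.eigh(R_k)
        X = (V * np.clip(w, 0.0, None)) @ V.T
        X = 0.5 * (X + X.T)
        ds = X - R_k
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)  # projection onto unit-diagonal set
        residual = float(np.max(np.abs(Y_new - Y)))
        Y = Y_new
        # converged only once the diagonal-corrected iterate is itself
        # within tolerance of the PSD cone
        if residual < tol and np.linalg.eigvalsh(Y).min() >= -tol:
            return Y
    raise NearestCorrelationError(residual, max_iter)
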