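"""LD pruning, genotype PCA on an unrelated subset, and PC projection.

Principal components are fit only on mutually unrelated individuals so
family structure does not masquerade as ancestry; scores are then
carried onto relatives by the parental-mean rule (each offspring gets
the average of its parents' scores, recursively in generation order).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = ["ld_prune", "pca_unrelated", "project_scores", "build_covariates", "PCAResult"]


def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of SNP columns (mean-imputed)."""
    X = dos.copy()
    col_mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.take(col_mean, np.where(nan)[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    C = (X.T @ X) / len(X)
    r = C / np.outer(sd, sd)
    return r**2


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list[str]:
    """Greedy sliding-window LD pruning; returns surviving SNP ids.

    Within each window of ``window`` SNPs (per chromosome), the SNP pair
    with the highest r^2 above the threshold is found and the member with
    the lower MAF is dropped (tie: the later position), repeating until
    all pairs satisfy r^2 <= r2_max; the window then advances by ``step``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    maf = G.maf()
    keep = np.ones(G.n_snps, dtype=bool)
    for _, grp in G.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            win = win[keep[win]]
            if len(win) >= 2:
                r2 = _r2_matrix(G.dosages[:, win])
                np.fill_diagonal(r2, 0.0)
                r2 = np.nan_to_num(r2)
                while True:
                    a, b = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[a, b] <= r2_max:
                        break
                    ia, ib = win[a], win[b]
                    # drop lower-MAF member; tie -> later position
                    drop = a if (maf[ia], -ia) < (maf[ib], -ib) else b
                    keep[win[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + window >= len(idx):
                break
            start += step
    return G.snps.loc[keep, "snp"].tolist()


class PCAResult:
    """Loadings/scores of a genotype PCA anchored on unrelated samples."""

    def __init__(self, loadings, scores, explained, snp_ids, sample_ids):
        self.loadings = loadings            # m x k
        self.scores = scores                # DataFrame indexed by sample id
        self.explained = explained          # variance-explained fractions
        self.snp_ids = snp_ids
        self.sample_ids = sample_ids


def pca_unrelated(
    G: GenotypeMatrix,
    unrelated_ids: set[str] | list[str],
    k: int = 3,
    scale: bool = True,
) -> PCAResult:
    """PCA of genotypes fit on the unrelated subset, scored for all samples.

    SNPs are centred at 2p and (optionally) scaled by sqrt(2p(1-p)),
    with p the allele frequency in the unrelated subset; loadings come
    from an SVD of the standardized unrelated rows, and every sample in
    ``G`` is scored with those loadings.  Missing dosages are imputed at
    the mean.
    """
    unrel = [s for s in G.sample_ids if s in set(unrelated_ids)]
    if len(unrel) < 2:
        raise ValueError("need at least 2 unrelated individuals for PCA")
    if len(unrel) < k:
        raise ValueError(f"fewer unrelated individuals ({len(unrel)}) than components ({k})")
    pos = {s: i for i, s in enumerate(G.sample_ids)}
    rows = np.array([pos[s] for s in unrel])

    dos = G.dosages.copy()
    p = np.nanmean(dos[rows], axis=0) / 2.0
    informative = (p > 0) & (p < 1)
    if not informative.any():
        raise ValueError("no SNP varies within the unrelated subset")
    dos = dos[:, informative]
    p = p[informative]
    nan = np.isnan(dos)
    dos[nan] = np.take(2.0 * p, np.where(nan)[1])
    Z = dos - 2.0 * p
    if scale:
        Z = Z / np.sqrt(2.0 * p * (1.0 - p))

    U, s, Vt = np.linalg.svd(Z[rows], full_matrices=False)
    if s[0] == 0:
        raise ValueError("zero genotypic variance in unrelated subset")
    k_eff = min(k, len(s))
    loadings = Vt[:k_eff].T
    scores_all = Z @ loadings
    var = s**2 / (len(rows) - 1)
    explained = var[:k_eff] / var.sum()
    cols = [f"PC{i + 1}" for i in range(k_eff)]
    scores = pd.DataFrame(scores_all, index=list(G.sample_ids), columns=cols)
    snp_ids = G.snps.loc[informative, "snp"].tolist()
    return PCAResult(loadings, scores, explained, snp_ids, list(G.sample_ids))


def project_scores(ped: Pedigree, founder_scores: pd.DataFrame) -> pd.DataFrame:
    """Propagate PC scores through the pedigree by parental means.

    Founders keep their own scores (all founders must be present in
    ``founder_scores``); each non-founder, visited in generation order,
    receives the mean of its parents' scores.
    """
    missing = [f for f in ped.founders if f not in founder_scores.index]
    if missing:
        raise ValueError(f"founder(s) without scores: {missing[:5]}")
    cols = list(founder_scores.columns)
    out = pd.DataFrame(index=pd.Index(ped.ids, name="id"), columns=cols, dtype=float)
    for iid in ped.order:
        ind = ped[iid]
        if ind.is_founder:
            out.loc[iid] = founder_scores.loc[iid, cols].astype(float)
        else:
            out.loc[iid] = (out.loc[ind.father] + out.loc[ind.mother]) / 2.0
    return out


def build_covariates(
    ped: Pedigree, age: pd.Series, sex: pd.Series, pcs: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the covariate table (id, age, sex, PC1..PCk) for all ids."""
    df = pd.DataFrame(index=pd.Index(ped.ids, name="id"))
    df["age"] = age.reindex(ped.ids)
    df["sex"] = sex.reindex(ped.ids)
    for c in pcs.columns:
        df[c] = pcs[c].reindex(ped.ids)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete covariates for id(s): {bad[:5]}")
    return df
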