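"""True/false-positive adjudication against a known causal architecture.

Because the phenotype simulator knows exactly which SNPs are causal, the
false-discovery rate of a scan is computable exactly: a significant SNP
is a true positive if it lies in an LD block (r^2 >= 0.2 by default)
around a causal gene — operationalized as max r^2 with any causal SNP of
that gene on the same chromosome — otherwise it is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "CausalGene",
    "CausalArchitecture",
    "pairwise_r2",
    "classify_hits",
    "fdr_summary",
    "gene_hit_table",
    "gene_variance_fraction",
    "independent_columns",
]


@dataclass
class CausalGene:
    name: str
    chrom: str
    snp_ids: list[str]
    effects: list[float]
    variance_fraction: float  # designed share of total phenotypic variance


@dataclass
class CausalArchitecture:
    genes: list[CausalGene]
    h2_polygenic: float = 0.0

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.variance_fraction < 0:
                raise ValueError(f"gene {g.name}: negative variance fraction")
        total = sum(g.variance_fraction for g in self.genes) + self.h2_polygenic
        if total > 1 + 1e-9:
            raise ValueError(f"variance budget exceeds 1 (total {total:.3f})")

    @property
    def causal_snp_ids(self) -> list[str]:
        return [s for g in self.genes for s in g.snp_ids]

    def to_dict(self) -> dict:
        return {
            "h2_polygenic": self.h2_polygenic,
            "genes": [
                {
                    "name": g.name,
                    "chrom": g.chrom,
                    "snp_ids": list(g.snp_ids),
                    "effects": [float(e) for e in g.effects],
                    "variance_fraction": g.variance_fraction,
                }
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CausalArchitecture":
        return cls(
            genes=[
                CausalGene(g["name"], str(g["chrom"]), list(g["snp_ids"]),
                           list(g["effects"]), g["variance_fraction"])
                for g in d["genes"]
            ],
            h2_polygenic=d.get("h2_polygenic", 0.0),
        )


def pairwise_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete)."""
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    ok = ~np.isnan(g_a) & ~np.isnan(g_b)
    a, b = g_a[ok], g_b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage vector; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def classify_hits(
    sig_snps: list[str],
    arch: CausalArchitecture,
    G: GenotypeMatrix,
    r2_block: float = 0.2,
) -> pd.DataFrame:
    """Label each significant SNP as true or false positive via LD.

    A hit is a true positive iff its max r^2 with a causal SNP on the
    same chromosome reaches ``r2_block``; it is attributed to the gene
    of the best-matching causal SNP (ties: nearest genomic distance,
    then gene name) and additionally to every gene clearing the
    threshold (column ``genes_all`` drives the per-gene tables).
    Monomorphic hits cannot be classified and count as false positives.
    """
    snp_index = {s: k for k, s in enumerate(G.snps["snp"].astype(str))}
    missing = [s for s in sig_snps if s not in snp_index]
    if missing:
        raise ValueError(f"significant SNP(s) not in genotype matrix: {missing[:5]}")
    chrom = G.snps["chrom"].astype(str).to_numpy()
    pos = G.snps["pos"].to_numpy()

    causal: list[tuple[str, str, int, str]] = []  # (snp, chrom, pos, gene)
    for gene in arch.genes:
        for s in gene.snp_ids:
            if s not in snp_index:
                raise ValueError(f"causal SNP {s!r} of gene {gene.name} not in G")
            k = snp_index[s]
            causal.append((s, chrom[k], int(pos[k]), gene.name))

    rows = []
    for s in sig_snps:
        k = snp_index[s]
        g_hit = G.dosages[:, k]
        best: tuple[float, int, str] | None = None  # (-r2, distance, gene)
        gene_best_r2: dict[str, float] = {}
        classifiable = True
        for cs, cchrom, cpos, gname in causal:
            if cchrom != chrom[k]:
                continue
            try:
                r2 = pairwise_r2(g_hit, G.dosages[:, snp_index[cs]])
            except ValueError:
                classifiable = False
                continue
            classifiable = True
            gene_best_r2[gname] = max(gene_best_r2.get(gname, 0.0), r2)
            key = (-r2, abs(int(pos[k]) - cpos), gname)
            if best is None or key < best:
                best = key
        hit_genes = sorted(g for g, r2 in gene_best_r2.items() if r2 >= r2_block)
        is_tp = bool(best is not None and -best[0] >= r2_block)
        rows.append(
            {
                "snp": s,
                "chrom": chrom[k],
                "pos": int(pos[k]),
                "true_positive": is_tp,
                "best_gene": best[2] if is_tp else None,
                "best_r2": -best[0] if best is not None else np.nan,
                "genes_all": ";".join(hit_genes),
            }
        )
    return pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "true_positive", "best_gene",
                       "best_r2", "genes_all"],
    )


def fdr_summary(
    labeled: pd.DataFrame,
    maf: pd.Series | dict,
    methods: list[str] | None = None,
    baseline: str = "SBP",
) -> pd.DataFrame:
    """Per-method summary of scan hits across replicates.

    ``labeled`` needs columns (method, replicate, snp, true_positive);
    ``maf`` maps snp id -> minor allele frequency.  Rows of the output
    mirror the usual report layout: total significant SNPs, the shares
    at MAF < 0.05 and < 0.01, per-replicate count statistics, pooled
    FDR, the FDR restricted to hits the baseline method did not find,
    and per-replicate count comparisons against the baseline.
    """
    maf = pd.Series(maf)
    if methods is None:
        methods = list(pd.unique(labeled["method"]))
    reps = sorted(pd.unique(labeled["replicate"]))
    base = labeled[labeled["method"] == baseline]
    base_hits = {r: set(base.loc[base["replicate"] == r, "snp"]) for r in reps}

    out: dict[str, dict] = {}
    for m in methods:
        sub = labeled[labeled["method"] == m]
        total = len(sub)
        counts = np.array(
            [int((sub["replicate"] == r).sum()) for r in reps], dtype=float
        )
        fp = int((~sub["true_positive"]).sum())
        snp_mafs = maf.reindex(sub["snp"]).to_numpy(dtype=float)
        novel = sub[
            [s not in base_hits.get(r, set())
             for r, s in zip(sub["replicate"], sub["snp"])]
        ] if m != baseline else None
        row = {
            "total_significant": total,
            "pct_maf_lt_0.05": 100.0 * np.mean(snp_mafs < 0.05) if total else np.nan,
            "pct_maf_lt_0.01": 100.0 * np.mean(snp_mafs < 0.01) if total else np.nan,
            "mean_sig_per_replicate": counts.mean() if len(counts) else np.nan,
            "median_sig_per_replicate": float(np.median(counts)) if len(counts) else np.nan,
            "stdev_sig_per_replicate": float(counts.std(ddof=1)) if len(counts) > 1 else np.nan,
            "fdr_pct": 100.0 * fp / total if total else np.nan,
            "fdr_not_in_baseline_pct": (
                100.0 * (~novel["true_positive"]).sum() / len(novel)
                if novel is not None and len(novel) else np.nan
            ),
            "replicates_more_than_baseline": np.nan,
            "replicates_fewer_than_baseline": np.nan,
            "replicates_same_as_baseline": np.nan,
        }
        if m != baseline:
            base_counts = np.array([len(base_hits.get(r, set())) for r in reps], dtype=float)
            row["replicates_more_than_baseline"] = int((counts > base_counts).sum())
            row["replicates_fewer_than_baseline"] = int((counts < base_counts).sum())
            row["replicates_same_as_baseline"] = int((counts == base_counts).sum())
        out[m] = row
    return pd.DataFrame(out)


def gene_hit_table(
    labeled: pd.DataFrame, arch: CausalArchitecture, methods: list[str] | None = None
) -> pd.DataFrame:
    """Replicate counts with >= 1 significant hit attributed to each gene.

    A hit counts for every gene whose max-r^2 clears the block threshold
    (``genes_all``), so one SNP may register for overlapping genes.
    Genes never hit are still listed with zero counts.
    """
    if methods is None:
        methods = list(pd.unique(labeled["method"]))
    rows = {}
    for gene in arch.genes:
        counts = {}
        for m in methods:
            sub = labeled[labeled["method"] == m]
            hit_reps = {
                r
                for r, gl in zip(sub["replicate"], sub["genes_all"])
                if gl and gene.name in gl.split(";")
            }
            counts[m] = len(hit_reps)
        rows[gene.name] = {"chrom": gene.chrom, **counts}
    return pd.DataFrame.from_dict(rows, orient="index")


def independent_columns(A: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a linearly independent column subset (pivoted QR).

    Used to reduce a near-collinear dosage block (e.g. causal SNPs in
    tight LD) to a full-rank design before regression.
    """
    from scipy.linalg import qr

    A = np.atleast_2d(np.asarray(A, dtype=float))
    Ac = A - A.mean(axis=0)
    _, r, piv = qr(Ac, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int((diag > tol * diag[0]).sum())
    return np.sort(piv[:rank])


def gene_variance_fraction(
    y: np.ndarray,
    X_covar: np.ndarray,
    dosages: np.ndarray,
    eig,
    method: str = "REML",
) -> float:
    """Fraction of phenotypic variance explained by a set of causal dosages.

    Joint mixed-model regression: the phenotype is regressed on the
    covariates plus all of the gene's dosage columns under the polygenic
    covariance (GLS with the additive relationship matrix), so that
    family-structured polygenic variation is absorbed by the random
    effect rather than by the dosage coefficients.  The naive quadratic
    form b' S b (S the dosage covariance) overstates the gene's variance
    by tr(Cov(b) S); that trace is subtracted, giving an unbiased
    estimate of Var(D a) / Var(y).  REML variance components (the
    default) keep the correction unbiased when the design has many
    columns.

    ``eig`` is a :class:`egvkit.polygenic.KinshipEigen` of the expected
    relatedness matrix.
    """
    from .polygenic import fit_polygenic

    y = np.asarray(y, dtype=float).ravel()
    D = np.atleast_2d(np.asarray(dosages, dtype=float))
    if D.shape[0] != y.size:
        D = D.T
    k = D.shape[1]
    X = np.column_stack([np.atleast_2d(np.asarray(X_covar, dtype=float)), D])
    fit = fit_polygenic(y, X, eig, method=method)
    kd = fit.h2 * eig.d + (1.0 - fit.h2)
    Xt = eig.rotate(X)
    C = fit.sigma_p2 * np.linalg.inv(Xt.T @ (Xt / kd[:, None]))
    b = fit.beta[-k:]
    S = np.cov(D.T, ddof=1) if k > 1 else np.array([[D.var(ddof=1)]])
    v = float(b @ S @ b - np.trace(C[-k:, -k:] @ S))
    return v / float(np.var(y, ddof=1))
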