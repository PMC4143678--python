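"""Synthetic study generator: pedigrees, gene-dropped genotypes, phenotypes.

Emulates the structure of a family blood-pressure study: ~20 extended
families totalling ~850 individuals, dense SNP genotypes produced by
dropping founder haplotypes through the pedigree with recombination, and
replicate phenotypes combining age/sex effects, a handful of multi-SNP
causal genes with fixed variance fractions (the largest contributing
7.79% of trait variance, the smallest named gene 2.06%), a polygenic
background distributed around 2*Phi, and i.i.d. environmental noise.
Genotypes and covariates are fixed across replicates; the polygenic and
environmental deviations are redrawn each replicate.

Founder haplotypes use a Gaussian-copula AR(1): a latent autoregressive
series is thresholded at each site's allele frequency, which preserves
the designed marginal frequencies exactly (a rare site stays rare) while
giving monotone LD decay controlled by rho.

All randomness flows from one master seed through named substreams, so
any stage can be re-run independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .evaluation import CausalArchitecture, CausalGene
from .genotypes import GenotypeMatrix
from .pedigree import Individual, Pedigree, expected_relatedness

__all__ = [
    "GeneConfig",
    "SimulationConfig",
    "StudyData",
    "simulate_pedigree",
    "simulate_founder_haplotypes",
    "gene_drop",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_study",
]

_SNP_SPACING = 10_000  # mean bp between adjacent SNPs


@dataclass(frozen=True)
class GeneConfig:
    name: str
    n_snps: int
    variance_fraction: float
    lead_share: float = 0.6  # share of the gene's variance on its lead SNP


def _default_genes() -> list[GeneConfig]:
    # four named genes with the stated variance fractions plus one
    # tiny-effect gene, 55 causal SNPs in total
    return [
        GeneConfig("GENE_A", 15, 0.0779),
        GeneConfig("GENE_B", 14, 0.0467),
        GeneConfig("GENE_C", 16, 0.0387),
        GeneConfig("GENE_D", 8, 0.0206),
        GeneConfig("GENE_E", 2, 0.0030),
    ]


@dataclass
class SimulationConfig:
    """Study-design knobs; defaults emulate the workshop data set."""

    n_families: int = 20
    target_n: int = 847
    size_tolerance: float = 0.10     # accept total within +-10% of target
    generations: int = 3
    sibship_mean: float = 5.4        # sibship ~ 1 + Poisson(mean - 1)

    n_chroms: int = 4
    snps_per_chrom: int = 500
    rare_frac: float = 0.25          # background sites with MAF in (0.001, 0.01)
    rho: float = 0.9                 # latent AR(1) coefficient -> LD decay
    recomb_per_chrom: float = 1.0    # Poisson crossovers per meiosis

    genes: list[GeneConfig] = field(default_factory=_default_genes)
    causal_rare_lt01: int = 10       # causal sites designed at MAF < 1%
    causal_rare_lt05: int = 28       # causal sites designed at MAF < 5% (incl. above)

    h2_polygenic: float = 0.2
    covar_frac_age: float = 0.07
    covar_frac_sex: float = 0.03
    total_variance: float = 200.0    # mm Hg^2; SBP-like scale
    mean: float = 120.0              # mm Hg
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        budget = (
            sum(g.variance_fraction for g in self.genes)
            + self.h2_polygenic
            + self.covar_frac_age
            + self.covar_frac_sex
        )
        if budget > 1 + 1e-9:
            raise ValueError(f"variance budget exceeds 1 (total {budget:.3f})")
        n_causal = sum(g.n_snps for g in self.genes)
        if self.causal_rare_lt05 > n_causal or self.causal_rare_lt01 > self.causal_rare_lt05:
            raise ValueError("causal rare-variant quotas inconsistent")


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    ped: Pedigree
    G: GenotypeMatrix
    covariates: pd.DataFrame          # id-indexed: age, sex
    pheno: pd.DataFrame               # long: id, replicate, y
    arch: CausalArchitecture
    true_g: pd.DataFrame              # long: id, replicate, g
    config: SimulationConfig
    seed: int


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# pedigree


def _draw_family(fid: str, cfg: SimulationConfig, rng: np.random.Generator) -> list[Individual]:
    inds: list[Individual] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{fid}_I{counter[0]:03d}"

    def add(father, mother, sex) -> str:
        iid = new_id()
        inds.append(Individual(iid, fid, father, mother, sex))
        return iid

    pa, ma = add(None, None, 1), add(None, None, 2)
    couples = [(pa, ma)]
    for gen in range(2, cfg.generations + 1):
        next_couples = []
        for fa, mo in couples:
            k = 1 + rng.poisson(cfg.sibship_mean - 1.0)
            for c in range(k):
                sex = 1 + (c % 2)
                child = add(fa, mo, sex)
                if gen < cfg.generations:  # marries in a spouse, has children
                    spouse = add(None, None, 2 if sex == 1 else 1)
                    next_couples.append((child, spouse) if sex == 1 else (spouse, child))
        couples = next_couples
    return inds


def simulate_pedigree(cfg: SimulationConfig, seed: int) -> Pedigree:
    """Extended families of founder couples, in-marrying spouses and sibships.

    Family sizes are redrawn until the total lands within
    ``size_tolerance`` of ``target_n``.
    """
    rng = _substream(seed, 0)
    lo = cfg.target_n * (1 - cfg.size_tolerance)
    hi = cfg.target_n * (1 + cfg.size_tolerance)
    for _ in range(500):
        fams = [_draw_family(f"F{k + 1:02d}", cfg, rng) for k in range(cfg.n_families)]
        total = sum(len(f) for f in fams)
        if lo <= total <= hi:
            return Pedigree([ind for fam in fams for ind in fam])
    raise RuntimeError(
        "could not hit the target sample size; check sibship_mean/generations"
    )


# ---------------------------------------------------------------------------
# haplotypes and gene drop


def _causal_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Column indices and designed frequencies for every causal SNP.

    Genes occupy disjoint contiguous blocks, round-robin across
    chromosomes; MAF classes (rare < 1%, low 1-5%, common >= 5%) are
    spread over the causal slots to honour the configured quotas.
    """
    n_causal = sum(g.n_snps for g in cfg.genes)
    classes = (
        ["rare"] * cfg.causal_rare_lt01
        + ["low"] * (cfg.causal_rare_lt05 - cfg.causal_rare_lt01)
        + ["common"] * (n_causal - cfg.causal_rare_lt05)
    )
    rng.shuffle(classes)
    bounds = {"rare": (0.002, 0.01), "low": (0.011, 0.05), "common": (0.05, 0.5)}

    m = cfg.snps_per_chrom
    layout = []  # (gene, chrom_index, column indices within chrom, freqs)
    offset_by_chrom = [m // 10] * cfg.n_chroms
    slot = 0
    for k, gene in enumerate(cfg.genes):
        c = k % cfg.n_chroms
        start = offset_by_chrom[c]
        cols = np.arange(start, start + gene.n_snps)
        if cols[-1] >= m:
            raise ValueError("chromosome too short for the causal layout")
        offset_by_chrom[c] = start + gene.n_snps + m // 10
        freqs = np.array(
            [rng.uniform(*bounds[classes[slot + j]]) for j in range(gene.n_snps)]
        )
        layout.append((gene, c, cols, freqs))
        slot += gene.n_snps
    return layout


def simulate_founder_haplotypes(
    cfg: SimulationConfig, seed: int, n_founders: int
) -> tuple[list[np.ndarray], pd.DataFrame, list]:
    """Founder haplotypes with designed frequencies and AR(1)-copula LD.

    Returns (haplotype arrays per chromosome of shape (2*n_founders, m),
    SNP table, causal layout).  Causal columns are guaranteed at least
    two alternate-allele copies among founder haplotypes so realized
    dosage variance is never zero.
    """
    rng = _substream(seed, 1)
    n_hap = 2 * n_founders
    m = cfg.snps_per_chrom

    # designed background frequencies
    freqs_by_chrom = []
    for _ in range(cfg.n_chroms):
        rare = rng.random(m) < cfg.rare_frac
        p = np.where(rare, rng.uniform(0.001, 0.01, m), rng.uniform(0.05, 0.5, m))
        freqs_by_chrom.append(p)

    layout = _causal_layout(cfg, rng)
    for gene, c, cols, freqs in layout:
        freqs_by_chrom[c][cols] = freqs

    haps, snp_rows = [], []
    for c in range(cfg.n_chroms):
        p = freqs_by_chrom[c]
        # latent AR(1) thresholded at the per-site quantile
        z = np.empty((n_hap, m))
        z[:, 0] = rng.standard_normal(n_hap)
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1 - cfg.rho**2)
        for j in range(1, m):
            z[:, j] = cfg.rho * z[:, j - 1] + innov[:, j - 1]
        h = (z < norm.ppf(p)).astype(np.int8)
        haps.append(h)
        pos = np.sort(rng.integers(1, m * _SNP_SPACING, size=m))
        pos = pos + np.arange(m)  # break ties, keep strictly increasing
        for j in range(m):
            snp_rows.append(
                {"snp": f"c{c + 1}s{j + 1}", "chrom": str(c + 1), "pos": int(pos[j]),
                 "ref": "A", "alt": "G"}
            )

    # keep causal sites polymorphic among founders
    for gene, c, cols, _ in layout:
        for j in cols:
            count = int(haps[c][:, j].sum())
            if count < 2:
                add = rng.choice(n_hap, size=2 - count, replace=False)
                haps[c][add, j] = 1

    snps = pd.DataFrame(snp_rows)
    return haps, snps, layout


def _gamete(h0, h1, n_x: int, rng: np.random.Generator) -> np.ndarray:
    """One recombined gamete from a parent's two haplotypes."""
    m = h0.shape[0]
    cur = int(rng.integers(2))
    if n_x == 0:
        return (h0 if cur == 0 else h1).copy()
    cuts = np.sort(rng.integers(1, m, size=n_x))
    out = np.empty(m, dtype=np.int8)
    prev = 0
    for cut in np.append(cuts, m):
        src = h0 if cur == 0 else h1
        out[prev:cut] = src[prev:cut]
        cur ^= 1
        prev = cut
    return out


def gene_drop(
    ped: Pedigree,
    founder_haps: list[np.ndarray],
    snps: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int,
) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree with recombination.

    Each meiosis transmits one recombined parental haplotype; crossover
    counts are Poisson(``recomb_per_chrom``) with uniform positions.
    """
    rng = _substream(seed, 2)
    founders = ped.founders
    if founder_haps[0].shape[0] != 2 * len(founders):
        raise ValueError("founder haplotype count does not match pedigree founders")
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    n = len(ped)
    dos_blocks = []
    for c, fh in enumerate(founder_haps):
        m = fh.shape[1]
        hap = np.empty((n, 2, m), dtype=np.int8)
        for k, iid in enumerate(founders):
            hap[pos[iid], 0] = fh[2 * k]
            hap[pos[iid], 1] = fh[2 * k + 1]
        for iid in ped.order:
            ind = ped[iid]
            if ind.is_founder:
                continue
            i = pos[iid]
            for s, parent in enumerate((ind.father, ind.mother)):
                p = pos[parent]
                n_x = int(rng.poisson(cfg.recomb_per_chrom))
                hap[i, s] = _gamete(hap[p, 0], hap[p, 1], n_x, rng)
        dos_blocks.append(hap.sum(axis=1, dtype=np.int16))
    dosages = np.concatenate(dos_blocks, axis=1).astype(float)
    return GenotypeMatrix(ped.ids, snps.reset_index(drop=True), dosages)


# ---------------------------------------------------------------------------
# covariates and phenotypes


def _generation_depth(ped: Pedigree) -> dict[str, int]:
    depth = {}
    children: dict[str, list[str]] = {i: [] for i in ped.ids}
    for ind in ped.individuals:
        if not ind.is_founder:
            children[ind.father].append(ind.iid)
            children[ind.mother].append(ind.iid)
    for iid in ped.order:
        ind = ped[iid]
        if ind.is_founder:
            depth[iid] = 0
        else:
            depth[iid] = max(depth[ind.father], depth[ind.mother]) + 1
    # married-in founders belong to their partner's generation band
    for iid in ped.founders:
        kid_depths = [depth[c] for c in children[iid]]
        if kid_depths:
            depth[iid] = max(depth[iid], min(kid_depths) - 1)
    return depth


def simulate_covariates(ped: Pedigree, seed: int) -> pd.DataFrame:
    """Ages by generation band (older generations older) plus sex from the pedigree."""
    rng = _substream(seed, 3)
    depth = _generation_depth(ped)
    rows = {}
    for iid in ped.ids:
        hi = max(80.0 - 20.0 * depth[iid], 40.0)
        rows[iid] = {"age": rng.uniform(hi - 20.0, hi), "sex": ped[iid].sex}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


def simulate_phenotypes(
    ped: Pedigree,
    G: GenotypeMatrix,
    covariates: pd.DataFrame,
    layout,
    cfg: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, CausalArchitecture, pd.DataFrame]:
    """Replicate phenotypes with designed variance fractions.

    Gene effect sizes are calibrated against the realized dosage
    covariance so each gene's causal score has variance exactly
    ``variance_fraction * total_variance`` despite LD among its SNPs.
    Causal scores and covariate effects are fixed across replicates;
    the polygenic deviate (MVN around 2*Phi) and environmental noise are
    redrawn per replicate.  Returns (phenotypes, architecture, true
    genetic values), the latter two being the evaluation ground truth.
    """
    rng = _substream(seed, 4)
    n = len(ped)
    V = cfg.total_variance
    cov = covariates.reindex(ped.ids)
    age = cov["age"].to_numpy(dtype=float)
    sex = (cov["sex"].to_numpy(dtype=float) == 2).astype(float)

    snp_ids = G.snps["snp"].astype(str).to_numpy()
    col_of = {s: k for k, s in enumerate(snp_ids)}
    chrom_offset = {}
    for k, (_, row) in enumerate(G.snps.iterrows()):
        chrom_offset.setdefault(str(row["chrom"]), k)

    genes: list[CausalGene] = []
    score_total = np.zeros(n)
    for gene_cfg, c, cols, _ in layout:
        gcols = [chrom_offset[str(c + 1)] + int(j) for j in cols]
        D = G.dosages[:, gcols]
        Dc = D - D.mean(axis=0)
        sd = Dc.std(axis=0)
        if np.any(sd == 0):
            raise RuntimeError(f"monomorphic causal SNP in {gene_cfg.name}")
        k = len(gcols)
        lead = int(np.argmax(D.mean(axis=0)))  # most common causal SNP leads
        share = np.full(k, (1.0 - gene_cfg.lead_share) / max(k - 1, 1))
        share[lead] = gene_cfg.lead_share if k > 1 else 1.0
        w = np.sqrt(share) / sd
        raw = Dc @ w
        v = raw.var()
        scale = np.sqrt(gene_cfg.variance_fraction * V / v) if v > 0 else 0.0
        a = w * scale
        score_total += Dc @ a
        genes.append(
            CausalGene(
                gene_cfg.name, str(c + 1), [snp_ids[j] for j in gcols],
                [float(x) for x in a], gene_cfg.variance_fraction,
            )
        )
    arch = CausalArchitecture(genes, h2_polygenic=cfg.h2_polygenic)

    b_age = np.sqrt(cfg.covar_frac_age * V / age.var()) if age.var() > 0 else 0.0
    b_sex = np.sqrt(cfg.covar_frac_sex * V / sex.var()) if sex.var() > 0 else 0.0
    fixed = cfg.mean + b_age * (age - age.mean()) + b_sex * (sex - sex.mean())

    f_env = 1.0 - (
        sum(g.variance_fraction for g in cfg.genes)
        + cfg.h2_polygenic + cfg.covar_frac_age + cfg.covar_frac_sex
    )
    R = expected_relatedness(ped).values
    L = np.linalg.cholesky(R + 1e-10 * np.eye(n))

    ph_rows, g_rows = [], []
    for rep in range(1, cfg.n_replicates + 1):
        g_poly = np.sqrt(cfg.h2_polygenic * V) * (L @ rng.standard_normal(n))
        e = np.sqrt(max(f_env, 0.0) * V) * rng.standard_normal(n)
        g_true = score_total + g_poly
        y = fixed + g_true + e
        ph_rows.append(pd.DataFrame({"id": ped.ids, "replicate": rep, "y": y}))
        g_rows.append(pd.DataFrame({"id": ped.ids, "replicate": rep, "g": g_true}))
    return pd.concat(ph_rows, ignore_index=True), arch, pd.concat(g_rows, ignore_index=True)


def simulate_study(cfg: SimulationConfig | None = None, seed: int = 0) -> StudyData:
    """Run the whole generator: pedigree, genotypes, covariates, phenotypes."""
    cfg = cfg or SimulationConfig()
    ped = simulate_pedigree(cfg, seed)
    haps, snps, layout = simulate_founder_haplotypes(cfg, seed, len(ped.founders))
    G = gene_drop(ped, haps, snps, cfg, seed)
    covariates = simulate_covariates(ped, seed)
    pheno, arch, true_g = simulate_phenotypes(ped, G, covariates, layout, cfg, seed)
    return StudyData(ped, G, covariates, pheno, arch, true_g, cfg, seed)
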