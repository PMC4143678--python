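"""Shared fixtures: small pedigrees and mid-scale simulated studies."""

import numpy as np
import pytest

from egvkit.pedigree import Individual, Pedigree, expected_relatedness
from egvkit.polygenic import KinshipEigen
from egvkit.simulate import GeneConfig, SimulationConfig, simulate_study


def make_trio() -> Pedigree:
    return Pedigree([
        Individual("F", "FAM1", None, None, 1),
        Individual("M", "FAM1", None, None, 2),
        Individual("C", "FAM1", "F", "M", 1),
    ])


def make_four_gen() -> Pedigree:
    """4-generation, 14-member pedigree incl. a full-sib mating (inbred child)."""
    rows = [
        ("g1a", None, None, 1), ("g1b", None, None, 2),
        ("g2a", "g1a", "g1b", 1), ("g2b", "g1a", "g1b", 2),
        ("g2c", "g1a", "g1b", 1),
        ("sp2", None, None, 2), ("sp3", None, None, 1),
        ("g3a", "g2a", "sp2", 1), ("g3b", "g2a", "sp2", 2),
        ("g3c", "sp3", "g2b", 2),
        ("inb", "g2a", "g2b", 1),           # full-sib mating
        ("sp4", None, None, 2),
        ("g4a", "g3a", "g3c", 1), ("g4b", "g3a", "sp4", 2),
    ]
    return Pedigree([Individual(i, "FAM1", f, m, s) for i, f, m, s in rows])


def gene_drop_ibd(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo relatedness oracle: drop one unlinked locus many times.

    Founder alleles get unique labels; relatedness 2*phi between i and j
    is estimated as half the mean count of IBD allele matches over the
    four allele pairings.
    """
    rng = np.random.default_rng(seed)
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    n = len(ped)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    label = 0
    for iid in ped.founders:
        alleles[pos[iid], 0] = label
        alleles[pos[iid], 1] = label + 1
        label += 2
    for iid in ped.order:
        ind = ped[iid]
        if ind.is_founder:
            continue
        i = pos[iid]
        for s, parent in enumerate((ind.father, ind.mother)):
            p = pos[parent]
            pick = rng.integers(0, 2, size=n_drops)
            alleles[i, s] = np.where(pick == 0, alleles[p, 0], alleles[p, 1])
    R = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m = 0.0
            for a in range(2):
                for b in range(2):
                    m += np.mean(alleles[i, a] == alleles[j, b])
            R[i, j] = R[j, i] = m / 2.0
    return R


@pytest.fixture(scope="session")
def small_study():
    """~120 individuals in 3 families, 2 chromosomes; cheap, reused widely."""
    cfg = SimulationConfig(
        n_families=3, target_n=120, n_chroms=2, snps_per_chrom=150,
        n_replicates=5,
        genes=[GeneConfig("GENE_A", 6, 0.15), GeneConfig("GENE_B", 4, 0.05)],
        causal_rare_lt01=2, causal_rare_lt05=4, h2_polygenic=0.25,
    )
    return simulate_study(cfg, seed=11)


@pytest.fixture(scope="session")
def small_eig(small_study):
    return KinshipEigen.from_matrix(expected_relatedness(small_study.ped))


@pytest.fixture(scope="session")
def default_study():
    """Default-scale study (~850 individuals, 20 families, 50 replicates)."""
    cfg = SimulationConfig(n_replicates=50)
    return simulate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def default_eig(default_study):
    return KinshipEigen.from_matrix(expected_relatedness(default_study.ped))


@pytest.fixture(scope="session")
def kinship_study():
    """~850 individuals genotyped at ~22k sites with moderate LD.

    Dense-marker conditions for marker-based kinship: most sites are
    common, LD is mild so many markers are informative.
    """
    cfg = SimulationConfig(
        n_chroms=4, snps_per_chrom=5500, rho=0.5, rare_frac=0.1,
        n_replicates=1,
    )
    return simulate_study(cfg, seed=19)
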