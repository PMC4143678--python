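"""Dosage-matrix container shared by kinship, PCA, association and LD code."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """n samples x m SNPs of alternate-allele dosages in {0, 1, 2, NaN}.

    ``snps`` is a DataFrame with columns (snp, chrom, pos, ref, alt);
    positions are 1-based and non-decreasing within each chromosome.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.sample_ids), len(self.snps)
        if self.dosages.shape != (n, m):
            raise ValueError(f"dosage shape {self.dosages.shape} != ({n}, {m})")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency per SNP (missing excluded)."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.sample_ids,
            self.snps.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        take = [pos[s] for s in ids]
        return GenotypeMatrix(list(ids), self.snps, self.dosages[take, :])
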