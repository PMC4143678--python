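"""Readers and writers: FAM, VCF, CSV tables, matrix text, JSON manifests.

Everything round-trips: write-then-read returns equal objects (dosages
exactly, floats to full double precision in the square-matrix format).
VCF is written as plain uncompressed text and read back with cyvcf2.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, RelatednessMatrix, read_pedigree, write_pedigree

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "write_vcf",
    "read_vcf",
    "write_matrix",
    "read_matrix",
    "write_matrix_long",
    "write_phenotypes",
    "read_phenotypes",
    "write_covariates",
    "read_covariates",
    "file_sha256",
    "write_manifest",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a plain-text VCF 4.2 with GT genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for k in range(G.n_snps):
            row = G.snps.iloc[k]
            gts = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in G.dosages[:, k]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT dosages from a VCF; missing genotypes become NaN, not 0."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for var in vcf:
        rows.append(
            {
                "snp": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        dosage_rows.append(d)
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix(samples, pd.DataFrame(rows), np.array(dosage_rows).T)


def write_matrix(R: RelatednessMatrix, path: str | Path) -> None:
    """Square matrix text: header row of ids, full double precision."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(R.ids) + f"\t#source={R.source}\n")
        for i, iid in enumerate(R.ids):
            vals = "\t".join(repr(float(v)) for v in R.values[i])
            fh.write(f"{iid}\t{vals}\n")


def read_matrix(path: str | Path) -> RelatednessMatrix:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    source = "ped"
    if header[-1].startswith("#source="):
        source = header[-1].split("=", 1)[1]
        header = header[:-1]
    ids = header[1:]
    vals = np.array(
        [[float(x) for x in ln.split("\t")[1 : len(ids) + 1]] for ln in lines[1:]]
    )
    return RelatednessMatrix(ids, vals, source=source)


def write_matrix_long(R: RelatednessMatrix, path: str | Path) -> None:
    """Long-format text (id1, id2, value), upper triangle incl. diagonal."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i, a in enumerate(R.ids):
            for j in range(i, len(R.ids)):
                fh.write(f"{a}\t{R.ids[j]}\t{repr(float(R.values[i, j]))}\n")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path: str | Path, ped: Pedigree | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    need = {"id", "replicate", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: phenotype CSV needs columns {sorted(need)}")
    if ped is not None:
        unknown = set(df["id"]) - set(ped.ids)
        if unknown:
            raise ValueError(f"{path}: unknown id(s): {sorted(unknown)[:5]}")
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, index=True)


def read_covariates(path: str | Path, ped: Pedigree | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str}).set_index("id")
    if ped is not None:
        unknown = set(df.index) - set(ped.ids)
        if unknown:
            raise ValueError(f"{path}: unknown id(s): {sorted(unknown)[:5]}")
    return df


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path, config: dict, seed: int, outputs: dict[str, str | Path]
) -> dict:
    """Record config, seed and a content hash per output file."""
    manifest = {
        "seed": seed,
        "config": config,
        "outputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in outputs.items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
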