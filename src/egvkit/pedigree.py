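"""Pedigree parsing, expected relatedness (2Φ) and unrelated-subset selection.

The expected relationship matrix R = 2Φ (twice the kinship matrix) is
computed by the recursive (tabular) method in topological order: founders
are mutually unrelated with self-kinship 1/2; for a non-founder i with
parents f and m,

    φ(i, j) = (φ(f, j) + φ(m, j)) / 2        for j processed before i,
    φ(i, i) = (1 + φ(f, m)) / 2.

The diagonal of R is therefore 1 + F where F is the inbreeding
coefficient.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "RelatednessMatrix",
    "read_pedigree",
    "expected_relatedness",
    "select_unrelated",
]

MALE, FEMALE = 1, 2
_MISSING_PARENT = {"0", "NA", "na", ".", ""}


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (cycles, duplicates, half parentage)."""


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None
    mother: str | None
    sex: int  # 1 = male, 2 = female, 0 = unknown

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A validated multi-family pedigree.

    ``order`` lists individual ids topologically: every parent precedes
    its offspring, so recursive kinship and gene-drop passes can run in a
    single sweep.
    """

    individuals: list[Individual]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {dup}")
        self._by_id = {ind.iid: ind for ind in self.individuals}
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid!r}: exactly one parent specified; "
                    "records must name both parents or neither"
                )
            for p in (ind.father, ind.mother):
                if p is not None and p not in self._by_id:
                    raise PedigreeError(
                        f"individual {ind.iid!r}: parent {p!r} not in pedigree"
                    )
        if not self.order:
            self.order = self._toposort()
        else:
            self._check_order(self.order)

    def _toposort(self) -> list[str]:
        # Kahn's algorithm on the parent->child DAG; detects cycles.
        n_parents = {
            ind.iid: (0 if ind.is_founder else 2) for ind in self.individuals
        }
        children: dict[str, list[str]] = {ind.iid: [] for ind in self.individuals}
        for ind in self.individuals:
            if not ind.is_founder:
                children[ind.father].append(ind.iid)
                children[ind.mother].append(ind.iid)
        queue = sorted(i for i, k in n_parents.items() if k == 0)
        out: list[str] = []
        while queue:
            cur = queue.pop(0)
            out.append(cur)
            for ch in children[cur]:
                n_parents[ch] -= 1
                if n_parents[ch] == 0:
                    queue.append(ch)
        if len(out) != len(self.individuals):
            cyclic = sorted(set(n_parents) - set(out))
            raise PedigreeError(f"cycle detected involving id(s): {cyclic}")
        return out

    def _check_order(self, order: list[str]) -> None:
        pos = {iid: k for k, iid in enumerate(order)}
        if set(pos) != set(self._by_id):
            raise PedigreeError("order does not cover exactly the pedigree ids")
        for ind in self.individuals:
            if not ind.is_founder and (
                pos[ind.father] > pos[ind.iid] or pos[ind.mother] > pos[ind.iid]
            ):
                raise PedigreeError(f"order places {ind.iid!r} before a parent")

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def founders(self) -> list[str]:
        return [ind.iid for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [ind.iid for ind in self.individuals if not ind.is_founder]

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.fid)
        return list(seen)


@dataclass
class RelatednessMatrix:
    """Symmetric relatedness matrix R = 2Φ over an ordered id list.

    ``source`` records provenance: "ped" (expected, from the pedigree),
    "snp" (empirical, common variants) or "seq" (empirical, all
    variants).  For source="ped" the diagonal equals 1 + F.
    """

    ids: list[str]
    values: np.ndarray
    source: str = "ped"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relatedness matrix is not symmetric")

    def loc(self, i: str, j: str) -> float:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def reorder(self, ids: list[str]) -> "RelatednessMatrix":
        idx = {iid: k for k, iid in enumerate(self.ids)}
        take = np.array([idx[i] for i in ids])
        return RelatednessMatrix(list(ids), self.values[np.ix_(take, take)], self.source)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK FAM-style pedigree (FAM, ID, FATHER, MOTHER, SEX[, ...]).

    Whitespace- or comma-delimited; '0'/'NA' marks a missing parent.
    """
    inds: list[Individual] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) < 5:
            raise PedigreeError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
        fid, iid, fa, mo, sex = fields[:5]
        father = None if fa in _MISSING_PARENT else fa
        mother = None if mo in _MISSING_PARENT else mo
        if father == iid or mother == iid:
            raise PedigreeError(f"{path}:{lineno}: cycle — {iid!r} is its own parent")
        try:
            sex_code = int(sex)
        except ValueError:
            sex_code = {"M": MALE, "F": FEMALE}.get(sex.upper(), 0)
        inds.append(Individual(iid, fid, father, mother, sex_code))
    return Pedigree(inds)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a 5-column FAM file (missing parents as 0)."""
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}\t{ind.sex}\n"
            )


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship matrix Φ in pedigree (individuals) order, by the tabular method."""
    n = len(ped)
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    phi = np.zeros((n, n))
    # process in topological order so parents' rows are complete first
    for iid in ped.order:
        i = pos[iid]
        ind = ped[iid]
        if ind.is_founder:
            phi[i, i] = 0.5
            continue
        f, m = pos[ind.father], pos[ind.mother]
        row = 0.5 * (phi[f, :] + phi[m, :])
        row[i] = 0.5 * (1.0 + phi[f, m])
        phi[i, :] = row
        phi[:, i] = row
    return phi


def expected_relatedness(ped: Pedigree) -> RelatednessMatrix:
    """Expected relatedness R = 2Φ from the pedigree (diagonal 1 + F)."""
    if len(ped) == 0:
        raise PedigreeError("empty pedigree")
    return RelatednessMatrix(ped.ids, 2.0 * kinship_matrix(ped), source="ped")


def select_unrelated(
    ped: Pedigree, R: RelatednessMatrix, max_relatedness: float = 0.05
) -> set[str]:
    """Greedy maximal set with all pairwise off-diagonal R < ``max_relatedness``.

    Candidates are visited in ascending order of how many others they are
    related to (ties broken by id), so members of large sibships are
    dropped before their founder parents.  Deterministic for a fixed id set.
    """
    if len(ped) == 0:
        raise PedigreeError("empty pedigree")
    Rm = R.reorder(ped.ids)
    n = len(ped.ids)
    rel = (Rm.values >= max_relatedness) & ~np.eye(n, dtype=bool)
    degree = rel.sum(axis=1)
    order = sorted(range(n), key=lambda k: (degree[k], ped.ids[k]))
    chosen: list[int] = []
    for k in order:
        if all(not rel[k, j] for j in chosen):
            chosen.append(k)
    return {ped.ids[k] for k in chosen}
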