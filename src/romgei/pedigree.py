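"""Pedigree construction and kinship computation.

The simulation design uses two family shapes:

* a *nuclear* family: two founder parents with two offspring (4 members,
  2 founders);
* a *three-generation extended* family: two founder grandparents, three
  second-generation offspring each married to a founder spouse, and three
  grandchildren per second-generation couple (17 members, 5 founders).

Kinship coefficients follow the standard recursive definition (the
convention used by pedigree packages such as kinship2): the self-kinship
of a non-inbred individual is 0.5, a parent-offspring or full-sib pair
has kinship 0.25, and all founders are mutually unrelated.  The additive
relationship matrix is twice the kinship matrix and has unit diagonal
for non-inbred pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Member",
    "Pedigree",
    "KinshipModel",
    "build_pedigree",
    "compute_kinship",
]

DEFAULT_N_NUCLEAR = 12_750
DEFAULT_N_EXTENDED = 2_000


@dataclass(frozen=True)
class Member:
    """One pedigree member; founders have ``father is None and mother is None``."""

    iid: str
    fid: str
    father: str | None
    mother: str | None
    generation: int

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """An ordered collection of members partitioned into families.

    Members are stored in an order in which every parent precedes each of
    its children, which the constructors guarantee and ``validate``
    checks; gene-dropping and kinship recursion rely on it.
    """

    members: list[Member]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {m.iid: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise ValueError("duplicate individual ids in pedigree")
        self.validate()

    # -- basic counts -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.members)

    @property
    def n_founders(self) -> int:
        return sum(m.is_founder for m in self.members)

    @property
    def n_families(self) -> int:
        return len({m.fid for m in self.members})

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of father/mother row indices; -1 for founders."""
        fa = np.full(self.n_individuals, -1, dtype=np.int64)
        mo = np.full(self.n_individuals, -1, dtype=np.int64)
        for i, m in enumerate(self.members):
            if not m.is_founder:
                fa[i] = self._index[m.father]
                mo[i] = self._index[m.mother]
        return fa, mo

    def families(self) -> dict[str, np.ndarray]:
        """Family id -> member row indices, in pedigree order."""
        fams: dict[str, list[int]] = {}
        for i, m in enumerate(self.members):
            fams.setdefault(m.fid, []).append(i)
        return {fid: np.asarray(idx, dtype=np.int64) for fid, idx in fams.items()}

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if (m.father is None) != (m.mother is None):
                raise ValueError(f"{m.iid}: exactly one parent recorded")
            if not m.is_founder:
                for p in (m.father, m.mother):
                    if p not in self._index:
                        raise ValueError(f"{m.iid}: unknown parent {p}")
                    if p not in seen:
                        raise ValueError(f"{m.iid}: parent {p} does not precede child")
                    if self.members[self._index[p]].fid != m.fid:
                        raise ValueError(f"{m.iid}: parent {p} in a different family")
            seen.add(m.iid)


def build_pedigree(
    n_nuclear: int = DEFAULT_N_NUCLEAR, n_extended: int = DEFAULT_N_EXTENDED
) -> Pedigree:
    """Build the simulated cohort pedigree.

    Parameters
    ----------
    n_nuclear
        Number of nuclear families (2 founder parents, 2 offspring).
    n_extended
        Number of three-generation extended families (2 founder
        grandparents; 3 second-generation offspring each with a founder
        spouse; 3 grandchildren per couple).

    The default configuration yields 85,000 individuals in 14,750
    families with 35,500 founders.
    """
    if n_nuclear < 0 or n_extended < 0:
        raise ValueError("family counts must be nonnegative")
    members: list[Member] = []
    for k in range(n_nuclear):
        fid = f"nuc{k}"
        pa, ma = f"{fid}_pa", f"{fid}_ma"
        members.append(Member(pa, fid, None, None, 1))
        members.append(Member(ma, fid, None, None, 1))
        for j in range(2):
            members.append(Member(f"{fid}_o{j}", fid, pa, ma, 2))
    for k in range(n_extended):
        fid = f"ext{k}"
        gpa, gma = f"{fid}_gpa", f"{fid}_gma"
        members.append(Member(gpa, fid, None, None, 1))
        members.append(Member(gma, fid, None, None, 1))
        for j in range(3):
            child = f"{fid}_c{j}"
            spouse = f"{fid}_s{j}"
            members.append(Member(child, fid, gpa, gma, 2))
            members.append(Member(spouse, fid, None, None, 2))
            for g in range(3):
                members.append(Member(f"{fid}_g{j}{g}", fid, child, spouse, 3))
    return Pedigree(members)


@dataclass
class KinshipModel:
    """Block-diagonal kinship structure of a pedigree or GRM.

    ``blocks[k]`` is the dense kinship-coefficient block of family
    ``family_ids[k]`` whose members sit at rows ``indices[k]`` of the
    sample ordering.  The additive relationship matrix is ``2 * Psi``.
    """

    family_ids: list[str]
    blocks: list[np.ndarray]
    indices: list[np.ndarray]
    n: int

    @property
    def cluster_map(self) -> dict[str, np.ndarray]:
        return dict(zip(self.family_ids, self.indices))

    @property
    def clusters(self) -> list[np.ndarray]:
        return list(self.indices)

    def cluster_labels(self) -> np.ndarray:
        lab = np.empty(self.n, dtype=object)
        for fid, idx in zip(self.family_ids, self.indices):
            lab[idx] = fid
        return lab

    def relationship_blocks(self) -> list[np.ndarray]:
        """Per-family additive relationship (2 * kinship) blocks."""
        return [2.0 * b for b in self.blocks]

    def to_sparse(self, scale: float = 2.0) -> sp.csr_matrix:
        """Assemble ``scale * Psi`` as a sparse symmetric matrix."""
        rows, cols, data = [], [], []
        for blk, idx in zip(self.blocks, self.indices):
            b = len(idx)
            rows.append(np.repeat(idx, b))
            cols.append(np.tile(idx, b))
            data.append(scale * blk.ravel())
        if not rows:
            return sp.csr_matrix((self.n, self.n))
        return sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )


def compute_kinship(ped: Pedigree) -> KinshipModel:
    """Kinship coefficients via the standard recursion, one family at a time.

    phi(i,i) = 0.5 + 0.5 * phi(father_i, mother_i); for i a non-founder
    listed after j, phi(i,j) = 0.5 * (phi(father_i, j) + phi(mother_i, j));
    founders are mutually unrelated with self-kinship 0.5.
    """
    fa, mo = ped.parent_indices()
    fams = ped.families()
    family_ids, blocks, indices = [], [], []
    for fid, idx in fams.items():
        pos = {g: k for k, g in enumerate(idx)}
        b = len(idx)
        phi = np.zeros((b, b))
        for k, g in enumerate(idx):
            if fa[g] < 0:
                phi[k, k] = 0.5
            else:
                f, m = pos[fa[g]], pos[mo[g]]
                if f >= k or m >= k:
                    raise ValueError(f"cyclic or out-of-order parentage in family {fid}")
                phi[k, k] = 0.5 + 0.5 * phi[f, m]
                for j in range(k):
                    phi[k, j] = phi[j, k] = 0.5 * (phi[f, j] + phi[m, j])
        family_ids.append(fid)
        blocks.append(phi)
        indices.append(idx)
    return KinshipModel(family_ids, blocks, indices, ped.n_individuals)
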