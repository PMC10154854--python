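"""Pedigree handling and the additive (numerator) relationship matrix.

The pedigree is the covariance backbone of the animal model: the additive
genetic covariance between individuals i and j is ``a_ij * sigma2_a`` where
``a_ij`` is the entry of the numerator relationship matrix A, computed
recursively from parent links (Henderson's tabular method).  The sparse
inverse of A is built directly from the pedigree (Meuwissen & Luo style,
accounting for inbreeding), which is what makes mixed-model computations on
thousands of individuals tractable.

Conventions
-----------
* Identifiers are opaque strings; the missing-parent token in files is "0".
* Founders (both parents unknown) are treated as unrelated and non-inbred.
* Matrix row/column order is the topological sort order of the pedigree,
  ties broken by input order.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

MISSING = "0"

__all__ = [
    "MISSING",
    "PedigreeError",
    "PedigreeRecord",
    "PedigreeTable",
    "RelationshipMatrix",
    "validate_and_sort",
    "additive_relationship",
    "inverse_relationship",
    "inbreeding_coefficients",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identifier, parent links and bookkeeping labels.

    ``sire``/``dam`` are ``None`` for unknown parents.  ``sex`` is one of
    ``{"male", "female", "unknown"}``; ``generation`` is a non-negative
    integer label and ``line_origin`` a free-form origin code
    (``F``, ``M``, ``F1``, ``BC``, ``other``).
    """

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = "unknown"
    generation: int = 0
    line_origin: str = "other"


class PedigreeTable:
    """A validated, topologically sorted pedigree.

    Every parent precedes its offspring; construction is via
    :func:`validate_and_sort`.
    """

    def __init__(self, records: Sequence[PedigreeRecord], _sorted: bool = False):
        if not _sorted:
            raise PedigreeError(
                "unsorted pedigree: build tables via validate_and_sort()"
            )
        self.records: list[PedigreeRecord] = list(records)
        self.index: dict[str, int] = {r.id: k for k, r in enumerate(self.records)}
        self.sire_idx = np.array(
            [self.index[r.sire] if r.sire is not None else -1 for r in self.records],
            dtype=np.int64,
        )
        self.dam_idx = np.array(
            [self.index[r.dam] if r.dam is not None else -1 for r in self.records],
            dtype=np.int64,
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def parents_of(self) -> set[int]:
        """Indices of individuals that appear as a sire or dam."""
        out = set(self.sire_idx[self.sire_idx >= 0].tolist())
        out |= set(self.dam_idx[self.dam_idx >= 0].tolist())
        return out


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with per-individual inbreeding.

    ``entries[i, j]`` is the additive relationship a_ij (dimensionless,
    founders' diagonal exactly 1); ``inbreeding[i] = entries[i, i] - 1``.
    """

    ids: list[str]
    entries: np.ndarray
    inbreeding: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.inbreeding = np.diag(self.entries) - 1.0


def validate_and_sort(records: Iterable[PedigreeRecord]) -> PedigreeTable:
    """Validate parent links and return a topologically sorted table.

    Raises :class:`PedigreeError` with message containing "pedigree cycle"
    (self-ancestry or longer cycles), "dangling parent" (parent id with no
    record) or "sex inconsistency" (a sire recorded as female, or a dam
    recorded as male).
    """
    recs = list(records)
    if not recs:
        raise PedigreeError("empty pedigree")
    pos = {}
    for k, r in enumerate(recs):
        if r.id in pos:
            raise PedigreeError(f"duplicate id {r.id!r}")
        pos[r.id] = k
    for r in recs:
        if r.id == r.sire or r.id == r.dam:
            raise PedigreeError(f"pedigree cycle: {r.id!r} is its own parent")
        for p in (r.sire, r.dam):
            if p is not None and p not in pos:
                raise PedigreeError(f"dangling parent {p!r} of {r.id!r}")
        if r.sire is not None and recs[pos[r.sire]].sex == "female":
            raise PedigreeError(f"sex inconsistency: sire {r.sire!r} is female")
        if r.dam is not None and recs[pos[r.dam]].sex == "male":
            raise PedigreeError(f"sex inconsistency: dam {r.dam!r} is male")

    # Kahn's algorithm; ready queue ordered by input position for stable ties.
    children: dict[str, list[str]] = {r.id: [] for r in recs}
    n_par = {r.id: 0 for r in recs}
    for r in recs:
        for p in (r.sire, r.dam):
            if p is not None:
                children[p].append(r.id)
                n_par[r.id] += 1
    import heapq

    ready = [pos[i] for i, c in n_par.items() if c == 0]
    heapq.heapify(ready)
    order: list[PedigreeRecord] = []
    while ready:
        k = heapq.heappop(ready)
        order.append(recs[k])
        for ch in children[recs[k].id]:
            n_par[ch] -= 1
            if n_par[ch] == 0:
                heapq.heappush(ready, pos[ch])
    if len(order) != len(recs):
        raise PedigreeError("pedigree cycle detected")
    return PedigreeTable(order, _sorted=True)


def _kinship_fn(sire_idx: np.ndarray, dam_idx: np.ndarray):
    """Memoized kinship phi(i, j) on topologically sorted index arrays.

    Index -1 denotes an unknown parent (kinship 0 with everything).
    ``a_ij = 2 phi(i, j)`` and ``F_i = phi(sire_i, dam_i)``.
    """
    memo: dict[tuple[int, int], float] = {}
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * len(sire_idx) + 1000))

    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        v = memo.get(key)
        if v is not None:
            return v
        if i == j:
            v = 0.5 * (1.0 + phi(sire_idx[i], dam_idx[i]))
        else:
            # j is later in the sort, so recurse through j's parents
            v = 0.5 * (phi(i, sire_idx[j]) + phi(i, dam_idx[j]))
        memo[key] = v
        return v

    return phi


def inbreeding_coefficients(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficient F of every individual (founders exactly 0)."""
    phi = _kinship_fn(ped.sire_idx, ped.dam_idx)
    return np.array(
        [phi(ped.sire_idx[i], ped.dam_idx[i]) for i in range(len(ped))]
    )


def additive_relationship(ped: PedigreeTable) -> RelationshipMatrix:
    """Dense A by the tabular method.

    a_ii = 1 + 0.5 a_{sire,dam}; a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)})
    for j earlier in the sort, missing-parent terms contributing 0.
    """
    if not isinstance(ped, PedigreeTable):
        raise PedigreeError("unsorted pedigree")
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * A[s[i], :i]
        if d[i] >= 0:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return RelationshipMatrix(ids=ped.ids, entries=A)


def mendelian_variance_scale(ped: PedigreeTable, F: Optional[np.ndarray] = None) -> np.ndarray:
    """Mendelian-sampling variance d_i (in units of sigma2_a).

    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one, and 1 for founders.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    s, d = ped.sire_idx, ped.dam_idx
    out = np.ones(len(ped))
    both = (s >= 0) & (d >= 0)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    only_s = (s >= 0) & (d < 0)
    out[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (d >= 0) & (s < 0)
    out[only_d] = 0.75 - 0.25 * F[d[only_d]]
    return out


def inverse_relationship(ped: PedigreeTable) -> sp.csc_matrix:
    """Sparse A^-1 directly from the pedigree, with inbreeding.

    Builds the factorization A^-1 = (I - P)' D^-1 (I - P), where P maps
    individuals to half their parents and D holds Mendelian-sampling
    variances; equivalently accumulates the classic per-individual
    contributions alpha = 1/d_i.
    """
    if not isinstance(ped, PedigreeTable):
        raise PedigreeError("unsorted pedigree")
    n = len(ped)
    F = inbreeding_coefficients(ped)
    dvec = mendelian_variance_scale(ped, F)
    s, d = ped.sire_idx, ped.dam_idx
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / dvec[i]
        parents = [p for p in (s[i], d[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


# ---------------------------------------------------------------------------
# CSV dialect: id,sire,dam,sex,generation,line_origin ; missing parent "0"

def read_pedigree_csv(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str)
    required = ["id", "sire", "dam", "sex", "generation", "line_origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns {missing}")
    recs = [
        PedigreeRecord(
            id=row.id,
            sire=None if row.sire in (MISSING, None) or pd.isna(row.sire) else row.sire,
            dam=None if row.dam in (MISSING, None) or pd.isna(row.dam) else row.dam,
            sex=row.sex if isinstance(row.sex, str) else "unknown",
            generation=int(row.generation),
            line_origin=row.line_origin,
        )
        for row in df.itertuples()
    ]
    return validate_and_sort(recs)


def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in ped],
            "sire": [r.sire or MISSING for r in ped],
            "dam": [r.dam or MISSING for r in ped],
            "sex": [r.sex for r in ped],
            "generation": [r.generation for r in ped],
            "line_origin": [r.line_origin for r in ped],
        }
    ).to_csv(path, index=False)
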