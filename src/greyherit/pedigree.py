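"""Pedigree structures, inbreeding, and the additive relationship matrix.

The animal model treats each individual's polygenic breeding value as a
random effect whose covariance is proportional to the additive (numerator)
relationship matrix A derived from the pedigree.  This module loads and
validates pedigrees, computes inbreeding coefficients (Meuwissen & Luo
style path tracing), builds A by the tabular method, and assembles the
sparse inverse of A directly from pedigree structure (Henderson's rules,
accounting for inbreeding).

Unknown parents are treated as unrelated, non-inbred founders; the
missing-parent sentinel in CSV files is an empty field, "0", "NA" or ".".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

MISSING_PARENT = {"", "0", "NA", "na", "NaN", "nan", ".", "-", None}

__all__ = [
    "Pedigree",
    "PedigreeError",
    "load_pedigree",
    "write_pedigree",
    "inbreeding",
    "build_A",
    "build_A_inverse",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate, unknown parent)."""


@dataclass
class Pedigree:
    """A validated pedigree in topological order (parents before offspring).

    Attributes
    ----------
    ids : list of str
        Animal identifiers in topological order.
    sire, dam : ndarray of int
        Positional index of each animal's sire/dam in ``ids``; -1 if unknown.
    sex : ndarray of str
        "M", "F" or "U" per animal.
    birth_year : ndarray of float
        Birth year per animal, NaN when unknown.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def n(self):
        return len(self.ids)

    def position(self, animal_id):
        return self._index[animal_id]

    def positions(self, animal_ids):
        return np.array([self._index[a] for a in animal_ids], dtype=np.int64)

    def is_founder(self):
        return (self.sire < 0) & (self.dam < 0)

    def offspring_counts(self):
        """Number of offspring per animal (as sire or dam)."""
        counts = np.zeros(self.n, dtype=np.int64)
        for par in (self.sire, self.dam):
            known = par[par >= 0]
            np.add.at(counts, known, 1)
        return counts

    def to_frame(self):
        sire_ids = [self.ids[s] if s >= 0 else "" for s in self.sire]
        dam_ids = [self.ids[d] if d >= 0 else "" for d in self.dam]
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": sire_ids,
                "dam": dam_ids,
                "sex": self.sex,
                "birth_year": self.birth_year,
            }
        )

    @classmethod
    def from_records(cls, records, unknown_parents="add"):
        """Build a pedigree from an iterable of dicts with keys
        id/sire/dam and optional sex/birth_year.

        Parameters
        ----------
        unknown_parents : {"add", "error"}
            Parents referenced but never defined are auto-added as founders
            ("add", default) or rejected ("error").
        """
        recs = list(records)
        raw_ids = [str(r["id"]) for r in recs]
        seen = set()
        for a in raw_ids:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)

        def norm(v):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            s = str(v).strip()
            return None if s in MISSING_PARENT else s

        parents = {}
        sexes = {}
        years = {}
        for r in recs:
            a = str(r["id"])
            s, d = norm(r.get("sire")), norm(r.get("dam"))
            if s == a or d == a:
                raise PedigreeError(f"animal {a!r} is its own parent")
            parents[a] = (s, d)
            sx = str(r.get("sex", "U") or "U").upper()[:1]
            sexes[a] = sx if sx in ("M", "F") else "U"
            by = r.get("birth_year")
            try:
                years[a] = float(by)
            except (TypeError, ValueError):
                years[a] = np.nan

        undefined = [
            p
            for a in raw_ids
            for p in parents[a]
            if p is not None and p not in seen
        ]
        if undefined:
            if unknown_parents == "error":
                raise PedigreeError(
                    f"parent id(s) referenced but never defined: {sorted(set(undefined))}"
                )
            for p in undefined:
                if p not in seen:
                    seen.add(p)
                    raw_ids.append(p)
                    parents[p] = (None, None)
                    sexes[p] = "U"
                    years[p] = np.nan

        order = _topological_order(raw_ids, parents)
        idx = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [idx[parents[a][0]] if parents[a][0] else -1 for a in order],
            dtype=np.int64,
        )
        dam = np.array(
            [idx[parents[a][1]] if parents[a][1] else -1 for a in order],
            dtype=np.int64,
        )
        sex = np.array([sexes[a] for a in order])
        birth_year = np.array([years[a] for a in order])
        return cls(order, sire, dam, sex, birth_year, idx)


def _topological_order(ids, parents):
    """Kahn's algorithm; ties broken by input order for reproducibility."""
    input_rank = {a: i for i, a in enumerate(ids)}
    children = {a: [] for a in ids}
    indeg = {a: 0 for a in ids}
    for a in ids:
        for p in parents[a]:
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    ready = sorted((a for a in ids if indeg[a] == 0), key=input_rank.__getitem__)
    order = []
    import heapq

    heap = [(input_rank[a], a) for a in ready]
    heapq.heapify(heap)
    while heap:
        _, a = heapq.heappop(heap)
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (input_rank[c], c))
    if len(order) < len(ids):
        on_cycle = sorted(a for a in ids if indeg[a] > 0)
        raise PedigreeError(
            f"pedigree contains a parentage cycle involving animal {on_cycle[0]!r}"
        )
    return order


def load_pedigree(path, unknown_parents="add"):
    """Read a pedigree CSV (columns id,sire,dam[,sex,birth_year])."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"id", "sire", "dam"} - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree CSV lacks required column(s) {sorted(missing)}")
    return Pedigree.from_records(
        df.to_dict("records"), unknown_parents=unknown_parents
    )


def write_pedigree(ped: Pedigree, path):
    df = ped.to_frame()
    df["birth_year"] = df["birth_year"].map(
        lambda v: "" if np.isnan(v) else str(int(v))
    )
    df.to_csv(path, index=False)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo algorithm.

    F_i is half the additive relationship between i's parents; founders
    (and animals with an unknown parent) have F = 0.  Runs in
    O(n * generations^2) without forming A, so it is usable on the full
    multi-thousand-member pedigree.
    """
    n = ped.n
    F = np.zeros(n)
    # D holds within-family (Mendelian sampling) variances of ancestors,
    # which depend only on earlier F values (topological order guarantees it).
    D = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        Fs = F[s] if s >= 0 else 0.0
        Fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (Fs + Fd)
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * (Fs if s >= 0 else Fd)
        else:
            D[i] = 1.0
        if s >= 0 and d >= 0:
            # F_i = 0.5 * a(sire, dam), with a(x, y) expanded over common
            # ancestors' Mendelian-sampling terms: a = sum_j Lx[j] Ly[j] D[j]
            F[i] = 0.5 * _relationship_via_paths(ped, s, d, F, D)
    return F


def _relationship_via_paths(ped, x, y, F, D):
    """Additive relationship a(x, y) via common-ancestor path coefficients."""
    Lx = _ancestor_coefficients(ped, x)
    Ly = _ancestor_coefficients(ped, y)
    if len(Ly) < len(Lx):
        Lx, Ly = Ly, Lx
    return sum(c * Ly.get(j, 0.0) * D[j] for j, c in Lx.items())


def _ancestor_coefficients(ped, x):
    """Coefficients L[j] of the unit lower-triangular factor row for x
    (contribution of ancestor j's Mendelian sampling term to x)."""
    L = {x: 1.0}
    stack = [x]
    visited = set()
    while stack:
        j = stack.pop()
        if j in visited:
            continue
        visited.add(j)
        for p in (ped.sire[j], ped.dam[j]):
            if p >= 0:
                stack.append(p)
    # propagate in reverse topological order (descending position index)
    for j in sorted(visited, reverse=True):
        c = L.get(j, 0.0)
        if c == 0.0:
            continue
        for p in (ped.sire[j], ped.dam[j]):
            if p >= 0:
                L[p] = L.get(p, 0.0) + 0.5 * c
    return L


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the tabular (recursive) method.

    a_ii = 1 + 0.5 * a_{sire,dam}; a_ij = 0.5 * (a_{j,sire(i)} + a_{j,dam(i)})
    for previously processed j.  Suitable up to a few thousand animals.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def mendelian_sampling_variances(ped: Pedigree, F=None) -> np.ndarray:
    """Within-family variance multipliers d_i (share of V_POLY contributed
    by Mendelian sampling): 1 for founders, 0.5 - 0.25(F_s + F_d) with both
    parents known, 0.75 - 0.25 F_p with one."""
    if F is None:
        F = inbreeding(ped)
    d = np.ones(ped.n)
    both = (ped.sire >= 0) & (ped.dam >= 0)
    one_s = (ped.sire >= 0) & ~both
    one_d = (ped.dam >= 0) & ~both
    d[both] = 0.5 - 0.25 * (F[ped.sire[both]] + F[ped.dam[both]])
    d[one_s] = 0.75 - 0.25 * F[ped.sire[one_s]]
    d[one_d] = 0.75 - 0.25 * F[ped.dam[one_d]]
    return d


def build_A_inverse(ped: Pedigree, F=None) -> sparse.csr_matrix:
    """Sparse inverse of A assembled by Henderson's rules with inbreeding.

    Uses A^{-1} = (I - P)' D^{-1} (I - P) where P maps each animal to half
    its known parents and D holds Mendelian-sampling variances.
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    d_inv = 1.0 / mendelian_sampling_variances(ped, F)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        di = d_inv[i]
        par = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, di)
        for p in par:
            add(i, p, -0.5 * di)
            add(p, i, -0.5 * di)
            for q in par:
                add(p, q, 0.25 * di)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n)
    )
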