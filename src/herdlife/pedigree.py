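"""Pedigree handling for the animal model.

Provides pruning to ancestors of phenotyped animals, inbreeding coefficients
(Meuwissen & Luo style recursion on the Cholesky of A), Henderson's rules
for the sparse inverse numerator relationship matrix A^-1 accounting for
inbreeding, and a small dense tabular-method oracle used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PedigreeTable",
    "prune_pedigree",
    "inbreeding_coefficients",
    "build_A_inverse",
    "relationship_matrix_bruteforce",
]

UNKNOWN = 0  # internal code for an unknown parent


@dataclass
class PedigreeTable:
    """Pedigree as parallel arrays in topological order.

    ``sire`` and ``dam`` hold 0-based positional indices into the same
    table, or -1 for an unknown parent.  ``ids`` are the external animal
    identifiers; ``birth_year`` is informational.  ``sex`` is 'M'/'F'
    where known (used by the simulator; longevity is sex-limited).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
        n = len(self.ids)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par >= np.arange(n)):
                raise ValueError(
                    f"pedigree not topologically ordered: a {name} index "
                    "does not precede its offspring"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in np.atleast_1d(ids)])
        except KeyError as exc:
            raise KeyError(f"animal id not in pedigree: {exc.args[0]}") from None

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeTable":
        """Build from a 4-column frame (animal, sire, dam, birth_year).

        Unknown parents are 0, empty, or NA.  Rows are topologically
        sorted; a cycle raises ``ValueError``.
        """
        df = df.copy()
        cols = list(df.columns[:4])
        animal, sire, dam, year = (df[c] for c in cols)
        sex = df["sex"] if "sex" in df.columns else None

        def norm(parent):
            out = []
            for v in parent:
                if pd.isna(v) or v == 0 or v == "0" or v == "":
                    out.append(None)
                else:
                    out.append(v)
            return out

        sire_l, dam_l = norm(sire), norm(dam)
        parents = {
            a: (s, d) for a, s, d in zip(animal, sire_l, dam_l)
        }
        order = _topological_order(parents)
        pos = {a: i for i, a in enumerate(order)}
        meta: dict = {a: (y, (sex.iloc[i] if sex is not None else "U"))
                      for i, (a, y) in enumerate(zip(animal, year))}
        for a in order:  # parents absent from the animal column: founders
            if a not in meta:
                meta[a] = (int(min(year)) if len(year) else 0, "U")
        sire_idx = np.array(
            [pos.get(parents[a][0], -1) if parents[a][0] is not None else -1
             for a in order], dtype=np.int64)
        dam_idx = np.array(
            [pos.get(parents[a][1], -1) if parents[a][1] is not None else -1
             for a in order], dtype=np.int64)
        years = np.array([meta[a][0] for a in order], dtype=np.int64)
        sexes = np.array([meta[a][1] for a in order]) if sex is not None else None
        return cls(np.asarray(order), sire_idx, dam_idx, years, sexes)

    @classmethod
    def read(cls, path) -> "PedigreeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        def ext(par):
            return np.where(par >= 0, self.ids[np.maximum(par, 0)], 0)

        df = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": ext(self.sire),
                "dam": ext(self.dam),
                "birth_year": self.birth_year,
            }
        )
        if self.sex is not None:
            df["sex"] = self.sex
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _topological_order(parents: dict) -> list:
    """Kahn-style DFS ordering; parents precede offspring.

    Parent ids that never appear as animals are inserted as founders.
    """
    order: list = []
    state: dict = {}  # 0 visiting, 1 done

    all_ids = list(parents)
    for a in all_ids:
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)

    def visit(a):
        stack = [(a, False)]
        while stack:
            node, expanded = stack.pop()
            if state.get(node) == 1:
                continue
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 0:
                raise ValueError(f"pedigree cycle detected at animal {node!r}")
            state[node] = 0
            stack.append((node, True))
            for p in parents[node]:
                if p is not None and state.get(p) != 1:
                    stack.append((p, False))

    for a in list(parents):
        if state.get(a) != 1:
            visit(a)
    return order


def prune_pedigree(
    ped: PedigreeTable, phenotyped_ids, max_generations: int = 10
) -> PedigreeTable:
    """Restrict the pedigree to phenotyped animals and their ancestors.

    Ancestors are kept up to ``max_generations`` back, counting the
    shortest generation distance from any phenotyped descendant.  The
    result is closed under parenthood: a kept animal's parent is either
    kept or set to unknown.
    """
    phen_idx = ped.index_of(phenotyped_ids)  # raises on missing ids
    n = len(ped)
    dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    dist[phen_idx] = 0
    # animals are topologically ordered, so one reverse sweep propagates
    # shortest distances from descendants to ancestors
    for i in range(n - 1, -1, -1):
        if dist[i] == np.iinfo(np.int64).max:
            continue
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                dist[p] = min(dist[p], dist[i] + 1)
    keep = dist <= max_generations
    new_pos = np.full(n, -1, dtype=np.int64)
    new_pos[keep] = np.arange(keep.sum())

    def remap(par):
        out = np.where((par >= 0) & keep[np.maximum(par, 0)],
                       new_pos[np.maximum(par, 0)], -1)
        return out[keep]

    return PedigreeTable(
        ped.ids[keep], remap(ped.sire), remap(ped.dam),
        ped.birth_year[keep],
        ped.sex[keep] if ped.sex is not None else None,
    )


def inbreeding_coefficients(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficient F per animal (Meuwissen & Luo recursion).

    Computes diag(A) - 1 through the L D L' decomposition of the numerator
    relationship matrix without forming A.  Founders have F = 0.
    """
    import heapq

    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.zeros(n)  # within-family (Mendelian sampling) variances
    for i in range(n):
        s, dm = sire[i], dam[i]
        Fs = F[s] if s >= 0 else -1.0  # convention: unknown parent F = -1
        Fd = F[dm] if dm >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (Fs + Fd)
        if s < 0 or dm < 0:
            F[i] = 0.0
            continue
        # L-row of animal i over its ancestors: A_ii = d_i + sum_j L_ij^2 d_j
        coeff: dict[int, float] = {}
        coeff[s] = coeff.get(s, 0.0) + 0.5
        coeff[dm] = coeff.get(dm, 0.0) + 0.5
        fi = d[i] - 1.0
        # process ancestors from youngest to oldest
        heap = [-a for a in coeff]
        heapq.heapify(heap)
        inheap = set(coeff)
        while heap:
            j = -heapq.heappop(heap)
            inheap.discard(j)
            r = coeff.pop(j)
            fi += r * r * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * r
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = fi
    return F


def build_A_inverse(
    ped: PedigreeTable, F: np.ndarray | None = None
) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Each animal contributes at most 9 nonzeros through its Mendelian
    sampling precision ``alpha = 1 / d_i`` with
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` (unknown parents enter with F = -1,
    i.e. d grows toward 1 as parents become unknown).
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    n = len(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[dm] if dm >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (Fs + Fd))
        entries = [(i, 1.0)]
        if s >= 0:
            entries.append((s, -0.5))
        if dm >= 0:
            entries.append((dm, -0.5))
        for a, ca in entries:
            for b, cb in entries:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ca * cb)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv


def relationship_matrix_bruteforce(
    ped: PedigreeTable, max_animals: int = 2000
) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Test oracle only; guarded against large pedigrees.
    """
    n = len(ped)
    if n > max_animals:
        raise ValueError(f"pedigree too large for dense oracle: {n} animals")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A
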