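"""Pedigree handling and additive-relationship algebra.

Reads animal/sire/dam pedigrees, topologically orders them, computes
inbreeding coefficients (Meuwissen & Luo's indirect method), the numerator
relationship matrix ``A`` by the tabular method, and its sparse inverse by
Henderson's rules with inbreeding-adjusted Mendelian-sampling variances.
"""

from __future__ import annotations

import csv
import heapq
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1  # dense-index sentinel for a missing parent

__all__ = [
    "Pedigree",
    "PedigreeError",
    "PedigreeSummary",
    "read_pedigree",
    "pedigree_from_records",
    "prune_pedigree",
    "inbreeding_coefficients",
    "relationship_matrix",
    "relationship_inverse",
    "summarize_pedigree",
]


class PedigreeError(ValueError):
    """Structural or validation failure in a pedigree."""


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree with dense integer indexing.

    ``sire`` / ``dam`` hold the dense index of each animal's parents
    (:data:`UNKNOWN` for a missing parent); parents always precede
    offspring.  ``inbreeding`` holds Wright's F per animal.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    inbreeding: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.inbreeding is None:
            object.__setattr__(self, "inbreeding", inbreeding_coefficients(self))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def index_map(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as a tidy frame with string ids ('0' = unknown)."""
        lookup = np.asarray(["0", *self.ids], dtype=object)
        return pd.DataFrame(
            {
                "animal": list(self.ids),
                "sire": lookup[self.sire + 1],
                "dam": lookup[self.dam + 1],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PedigreeSummary:
    n_total: int
    n_inbred: int
    n_sires: int
    n_dams: int
    n_both_known: int
    n_both_unknown: int
    n_one_unknown: int
    mean_f_inbred: float
    max_f: float
    min_f_positive: float

    def to_text(self) -> str:
        rows = [
            ("Individuals in total", self.n_total),
            ("Inbreds in total", self.n_inbred),
            ("Sires in total", self.n_sires),
            ("Dams in total", self.n_dams),
            ("Individuals with both parents known", self.n_both_known),
            ("Individuals with both parents unknown", self.n_both_unknown),
            ("Individuals with one parent unknown", self.n_one_unknown),
            ("Average inbreeding in the inbreds (percent)", f"{100 * self.mean_f_inbred:.2f}"),
            ("Maximum inbreeding (percent)", f"{100 * self.max_f:.2f}"),
            ("Minimum positive inbreeding (percent)", f"{100 * self.min_f_positive:.2f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# construction


def pedigree_from_records(
    records: list[tuple[str, str | None, str | None]]
) -> Pedigree:
    """Build an ordered :class:`Pedigree` from (animal, sire, dam) triples.

    Parents that never appear as animals are inserted as founders.  Raises
    :class:`PedigreeError` on duplicate animals, self-parenting, or cycles.
    """
    parents: dict[str, tuple[str | None, str | None]] = {}
    for animal, s, d in records:
        if animal in parents:
            raise PedigreeError(f"duplicate animal id {animal!r}")
        if animal == s or animal == d:
            raise PedigreeError(f"animal {animal!r} is its own parent")
        parents[animal] = (s, d)
    # implied founders
    for s, d in list(parents.values()):
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)

    # Kahn topological sort, deterministic in first-appearance order
    order: list[str] = []
    state: dict[str, int] = {}  # 0 unvisited, 1 on stack, 2 done

    def visit(a: str) -> None:
        stack = [(a, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state.get(node) == 2:
                continue
            if state.get(node) == 1:
                raise PedigreeError(f"pedigree cycle through animal {node!r}")
            state[node] = 1
            stack.append((node, True))
            s, d = parents[node]
            for p in (d, s):
                if p is not None and state.get(p) != 2:
                    if state.get(p) == 1:
                        raise PedigreeError(f"pedigree cycle through animal {p!r}")
                    stack.append((p, False))

    for a in parents:
        if state.get(a) != 2:
            visit(a)

    idx = {a: i for i, a in enumerate(order)}
    sire = np.full(len(order), UNKNOWN, dtype=np.int64)
    dam = np.full(len(order), UNKNOWN, dtype=np.int64)
    for a, (s, d) in parents.items():
        i = idx[a]
        if s is not None:
            sire[i] = idx[s]
        if d is not None:
            dam[i] = idx[d]
    return Pedigree(ids=tuple(order), sire=sire, dam=dam)


def read_pedigree(path, unknown_code: str = "0", delimiter: str | None = None) -> Pedigree:
    """Read a header-bearing delimited pedigree file (animal, sire, dam).

    The delimiter is sniffed from the header line unless given.  Parents
    equal to ``unknown_code`` (or empty) are treated as unknown.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    if not text.strip():
        raise PedigreeError("empty pedigree file")
    if delimiter is None:
        header = text.splitlines()[0]
        delimiter = csv.Sniffer().sniff(header, delimiters=",;\t ").delimiter
    frame = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str)
    if frame.shape[1] < 3:
        raise PedigreeError("pedigree file needs >= 3 columns (animal, sire, dam)")
    recs = []
    for animal, s, d in frame.iloc[:, :3].itertuples(index=False):
        clean = lambda v: None if (pd.isna(v) or str(v).strip() in (unknown_code, "")) else str(v).strip()
        recs.append((str(animal).strip(), clean(s), clean(d)))
    return pedigree_from_records(recs)


# ---------------------------------------------------------------------------
# inbreeding and relationship algebra


def prune_pedigree(ped: Pedigree, keep_ids) -> Pedigree:
    """Restrict a pedigree to the given animals and all their ancestors.

    Animals outside the ancestor closure of ``keep_ids`` are leaves with
    respect to the kept set, so dropping them leaves the joint distribution
    of the kept animals' breeding values (and hence any analysis of their
    records) unchanged.  Order and inbreeding are preserved.
    """
    index_map = ped.index_map
    keep = np.zeros(ped.n, dtype=bool)
    stack = []
    for aid in keep_ids:
        i = index_map.get(str(aid))
        if i is None:
            raise PedigreeError(f"animal {aid!r} not in the pedigree")
        stack.append(i)
    while stack:
        i = stack.pop()
        if keep[i]:
            continue
        keep[i] = True
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN and not keep[p]:
                stack.append(p)
    old_idx = np.flatnonzero(keep)
    new_of_old = np.full(ped.n, UNKNOWN, dtype=np.int64)
    new_of_old[old_idx] = np.arange(old_idx.size)
    remap = lambda v: np.where(v == UNKNOWN, UNKNOWN, new_of_old[v])
    return Pedigree(
        ids=tuple(ped.ids[i] for i in old_idx),
        sire=remap(ped.sire[old_idx]),
        dam=remap(ped.dam[old_idx]),
        inbreeding=ped.inbreeding[old_idx].copy(),
    )


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo indirect method.

    Traverses each animal's ancestor tree through the Cholesky factor
    ``A = L D L'``: F_i = sum_j L_ij^2 d_j - 1.  Unknown parents contribute
    as unrelated non-inbred founders (F = 0 when either parent is unknown).
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    f = np.zeros(n)
    dvec = np.empty(n)  # Mendelian-sampling (within-family) variances
    for i in range(n):
        si, di = s[i], d[i]
        if si == UNKNOWN and di == UNKNOWN:
            dvec[i] = 1.0
            continue
        fs = f[si] if si != UNKNOWN else 0.0
        fd = f[di] if di != UNKNOWN else 0.0
        if si == UNKNOWN or di == UNKNOWN:
            dvec[i] = 0.75 - 0.25 * (fs + fd)
            continue
        dvec[i] = 0.5 - 0.25 * (fs + fd)
        # accumulate L-row contributions over the ancestor closure of i
        # (descending-index worklist); the row sum gives A_ii - d_i, hence
        # F_i = sum + d_i - 1
        coef: dict[int, float] = {si: 0.5, di: 0.5}
        heap = [-si, -di] if si != di else [-si]
        heapq.heapify(heap)
        total = 0.0
        while heap:
            j = -heapq.heappop(heap)
            while heap and heap[0] == -j:  # drop duplicate worklist entries
                heapq.heappop(heap)
            c = coef.pop(j)
            total += c * c * dvec[j]
            for p in (s[j], d[j]):
                if p != UNKNOWN:
                    if p not in coef:
                        heapq.heappush(heap, -p)
                        coef[p] = 0.5 * c
                    else:
                        coef[p] += 0.5 * c
        f[i] = total + dvec[i] - 1.0
    return f


def relationship_matrix(ped: Pedigree, max_n: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    A_ij = 0.5 (A_i,sire(j) + A_i,dam(j)) for i < j; A_ii = 1 + F_i.
    Guarded by ``max_n`` to avoid accidental huge dense allocations.
    """
    n = ped.n
    if n > max_n:
        raise PedigreeError(
            f"pedigree of {n} animals exceeds the dense cap ({max_n}); "
            "use relationship_inverse for large pedigrees"
        )
    s, d = ped.sire, ped.dam
    a = np.zeros((n, n))
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj != UNKNOWN:
            row += 0.5 * a[:j, sj]
        if dj != UNKNOWN:
            row += 0.5 * a[:j, dj]
        a[:j, j] = row
        a[j, :j] = row
        diag = 1.0
        if sj != UNKNOWN and dj != UNKNOWN:
            diag += 0.5 * a[sj, dj]
        a[j, j] = diag
    return a


def relationship_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Each animal contributes 1/d_i to the (i, i) cell, -0.5/d_i to
    (i, parent) and 0.25/d_i to (parent, parent') cells, where the
    Mendelian-sampling variance d_i is 0.5 - 0.25 (F_s + F_d) with both
    parents known, 0.75 - 0.25 F_p with one, and 1 with none.
    """
    n = ped.n
    s, d, f = ped.sire, ped.dam, ped.inbreeding
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        si, di = s[i], d[i]
        fs = f[si] if si != UNKNOWN else 0.0
        fd = f[di] if di != UNKNOWN else 0.0
        if si != UNKNOWN and di != UNKNOWN:
            dm = 0.5 - 0.25 * (fs + fd)
        elif si != UNKNOWN or di != UNKNOWN:
            dm = 0.75 - 0.25 * (fs + fd)
        else:
            dm = 1.0
        w = 1.0 / dm
        rows.append(i); cols.append(i); vals.append(w)
        for p in (si, di):
            if p != UNKNOWN:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * w, -0.5 * w]
        for p in (si, di):
            if p != UNKNOWN:
                for q in (si, di):
                    if q != UNKNOWN:
                        rows.append(p); cols.append(q); vals.append(0.25 * w)
    ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return ainv.tocsr()


def summarize_pedigree(ped: Pedigree) -> PedigreeSummary:
    """Structure counts and inbreeding summary of a pedigree."""
    s, d, f = ped.sire, ped.dam, ped.inbreeding
    both_known = (s != UNKNOWN) & (d != UNKNOWN)
    both_unknown = (s == UNKNOWN) & (d == UNKNOWN)
    inbred = f > 0
    pos = f[inbred]
    return PedigreeSummary(
        n_total=ped.n,
        n_inbred=int(inbred.sum()),
        n_sires=int(np.unique(s[s != UNKNOWN]).size),
        n_dams=int(np.unique(d[d != UNKNOWN]).size),
        n_both_known=int(both_known.sum()),
        n_both_unknown=int(both_unknown.sum()),
        n_one_unknown=int(ped.n - both_known.sum() - both_unknown.sum()),
        mean_f_inbred=float(pos.mean()) if pos.size else 0.0,
        max_f=float(f.max()) if ped.n else 0.0,
        min_f_positive=float(pos.min()) if pos.size else 0.0,
    )
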