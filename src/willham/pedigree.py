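"""Pedigree handling and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` underlies every animal
model fitted by this package.  Its inverse is never formed by inversion:
Henderson's rules build ``A``:sup:`-1` directly from the pedigree with at
most nine contributions per animal, and the Meuwissen & Luo recursion
supplies the inbreeding coefficients needed for exactness under selection
and repeated use of parents.

Internally animals are coded ``0..N-1`` in topological order (parents
before offspring); every public surface re-maps to the caller's original
identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

UNKNOWN = -1

__all__ = [
    "Pedigree",
    "PedigreeError",
    "load_and_sort",
    "inbreeding",
    "a_inverse",
    "relationship_submatrix",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent, bad sex)."""


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Attributes
    ----------
    ids
        Original identifiers, position = internal code.
    sire, dam
        Internal parent codes, ``-1`` for unknown.  Every known parent has
        a smaller code than its offspring.
    sex
        ``'F'``/``'M'`` per animal, ``''`` when not provided.
    sr
        Selection round of birth (0 for founders of unknown origin).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    sr: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _F: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def code(self, external_ids) -> np.ndarray:
        """Map external identifiers to internal codes."""
        try:
            return np.array([self._index[a] for a in external_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"unknown animal {exc.args[0]!r}") from None

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F (cached)."""
        if self._F is None:
            self._F = _inbreeding_ml(self.sire, self.dam)
        return self._F

    def mendelian_variance(self, use_inbreeding: bool = True) -> np.ndarray:
        """Within-family (Mendelian sampling) variance coefficients d.

        ``A = T D T'`` with ``D = diag(d)``; ``d`` is 1 for founders, 0.75
        with one known parent and 0.5 with two known non-inbred parents,
        reduced by parental inbreeding when ``use_inbreeding``.
        """
        F = self.inbreeding if use_inbreeding else np.zeros(self.n)
        Fs = np.where(self.sire >= 0, F[np.maximum(self.sire, 0)], -1.0)
        Fd = np.where(self.dam >= 0, F[np.maximum(self.dam, 0)], -1.0)
        d = np.ones(self.n)
        both = (self.sire >= 0) & (self.dam >= 0)
        only_s = (self.sire >= 0) & ~both
        only_d = (self.dam >= 0) & ~both
        d[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
        d[only_s] = 0.75 - 0.25 * Fs[only_s]
        d[only_d] = 0.75 - 0.25 * Fd[only_d]
        return d

    def log_det_a(self, use_inbreeding: bool = True) -> float:
        """log|A| = sum of log Mendelian variance coefficients."""
        return float(np.sum(np.log(self.mendelian_variance(use_inbreeding))))

    def to_frame(self) -> pd.DataFrame:
        sentinel = np.concatenate([self.ids, [0]])
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sentinel[self.sire],
                "dam": sentinel[self.dam],
                "sex": self.sex,
                "sr": self.sr,
            }
        )


def load_and_sort(records, *, auto_insert_parents: bool = True) -> Pedigree:
    """Build a :class:`Pedigree` from raw records, topologically sorted.

    Parameters
    ----------
    records
        Iterable of ``(animal, sire, dam)`` or ``(animal, sire, dam, sex, sr)``
        tuples, or a DataFrame with those columns.  ``0``, ``None``, ``''``
        and ``-1`` denote an unknown parent.
    auto_insert_parents
        Insert parents that never appear as animals as founders (default);
        otherwise raise :class:`PedigreeError`.

    Raises
    ------
    PedigreeError
        On duplicate animals, cycles, sex conflicts, or (when
        ``auto_insert_parents=False``) undefined parents.
    """
    if isinstance(records, pd.DataFrame):
        rows = []
        for r in records.itertuples(index=False):
            rows.append(tuple(r))
        records = rows
    parsed = []
    for r in records:
        r = tuple(r)
        animal, sire, dam = r[0], r[1], r[2]
        sex = r[3] if len(r) > 3 else ""
        sr = int(r[4]) if len(r) > 4 else 0
        parsed.append((animal, _norm(sire), _norm(dam), _norm_sex(sex), sr))

    seen = set()
    for a, *_ in parsed:
        if a in seen:
            raise PedigreeError(f"duplicate animal {a!r}")
        seen.add(a)

    # auto-insert unknown parents as founders ahead of everything else
    extra = []
    for _, s, d, _, _ in parsed:
        for p, psex in ((s, "M"), (d, "F")):
            if p is not None and p not in seen:
                if not auto_insert_parents:
                    raise PedigreeError(f"parent {p!r} never defined as an animal")
                seen.add(p)
                extra.append((p, None, None, psex, 0))
    parsed = extra + parsed

    # Kahn topological sort, stable in input order
    pos = {a: i for i, (a, *_) in enumerate(parsed)}
    children: dict = {a: [] for a in pos}
    indeg = {a: 0 for a in pos}
    for a, s, d, _, _ in parsed:
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    import heapq

    heap = [pos[a] for a in pos if indeg[a] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        a = parsed[i][0]
        order.append(i)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, pos[c])
    if len(order) != len(parsed):
        cyclic = [a for a in indeg if indeg[a] > 0]
        raise PedigreeError(f"pedigree cycle involving animal {cyclic[0]!r}")

    parsed = [parsed[i] for i in order]
    index = {a: i for i, (a, *_) in enumerate(parsed)}
    n = len(parsed)
    ids = np.array([a for a, *_ in parsed], dtype=object)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sex = np.array([x[3] for x in parsed], dtype=object)
    sr = np.array([x[4] for x in parsed], dtype=np.int64)
    for i, (a, s, d, _, _) in enumerate(parsed):
        if s is not None:
            sire[i] = index[s]
            if sex[sire[i]] == "F":
                raise PedigreeError(f"sire {s!r} is recorded as female")
        if d is not None:
            dam[i] = index[d]
            if sex[dam[i]] == "M":
                raise PedigreeError(f"dam {d!r} is recorded as male")
    return Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, sr=sr, _index=index)


def _norm(parent):
    if parent is None:
        return None
    if isinstance(parent, float) and np.isnan(parent):
        return None
    if parent in (0, -1, "0", "", "."):
        return None
    return parent


def _norm_sex(sex):
    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        return ""
    s = str(sex).strip().upper()
    if s in ("F", "FEMALE", "2"):
        return "F"
    if s in ("M", "MALE", "1"):
        return "M"
    if s == "":
        return ""
    raise PedigreeError(f"unrecognised sex code {sex!r}")


@njit(cache=True)
def _inbreeding_ml(sire, dam):  # pragma: no cover - numba kernel
    # Meuwissen & Luo (1992) recursion: F_i = A_ii - 1 accumulated from
    # squared gene-flow coefficients times Mendelian variances.
    n = sire.shape[0]
    F = np.zeros(n)
    v = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            F[i] = 0.0
            continue
        # Mendelian variance of ancestors uses F of their parents, all < i
        aii = 0.0
        v[i] = 1.0
        for j in range(i, -1, -1):
            if v[j] == 0.0:
                continue
            js, jd = sire[j], dam[j]
            if js >= 0:
                v[js] += 0.5 * v[j]
            if jd >= 0:
                v[jd] += 0.5 * v[j]
            if js >= 0 and jd >= 0:
                dj = 0.5 - 0.25 * (F[js] + F[jd])
            elif js >= 0:
                dj = 0.75 - 0.25 * F[js]
            elif jd >= 0:
                dj = 0.75 - 0.25 * F[jd]
            else:
                dj = 1.0
            aii += v[j] * v[j] * dj
            v[j] = 0.0
        F[i] = aii - 1.0
    return F


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F for all animals (Meuwissen & Luo)."""
    return ped.inbreeding


def a_inverse(ped: Pedigree, use_inbreeding: bool = True) -> sp.csc_matrix:
    """Sparse inverse of the numerator relationship matrix, Henderson's rules.

    With ``use_inbreeding`` (default) the Mendelian variances are adjusted
    by parental F so that the product with the tabular ``A`` is exactly the
    identity even in inbred pedigrees.
    """
    n = ped.n
    alpha = 1.0 / ped.mendelian_variance(use_inbreeding)
    rows, cols, vals = [], [], []

    idx = np.arange(n)
    rows.append(idx)
    cols.append(idx)
    vals.append(alpha)
    for p in (ped.sire, ped.dam):
        known = p >= 0
        i, pi = idx[known], p[known]
        rows.append(i)
        cols.append(pi)
        vals.append(-0.5 * alpha[known])
        rows.append(pi)
        cols.append(i)
        vals.append(-0.5 * alpha[known])
        rows.append(pi)
        cols.append(pi)
        vals.append(0.25 * alpha[known])
    both = (ped.sire >= 0) & (ped.dam >= 0)
    s, d = ped.sire[both], ped.dam[both]
    rows.append(s)
    cols.append(d)
    vals.append(0.25 * alpha[both])
    rows.append(d)
    cols.append(s)
    vals.append(0.25 * alpha[both])

    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    Ainv.sum_duplicates()
    return Ainv


def relationship_submatrix(ped: Pedigree, animal_subset) -> np.ndarray:
    """Dense additive-relationship block for a subset of animals.

    Computed by the recursive tabular method over the full pedigree
    (diagonal ``1 + F``) and sliced; intended for modest pedigrees and as a
    reference for tests.
    """
    codes = ped.code(animal_subset)
    A = _tabular_a(ped.sire, ped.dam)
    return A[np.ix_(codes, codes)]


@njit(cache=True)
def _tabular_a(sire, dam):  # pragma: no cover - numba kernel
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
    return A
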