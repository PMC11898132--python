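"""Pedigree handling for animal models.

Reads delimited pedigree files, validates and topologically sorts them,
computes inbreeding coefficients (Meuwissen & Luo algorithm), builds the
sparse inverse numerator relationship matrix A^-1 (Henderson's rules with
inbreeding), and reports pedigree-depth statistics (complete and equivalent
generations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Pedigree", "PedigreeError", "read_pedigree"]

#: tokens accepted as "unknown parent" in input files
MISSING_TOKENS = {"", "0", "na", "nan", "none", ".", "unknown"}

UNKNOWN = -1  # internal index sentinel for an unknown parent


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, duplicates)."""


def _is_missing(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip().lower() in MISSING_TOKENS


@dataclass
class Pedigree:
    """A validated, parent-before-offspring ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Animal identifiers in topological order (parents precede offspring).
    sire, dam : ndarray of int
        Index of each animal's sire/dam within ``ids``; -1 if unknown.
    sex : ndarray of str
        'M', 'F' or 'U' per animal.
    birth_year : ndarray of float
        Birth year per animal; NaN if unknown.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _inbreeding: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id) -> int:
        return self._index[str(animal_id)]

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        """Build a Pedigree from columns animal, sire, dam[, sex, birth_year].

        Input row order is not trusted: the pedigree is topologically sorted
        (parents before offspring), with ties broken by input order. Parents
        referenced but never defined as animals are auto-added as founders
        (with a warning). Duplicate animal rows and ancestry cycles are
        rejected.
        """
        cols = {c.lower().strip(): c for c in df.columns}
        for needed in ("animal", "sire", "dam"):
            if needed not in cols:
                raise PedigreeError(
                    f"pedigree file must have an '{needed}' column; "
                    f"found {list(df.columns)}"
                )
        animals = [str(a).strip() for a in df[cols["animal"]]]
        if len(set(animals)) != len(animals):
            seen, dups = set(), []
            for a in animals:
                if a in seen:
                    dups.append(a)
                seen.add(a)
            raise PedigreeError(f"duplicated animal rows: {sorted(set(dups))}")

        sires = [None if _is_missing(s) else str(s).strip() for s in df[cols["sire"]]]
        dams = [None if _is_missing(d) else str(d).strip() for d in df[cols["dam"]]]

        if "sex" in cols:
            sex_in = {
                a: str(s).strip().upper()[:1] if not _is_missing(s) else "U"
                for a, s in zip(animals, df[cols["sex"]])
            }
        else:
            sex_in = {}
        if "birth_year" in cols:
            by_in = {
                a: (np.nan if _is_missing(y) else float(y))
                for a, y in zip(animals, df[cols["birth_year"]])
            }
        else:
            by_in = {}

        parent_of = dict(zip(animals, zip(sires, dams)))

        # auto-add undefined parents as founders
        defined = set(animals)
        extra = []
        for s, d in zip(sires, dams):
            for parent in (s, d):
                if parent is not None and parent not in defined:
                    defined.add(parent)
                    extra.append(parent)
        if extra:
            warnings.warn(
                f"{len(extra)} parent(s) referenced but never defined; "
                "added as founders",
                stacklevel=2,
            )
        all_ids = extra + animals  # undefined parents first, then input order
        for e in extra:
            parent_of[e] = (None, None)

        order = _topological_sort(all_ids, parent_of)

        idx = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire_ix = np.full(n, UNKNOWN, dtype=np.int64)
        dam_ix = np.full(n, UNKNOWN, dtype=np.int64)
        sex = np.full(n, "U", dtype="U1")
        birth_year = np.full(n, np.nan)
        for a in order:
            i = idx[a]
            s, d = parent_of[a]
            if s is not None:
                sire_ix[i] = idx[s]
            if d is not None:
                dam_ix[i] = idx[d]
            sex[i] = sex_in.get(a, "U")
            birth_year[i] = by_in.get(a, np.nan)
        # infer sex from usage where not given
        for i in range(n):
            if sex[i] == "U":
                if i in sire_ix:
                    sex[i] = "M"
                elif i in dam_ix:
                    sex[i] = "F"
        return cls(order, sire_ix, dam_ix, sex, birth_year, _index=idx)

    @classmethod
    def from_file(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        return cls.from_dataframe(df)

    # ------------------------------------------------------------------ #
    # genetics
    # ------------------------------------------------------------------ #

    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F by Meuwissen & Luo.

        Unknown parents are treated as unrelated founders. Works row by row
        on L (the Cholesky factor of A = L D L'): for animal i,
        a_ii = 1 + F_i = d_i + sum_{j<i} L_ij^2 d_j, with the L row obtained
        by tracing ancestors backwards (L_ij = (L_sj + L_dj)/2).
        """
        if self._inbreeding is not None:
            return self._inbreeding
        n = len(self)
        sire, dam = self.sire, self.dam
        F = np.zeros(n)
        d = np.zeros(n)  # Mendelian-sampling variance contributions
        for i in range(n):
            d[i] = _mendelian_variance(sire[i], dam[i], F)
            if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
                F[i] = 0.0
                continue
            # accumulate L_ij coefficients over ancestors, descending index
            coef = {sire[i]: 0.5, dam[i]: 0.5}
            aii = d[i]
            while coef:
                j = max(coef)
                lij = coef.pop(j)
                aii += lij * lij * d[j]
                half = 0.5 * lij
                for parent in (sire[j], dam[j]):
                    if parent != UNKNOWN:
                        coef[parent] = coef.get(parent, 0.0) + half
            F[i] = aii - 1.0
        self._inbreeding = F
        return F

    def a_inverse(self, use_inbreeding: bool = True) -> sp.csr_matrix:
        """Sparse inverse numerator relationship matrix by Henderson's rules.

        For animal i with parents s, d the Mendelian-sampling variance is
        d_i = 0.5 - 0.25 (F_s + F_d), dropping the term for an unknown
        parent (0.75 - 0.25 F_known for one known parent, 1 for none); the
        rule contributions are 1/d_i at (i,i), -0.5/d_i at (i, parent) and
        0.25/d_i at each (parent, parent') pair.

        Parameters
        ----------
        use_inbreeding : bool
            If False, all F are taken as 0 (the classical no-inbreeding
            rules). Exact inbreeding is the default.
        """
        n = len(self)
        F = self.inbreeding() if use_inbreeding else np.zeros(n)
        rows, cols, vals = [], [], []
        for i in range(n):
            di = _mendelian_variance(self.sire[i], self.dam[i], F)
            if di <= 0:
                raise PedigreeError(
                    f"non-positive Mendelian-sampling variance for "
                    f"{self.ids[i]} (corrupt inbreeding?)"
                )
            w = 1.0 / di
            parents = [p for p in (self.sire[i], self.dam[i]) if p != UNKNOWN]
            rows.append(i), cols.append(i), vals.append(w)
            for p in parents:
                rows += [i, p]
                cols += [p, i]
                vals += [-0.5 * w, -0.5 * w]
            for p in parents:
                for q in parents:
                    rows.append(p), cols.append(q), vals.append(0.25 * w)
        A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        A_inv.sum_duplicates()
        return A_inv

    def depth(self) -> pd.DataFrame:
        """Pedigree-depth statistics per animal.

        ``complete_generations``: largest g such that every one of the 2^g
        ancestors at generation g is known. ``equivalent_generations``: sum
        over all known ancestors of (1/2)^(ancestor generation).
        """
        n = len(self)
        complete = np.zeros(n, dtype=np.int64)
        equivalent = np.zeros(n)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                continue
            cs = complete[s] + 1 if s != UNKNOWN else 0
            cd = complete[d] + 1 if d != UNKNOWN else 0
            complete[i] = min(cs, cd)
            es = 0.5 * (1.0 + equivalent[s]) if s != UNKNOWN else 0.0
            ed = 0.5 * (1.0 + equivalent[d]) if d != UNKNOWN else 0.0
            equivalent[i] = es + ed
        return pd.DataFrame(
            {
                "animal": self.ids,
                "complete_generations": complete,
                "equivalent_generations": equivalent,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        def name(ix):
            return [self.ids[j] if j != UNKNOWN else "0" for j in ix]

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "sex": self.sex,
                "birth_year": self.birth_year,
            }
        )

    def to_file(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _mendelian_variance(s: int, d: int, F: np.ndarray) -> float:
    if s != UNKNOWN and d != UNKNOWN:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s != UNKNOWN:
        return 0.75 - 0.25 * F[s]
    if d != UNKNOWN:
        return 0.75 - 0.25 * F[d]
    return 1.0


def _topological_sort(ids: list, parent_of: dict) -> list:
    """Kahn's algorithm, parents first; ties broken by input order.

    Raises PedigreeError with an offending chain if a cycle exists (an
    animal that is its own ancestor).
    """
    pos = {a: i for i, a in enumerate(ids)}
    children = {a: [] for a in ids}
    n_parents = {a: 0 for a in ids}
    for a in ids:
        for p in parent_of[a]:
            if p is not None:
                children[p].append(a)
                n_parents[a] += 1
    import heapq

    ready = [pos[a] for a in ids if n_parents[a] == 0]
    heapq.heapify(ready)
    order = []
    while ready:
        a = ids[heapq.heappop(ready)]
        order.append(a)
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(ready, pos[c])
    if len(order) != len(ids):
        # extract one cycle for the error message
        stuck = [a for a in ids if n_parents[a] > 0]
        chain = _find_cycle(stuck, parent_of)
        raise PedigreeError(
            "pedigree contains an ancestry cycle: " + " -> ".join(chain)
        )
    return order


def _find_cycle(stuck: list, parent_of: dict) -> list:
    node = stuck[0]
    seen = {}
    path = []
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        s, d = parent_of[node]
        node = s if (s in parent_of and s in stuck) else d
        if node is None:
            return path
    return path[seen[node]:] + [node]


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (see :meth:`Pedigree.from_dataframe`)."""
    return Pedigree.from_file(path)
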