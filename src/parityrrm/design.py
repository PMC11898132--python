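"""Records handling and design-matrix assembly.

A lambing record carries the ewe, a year-of-lambing level, a
month-of-lambing level (September-November), the parity 1..6 (later
parities collapsed to 6) and the litter size. Litter size is analysed as
an ordered categorical trait on the liability scale: three categories
(1, 2, >2) for the prolific line, two (1, >1) for the conventional line.
Residual variances are heterogeneous across parity classes:

    prolific:      {1} | {2,3,4} | {5,6}
    conventional:  {1} | {2,6}   | {3,4,5}

The model in matrix form is y = Xb + Za + Wp + e with X holding year and
month incidence columns plus the fixed-regression Legendre covariates, Z
the genetic random-regression covariates (a block of order+1 columns per
pedigree animal) and W the permanent-environment covariates (a block per
recorded ewe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .basis import LegendreBasis
from .pedigree import Pedigree

__all__ = [
    "encode_category",
    "assign_residual_class",
    "read_records",
    "RecordSet",
    "DesignMatrices",
    "build_design",
]

LINES = ("prolific", "conventional")

#: number of liability categories per line
N_CATEGORIES = {"prolific": 3, "conventional": 2}

#: residual-variance class per parity (1-based classes), per line
RESIDUAL_CLASSES = {
    "prolific": {1: 1, 2: 2, 3: 2, 4: 2, 5: 3, 6: 3},
    "conventional": {1: 1, 2: 2, 3: 3, 4: 3, 5: 3, 6: 2},
}

_MONTHS = {
    "9": 0, "sep": 0, "september": 0,
    "10": 1, "oct": 1, "october": 1,
    "11": 2, "nov": 2, "november": 2,
}


def _check_line(line: str) -> str:
    line = str(line).lower()
    if line not in LINES:
        raise ValueError(f"line must be one of {LINES}, got {line!r}")
    return line


def encode_category(litter_size: int, line: str) -> int:
    """Map a litter-size count to its ordered category.

    prolific: 1 -> 1, 2 -> 2, >=3 -> 3; conventional: 1 -> 1, >=2 -> 2.
    """
    line = _check_line(line)
    ls = int(litter_size)
    if ls < 1:
        raise ValueError(f"litter size must be a positive count, got {ls}")
    if line == "prolific":
        return min(ls, 3)
    return min(ls, 2)


def assign_residual_class(parity: int, line: str) -> int:
    """Residual-variance class (1..3) of a parity for the given line."""
    line = _check_line(line)
    p = int(parity)
    if not 1 <= p <= 6:
        raise ValueError(f"parity must be in 1..6, got {p}")
    return RESIDUAL_CLASSES[line][p]


@dataclass
class RecordSet:
    """Validated lambing records ready for design construction.

    All per-record fields are aligned numpy arrays; ``ewe_ids`` are the
    distinct ewes in order of first appearance.
    """

    line: str
    ewe: np.ndarray          # index into ewe_ids
    ewe_ids: list
    year: np.ndarray         # 0-based year level
    year_levels: list
    month: np.ndarray        # 0..2 (Sep, Oct, Nov)
    parity: np.ndarray       # 1..6
    litter_size: np.ndarray
    category: np.ndarray     # 1..n_categories
    residual_class: np.ndarray  # 1..3

    def __len__(self):
        return len(self.parity)

    @property
    def n_categories(self) -> int:
        return N_CATEGORIES[self.line]

    @property
    def n_ewes(self) -> int:
        return len(self.ewe_ids)

    @property
    def n_years(self) -> int:
        return len(self.year_levels)


def read_records(path_or_df, line: str) -> RecordSet:
    """Read a delimited records file (ewe,year,month,parity,litter_size).

    Month may be numeric (9/10/11) or named (Sep/Oct/Nov). Parities above 6
    are collapsed to 6; litter sizes below 1 are rejected. The returned
    categories follow the line's coding.
    """
    line = _check_line(line)
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    for needed in ("ewe", "year", "month", "parity", "litter_size"):
        if needed not in cols:
            raise ValueError(
                f"records file must have a '{needed}' column; "
                f"found {list(df.columns)}"
            )

    ewes_raw = [str(e).strip() for e in df[cols["ewe"]]]
    ewe_ids, ewe_ix = [], {}
    ewe = np.empty(len(df), dtype=np.int64)
    for r, e in enumerate(ewes_raw):
        if e not in ewe_ix:
            ewe_ix[e] = len(ewe_ids)
            ewe_ids.append(e)
        ewe[r] = ewe_ix[e]

    years_raw = [str(y).strip() for y in df[cols["year"]]]
    year_levels = sorted(set(years_raw), key=lambda y: (len(y), y))
    year_map = {y: i for i, y in enumerate(year_levels)}
    year = np.array([year_map[y] for y in years_raw], dtype=np.int64)

    month = np.empty(len(df), dtype=np.int64)
    for r, m in enumerate(df[cols["month"]]):
        key = str(m).strip().lower()[:3] if not str(m).isdigit() else str(m)
        if key not in _MONTHS:
            raise ValueError(f"unrecognised lambing month {m!r} (row {r})")
        month[r] = _MONTHS[key]

    parity = pd.to_numeric(df[cols["parity"]]).to_numpy(dtype=np.int64)
    if np.any(parity < 1):
        raise ValueError("parity must be >= 1")
    parity = np.minimum(parity, 6)

    litter = pd.to_numeric(df[cols["litter_size"]]).to_numpy()
    if np.any(litter != np.round(litter)) or np.any(litter < 1):
        raise ValueError("litter_size must be integer counts >= 1")
    litter = litter.astype(np.int64)

    category = np.array(
        [encode_category(ls, line) for ls in litter], dtype=np.int64
    )
    rclass = np.array(
        [assign_residual_class(p, line) for p in parity], dtype=np.int64
    )
    return RecordSet(
        line, ewe, ewe_ids, year, year_levels, month, parity, litter,
        category, rclass,
    )


@dataclass
class DesignMatrices:
    """Assembled model matrices and the index arrays the sampler uses.

    X : records x (n_years + n_months - 1 + n_coef) fixed-effect matrix
        (all year levels, month reference level dropped, fixed-regression
        covariates).
    Z : sparse, records x n_coef * n_animals — genetic covariates; every
        pedigree animal owns a column block so breeding values span the
        whole pedigree.
    W : sparse, records x n_coef * n_ewes — permanent-environment
        covariates for recorded ewes only.
    """

    X: sp.csr_matrix
    Z: sp.csr_matrix
    W: sp.csr_matrix
    phi_rec: np.ndarray        # records x n_coef covariate rows
    animal_of: np.ndarray      # record -> pedigree animal index
    ewe_of: np.ndarray         # record -> ewe index (0..n_ewes-1)
    residual_class: np.ndarray  # record -> 1..3
    n_coef: int
    n_animals: int
    n_ewes: int
    n_years: int
    n_months: int = 3

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def build_design(
    records: RecordSet,
    ped: Pedigree,
    basis: LegendreBasis | None,
    repeatability: bool = False,
) -> DesignMatrices:
    """Assemble X, Z, W for the random-regression (or repeatability) model.

    With ``repeatability=True`` the trajectory covariate per random effect
    is the raw constant 1 (a single column block per animal/ewe) and the
    fixed regression reduces to one intercept column; the residual classes
    collapse to a single class.
    """
    n_rec = len(records)
    missing = sorted(
        {records.ewe_ids[e] for e in set(records.ewe)}
        - set(map(str, ped.ids))
    )
    if missing:
        raise ValueError(
            f"{len(missing)} recorded ewe(s) missing from pedigree: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )

    if repeatability:
        phi_rec = np.ones((n_rec, 1))
        n_coef = 1
        rclass = np.ones(n_rec, dtype=np.int64)
    else:
        if basis is None:
            raise ValueError("a LegendreBasis is required for the RRM")
        phi_rec = basis.phi[records.parity - basis.t_min]
        n_coef = basis.n_coef
        rclass = records.residual_class

    animal_of = np.array(
        [ped.index_of(records.ewe_ids[e]) for e in records.ewe],
        dtype=np.int64,
    )
    ewe_of = records.ewe.astype(np.int64)

    n_animals, n_ewes, n_years = len(ped), records.n_ewes, records.n_years

    rows = np.arange(n_rec)
    # X: year dummies (all levels) | month dummies (ref = Sep dropped) | phi
    X_year = sp.coo_matrix(
        (np.ones(n_rec), (rows, records.year)), shape=(n_rec, n_years)
    )
    keep = records.month > 0
    X_month = sp.coo_matrix(
        (np.ones(keep.sum()), (rows[keep], records.month[keep] - 1)),
        shape=(n_rec, 2),
    )
    X = sp.hstack([X_year, X_month, sp.csr_matrix(phi_rec)]).tocsr()

    def blocked(owner, n_owner):
        r = np.repeat(rows, n_coef)
        c = (owner[:, None] * n_coef + np.arange(n_coef)).ravel()
        return sp.coo_matrix(
            (phi_rec.ravel(), (r, c)), shape=(n_rec, n_coef * n_owner)
        ).tocsr()

    Z = blocked(animal_of, n_animals)
    W = blocked(ewe_of, n_ewes)

    return DesignMatrices(
        X=X, Z=Z, W=W, phi_rec=phi_rec, animal_of=animal_of, ewe_of=ewe_of,
        residual_class=rclass, n_coef=n_coef, n_animals=n_animals,
        n_ewes=n_ewes, n_years=n_years,
    )
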