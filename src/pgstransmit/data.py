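"""Twin-family data: reading, validation, and preprocessing.

One analysis row is a *family*: zygosity plus six possibly-missing values
(mother/father/twin1/twin2 PGS and the two twin phenotype scores).
Preprocessing helpers cover symptom-score construction (item averaging
within occasion, then across occasions), square-root transformation with
sex adjustment, covariate residualization of the PGS, and propagation of
an observed twin genotype to the MZ co-twin.

Preprocessing never imputes: arbitrary missingness is left in place and
handled downstream by full-information maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .moments import VARIABLE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyRecord",
    "FamilyData",
    "CANONICAL_COLUMNS",
    "read_family_table",
    "propagate_mz_genotypes",
    "score_symptoms",
    "transform_adjust",
    "residualize_pgs",
    "preprocess_person_table",
]

#: Canonical column names of the family-wide table.
CANONICAL_COLUMNS = ("family_id", "zygosity") + VARIABLE_NAMES

_ZYGOSITY_CODES = {
    "MZ": "MZ", "DZ": "DZ", "mz": "MZ", "dz": "DZ",
    "monozygotic": "MZ", "dizygotic": "DZ", "1": "MZ", "2": "DZ",
}


@dataclass(frozen=True)
class FamilyRecord:
    """Observed vector of one twin family; ``None`` marks a missing value."""

    family_id: str
    zygosity: str
    pgs_mother: float | None = None
    pgs_father: float | None = None
    pgs_twin1: float | None = None
    pgs_twin2: float | None = None
    pheno_twin1: float | None = None
    pheno_twin2: float | None = None

    def values(self) -> np.ndarray:
        """The 6-vector (NaN for missing), model variable order."""
        return np.array(
            [np.nan if getattr(self, n) is None else getattr(self, n)
             for n in VARIABLE_NAMES],
            dtype=float,
        )

    @property
    def usable(self) -> bool:
        """False when all six observed slots are missing."""
        return bool(np.isfinite(self.values()).any())


class FamilyData:
    """Container for a set of family records.

    Wraps a canonical :class:`pandas.DataFrame` (one row per family) and
    provides the numeric arrays the likelihood consumes.
    """

    def __init__(self, frame: pd.DataFrame):
        missing_cols = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"family table lacks columns: {missing_cols}")
        frame = frame.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        zyg = frame["zygosity"].astype(str).map(_ZYGOSITY_CODES)
        bad = frame.loc[zyg.isna(), "zygosity"]
        if len(bad):
            row = bad.index[0]
            raise ValueError(
                f"unknown zygosity code {bad.iloc[0]!r} in row {row}"
            )
        frame["zygosity"] = zyg
        ids = frame["family_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicated family_id: {dup.iloc[0]!r}")
        frame["family_id"] = ids
        for col in VARIABLE_NAMES:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        self.frame = frame

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[FamilyRecord]) -> "FamilyData":
        rows = [
            {"family_id": r.family_id, "zygosity": r.zygosity,
             **{n: getattr(r, n) for n in VARIABLE_NAMES}}
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(frame)

    # -- views ----------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[FamilyRecord]:
        out = []
        for _, row in self.frame.iterrows():
            vals = {
                n: (None if pd.isna(row[n]) else float(row[n]))
                for n in VARIABLE_NAMES
            }
            out.append(FamilyRecord(family_id=row["family_id"],
                                    zygosity=row["zygosity"], **vals))
        return out

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(values, is_mz)``: (n, 6) float with NaN, (n,) bool."""
        values = self.frame.loc[:, list(VARIABLE_NAMES)].to_numpy(dtype=float)
        is_mz = (self.frame["zygosity"] == "MZ").to_numpy()
        return values, is_mz

    def n_by_zygosity(self) -> dict[str, int]:
        return self.frame["zygosity"].value_counts().to_dict()

    def missingness_patterns(self) -> pd.Series:
        """Counts of observed/missing patterns, e.g. ``'110011'``."""
        obs = np.isfinite(self.frame.loc[:, list(VARIABLE_NAMES)].to_numpy(float))
        keys = ["".join("1" if o else "0" for o in row) for row in obs]
        return pd.Series(keys).value_counts()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def read_family_table(
    path,
    schema: Mapping[str, str] | None = None,
    na_values: Sequence[str] = ("", "NA"),
) -> FamilyData:
    """Read a family-wide CSV into a validated :class:`FamilyData`.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per family.
    schema : mapping, optional
        Map from canonical column name to the column name used in the
        file, for files that do not use the canonical header.
    na_values : sequence of str
        Sentinels to treat as missing (in addition to empty cells).
    """
    try:
        frame = pd.read_csv(path, na_values=list(na_values),
                            keep_default_na=True, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        logger.warning("empty family table at %r", path)
        frame = pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    if schema:
        rename = {src: canon for canon, src in schema.items()}
        missing = [src for src in rename if src not in frame.columns]
        if missing:
            raise ValueError(f"column map names absent columns: {missing}")
        frame = frame.rename(columns=rename)
    data = FamilyData(frame)
    patterns = data.missingness_patterns()
    logger.info("read %d families; missingness patterns: %s",
                len(data), patterns.to_dict())
    return data


def propagate_mz_genotypes(data: FamilyData, tolerance: float = 1e-8) -> FamilyData:
    """Copy the observed twin PGS to the missing MZ co-twin slot.

    MZ twins are assumed to share identical genotypes, so an MZ family
    with exactly one observed twin PGS has the value copied to the
    co-twin.  DZ families are untouched.  MZ families whose two observed
    twin PGS differ by more than ``tolerance`` are left as-is with a
    warning.  Idempotent.
    """
    frame = data.frame.copy()
    mz = frame["zygosity"] == "MZ"
    t1 = frame["pgs_twin1"]
    t2 = frame["pgs_twin2"]
    n_prop = 0

    fill_t2 = mz & t1.notna() & t2.isna()
    fill_t1 = mz & t2.notna() & t1.isna()
    n_prop = int(fill_t2.sum() + fill_t1.sum())
    frame.loc[fill_t2, "pgs_twin2"] = frame.loc[fill_t2, "pgs_twin1"]
    frame.loc[fill_t1, "pgs_twin1"] = frame.loc[fill_t1, "pgs_twin2"]

    both = mz & t1.notna() & t2.notna()
    mismatch = both & ((t1 - t2).abs() > tolerance)
    for fid in frame.loc[mismatch, "family_id"]:
        logger.warning("MZ family %s has unequal twin PGS; values left as-is", fid)

    logger.info("propagated %d MZ twin genotypes", n_prop)
    return FamilyData(frame)


def score_symptoms(ratings) -> float:
    """Period symptom score from per-occasion item ratings for one twin.

    ``ratings`` is an (occasions x items) array of values in {0, 1, 2}
    with NaN for unrated items.  Items are averaged within each
    measurement occasion, and the resulting occasion means are averaged
    across occasions; occasions with no rated item are skipped.  Returns
    NaN when no occasion has any rated item.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2:
        raise ValueError("ratings must be an (occasions x items) array")
    finite = np.isfinite(arr)
    vals = arr[finite]
    if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
        raise ValueError("item ratings must lie in {0, 1, 2}")
    any_rated = finite.any(axis=1)
    if not any_rated.any():
        return float("nan")
    with np.errstate(invalid="ignore"):
        occ_means = np.nanmean(arr[any_rated], axis=1)
    return float(np.mean(occ_means))


def transform_adjust(scores, sex) -> np.ndarray:
    """Square-root transform period scores and residualize on sex.

    ``scores`` are non-negative period symptom scores (one per child,
    twins as separate observations; NaN allowed) and ``sex`` a binary
    indicator.  Returns OLS residuals of ``sqrt(score)`` on an intercept
    and the sex indicator; when only one sex is present the indicator is
    dropped and the adjustment is intercept-only.
    """
    scores = np.asarray(scores, dtype=float)
    sex = np.asarray(sex)
    if scores.shape != sex.shape:
        raise ValueError("scores and sex must have equal length")
    obs = np.isfinite(scores)
    if (scores[obs] < 0).any():
        raise ValueError("symptom scores must be non-negative")
    y = np.sqrt(scores[obs])

    codes = pd.Categorical(sex[obs]).codes.astype(float)
    if len(np.unique(codes)) > 1:
        X = sm.add_constant(codes)
    else:
        X = np.ones((len(y), 1))
    resid = sm.OLS(y, X).fit().resid

    out = np.full(scores.shape, np.nan)
    out[obs] = resid
    return out


def residualize_pgs(pgs, covariates, standardize: bool = True) -> np.ndarray:
    """Residualize PGS on ancestry covariates and re-standardize.

    Each person's PGS is regressed on an intercept plus the covariate
    columns (default expectation: 10 genetic principal components); the
    residuals are re-standardized to mean 0, SD 1 over non-missing
    persons.  Persons with missing covariates get a missing PGS.
    Constant covariate columns are dropped; remaining collinearity is an
    error naming the offending columns.
    """
    pgs = np.asarray(pgs, dtype=float)
    cov = pd.DataFrame(covariates)
    if len(cov) != len(pgs):
        raise ValueError("covariates and pgs must have equal length")

    cov_ok = cov.notna().all(axis=1).to_numpy()
    obs = np.isfinite(pgs) & cov_ok
    n_dropped = int((np.isfinite(pgs) & ~cov_ok).sum())
    if n_dropped:
        logger.info("dropping %d persons with missing covariates", n_dropped)

    X = cov.loc[obs]
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X.loc[:, keep].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify a minimal set of collinear columns by greedy elimination
        bad = []
        base_rank = np.linalg.matrix_rank(sm.add_constant(X[:, :0], has_constant="add"))
        cols_in = []
        for j, name in enumerate(keep):
            trial = sm.add_constant(X[:, cols_in + [j]], has_constant="add")
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols_in.append(j)
            else:
                bad.append(name)
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")

    resid = sm.OLS(pgs[obs], Xc).fit().resid
    out = np.full(pgs.shape, np.nan)
    if standardize:
        sd = resid.std(ddof=0)
        if sd <= 1e-10 * max(1.0, np.abs(pgs[obs]).max()):
            raise ValueError("residual PGS has zero variance; cannot standardize")
        resid = (resid - resid.mean()) / sd
    out[obs] = resid
    return out


def preprocess_person_table(
    persons: pd.DataFrame,
    covariate_cols: Sequence[str] = (),
    occasion_items: Mapping[str, Sequence[str]] | None = None,
    score_col: str | None = None,
    propagate_mz: bool = True,
) -> FamilyData:
    """Turn a person-long table into the canonical family-wide dataset.

    ``persons`` has one row per family member with columns ``family_id``,
    ``role`` (mother/father/twin1/twin2), ``zygosity``, ``sex``, ``pgs``,
    plus either raw item-rating columns (``occasion_items`` maps each
    measurement occasion to its item columns; twins only) or a
    precomputed period score in ``score_col``.

    The full preprocessing chain is applied: symptom scoring (item means
    within occasion, then across occasions), square-root transform with
    sex adjustment over all twins, PGS residualization on
    ``covariate_cols`` with pooled re-standardization, pivot to one row
    per family, and (optionally) MZ genotype propagation.
    """
    required = {"family_id", "role", "zygosity", "pgs"}
    missing = required - set(persons.columns)
    if missing:
        raise ValueError(f"person table lacks columns: {sorted(missing)}")
    persons = persons.copy()
    bad_roles = set(persons["role"]) - {"mother", "father", "twin1", "twin2"}
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")

    is_twin = persons["role"].str.startswith("twin")
    if occasion_items is not None:
        scores = np.full(len(persons), np.nan)
        for i in np.flatnonzero(is_twin.to_numpy()):
            ratings = np.array([
                persons.iloc[i][list(cols)].to_numpy(dtype=float)
                for cols in occasion_items.values()
            ])
            scores[i] = score_symptoms(ratings)
        persons["_score"] = scores
    elif score_col is not None:
        persons["_score"] = persons[score_col].where(is_twin)
    else:
        raise ValueError("need occasion_items or score_col for phenotypes")

    twins = persons.loc[is_twin]
    adjusted = transform_adjust(twins["_score"].to_numpy(dtype=float),
                                twins["sex"].to_numpy())
    persons.loc[is_twin, "_pheno"] = adjusted

    if covariate_cols:
        persons["_pgs"] = residualize_pgs(
            persons["pgs"].to_numpy(dtype=float), persons[list(covariate_cols)])
    else:
        persons["_pgs"] = persons["pgs"].astype(float)

    rows = []
    for fid, grp in persons.groupby("family_id", sort=False):
        by_role = {r: g for r, g in grp.groupby("role")}

        def pick(role, col):
            if role not in by_role:
                return np.nan
            return by_role[role][col].iloc[0]

        rows.append({
            "family_id": fid,
            "zygosity": grp["zygosity"].iloc[0],
            "pgs_mother": pick("mother", "_pgs"),
            "pgs_father": pick("father", "_pgs"),
            "pgs_twin1": pick("twin1", "_pgs"),
            "pgs_twin2": pick("twin2", "_pgs"),
            "pheno_twin1": pick("twin1", "_pheno"),
            "pheno_twin2": pick("twin2", "_pheno"),
        })
    data = FamilyData(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))
    if propagate_mz:
        data = propagate_mz_genotypes(data)
    return data
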