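"""Birth-record data model: CSV schema, exclusion rules, SGA derivation.

A cohort is one row per singleton birth with both parents' ages in whole
years, flags for Down syndrome (DS) and other chromosomal disorders (CD),
and ten binary neonatal morbidity/mortality (NMM) outcomes.  Empty CSV
cells encode missing values; booleans are written as 0/1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical outcome names, in reporting order.
OUTCOMES: tuple[str, ...] = (
    "preterm",
    "very_preterm",
    "sga",
    "low_apgar",
    "nicu",
    "antibiotics",
    "surfactant",
    "prolonged_ventilation",
    "seizures",
    "death",
)

#: CSV schema columns (optional trailing birthweight/gestation columns).
AGE_COLUMNS = ("mage", "page")
FLAG_COLUMNS = ("ds", "cd")
OPTIONAL_COLUMNS = ("birthweight_g", "gestation_days")
SCHEMA_COLUMNS = AGE_COLUMNS + FLAG_COLUMNS + OUTCOMES + OPTIONAL_COLUMNS

#: Default inclusive age spans for analysis.
MATERNAL_SPAN = (15, 49)
PATERNAL_SPAN = (15, 65)


class SchemaError(ValueError):
    """A mandatory column is absent or the header is malformed."""


class ParseError(ValueError):
    """A cell cannot be parsed; the message names the 1-based data row."""


@dataclass
class BirthRecord:
    """One singleton birth."""

    maternal_age: int | None
    paternal_age: int | None
    ds: bool
    cd: bool
    outcomes: Mapping[str, bool | None]
    birthweight_g: int | None = None
    gestation_days: int | None = None


@dataclass
class BirthCohort:
    """An ordered collection of birth records backed by a DataFrame.

    Columns: mage/page (nullable Int64), ds/cd (bool), the ten outcomes
    (nullable boolean), optionally birthweight_g/gestation_days.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[BirthRecord]:
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield BirthRecord(
                maternal_age=_none_if_na(d.get("mage")),
                paternal_age=_none_if_na(d.get("page")),
                ds=bool(d.get("ds", False)),
                cd=bool(d.get("cd", False)),
                outcomes={k: _bool_or_none(d.get(k)) for k in OUTCOMES},
                birthweight_g=_none_if_na(d.get("birthweight_g")),
                gestation_days=_none_if_na(d.get("gestation_days")),
            )

    def validate(self, strict: bool = False) -> list[str]:
        """Check record-level invariants; return the list of violations.

        Checks that ages are non-negative and that very_preterm implies
        preterm whenever both flags are present.  With ``strict`` a
        violation raises instead of being logged.
        """
        problems: list[str] = []
        for col in ("mage", "page"):
            if col in self.df and (self.df[col].dropna() < 0).any():
                problems.append(f"negative values in {col}")
        if {"preterm", "very_preterm"} <= set(self.df.columns):
            vp = self.df["very_preterm"]
            pt = self.df["preterm"]
            both = vp.notna() & pt.notna()
            bad = both & (vp.fillna(False).astype(bool)) & ~(pt.fillna(False).astype(bool))
            if bad.any():
                problems.append(f"{int(bad.sum())} records with very_preterm but not preterm")
        for p in problems:
            if strict:
                raise ValueError(p)
            logger.warning("cohort invariant violated: %s", p)
        return problems


@dataclass
class FilterReport:
    """Audit trail of the exclusion rules, one category per record.

    Parent-age deletions are applied before outcome-missingness deletions;
    within parent-age rules the precedence is mother-under, mother-over,
    father-missing-or-out-of-range, so each record is counted exactly once.
    """

    n_input: int
    n_mother_under_min: int
    n_mother_over_max: int
    n_father_out_of_range_or_missing: int
    n_deleted_for_parent_age: int
    n_deleted_for_missing_outcome: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_mother_under_min,
            self.n_mother_over_max,
            self.n_father_out_of_range_or_missing,
            self.n_deleted_for_parent_age,
            self.n_deleted_for_missing_outcome,
            self.n_retained,
        )
        if any(c < 0 for c in counts):
            raise ValueError("filter report counts must be non-negative")
        if self.n_deleted_for_parent_age != (
            self.n_mother_under_min
            + self.n_mother_over_max
            + self.n_father_out_of_range_or_missing
        ):
            raise ValueError("parent-age deletion categories do not sum")
        if self.n_retained != (
            self.n_input - self.n_deleted_for_parent_age - self.n_deleted_for_missing_outcome
        ):
            raise ValueError("filter report does not conserve records")

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def _none_if_na(v):
    return None if v is None or pd.isna(v) else int(v)


def _bool_or_none(v):
    return None if v is None or pd.isna(v) else bool(v)


def _parse_int_column(raw: pd.Series, name: str) -> pd.Series:
    """Parse a string column to nullable Int64; empty string is missing."""
    s = raw.str.strip()
    missing = s == ""
    vals = pd.to_numeric(s.where(~missing, None), errors="coerce")
    bad = vals.isna() & ~missing
    if not bad.any():
        frac = vals.dropna() % 1
        if (frac != 0).any():
            bad = vals.notna() & (vals % 1 != 0)
    if bad.any():
        row = int(bad.idxmax()) + 1  # 1-based data row
        raise ParseError(f"column {name!r}: cannot parse {raw[bad.idxmax()]!r} as an integer (data row {row})")
    return vals.astype("Int64")


_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _parse_bool_column(raw: pd.Series, name: str, nullable: bool) -> pd.Series:
    s = raw.str.strip().str.lower()
    missing = s == ""
    ok = missing | s.isin(_TRUE) | s.isin(_FALSE)
    if not ok.all():
        i = int((~ok).idxmax())
        raise ParseError(f"column {name!r}: cannot parse {raw[i]!r} as a boolean (data row {i + 1})")
    out = pd.Series(pd.NA, index=s.index, dtype="boolean")
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    if nullable:
        return out
    # DS/CD flags: an empty cell means the diagnosis was not recorded -> False.
    return out.fillna(False).astype(bool)


def read_births(path, provenance: str | None = None) -> BirthCohort:
    """Read a births CSV into a :class:`BirthCohort`.

    The header must name the schema columns; ``mage`` is mandatory.
    Unknown columns are ignored with a logged warning.  Empty cells are
    missing; booleans accept 0/1 (and true/false).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "mage" not in raw.columns:
        raise SchemaError("mandatory column 'mage' (maternal age) is missing")
    unknown = [c for c in raw.columns if c not in SCHEMA_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", ", ".join(unknown))
        raw = raw.drop(columns=unknown)

    cols: dict[str, pd.Series] = {}
    for c in AGE_COLUMNS + OPTIONAL_COLUMNS:
        if c in raw.columns:
            cols[c] = _parse_int_column(raw[c], c)
        elif c in AGE_COLUMNS:
            cols[c] = pd.Series(pd.NA, index=raw.index, dtype="Int64")
    for c in FLAG_COLUMNS:
        if c in raw.columns:
            cols[c] = _parse_bool_column(raw[c], c, nullable=False)
        else:
            cols[c] = pd.Series(False, index=raw.index, dtype=bool)
    for c in OUTCOMES:
        if c in raw.columns:
            cols[c] = _parse_bool_column(raw[c], c, nullable=True)
        else:
            cols[c] = pd.Series(pd.NA, index=raw.index, dtype="boolean")

    cohort = BirthCohort(pd.DataFrame(cols), provenance=provenance or str(path))
    cohort.validate(strict=False)
    return cohort


def write_births(cohort: BirthCohort, path) -> None:
    """Write a cohort in the births CSV schema (empty cell = missing)."""
    out = {}
    for c in cohort.df.columns:
        s = cohort.df[c]
        if str(s.dtype) in ("boolean", "bool"):
            vals = s.astype("boolean")
            out[c] = vals.map({True: "1", False: "0"}).astype(object).where(vals.notna(), "")
        else:
            out[c] = s.astype(object).where(s.notna(), "")
    pd.DataFrame(out).to_csv(path, index=False)


def filter_cohort(
    cohort: BirthCohort,
    maternal_range: tuple[int, int] = MATERNAL_SPAN,
    paternal_range: tuple[int, int] = PATERNAL_SPAN,
) -> tuple[BirthCohort, FilterReport]:
    """Apply the study exclusion rules and return the retained cohort + audit.

    Retains records with both parent ages present and inside the inclusive
    ranges and with all ten outcomes non-missing.  Parent-age deletions are
    tallied before outcome-missingness deletions, and each record lands in
    exactly one category.
    """
    m_lo, m_hi = maternal_range
    p_lo, p_hi = paternal_range
    if m_lo > m_hi or p_lo > p_hi:
        raise ValueError("inverted age range: lower bound exceeds upper bound")

    df = cohort.df
    mage = df["mage"]
    page = df["page"]
    # A missing maternal age cannot be placed under/over a bound; it is
    # counted with the under-min category.
    mother_under = (mage.isna() | (mage < m_lo)).fillna(True).to_numpy(dtype=bool)
    mother_over = (mage > m_hi).fillna(False).to_numpy(dtype=bool)
    father_bad = (page.isna() | (page < p_lo) | (page > p_hi)).fillna(True).to_numpy(dtype=bool)

    cat_under = mother_under
    cat_over = mother_over & ~cat_under
    cat_father = father_bad & ~cat_under & ~cat_over
    parent_del = cat_under | cat_over | cat_father

    outcome_missing = np.zeros(len(df), dtype=bool)
    for k in OUTCOMES:
        outcome_missing |= df[k].isna().to_numpy(dtype=bool)
    cat_outcome = outcome_missing & ~parent_del

    keep = ~(parent_del | cat_outcome)
    report = FilterReport(
        n_input=len(df),
        n_mother_under_min=int(cat_under.sum()),
        n_mother_over_max=int(cat_over.sum()),
        n_father_out_of_range_or_missing=int(cat_father.sum()),
        n_deleted_for_parent_age=int(parent_del.sum()),
        n_deleted_for_missing_outcome=int(cat_outcome.sum()),
        n_retained=int(keep.sum()),
    )
    retained = BirthCohort(df.loc[keep].reset_index(drop=True), provenance=cohort.provenance)
    return retained, report


def derive_sga(cohort: BirthCohort, quantile: float = 0.10) -> BirthCohort:
    """Flag small-for-gestational-age births.

    For every distinct gestational length (in days) the empirical
    ``quantile`` of birthweight is computed with linear interpolation
    between order statistics, and records strictly below the threshold are
    flagged ``sga=True`` (at-or-above get ``False``).  Records lacking
    birthweight or gestation keep their existing flag.  Days with fewer
    than 10 births still get a threshold, with a logged warning.
    """
    df = cohort.df.copy()
    if "birthweight_g" not in df or "gestation_days" not in df:
        raise ValueError("cohort lacks birthweight_g/gestation_days columns")
    usable = df["birthweight_g"].notna() & df["gestation_days"].notna()
    sga = df["sga"].copy() if "sga" in df else pd.Series(pd.NA, index=df.index, dtype="boolean")
    sub = df.loc[usable, ["birthweight_g", "gestation_days"]].astype(int)
    for day, grp in sub.groupby("gestation_days"):
        w = grp["birthweight_g"].to_numpy(dtype=float)
        if len(w) < 10:
            logger.warning("gestation day %d has only %d births; percentile is noisy", day, len(w))
        thr = float(np.quantile(w, quantile, method="linear"))
        sga.loc[grp.index] = pd.array(w < thr, dtype="boolean")
    df["sga"] = sga.astype("boolean")
    return BirthCohort(df, provenance=cohort.provenance)
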