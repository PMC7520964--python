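"""Cross-tabulated case/birth counts feeding the binomial models.

Every model in the package consumes counts, not records: case counts Y and
birth counts n by single year of parent age (one axis or the full
maternal x paternal grid), or by a binary DS/CD exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import BirthCohort, MATERNAL_SPAN, OUTCOMES, PATERNAL_SPAN

AXES = ("maternal", "paternal")
_AGE_COL = {"maternal": "mage", "paternal": "page"}
DEFAULT_SPANS = {"maternal": MATERNAL_SPAN, "paternal": PATERNAL_SPAN}


def _span_ages(span: tuple[int, int]) -> np.ndarray:
    lo, hi = span
    if lo > hi:
        raise ValueError("inverted age span")
    return np.arange(lo, hi + 1)


@dataclass
class AgeOutcomeTable:
    """Counts by single year of one parent's age.

    ``Y[k]`` is the per-age case-count vector for outcome ``k`` and ``n``
    the shared per-age birth counts.  When the table was built with
    per-outcome denominators (records missing an outcome dropped for that
    outcome only), ``n_by_outcome`` holds them and ``n_for`` dispatches.
    """

    axis: str
    ages: np.ndarray
    Y: dict[str, np.ndarray]
    n: np.ndarray
    n_by_outcome: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous and strictly increasing by 1")
        for k, y in self.Y.items():
            n = self.n_for(k)
            if np.any(y < 0) or np.any(y > n):
                raise ValueError(f"outcome {k!r}: need 0 <= Y <= n elementwise")

    def n_for(self, outcome: str) -> np.ndarray:
        if self.n_by_outcome is not None:
            return self.n_by_outcome[outcome]
        return self.n

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.Y)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.Y:
            n = self.n_for(k)
            for a, y, nn in zip(self.ages, self.Y[k], n):
                rows.append((k, int(a), int(y), int(nn)))
        return pd.DataFrame(rows, columns=["outcome", "age", "Y", "n"])


@dataclass
class JointAgeOutcomeTable:
    """Counts on the complete maternal x paternal age grid."""

    maternal_ages: np.ndarray
    paternal_ages: np.ndarray
    Y: dict[str, np.ndarray]  # outcome -> (n_maternal, n_paternal)
    n: np.ndarray
    n_by_outcome: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for ages in (self.maternal_ages, self.paternal_ages):
            if np.any(np.diff(ages) != 1):
                raise ValueError("ages must be contiguous and strictly increasing by 1")
        shape = (len(self.maternal_ages), len(self.paternal_ages))
        if self.n.shape != shape:
            raise ValueError("n grid does not match the age spans")
        for k, y in self.Y.items():
            n = self.n_for(k)
            if y.shape != shape or np.any(y < 0) or np.any(y > n):
                raise ValueError(f"outcome {k!r}: need a complete grid with 0 <= Y <= n")

    def n_for(self, outcome: str) -> np.ndarray:
        if self.n_by_outcome is not None:
            return self.n_by_outcome[outcome]
        return self.n

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.Y)

    def marginal(self, axis: str) -> AgeOutcomeTable:
        """Collapse the grid to one axis; equals the univariate tabulation."""
        if axis == "maternal":
            red, ages = 1, self.maternal_ages
        elif axis == "paternal":
            red, ages = 0, self.paternal_ages
        else:
            raise ValueError(f"axis must be one of {AXES}")
        nbo = None
        if self.n_by_outcome is not None:
            nbo = {k: v.sum(axis=red) for k, v in self.n_by_outcome.items()}
        return AgeOutcomeTable(
            axis=axis,
            ages=ages,
            Y={k: v.sum(axis=red) for k, v in self.Y.items()},
            n=self.n.sum(axis=red),
            n_by_outcome=nbo,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.Y:
            n = self.n_for(k)
            for i, ma in enumerate(self.maternal_ages):
                for j, pa in enumerate(self.paternal_ages):
                    rows.append((k, int(ma), int(pa), int(self.Y[k][i, j]), int(n[i, j])))
        return pd.DataFrame(rows, columns=["outcome", "mage", "page", "Y", "n"])


class ExposureCounts(NamedTuple):
    cases_exposed: int
    births_exposed: int
    cases_unexposed: int
    births_unexposed: int


@dataclass
class TwoByTwoTable:
    """Exposed/unexposed case and birth counts per outcome for DS or CD."""

    exposure: str
    counts: dict[str, ExposureCounts]

    def __post_init__(self) -> None:
        if self.exposure not in ("ds", "cd"):
            raise ValueError("exposure must be 'ds' or 'cd'")
        for k, c in self.counts.items():
            if c.cases_exposed > c.births_exposed or c.cases_unexposed > c.births_unexposed:
                raise ValueError(f"outcome {k!r}: cases exceed births")

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.counts)


def _outcome_bool(df: pd.DataFrame, k: str) -> np.ndarray:
    return df[k].fillna(False).to_numpy(dtype=bool)


def tabulate_by_age(
    cohort: BirthCohort,
    axis: str,
    span: tuple[int, int] | None = None,
    outcomes: tuple[str, ...] = OUTCOMES,
    per_outcome_n: bool = False,
) -> AgeOutcomeTable:
    """Cross-tabulate case and birth counts by one parent's age.

    The cohort must already be filtered: every record needs the axis age
    present and inside the span.  Ages with zero births appear with n=0.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    span = span or DEFAULT_SPANS[axis]
    ages = _span_ages(span)
    df = cohort.df
    a = df[_AGE_COL[axis]]
    if a.isna().any() or ((a < span[0]) | (a > span[1])).any():
        raise ValueError(f"{axis} ages missing or outside {span}; filter the cohort first")
    idx = (a.to_numpy(dtype=int) - span[0])
    K = len(ages)
    n = np.bincount(idx, minlength=K).astype(np.int64)
    Y: dict[str, np.ndarray] = {}
    nbo: dict[str, np.ndarray] = {}
    for k in outcomes:
        present = df[k].notna().to_numpy(dtype=bool)
        flag = _outcome_bool(df, k)
        Y[k] = np.bincount(idx[flag & present], minlength=K).astype(np.int64)
        nbo[k] = np.bincount(idx[present], minlength=K).astype(np.int64)
    if per_outcome_n:
        return AgeOutcomeTable(axis=axis, ages=ages, Y=Y, n=n, n_by_outcome=nbo)
    for k in outcomes:
        if (nbo[k] != n).any():
            raise ValueError(
                f"outcome {k!r} has missing values; filter them out or pass per_outcome_n=True"
            )
    return AgeOutcomeTable(axis=axis, ages=ages, Y=Y, n=n)


def tabulate_joint(
    cohort: BirthCohort,
    maternal_span: tuple[int, int] | None = None,
    paternal_span: tuple[int, int] | None = None,
    outcomes: tuple[str, ...] = OUTCOMES,
    per_outcome_n: bool = False,
) -> JointAgeOutcomeTable:
    """Cross-tabulate on the complete maternal x paternal grid."""
    m_span = maternal_span or DEFAULT_SPANS["maternal"]
    p_span = paternal_span or DEFAULT_SPANS["paternal"]
    m_ages, p_ages = _span_ages(m_span), _span_ages(p_span)
    df = cohort.df
    ma, pa = df["mage"], df["page"]
    for a, span, name in ((ma, m_span, "maternal"), (pa, p_span, "paternal")):
        if a.isna().any() or ((a < span[0]) | (a > span[1])).any():
            raise ValueError(f"{name} ages missing or outside {span}; filter the cohort first")
    Km, Kp = len(m_ages), len(p_ages)
    flat = (ma.to_numpy(dtype=int) - m_span[0]) * Kp + (pa.to_numpy(dtype=int) - p_span[0])
    n = np.bincount(flat, minlength=Km * Kp).reshape(Km, Kp).astype(np.int64)
    Y: dict[str, np.ndarray] = {}
    nbo: dict[str, np.ndarray] = {}
    for k in outcomes:
        present = df[k].notna().to_numpy(dtype=bool)
        flag = _outcome_bool(df, k)
        Y[k] = np.bincount(flat[flag & present], minlength=Km * Kp).reshape(Km, Kp).astype(np.int64)
        nbo[k] = np.bincount(flat[present], minlength=Km * Kp).reshape(Km, Kp).astype(np.int64)
    if per_outcome_n:
        return JointAgeOutcomeTable(m_ages, p_ages, Y, n, n_by_outcome=nbo)
    for k in outcomes:
        if (nbo[k] != n).any():
            raise ValueError(
                f"outcome {k!r} has missing values; filter them out or pass per_outcome_n=True"
            )
    return JointAgeOutcomeTable(m_ages, p_ages, Y, n)


def tabulate_binary(
    cohort: BirthCohort,
    exposure: str,
    outcomes: tuple[str, ...] = OUTCOMES,
) -> TwoByTwoTable:
    """Two-by-two exposed/unexposed counts for a chromosomal exposure.

    DS and CD are tabulated as separate exposures: for ``exposure='cd'``
    a DS-positive but CD-negative record counts as unexposed.
    """
    if exposure not in ("ds", "cd"):
        raise ValueError("exposure must be 'ds' or 'cd'")
    df = cohort.df
    exp_mask = df[exposure].to_numpy(dtype=bool)
    counts: dict[str, ExposureCounts] = {}
    for k in outcomes:
        present = df[k].notna().to_numpy(dtype=bool)
        flag = _outcome_bool(df, k)
        counts[k] = ExposureCounts(
            cases_exposed=int((flag & present & exp_mask).sum()),
            births_exposed=int((present & exp_mask).sum()),
            cases_unexposed=int((flag & present & ~exp_mask).sum()),
            births_unexposed=int((present & ~exp_mask).sum()),
        )
    return TwoByTwoTable(exposure=exposure, counts=counts)


def write_counts(table: AgeOutcomeTable | JointAgeOutcomeTable, path) -> None:
    """Write a count table as long-format CSV with bit-exact integer cells."""
    table.to_frame().to_csv(path, index=False)


def read_counts(path) -> AgeOutcomeTable | JointAgeOutcomeTable:
    """Read a long-format count CSV written by :func:`write_counts`."""
    df = pd.read_csv(path)
    if {"mage", "page"} <= set(df.columns):
        m_ages = np.arange(df["mage"].min(), df["mage"].max() + 1)
        p_ages = np.arange(df["page"].min(), df["page"].max() + 1)
        Km, Kp = len(m_ages), len(p_ages)
        Y: dict[str, np.ndarray] = {}
        n_ref: np.ndarray | None = None
        for k, grp in df.groupby("outcome", sort=False):
            grp = grp.sort_values(["mage", "page"])
            if len(grp) != Km * Kp:
                raise ValueError("incomplete joint grid in counts file")
            Y[k] = grp["Y"].to_numpy().reshape(Km, Kp)
            n_ref = grp["n"].to_numpy().reshape(Km, Kp)
        return JointAgeOutcomeTable(m_ages, p_ages, Y, n_ref)
    axis = "maternal" if df["age"].max() <= MATERNAL_SPAN[1] else "paternal"
    ages = np.arange(df["age"].min(), df["age"].max() + 1)
    Y = {}
    n_ref = None
    for k, grp in df.groupby("outcome", sort=False):
        grp = grp.sort_values("age")
        Y[k] = grp["Y"].to_numpy()
        n_ref = grp["n"].to_numpy()
    return AgeOutcomeTable(axis=axis, ages=ages, Y=Y, n=n_ref)
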