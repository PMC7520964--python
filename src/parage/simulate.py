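"""Synthetic birth-cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: correlated
parent ages (paternal = maternal + gap), paternal-age missingness
concentrated at young maternal ages, maternal-age-dependent DS/CD risk,
and outcome risks that are additive on the logit scale in a maternal
curve, a paternal curve, and DS/CD log-odds multipliers.  Every draw is
reproducible from the config seed, and the generator records the exact
OR curves and planted filter violations for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BirthCohort, MATERNAL_SPAN, OUTCOMES, PATERNAL_SPAN
from .curves import ORCurve

__all__ = [
    "QuadraticCurve",
    "TableCurve",
    "curve_from_endpoints",
    "ExposureRisk",
    "OutcomeSpec",
    "SimConfig",
    "TruthTables",
    "simulate_cohort",
    "true_or_curve",
    "default_sim_config",
    "shape_scenario_config",
    "recovery_config",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class QuadraticCurve:
    """Piecewise-quadratic log-OR curve about a trough age.

    f(a) = curv_young * (a - trough)^2 below the trough and
    curv_old * (a - trough)^2 above it; f(trough) = 0.  Equal curvatures
    give the symmetric (U) form.
    """

    trough: float
    curv_young: float
    curv_old: float | None = None

    def __call__(self, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        d = a - self.trough
        c_old = self.curv_young if self.curv_old is None else self.curv_old
        return np.where(d < 0, self.curv_young, c_old) * d * d

    def to_dict(self) -> dict:
        return {
            "kind": "quadratic",
            "trough": self.trough,
            "curv_young": self.curv_young,
            "curv_old": self.curv_old,
        }


@dataclass(frozen=True)
class TableCurve:
    """Explicit per-age log-OR table, clamped to its end ages outside."""

    ages: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.values):
            raise ValueError("ages and values must have equal length")

    def __call__(self, age) -> np.ndarray:
        a = np.clip(np.asarray(age, dtype=float), self.ages[0], self.ages[-1])
        return np.interp(a, self.ages, self.values)

    def to_dict(self) -> dict:
        return {"kind": "table", "ages": list(self.ages), "values": list(self.values)}


def _curve_from_dict(d: dict | None):
    if d is None:
        return None
    if d["kind"] == "quadratic":
        return QuadraticCurve(d["trough"], d["curv_young"], d.get("curv_old"))
    if d["kind"] == "table":
        return TableCurve(tuple(d["ages"]), tuple(d["values"]))
    raise ValueError(f"unknown curve kind {d['kind']!r}")


def curve_from_endpoints(
    trough: float, young_age: float, young_or: float, old_age: float, old_or: float
) -> QuadraticCurve:
    """Piecewise quadratic hitting given ORs at the two end ages."""
    cy = np.log(young_or) / (young_age - trough) ** 2 if young_or != 1.0 else 0.0
    co = np.log(old_or) / (old_age - trough) ** 2 if old_or != 1.0 else 0.0
    return QuadraticCurve(trough=trough, curv_young=float(cy), curv_old=float(co))


@dataclass(frozen=True)
class ExposureRisk:
    """Maternal-age-dependent risk of a chromosomal exposure.

    Probability is ``baseline`` up to the knot age; above it the log-odds
    rise by ``slope`` per year (the classic steep rise of Down-syndrome
    risk with advancing maternal age).
    """

    baseline: float
    knot: float = 30.0
    slope: float = 0.25

    def prob(self, mage) -> np.ndarray:
        a = np.asarray(mage, dtype=float)
        eta = _logit(self.baseline) + self.slope * np.maximum(0.0, a - self.knot)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {"baseline": self.baseline, "knot": self.knot, "slope": self.slope}


@dataclass(frozen=True)
class OutcomeSpec:
    """Risk model for one outcome: logit(p) = logit(baseline) + f_m + f_p
    + log(or_ds)*DS + log(or_cd)*CD."""

    baseline: float
    maternal: QuadraticCurve | TableCurve | None = None
    paternal: QuadraticCurve | TableCurve | None = None
    or_ds: float = 1.0
    or_cd: float = 1.0
    missing_prob: float = 0.0

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "maternal": self.maternal.to_dict() if self.maternal else None,
            "paternal": self.paternal.to_dict() if self.paternal else None,
            "or_ds": self.or_ds,
            "or_cd": self.or_cd,
            "missing_prob": self.missing_prob,
        }


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; defaults emulate the study cohort."""

    n_births: int = 100_000
    seed: int = 0
    maternal_mean: float = 29.0
    maternal_sd: float = 6.0
    maternal_span: tuple[int, int] = (13, 52)
    gap_mean: float = 2.5
    gap_sd: float = 4.0
    paternal_span: tuple[int, int] = (13, 70)
    father_missing_base: float = 0.12
    father_missing_young: float = 0.72
    father_missing_cutoff: int = 15
    ds: ExposureRisk = ExposureRisk(baseline=8e-4, knot=30.0, slope=0.25)
    cd: ExposureRisk = ExposureRisk(baseline=4e-4, knot=30.0, slope=0.20)
    outcomes: tuple[tuple[str, OutcomeSpec], ...] = ()
    include_birthweight: bool = False

    def __post_init__(self) -> None:
        for p in (
            self.father_missing_base,
            self.father_missing_young,
            self.ds.baseline,
            self.cd.baseline,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for name, spec in self.outcomes:
            if not (0.0 < spec.baseline < 1.0):
                raise ValueError(f"outcome {name!r}: baseline must lie in (0, 1)")
            if not (0.0 <= spec.missing_prob <= 1.0):
                raise ValueError(f"outcome {name!r}: missing_prob must lie in [0, 1]")

    @property
    def outcome_dict(self) -> dict[str, OutcomeSpec]:
        return dict(self.outcomes)

    def to_dict(self) -> dict:
        return {
            "n_births": self.n_births,
            "seed": self.seed,
            "maternal_mean": self.maternal_mean,
            "maternal_sd": self.maternal_sd,
            "maternal_span": list(self.maternal_span),
            "gap_mean": self.gap_mean,
            "gap_sd": self.gap_sd,
            "paternal_span": list(self.paternal_span),
            "father_missing_base": self.father_missing_base,
            "father_missing_young": self.father_missing_young,
            "father_missing_cutoff": self.father_missing_cutoff,
            "ds": self.ds.to_dict(),
            "cd": self.cd.to_dict(),
            "outcomes": {k: v.to_dict() for k, v in self.outcomes},
            "include_birthweight": self.include_birthweight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        outcomes = tuple(
            (
                k,
                OutcomeSpec(
                    baseline=v["baseline"],
                    maternal=_curve_from_dict(v.get("maternal")),
                    paternal=_curve_from_dict(v.get("paternal")),
                    or_ds=v.get("or_ds", 1.0),
                    or_cd=v.get("or_cd", 1.0),
                    missing_prob=v.get("missing_prob", 0.0),
                ),
            )
            for k, v in d.get("outcomes", {}).items()
        )
        return cls(
            n_births=d.get("n_births", 100_000),
            seed=d.get("seed", 0),
            maternal_mean=d.get("maternal_mean", 29.0),
            maternal_sd=d.get("maternal_sd", 6.0),
            maternal_span=tuple(d.get("maternal_span", (13, 52))),
            gap_mean=d.get("gap_mean", 2.5),
            gap_sd=d.get("gap_sd", 4.0),
            paternal_span=tuple(d.get("paternal_span", (13, 70))),
            father_missing_base=d.get("father_missing_base", 0.12),
            father_missing_young=d.get("father_missing_young", 0.72),
            father_missing_cutoff=d.get("father_missing_cutoff", 15),
            ds=ExposureRisk(**d["ds"]) if "ds" in d else ExposureRisk(8e-4),
            cd=ExposureRisk(**d["cd"]) if "cd" in d else ExposureRisk(4e-4, slope=0.20),
            outcomes=outcomes,
            include_birthweight=d.get("include_birthweight", False),
        )


@dataclass
class TruthTables:
    """Ground truth accompanying a simulated cohort."""

    or_curves: dict[tuple[str, str], ORCurve]
    ds_or: dict[str, float]
    cd_or: dict[str, float]
    planted: dict[str, int]

    def to_json(self, path) -> None:
        payload = {
            "planted": self.planted,
            "ds_or": self.ds_or,
            "cd_or": self.cd_or,
            "or_curves": {
                f"{k[0]}|{k[1]}": {
                    "reference_age": int(c.reference_age),
                    "ages": [int(a) for a in c.ages],
                    "or": [float(v) for v in c.median],
                }
                for k, c in self.or_curves.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def true_or_curve(config: SimConfig, outcome: str, axis: str, reference_age: int = 15) -> ORCurve:
    """Exact configured OR curve over the analysis span (zero-width CIs)."""
    spec = config.outcome_dict[outcome]
    curve = spec.maternal if axis == "maternal" else spec.paternal
    span = MATERNAL_SPAN if axis == "maternal" else PATERNAL_SPAN
    ages = np.arange(span[0], span[1] + 1)
    f = curve(ages) if curve is not None else np.zeros(len(ages))
    fr = curve(reference_age) if curve is not None else 0.0
    orr = np.exp(f - fr)
    i_ref = reference_age - span[0]
    orr[i_ref] = 1.0  # exact, not merely up to rounding
    return ORCurve(
        axis=axis,
        reference_age=reference_age,
        ages=ages,
        median=orr,
        lo=orr.copy(),
        hi=orr.copy(),
        sig_prob=np.full(len(ages), np.nan),
        source="truth",
        outcome=outcome,
    )


def _planted_counts(mage, page, father_missing, any_outcome_missing) -> dict[str, int]:
    """Filter-rule bookkeeping with the same precedence as filter_cohort,
    derived directly from the generator's arrays."""
    m_lo, m_hi = MATERNAL_SPAN
    p_lo, p_hi = PATERNAL_SPAN
    under = mage < m_lo
    over = (~under) & (mage > m_hi)
    father = (~under) & (~over) & (father_missing | (page < p_lo) | (page > p_hi))
    parent = under | over | father
    outcome = (~parent) & any_outcome_missing
    return {
        "n_input": int(len(mage)),
        "n_mother_under_min": int(under.sum()),
        "n_mother_over_max": int(over.sum()),
        "n_father_out_of_range_or_missing": int(father.sum()),
        "n_deleted_for_parent_age": int(parent.sum()),
        "n_deleted_for_missing_outcome": int(outcome.sum()),
        "n_retained": int(len(mage) - parent.sum() - outcome.sum()),
    }


def simulate_cohort(config: SimConfig) -> tuple[BirthCohort, TruthTables]:
    """Generate a cohort and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    N = config.n_births
    m_lo, m_hi = config.maternal_span
    p_lo, p_hi = config.paternal_span

    mage = np.clip(
        np.round(rng.normal(config.maternal_mean, config.maternal_sd, size=N)), m_lo, m_hi
    ).astype(np.int64)
    gap = rng.normal(config.gap_mean, config.gap_sd, size=N)
    page = np.clip(np.round(mage + gap), p_lo, p_hi).astype(np.int64)

    p_miss = np.where(
        mage < config.father_missing_cutoff, config.father_missing_young, config.father_missing_base
    )
    father_missing = rng.random(N) < p_miss

    ds = rng.random(N) < config.ds.prob(mage)
    cd = rng.random(N) < config.cd.prob(mage)

    # Records with a missing father still need a paternal contribution to
    # their outcome risk; the convention is the maternal age + mean gap.
    page_eff = np.where(
        father_missing,
        np.clip(np.round(mage + config.gap_mean), p_lo, p_hi),
        page,
    )

    cols: dict[str, object] = {
        "mage": pd.array(mage, dtype="Int64"),
        "page": pd.Series(pd.array(page, dtype="Int64")).where(~father_missing, pd.NA).array,
        "ds": ds,
        "cd": cd,
    }

    any_missing = np.zeros(N, dtype=bool)
    outcome_dict = config.outcome_dict
    for k in OUTCOMES:
        spec = outcome_dict.get(k)
        if spec is None:
            # outcomes not configured are all-negative, never missing
            cols[k] = pd.array(np.zeros(N, dtype=bool), dtype="boolean")
            continue
        eta = np.full(N, _logit(spec.baseline))
        if spec.maternal is not None:
            eta += spec.maternal(mage)
        if spec.paternal is not None:
            eta += spec.paternal(page_eff)
        if spec.or_ds != 1.0:
            eta += np.log(spec.or_ds) * ds
        if spec.or_cd != 1.0:
            eta += np.log(spec.or_cd) * cd
        flag = rng.random(N) < 1.0 / (1.0 + np.exp(-eta))
        s = pd.Series(pd.array(flag, dtype="boolean"))
        if spec.missing_prob > 0:
            miss = rng.random(N) < spec.missing_prob
            s = s.where(~miss, pd.NA)
            any_missing |= miss
        cols[k] = s.array

    if config.include_birthweight:
        gest = np.clip(np.round(rng.normal(273.0, 12.0, size=N)), 140, 310).astype(np.int64)
        weight = np.clip(
            np.round(rng.normal(3300.0 + 12.0 * (gest - 273.0), 400.0)), 250, None
        ).astype(np.int64)
        cols["gestation_days"] = pd.array(gest, dtype="Int64")
        cols["birthweight_g"] = pd.array(weight, dtype="Int64")

    cohort = BirthCohort(pd.DataFrame(cols), provenance=f"simulated(seed={config.seed})")

    truth = TruthTables(
        or_curves={
            (k, ax): true_or_curve(config, k, ax)
            for k in outcome_dict
            for ax in ("maternal", "paternal")
        },
        ds_or={k: s.or_ds for k, s in outcome_dict.items()},
        cd_or={k: s.or_cd for k, s in outcome_dict.items()},
        planted=_planted_counts(mage, page, father_missing, any_missing),
    )
    return cohort, truth


def default_sim_config(n_births: int = 100_000, seed: int = 0) -> SimConfig:
    """Defaults echoing the study's qualitative landscape.

    Troughs near maternal age 30 and paternal age 35, endpoint ORs and
    DS/CD odds multipliers of the magnitudes the national analysis
    reports; these are emulation defaults, not claimed effect sizes.
    """
    m = MATERNAL_SPAN
    p = PATERNAL_SPAN

    def mat(young_or, old_or, trough=30):
        return curve_from_endpoints(trough, m[0], young_or, m[1], old_or)

    def pat(young_or, old_or, trough=35):
        return curve_from_endpoints(trough, p[0], young_or, p[1], old_or)

    specs = {
        "preterm": OutcomeSpec(0.08, mat(1.22, 2.20), pat(1.31, 1.30), 4.2, 6.0, 0.001),
        "very_preterm": OutcomeSpec(0.012, mat(1.47, 2.00), pat(1.45, 1.39), 2.8, 8.1, 0.001),
        "sga": OutcomeSpec(0.10, mat(1.60, 1.0, trough=49), pat(1.13, 1.46), 2.3, 5.2, 0.001),
        "low_apgar": OutcomeSpec(0.005, mat(1.41, 1.32), pat(1.42, 1.38), 4.7, 31.4, 0.001),
        "nicu": OutcomeSpec(0.08, mat(1.12, 1.80), pat(1.19, 1.34), 15.7, 15.9, 0.001),
        "antibiotics": OutcomeSpec(0.02, mat(1.25, 1.22), pat(1.12, 1.17), 7.8, 11.4, 0.001),
        "surfactant": OutcomeSpec(0.005, mat(1.23, 1.67), pat(1.17, 1.14), 6.0, 16.4, 0.001),
        "prolonged_ventilation": OutcomeSpec(0.007, mat(1.06, 1.76), pat(1.20, 1.13), 12.7, 22.9, 0.001),
        "seizures": OutcomeSpec(0.0005, None, None, 11.7, 49.7, 0.001),
        "death": OutcomeSpec(0.002, mat(1.48, 1.79), pat(1.17, 1.16), 12.6, 70.2, 0.001),
    }
    return SimConfig(n_births=n_births, seed=seed, outcomes=tuple(specs.items()))


def shape_scenario_config(shape: str, n_births: int = 200_000, seed: int = 0) -> SimConfig:
    """Canonical single-outcome scenarios for shape-recovery testing.

    All use a preterm-like baseline (0.08) on the maternal axis with no
    paternal effect and no DS/CD, so the univariate total fit sees the
    configured curve exactly.  The maternal-age spread is wider than the
    study-like default (mean 30, sd 8.5) so every age of the span carries
    real case counts: the scenarios exercise the classifier's decision
    rules, which compare the span's extreme ages, not the demography.
    """
    m = MATERNAL_SPAN
    curves = {
        "U": curve_from_endpoints(30, m[0], 1.6, m[1], 1.6),
        "J": curve_from_endpoints(30, m[0], 1.3, m[1], 2.2),
        "increasing": curve_from_endpoints(m[0], m[0], 1.0, m[1], 2.0),
        "decreasing": curve_from_endpoints(m[1], m[0], 1.8, m[1], 1.0),
        "flat": None,
    }
    if shape not in curves:
        raise ValueError(f"unknown scenario {shape!r}; choose from {sorted(curves)}")
    spec = OutcomeSpec(baseline=0.08, maternal=curves[shape], paternal=None)
    return SimConfig(
        n_births=n_births,
        seed=seed,
        maternal_mean=30.0,
        maternal_sd=8.5,
        father_missing_base=0.0,
        father_missing_young=0.0,
        ds=ExposureRisk(baseline=1e-9),
        cd=ExposureRisk(baseline=1e-9),
        outcomes=(("preterm", spec),),
    )


def recovery_config(n_births: int = 100_000, seed: int = 0) -> SimConfig:
    """Parameter-recovery scenario: correlated ages, distinct maternal and
    paternal quadratic curves, strong DS/CD multipliers (OR 5 and 10).

    The paternal curve is deliberately of the same order as the maternal
    one: with a parent-age correlation near 0.8 the experiment must carry
    a confounder strong enough that ignoring it visibly distorts the
    univariate (total) curve relative to the posterior noise at this
    cohort size — that distortion is exactly what the adjusted model is
    meant to remove.
    """
    m, p = MATERNAL_SPAN, PATERNAL_SPAN
    spec = OutcomeSpec(
        baseline=0.08,
        maternal=curve_from_endpoints(30, m[0], 1.5, m[1], 2.0),
        paternal=curve_from_endpoints(35, p[0], 1.6, p[1], 2.2),
        or_ds=5.0,
        or_cd=10.0,
    )
    return SimConfig(n_births=n_births, seed=seed, outcomes=(("preterm", spec),))
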