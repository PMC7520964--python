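"""The four study model presets: total/adjusted x maternal/paternal.

Total effects fit the univariate model on the full filtered cohort.  The
adjusted maternal effect restricts to DS/CD-negative neonates (removing
the chromosomal-disorder mediation pathway) and fits the joint
maternal x paternal model; the adjusted paternal effect fits the joint
model on all data (DS/CD can confound but does not mediate paternal age,
so no restriction is applied).  All curves are standardized to age 15.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import BirthCohort, OUTCOMES
from .curves import ORCurve
from .model import AgeRiskModel, MCMCConfig
from .results import AgeRiskResults, ConvergenceReport
from .shapes import ShapeClassification
from .tables import tabulate_by_age, tabulate_joint

PRESETS = ("total_maternal", "total_paternal", "adjusted_maternal", "adjusted_paternal")


@dataclass
class PresetResult:
    preset: str
    outcome: str
    curve: ORCurve
    shape: ShapeClassification
    results: AgeRiskResults

    def convergence(self, threshold: float = 1.05) -> ConvergenceReport:
        return self.results.convergence(threshold=threshold)


def restrict_ds_cd_negative(cohort: BirthCohort) -> BirthCohort:
    """Neonates negative for both DS and CD."""
    keep = ~(cohort.df["ds"].astype(bool) | cohort.df["cd"].astype(bool))
    return BirthCohort(cohort.df.loc[keep].reset_index(drop=True), provenance=cohort.provenance)


def run_preset(
    cohort: BirthCohort,
    preset: str,
    mcmc_config: MCMCConfig | None = None,
    outcomes: tuple[str, ...] = OUTCOMES,
    reference_age: int = 15,
) -> dict[str, PresetResult]:
    """Fit one preset for each outcome on an already-filtered cohort.

    Returns a mapping outcome -> (standardized OR curve, shape
    classification, full results object).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    mcmc_config = mcmc_config or MCMCConfig()

    if preset == "adjusted_maternal":
        data = restrict_ds_cd_negative(cohort)
    else:
        data = cohort

    axis = "maternal" if "maternal" in preset else "paternal"
    joint = preset.startswith("adjusted")
    if joint:
        table = tabulate_joint(data, outcomes=outcomes)
    else:
        table = tabulate_by_age(data, axis, outcomes=outcomes)

    out: dict[str, PresetResult] = {}
    for k in outcomes:
        model = AgeRiskModel.from_table(table, k)
        res = model.fit(mcmc_config)
        out[k] = PresetResult(
            preset=preset,
            outcome=k,
            curve=res.or_curve(axis=axis, reference_age=reference_age, source=preset),
            shape=res.classify_shape(axis=axis),
            results=res,
        )
    return out
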