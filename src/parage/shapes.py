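"""U/J-shape classification of parental-age risk curves.

A risk curve over age is summarized by three posterior contrasts against
the trough (the age with the lowest posterior-median OR): youngest vs
trough, oldest vs trough, and oldest vs youngest.  "a significantly
higher than b" means the two-sided posterior tail probability of
OR_a/OR_b is below the significance level with posterior median ratio
above 1.  Labels:

    J           both ends rise from the trough and the old end is
                significantly above the young end
    U           both ends rise, ends not significantly different
    increasing  only the old end rises (trough at/near the youngest age)
    decreasing  only the young end rises
    flat        neither end rises significantly
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import _two_sided_prob, or_draws
from .model import PosteriorDraws

SHAPE_LABELS = ("U", "J", "increasing", "decreasing", "flat")


@dataclass
class PairEvidence:
    """One pairwise contrast: is age_a significantly higher than age_b?"""

    age_a: int
    age_b: int
    median_ratio: float
    p_two_sided: float
    significantly_higher: bool


@dataclass
class ShapeClassification:
    label: str
    trough_age: int
    young_vs_trough: PairEvidence
    old_vs_trough: PairEvidence
    old_vs_young: PairEvidence
    any_age_significant: bool

    def as_dict(self) -> dict:
        def pe(p: PairEvidence) -> dict:
            return {
                "age_a": p.age_a,
                "age_b": p.age_b,
                "median_ratio": p.median_ratio,
                "p_two_sided": p.p_two_sided,
                "significantly_higher": p.significantly_higher,
            }

        return {
            "label": self.label,
            "trough_age": self.trough_age,
            "young_vs_trough": pe(self.young_vs_trough),
            "old_vs_trough": pe(self.old_vs_trough),
            "old_vs_young": pe(self.old_vs_young),
            "any_age_significant": self.any_age_significant,
        }


def _contrast(orm: np.ndarray, ages: np.ndarray, a: int, b: int, alpha_level: float) -> PairEvidence:
    ia = int(np.where(ages == a)[0][0])
    ib = int(np.where(ages == b)[0][0])
    r = orm[:, ia] / orm[:, ib]
    med = float(np.median(r))
    p = _two_sided_prob(r)
    return PairEvidence(
        age_a=a,
        age_b=b,
        median_ratio=med,
        p_two_sided=p,
        significantly_higher=bool(p < alpha_level and med > 1.0),
    )


def classify_shape(
    draws: PosteriorDraws, axis: str, alpha_level: float = 0.05
) -> ShapeClassification:
    """Classify the posterior OR curve of one axis as U/J/monotone/flat.

    The trough is the age with the minimum posterior-median OR (ties go to
    the youngest such age).  Also reports whether any age differs
    significantly from the youngest (reference) age — the study's notion
    of "a significant age effect".
    """
    ages = draws.spec.ages(axis)
    if len(ages) < 3:
        raise ValueError("shape classification needs a span of at least 3 ages")
    ages, orm = or_draws(draws, axis, int(ages[0]))
    med = np.median(orm, axis=0)
    trough = int(ages[np.argmin(med)])
    youngest, oldest = int(ages[0]), int(ages[-1])

    yt = _contrast(orm, ages, youngest, trough, alpha_level)
    ot = _contrast(orm, ages, oldest, trough, alpha_level)
    oy = _contrast(orm, ages, oldest, youngest, alpha_level)

    if yt.significantly_higher and ot.significantly_higher:
        label = "J" if oy.significantly_higher else "U"
    elif ot.significantly_higher:
        label = "increasing"
    elif yt.significantly_higher:
        label = "decreasing"
    else:
        label = "flat"

    sig_any = False
    for i in range(1, orm.shape[1]):
        if _two_sided_prob(orm[:, i]) < alpha_level:
            sig_any = True
            break

    return ShapeClassification(
        label=label,
        trough_age=trough,
        young_vs_trough=yt,
        old_vs_trough=ot,
        old_vs_young=oy,
        any_age_significant=sig_any,
    )
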