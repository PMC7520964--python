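"""Odds ratios for the binary DS/CD exposures.

Each arm's rate gets a Uniform(0,1) prior, so its posterior is
Beta(Y+1, n-Y+1) exactly; OR draws are formed as the ratio of the two
arms' posterior odds and summarized by the median and central 95%
credible interval.
"""

from __future__ import annotations

import numpy as np

from .curves import ORSummary
from .tables import TwoByTwoTable


def estimate_binary_or(
    table: TwoByTwoTable,
    n_draws: int = 100_000,
    seed: int = 0,
) -> dict[str, ORSummary]:
    """Posterior OR of exposure vs non-exposure for every outcome.

    Zero cases (or all cases) in an arm are fine — the Beta posterior
    handles them — but an arm with zero births leaves the OR undefined and
    raises.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, ORSummary] = {}
    for k, c in table.counts.items():
        if c.births_exposed == 0 or c.births_unexposed == 0:
            raise ValueError(
                f"outcome {k!r}: an arm has zero births; the odds ratio is undefined"
            )
        mu_e = rng.beta(c.cases_exposed + 1.0, c.births_exposed - c.cases_exposed + 1.0, size=n_draws)
        mu_u = rng.beta(c.cases_unexposed + 1.0, c.births_unexposed - c.cases_unexposed + 1.0, size=n_draws)
        ors = (mu_e / (1.0 - mu_e)) / (mu_u / (1.0 - mu_u))
        lo, med, hi = np.percentile(ors, [2.5, 50.0, 97.5])
        p_ge = np.mean(ors >= 1.0)
        p_le = np.mean(ors <= 1.0)
        out[k] = ORSummary(
            label=f"{table.exposure} exposure",
            median=float(med),
            lo=float(lo),
            hi=float(hi),
            n_draws=n_draws,
            sig_prob=float(min(1.0, 2.0 * min(p_ge, p_le))),
            outcome=k,
            exposure=table.exposure,
        )
    return out
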