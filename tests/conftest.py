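import numpy as np
import pandas as pd
import pytest

from parage import (
    BirthCohort,
    MCMCConfig,
    ModelSpec,
    OUTCOMES,
    PosteriorDraws,
    default_sim_config,
    filter_cohort,
    simulate_cohort,
)


def make_cohort(rows, provenance="test") -> BirthCohort:
    """Build a cohort from dicts; unspecified outcomes default to False."""
    recs = []
    for r in rows:
        rec = {"mage": r.get("mage"), "page": r.get("page"),
               "ds": r.get("ds", False), "cd": r.get("cd", False)}
        for k in OUTCOMES:
            rec[k] = r.get(k, False)
        for opt in ("birthweight_g", "gestation_days"):
            if opt in r:
                rec[opt] = r[opt]
        recs.append(rec)
    base_cols = ["mage", "page", "ds", "cd", *OUTCOMES]
    df = pd.DataFrame(recs, columns=base_cols if not recs else None)
    df["mage"] = df["mage"].astype("Int64")
    df["page"] = df["page"].astype("Int64")
    for k in OUTCOMES:
        df[k] = df[k].astype("boolean")
    for opt in ("birthweight_g", "gestation_days"):
        if opt in df:
            df[opt] = df[opt].astype("Int64")
    return BirthCohort(df, provenance=provenance)


def draws_from_effects(effect_draws: np.ndarray, axis: str = "maternal", age_lo: int = 15) -> PosteriorDraws:
    """Wrap a (n_draws, K) effect matrix as a two-chain PosteriorDraws."""
    n, K = effect_draws.shape
    half = n // 2
    e = np.stack([effect_draws[:half], effect_draws[half : 2 * half]])
    other = "paternal" if axis == "maternal" else "maternal"
    spec = ModelSpec(
        axes=(axis,),
        spans=((axis, (age_lo, age_lo + K - 1)), (other, (15, 65))),
    )
    cfg = MCMCConfig(n_chains=2, burn_in=0, iterations=half, thin=1, seed=0)
    return PosteriorDraws(
        spec=spec,
        config=cfg,
        alpha=np.zeros((2, half)),
        effects={axis: e},
        sd={axis: np.ones((2, half))},
    )


@pytest.fixture(scope="session")
def sim_default():
    """A modest study-like cohort with its truth tables and filter output."""
    cohort, truth = simulate_cohort(default_sim_config(n_births=20000, seed=1))
    filtered, report = filter_cohort(cohort)
    return {"cohort": cohort, "truth": truth, "filtered": filtered, "report": report}
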