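"""Model-facing API: specification, MCMC configuration, draws, Model class.

`AgeRiskModel` is constructed from per-age count data (or a cohort) and
`fit()` returns an :class:`~parage.results.AgeRiskResults` carrying the
posterior draws, convergence diagnostics, OR curves and shape
classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import BirthCohort, MATERNAL_SPAN, PATERNAL_SPAN
from .tables import AgeOutcomeTable, JointAgeOutcomeTable, tabulate_by_age, tabulate_joint
from . import engine

_DEFAULT_SPANS = {"maternal": MATERNAL_SPAN, "paternal": PATERNAL_SPAN}


@dataclass(frozen=True)
class ModelSpec:
    """Which parent-age axes enter the model and their priors.

    ``sd_bounds`` is the support of the uniform hyperprior on each
    random-walk standard deviation (default Uniform(0, 10)); the intercept
    prior is flat and improper.
    """

    axes: tuple[str, ...] = ("maternal",)
    spans: tuple[tuple[str, tuple[int, int]], ...] = (
        ("maternal", MATERNAL_SPAN),
        ("paternal", PATERNAL_SPAN),
    )
    sd_bounds: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if not self.axes or any(a not in ("maternal", "paternal") for a in self.axes):
            raise ValueError("axes must be a non-empty subset of ('maternal', 'paternal')")
        if len(set(self.axes)) != len(self.axes):
            raise ValueError("duplicate axis")
        if not (0 <= self.sd_bounds[0] < self.sd_bounds[1]):
            raise ValueError("need 0 <= sd lower bound < upper bound")

    def span(self, axis: str) -> tuple[int, int]:
        return dict(self.spans)[axis]

    def ages(self, axis: str) -> np.ndarray:
        lo, hi = self.span(axis)
        return np.arange(lo, hi + 1)

    def span_length(self, axis: str) -> int:
        lo, hi = self.span(axis)
        return hi - lo + 1

    @property
    def sd_upper(self) -> float:
        return self.sd_bounds[1]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: 5,000 burn-in then 200,000 iterations thinned by 100
    is the default; tests and quick looks use much shorter chains."""

    n_chains: int = 2
    burn_in: int = 5000
    iterations: int = 200000
    thin: int = 100
    seed: int = 2020
    adapt_during_burn_in: bool = True
    target_acceptance: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need n_chains >= 1")
        if self.burn_in < 0:
            raise ValueError("need burn_in >= 0")
        if self.iterations % self.thin != 0:
            raise ValueError("iterations must be divisible by thin")
        if not (0.0 < self.target_acceptance < 1.0):
            raise ValueError("target_acceptance must lie in (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorDraws:
    """Thinned multi-chain posterior draws.

    Arrays are ``alpha[chain, draw]``, ``effects[axis][chain, draw, age]``
    and ``sd[axis][chain, draw]``.  Every stored draw satisfies the
    sum-to-zero identifiability constraint per axis.
    """

    spec: ModelSpec
    config: MCMCConfig
    alpha: np.ndarray
    effects: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    acceptance: list[dict[str, float]] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def pooled_alpha(self) -> np.ndarray:
        return self.alpha.reshape(-1)

    def pooled_effects(self, axis: str) -> np.ndarray:
        """All chains stacked: (n_chains * n_draws, span_length)."""
        e = self.effects[axis]
        return e.reshape(-1, e.shape[-1])

    def pooled_sd(self, axis: str) -> np.ndarray:
        return self.sd[axis].reshape(-1)

    def parameter_names(self) -> list[str]:
        names = ["alpha"]
        for ax in self.spec.axes:
            names += [f"{ax}[{a}]" for a in self.spec.ages(ax)]
            names.append(f"sd[{ax}]")
        return names

    def parameter_chains(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) matrix for one named parameter."""
        if name == "alpha":
            return self.alpha
        if name.startswith("sd["):
            return self.sd[name[3:-1]]
        ax, age = name[:-1].split("[")
        lo, _ = self.spec.span(ax)
        return self.effects[ax][:, :, int(age) - lo]

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, draw, parameter, value)."""
        recs = []
        for name in self.parameter_names():
            m = self.parameter_chains(name)
            for c in range(self.n_chains):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": np.arange(self.n_draws),
                            "parameter": name,
                            "value": m[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def save_csv(self, path) -> None:
        """Draws as CSV plus a JSON metadata sidecar (<path>.meta.json)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        meta = {
            "spec": {
                "axes": list(self.spec.axes),
                "spans": {a: list(self.spec.span(a)) for a in self.spec.axes},
                "sd_bounds": list(self.spec.sd_bounds),
            },
            "config": asdict(self.config),
            "acceptance": self.acceptance,
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load_csv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        spec = ModelSpec(
            axes=tuple(meta["spec"]["axes"]),
            spans=tuple((a, tuple(s)) for a, s in meta["spec"]["spans"].items()),
            sd_bounds=tuple(meta["spec"]["sd_bounds"]),
        )
        config = MCMCConfig(**meta["config"])
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["draw"].max()) + 1

        def grab(name):
            sub = df[df["parameter"] == name].sort_values(["chain", "draw"])
            return sub["value"].to_numpy().reshape(n_chains, n_draws)

        effects = {}
        sd = {}
        for ax in spec.axes:
            lo, hi = spec.span(ax)
            effects[ax] = np.stack([grab(f"{ax}[{a}]") for a in range(lo, hi + 1)], axis=-1)
            sd[ax] = grab(f"sd[{ax}]")
        return cls(
            spec=spec,
            config=config,
            alpha=grab("alpha"),
            effects=effects,
            sd=sd,
            acceptance=meta.get("acceptance", []),
        )


class AgeRiskModel:
    """Binomial-logit model of one NMM outcome against parent age(s).

    Parameters
    ----------
    Y, n : arrays of case and birth counts over the spec's age span(s)
        1-D for a single axis, 2-D (maternal x paternal) for the joint
        model.
    spec : ModelSpec
    outcome : optional label carried through to results.
    """

    def __init__(self, Y, n, spec: ModelSpec | None = None, outcome: str | None = None):
        self.spec = spec or ModelSpec()
        self.Y = np.asarray(Y, dtype=np.int64)
        self.n = np.asarray(n, dtype=np.int64)
        self.outcome = outcome
        if np.any(self.Y > self.n) or np.any(self.Y < 0):
            raise ValueError("need 0 <= Y <= n elementwise")
        expect = tuple(self.spec.span_length(a) for a in self.spec.axes)
        got = self.Y.shape
        if len(got) != len(expect) or got != expect:
            raise ValueError(f"count shape {got} does not match axes {self.spec.axes} spans {expect}")

    @classmethod
    def from_table(
        cls,
        table: AgeOutcomeTable | JointAgeOutcomeTable,
        outcome: str,
        sd_bounds: tuple[float, float] = (0.0, 10.0),
    ) -> "AgeRiskModel":
        if isinstance(table, JointAgeOutcomeTable):
            spec = ModelSpec(
                axes=("maternal", "paternal"),
                spans=(
                    ("maternal", (int(table.maternal_ages[0]), int(table.maternal_ages[-1]))),
                    ("paternal", (int(table.paternal_ages[0]), int(table.paternal_ages[-1]))),
                ),
                sd_bounds=sd_bounds,
            )
        else:
            spec = ModelSpec(
                axes=(table.axis,),
                spans=((table.axis, (int(table.ages[0]), int(table.ages[-1]))),
                       ({"maternal": "paternal", "paternal": "maternal"}[table.axis],
                        _DEFAULT_SPANS[{"maternal": "paternal", "paternal": "maternal"}[table.axis]])),
                sd_bounds=sd_bounds,
            )
        return cls(table.Y[outcome], table.n_for(outcome), spec=spec, outcome=outcome)

    @classmethod
    def from_cohort(
        cls,
        cohort: BirthCohort,
        outcome: str,
        axes: tuple[str, ...] = ("maternal",),
        sd_bounds: tuple[float, float] = (0.0, 10.0),
    ) -> "AgeRiskModel":
        if len(axes) == 2:
            table = tabulate_joint(cohort, outcomes=(outcome,))
        else:
            table = tabulate_by_age(cohort, axes[0], outcomes=(outcome,))
        return cls.from_table(table, outcome, sd_bounds=sd_bounds)

    def loglike(self, alpha: float, effects: dict[str, np.ndarray]) -> float:
        """Binomial-logit log likelihood at the given parameter values."""
        return engine.binomial_logit_loglik(
            self.Y, self.n, alpha, [effects[a] for a in self.spec.axes]
        )

    def fit(self, config: MCMCConfig | None = None) -> "AgeRiskResults":
        from .results import AgeRiskResults

        config = config or MCMCConfig()
        draws = engine.sample_posterior(self.spec, self.Y, self.n, config)
        return AgeRiskResults(model=self, draws=draws)
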