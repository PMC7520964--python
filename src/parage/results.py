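"""Results object and convergence diagnostics (split R-hat, ESS)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AgeRiskModel, PosteriorDraws


@dataclass
class ConvergenceReport:
    """Split-R-hat and effective sample size per parameter."""

    rhat: dict[str, float]
    ess: dict[str, float]
    threshold: float
    converged: bool

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.rhat), "rhat": list(self.rhat.values()), "ess": [self.ess[k] for k in self.rhat]}
        )


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_draws) matrix.

    Each chain is split in half; R-hat compares between- and within-half
    variance.  A constant parameter returns 1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    chains = chains - chains.mean()  # exact zeros for constant parameters
    c, n = chains.shape
    half = n // 2
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, N = seqs.shape
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    W = variances.mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (N - 1) / N * W + B_over_n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Multi-chain ESS with Geyer's initial-positive-sequence truncation."""
    chains = np.asarray(chains, dtype=float)
    c, n = chains.shape
    if n < 4:
        return float(c * n)
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return float(c * n)
    B_over_n = chains.mean(axis=1).var(ddof=1) if c > 1 else 0.0
    var_plus = (n - 1) / n * W + B_over_n

    # mean autocovariance across chains via FFT
    acov = np.zeros(n)
    for x in chains:
        xd = x - x.mean()
        f = np.fft.rfft(xd, 2 * n)
        acov += np.fft.irfft(f * np.conj(f), 2 * n)[:n].real / n
    acov /= c

    rho = 1.0 - (W - acov) / var_plus
    # Geyer: sum consecutive pairs while the pair sum stays positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(c * n, c * n / tau))


def compute_rhat(draws: PosteriorDraws, threshold: float = 1.05) -> ConvergenceReport:
    """Convergence report over all parameters of a multi-chain run.

    Requires at least 2 chains and 10 draws per chain; with a single chain
    the split halves would come from the same trajectory and the statistic
    loses its between-chain meaning, so that is an error.
    """
    if draws.n_chains < 2:
        raise ValueError("split R-hat needs n_chains >= 2; rerun with more chains")
    if draws.n_draws < 10:
        raise ValueError("need at least 10 draws per chain")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name in draws.parameter_names():
        m = draws.parameter_chains(name)
        rhat[name] = split_rhat(m)
        ess[name] = effective_sample_size(m)
    converged = max(rhat.values()) < threshold
    return ConvergenceReport(rhat=rhat, ess=ess, threshold=threshold, converged=converged)


class AgeRiskResults:
    """Posterior of an :class:`AgeRiskModel` fit.

    Wraps the draws and exposes the quantities reported for each outcome:
    standardized OR curves, pairwise ORs between ages, U/J-shape
    classification, convergence diagnostics and a text summary.
    """

    def __init__(self, model: AgeRiskModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def outcome(self) -> str | None:
        return self.model.outcome

    def _axis(self, axis: str | None) -> str:
        axes = self.draws.spec.axes
        if axis is None:
            if len(axes) != 1:
                raise ValueError("axis must be named for a joint model")
            return axes[0]
        if axis not in axes:
            raise ValueError(f"axis {axis!r} not in model axes {axes}")
        return axis

    def or_curve(self, axis: str | None = None, reference_age: int = 15, source: str | None = None):
        from .curves import or_curve

        return or_curve(self.draws, self._axis(axis), reference_age, source=source, outcome=self.outcome)

    def pairwise_or(self, age_a: int, age_b: int, axis: str | None = None):
        from .curves import pairwise_or

        return pairwise_or(self.draws, self._axis(axis), age_a, age_b, outcome=self.outcome)

    def classify_shape(self, axis: str | None = None, alpha_level: float = 0.05):
        from .shapes import classify_shape

        return classify_shape(self.draws, self._axis(axis), alpha_level=alpha_level)

    def convergence(self, threshold: float = 1.05) -> ConvergenceReport:
        return compute_rhat(self.draws, threshold=threshold)

    def posterior_table(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per parameter."""
        rows = []
        for name in self.draws.parameter_names():
            v = self.draws.parameter_chains(name).reshape(-1)
            lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
            rows.append((name, v.mean(), v.std(ddof=1), lo, med, hi))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "q2.5", "median", "q97.5"])

    def summary(self, max_rows: int = 12) -> str:
        tab = self.posterior_table()
        try:
            conv = self.convergence()
            conv_line = f"max split-Rhat {conv.max_rhat:.3f} ({'converged' if conv.converged else 'NOT converged'})"
        except ValueError:
            conv_line = "convergence: n/a (single chain)"
        head = [
            "Parental-age risk model"
            + (f" — outcome {self.outcome!r}" if self.outcome else ""),
            f"axes: {', '.join(self.draws.spec.axes)}; "
            f"chains: {self.draws.n_chains} x {self.draws.n_draws} draws "
            f"(burn-in {self.draws.config.burn_in}, thin {self.draws.config.thin})",
            conv_line,
            "",
        ]
        show = pd.concat([tab.head(max_rows // 2), tab.tail(max_rows // 2)]) if len(tab) > max_rows else tab
        return "\n".join(head) + show.to_string(index=False, float_format=lambda x: f"{x:.4f}")
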