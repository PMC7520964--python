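"""Dense-quadrature posterior oracle for tiny fixtures.

Independent of the MCMC code path: integrates the binomial-logit RW1
posterior (random-walk SD held fixed) on a tensor grid over the
sum-to-zero-constrained parameter space.  Only spans of up to 4 ages are
accepted — the grid is exponential in the span length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class GridSpec:
    """Quadrature grid: points per dimension and half-width in posterior SDs."""

    n_points: int = 41
    half_width_sd: float = 6.0


@dataclass
class OracleMoments:
    """Posterior means/SDs of alpha and the (sum-to-zero) effects, plus a
    discretization-error estimate from a coarser companion grid."""

    mean_alpha: float
    sd_alpha: float
    mean_effects: np.ndarray
    sd_effects: np.ndarray
    error_estimate: float

    def as_dict(self) -> dict[str, float]:
        d = {"alpha": self.mean_alpha}
        for i, m in enumerate(self.mean_effects):
            d[f"effect[{i}]"] = float(m)
        return d


def _log_post_points(theta: np.ndarray, Y: np.ndarray, n: np.ndarray, sd: float) -> np.ndarray:
    """Vectorized log posterior at points (M, K): columns alpha, e_1..e_{K-1}."""
    K = Y.size
    alpha = theta[:, 0]
    u = theta[:, 1:]
    e = np.concatenate([u, -u.sum(axis=1, keepdims=True)], axis=1)  # sum-to-zero
    eta = alpha[:, None] + e
    ll = (Y[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta)).sum(axis=1)
    inc = np.diff(e, axis=1)
    return ll - 0.5 * (inc * inc).sum(axis=1) / (sd * sd)


def _moments_on_grid(Y, n, sd, center, widths, n_points):
    K = Y.size
    d = K  # alpha + (K-1) free effects
    axes = [np.linspace(center[i] - widths[i], center[i] + widths[i], n_points) for i in range(d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.reshape(-1) for m in mesh], axis=1)
    lp = np.empty(len(pts))
    chunk = 400_000
    for s in range(0, len(pts), chunk):
        lp[s : s + chunk] = _log_post_points(pts[s : s + chunk], Y, n, sd)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    means = w @ pts
    second = w @ (pts * pts)
    sds = np.sqrt(np.maximum(second - means**2, 0.0))
    # full effect vector including the constrained last element
    e_mean = np.concatenate([means[1:], [-means[1:].sum()]])
    u = pts[:, 1:]
    last = -u.sum(axis=1)
    e_last_sd = np.sqrt(max(w @ (last * last) - (w @ last) ** 2, 0.0))
    e_sd = np.concatenate([sds[1:], [e_last_sd]])
    return means[0], sds[0], e_mean, e_sd


def grid_posterior_oracle(
    Y,
    n,
    fixed_sd: float,
    grid_spec: GridSpec | None = None,
) -> OracleMoments:
    """Posterior moments by dense numerical quadrature (<= 4 ages, one axis).

    The grid is centred on the posterior mode (found by quasi-Newton
    optimization) and spans ``half_width_sd`` Laplace standard deviations
    in each direction.  The error estimate is the largest absolute change
    in any reported moment when the grid is thinned to roughly half the
    points per dimension — refining the grid should shrink it.
    """
    Y = np.asarray(Y, dtype=float).reshape(-1)
    n = np.asarray(n, dtype=float).reshape(-1)
    if Y.size > 4:
        raise ValueError("grid oracle refuses spans longer than 4 ages (combinatorial blow-up)")
    if np.any(Y > n) or np.any(Y < 0):
        raise ValueError("need 0 <= Y <= n elementwise")
    if fixed_sd <= 0:
        raise ValueError("fixed_sd must be positive")
    gs = grid_spec or GridSpec()

    d = Y.size

    def neg(theta):
        return -_log_post_points(theta[None, :], Y, n, fixed_sd)[0]

    x0 = np.zeros(d)
    ytot, ntot = Y.sum(), n.sum()
    if ntot > 0:
        x0[0] = np.log((ytot + 0.5) / (ntot - ytot + 0.5))
    res = optimize.minimize(neg, x0, method="BFGS")
    center = res.x
    cov = res.hess_inv if isinstance(res.hess_inv, np.ndarray) else res.hess_inv.todense()
    lap_sd = np.sqrt(np.maximum(np.diag(np.asarray(cov)), 1e-8))
    widths = gs.half_width_sd * lap_sd

    fine = _moments_on_grid(Y, n, fixed_sd, center, widths, gs.n_points)
    coarse_n = max(9, gs.n_points // 2 + 1)
    coarse = _moments_on_grid(Y, n, fixed_sd, center, widths, coarse_n)
    err = max(
        abs(fine[0] - coarse[0]),
        float(np.max(np.abs(fine[2] - coarse[2]))),
        abs(fine[1] - coarse[1]),
        float(np.max(np.abs(fine[3] - coarse[3]))),
    )
    return OracleMoments(
        mean_alpha=float(fine[0]),
        sd_alpha=float(fine[1]),
        mean_effects=fine[2],
        sd_effects=fine[3],
        error_estimate=float(err),
    )
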