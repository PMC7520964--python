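"""Binomial-logit likelihood, RW1 (intrinsic CAR) prior, and the sampler.

The model for a single outcome is

    Y_c ~ Binomial(n_c, mu_c),   logit(mu_c) = alpha + sum_axes effect[age_c]

with a flat improper prior on the intercept alpha, a first-order
random-walk prior on each axis's per-age effect vector (squared adjacent
differences penalized, scale sd), and a Uniform(lo, hi) hyperprior on each
sd (default (0, 10)).  Effects are identified by recentring each axis's
vector to sum to zero after every sweep, with the removed mean absorbed
into alpha; odds ratios standardized to a reference age are invariant to
this choice.

The sampler is single-site adaptive Metropolis-within-Gibbs.  Sites of a
random-walk vector are updated in an even/odd checkerboard order so each
coloured block can be proposed and accepted element-wise with vectorized
arithmetic while remaining exactly a sequence of single-site updates (the
RW1 prior couples only adjacent sites, which sit in the other colour).
Proposal scales adapt during burn-in only, targeting 0.44 acceptance, and
are frozen afterwards so the retained chain is Markovian.

Two auxiliary Metropolis moves per axis supplement the single-site sweep,
both cheap and both needed for healthy mixing of the weakly identified
directions of an intrinsic random-walk field:

* a *rescale* move proposing ``(sd, effects) -> (g*sd, g*effects)`` about
  the effect mean with log-normal ``g`` — the RW1 prior exponent is
  invariant under this map, so in data-free regions the hyperprior scale
  mixes freely instead of creeping behind the effect field;
* a *spectral* move perturbing the effect vector along one discrete-cosine
  eigenvector of the RW1 precision, with proposal scale proportional to
  the prior standard deviation ``sd / (2 sin(pi m / 2K))`` of that mode —
  this refreshes the slow long-wavelength modes (e.g. age spans with few
  births) that single-site updates relax only diffusively.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rw_log_prior", "binomial_logit_loglik", "sample_posterior"]


def rw_log_prior(effects: np.ndarray, sd: float, sd_bounds: tuple[float, float] = (0.0, 10.0)) -> float:
    """Log density of the RW1 prior on an effect vector, up to a constant.

    Returns ``(K-1) * (-log sd) - sum(diff(effects)^2) / (2 sd^2)`` for a
    span of length K; ``-inf`` when ``sd`` falls outside ``sd_bounds``
    (a rejected state, not an exception).
    """
    lo, hi = sd_bounds
    if not (lo < sd < hi):
        return -np.inf
    effects = np.asarray(effects, dtype=float)
    inc = np.diff(effects)
    K = effects.size
    return -(K - 1) * np.log(sd) - 0.5 * float(inc @ inc) / (sd * sd)


def binomial_logit_loglik(Y, n, alpha: float, effects) -> float:
    """Binomial log likelihood with the binomial coefficients omitted.

    ``Y`` and ``n`` are count arrays over one axis (1-D) or the joint age
    grid (2-D); ``effects`` is the matching sequence of per-axis effect
    vectors (an empty sequence fits an intercept-only model).  Cells with
    n = 0 contribute zero.
    """
    Y = np.asarray(Y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(Y > n) or np.any(Y < 0):
        raise ValueError("need 0 <= Y <= n elementwise")
    effects = [np.asarray(e, dtype=float) for e in effects]
    if len(effects) != Y.ndim and not (Y.ndim == 1 and len(effects) == 0):
        raise ValueError("one effect vector per table axis is required")
    eta = np.full_like(Y, float(alpha))
    if len(effects) >= 1:
        eta += effects[0] if Y.ndim == 1 else effects[0][:, None]
    if len(effects) == 2:
        eta += effects[1][None, :]
    return float((Y * eta - n * np.logaddexp(0.0, eta)).sum())


class _AxisBlocks:
    """Precomputed checkerboard blocks and nonzero cells for one axis."""

    def __init__(self, Y: np.ndarray, n: np.ndarray, along_rows: bool):
        # Work with the axis being updated laid out as rows.
        A = Y if along_rows else Y.T
        N = n if along_rows else n.T
        self.K = A.shape[0]
        self.blocks = []
        for parity in (0, 1):
            idx = np.arange(parity, self.K, 2)
            rows_nz = [np.nonzero(N[i] > 0)[0] for i in idx]
            local = np.concatenate([np.full(len(c), j) for j, c in enumerate(rows_nz)]) if idx.size else np.empty(0, int)
            cols = np.concatenate(rows_nz) if idx.size else np.empty(0, int)
            self.blocks.append(
                dict(
                    idx=idx,
                    has_left=idx > 0,
                    has_right=idx < self.K - 1,
                    local=local.astype(np.intp),
                    cols=cols.astype(np.intp),
                    Yc=A[idx.repeat([len(c) for c in rows_nz]), cols].astype(float) if cols.size else np.empty(0),
                    nc=N[idx.repeat([len(c) for c in rows_nz]), cols].astype(float) if cols.size else np.empty(0),
                )
            )


def _block_ll(block, vals, other, alpha):
    """Per-site log likelihood for a coloured block given site values."""
    if block["cols"].size == 0:
        return np.zeros(block["idx"].size)
    eta = alpha + vals[block["local"]] + other[block["cols"]]
    contrib = block["Yc"] * eta - block["nc"] * np.logaddexp(0.0, eta)
    return np.bincount(block["local"], weights=contrib, minlength=block["idx"].size)


def _sd_init(chain: int, n_chains: int, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return lo + (chain + 1) / (n_chains + 1) * (hi - lo)


def _run_chain(Y, n, axes, sd_bounds, cfg, seed_seq, chain_idx, alpha0):
    """One MCMC chain; returns stored draws and post-burn-in acceptance rates."""
    rng = np.random.default_rng(seed_seq)
    two = len(axes) == 2
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    n2 = n if n.ndim == 2 else n[:, None]
    K = [Y2.shape[0]] + ([Y2.shape[1]] if two else [])
    eff = [np.zeros(k) for k in K]
    sds = [_sd_init(chain_idx, cfg.n_chains, sd_bounds) for _ in K]
    alpha = alpha0 + 2.0 * chain_idx * (-1.0) ** chain_idx
    lo, hi = sd_bounds

    blocks = [_AxisBlocks(Y2, n2, along_rows=True)]
    if two:
        blocks.append(_AxisBlocks(Y2, n2, along_rows=False))
    zeros1 = np.zeros(1)

    # cells with n > 0, flattened, for the intercept update
    nz = np.nonzero(n2 > 0)
    Ynz, nnz = Y2[nz].astype(float), n2[nz].astype(float)
    rnz, cnz = nz
    Ysum = float(Ynz.sum())

    scales = [np.full(k, 0.3) for k in K]
    s_alpha = 0.1
    s_sd = [0.5 for _ in K]
    s_resc = [0.5 for _ in K]
    s_mode = [1.0 for _ in K]
    # DCT-II eigvectors/eigenvalue roots of the RW1 precision, per axis
    modes = []
    for k in K:
        if k >= 2:
            i = np.arange(k)
            V = np.cos(np.pi * np.arange(1, k)[:, None] * (i[None, :] + 0.5) / k)
            lam = 2.0 * np.sin(np.pi * np.arange(1, k) / (2.0 * k))
            modes.append((V, lam))
        else:
            modes.append(None)
    target = cfg.target_acceptance

    def full_ll(a_, e0_, e1_):
        if Ynz.size == 0:
            return 0.0
        eta = a_ + e0_[rnz] + (e1_[cnz] if two else 0.0)
        return float((Ynz * eta - nnz * np.logaddexp(0.0, eta)).sum())

    n_keep = cfg.iterations // cfg.thin
    out_alpha = np.empty(n_keep)
    out_eff = [np.empty((n_keep, k)) for k in K]
    out_sd = [np.empty(n_keep) for _ in K]

    acc = {f"effects[{axes[a]}]": 0 for a in range(len(K))}
    acc["alpha"] = 0
    for a in range(len(K)):
        acc[f"sd[{axes[a]}]"] = 0
        acc[f"rescale[{axes[a]}]"] = 0
        acc[f"mode[{axes[a]}]"] = 0
    att = {key: 0 for key in acc}

    # burn-in adaptation bookkeeping
    batch = 50
    b_acc = [np.zeros(k) for k in K]
    b_alpha = 0
    b_sd = [0 for _ in K]
    b_resc = [0 for _ in K]
    b_mode = [0 for _ in K]
    n_batches = 0

    total = cfg.burn_in + cfg.iterations
    kept = 0
    for it in range(total):
        in_burn = it < cfg.burn_in
        # --- effect sites, checkerboard within each axis ---
        for a, bl in enumerate(blocks):
            e = eff[a]
            other = eff[1 - a] if two else zeros1
            sd2 = 2.0 * sds[a] * sds[a]
            for block in bl.blocks:
                idx = block["idx"]
                cur = e[idx]
                prop = cur + scales[a][idx] * rng.standard_normal(idx.size)
                ll_old = _block_ll(block, cur, other, alpha)
                ll_new = _block_ll(block, prop, other, alpha)
                dpr = np.zeros(idx.size)
                hl, hr = block["has_left"], block["has_right"]
                left = e[idx[hl] - 1]
                dpr[hl] -= (prop[hl] - left) ** 2 - (cur[hl] - left) ** 2
                right = e[idx[hr] + 1]
                dpr[hr] -= (right - prop[hr]) ** 2 - (right - cur[hr]) ** 2
                ok = np.log(rng.random(idx.size)) < ll_new - ll_old + dpr / sd2
                e[idx[ok]] = prop[ok]
                if in_burn:
                    b_acc[a][idx[ok]] += 1
                else:
                    acc[f"effects[{axes[a]}]"] += int(ok.sum())
                    att[f"effects[{axes[a]}]"] += idx.size

        # one batch of scalar randomness for the remaining moves this sweep
        z = rng.standard_normal(7)
        logu = np.log(rng.random(7))
        e1cur = eff[1] if two else zeros1
        ll_cur = full_ll(alpha, eff[0], e1cur)

        # --- intercept (flat prior) ---
        delta = s_alpha * z[0]
        ll_new = full_ll(alpha + delta, eff[0], e1cur)
        if logu[0] < ll_new - ll_cur:
            alpha += delta
            ll_cur = ll_new
            if in_burn:
                b_alpha += 1
            else:
                acc["alpha"] += 1
        if not in_burn:
            att["alpha"] += 1

        # --- random-walk SDs, log-scale proposal, hard bounds ---
        for a in range(len(K)):
            inc = np.diff(eff[a])
            ss = float(inc @ inc)
            sd_new = sds[a] * np.exp(s_sd[a] * z[1 + a])
            if lo < sd_new < hi:
                k1 = K[a] - 1
                logr = (
                    -k1 * np.log(sd_new) - 0.5 * ss / (sd_new * sd_new)
                    + k1 * np.log(sds[a]) + 0.5 * ss / (sds[a] * sds[a])
                    + np.log(sd_new) - np.log(sds[a])  # log-scale proposal Jacobian
                )
                if logu[1 + a] < logr:
                    sds[a] = sd_new
                    if in_burn:
                        b_sd[a] += 1
                    else:
                        acc[f"sd[{axes[a]}]"] += 1
            if not in_burn:
                att[f"sd[{axes[a]}]"] += 1

        # --- auxiliary moves: rescale and spectral refresh per axis ---
        for a in range(len(K)):
            e = eff[a]
            other = eff[1 - a] if two else zeros1

            # (sd, centered effects) -> (g*sd, g*centered effects)
            g = np.exp(s_resc[a] * z[3 + a])
            sd_new = sds[a] * g
            if lo < sd_new < hi:
                mu = e.mean()
                e_new = mu + g * (e - mu)
                en0, en1 = (e_new, other) if a == 0 else (other, e_new)
                ll_new = full_ll(alpha, en0, en1)
                # prior exponent invariant; Jacobian K*log g minus prior (K-1)*log g
                if logu[3 + a] < ll_new - ll_cur + np.log(g):
                    eff[a] = e_new
                    sds[a] = sd_new
                    ll_cur = ll_new
                    if in_burn:
                        b_resc[a] += 1
                    else:
                        acc[f"rescale[{axes[a]}]"] += 1
            if not in_burn:
                att[f"rescale[{axes[a]}]"] += 1

            if modes[a] is None:
                continue
            V, lam = modes[a]
            m = int(rng.integers(K[a] - 1))
            c = s_mode[a] * (sds[a] / lam[m]) * rng.standard_normal()
            e = eff[a]
            e_new = e + c * V[m]
            inc_o = np.diff(e)
            inc_n = np.diff(e_new)
            dpr = -0.5 * (float(inc_n @ inc_n) - float(inc_o @ inc_o)) / (sds[a] * sds[a])
            en0, en1 = (e_new, other) if a == 0 else (other, e_new)
            ll_new = full_ll(alpha, en0, en1)
            if logu[5 + a] < ll_new - ll_cur + dpr:
                eff[a] = e_new
                ll_cur = ll_new
                if in_burn:
                    b_mode[a] += 1
                else:
                    acc[f"mode[{axes[a]}]"] += 1
            if not in_burn:
                att[f"mode[{axes[a]}]"] += 1

        # --- recentre: sum-to-zero per axis, mean absorbed into alpha ---
        for a in range(len(K)):
            m = eff[a].mean()
            eff[a] -= m
            alpha += m

        # --- proposal-scale adaptation, burn-in only ---
        if in_burn and cfg.adapt_during_burn_in and (it + 1) % batch == 0:
            n_batches += 1
            step = min(0.25, 1.0 / np.sqrt(n_batches))
            for a in range(len(K)):
                # each site is attempted once per sweep
                rate = b_acc[a] / batch
                scales[a] *= np.exp(step * np.where(rate > target, 1.0, -1.0))
                b_acc[a][:] = 0
                r = b_sd[a] / batch
                s_sd[a] *= np.exp(step * (1.0 if r > target else -1.0))
                b_sd[a] = 0
                s_resc[a] *= np.exp(step * (1.0 if b_resc[a] / batch > target else -1.0))
                b_resc[a] = 0
                s_mode[a] *= np.exp(step * (1.0 if b_mode[a] / batch > target else -1.0))
                b_mode[a] = 0
            s_alpha *= np.exp(step * (1.0 if b_alpha / batch > target else -1.0))
            b_alpha = 0

        if not in_burn and (it - cfg.burn_in + 1) % cfg.thin == 0:
            out_alpha[kept] = alpha
            for a in range(len(K)):
                out_eff[a][kept] = eff[a]
                out_sd[a][kept] = sds[a]
            kept += 1

    rates = {k: (acc[k] / att[k] if att[k] else np.nan) for k in acc}
    return out_alpha, out_eff, out_sd, rates


def sample_posterior(model_spec, Y, n, mcmc_config):
    """Draw from the posterior of the binomial-logit RW1 model.

    ``Y``/``n`` are count arrays matching ``model_spec.axes`` (1-D for one
    axis, 2-D maternal x paternal otherwise).  Returns a
    :class:`~parage.model.PosteriorDraws`.  Fully reproducible from
    ``mcmc_config.seed``.  An all-zero ``n`` is legal: the posterior is
    then the prior.
    """
    from .model import PosteriorDraws

    Y = np.asarray(Y, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(Y > n) or np.any(Y < 0):
        raise ValueError("need 0 <= Y <= n elementwise")
    axes = model_spec.axes
    expect = tuple(model_spec.span_length(a) for a in axes)
    got = Y.shape if len(axes) == 2 else (Y.shape[0],)
    if Y.ndim != len(axes) or got != expect:
        raise ValueError(f"count array shape {Y.shape} does not match axes {axes} spans {expect}")

    ytot, ntot = float(Y.sum()), float(n.sum())
    alpha0 = 0.0 if ntot == 0 else float(np.log((ytot + 0.5) / (ntot - ytot + 0.5)))

    seqs = np.random.SeedSequence(mcmc_config.seed).spawn(mcmc_config.n_chains)
    alphas, effects, sds, rates = [], [], [], []
    for c in range(mcmc_config.n_chains):
        a, e, s, r = _run_chain(Y, n, axes, model_spec.sd_bounds, mcmc_config, seqs[c], c, alpha0)
        alphas.append(a)
        effects.append(e)
        sds.append(s)
        rates.append(r)

    return PosteriorDraws(
        spec=model_spec,
        config=mcmc_config,
        alpha=np.stack(alphas),
        effects={ax: np.stack([effects[c][a] for c in range(mcmc_config.n_chains)]) for a, ax in enumerate(axes)},
        sd={ax: np.stack([sds[c][a] for c in range(mcmc_config.n_chains)]) for a, ax in enumerate(axes)},
        acceptance=rates,
    )
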