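"""Adaptive random-walk Metropolis sampler for the psychometric posterior.

Component-wise Gaussian proposals on transformed coordinates: a scaled logit
for the bounded parameters (m, floor, ceiling, relative to their prior
intervals) and a log for the slope scale w. Proposal step sizes adapt by
Robbins-Monro toward a target acceptance rate during warmup only and are
frozen afterwards, so the retained chain is Markov. Everything is driven by
one seeded generator: identical inputs give identical draws.

Convergence is summarised by split-R-hat and effective sample size (arviz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .psychometric import (
    PARAM_NAMES,
    ChoiceDataset,
    PriorSpec,
    log_likelihood_theta,
)

__all__ = ["SamplerConfig", "PosteriorDraws", "sample_posterior", "diagnostics"]

RHAT_LIMIT = 1.05
ESS_LIMIT = 400.0


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 2000
    thin: int = 2
    target_accept: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (required for split-R-hat)")
        if self.n_draws < 1 or self.n_warmup < 0 or self.thin < 1:
            raise ValueError("n_draws >= 1, n_warmup >= 0 and thin >= 1 required")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass(frozen=True)
class PosteriorDraws:
    """Posterior samples of (m, w, floor, ceiling) with per-draw diagnostics.

    ``draws`` has shape (n_chains, n_draws, 4); ``log_posterior`` and
    ``deviance`` align with it. ``proposal_scales`` are the frozen post-warmup
    step sizes (per chain, per parameter); ``proposal_scales_final`` must
    equal them, witnessing that no adaptation happened after warmup.
    """

    draws: np.ndarray
    log_posterior: np.ndarray
    deviance: np.ndarray
    accept_rate: np.ndarray
    proposal_scales: np.ndarray
    proposal_scales_final: np.ndarray
    config: SamplerConfig
    warnings: tuple = ()
    param_names: tuple = PARAM_NAMES

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        return self.draws[..., self.param_names.index(name)].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        posterior = {
            name: self.draws[..., i] for i, name in enumerate(self.param_names)
        }
        return az.from_dict(posterior=posterior)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for i, name in enumerate(self.param_names):
            x = self.draws[..., i].reshape(-1)
            rows[name] = {
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "median": np.median(x),
                "q5": np.quantile(x, 0.05),
                "q95": np.quantile(x, 0.95),
            }
        return pd.DataFrame(rows).T[["mean", "sd", "median", "q5", "q95"]]

    def to_dataframe(self) -> pd.DataFrame:
        c, d, _ = self.draws.shape
        chain = np.repeat(np.arange(c), d)
        it = np.tile(np.arange(d), c)
        flat = self.draws.reshape(c * d, 4)
        return pd.DataFrame(
            {
                "chain": chain,
                "iter": it,
                "m": flat[:, 0],
                "w": flat[:, 1],
                "floor": flat[:, 2],
                "ceiling": flat[:, 3],
                "log_post": self.log_posterior.reshape(-1),
                "deviance": self.deviance.reshape(-1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class _Transform:
    """Bijection between the open prior box and unconstrained coordinates."""

    def __init__(self, prior: PriorSpec):
        self.lo = prior.lows()
        self.hi = prior.highs()
        self.width = self.hi - self.lo
        # component 1 (w) uses log coordinates, the rest scaled logit
        self.is_log = np.array([False, True, False, False])

    def to_z(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = np.clip((x - self.lo) / self.width, 1e-12, 1.0 - 1e-12)
        z = np.log(u) - np.log1p(-u)
        return np.where(self.is_log, np.log(np.clip(x, 1e-300, None)), z)

    def to_x(self, z: np.ndarray) -> np.ndarray:
        x = self.lo + self.width * expit(z)
        return np.where(self.is_log, np.exp(np.clip(z, None, 700.0)), x)

    def log_jacobian(self, z: np.ndarray) -> np.ndarray:
        # log |d x / d z| summed over components, overflow-safe
        logit_term = np.log(self.width) - np.logaddexp(0.0, -z) - np.logaddexp(0.0, z)
        per_comp = np.where(self.is_log, z, logit_term)
        return per_comp.sum(axis=-1)


def _grid_map_estimate(data: ChoiceDataset, prior: PriorSpec, n_points: int = 11) -> np.ndarray:
    """Maximum-posterior point on a coarse grid strictly inside the prior box."""
    lo, hi = prior.lows(), prior.highs()
    axes = []
    for i, name in enumerate(PARAM_NAMES):
        pad = 0.5 / n_points * (hi[i] - lo[i])
        if name == "w":
            axes.append(np.geomspace(lo[i] + pad * 0.1, hi[i] - pad, n_points))
        else:
            axes.append(np.linspace(lo[i] + pad, hi[i] - pad, n_points))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    ll = log_likelihood_theta(grid, data)
    return grid[int(np.argmax(ll))]


def _logpost_x(theta: np.ndarray, data: ChoiceDataset, prior: PriorSpec) -> np.ndarray:
    inside = prior.contains(theta)
    ll = log_likelihood_theta(theta, data)
    return np.where(inside, ll + prior.log_density_inside, -np.inf)


def sample_posterior(
    data: ChoiceDataset,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of the four psychometric parameters.

    All chains run in lockstep (vectorised across chains); each iteration
    updates the four components in turn with Gaussian proposals in the
    transformed space. Returns the post-warmup draws, thinned, with
    log-posterior and deviance recomputed per retained draw.
    """
    prior = prior or PriorSpec()
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    tr = _Transform(prior)
    C = config.n_chains

    warnings = []
    if not data.is_empty and data.is_degenerate:
        warnings.append(
            "degenerate data: every level is all-risky or all-safe; "
            "the posterior may be dominated by the prior"
        )

    x0 = _grid_map_estimate(data, prior)
    z0 = tr.to_z(x0)
    z = None
    for _ in range(100):
        cand = z0 + 0.1 * rng.standard_normal((C, 4))
        lp = _logpost_x(tr.to_x(cand), data, prior) + tr.log_jacobian(cand)
        if np.all(np.isfinite(lp)):
            z, logp = cand, lp
            break
    if z is None:
        raise RuntimeError(
            "could not find finite initial log-posterior after 100 seeded restarts"
        )

    log_scale = np.full((C, 4), math.log(0.5))
    n_keep = config.n_draws
    total_iters = config.n_warmup + n_keep * config.thin
    out = np.empty((C, n_keep, 4))
    accept_post = np.zeros(4)
    scales_frozen = None
    keep_idx = 0

    for t in range(total_iters):
        warm = t < config.n_warmup
        if not warm and scales_frozen is None:
            scales_frozen = np.exp(log_scale).copy()
        for j in range(4):
            step = np.exp(log_scale[:, j])
            z_prop = z.copy()
            z_prop[:, j] = z[:, j] + step * rng.standard_normal(C)
            lp_prop = _logpost_x(tr.to_x(z_prop), data, prior) + tr.log_jacobian(z_prop)
            accept = np.log(rng.random(C)) < lp_prop - logp
            z[accept] = z_prop[accept]
            logp = np.where(accept, lp_prop, logp)
            if warm:
                gamma = (t + 1) ** -0.6
                log_scale[:, j] += gamma * (accept.astype(float) - config.target_accept)
            else:
                accept_post[j] += accept.mean()
        if not warm and (t - config.n_warmup + 1) % config.thin == 0:
            out[:, keep_idx, :] = tr.to_x(z)
            keep_idx += 1

    if scales_frozen is None:  # n_warmup covers everything only if n_draws == 0, guarded above
        scales_frozen = np.exp(log_scale).copy()
    accept_rate = accept_post / (n_keep * config.thin)

    ll = log_likelihood_theta(out, data)
    dev = -2.0 * ll
    log_post = ll + prior.log_density_inside
    return PosteriorDraws(
        draws=out,
        log_posterior=log_post,
        deviance=dev,
        accept_rate=accept_rate,
        proposal_scales=scales_frozen,
        proposal_scales_final=np.exp(log_scale).copy(),
        config=config,
        warnings=tuple(warnings),
    )


def diagnostics(draws: PosteriorDraws) -> dict:
    """Split-R-hat, bulk ESS and acceptance rate per parameter.

    Flags a convergence failure when any R-hat exceeds 1.05 or any ESS falls
    below 400.
    """
    if draws.n_chains < 2:
        raise ValueError("diagnostics require n_chains >= 2; rerun with more chains")
    idata = draws.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    per_param = {}
    failed = []
    for i, name in enumerate(draws.param_names):
        r = float(rhat[name].values)
        e = float(ess[name].values)
        per_param[name] = {
            "rhat": r,
            "ess": e,
            "accept_rate": float(draws.accept_rate[i]),
        }
        if r > RHAT_LIMIT or e < ESS_LIMIT:
            failed.append(name)
    return {
        "parameters": per_param,
        "converged": not failed,
        "failed_parameters": failed,
        "max_rhat": max(v["rhat"] for v in per_param.values()),
        "min_ess": min(v["ess"] for v in per_param.values()),
    }
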