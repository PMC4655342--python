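"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation: exact rational arithmetic for the mid-P enumeration,
dense-grid numerical integration for the posterior, per-trial products for
the likelihood, and explicit normal-equations least squares for the ANOVA.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

from riskshift.psychometric import ChoiceDataset, PriorSpec


def midp_fraction_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided mid-P by exhaustive enumeration in exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    total = Fraction(0)
    for p in pmf.values():
        if p < p_obs:
            total += p
        elif p == p_obs:
            total += Fraction(p, 2)
    return total


def per_trial_loglik_oracle(params, data: ChoiceDataset) -> float:
    """Bernoulli log-likelihood summed one simulated trial at a time."""
    from riskshift.psychometric import psi

    total = 0.0
    for p, k, n in zip(data.p, data.k, data.n):
        prob = psi(params, float(p))
        for _ in range(int(k)):
            total += math.log(prob)
        for _ in range(int(n - k)):
            total += math.log(1.0 - prob)
    return total


def grid_posterior(
    data: ChoiceDataset,
    prior: PriorSpec,
    n_m: int = 60,
    n_w: int = 40,
    n_f: int = 30,
    n_c: int = 30,
):
    """Dense-grid integration of the 4-D posterior over the prior box.

    Returns (axes, cell_probs) where cell_probs is the normalised posterior
    mass per grid cell, shape (n_m, n_w, n_f, n_c). Midpoint rule on a
    uniform grid per axis; with a flat prior the cell probability is
    proportional to the likelihood at the cell midpoint.
    """
    from scipy.special import logsumexp, xlogy, expit

    lo, hi = prior.lows(), prior.highs()

    def axis(i, n):
        edges = np.linspace(lo[i], hi[i], n + 1)
        return (edges[:-1] + edges[1:]) / 2.0

    m_ax, w_ax, f_ax, c_ax = axis(0, n_m), axis(1, n_w), axis(2, n_f), axis(3, n_c)
    logpost = np.empty((n_m, n_w, n_f, n_c))
    p = data.p
    k = data.k.astype(float)
    nk = (data.n - data.k).astype(float)
    for i, m in enumerate(m_ax):
        # (w, f, c, level) for this m slice
        z = (p[None, None, None, :] - m) / w_ax[:, None, None, None]
        s = expit(z)
        prob = (
            f_ax[None, :, None, None]
            + (c_ax[None, None, :, None] - f_ax[None, :, None, None]) * s
        )
        ll = xlogy(k, prob) + xlogy(nk, 1.0 - prob)
        logpost[i] = ll.sum(axis=-1)
    logpost -= logsumexp(logpost)
    return (m_ax, w_ax, f_ax, c_ax), np.exp(logpost)


def grid_m_marginal(data, prior, **kw):
    axes, probs = grid_posterior(data, prior, **kw)
    return axes[0], probs.sum(axis=(1, 2, 3))


def tv_distance_binned(m_draws: np.ndarray, m_axis: np.ndarray, m_marg: np.ndarray,
                       n_bins: int = 10) -> float:
    """Total variation between MCMC draws and the grid marginal of m,
    on equal-mass bins defined by the grid marginal's quantiles."""
    cdf = np.concatenate([[0.0], np.cumsum(m_marg)])
    half = m_axis[1] - m_axis[0]
    edges_axis = np.concatenate([[m_axis[0] - half / 2], m_axis + half / 2])
    targets = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    cut = np.interp(targets, cdf / cdf[-1], edges_axis)
    edges = np.concatenate([[-np.inf], cut, [np.inf]])
    grid_mass = np.diff(np.interp(
        np.concatenate([[edges_axis[0]], cut, [edges_axis[-1]]]),
        edges_axis, cdf / cdf[-1],
    ))
    draw_mass, _ = np.histogram(m_draws, bins=edges)
    draw_mass = draw_mass / m_draws.size
    return 0.5 * float(np.abs(grid_mass - draw_mass).sum())


def grid_summaries(axes, probs):
    """Posterior mean and 5/95% quantiles per parameter from a grid posterior."""
    out = {}
    names = ("m", "w", "floor", "ceiling")
    for i, name in enumerate(names):
        other = tuple(j for j in range(4) if j != i)
        marg = probs.sum(axis=other)
        ax = axes[i]
        mean = float((ax * marg).sum())
        cdf = np.cumsum(marg)
        q5 = float(np.interp(0.05, cdf, ax))
        q95 = float(np.interp(0.95, cdf, ax))
        out[name] = {"mean": mean, "q5": q5, "q95": q95}
    return out


# ---------------------------------------------------------------------------
# Type II ANOVA via explicit nested least squares


def _factor_columns(values: np.ndarray) -> np.ndarray:
    """Treatment (drop-first) dummy coding, one column per non-reference level."""
    levels = np.unique(values)
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]])


def _term_columns(df, factors):
    cols = None
    for f in factors:
        block = _factor_columns(df[f].to_numpy())
        if cols is None:
            cols = block
        else:
            cols = np.concatenate(
                [cols[:, i : i + 1] * block for i in range(cols.shape[1])], axis=1
            )
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def type2_anova_oracle(df, response="rt_ms", factors=("condition", "choice", "cue_prob")):
    """Type II sums of squares by brute-force comparison of nested models.

    For each term T, the reduced model contains every term that does not
    include T; SS(T) is the drop in residual sum of squares when T joins it.
    F uses the full model's residual mean square.
    """
    terms = []
    for r in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, r))
    y = df[response].to_numpy(float)
    n = y.size
    ones = np.ones((n, 1))
    col_cache = {t: _term_columns(df, t) for t in terms}

    def model_matrix(term_set):
        blocks = [ones] + [col_cache[t] for t in term_set]
        return np.concatenate(blocks, axis=1)

    full_terms = list(terms)
    rss_full = _rss(model_matrix(full_terms), y)
    df_model = {t: col_cache[t].shape[1] for t in terms}
    df_resid = n - 1 - sum(df_model.values())
    ms_resid = rss_full / df_resid

    rows = {}
    for t in terms:
        others = [u for u in terms if not set(t) <= set(u)]
        rss_without = _rss(model_matrix(others), y)
        rss_with = _rss(model_matrix(others + [t]), y)
        ss = rss_without - rss_with
        f_stat = (ss / df_model[t]) / ms_resid
        rows[t] = {"sum_sq": ss, "df": df_model[t], "F": f_stat}
    rows["Residual"] = {"sum_sq": rss_full, "df": df_resid, "F": np.nan}
    return rows
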