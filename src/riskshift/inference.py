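"""Condition-wise psychometric fits and threshold-shift inference.

Each stimulation condition is fitted independently. Fit quality is screened
with a posterior-predictive check built on a chi-square style discrepancy
over levels; non-monotonic choice patterns (which the logistic model cannot
produce) drive the predictive p toward zero and are classified as poor fits
or, at an extreme, unfittable. The stimulation effect is summarised by the
posterior distribution of the threshold difference m_on - m_off over a
seeded random pairing of independent posterior draws; P(m_on < m_off) is the
posterior probability of a left shift, i.e. of increased risk-seeking under
stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometric import ChoiceDataset, PriorSpec, psi_theta
from .sampler import PosteriorDraws, SamplerConfig, diagnostics, sample_posterior
from .simulate import TrialRecord

__all__ = [
    "FitResult",
    "ShiftSummary",
    "ShiftReport",
    "choice_dataset_from_records",
    "fit_condition",
    "posterior_predictive_check",
    "threshold_shift",
]

PPC_POOR_FIT = 0.05
PPC_UNFITTABLE = 0.005


def choice_dataset_from_records(
    records: list[TrialRecord], condition: str | None = None
) -> ChoiceDataset:
    """Aggregate trials into per-level counts, excluding omissions."""
    rows = [
        r
        for r in records
        if r.choice != "omit" and (condition is None or r.condition == condition)
    ]
    if not rows:
        return ChoiceDataset.empty()
    levels = sorted({r.cue_probability for r in rows})
    k = np.array(
        [sum(1 for r in rows if r.cue_probability == p and r.choice == "risky") for p in levels],
        dtype=np.int64,
    )
    n = np.array(
        [sum(1 for r in rows if r.cue_probability == p) for p in levels], dtype=np.int64
    )
    return ChoiceDataset(np.array(levels), k, n)


@dataclass(frozen=True)
class FitResult:
    """Posterior fit of one condition with its quality classification."""

    condition: str
    draws: PosteriorDraws
    data: ChoiceDataset
    status: str  # ok | poor_fit | unfittable
    ppc_pvalue: float
    diagnostics: dict
    summary: pd.DataFrame

    @property
    def m_draws(self) -> np.ndarray:
        return self.draws.flat("m")


def _discrepancy(k: np.ndarray, n: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """Chi-square style distance between counts and model expectation.

    ``prob`` has shape (draws, levels); ``k``/``n`` broadcast against it.
    """
    expected = n * prob
    var = n * prob * (1.0 - prob)
    var = np.clip(var, 1e-12, None)
    return ((k - expected) ** 2 / var).sum(axis=-1)


def posterior_predictive_check(
    draws: PosteriorDraws, data: ChoiceDataset, seed: int = 0, n_rep: int = 500
) -> float:
    """P(T_rep >= T_obs) for the chi-square discrepancy over posterior draws.

    For each of ``n_rep`` subsampled posterior draws, counts are replicated
    from the fitted binomial model and the discrepancy of the replicate is
    compared with that of the observed counts under the same draw.
    """
    if data.is_empty:
        return 1.0
    rng = np.random.default_rng(seed)
    flat = draws.draws.reshape(-1, 4)
    idx = rng.choice(flat.shape[0], size=min(n_rep, flat.shape[0]), replace=False)
    theta = flat[idx]
    prob = psi_theta(theta, data.p)  # (n_rep, levels)
    t_obs = _discrepancy(data.k, data.n, prob)
    k_rep = rng.binomial(data.n, prob)
    t_rep = _discrepancy(k_rep, data.n, prob)
    return float(np.mean(t_rep >= t_obs))


def classify_fit(ppc_pvalue: float, converged: bool) -> str:
    if ppc_pvalue < PPC_UNFITTABLE:
        return "unfittable"
    if ppc_pvalue < PPC_POOR_FIT or not converged:
        return "poor_fit"
    return "ok"


def fit_condition(
    records: list[TrialRecord],
    condition: str,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    ppc_seed: int | None = None,
) -> FitResult:
    """Fit the psychometric model to one condition's responded trials."""
    data = choice_dataset_from_records(records, condition)
    if data.is_empty:
        raise ValueError(f"no responded trials in condition {condition!r}")
    prior = prior or PriorSpec()
    config = config or SamplerConfig()
    draws = sample_posterior(data, prior, config)
    diag = diagnostics(draws)
    if ppc_seed is None:
        ppc_seed = (config.seed + 0x5F5E) % (2**31)
    ppc = posterior_predictive_check(draws, data, seed=ppc_seed)
    status = classify_fit(ppc, diag["converged"])
    return FitResult(
        condition=condition,
        draws=draws,
        data=data,
        status=status,
        ppc_pvalue=ppc,
        diagnostics=diag,
        summary=draws.summary(),
    )


@dataclass(frozen=True)
class ShiftSummary:
    """Posterior summary of the threshold difference m_on - m_off."""

    delta_m: np.ndarray
    mean: float
    q5: float
    q95: float
    prob_left_shift: float
    available: bool
    flags: tuple = ()

    @classmethod
    def unavailable(cls, flags=()) -> "ShiftSummary":
        return cls(
            delta_m=np.empty(0),
            mean=float("nan"),
            q5=float("nan"),
            q95=float("nan"),
            prob_left_shift=float("nan"),
            available=False,
            flags=tuple(flags),
        )


def threshold_shift(fit_off: FitResult, fit_on: FitResult, seed: int = 0) -> ShiftSummary:
    """Posterior of m_on - m_off over a seeded pairing of independent draws.

    The two fits' threshold draws are independently permuted and paired,
    giving draws from the product posterior. prob_left_shift = P(delta < 0).
    Raises no error for poorly fitting conditions but flags them; only when
    both conditions are unfittable is the shift marked unavailable.
    """
    flags = [
        f"{fit.condition}_fit_{fit.status}"
        for fit in (fit_off, fit_on)
        if fit.status != "ok"
    ]
    if fit_off.status == "unfittable" and fit_on.status == "unfittable":
        return ShiftSummary.unavailable(flags)
    rng = np.random.default_rng(seed)
    m_off = fit_off.m_draws
    m_on = fit_on.m_draws
    n = min(m_off.size, m_on.size)
    delta = m_on[rng.permutation(m_on.size)[:n]] - m_off[rng.permutation(m_off.size)[:n]]
    return ShiftSummary(
        delta_m=delta,
        mean=float(delta.mean()),
        q5=float(np.quantile(delta, 0.05)),
        q95=float(np.quantile(delta, 0.95)),
        prob_left_shift=float(np.mean(delta < 0.0)),
        available=True,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class ShiftReport:
    """Complete per-session inference output."""

    shift: ShiftSummary
    fit_off: FitResult
    fit_on: FitResult
    level_tests: pd.DataFrame
    anova: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def fit_block(fit: FitResult) -> dict:
            return {
                "condition": fit.condition,
                "status": fit.status,
                "ppc_pvalue": fit.ppc_pvalue,
                "posterior_summary": {
                    name: {k: float(v) for k, v in row.items()}
                    for name, row in fit.summary.iterrows()
                },
                "diagnostics": {
                    "converged": fit.diagnostics["converged"],
                    "max_rhat": fit.diagnostics["max_rhat"],
                    "min_ess": fit.diagnostics["min_ess"],
                },
            }

        level_rows = []
        for level, row in self.level_tests.iterrows():
            level_rows.append(
                {
                    "cue_prob": float(level),
                    "off_risky": int(row["off_risky"]),
                    "off_safe": int(row["off_safe"]),
                    "on_risky": int(row["on_risky"]),
                    "on_safe": int(row["on_safe"]),
                    "midp": None if pd.isna(row["midp"]) else float(row["midp"]),
                    "tier": row["tier"],
                    "testable": bool(row["testable"]),
                }
            )
        anova_rows = {
            effect: {
                "sum_sq": float(row["sum_sq"]),
                "df": float(row["df"]),
                "F": None if pd.isna(row["F"]) else float(row["F"]),
                "p": None if pd.isna(row["PR(>F)"]) else float(row["PR(>F)"]),
            }
            for effect, row in self.anova.iterrows()
        }
        return {
            "schema_version": 1,
            "metadata": self.metadata,
            "threshold_shift": {
                "available": self.shift.available,
                "mean": None if not self.shift.available else self.shift.mean,
                "q5": None if not self.shift.available else self.shift.q5,
                "q95": None if not self.shift.available else self.shift.q95,
                "prob_left_shift": None
                if not self.shift.available
                else self.shift.prob_left_shift,
                "flags": list(self.shift.flags),
            },
            "fits": {"off": fit_block(self.fit_off), "on": fit_block(self.fit_on)},
            "per_level_tests": level_rows,
            "rt_anova": anova_rows,
        }
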