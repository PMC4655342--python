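"""Exact mid-P Fisher tests per risk level and the reaction-time ANOVA.

The per-level test asks whether stimulation changed the risky/safe split at
one cue probability, via Fisher's exact test with a two-sided P estimated by
the mid-P method: the hypergeometric distribution over all 2x2 tables with
the observed margins is enumerated, tables strictly less probable than the
observed one contribute their full probability and tables equally probable
contribute half. Mid-P reduces the conservatism of the conventional exact
test while keeping the enumeration exact.

Reaction times from responded trials are modelled with a fixed-effects
full-factorial ANOVA in stimulation condition, choice and reward-probability
level (all categorical), with Type II sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import hypergeom

from .simulate import TrialRecord, records_to_frame

__all__ = [
    "ContingencyTable2x2",
    "MidPResult",
    "fisher_midp",
    "per_level_tests",
    "rt_anova",
]

# relative tolerance deciding when two hypergeometric point probabilities
# count as tied for the half-weight rule
_TIE_RTOL = 1e-12

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b (off: risky, safe) over c,d (on: risky, safe)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self):
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class MidPResult:
    pvalue: float
    degenerate: bool


def fisher_midp(table: ContingencyTable2x2) -> MidPResult:
    """Two-sided mid-P value for a 2x2 table with fixed margins.

    Orders the conditional (hypergeometric) support by point probability;
    the mid-P is the total probability of tables strictly less probable than
    the observed one plus half the probability of those tied with it. A zero
    row or column margin leaves a single admissible table, reported as the
    degenerate mid-P of 0.5.
    """
    r1, r2, c1, _ = table.margins
    n_total = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n_total:
        return MidPResult(0.5, degenerate=True)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n_total, r1, c1)
    p_obs = pmf[int(table.a - support[0])]
    tied = np.isclose(pmf, p_obs, rtol=_TIE_RTOL, atol=0.0)
    less = (pmf < p_obs) & ~tied
    midp = float(pmf[less].sum() + 0.5 * pmf[tied].sum())
    return MidPResult(min(max(midp, 0.0), 1.0), degenerate=False)


def significance_tier(p: float) -> str:
    """Star tier by strict inequality: *** < 0.001, ** < 0.01, * < 0.05."""
    for cutoff, stars in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return stars
    return ""


def per_level_tests(records: list[TrialRecord]) -> pd.DataFrame:
    """Mid-P Fisher test of the stimulation effect at every probability level.

    Omissions are excluded. Levels with no responded trials in one condition
    are flagged untestable (mid-P reported as NaN).
    """
    df = records_to_frame(records)
    if set(df["condition"].unique()) != {"off", "on"}:
        raise ValueError("per-level tests require trials from both conditions")
    responded = df[df["choice"] != "omit"]
    rows = []
    for level, grp in responded.groupby("cue_prob"):
        counts = {
            (cond, choice): int(
                ((grp["condition"] == cond) & (grp["choice"] == choice)).sum()
            )
            for cond in ("off", "on")
            for choice in ("risky", "safe")
        }
        a, b = counts[("off", "risky")], counts[("off", "safe")]
        c, d = counts[("on", "risky")], counts[("on", "safe")]
        if a + b == 0 or c + d == 0:
            rows.append(
                {
                    "cue_prob": level,
                    "off_risky": a,
                    "off_safe": b,
                    "on_risky": c,
                    "on_safe": d,
                    "midp": np.nan,
                    "tier": "",
                    "testable": False,
                    "degenerate": False,
                }
            )
            continue
        res = fisher_midp(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "cue_prob": level,
                "off_risky": a,
                "off_safe": b,
                "on_risky": c,
                "on_safe": d,
                "midp": res.pvalue,
                "tier": significance_tier(res.pvalue),
                "testable": True,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("cue_prob")


_ANOVA_FORMULA = "rt_ms ~ C(condition) * C(choice) * C(cue_prob)"

_EFFECT_LABELS = {
    "C(condition)": "stimulation",
    "C(choice)": "choice",
    "C(cue_prob)": "probability",
    "C(condition):C(choice)": "stimulation:choice",
    "C(condition):C(cue_prob)": "stimulation:probability",
    "C(choice):C(cue_prob)": "choice:probability",
    "C(condition):C(choice):C(cue_prob)": "stimulation:choice:probability",
}


def rt_anova(records: list[TrialRecord]) -> pd.DataFrame:
    """Full-factorial Type II ANOVA of reaction time.

    Factors: stimulation condition, choice (risky/safe) and cue probability
    treated as a categorical level. Omissions carry no reaction time and are
    excluded. Constant reaction times are a degenerate input: every effect
    gets zero sum of squares and p = 1.
    """
    df = records_to_frame(records)
    df = df[df["choice"] != "omit"].dropna(subset=["rt_ms"]).copy()
    if df.empty:
        raise ValueError("no responded trials with reaction times")
    for factor, minimum in (("condition", 2), ("choice", 2), ("cue_prob", 2)):
        if df[factor].nunique() < minimum:
            raise ValueError(f"ANOVA requires at least {minimum} levels of {factor}")
    model = smf.ols(_ANOVA_FORMULA, data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the ANOVA")
    table = sm.stats.anova_lm(model, typ=2)
    if np.ptp(df["rt_ms"].to_numpy()) == 0.0:
        table["sum_sq"] = 0.0
        table["F"] = 0.0
        table["PR(>F)"] = 1.0
        resid = table.index == "Residual"
        table.loc[resid, ["F", "PR(>F)"]] = np.nan
    table = table.rename(index=_EFFECT_LABELS)
    table.index.name = "effect"
    return table[["sum_sq", "df", "F", "PR(>F)"]]
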