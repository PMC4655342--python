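"""Synthetic two-alternative forced-choice risk-task sessions.

A session is a sequence of trials in which a colour cue signals the reward
probability of a risky option (large reward or nothing) against a safe
option (small certain reward), under a response deadline. Stimulation is
toggled off/on per block. The simulated agent chooses according to a
four-parameter logistic psychometric function, with separate parameter sets
for the off and on conditions, omits a small fraction of trials, and
responds with log-normal reaction times truncated at the deadline.

The default :class:`SessionDesign` is the study layout this package targets:
960 trials in six blocks of 160, stimulation on in blocks 3 and 5, cue
probabilities {0.1, 0.3, 0.5, 0.7, 0.9}, risky outcome 50 or 0 points, safe
outcome 10 points, 1000 ms deadline. The default agent omits 3.3% of trials
and shows a -0.2 threshold shift under stimulation (greater risk-seeking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .psychometric import PsychometricParams, psi

__all__ = [
    "SessionDesign",
    "AgentParams",
    "TrialRecord",
    "generate_session",
    "summarize_session",
]

CONDITIONS = ("off", "on")
CHOICES = ("risky", "safe", "omit")


@dataclass(frozen=True)
class SessionDesign:
    """Immutable description of the block/trial structure and payoffs."""

    n_blocks: int = 6
    trials_per_block: int = 160
    stim_block_indices: frozenset = frozenset({3, 5})
    probability_levels: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    risky_win_points: int = 50
    risky_loss_points: int = 0
    safe_points: int = 10
    deadline_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one block and one trial per block")
        object.__setattr__(self, "stim_block_indices", frozenset(self.stim_block_indices))
        if not self.stim_block_indices <= set(range(1, self.n_blocks + 1)):
            raise ValueError(
                f"stim_block_indices must be 1-based block indices within "
                f"1..{self.n_blocks}, got {sorted(self.stim_block_indices)}"
            )
        levels = tuple(float(p) for p in self.probability_levels)
        object.__setattr__(self, "probability_levels", levels)
        if not all(0 < p < 1 for p in levels):
            raise ValueError("probability levels must lie strictly in (0, 1)")
        if not all(a < b for a, b in zip(levels, levels[1:])):
            raise ValueError("probability levels must be strictly increasing")
        if min(self.risky_win_points, self.risky_loss_points, self.safe_points) < 0:
            raise ValueError("point values must be nonnegative")
        if self.deadline_ms <= 0:
            raise ValueError("deadline must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_levels(self) -> int:
        return len(self.probability_levels)

    def condition_of_block(self, block: int) -> str:
        return "on" if block in self.stim_block_indices else "off"


def _default_off() -> PsychometricParams:
    return PsychometricParams(m=0.55, w=0.1, floor=0.05, ceiling=0.95)


def _default_on() -> PsychometricParams:
    return PsychometricParams(m=0.35, w=0.1, floor=0.05, ceiling=0.95)


@dataclass(frozen=True)
class AgentParams:
    """Generative agent: psychometric parameters per condition, omissions, RTs.

    ``rt_location_*`` and ``rt_scale`` parameterise a log-normal reaction-time
    law (location/scale on the log-millisecond axis), truncated at the
    deadline.
    """

    params_off: PsychometricParams = field(default_factory=_default_off)
    params_on: PsychometricParams = field(default_factory=_default_on)
    omission_rate: float = 0.033
    rt_location_off: float = math.log(650.0)
    rt_location_on: float = math.log(680.0)
    rt_scale: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.omission_rate < 1.0:
            raise ValueError(f"omission_rate must lie in [0, 1), got {self.omission_rate}")
        if self.rt_scale <= 0:
            raise ValueError("rt_scale must be positive")

    def params_for(self, condition: str) -> PsychometricParams:
        return self.params_on if condition == "on" else self.params_off

    def rt_location_for(self, condition: str) -> float:
        return self.rt_location_on if condition == "on" else self.rt_location_off


@dataclass(frozen=True)
class TrialRecord:
    """One trial: where it sat in the session, what was cued, what happened."""

    block: int
    trial_in_block: int
    condition: str
    cue_probability: float
    choice: str
    outcome_points: int
    rt_ms: float | None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.choice not in CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if (self.rt_ms is None) != (self.choice == "omit"):
            raise ValueError("rt_ms must be absent exactly when the trial is an omission")


def _truncated_lognormal(rng, location, scale, upper, size):
    """Inverse-CDF sampling of exp(N(location, scale)) conditioned on < upper."""
    z_hi = (math.log(upper) - location) / scale
    u = rng.random(size) * norm.cdf(z_hi)
    return np.exp(location + scale * norm.ppf(u))


def generate_session(
    design: SessionDesign, agent: AgentParams, seed: int
) -> list[TrialRecord]:
    """Simulate one full session, deterministically for a given seed.

    Every block contains each probability level equally often in a shuffled
    order (``trials_per_block`` must be divisible by the number of levels).
    Per trial: an independent omission draw, then a Bernoulli choice at the
    condition's psychometric value, a Bernoulli risky outcome at the cued
    probability, and a truncated log-normal reaction time.
    """
    if design.trials_per_block % design.n_levels != 0:
        raise ValueError(
            f"trials_per_block ({design.trials_per_block}) must be divisible by "
            f"the number of probability levels ({design.n_levels}) for a "
            f"balanced design"
        )
    rng = np.random.default_rng(seed)
    reps = design.trials_per_block // design.n_levels
    base_levels = np.repeat(np.asarray(design.probability_levels), reps)

    records: list[TrialRecord] = []
    for block in range(1, design.n_blocks + 1):
        condition = design.condition_of_block(block)
        params = agent.params_for(condition)
        cues = rng.permutation(base_levels)
        omitted = rng.random(design.trials_per_block) < agent.omission_rate
        p_risky = psi(params, cues)
        risky = rng.random(design.trials_per_block) < p_risky
        won = rng.random(design.trials_per_block) < cues
        rts = _truncated_lognormal(
            rng,
            agent.rt_location_for(condition),
            agent.rt_scale,
            design.deadline_ms,
            design.trials_per_block,
        )
        for i in range(design.trials_per_block):
            if omitted[i]:
                choice, outcome, rt = "omit", 0, None
            elif risky[i]:
                choice = "risky"
                outcome = design.risky_win_points if won[i] else design.risky_loss_points
                rt = float(rts[i])
            else:
                choice, outcome, rt = "safe", design.safe_points, float(rts[i])
            records.append(
                TrialRecord(
                    block=block,
                    trial_in_block=i + 1,
                    condition=condition,
                    cue_probability=float(cues[i]),
                    choice=choice,
                    outcome_points=outcome,
                    rt_ms=rt,
                )
            )
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": [r.block for r in records],
            "trial": [r.trial_in_block for r in records],
            "condition": [r.condition for r in records],
            "cue_prob": [r.cue_probability for r in records],
            "choice": [r.choice for r in records],
            "outcome": [r.outcome_points for r in records],
            "rt_ms": [r.rt_ms for r in records],
        }
    )


def summarize_session(records: list[TrialRecord]) -> pd.DataFrame:
    """Per-condition, per-level counts of risky, safe and omitted trials.

    Omissions are tabulated separately and excluded from the risky-choice
    proportion column.
    """
    if not records:
        raise ValueError("cannot summarise an empty session")
    for i, r in enumerate(records):
        if r.condition not in CONDITIONS or r.choice not in CHOICES:
            raise ValueError(f"record {i}: unknown condition/choice labels")
    df = records_to_frame(records)
    table = (
        df.groupby(["condition", "cue_prob"])["choice"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["risky", "safe", "omit"], fill_value=0)
    )
    table.columns = ["n_risky", "n_safe", "n_omit"]
    responded = table["n_risky"] + table["n_safe"]
    with np.errstate(invalid="ignore"):
        table["prop_risky"] = np.where(
            responded > 0, table["n_risky"] / responded, np.nan
        )
    return table
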