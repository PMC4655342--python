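"""Trial-log CSV reading and validation, block partitioning, configuration
and the end-to-end analysis pipeline.

Trial-log dialect (UTF-8, "." decimal separator, header required):

    block,trial,condition,cue_prob,choice,outcome,rt_ms

with condition in {off,on}, choice in {risky,safe,omit} and rt_ms empty for
omissions. All validation errors carry 1-based data row numbers and are
collected and reported together.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .freqtests import per_level_tests, rt_anova
from .inference import ShiftReport, fit_condition, threshold_shift
from .psychometric import PriorSpec, PsychometricParams
from .sampler import SamplerConfig
from .simulate import (
    CHOICES,
    CONDITIONS,
    AgentParams,
    SessionDesign,
    TrialRecord,
    generate_session,
    records_to_frame,
)

__all__ = [
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "partition_by_block",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("riskshift")

CSV_COLUMNS = ["block", "trial", "condition", "cue_prob", "choice", "outcome", "rt_ms"]


class TrialValidationError(ValueError):
    """Raised with the full list of per-row problems in a trial log."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            f"{len(problems)} invalid trial rows:\n" + "\n".join(problems)
        )


def write_trials(records: list[TrialRecord], path) -> None:
    df = records_to_frame(records)
    # shortest round-tripping decimal representation; empty for omissions
    df["rt_ms"] = ["" if r.rt_ms is None else repr(r.rt_ms) for r in records]
    df.to_csv(path, index=False)


def read_trials(path, deadline_ms: float = 1000.0) -> list[TrialRecord]:
    """Read and validate a trial-log CSV; errors name the offending rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial log not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != CSV_COLUMNS:
        raise TrialValidationError(
            [f"header mismatch: expected {CSV_COLUMNS}, got {list(df.columns)}"]
        )
    problems: list[str] = []
    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_problems = []
        if row.condition not in CONDITIONS:
            row_problems.append(f"row {i}: unknown condition {row.condition!r}")
        if row.choice not in CHOICES:
            row_problems.append(f"row {i}: unknown choice {row.choice!r}")
        rt_missing = pd.isna(row.rt_ms)
        if row.choice == "omit" and not rt_missing:
            row_problems.append(f"row {i}: omission must have empty rt_ms")
        if row.choice in ("risky", "safe"):
            if rt_missing:
                row_problems.append(f"row {i}: responded trial missing rt_ms")
            elif not float(row.rt_ms) < deadline_ms:
                row_problems.append(
                    f"row {i}: rt_ms {row.rt_ms} not below the deadline {deadline_ms}"
                )
        if not 0.0 < float(row.cue_prob) < 1.0:
            row_problems.append(f"row {i}: cue_prob {row.cue_prob} outside (0, 1)")
        if row_problems:
            problems.extend(row_problems)
            continue
        records.append(
            TrialRecord(
                block=int(row.block),
                trial_in_block=int(row.trial),
                condition=row.condition,
                cue_probability=float(row.cue_prob),
                choice=row.choice,
                outcome_points=int(row.outcome),
                rt_ms=None if rt_missing else float(row.rt_ms),
            )
        )
    if problems:
        raise TrialValidationError(problems)
    return records


def partition_by_block(records: list[TrialRecord], on_blocks) -> list[TrialRecord]:
    """Relabel the condition column by block membership.

    This reproduces the control-style partition used for unstimulated
    sessions: blocks in ``on_blocks`` become 'on', all others 'off', so the
    full pipeline can run on sessions where no stimulation was delivered.
    """
    on_blocks = set(on_blocks)
    max_block = max(r.block for r in records)
    bad = [b for b in on_blocks if not 1 <= b <= max_block]
    if bad:
        raise ValueError(f"on_blocks {sorted(bad)} outside 1..{max_block}")
    return [
        TrialRecord(
            block=r.block,
            trial_in_block=r.trial_in_block,
            condition="on" if r.block in on_blocks else "off",
            cue_probability=r.cue_probability,
            choice=r.choice,
            outcome_points=r.outcome_points,
            rt_ms=r.rt_ms,
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 1
    design: SessionDesign = field(default_factory=SessionDesign)
    agent: AgentParams = field(default_factory=AgentParams)
    prior: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    input_csv: str | None = None  # when set, analyse this log instead of simulating
    partition_on_blocks: tuple | None = None  # control-style relabelling
    make_figure: bool = False

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "design": {
                "n_blocks": self.design.n_blocks,
                "trials_per_block": self.design.trials_per_block,
                "stim_block_indices": sorted(self.design.stim_block_indices),
                "probability_levels": list(self.design.probability_levels),
                "risky_win_points": self.design.risky_win_points,
                "risky_loss_points": self.design.risky_loss_points,
                "safe_points": self.design.safe_points,
                "deadline_ms": self.design.deadline_ms,
            },
            "agent": {
                "params_off": asdict(self.agent.params_off),
                "params_on": asdict(self.agent.params_on),
                "omission_rate": self.agent.omission_rate,
                "rt_location_off": self.agent.rt_location_off,
                "rt_location_on": self.agent.rt_location_on,
                "rt_scale": self.agent.rt_scale,
            },
            "prior": {k: list(v) for k, v in self.prior.bounds.items()},
            "sampler": asdict(self.sampler),
            "input_csv": self.input_csv,
            "partition_on_blocks": (
                None if self.partition_on_blocks is None else list(self.partition_on_blocks)
            ),
            "make_figure": self.make_figure,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        design = SessionDesign(
            n_blocks=d["design"]["n_blocks"],
            trials_per_block=d["design"]["trials_per_block"],
            stim_block_indices=frozenset(d["design"]["stim_block_indices"]),
            probability_levels=tuple(d["design"]["probability_levels"]),
            risky_win_points=d["design"]["risky_win_points"],
            risky_loss_points=d["design"]["risky_loss_points"],
            safe_points=d["design"]["safe_points"],
            deadline_ms=d["design"]["deadline_ms"],
        )
        agent = AgentParams(
            params_off=PsychometricParams(**d["agent"]["params_off"]),
            params_on=PsychometricParams(**d["agent"]["params_on"]),
            omission_rate=d["agent"]["omission_rate"],
            rt_location_off=d["agent"]["rt_location_off"],
            rt_location_on=d["agent"]["rt_location_on"],
            rt_scale=d["agent"]["rt_scale"],
        )
        prior = PriorSpec({k: tuple(v) for k, v in d["prior"].items()})
        sampler = SamplerConfig(**d["sampler"])
        pob = d.get("partition_on_blocks")
        return cls(
            seed=d["seed"],
            design=design,
            agent=agent,
            prior=prior,
            sampler=sampler,
            input_csv=d.get("input_csv"),
            partition_on_blocks=None if pob is None else tuple(pob),
            make_figure=d.get("make_figure", False),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stage_seeds(master_seed: int, n: int = 6) -> list[int]:
    """Deterministic per-stage seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# pipeline


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig, out_dir) -> ShiftReport:
    """Run simulate/load -> fit both conditions -> shift -> tests -> artifacts.

    Fully deterministic under a fixed config: one master seed derives the
    per-stage seeds. Writes the trial log (when simulated), per-condition
    posterior CSVs, a diagnostics JSON, the ShiftReport JSON and optionally
    a summary figure into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    t0 = time.perf_counter()

    if config.input_csv is not None:
        log.info("stage read: loading %s", config.input_csv)
        records = read_trials(config.input_csv, deadline_ms=config.design.deadline_ms)
        simulated = False
    else:
        log.info("stage simulate: seed %d", seeds[0])
        records = generate_session(config.design, config.agent, seed=seeds[0])
        simulated = True
        write_trials(records, out_dir / "trials.csv")
    if config.partition_on_blocks is not None:
        log.info("stage partition: on blocks %s", sorted(config.partition_on_blocks))
        records = partition_by_block(records, config.partition_on_blocks)

    fits = {}
    for condition, seed in (("off", seeds[1]), ("on", seeds[2])):
        log.info("stage fit[%s]: sampler seed %d", condition, seed)
        cfg = SamplerConfig(
            n_chains=config.sampler.n_chains,
            n_warmup=config.sampler.n_warmup,
            n_draws=config.sampler.n_draws,
            thin=config.sampler.thin,
            target_accept=config.sampler.target_accept,
            seed=seed,
        )
        try:
            fits[condition] = fit_condition(records, condition, config.prior, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage fit[{condition}] failed: {exc}") from exc
        fits[condition].draws.to_csv(out_dir / f"posterior_{condition}.csv")

    log.info("stage shift: seed %d", seeds[3])
    shift = threshold_shift(fits["off"], fits["on"], seed=seeds[3])
    log.info("stage tests")
    try:
        level_tests = per_level_tests(records)
        anova = rt_anova(records)
    except Exception as exc:
        raise RuntimeError(f"stage tests failed: {exc}") from exc

    report = ShiftReport(
        shift=shift,
        fit_off=fits["off"],
        fit_on=fits["on"],
        level_tests=level_tests,
        anova=anova,
        metadata={
            "seed": config.seed,
            "stage_seeds": seeds,
            "simulated": simulated,
            "n_trials": len(records),
        },
    )
    diag = {
        cond: fits[cond].diagnostics for cond in ("off", "on")
    }
    (out_dir / "diagnostics.json").write_text(
        json.dumps(diag, indent=2, sort_keys=True, default=_json_default)
    )
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=_json_default)
    )
    if config.make_figure:
        from .plotting import plot_session

        plot_session(records, fits["off"], fits["on"], level_tests, out_dir / "session.png")
    log.info("pipeline done in %.1f s", time.perf_counter() - t0)
    return report
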