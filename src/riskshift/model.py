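"""Model/Results front-end over the psychometric machinery.

``PsychometricModel`` holds per-level choice data and the prior;
``fit()`` runs the MCMC sampler and returns a ``PsychometricResults``
carrying the posterior draws, their summaries, convergence diagnostics and
goodness-of-fit. ``StimulationComparison`` fits both stimulation conditions
of a session and returns the full :class:`~riskshift.inference.ShiftReport`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .freqtests import per_level_tests, rt_anova
from .inference import (
    FitResult,
    ShiftReport,
    choice_dataset_from_records,
    classify_fit,
    fit_condition,
    posterior_predictive_check,
    threshold_shift,
)
from .psychometric import ChoiceDataset, PriorSpec
from .sampler import SamplerConfig, diagnostics, sample_posterior

__all__ = ["PsychometricModel", "PsychometricResults", "StimulationComparison"]


class PsychometricModel:
    """Four-parameter logistic choice model for one condition's data.

    Parameters
    ----------
    data : ChoiceDataset
        Per-level cue probabilities and risky/responded counts.
    prior : PriorSpec, optional
        Independent uniform priors; defaults are weakly informative.
    """

    def __init__(self, data: ChoiceDataset, prior: PriorSpec | None = None):
        self.data = data
        self.prior = prior or PriorSpec()

    @classmethod
    def from_trials(cls, records, condition: str | None = None,
                    prior: PriorSpec | None = None) -> "PsychometricModel":
        """Build from trial records, aggregating to per-level counts
        (omissions excluded); ``condition`` filters to one stimulation state."""
        return cls(choice_dataset_from_records(records, condition), prior)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, prior: PriorSpec | None = None,
                       p_col: str = "cue_prob", k_col: str = "n_risky",
                       n_col: str = "n_responded") -> "PsychometricModel":
        data = ChoiceDataset(
            df[p_col].to_numpy(float),
            df[k_col].to_numpy(np.int64),
            df[n_col].to_numpy(np.int64),
        )
        return cls(data, prior)

    def fit(self, config: SamplerConfig | None = None, seed: int | None = None,
            ppc_seed: int | None = None) -> "PsychometricResults":
        config = config or SamplerConfig()
        if seed is not None:
            config = SamplerConfig(
                n_chains=config.n_chains, n_warmup=config.n_warmup,
                n_draws=config.n_draws, thin=config.thin,
                target_accept=config.target_accept, seed=seed,
            )
        draws = sample_posterior(self.data, self.prior, config)
        diag = diagnostics(draws)
        if ppc_seed is None:
            ppc_seed = (config.seed + 0x5F5E) % (2**31)
        ppc = posterior_predictive_check(draws, self.data, seed=ppc_seed)
        return PsychometricResults(self, draws, diag, ppc)


class PsychometricResults:
    """Posterior fit results: draws, summaries, diagnostics, fit status."""

    def __init__(self, model: PsychometricModel, draws, diag: dict, ppc_pvalue: float):
        self.model = model
        self.draws = draws
        self.diagnostics = diag
        self.ppc_pvalue = ppc_pvalue
        self.status = classify_fit(ppc_pvalue, diag["converged"])
        table = draws.summary()
        self.params = table["mean"]

    def summary(self) -> pd.DataFrame:
        """Posterior summary table with convergence diagnostics attached."""
        table = self.draws.summary().copy()
        table["rhat"] = [
            self.diagnostics["parameters"][name]["rhat"] for name in table.index
        ]
        table["ess"] = [
            self.diagnostics["parameters"][name]["ess"] for name in table.index
        ]
        return table

    def __repr__(self) -> str:
        return (
            f"<PsychometricResults status={self.status} "
            f"m={self.params['m']:.3f} w={self.params['w']:.3f} "
            f"ppc_p={self.ppc_pvalue:.3f}>"
        )


class StimulationComparison:
    """Off-vs-on analysis of a full session of trial records."""

    def __init__(self, records, prior: PriorSpec | None = None,
                 sampler_config: SamplerConfig | None = None):
        self.records = list(records)
        self.prior = prior or PriorSpec()
        self.sampler_config = sampler_config or SamplerConfig()

    def fit(self, seed: int = 0) -> ShiftReport:
        """Fit both conditions, infer the threshold shift and run the
        frequentist tests; seeds for the two samplers and the draw pairing
        are derived deterministically from ``seed``."""
        seeds = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint64)
        fits: dict[str, FitResult] = {}
        for condition, s in zip(("off", "on"), seeds[:2]):
            cfg = SamplerConfig(
                n_chains=self.sampler_config.n_chains,
                n_warmup=self.sampler_config.n_warmup,
                n_draws=self.sampler_config.n_draws,
                thin=self.sampler_config.thin,
                target_accept=self.sampler_config.target_accept,
                seed=int(s % (2**31)),
            )
            fits[condition] = fit_condition(self.records, condition, self.prior, cfg)
        shift = threshold_shift(fits["off"], fits["on"], seed=int(seeds[2] % (2**31)))
        return ShiftReport(
            shift=shift,
            fit_off=fits["off"],
            fit_on=fits["on"],
            level_tests=per_level_tests(self.records),
            anova=rt_anova(self.records),
            metadata={"seed": seed, "n_trials": len(self.records)},
        )
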