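"""Session summary figure: fitted psychometric curves per condition.

Draws the posterior-mean curve for off (black) and on (red), a spray of
posterior sample curves with opacity decreasing in deviance (worse draws
fade out), the observed per-level risky-choice proportions, and the mid-P
significance stars per level.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import FitResult, choice_dataset_from_records
from .psychometric import PsychometricParams, psi, psi_theta

_COLORS = {"off": "black", "on": "crimson"}


def _spaghetti(ax, fit: FitResult, color: str, n_curves: int = 20, seed: int = 0):
    rng = np.random.default_rng(seed)
    flat = fit.draws.draws.reshape(-1, 4)
    dev = fit.draws.deviance.reshape(-1)
    idx = rng.choice(flat.shape[0], size=min(n_curves, flat.shape[0]), replace=False)
    grid = np.linspace(0.0, 1.0, 101)
    dsel = dev[idx]
    # opacity proportional to (negated, rescaled) deviance: best draw most opaque
    span = dsel.max() - dsel.min()
    alpha = 0.5 * (1.0 - (dsel - dsel.min()) / span) + 0.05 if span > 0 else np.full(dsel.size, 0.3)
    curves = psi_theta(flat[idx], grid)
    for curve, a in zip(curves, alpha):
        ax.plot(grid, curve, color=color, alpha=float(a), lw=0.7)


def plot_session(records, fit_off: FitResult, fit_on: FitResult, level_tests, path):
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    grid = np.linspace(0.0, 1.0, 201)
    for fit in (fit_off, fit_on):
        color = _COLORS[fit.condition]
        _spaghetti(ax, fit, color)
        mean_params = PsychometricParams.from_array(
            fit.draws.draws.reshape(-1, 4).mean(axis=0)
        )
        ax.plot(grid, psi(mean_params, grid), color=color, lw=2.0,
                label=f"{fit.condition} ({fit.status})")
        data = choice_dataset_from_records(records, fit.condition)
        with np.errstate(invalid="ignore"):
            props = data.k / data.n
        ax.scatter(data.p, props, color=color, zorder=5, s=30,
                   edgecolor="white", linewidth=0.5)
    for level, row in level_tests.iterrows():
        if row["tier"]:
            ax.annotate(row["tier"], (level, 1.03), ha="center", fontsize=11)
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.02, 1.08)
    ax.set_xlabel("cued probability of reward on the risky option")
    ax.set_ylabel("P(choose risky)")
    ax.legend(frameon=False, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
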