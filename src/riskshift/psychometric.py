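"""Four-parameter logistic psychometric model of risky choice.

The model maps the cued probability of reward on the risky option, ``p``, to
the probability of choosing it:

    psi(p) = floor + (ceiling - floor) / (1 + exp(-(p - m) / w))

``m`` (threshold) is the reward probability at which the choice probability
sits midway between the asymptotes — lower values mean more risk-seeking.
``w`` is the logistic scale — smaller values mean a sharper transition
(higher risk sensitivity). ``floor`` and ``ceiling`` are probability-
independent biases toward the risky and safe option respectively.

Responded trials are modelled as independent Bernoulli draws; omissions are
not choices and are excluded. All densities are natural-log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, xlogy

__all__ = [
    "PsychometricParams",
    "ChoiceDataset",
    "PriorSpec",
    "psi",
    "log_likelihood",
    "log_posterior",
    "deviance",
]

PARAM_NAMES = ("m", "w", "floor", "ceiling")


@dataclass(frozen=True)
class PsychometricParams:
    """Threshold ``m``, slope scale ``w``, and the two asymptotes.

    Invariants: ``w > 0``, ``0 <= floor < ceiling <= 1``, ``m`` finite.
    """

    m: float
    w: float
    floor: float
    ceiling: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.m):
            raise ValueError("threshold m must be finite")
        if not self.w > 0:
            raise ValueError(f"slope scale w must be positive, got {self.w}")
        if not (0.0 <= self.floor < self.ceiling <= 1.0):
            raise ValueError(
                f"asymptotes must satisfy 0 <= floor < ceiling <= 1, "
                f"got floor={self.floor}, ceiling={self.ceiling}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.w, self.floor, self.ceiling])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "PsychometricParams":
        return cls(*(float(x) for x in theta))


@dataclass(frozen=True)
class ChoiceDataset:
    """Per-level risky-choice counts: cue probability, risky choices, responded trials."""

    p: np.ndarray
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        k = np.atleast_1d(np.asarray(self.k, dtype=np.int64))
        n = np.atleast_1d(np.asarray(self.n, dtype=np.int64))
        if not (p.shape == k.shape == n.shape and p.ndim == 1):
            raise ValueError("p, k, n must be 1-D arrays of equal length")
        if p.size and (np.any(p <= 0) or np.any(p >= 1)):
            raise ValueError("cue probabilities must lie strictly in (0, 1)")
        if np.unique(p).size != p.size:
            raise ValueError("cue probability levels must be distinct")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("counts must satisfy 0 <= k <= n per level")
        order = np.argsort(p)
        object.__setattr__(self, "p", p[order])
        object.__setattr__(self, "k", k[order])
        object.__setattr__(self, "n", n[order])
        self.p.setflags(write=False)
        self.k.setflags(write=False)
        self.n.setflags(write=False)

    @property
    def n_levels(self) -> int:
        return int(self.p.size)

    @property
    def is_empty(self) -> bool:
        return self.p.size == 0 or int(self.n.sum()) == 0

    @property
    def is_degenerate(self) -> bool:
        """True when every level is all-risky or all-safe (no interior count)."""
        return bool(np.all((self.k == 0) | (self.k == self.n)))

    @classmethod
    def empty(cls) -> "ChoiceDataset":
        return cls(np.empty(0), np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))


def _default_bounds() -> dict:
    return {
        "m": (-0.25, 1.25),
        "w": (0.01, 1.0),
        "floor": (0.0, 0.5),
        "ceiling": (0.5, 1.0),
    }


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one ``(low, high)`` interval per parameter.

    The defaults are weakly informative: they keep ``floor < ceiling``
    identifiable by construction and let the threshold sit outside the tested
    cue-probability range, which strongly shifted sessions require.
    """

    bounds: dict = field(default_factory=_default_bounds)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"prior bounds missing for {sorted(missing)}")
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"prior for {name}: need low < high, got ({lo}, {hi})")
        if self.bounds["w"][0] <= 0:
            raise ValueError("prior support for w must be positive")
        if self.bounds["floor"][0] < 0 or self.bounds["ceiling"][1] > 1:
            raise ValueError("asymptote priors must stay within [0, 1]")
        if self.bounds["floor"][1] > self.bounds["ceiling"][0]:
            raise ValueError(
                "floor and ceiling prior supports must not overlap "
                "(floor high must not exceed ceiling low)"
            )

    def lows(self) -> np.ndarray:
        return np.array([self.bounds[name][0] for name in PARAM_NAMES])

    def highs(self) -> np.ndarray:
        return np.array([self.bounds[name][1] for name in PARAM_NAMES])

    @property
    def log_density_inside(self) -> float:
        return -float(np.sum(np.log(self.highs() - self.lows())))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return np.all((theta >= self.lows()) & (theta <= self.highs()), axis=-1)

    def log_density(self, params) -> float:
        theta = params.as_array() if isinstance(params, PsychometricParams) else np.asarray(params)
        return self.log_density_inside if bool(self.contains(theta)) else -math.inf

    def means(self) -> np.ndarray:
        return (self.lows() + self.highs()) / 2.0


def psi(params: PsychometricParams, p):
    """Choice probability at cue probability ``p`` (scalar or array)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("cue probability must lie in [0, 1]")
    out = params.floor + (params.ceiling - params.floor) * expit((p - params.m) / params.w)
    return float(out) if out.ndim == 0 else out


def psi_theta(theta: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised psi for parameter stacks ``theta`` of shape (..., 4)."""
    theta = np.asarray(theta, dtype=float)
    m = theta[..., 0, None]
    w = theta[..., 1, None]
    lo = theta[..., 2, None]
    hi = theta[..., 3, None]
    return lo + (hi - lo) * expit((p - m) / w)


def log_likelihood_theta(theta: np.ndarray, data: ChoiceDataset) -> np.ndarray:
    """Bernoulli log-likelihood for parameter stacks of shape (..., 4)."""
    if data.is_empty:
        shape = np.asarray(theta).shape[:-1]
        return np.zeros(shape) if shape else np.float64(0.0)
    prob = psi_theta(theta, data.p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(data.k, prob) + xlogy(data.n - data.k, 1.0 - prob)
    return np.where(np.isnan(ll), -np.inf, ll).sum(axis=-1)


def log_likelihood(params: PsychometricParams, data: ChoiceDataset) -> float:
    """Sum over levels of k*log(psi) + (n-k)*log(1-psi); 0 for empty data.

    Returns -inf (never raises) when psi is numerically 0 or 1 yet the
    counts disagree with it.
    """
    return float(log_likelihood_theta(params.as_array(), data))


def log_posterior(params: PsychometricParams, data: ChoiceDataset, prior: PriorSpec) -> float:
    lp = prior.log_density(params)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(params, data)


def deviance(params: PsychometricParams, data: ChoiceDataset) -> float:
    """-2 x log-likelihood; nonnegative because each Bernoulli term has density <= 1."""
    return -2.0 * log_likelihood(params, data)
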