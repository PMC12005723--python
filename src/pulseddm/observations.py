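"""Observation models: spike-count likelihoods and lapse-contaminated choices.

Each neuron's conditional intensity is ``softplus(slope * a + theta0(t))``
where ``theta0(t)`` is a time-varying baseline represented on six Gaussian
radial basis functions and fit to trial-average activity before the joint
model is fit.  Spike counts are Poisson (or negative binomial) in each bin;
the binary choice thresholds the terminal accumulator value with a lapse
mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from ._kernels import RATE_FLOOR
from .latent_fp import LatentGrid

__all__ = [
    "NeuronModel",
    "BaselineBasis",
    "ChoiceParams",
    "softplus",
    "rbf_design",
    "fit_baseline",
    "conditional_intensity",
    "poisson_loglik",
    "negbin_loglik",
    "choice_weights",
    "choice_prob",
    "N_RBF",
]

log = logging.getLogger(__name__)

N_RBF = 6


def softplus(x):
    """Numerically stable ``log(1 + exp(x))``."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NeuronModel:
    """Tuning of one neuron: slope, RBF baseline weights, optional dispersion."""

    slope: float
    rbf_weights: np.ndarray
    dispersion: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "rbf_weights", np.asarray(self.rbf_weights, dtype=float))
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class ChoiceParams:
    """Choice criterion ``c`` (clicks) and lapse probability ``gamma``."""

    c: float
    gamma: float

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass(frozen=True)
class BaselineBasis:
    """Six unnormalized Gaussian bumps spanning the trial duration.

    The means are uniform on ``[0, max_duration]`` and the (squared-seconds)
    spread equals the inter-mean spacing, taken literally.
    """

    means: np.ndarray
    variance: float
    dt: float = field(default=0.01)

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Basis matrix of shape ``(len(times), 6)``; peak value 1 at each mean."""
        t = np.asarray(times, dtype=float)[:, None]
        return np.exp(-((t - self.means[None, :]) ** 2) / (2.0 * self.variance))

    def design(self, n_bins: int) -> np.ndarray:
        """Basis matrix evaluated at the spike-bin centers ``0, dt, ..., n_bins*dt``."""
        return self.evaluate(np.arange(n_bins + 1) * self.dt)


def rbf_design(max_duration: float, dt: float) -> BaselineBasis:
    if max_duration <= 0:
        raise ValueError("max_duration must be positive")
    means = np.linspace(0.0, max_duration, N_RBF)
    return BaselineBasis(means=means, variance=float(means[1] - means[0]), dt=dt)


def fit_baseline(
    counts: list[np.ndarray],
    exposures: list[np.ndarray],
    basis: BaselineBasis,
    linear_intensity: bool = False,
) -> np.ndarray:
    """Maximum-likelihood RBF weights for one neuron's trial-average rate.

    Parameters
    ----------
    counts:
        Per-trial spike-count vectors (ragged lengths allowed) on the
        half-offset spike bins.
    exposures:
        Matching per-trial observation-window lengths in seconds.
    linear_intensity:
        If True the intensity is the clamped-linear ``max(theta0, floor)``
        instead of the default ``softplus(theta0)``.

    Returns the fitted weight vector ``w`` such that
    ``theta0(t) = sum_i w_i RBF_i(t)``.
    """
    if not counts:
        raise ValueError("need at least one trial")
    X = [basis.design(len(y) - 1) for y in counts]
    ys = [np.asarray(y, dtype=float) for y in counts]
    es = [np.asarray(e, dtype=float) for e in exposures]
    total = sum(float(y.sum()) for y in ys)
    if total == 0:
        log.warning("fit_baseline: neuron has no spikes; intensity driven to floor")

    def nll(w):
        val = 0.0
        grad = np.zeros(N_RBF)
        for Xi, y, e in zip(X, ys, es):
            arg = Xi @ w
            if linear_intensity:
                rate = np.maximum(arg, RATE_FLOOR)
                drate = (arg > RATE_FLOOR).astype(float)
            else:
                rate = np.maximum(softplus(arg), RATE_FLOOR)
                drate = 1.0 / (1.0 + np.exp(-np.clip(arg, -500, 500)))
            ok = e > 0
            mu = rate * e
            val -= float(y[ok] @ np.log(mu[ok]) - mu[ok].sum())
            coef = np.where(ok, (mu - y) / rate * drate, 0.0)
            grad += Xi.T @ coef
        return val, grad

    # moment-matched start: softplus(theta0) ~ overall mean rate
    mean_rate = max(total / max(sum(float(e.sum()) for e in es), 1e-12), 1e-3)
    w0 = np.full(N_RBF, np.log(np.expm1(mean_rate)) if mean_rate > 1e-8 else -10.0)
    res = minimize(nll, w0, jac=True, method="L-BFGS-B")
    return res.x


def conditional_intensity(a, slope: float, theta0_t) -> np.ndarray:
    """Firing rate (Hz) ``softplus(slope * a + theta0)``, floored at 1e-6 Hz."""
    return np.maximum(softplus(slope * np.asarray(a, dtype=float) + theta0_t), RATE_FLOOR)


def poisson_loglik(y, rate, dt: float):
    """Full Poisson log-pmf of count ``y`` at intensity ``rate`` over ``dt`` s."""
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer) and np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer count")
    y = y.astype(float)
    mu = np.asarray(rate, dtype=float) * dt
    out = y * np.log(mu) - mu - gammaln(y + 1.0)
    return out if out.ndim else float(out)


def negbin_loglik(y, rate, dispersion: float, dt: float):
    """Negative-binomial log-pmf with mean ``rate*dt`` and shape ``dispersion``."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("y must be a non-negative integer count")
    y = y.astype(float)
    mu = np.asarray(rate, dtype=float) * dt
    th = dispersion
    out = (
        gammaln(y + th) - gammaln(th) - gammaln(y + 1.0)
        + th * np.log(th / (mu + th)) + y * np.log(mu / (mu + th))
    )
    return out if out.ndim else float(out)


def choice_weights(grid: LatentGrid, c: float, gamma: float) -> np.ndarray:
    """Per-bin probability of a rightward choice, ``P(d=R | a in bin i)``.

    Interior bins are treated as boxes of width ``grid.width``: the fraction
    of the box above the criterion enters the Heaviside term, which makes the
    choice probability continuous in ``c`` and resolves an exact tie
    (``center == c``) as 1/2.  Bound bins are point masses at ``+/-B`` (an
    exact tie there is also 1/2).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    centers = grid.centers
    h = np.empty(grid.n)
    half = grid.width / 2.0
    for i, x in enumerate(centers):
        if i == 0 or i == grid.n - 1:
            h[i] = 0.5 if x == c else (1.0 if x > c else 0.0)
        else:
            h[i] = np.clip((x + half - c) / grid.width, 0.0, 1.0)
    return gamma / 2.0 + (1.0 - gamma) * h


def choice_prob(pT: np.ndarray, grid: LatentGrid, c: float, gamma: float) -> float:
    """P(choose right) given the terminal latent distribution."""
    pT = np.asarray(pT, dtype=float)
    return float(pT @ choice_weights(grid, c, gamma))
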