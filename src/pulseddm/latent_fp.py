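"""Discretized Fokker-Planck propagation of the bounded accumulator.

The latent accumulator ``a(t)`` follows a linear SDE with leak ``lambda``,
diffusive noise ``sigma_a^2`` per second, click-driven impulses ``Delta_t``
with click noise ``sigma_s^2`` per unit adapted click, and a symmetric
absorbing bound at ``+/- B``.  The probability distribution over ``a`` is
discretized on an odd-sized uniform grid whose outer bins sit exactly at the
bounds and absorb all mass that reaches them; one time step is a
column-stochastic Markov operator built by exact deterministic drift plus a
settled Gaussian spread.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .stimulus import BinnedStimulus

__all__ = [
    "AccumulatorParams",
    "LatentGrid",
    "make_grid",
    "initial_distribution",
    "transition_matrix",
    "propagate",
    "forward_prior",
    "DEFAULT_N_BINS",
    "DEFAULT_DT",
    "DEFAULT_REFINE",
]

DEFAULT_N_BINS = 53
DEFAULT_DT = 0.01
DEFAULT_REFINE = 10


@dataclass(frozen=True)
class AccumulatorParams:
    """The seven latent-dynamics parameters.

    Attributes
    ----------
    sigma2_i : initial variance of a(0) (clicks^2)
    B        : absorbing bound magnitude (clicks)
    lam      : leak (<0) / instability (>0) rate (1/s)
    sigma2_a : diffusion variance rate (clicks^2 / s)
    sigma2_s : click noise variance per unit adapted click (clicks^2)
    phi      : adaptation strength (unitless, > 0)
    tau_phi  : adaptation recovery timescale (s)
    """

    sigma2_i: float
    B: float
    lam: float
    sigma2_a: float
    sigma2_s: float
    phi: float
    tau_phi: float

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("B must be positive")
        if min(self.sigma2_i, self.sigma2_a, self.sigma2_s) < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.phi <= 0 or self.tau_phi <= 0:
            raise ValueError("phi and tau_phi must be positive")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.sigma2_i, self.B, self.lam, self.sigma2_a, self.sigma2_s,
             self.phi, self.tau_phi]
        )

    @classmethod
    def from_array(cls, x) -> "AccumulatorParams":
        x = np.asarray(x, dtype=float)
        return cls(*x[:7])

    def replace(self, **kw) -> "AccumulatorParams":
        return replace(self, **kw)


PARAM_NAMES = ("sigma2_i", "B", "lam", "sigma2_a", "sigma2_s", "phi", "tau_phi")


@dataclass(frozen=True)
class LatentGrid:
    """Uniform symmetric discretization of the accumulator axis."""

    centers: np.ndarray
    width: float

    @property
    def n(self) -> int:
        return int(self.centers.size)

    @property
    def B(self) -> float:
        return float(self.centers[-1])

    @property
    def bound_bins(self) -> tuple[int, int]:
        return (0, self.n - 1)


def make_grid(B: float, n: int = DEFAULT_N_BINS) -> LatentGrid:
    """Build the latent grid: ``n`` uniform bins with centers from -B to +B.

    ``n`` must be odd (so a bin center sits exactly at zero) and at least 5.
    The outer bins are the absorbing bound bins.
    """
    if n % 2 == 0 or n < 5:
        raise ValueError("n must be odd and >= 5")
    if B <= 0:
        raise ValueError("B must be positive")
    centers = np.linspace(-B, B, n)
    return LatentGrid(centers=centers, width=2.0 * B / (n - 1))


def initial_distribution(
    sigma2_i: float, grid: LatentGrid, refine: int = DEFAULT_REFINE
) -> np.ndarray:
    """Zero-mean Gaussian initial mass settled onto the grid."""
    if sigma2_i < 0:
        raise ValueError("sigma2_i must be non-negative")
    return _kernels.initial_dist(grid.centers, grid.width, sigma2_i, refine)


def transition_matrix(
    theta_a: AccumulatorParams,
    delta_t: float,
    sigma_t: float,
    dt: float,
    grid: LatentGrid,
    refine: int = DEFAULT_REFINE,
) -> np.ndarray:
    """One-step mass-transfer operator for a bin with adapted click inputs.

    Column ``j`` is the destination distribution of unit mass starting at
    ``centers[j]``; the outer columns are identity (absorption).  Columns sum
    to 1 by construction.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = grid.n
    M = np.empty((n, n))
    tvar = theta_a.sigma2_a * dt + theta_a.sigma2_s * sigma_t
    _kernels.build_transition(
        M, grid.centers, grid.width, theta_a.lam, dt, delta_t, tvar, refine
    )
    return M


def propagate(p: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Advance a state distribution one step: ``p_t = M p_{t-1}``."""
    p = np.asarray(p, dtype=float)
    if M.shape[1] != p.size:
        raise ValueError("dimension mismatch between M and p")
    return M @ p


def forward_prior(
    theta_a: AccumulatorParams,
    stimulus: BinnedStimulus,
    grid: LatentGrid,
    refine: int = DEFAULT_REFINE,
) -> np.ndarray:
    """Latent prior marginals P(a_t) for t = 0 .. T, unconditioned on data.

    Returns a ``(T+1, n)`` array whose rows each sum to 1.
    """
    n = grid.n
    M0 = np.empty((n, n))
    _kernels.build_transition(
        M0, grid.centers, grid.width, theta_a.lam, stimulus.dt, 0.0,
        theta_a.sigma2_a * stimulus.dt, refine,
    )
    p0 = initial_distribution(theta_a.sigma2_i, grid, refine)
    dummy_w = np.zeros((stimulus.n_bins + 1, n))
    dummy_m = np.empty((1, n, n))
    _, alphas = _kernels.forward_filter(
        grid.centers, grid.width, p0, theta_a.lam, stimulus.dt,
        theta_a.sigma2_a * stimulus.dt, theta_a.sigma2_s,
        stimulus.delta, stimulus.sigma, dummy_w, False, refine,
        M0, dummy_m, False,
    )
    return alphas
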