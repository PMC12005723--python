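"""Synthetic session generation and parameter-recovery experiments.

The simulator is deliberately independent of the Fokker-Planck code: latent
trajectories are integrated by fine-step Euler-Maruyama with clicks applied
at their exact times (not binned), so simulator/propagator agreement is a
meaningful cross-check.  Spike counts are drawn per half-offset spike bin
from softplus rates evaluated on the window-averaged path, and choices from
the lapse-threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .inference import FitResult, ModelParams
from .latent_fp import PARAM_NAMES, AccumulatorParams
from .observations import ChoiceParams, softplus
from .session import Neuron, SessionData, Trial
from .stimulus import ClickTrain, n_time_bins, spike_bin_exposures

__all__ = [
    "SimConfig",
    "gen_click_train",
    "simulate_latent",
    "simulate_terminal",
    "simulate_markov_path",
    "simulate_spikes",
    "simulate_choice",
    "make_dataset",
    "recovery_report",
    "PLAUSIBLE_THETA",
]

# physiologically plausible generating parameters used by the recovery harness
PLAUSIBLE_THETA = ModelParams(
    theta_a=AccumulatorParams(
        sigma2_i=2.0, B=15.0, lam=-1.0, sigma2_a=20.0, sigma2_s=1.0,
        phi=0.3, tau_phi=0.05,
    ),
    choice=ChoiceParams(c=0.0, gamma=0.05),
)


@dataclass
class SimConfig:
    """Generation settings for a synthetic session."""

    n_trials: int = 100
    n_neurons: int = 4
    theta_a: AccumulatorParams = field(default_factory=lambda: PLAUSIBLE_THETA.theta_a)
    choice: ChoiceParams = field(default_factory=lambda: PLAUSIBLE_THETA.choice)
    slopes: np.ndarray | None = None  # default: alternating +/-3
    dispersions: np.ndarray | None = None  # None -> Poisson spikes
    baseline_hz: float = 10.0  # a=0 firing rate floor used for theta0
    baseline_mod_hz: float = 5.0  # amplitude of a slow baseline ramp
    total_rate: float = 40.0  # left+right click rate (Hz)
    min_right_frac: float = 0.05
    max_right_frac: float = 0.95
    duration_range: tuple[float, float] = (0.2, 1.0)
    dt: float = 0.01
    sim_step: float = 1e-4
    shared_noise: bool = True  # one accumulator per trial vs one per neuron
    n_sessions: int = 1  # trials are split evenly across sessions
    generator: str = "euler"  # "euler" (fine-step SDE) | "markov" (model-matched)
    grid_bins: int = 53  # latent grid of the markov generator
    refine: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sim_step > self.dt / 10:
            raise ValueError("sim_step must be at most dt/10")
        if self.generator not in ("euler", "markov"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.slopes is None:
            s = np.array([3.0 if i % 2 == 0 else -3.0 for i in range(self.n_neurons)])
            self.slopes = s
        self.slopes = np.asarray(self.slopes, dtype=float)

    def theta0_fn(self, t: np.ndarray) -> np.ndarray:
        """Baseline argument: softplus^-1 of a slow ramp around baseline_hz."""
        rate = self.baseline_hz + self.baseline_mod_hz * np.asarray(t)
        return np.log(np.expm1(np.maximum(rate, 1e-3)))


def gen_click_train(cfg: SimConfig, rng: np.random.Generator) -> ClickTrain:
    """Poisson left/right click trains with a random rate asymmetry."""
    duration = float(rng.uniform(*cfg.duration_range))
    frac = float(rng.uniform(cfg.min_right_frac, cfg.max_right_frac))
    r_right = cfg.total_rate * frac
    r_left = cfg.total_rate * (1.0 - frac)
    n_r = rng.poisson(r_right * duration)
    n_l = rng.poisson(r_left * duration)
    right = np.sort(rng.uniform(0.0, duration, n_r))
    left = np.sort(rng.uniform(0.0, duration, n_l))
    return ClickTrain(left_times=left, right_times=right, duration=duration)


def simulate_latent(
    theta_a: AccumulatorParams,
    train: ClickTrain,
    step: float,
    rng: np.random.Generator,
    n_paths: int = 1,
) -> np.ndarray:
    """Euler-Maruyama paths of the bounded accumulator, clicks at exact times.

    Returns ``(n_paths, n_steps+1)`` samples every ``step`` seconds; the path
    freezes at ``+/-B`` once the bound is crossed (sticky absorption).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    times, sides = train.merged()
    mags = _kernels.adapt_mags_pooled(times, theta_a.phi, theta_a.tau_phi)
    seeds = rng.integers(0, 2**31 - 1, size=n_paths).astype(np.int64)
    return _kernels.simulate_paths(
        times, sides, mags, train.duration, step, n_paths,
        theta_a.sigma2_i, theta_a.B, theta_a.lam, theta_a.sigma2_a,
        theta_a.sigma2_s, seeds,
    )


def simulate_terminal(
    theta_a: AccumulatorParams,
    train: ClickTrain,
    step: float,
    rng: np.random.Generator,
    n_paths: int,
) -> np.ndarray:
    """Terminal values a(T) of Euler-Maruyama paths without storing paths."""
    times, sides = train.merged()
    mags = _kernels.adapt_mags_pooled(times, theta_a.phi, theta_a.tau_phi)
    seeds = rng.integers(0, 2**31 - 1, size=n_paths).astype(np.int64)
    return _kernels.simulate_terminal(
        times, sides, mags, train.duration, step, n_paths,
        theta_a.sigma2_i, theta_a.B, theta_a.lam, theta_a.sigma2_a,
        theta_a.sigma2_s, seeds,
    )


def path_bin_means(path: np.ndarray, step: float, dt: float, duration: float) -> np.ndarray:
    """Average of a fine path within each half-offset spike-bin window."""
    return _kernels.bin_path_means(np.asarray(path, dtype=float), step, dt, duration)


def simulate_spikes(
    path: np.ndarray,
    step: float,
    duration: float,
    slopes: np.ndarray,
    theta0: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    dispersions: np.ndarray | None = None,
) -> np.ndarray:
    """Spike counts (neurons x spike bins) from softplus rates on a path.

    ``theta0`` is (n_neurons, T+1) baseline arguments at the spike-bin
    centers; counts are Poisson (or negative binomial with the given
    per-neuron dispersions) with mean ``rate * exposure``.
    """
    abar = path_bin_means(path, step, dt, duration)
    e = spike_bin_exposures(duration, dt)
    counts = np.zeros((len(slopes), abar.size), dtype=np.int64)
    for i, s in enumerate(slopes):
        rate = np.maximum(softplus(s * abar + theta0[i]), _kernels.RATE_FLOOR)
        mu = rate * e
        if dispersions is None:
            counts[i] = rng.poisson(mu)
        else:
            th = dispersions[i]
            # Gamma-Poisson mixture with mean mu, shape th
            counts[i] = rng.poisson(rng.gamma(th, mu / th))
    return counts


def simulate_choice(
    a_T: float, c: float, gamma: float, rng: np.random.Generator
) -> int:
    """Lapse-mixture threshold rule on the terminal accumulator value."""
    if rng.random() < gamma:
        return int(rng.random() < 0.5)
    if a_T == c:
        return int(rng.random() < 0.5)
    return int(a_T > c)


def simulate_markov_path(
    theta_a: AccumulatorParams,
    train: ClickTrain,
    dt: float,
    rng: np.random.Generator,
    grid_bins: int = 53,
    refine: int = 10,
) -> np.ndarray:
    """Sample a latent path from the discretized Markov chain itself.

    The path lives on the grid bin centers and follows exactly the settled
    transition operator the likelihood uses, so data generated this way is
    model-matched — the right oracle for parameter-recovery calibration
    (the fine-step SDE simulator instead probes discretization fidelity).
    Returns the (T+1,) sequence of bin-center values.
    """
    from .latent_fp import make_grid
    from .stimulus import adapt_clicks, bin_stimulus

    grid = make_grid(theta_a.B, grid_bins)
    mags = adapt_clicks(train, theta_a.phi, theta_a.tau_phi)
    stim = bin_stimulus(train, mags, dt)
    p0 = _kernels.initial_dist(grid.centers, grid.width, theta_a.sigma2_i, refine)
    i = int(rng.choice(grid.n, p=p0 / p0.sum()))
    path = np.empty(stim.n_bins + 1)
    path[0] = grid.centers[i]
    col = np.zeros(grid.n)
    ed = np.exp(theta_a.lam * dt)
    g = _kernels.drift_gain(theta_a.lam, dt)
    for t in range(stim.n_bins):
        if i == 0 or i == grid.n - 1:
            path[t + 1] = grid.centers[i]  # absorbed
            continue
        mu = grid.centers[i] * ed + stim.delta[t] * g
        tvar = theta_a.sigma2_a * dt + theta_a.sigma2_s * stim.sigma[t]
        _kernels._settle_gaussian(col, grid.centers, grid.width, mu, tvar, refine)
        i = int(rng.choice(grid.n, p=col / col.sum()))
        path[t + 1] = grid.centers[i]
    return path


def _counts_to_times(
    counts: np.ndarray, dt: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Place spike times uniformly within each bin's observation window."""
    times = []
    for k, y in enumerate(counts):
        if y == 0:
            continue
        lo = max(k * dt - dt / 2, 0.0)
        hi = min(k * dt + dt / 2, duration)
        times.append(rng.uniform(lo, hi, int(y)))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def make_dataset(cfg: SimConfig) -> SessionData:
    """Generate a complete synthetic session (clicks, spikes, choices).

    With ``shared_noise`` a single latent path per trial drives all neurons
    and the choice; otherwise each neuron gets an independent path and the
    choice is read from one path selected uniformly at random.  Trials are
    split evenly across ``n_sessions`` session labels; all neurons are
    recorded on all trials.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = [f"n{i}" for i in range(cfg.n_neurons)]
    neurons = [Neuron(id=nid, region="synthetic", latency=0.0) for nid in ids]
    trials = []
    cw = None
    if cfg.generator == "markov":
        from .latent_fp import make_grid
        from .observations import choice_weights

        grid = make_grid(cfg.theta_a.B, cfg.grid_bins)
        cw = choice_weights(grid, cfg.choice.c, cfg.choice.gamma)
    for k in range(cfg.n_trials):
        train = gen_click_train(cfg, rng)
        T = n_time_bins(train.duration, cfg.dt)
        tgrid = np.arange(T + 1) * cfg.dt
        theta0 = np.tile(cfg.theta0_fn(tgrid), (cfg.n_neurons, 1))
        if cfg.generator == "markov":
            e = spike_bin_exposures(train.duration, cfg.dt)
            n_paths = 1 if cfg.shared_noise else cfg.n_neurons
            paths = [
                simulate_markov_path(
                    cfg.theta_a, train, cfg.dt, rng, cfg.grid_bins, cfg.refine
                )
                for _ in range(n_paths)
            ]
            counts = np.zeros((cfg.n_neurons, T + 1), dtype=np.int64)
            for i in range(cfg.n_neurons):
                a = paths[0] if cfg.shared_noise else paths[i]
                rate = np.maximum(
                    softplus(cfg.slopes[i] * a + theta0[i]), _kernels.RATE_FLOOR
                )
                if cfg.dispersions is None:
                    counts[i] = rng.poisson(rate * e)
                else:
                    th = cfg.dispersions[i]
                    counts[i] = rng.poisson(rng.gamma(th, rate * e / th))
            a_T = paths[0 if cfg.shared_noise else rng.integers(cfg.n_neurons)][-1]
            i_T = int(round((a_T - grid.centers[0]) / grid.width))
            choice = int(rng.random() < cw[i_T])
        elif cfg.shared_noise:
            path = simulate_latent(cfg.theta_a, train, cfg.sim_step, rng)[0]
            counts = simulate_spikes(
                path, cfg.sim_step, train.duration, cfg.slopes, theta0, cfg.dt, rng,
                cfg.dispersions,
            )
            a_T = float(path[-1])
        else:
            paths = simulate_latent(
                cfg.theta_a, train, cfg.sim_step, rng, n_paths=cfg.n_neurons
            )
            counts = np.zeros((cfg.n_neurons, T + 1), dtype=np.int64)
            for i in range(cfg.n_neurons):
                counts[i] = simulate_spikes(
                    paths[i], cfg.sim_step, train.duration, cfg.slopes[i : i + 1],
                    theta0[i : i + 1], cfg.dt, rng, cfg.dispersions,
                )[0]
            a_T = float(paths[rng.integers(cfg.n_neurons)][-1])
        if cfg.generator != "markov":
            choice = simulate_choice(a_T, cfg.choice.c, cfg.choice.gamma, rng)
        spikes = {
            nid: _counts_to_times(counts[i], cfg.dt, train.duration, rng)
            for i, nid in enumerate(ids)
        }
        trials.append(
            Trial(
                train=train, choice=choice, neuron_ids=tuple(ids), spikes=spikes,
                session=k * cfg.n_sessions // cfg.n_trials,
            )
        )
    meta = {"generator": "pulseddm.synthetic", "seed": cfg.seed,
            "shared_noise": cfg.shared_noise}
    return SessionData(neurons=neurons, trials=trials, meta=meta)


def recovery_report(theta_true: ModelParams, fit: FitResult) -> dict:
    """Per-parameter recovery table: truth, estimate, CI, coverage flag."""
    truth = list(theta_true.theta_a.to_array()) + [
        theta_true.choice.c, theta_true.choice.gamma,
    ]
    names = list(PARAM_NAMES) + ["c", "gamma"]
    for nid in fit.neuron_ids:
        if fit.spec.variant != "choice" and nid in theta_true.slopes:
            truth.append(theta_true.slopes[nid])
            names.append(f"slope[{nid}]")
    rows = {}
    for i, name in enumerate(names):
        est = float(fit.theta_hat[i])
        lo, hi = (float("nan"), float("nan")) if fit.ci is None else map(float, fit.ci[i])
        rows[name] = {
            "true": float(truth[i]),
            "estimate": est,
            "ci_lower": lo,
            "ci_upper": hi,
            "error": est - float(truth[i]),
            "in_ci": bool(lo <= truth[i] <= hi) if np.isfinite(lo) else False,
        }
    n_acc_in = sum(rows[nm]["in_ci"] for nm in PARAM_NAMES)
    return {"params": rows, "n_accumulator_in_ci": int(n_acc_in)}
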