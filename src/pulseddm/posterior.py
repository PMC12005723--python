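"""Posteriors over the latent accumulator and choice decoding.

Smoothing runs forward-backward over the discretized Markov chain using the
stored per-bin transition operators (the backward pass uses their
transposes), conditioning on any subset of {spikes, choice}.  Choice
decoding thresholds the model's P(right) at 0.5; two GLM baselines
(a lapse-scaled Bernoulli GLM on click/spike-count features and a
deterministic-accumulator Poisson GLM) are provided for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .inference import (
    ModelParams,
    ModelSpec,
    PreparedData,
    _make_context,
    _trial_forward,
    _trial_spike_logw,
    _trial_stim,
    pack_params,
    prepare,
)
from .observations import softplus
from .session import SessionData
from .stimulus import adapt_clicks

__all__ = [
    "LatentPosterior",
    "ChoicePrediction",
    "posterior_latent",
    "posterior_moments",
    "predict_choice",
    "BernoulliGLM",
    "bernoulli_glm",
    "glm_features",
    "PoissonGLMFit",
    "poisson_glm",
]

CONDITIONS = ("none", "choice", "spikes", "spikes+choice")


@dataclass
class LatentPosterior:
    """Per-time-bin distribution over the accumulator for one trial."""

    probs: np.ndarray  # (T+1, n), each row sums to 1
    centers: np.ndarray
    dt: float
    condition: str

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.probs.shape[0]) * self.dt

    def mean(self, exclude_bound: bool = False) -> np.ndarray:
        p, c = self._masses(exclude_bound)
        return p @ c

    def sd(self, exclude_bound: bool = False) -> np.ndarray:
        p, c = self._masses(exclude_bound)
        m = p @ c
        var = p @ (c**2) - m**2
        return np.sqrt(np.maximum(var, 0.0))

    def _masses(self, exclude_bound: bool):
        if not exclude_bound:
            return self.probs, self.centers
        p = self.probs[:, 1:-1].copy()
        tot = p.sum(axis=1, keepdims=True)
        # rows with all mass at the bounds keep the inclusive distribution
        degenerate = tot[:, 0] <= 1e-12
        p = np.where(degenerate[:, None], self.probs[:, 1:-1], p / np.maximum(tot, 1e-300))
        if np.any(degenerate):
            return self.probs, self.centers
        return p, self.centers[1:-1]


@dataclass
class ChoicePrediction:
    p_right: float
    predicted: int  # 1 = right
    ll_contribution: float  # nats, log P(observed choice)


def _resolve(data, spec):
    return data if isinstance(data, PreparedData) else prepare(data, spec)


def posterior_latent(
    params: ModelParams,
    data: SessionData | PreparedData,
    trial_index: int,
    spec: ModelSpec | None = None,
    condition: str = "spikes+choice",
) -> LatentPosterior:
    """Smoothed marginals of a(t) conditioned on the requested data sources.

    ``condition='none'`` reduces exactly to the stimulus-driven forward
    prior.  With spikes, the forward pass weights each step by the spike
    likelihoods; the backward pass applies the choice factor (if requested)
    at T and propagates through the transposed transition operators.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    spec = spec or ModelSpec(variant="joint")
    prep = _resolve(data, spec)
    tr = prep.trials[trial_index]
    ctx = _make_context(
        pack_params(params, spec, list(prep.neuron_ids)), spec, len(prep.neuron_ids)
    )
    use_spikes = "spikes" in condition and tr.active.size > 0
    use_choice = "choice" in condition
    deltas, sigmas = _trial_stim(tr, ctx.phi, ctx.tau_phi)
    logw = _trial_spike_logw(ctx, tr) if use_spikes else np.zeros((tr.T + 1, ctx.grid.n))
    Ms = np.empty((tr.T, ctx.grid.n, ctx.grid.n))
    _, alphas = _trial_forward(ctx, tr, deltas, sigmas, logw, use_spikes, Ms=Ms)
    if use_choice:
        beta_T = ctx.cw if tr.choice == 1 else 1.0 - ctx.cw
    else:
        beta_T = np.ones(ctx.grid.n)
    probs = _kernels.backward_smooth(alphas, Ms, logw, use_spikes, beta_T)
    return LatentPosterior(
        probs=probs, centers=ctx.grid.centers.copy(), dt=spec.dt, condition=condition
    )


def posterior_moments(
    post: LatentPosterior, exclude_bound: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Grid-weighted mean and SD per time bin."""
    return post.mean(exclude_bound), post.sd(exclude_bound)


def predict_choice(
    params: ModelParams,
    data: SessionData | PreparedData,
    trial_index: int,
    spec: ModelSpec | None = None,
    use_spikes: bool = True,
) -> ChoicePrediction:
    """Model probability of a rightward choice, with or without the spikes."""
    spec = spec or ModelSpec(variant="joint")
    prep = _resolve(data, spec)
    tr = prep.trials[trial_index]
    ctx = _make_context(
        pack_params(params, spec, list(prep.neuron_ids)), spec, len(prep.neuron_ids)
    )
    cond_spikes = use_spikes and tr.active.size > 0
    deltas, sigmas = _trial_stim(tr, ctx.phi, ctx.tau_phi)
    logw = _trial_spike_logw(ctx, tr) if cond_spikes else None
    _, alphas = _trial_forward(ctx, tr, deltas, sigmas, logw, cond_spikes)
    p_right = float(alphas[-1] @ ctx.cw)
    p_right = min(max(p_right, 1e-300), 1.0 - 1e-16)
    ll = np.log(p_right) if tr.choice == 1 else np.log(1.0 - p_right)
    return ChoicePrediction(
        p_right=p_right, predicted=int(p_right > 0.5), ll_contribution=float(ll)
    )


# ---------------------------------------------------------------------------
# GLM baselines


@dataclass
class BernoulliGLM:
    """Lapse-scaled logistic choice decoder.

    ``P(right | x) = lapse/2 + (1 - lapse) * sigmoid(coef @ x + bias)``.
    """

    coef: np.ndarray
    bias: float
    lapse: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.asarray(X, dtype=float) @ self.coef + self.bias
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return self.lapse / 2.0 + (1.0 - self.lapse) * s

    def loglik(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self.predict_proba(X), 1e-12, 1 - 1e-12)
        y = np.asarray(y, dtype=float)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((self.predict_proba(X) > 0.5) == (np.asarray(y) == 1)))


def glm_features(
    data: SessionData, window: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix: final click difference + per-neuron trailing spike counts.

    ``window`` is the length (s) of the spike-count window measured backward
    from stimulus offset; None uses the whole trial.  Neurons not recorded on
    a trial contribute zero counts.
    """
    ids = data.neuron_ids
    X = np.zeros((data.n_trials, 1 + len(ids)))
    y = np.zeros(data.n_trials, dtype=int)
    for k, tr in enumerate(data.trials):
        X[k, 0] = tr.train.n_right - tr.train.n_left
        t0 = 0.0 if window is None else max(tr.train.duration - window, 0.0)
        for j, nid in enumerate(ids):
            if nid in tr.spikes:
                s = tr.spikes[nid]
                X[k, 1 + j] = np.count_nonzero(s >= t0)
        y[k] = tr.choice
    return X, y


def bernoulli_glm(X: np.ndarray, y: np.ndarray, seed: int = 0) -> BernoulliGLM:
    """Fit the lapse-scaled logistic decoder by maximum likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        import logging

        logging.getLogger(__name__).warning(
            "bernoulli_glm: all choices identical; fit is lapse-bounded"
        )
    p_feat = X.shape[1]
    # standardize features for optimizer conditioning
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    def nll(w):
        coef, bias, lg = w[:p_feat], w[p_feat], w[p_feat + 1]
        lapse = 1.0 / (1.0 + np.exp(-lg))
        z = Z @ coef + bias
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        p = np.clip(lapse / 2.0 + (1.0 - lapse) * s, 1e-12, 1 - 1e-12)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(3):
        w0 = np.concatenate([0.1 * rng.standard_normal(p_feat), [0.0], [-4.0]])
        res = minimize(nll, w0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    coef = best.x[:p_feat] / sd
    bias = float(best.x[p_feat] - (mu / sd) @ best.x[:p_feat])
    lapse = float(1.0 / (1.0 + np.exp(-best.x[p_feat + 1])))
    return BernoulliGLM(coef=coef, bias=bias, lapse=lapse)


@dataclass
class PoissonGLMFit:
    lam: float
    B: float | None
    phi: float
    tau_phi: float
    slopes: np.ndarray
    loglik: float


def _glm_accumulator(tr, phi, tau_phi, lam, dt, B=None):
    """Deterministic (noise-free) adapted-click accumulator on the time grid."""
    from .stimulus import ClickTrain, bin_stimulus

    train = ClickTrain(tr.train.left_times, tr.train.right_times, tr.train.duration)
    mags = adapt_clicks(train, phi, tau_phi)
    stim = bin_stimulus(train, mags, dt)
    T = stim.n_bins
    a = np.zeros(T + 1)
    ed = np.exp(lam * dt)
    g = _kernels.drift_gain(lam, dt)
    stuck = False
    for t in range(T):
        if stuck:
            a[t + 1] = a[t]
            continue
        a[t + 1] = a[t] * ed + stim.delta[t] * g
        if B is not None and abs(a[t + 1]) >= B:
            a[t + 1] = np.sign(a[t + 1]) * B
            stuck = True
    return a


def poisson_glm(
    data: SessionData,
    spec: ModelSpec | None = None,
    baselines: dict | None = None,
    use_bound: bool = False,
    seed: int = 0,
    maxiter: int = 200,
) -> PoissonGLMFit:
    """Poisson GLM on a deterministic adapted-click accumulator regressor.

    Fits (lam, phi, tau_phi, per-neuron slopes) — and the sticky bound B when
    ``use_bound`` — by maximizing the Poisson spike likelihood with softplus
    rates on top of the pre-fit baselines.  Serves as an independent check on
    the sign of the leak parameter.
    """
    from .inference import fit_baselines as _fb
    from .stimulus import bin_spikes, spike_bin_exposures

    spec = spec or ModelSpec(variant="joint")
    if baselines is None:
        baselines = _fb(data, spec)
    ids = [nid for nid in data.neuron_ids if nid in baselines]
    counts, theta0s, exposures = [], [], []
    for tr in data.trials:
        dur = tr.train.duration
        from .stimulus import n_time_bins

        T = n_time_bins(dur, spec.dt)
        cc, tt = [], []
        for nid in ids:
            if nid in tr.neuron_ids:
                cc.append(
                    bin_spikes(tr.spikes.get(nid, np.empty(0)), spec.dt, dur,
                               data.latency_of(nid))
                )
                w, basis = baselines[nid]
                tt.append(basis.design(T) @ w)
            else:
                cc.append(None)
                tt.append(None)
        counts.append(cc)
        theta0s.append(tt)
        exposures.append(spike_bin_exposures(dur, spec.dt))

    nN = len(ids)

    def nll(w):
        lam, lphi, ltau = w[0], w[1], w[2]
        phi, tau_phi = np.exp(lphi), np.exp(ltau)
        B = np.exp(w[3]) if use_bound else None
        slopes = w[4 : 4 + nN] if use_bound else w[3 : 3 + nN]
        val = 0.0
        for tr, cc, tt, e in zip(data.trials, counts, theta0s, exposures):
            a = _glm_accumulator(tr, phi, tau_phi, lam, spec.dt, B)
            for j in range(nN):
                if cc[j] is None:
                    continue
                rate = np.maximum(softplus(slopes[j] * a + tt[j]), _kernels.RATE_FLOOR)
                mu = rate * e
                ok = e > 0
                val -= float(np.sum(cc[j][ok] * np.log(mu[ok]) - mu[ok]))
        return val

    w0 = np.concatenate(
        [[0.0, np.log(0.5), np.log(0.05)], [np.log(10.0)] if use_bound else [],
         np.zeros(nN)]
    )
    res = minimize(nll, w0, method="L-BFGS-B", options={"maxiter": maxiter})
    w = res.x
    return PoissonGLMFit(
        lam=float(w[0]),
        B=float(np.exp(w[3])) if use_bound else None,
        phi=float(np.exp(w[1])),
        tau_phi=float(np.exp(w[2])),
        slopes=np.asarray(w[4 : 4 + nN] if use_bound else w[3 : 3 + nN]),
        loglik=-float(res.fun),
    )
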