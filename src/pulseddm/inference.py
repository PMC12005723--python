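"""Maximum-likelihood inference for the joint neural-behavioral model.

Three likelihood variants share one accumulator parameterization:

* ``joint`` — a single latent accumulator per trial drives all recorded
  neurons and the choice (single forward pass per trial).
* ``independent`` — each neuron has its own accumulator with independent
  noise; the spike likelihood factorizes over neurons and the choice
  probability is the average of the per-accumulator choice probabilities.
* ``choice`` — choices only; no spike factors.

Fitting is box-constrained quasi-Newton ascent (L-BFGS-B with
finite-difference gradients); confidence intervals come from the Laplace
approximation with eigenvalue repair of non-concave Hessians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .latent_fp import PARAM_NAMES, AccumulatorParams, make_grid
from .observations import (
    ChoiceParams,
    choice_weights,
    rbf_design,
    fit_baseline,
    softplus,
)
from .session import SessionData
from .stimulus import bin_spikes, n_time_bins, spike_bin_exposures

__all__ = [
    "ModelSpec",
    "ModelParams",
    "FitResult",
    "DEFAULT_BOUNDS",
    "fit_baselines",
    "prepare",
    "pack_params",
    "unpack_params",
    "param_names",
    "default_bounds",
    "joint_loglik",
    "choice_only_loglik",
    "independent_loglik",
    "fit_mle",
    "laplace_ci",
    "fd_hessian",
    "kfold_split",
    "bits_per_trial",
    "null_models",
]

log = logging.getLogger(__name__)

# optimization domain; the two printed variance ranges are assigned
# sigma2_i <= 100 and sigma2_a <= 400 (configurable via the bounds argument)
DEFAULT_BOUNDS = {
    "sigma2_i": (1e-3, 100.0),
    "B": (8.0, 40.0),
    "lam": (-5.0, 5.0),
    "sigma2_a": (1e-3, 400.0),
    "sigma2_s": (1e-3, 10.0),
    "phi": (1e-3, 1.2),
    "tau_phi": (5e-3, 1.0),
    "c": (-10.0, 10.0),
    "gamma": (0.0, 1.0),
    "slope": (-10.0, 10.0),
    "dispersion": (1e-3, 1e4),
}


@dataclass(frozen=True)
class ModelSpec:
    """Model variant, observation family, and discretization settings."""

    variant: str = "joint"  # joint | independent | choice
    obs_family: str = "poisson"  # poisson | negbinomial
    n_bins: int = 53
    dt: float = 0.01
    refine: int = 10

    def __post_init__(self):
        if self.variant not in ("joint", "independent", "choice"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.obs_family not in ("poisson", "negbinomial"):
            raise ValueError(f"unknown obs_family {self.obs_family!r}")

    @property
    def use_nb(self) -> bool:
        return self.variant != "choice" and self.obs_family == "negbinomial"


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: accumulator, choice, and per-neuron tuning."""

    theta_a: AccumulatorParams
    choice: ChoiceParams
    slopes: dict[str, float] = field(default_factory=dict)
    dispersions: dict[str, float] = field(default_factory=dict)


def param_names(spec: ModelSpec, neuron_ids: list[str]) -> list[str]:
    names = list(PARAM_NAMES) + ["c", "gamma"]
    if spec.variant != "choice":
        names += [f"slope[{nid}]" for nid in neuron_ids]
        if spec.use_nb:
            names += [f"dispersion[{nid}]" for nid in neuron_ids]
    return names


def pack_params(params: ModelParams, spec: ModelSpec, neuron_ids: list[str]) -> np.ndarray:
    x = list(params.theta_a.to_array()) + [params.choice.c, params.choice.gamma]
    if spec.variant != "choice":
        x += [params.slopes[nid] for nid in neuron_ids]
        if spec.use_nb:
            x += [params.dispersions[nid] for nid in neuron_ids]
    return np.array(x, dtype=float)


def unpack_params(x: np.ndarray, spec: ModelSpec, neuron_ids: list[str]) -> ModelParams:
    x = np.asarray(x, dtype=float)
    theta_a = AccumulatorParams.from_array(x[:7])
    choice = ChoiceParams(c=float(x[7]), gamma=float(x[8]))
    slopes, disps = {}, {}
    if spec.variant != "choice":
        N = len(neuron_ids)
        slopes = {nid: float(v) for nid, v in zip(neuron_ids, x[9 : 9 + N])}
        if spec.use_nb:
            disps = {nid: float(v) for nid, v in zip(neuron_ids, x[9 + N : 9 + 2 * N])}
    return ModelParams(theta_a=theta_a, choice=choice, slopes=slopes, dispersions=disps)


def default_bounds(spec: ModelSpec, neuron_ids: list[str], overrides=None) -> list[tuple]:
    b = dict(DEFAULT_BOUNDS)
    if overrides:
        b.update(overrides)
    out = [b[name] for name in PARAM_NAMES] + [b["c"], b["gamma"]]
    if spec.variant != "choice":
        out += [b["slope"]] * len(neuron_ids)
        if spec.use_nb:
            out += [b["dispersion"]] * len(neuron_ids)
    return out


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class PreparedTrial:
    times: np.ndarray  # pooled sorted click times
    sides: np.ndarray  # +1 right / -1 left
    bin_idx: np.ndarray  # click bin of each click
    T: int
    exposures: np.ndarray  # (T+1,) spike-bin windows (s)
    choice: int
    active: np.ndarray  # indices into the registry order
    counts: np.ndarray  # (n_active, T+1) spike counts
    theta0: np.ndarray  # (n_active, T+1) baseline arguments


@dataclass
class PreparedData:
    trials: list[PreparedTrial]
    neuron_ids: list[str]
    spec: ModelSpec
    baselines: dict
    _packed: dict | None = None
    _logw_cache: tuple | None = None

    @property
    def packed(self) -> dict:
        """Flat-array layout of all trials for the batched likelihood kernel."""
        if self._packed is None:
            trs = self.trials
            click_off = np.zeros(len(trs) + 1, dtype=np.int64)
            act_off = np.zeros(len(trs) + 1, dtype=np.int64)
            t_off = np.zeros(len(trs) + 1, dtype=np.int64)
            row_off = np.zeros(len(trs), dtype=np.int64)
            pos = 0
            for k, tr in enumerate(trs):
                click_off[k + 1] = click_off[k] + tr.times.size
                act_off[k + 1] = act_off[k] + tr.active.size
                t_off[k + 1] = t_off[k] + tr.T + 1
                row_off[k] = pos
                pos += tr.active.size * (tr.T + 1)
            self._packed = {
                "click_t": np.concatenate([tr.times for tr in trs]) if trs else np.empty(0),
                "click_s": np.concatenate([tr.sides for tr in trs]) if trs else np.empty(0),
                "click_bin": np.concatenate(
                    [tr.bin_idx for tr in trs]
                ).astype(np.int64) if trs else np.empty(0, dtype=np.int64),
                "click_off": click_off,
                "counts_flat": np.concatenate(
                    [tr.counts.ravel() for tr in trs]
                ).astype(np.int64) if pos else np.empty(0, dtype=np.int64),
                "theta0_flat": np.concatenate(
                    [tr.theta0.ravel() for tr in trs]
                ) if pos else np.empty(0),
                "row_off": row_off,
                "active_flat": np.concatenate(
                    [tr.active for tr in trs]
                ).astype(np.int64) if trs else np.empty(0, dtype=np.int64),
                "act_off": act_off,
                "exposures_flat": np.concatenate([tr.exposures for tr in trs]),
                "t_off": t_off,
                "T_arr": np.array([tr.T for tr in trs], dtype=np.int64),
                "choices": np.array([tr.choice for tr in trs], dtype=np.int64),
            }
        return self._packed


def fit_baselines(data: SessionData, spec: ModelSpec, linear_intensity: bool = False) -> dict:
    """Pre-fit each neuron's time-varying baseline (held fixed afterwards).

    Returns ``{neuron_id: (weights, basis)}``.
    """
    out = {}
    for nid in data.neuron_ids:
        counts, exposures, max_dur = [], [], 0.0
        lat = data.latency_of(nid)
        for tr in data.trials:
            if nid not in tr.neuron_ids:
                continue
            dur = tr.train.duration
            max_dur = max(max_dur, dur)
            counts.append(bin_spikes(tr.spikes.get(nid, np.empty(0)), spec.dt, dur, lat))
            exposures.append(spike_bin_exposures(dur, spec.dt))
        if not counts:
            continue
        basis = rbf_design(max_dur, spec.dt)
        w = fit_baseline(counts, exposures, basis, linear_intensity=linear_intensity)
        out[nid] = (w, basis)
    return out


def prepare(data: SessionData, spec: ModelSpec, baselines: dict | None = None) -> PreparedData:
    """Bin clicks and spikes and cache per-trial design arrays."""
    if spec.variant != "choice" and baselines is None:
        baselines = fit_baselines(data, spec)
    baselines = baselines or {}
    id_to_idx = {nid: i for i, nid in enumerate(data.neuron_ids)}
    trials = []
    for tr in data.trials:
        times, sides = tr.train.merged()
        dur = tr.train.duration
        T = n_time_bins(dur, spec.dt)
        bin_idx = np.minimum((times / spec.dt).astype(np.int64), T - 1)
        exposures = spike_bin_exposures(dur, spec.dt)
        if spec.variant == "choice":
            active = np.empty(0, dtype=np.int64)
            counts = np.zeros((0, T + 1), dtype=np.int64)
            theta0 = np.zeros((0, T + 1))
        else:
            ids = [nid for nid in tr.neuron_ids if nid in baselines]
            active = np.array([id_to_idx[nid] for nid in ids], dtype=np.int64)
            counts = np.zeros((len(ids), T + 1), dtype=np.int64)
            theta0 = np.zeros((len(ids), T + 1))
            for i, nid in enumerate(ids):
                counts[i] = bin_spikes(
                    tr.spikes.get(nid, np.empty(0)), spec.dt, dur, data.latency_of(nid)
                )
                w, basis = baselines[nid]
                theta0[i] = basis.design(T) @ w
        trials.append(
            PreparedTrial(
                times=times, sides=sides, bin_idx=bin_idx, T=T,
                exposures=exposures, choice=tr.choice, active=active,
                counts=counts, theta0=theta0,
            )
        )
    return PreparedData(trials=trials, neuron_ids=list(data.neuron_ids), spec=spec,
                        baselines=baselines)


# ---------------------------------------------------------------------------
# likelihoods


def _clip_valid(x: np.ndarray, spec: ModelSpec, n_neurons: int) -> np.ndarray:
    """Clamp a parameter vector into the mathematically valid domain.

    Used so finite-difference stencils just outside the optimization box
    still evaluate (variances non-negative, gamma a probability, ...).
    """
    x = np.array(x, dtype=float)
    x[0] = max(x[0], 0.0)  # sigma2_i
    x[1] = max(x[1], 1e-3)  # B
    x[3] = max(x[3], 0.0)  # sigma2_a
    x[4] = max(x[4], 0.0)  # sigma2_s
    x[5] = max(x[5], 1e-8)  # phi
    x[6] = max(x[6], 1e-8)  # tau_phi
    x[8] = min(max(x[8], 0.0), 1.0)  # gamma
    if spec.use_nb:
        x[9 + n_neurons :] = np.maximum(x[9 + n_neurons :], 1e-8)
    return x


@dataclass
class _EvalContext:
    """Grid-dependent quantities shared by every trial at one parameter vector."""

    spec: ModelSpec
    grid: object
    p0: np.ndarray
    M0: np.ndarray
    cw: np.ndarray  # per-bin P(choose right)
    lam: float
    sigma2_a: float
    sigma2_s: float
    phi: float
    tau_phi: float
    slopes: np.ndarray
    disps: np.ndarray


def _make_context(x: np.ndarray, spec: ModelSpec, N: int) -> _EvalContext:
    x = _clip_valid(x, spec, N)
    sigma2_i, B, lam, sigma2_a, sigma2_s, phi, tau_phi = x[:7]
    c, gamma = x[7], x[8]
    if spec.variant != "choice":
        slopes = x[9 : 9 + N]
        disps = x[9 + N : 9 + 2 * N] if spec.use_nb else np.ones(N)
    else:
        slopes = np.zeros(N)
        disps = np.ones(N)
    grid = make_grid(B, spec.n_bins)
    centers, dx, n = grid.centers, grid.width, grid.n
    p0 = _kernels.initial_dist(centers, dx, sigma2_i, spec.refine)
    M0 = np.empty((n, n))
    _kernels.build_transition(
        M0, centers, dx, lam, spec.dt, 0.0, sigma2_a * spec.dt, spec.refine
    )
    cw = choice_weights(grid, c, gamma)
    return _EvalContext(
        spec=spec, grid=grid, p0=p0, M0=M0, cw=cw, lam=lam,
        sigma2_a=sigma2_a, sigma2_s=sigma2_s, phi=phi, tau_phi=tau_phi,
        slopes=slopes, disps=disps,
    )


def _trial_stim(tr: PreparedTrial, phi: float, tau_phi: float):
    """Binned adapted click difference and sum for one trial."""
    mags = _kernels.adapt_mags_pooled(tr.times, phi, tau_phi)
    deltas = np.zeros(tr.T)
    sigmas = np.zeros(tr.T)
    np.add.at(deltas, tr.bin_idx, tr.sides * mags)
    np.add.at(sigmas, tr.bin_idx, mags)
    return deltas, sigmas


def _trial_spike_logw(ctx: _EvalContext, tr: PreparedTrial, rows=None):
    """(T+1, n) spike log-weights for a trial (optionally one neuron row)."""
    sel = slice(None) if rows is None else rows
    return _kernels.spike_log_weights(
        tr.counts[sel], tr.exposures, ctx.slopes[tr.active[sel]],
        tr.theta0[sel], ctx.grid.centers, ctx.disps[tr.active[sel]],
        ctx.spec.use_nb, ctx.spec.dt,
    )


def _trial_forward(
    ctx: _EvalContext, tr: PreparedTrial, deltas, sigmas, logw, use_spikes, Ms=None
):
    """Run the filtering kernel for one trial; returns (ll, alphas)."""
    grid = ctx.grid
    store = Ms is not None
    if not store:
        Ms = np.empty((1, grid.n, grid.n))
    if logw is None:
        logw = np.zeros((1, grid.n))
    return _kernels.forward_filter(
        grid.centers, grid.width, ctx.p0, ctx.lam, ctx.spec.dt,
        ctx.sigma2_a * ctx.spec.dt, ctx.sigma2_s,
        deltas, sigmas, logw, use_spikes, ctx.spec.refine, ctx.M0, Ms, store,
    )


def _dataset_logw(ctx: _EvalContext, prep: PreparedData) -> np.ndarray:
    """Per-row spike log-weights, cached across evaluations.

    The weights depend only on (B via the grid, slopes, dispersions); a
    finite-difference gradient perturbs one parameter at a time, so most
    evaluations hit the single-entry cache.
    """
    pk = prep.packed
    key = (
        float(ctx.grid.B), ctx.slopes.tobytes(), ctx.disps.tobytes(),
        ctx.spec.use_nb,
    )
    cached = prep._logw_cache
    if cached is not None and cached[0] == key:
        return cached[1]
    logw = _kernels.dataset_spike_logw(
        pk["counts_flat"], pk["theta0_flat"], pk["row_off"],
        pk["active_flat"], pk["act_off"], pk["exposures_flat"], pk["t_off"],
        pk["T_arr"], ctx.grid.centers, ctx.slopes, ctx.disps, ctx.spec.use_nb,
    )
    prep._logw_cache = (key, logw)
    return logw


def _loglik_vector(x: np.ndarray, prep: PreparedData, per_trial: bool = False):
    """Log-likelihood of a prepared dataset at packed parameter vector x."""
    spec = prep.spec
    N = len(prep.neuron_ids)
    ctx = _make_context(np.asarray(x, dtype=float), spec, N)
    pk = prep.packed
    if spec.variant != "choice":
        logw_flat = _dataset_logw(ctx, prep)
    else:
        logw_flat = np.zeros(0)
    lls = _kernels.dataset_loglik(
        ctx.grid.centers, ctx.grid.width, ctx.p0, ctx.M0, ctx.lam, spec.dt,
        ctx.sigma2_a * spec.dt, ctx.sigma2_s, ctx.phi, ctx.tau_phi, spec.refine,
        pk["click_t"], pk["click_s"], pk["click_bin"], pk["click_off"],
        pk["counts_flat"], pk["theta0_flat"], pk["row_off"], pk["active_flat"],
        pk["act_off"], pk["exposures_flat"], pk["t_off"], pk["T_arr"],
        logw_flat,
        ctx.slopes, ctx.disps, spec.use_nb, ctx.cw, pk["choices"],
        spec.variant != "choice", spec.variant == "independent",
    )
    bad = ~np.isfinite(lls)
    if np.any(bad):
        raise FloatingPointError(
            f"non-finite log-likelihood on trial {int(np.where(bad)[0][0])} "
            f"at parameters {x}"
        )
    return lls if per_trial else float(lls.sum())


def _make_params_vector(params: ModelParams, data_or_prep, spec: ModelSpec) -> np.ndarray:
    ids = data_or_prep.neuron_ids if hasattr(data_or_prep, "neuron_ids") else []
    return pack_params(params, spec, list(ids))


def joint_loglik(
    params: ModelParams,
    data: SessionData | PreparedData,
    spec: ModelSpec | None = None,
    per_trial: bool = False,
):
    """Joint spikes-and-choice log-likelihood (nats) under a shared accumulator."""
    spec = spec or ModelSpec(variant="joint")
    prep = data if isinstance(data, PreparedData) else prepare(data, spec)
    x = pack_params(params, spec, list(prep.neuron_ids))
    return _loglik_vector(x, prep, per_trial=per_trial)


def choice_only_loglik(
    theta_a: AccumulatorParams,
    theta_d: ChoiceParams,
    data: SessionData | PreparedData,
    spec: ModelSpec | None = None,
    per_trial: bool = False,
):
    """Choice-only log-likelihood (nats): forward prior times the choice factor."""
    spec = spec or ModelSpec(variant="choice")
    if spec.variant != "choice":
        spec = replace(spec, variant="choice")
    prep = data if isinstance(data, PreparedData) else prepare(data, spec)
    params = ModelParams(theta_a=theta_a, choice=theta_d)
    x = pack_params(params, spec, [])
    return _loglik_vector(x, prep, per_trial=per_trial)


def independent_loglik(
    params: ModelParams,
    data: SessionData | PreparedData,
    spec: ModelSpec | None = None,
    per_trial: bool = False,
):
    """Independent-noise log-likelihood: one accumulator per neuron."""
    spec = spec or ModelSpec(variant="independent")
    if spec.variant != "independent":
        spec = replace(spec, variant="independent")
    prep = data if isinstance(data, PreparedData) else prepare(data, spec)
    x = pack_params(params, spec, list(prep.neuron_ids))
    return _loglik_vector(x, prep, per_trial=per_trial)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    theta_hat: np.ndarray
    names: list[str]
    loglik: float
    bounds: list[tuple]
    spec: ModelSpec
    neuron_ids: list[str]
    seed: int
    n_iter: int
    n_fev: int
    converged: bool
    message: str = ""
    hessian: np.ndarray | None = None
    ci: np.ndarray | None = None  # (p, 2) lower/upper
    loglik_fn: object = field(default=None, repr=False)

    @property
    def params(self) -> ModelParams:
        return unpack_params(self.theta_hat, self.spec, self.neuron_ids)

    def to_dict(self) -> dict:
        return {
            "theta_hat": dict(zip(self.names, self.theta_hat.tolist())),
            "loglik": self.loglik,
            "ci": None if self.ci is None else dict(
                zip(self.names, [list(map(float, row)) for row in self.ci])
            ),
            "seed": self.seed,
            "n_iter": self.n_iter,
            "n_fev": self.n_fev,
            "converged": self.converged,
            "message": self.message,
            "variant": self.spec.variant,
            "obs_family": self.spec.obs_family,
            "n_bins": self.spec.n_bins,
            "dt": self.spec.dt,
        }


# generic starting values for the shared parameters (domain midpoints proved
# to sit in a mirrored local mode where slopes flip sign and gamma -> 1)
_INIT_BASE = {
    "sigma2_i": 1.0, "B": 20.0, "lam": 0.0, "sigma2_a": 10.0, "sigma2_s": 1.0,
    "phi": 0.5, "tau_phi": 0.05, "c": 0.0, "gamma": 0.1, "dispersion": 10.0,
}


def _slope_inits(prep: PreparedData) -> np.ndarray:
    """Data-driven slope starting values.

    Correlating each neuron's trial-total spike count with the trial's final
    click difference fixes the sign (breaking the slope/latent mirror
    symmetry) and gives a rough magnitude.
    """
    N = len(prep.neuron_ids)
    sums = [[] for _ in range(N)]
    diffs = [[] for _ in range(N)]
    for tr in prep.trials:
        d = float((tr.sides > 0).sum() - (tr.sides < 0).sum())
        for a, nid in enumerate(tr.active):
            sums[nid].append(tr.counts[a].sum())
            diffs[nid].append(d)
    out = np.zeros(N)
    for i in range(N):
        if len(sums[i]) >= 3 and np.std(sums[i]) > 0 and np.std(diffs[i]) > 0:
            r = np.corrcoef(sums[i], diffs[i])[0, 1]
            out[i] = np.clip(8.0 * r, -6.0, 6.0)
    return out


def _default_inits(bounds, names, seed, n_starts, prep=None):
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    base = np.empty(len(bounds))
    slope_idx = []
    for i, nm in enumerate(names):
        key = nm.split("[")[0]
        base[i] = _INIT_BASE.get(key, 0.5 * (lo[i] + hi[i]))
        if key == "slope":
            slope_idx.append(i)
    if prep is not None and slope_idx:
        base[slope_idx] = _slope_inits(prep)
    span = hi - lo
    inits = []
    for _ in range(n_starts):
        x = base + 0.1 * np.minimum(span, 10.0) * (2 * rng.random(len(bounds)) - 1)
        inits.append(np.clip(x, lo, hi))
    return inits


def fit_mle(
    spec: ModelSpec,
    data: SessionData | PreparedData,
    bounds: dict | None = None,
    init: np.ndarray | None = None,
    seed: int = 0,
    n_starts: int = 3,
    maxiter: int = 1000,
    gtol: float = 1e-6,
    fd_rel_step: float = 1e-5,
    compute_ci: bool = False,
) -> FitResult:
    """Box-constrained maximum-likelihood fit of the requested model variant.

    Deterministic given ``(init, seed)``.  When ``init`` is None, ``n_starts``
    starting points are drawn at the domain midpoints with +/-10% jitter and
    the best final likelihood wins.
    """
    prep = data if isinstance(data, PreparedData) else prepare(data, spec)
    ids = list(prep.neuron_ids)
    bnds = default_bounds(spec, ids, overrides=bounds)
    names = param_names(spec, ids)
    lo = np.array([b[0] for b in bnds])
    hi = np.array([b[1] for b in bnds])

    # optimize strictly-positive-domain parameters in log space: the raw
    # scales span five orders of magnitude and cripple the quasi-Newton steps
    pos = lo > 0

    def to_internal(theta):
        u = np.array(theta, dtype=float)
        u[pos] = np.log(u[pos])
        return u

    def to_natural(u):
        theta = np.array(u, dtype=float)
        theta[pos] = np.exp(theta[pos])
        return theta

    u_bounds = list(zip(to_internal(lo), to_internal(hi)))

    def negll(u):
        return -_loglik_vector(to_natural(u), prep)

    inits = [np.asarray(init, dtype=float)] if init is not None else _default_inits(
        bnds, names, seed, n_starts, prep=prep
    )
    best = None
    for x0 in inits:
        if np.any(x0 < lo) or np.any(x0 > hi):
            raise ValueError("init outside the optimization domain")
        res = minimize(
            negll, to_internal(x0), method="L-BFGS-B", bounds=u_bounds,
            options={
                "maxiter": maxiter, "gtol": gtol,
                "finite_diff_rel_step": fd_rel_step,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        log.warning("fit_mle: optimizer did not fully converge (%s)", best.message)
    fit = FitResult(
        theta_hat=np.clip(to_natural(best.x), lo, hi),
        names=names,
        loglik=-float(best.fun),
        bounds=bnds,
        spec=spec,
        neuron_ids=ids,
        seed=seed,
        n_iter=int(best.nit),
        n_fev=int(best.nfev),
        converged=bool(best.success),
        message=str(best.message),
        loglik_fn=lambda x: _loglik_vector(x, prep),
    )
    if compute_ci:
        laplace_ci(fit)
    return fit


def fd_hessian(fn, x, steps, scheme: str = "central"):
    """Finite-difference Hessian of ``fn`` at ``x``.

    ``central`` uses the full 4-point cross stencil (O(h^2), ~2p^2 calls);
    ``forward`` reuses the one-sided evaluations (O(h), ~p^2/2 calls) —
    adequate when only the interval scale is needed.
    """
    p = len(x)
    H = np.empty((p, p))
    f0 = fn(x)
    if scheme == "forward":
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = steps[i]
            fp[i] = fn(x + ei)
            fm[i] = fn(x - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = steps[i]
            for j in range(i + 1, p):
                ej = np.zeros(p)
                ej[j] = steps[j]
                fij = fn(x + ei + ej)
                H[i, j] = H[j, i] = (fij - fp[i] - fp[j] + f0) / (
                    steps[i] * steps[j]
                )
        return H
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = steps[i]
        fpp = fn(x + ei)
        fmm = fn(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = steps[j]
            fa = fn(x + ei + ej)
            fb = fn(x + ei - ej)
            fc = fn(x - ei + ej)
            fd = fn(x - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4 * steps[i] * steps[j])
    return H


def laplace_ci(
    fit: FitResult,
    rel_step: float = 3e-3,
    line_radius: float = 0.25,
    n_line: int = 9,
    log_space: bool = True,
    hess_scheme: str = "central",
) -> np.ndarray:
    """Laplace +/-2 SD intervals, with eigenvalue repair of non-concave Hessians.

    The Hessian of the log-likelihood is computed by central finite
    differences at the optimum — in log coordinates for strictly-positive
    parameters when ``log_space`` (the likelihood surface is closer to
    quadratic there and the mapped-back intervals respect positivity).
    Eigen-directions with non-negative curvature are repaired by a numerical
    line search along the eigenvector: the profile is fit with a quadratic
    and the eigenvalue replaced with twice the quadratic coefficient.
    Intervals are truncated at the optimization bounds; irreparable
    directions yield NaN intervals.
    """
    if fit.loglik_fn is None:
        raise ValueError("fit carries no likelihood function")
    x = fit.theta_hat
    lo = np.array([b[0] for b in fit.bounds])
    hi = np.array([b[1] for b in fit.bounds])
    pos = (lo > 0) & log_space  # strictly-positive-domain parameters

    def to_internal(theta):
        u = np.array(theta, dtype=float)
        u[pos] = np.log(np.maximum(u[pos], 1e-300))
        return u

    def to_natural(u):
        theta = np.array(u, dtype=float)
        theta[pos] = np.exp(theta[pos])
        return theta

    ll_u = lambda u: fit.loglik_fn(to_natural(u))  # noqa: E731
    xu = to_internal(x)
    scale = np.maximum(np.abs(xu), 0.01 * np.abs(to_internal(hi) - to_internal(np.maximum(lo, 1e-6))))
    steps = rel_step * np.maximum(scale, 1e-3)
    if fit.hessian is None:
        fit.hessian = fd_hessian(ll_u, xu, steps, scheme=hess_scheme)
    H = 0.5 * (fit.hessian + fit.hessian.T)
    evals, evecs = np.linalg.eigh(H)
    bad = evals >= -1e-12
    if np.any(bad):
        base_radius = max(line_radius * float(np.linalg.norm(steps)), 1e-3)
        for idx in np.where(bad)[0]:
            v = evecs[:, idx]
            repaired = False
            # widen the profile until global concavity shows (the local
            # non-concavity is typically a numerical artifact near a bound)
            for radius in (base_radius, 10 * base_radius, 100 * base_radius):
                s_grid = np.linspace(-radius, radius, n_line)
                vals = []
                for s in s_grid:
                    try:
                        vals.append(ll_u(xu + s * v))
                    except FloatingPointError:
                        vals.append(np.nan)
                vals = np.asarray(vals)
                ok = np.isfinite(vals)
                if ok.sum() >= 3:
                    coef = np.polyfit(s_grid[ok], vals[ok], 2)
                    if coef[0] < 0:
                        evals[idx] = 2.0 * coef[0]
                        repaired = True
                        break
            if not repaired:
                evals[idx] = np.nan
                log.warning(
                    "laplace_ci: irreparable curvature along eigenvector %d", idx
                )
    ci = np.full((len(x), 2), np.nan)
    good = np.isfinite(evals)
    if np.any(good):
        # covariance from the repaired (invertible) subspace; parameters with
        # appreciable loading on an irreparable direction stay unavailable
        inv_info = np.zeros_like(H)
        for e, v in zip(evals[good], evecs[:, good].T):
            inv_info += np.outer(v, v) / (-e)
        sd = np.sqrt(np.maximum(np.diag(inv_info), 0.0))
        ci[:, 0] = np.maximum(to_natural(xu - 2.0 * sd), lo)
        ci[:, 1] = np.minimum(to_natural(xu + 2.0 * sd), hi)
        if not np.all(good):
            loaded = np.abs(evecs[:, ~good]).max(axis=1) > 0.3
            ci[loaded] = np.nan
    fit.ci = ci
    return ci


# ---------------------------------------------------------------------------
# model comparison utilities


def kfold_split(data: SessionData, k: int = 5, seed: int = 0):
    """Per-session k-fold partition of trial indices.

    Trials are shuffled within each session and dealt round-robin into folds,
    so every fold's test set draws from every session.  Returns a list of
    ``(train_indices, test_indices)`` pairs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sessions = {}
    for i, tr in enumerate(data.trials):
        sessions.setdefault(tr.session, []).append(i)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(data.n_trials, dtype=int)
    for sess, idx in sorted(sessions.items()):
        if len(idx) < k:
            raise ValueError(f"session {sess} has fewer trials than k={k}")
        idx = np.array(idx)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    folds = []
    all_idx = np.arange(data.n_trials)
    for f in range(k):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        folds.append((train, test))
    return folds


def bits_per_trial(ll_model: float, ll_null: float, n_trials: int) -> float:
    """Log-likelihood improvement over a null model, in bits per trial."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return (ll_model - ll_null) / (n_trials * np.log(2.0))


def null_models(
    data: SessionData,
    spec: ModelSpec | None = None,
    baselines: dict | None = None,
    right_rate: float | None = None,
) -> tuple[float, float]:
    """Null choice and null joint log-likelihoods.

    The choice null is a Bernoulli at the empirical right-choice fraction
    (or at ``right_rate``, e.g. estimated on training data).  The spike null
    assumes each neuron fires at its fitted trial-average baseline rate.
    Returns ``(ll_choice_null, ll_joint_null)`` where the joint null adds the
    spike null to the choice null.
    """
    spec = spec or ModelSpec(variant="joint")
    choices = np.array([tr.choice for tr in data.trials], dtype=float)
    if data.n_trials == 0:
        raise ValueError("need at least one trial")
    p = float(choices.mean()) if right_rate is None else float(right_rate)
    n_right, K = float(choices.sum()), float(choices.size)
    if p <= 0.0:
        ll_choice = 0.0 if n_right == 0 else -np.inf
    elif p >= 1.0:
        ll_choice = 0.0 if n_right == K else -np.inf
    else:
        ll_choice = n_right * np.log(p) + (K - n_right) * np.log(1.0 - p)
    ll_choice = float(ll_choice)
    if spec.variant == "choice":
        return ll_choice, ll_choice
    if baselines is None:
        baselines = fit_baselines(data, spec)
    ll_spikes = 0.0
    from scipy.special import gammaln

    for tr in data.trials:
        T = n_time_bins(tr.train.duration, spec.dt)
        exposures = spike_bin_exposures(tr.train.duration, spec.dt)
        for nid in tr.neuron_ids:
            if nid not in baselines:
                continue
            w, basis = baselines[nid]
            rate = np.maximum(softplus(basis.design(T) @ w), _kernels.RATE_FLOOR)
            y = bin_spikes(
                tr.spikes.get(nid, np.empty(0)), spec.dt, tr.train.duration,
                data.latency_of(nid),
            ).astype(float)
            mu = rate * exposures
            ok = exposures > 0
            ll_spikes += float(
                np.sum(y[ok] * np.log(mu[ok]) - mu[ok] - gammaln(y[ok] + 1.0))
            )
    return ll_choice, ll_choice + ll_spikes
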