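import numpy as np
import pytest

from pulseddm import AccumulatorParams, ChoiceParams, ClickTrain
from pulseddm.inference import ModelParams, ModelSpec
from pulseddm.synthetic import SimConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theta_a():
    return AccumulatorParams(
        sigma2_i=1.0, B=10.0, lam=-0.5, sigma2_a=4.0, sigma2_s=1.0,
        phi=0.4, tau_phi=0.05,
    )


@pytest.fixture
def small_train():
    return ClickTrain(
        left_times=np.array([0.05, 0.12, 0.30]),
        right_times=np.array([0.02, 0.12, 0.20, 0.41]),
        duration=0.5,
    )


def tiny_session(n_trials=3, n_neurons=2, seed=0, duration=(0.04, 0.05)):
    """A very small synthetic session for oracle-sized tests."""
    cfg = SimConfig(
        n_trials=n_trials, n_neurons=n_neurons, seed=seed,
        duration_range=duration, total_rate=60.0, baseline_hz=25.0,
        baseline_mod_hz=0.0,
    )
    return cfg, make_dataset(cfg)


@pytest.fixture
def tiny_data():
    return tiny_session()


@pytest.fixture
def sim_params():
    cfg = SimConfig()
    return ModelParams(
        theta_a=cfg.theta_a,
        choice=cfg.choice,
        slopes={f"n{i}": float(cfg.slopes[i]) for i in range(cfg.n_neurons)},
    )


def params_for(cfg: SimConfig) -> ModelParams:
    return ModelParams(
        theta_a=cfg.theta_a,
        choice=cfg.choice,
        slopes={f"n{i}": float(cfg.slopes[i]) for i in range(cfg.n_neurons)},
        dispersions={}
        if cfg.dispersions is None
        else {f"n{i}": float(cfg.dispersions[i]) for i in range(cfg.n_neurons)},
    )


def brute_force_loglik(params, data, spec, variant="joint"):
    """Exhaustive-path oracle: sum P(a_path, Y, d) over all grid paths.

    Independent of the forward-filter code path: uses the public
    transition_matrix / initial_distribution / choice_weights building blocks
    and enumerates every latent path explicitly.
    """
    import itertools

    from pulseddm.inference import pack_params, prepare, _make_context, _trial_stim
    from pulseddm.observations import choice_weights
    from pulseddm import _kernels

    prep = prepare(data, spec)
    N = len(prep.neuron_ids)
    ctx = _make_context(pack_params(params, spec, list(prep.neuron_ids)), spec, N)
    grid = ctx.grid
    n = grid.n
    total = 0.0
    for tr in prep.trials:
        deltas, sigmas = _trial_stim(tr, ctx.phi, ctx.tau_phi)
        # per-step transition matrices from the public constructor
        Ms = []
        for t in range(tr.T):
            M = np.empty((n, n))
            _kernels.build_transition(
                M, grid.centers, grid.width, ctx.lam, spec.dt, deltas[t],
                ctx.sigma2_a * spec.dt + ctx.sigma2_s * sigmas[t], spec.refine,
            )
            Ms.append(M)
        cw = ctx.cw
        fvec = cw if tr.choice == 1 else 1.0 - cw

        def spike_weight_table(rows):
            """(T+1, n) per-bin spike likelihood for the given neuron rows."""
            W = np.ones((tr.T + 1, n))
            for r in rows:
                lw = _kernels.spike_log_weights(
                    tr.counts[r : r + 1], tr.exposures,
                    ctx.slopes[tr.active[r : r + 1]], tr.theta0[r : r + 1],
                    grid.centers, ctx.disps[tr.active[r : r + 1]],
                    spec.use_nb, spec.dt,
                )
                W *= np.exp(lw)
            return W

        def enumerate_paths(W):
            """Sum P(path, spikes) and P(path, spikes, choice) over all paths."""
            lik = 0.0
            lik_choice = 0.0
            for path in itertools.product(range(n), repeat=tr.T + 1):
                p = ctx.p0[path[0]] * W[0, path[0]]
                for t in range(tr.T):
                    p *= Ms[t][path[t + 1], path[t]] * W[t + 1, path[t + 1]]
                lik += p
                lik_choice += p * fvec[path[-1]]
            return lik, lik_choice

        if variant == "independent" and tr.active.size > 1:
            ll = 0.0
            prs = []
            for r in range(tr.active.size):
                lik, lik_choice = enumerate_paths(spike_weight_table([r]))
                ll += np.log(lik)
                prs.append(lik_choice / lik)
            total += ll + np.log(np.mean(prs))
        else:
            rows = list(range(tr.active.size)) if variant != "choice" else []
            _, lik_choice = enumerate_paths(spike_weight_table(rows))
            total += np.log(lik_choice)
    return total
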