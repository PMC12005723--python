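"""Validation experiments: the harness behind the acceptance checks.

Each function runs one self-contained experiment end to end (generate
synthetic data, run the method, measure the result) and returns plain
numbers.  Both the test suite and ``scripts/acceptance.py`` call these, so
the quantities asserted and the quantities reported are computed by the
same code.  Scales are reduced relative to the paper's datasets to fit the
single-CPU runtime budget; every scale knob is an explicit argument.
"""

from __future__ import annotations

import numpy as np

from .analyses import detect_com
from .inference import (
    ModelParams,
    ModelSpec,
    bits_per_trial,
    fit_mle,
    joint_loglik,
    independent_loglik,
    laplace_ci,
    null_models,
    prepare,
)
from .latent_fp import forward_prior, make_grid
from .posterior import bernoulli_glm, glm_features, posterior_latent, predict_choice
from .stimulus import adapt_clicks, bin_stimulus
from .synthetic import (
    PLAUSIBLE_THETA,
    SimConfig,
    gen_click_train,
    make_dataset,
    recovery_report,
    simulate_terminal,
)

# declared generating accumulator for the recovery harness: stimulus noise
# and leak magnitudes within the published fit ranges, bound low enough to
# be exercised by the stimulus
RECOVERY_THETA = PLAUSIBLE_THETA.theta_a.replace(
    sigma2_i=1.0, B=12.0, sigma2_a=6.0, sigma2_s=0.5, phi=0.4
)

__all__ = [
    "fokker_planck_vs_monte_carlo",
    "mass_conservation_check",
    "recovery_experiment",
    "decoding_experiment",
    "model_selection_experiment",
    "com_false_positive_scan",
]


def _params_for(cfg: SimConfig) -> ModelParams:
    return ModelParams(
        theta_a=cfg.theta_a,
        choice=cfg.choice,
        slopes={f"n{i}": float(cfg.slopes[i]) for i in range(cfg.n_neurons)},
    )


def fokker_planck_vs_monte_carlo(
    seed: int = 0,
    n_paths: int = 100_000,
    lams=(-2.0, 0.0, 2.0),
    bounds=(12.0, 4.0),
    duration: float = 0.4,
    dt: float = 0.001,
    n_bins: int = 1001,
    em_step: float = 2e-4,
):
    """Terminal mean/variance of the propagated distribution vs EM simulation.

    Returns a list of dicts with the deviations expressed in Monte-Carlo
    standard errors, across a leak grid with and without a binding bound.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(duration_range=(duration, duration), seed=seed)
    train = gen_click_train(cfg, rng)
    rows = []
    for lam in lams:
        for B in bounds:
            th = cfg.theta_a.replace(
                lam=lam, B=B, sigma2_i=1.0, sigma2_a=1.0, sigma2_s=1.0,
                phi=0.4, tau_phi=0.05,
            )
            aT = simulate_terminal(
                th, train, em_step, np.random.default_rng(seed + 1), n_paths
            )
            grid = make_grid(B, n_bins)
            stim = bin_stimulus(train, adapt_clicks(train, th.phi, th.tau_phi), dt)
            pT = forward_prior(th, stim, grid)[-1]
            mean_fp = float(pT @ grid.centers)
            var_fp = float(pT @ grid.centers**2 - mean_fp**2)
            se_m = aT.std() / np.sqrt(aT.size)
            se_v = np.sqrt(np.var((aT - aT.mean()) ** 2) / aT.size)
            rows.append({
                "lam": lam, "B": B,
                "mean_se": abs(mean_fp - aT.mean()) / se_m,
                "var_se": abs(var_fp - aT.var()) / se_v,
            })
    return rows


def mass_conservation_check(seed: int = 0, n_trials: int = 20):
    """Mass conservation, bound monotonicity, and operator stochasticity.

    Returns the worst deviation of any propagated distribution's total mass
    from 1, the most negative step change of bound mass, and the worst
    transition-matrix column-sum deviation, over random stimuli/parameters.
    """
    from .latent_fp import AccumulatorParams, transition_matrix

    rng = np.random.default_rng(seed)
    worst_mass = 0.0
    worst_monotone = 0.0
    worst_colsum = 0.0
    for _ in range(n_trials):
        cfg = SimConfig(seed=int(rng.integers(2**31)))
        train = gen_click_train(cfg, rng)
        th = AccumulatorParams(
            sigma2_i=float(rng.uniform(0, 4)),
            B=float(rng.uniform(4, 20)),
            lam=float(rng.uniform(-3, 3)),
            sigma2_a=float(rng.uniform(0, 30)),
            sigma2_s=float(rng.uniform(0, 4)),
            phi=float(rng.uniform(0.1, 1.2)),
            tau_phi=float(rng.uniform(0.01, 0.3)),
        )
        grid = make_grid(th.B, 53)
        stim = bin_stimulus(train, adapt_clicks(train, th.phi, th.tau_phi), 0.01)
        pr = forward_prior(th, stim, grid)
        worst_mass = max(worst_mass, float(np.abs(pr.sum(axis=1) - 1.0).max()))
        bound = pr[:, 0] + pr[:, -1]
        worst_monotone = min(worst_monotone, float(np.diff(bound).min()))
        M = transition_matrix(th, 1.0, 2.0, 0.01, grid)
        worst_colsum = max(worst_colsum, float(np.abs(M.sum(axis=0) - 1.0).max()))
        assert M[0, 0] == 1.0 and M[-1, -1] == 1.0
    return {
        "max_mass_error": worst_mass,
        "min_bound_mass_step": worst_monotone,
        "max_colsum_error": worst_colsum,
    }


def recovery_experiment(
    seeds,
    n_trials: int = 200,
    n_neurons: int = 5,
    lam_values=(-2.0, 2.0),
    duration_range=(0.3, 0.6),
    n_bins: int = 27,
    refine: int = 5,
    maxiter: int = 60,
):
    """Parameter-recovery runs: one joint fit with Laplace CIs per seed.

    Seeds alternate between leaky (lam<0) and unstable (lam>0) generating
    dynamics; data is drawn from the model-matched markov generator so CI
    coverage is a calibration check of the inference machinery.  Returns per
    seed: number of accumulator parameters inside their +/-2 SD intervals,
    the recovered lam, and the generating lam.
    """
    rows = []
    for i, seed in enumerate(seeds):
        lam = lam_values[i % len(lam_values)]
        cfg = SimConfig(
            n_trials=n_trials, n_neurons=n_neurons, seed=seed,
            duration_range=duration_range,
            theta_a=RECOVERY_THETA.replace(lam=lam),
            slopes=np.array(
                [2.0 if i % 2 == 0 else -2.0 for i in range(n_neurons)]
            ),
            generator="markov", grid_bins=n_bins, refine=refine,
        )
        data = make_dataset(cfg)
        spec = ModelSpec(variant="joint", n_bins=n_bins, refine=refine)
        prep = prepare(data, spec)
        fit = fit_mle(spec, prep, seed=seed, n_starts=1, maxiter=maxiter)
        laplace_ci(fit, hess_scheme="forward")
        rep = recovery_report(_params_for(cfg), fit)
        rows.append({
            "seed": seed,
            "lam_true": lam,
            "lam_hat": float(fit.theta_hat[2]),
            "n_in_ci": rep["n_accumulator_in_ci"],
            "report": rep,
        })
    return rows


def decoding_experiment(
    seeds,
    n_trials: int = 300,
    n_neurons: int = 4,
    slope_mag: float = 5.0,
    duration_range=(0.3, 0.6),
    n_bins: int = 27,
    refine: int = 5,
):
    """Posterior sharpening and choice-decoding ordering (joint vs ablations).

    For each seed: generate joint-model data with strongly tuned neurons,
    split 80/20, and compare on the test set (a) average posterior SD with
    spikes+choice vs choice alone, (b) choice decoding bits/trial and
    accuracy of the joint model (spike-conditioned, generating parameters)
    vs the choice-only model (same latent/choice parameters, stimulus only)
    vs a Bernoulli GLM fit on the training set.
    """
    out = []
    for seed in seeds:
        slopes = np.array(
            [slope_mag if i % 2 == 0 else -slope_mag for i in range(n_neurons)]
        )
        cfg = SimConfig(
            n_trials=n_trials, n_neurons=n_neurons, seed=seed,
            duration_range=duration_range, slopes=slopes,
            generator="markov", grid_bins=n_bins, refine=refine,
        )
        data = make_dataset(cfg)
        spec = ModelSpec(variant="joint", n_bins=n_bins, refine=refine)
        prep = prepare(data, spec)
        params = _params_for(cfg)
        rng = np.random.default_rng(seed)
        idx = rng.permutation(data.n_trials)
        n_test = data.n_trials // 5
        test, train = idx[:n_test], idx[n_test:]

        sd_choice, sd_spikes = [], []
        ll_joint = ll_choice = 0.0
        acc_joint = acc_choice = 0
        for k in test:
            sd_choice.append(
                posterior_latent(params, prep, k, spec, "choice").sd().mean()
            )
            sd_spikes.append(
                posterior_latent(params, prep, k, spec, "spikes+choice").sd().mean()
            )
            pj = predict_choice(params, prep, k, spec, use_spikes=True)
            pc = predict_choice(params, prep, k, spec, use_spikes=False)
            ll_joint += pj.ll_contribution
            ll_choice += pc.ll_contribution
            ch = data.trials[k].choice
            acc_joint += pj.predicted == ch
            acc_choice += pc.predicted == ch

        X, y = glm_features(data)
        glm = bernoulli_glm(X[train], y[train], seed=seed)
        ll_glm = glm.loglik(X[test], y[test])
        acc_glm = glm.accuracy(X[test], y[test])

        p_test = float(y[train].mean())
        sub = type(data)(neurons=data.neurons, trials=[data.trials[k] for k in test])
        ll_null, _ = null_models(sub, spec, baselines={}, right_rate=p_test)
        out.append({
            "seed": seed,
            "sd_choice": float(np.mean(sd_choice)),
            "sd_spikes": float(np.mean(sd_spikes)),
            "bits_joint": bits_per_trial(ll_joint, ll_null, n_test),
            "bits_choice": bits_per_trial(ll_choice, ll_null, n_test),
            "bits_glm": bits_per_trial(ll_glm, ll_null, n_test),
            "acc_joint": acc_joint / n_test,
            "acc_choice": acc_choice / n_test,
            "acc_glm": acc_glm,
        })
    return out


def model_selection_experiment(
    seeds,
    n_trials: int = 150,
    n_neurons: int = 2,
    duration_range=(0.25, 0.45),
    n_bins: int = 27,
    refine: int = 5,
    maxiter: int = 30,
):
    """Shared vs independent noise-structure selection by test likelihood.

    For each seed and each generating structure, fit both the shared and the
    independent-noise model on an 80% training split and compare their test
    log-likelihoods.  Returns per (seed, structure) whether the generating
    structure won.
    """
    rows = []
    for seed in seeds:
        for shared in (True, False):
            cfg = SimConfig(
                n_trials=n_trials, n_neurons=n_neurons, seed=seed,
                duration_range=duration_range, shared_noise=shared,
                generator="markov", grid_bins=n_bins, refine=refine,
            )
            data = make_dataset(cfg)
            rng = np.random.default_rng(seed + 1000)
            idx = rng.permutation(data.n_trials)
            n_test = data.n_trials // 5
            test_idx, train_idx = idx[:n_test], idx[n_test:]
            train = type(data)(
                neurons=data.neurons, trials=[data.trials[k] for k in train_idx]
            )
            test = type(data)(
                neurons=data.neurons, trials=[data.trials[k] for k in test_idx]
            )
            test_lls = {}
            baselines = None
            for variant in ("joint", "independent"):
                spec = ModelSpec(variant=variant, n_bins=n_bins, refine=refine)
                prep_tr = prepare(train, spec, baselines=baselines)
                baselines = prep_tr.baselines
                fit = fit_mle(spec, prep_tr, seed=seed, n_starts=1, maxiter=maxiter)
                prep_te = prepare(test, spec, baselines=baselines)
                params = fit.params
                if variant == "joint":
                    test_lls[variant] = joint_loglik(params, prep_te, spec)
                else:
                    test_lls[variant] = independent_loglik(params, prep_te, spec)
            winner = "joint" if test_lls["joint"] >= test_lls["independent"] else "independent"
            generating = "joint" if shared else "independent"
            rows.append({
                "seed": seed,
                "generating": generating,
                "winner": winner,
                "correct": winner == generating,
                "ll_gap": float(test_lls["joint"] - test_lls["independent"]),
            })
    return rows


def com_false_positive_scan(seed: int = 0, n_traces: int = 10_000):
    """Random monotone traces staying on one side of the criterion: the
    change-of-mind detector must flag none of them."""
    rng = np.random.default_rng(seed)
    false_events = 0
    for _ in range(n_traces):
        T = int(rng.integers(15, 80))
        sign = rng.choice([-1.0, 1.0])
        start = rng.uniform(0.05, 3.0)
        trace = sign * (start + np.cumsum(rng.uniform(0, 0.2, T)))
        false_events += len(detect_com(trace, 0.01, c=0.0))
    return {"false_events": false_events, "n_traces": n_traces}
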