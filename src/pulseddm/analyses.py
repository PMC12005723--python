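"""Descriptive and diagnostic analyses.

PSTHs grouped by evidence strength and their coefficient of determination,
shuffle-corrected cross-correlations, lapse-logistic psychometric curves,
change-of-mind detection from latent posterior means, participation ratio,
choice-tuned neuron selection, and event-time vs response-latency regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import linregress, ttest_ind

__all__ = [
    "single_trial_rate",
    "group_by_evidence",
    "psth",
    "model_expected_rates",
    "synthetic_psth",
    "psth_r2",
    "xcorr_shuffle_corrected",
    "psychometric",
    "PsychometricFit",
    "ChangeOfMindEvent",
    "detect_com",
    "participation_ratio",
    "select_tuned_neurons",
    "com_latency_regression",
]

log = logging.getLogger(__name__)


def single_trial_rate(counts: np.ndarray, dt: float, kernel_sd: float = 0.05) -> np.ndarray:
    """Gaussian-filtered firing rate (Hz) from binned spike counts.

    Filtering conserves the total spike count up to edge truncation.
    Accepts a 1-d count vector or an array whose last axis is time.
    """
    counts = np.asarray(counts, dtype=float)
    return gaussian_filter1d(counts / dt, sigma=kernel_sd / dt, axis=-1, mode="constant")


def group_by_evidence(click_diffs: np.ndarray, groups: int = 2) -> np.ndarray:
    """Partition trials into equal-sized groups by final click difference.

    Returns a group index per trial (0 = lowest evidence for right).  Ties
    are broken by trial order so groups are equal-sized up to remainder.
    """
    click_diffs = np.asarray(click_diffs, dtype=float)
    order = np.argsort(click_diffs, kind="stable")
    g = np.empty(click_diffs.size, dtype=int)
    splits = np.array_split(order, groups)
    for gi, idx in enumerate(splits):
        g[idx] = gi
    return g


def psth(
    rates: list[np.ndarray], group_idx: np.ndarray, groups: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Ragged trial-average of single-trial rates per evidence group.

    ``rates`` holds per-trial rate traces of possibly different lengths;
    at every time bin the average is over whichever trials have data there.
    Returns ``(psth, n_contrib)`` each of shape ``(groups, T_max)``.
    """
    T_max = max(r.shape[-1] for r in rates)
    out = np.zeros((groups, T_max))
    cnt = np.zeros((groups, T_max))
    for r, g in zip(rates, group_idx):
        L = r.shape[-1]
        out[g, :L] += r
        cnt[g, :L] += 1.0
    if np.any(cnt.sum(axis=1) == 0):
        raise ValueError("empty evidence group")
    with np.errstate(invalid="ignore"):
        avg = np.where(cnt > 0, out / np.maximum(cnt, 1), np.nan)
    return avg, cnt


def model_expected_rates(
    params,
    data,
    spec,
    baselines: dict,
    n_reals: int = 20,
    seed: int = 0,
    step: float = 1e-3,
) -> dict:
    """Per-trial expected firing rates under the model (Hz).

    For each trial the latent path is simulated ``n_reals`` times and the
    softplus rate averaged over realizations, reducing latent-noise variance;
    baselines come from the pre-fit RBF weights.  Returns
    ``{neuron_id: [trace per trial]}`` on the spike-bin time grid.
    """
    from .stimulus import n_time_bins
    from .synthetic import path_bin_means, simulate_latent

    rng = np.random.default_rng(seed)
    out = {nid: [] for nid in baselines}
    for tr in data.trials:
        T = n_time_bins(tr.train.duration, spec.dt)
        paths = simulate_latent(params.theta_a, tr.train, step, rng, n_paths=n_reals)
        abar = np.stack(
            [path_bin_means(p, step, spec.dt, tr.train.duration) for p in paths]
        )
        for nid in baselines:
            if nid not in tr.neuron_ids:
                out[nid].append(None)
                continue
            w, basis = baselines[nid]
            theta0 = basis.design(T) @ w
            slope = params.slopes.get(nid, 0.0)
            from .observations import softplus as _sp

            rate = _sp(slope * abar + theta0[None, :]).mean(axis=0)
            out[nid].append(rate)
    return out


def synthetic_psth(
    rates: list[np.ndarray],
    group_idx: np.ndarray,
    dt: float,
    groups: int = 2,
    kernel_sd: float = 0.05,
):
    """Evidence-grouped average of model expected rates, smoothed like the
    empirical single-trial rates so the two PSTHs are directly comparable."""
    keep = [(r, g) for r, g in zip(rates, group_idx) if r is not None]
    filtered = [
        gaussian_filter1d(r, sigma=kernel_sd / dt, mode="constant") for r, _ in keep
    ]
    return psth(filtered, np.array([g for _, g in keep]), groups=groups)


def psth_r2(
    empirical: np.ndarray,
    synthetic: np.ndarray,
    times: np.ndarray | None = None,
    window: tuple[float, float] = (-0.2, 0.5),
) -> float:
    """Coefficient of determination between empirical and model PSTHs.

    ``1 - SSE/SST`` pooled over groups and the time window (clipped to the
    available times); SST is about the grand mean over groups and times.
    """
    emp = np.asarray(empirical, dtype=float)
    syn = np.asarray(synthetic, dtype=float)
    if emp.shape != syn.shape:
        raise ValueError("PSTH shapes must match")
    if times is not None:
        keep = (times >= window[0]) & (times <= window[1])
        emp, syn = emp[:, keep], syn[:, keep]
    ok = np.isfinite(emp) & np.isfinite(syn)
    emp, syn = emp[ok], syn[ok]
    sst = float(np.sum((emp - emp.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero-variance empirical PSTH")
    return 1.0 - float(np.sum((emp - syn) ** 2)) / sst


def xcorr_shuffle_corrected(
    counts_m: list[np.ndarray],
    counts_n: list[np.ndarray],
    psth_m: np.ndarray,
    psth_n: np.ndarray,
    group_idx: np.ndarray,
    dt: float,
    tau_range: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle-corrected cross-correlation of a simultaneously recorded pair.

    The raw correlation averages ``y_n(t) * y_m(t - tau)`` rates over valid
    ragged bins and trials, normalized by neuron m's mean rate with neuron
    n's mean rate subtracted; the PSTH correlation (same formula on the
    evidence-grouped PSTHs) is subtracted out, leaving excess rate.
    Returns ``(taus_seconds, corrected)``.

    A neuron correlated with itself retains the Poisson self-peak at tau=0;
    exclude self-pairs from pair summaries.
    """
    L = int(round(tau_range / dt))
    taus = np.arange(-L, L + 1)
    mean_m = np.mean(np.concatenate([c for c in counts_m])) / dt
    mean_n = np.mean(np.concatenate([c for c in counts_n])) / dt
    if mean_m == 0:
        raise ValueError("neuron m never fires; correlation undefined")

    def raw(traces_n, traces_m):
        acc = np.zeros(taus.size)
        K = len(traces_n)
        for yn, ym in zip(traces_n, traces_m):
            T = min(yn.shape[0], ym.shape[0])
            for i, tau in enumerate(taus):
                t = np.arange(max(0, tau), min(T, T + tau))
                src = t - tau
                n_valid = t.size
                if n_valid == 0:
                    continue
                acc[i] += float(yn[t] @ ym[src]) / n_valid
        return acc / K

    rates_m = [c / dt for c in counts_m]
    rates_n = [c / dt for c in counts_n]
    raw_corr = raw(rates_n, rates_m) / mean_m - mean_n

    groups = int(group_idx.max()) + 1
    psth_pairs_n = [psth_n[g][np.isfinite(psth_n[g])] for g in range(groups)]
    psth_pairs_m = [psth_m[g][np.isfinite(psth_m[g])] for g in range(groups)]
    psth_corr = raw(psth_pairs_n, psth_pairs_m) / mean_m - mean_n
    return taus * dt, raw_corr - psth_corr


@dataclass
class PsychometricFit:
    """Lapse-scaled logistic of choice against final click difference."""

    slope: float
    bias: float
    lapse: float

    def predict(self, x) -> np.ndarray:
        z = self.slope * np.asarray(x, dtype=float) + self.bias
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return self.lapse / 2.0 + (1.0 - self.lapse) * s


def psychometric(choices: np.ndarray, click_diffs: np.ndarray, seed: int = 0) -> PsychometricFit:
    """Fit the lapse-logistic psychometric curve by maximum likelihood."""
    from .posterior import bernoulli_glm

    x = np.asarray(click_diffs, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct click differences")
    glm = bernoulli_glm(x[:, None], np.asarray(choices), seed=seed)
    return PsychometricFit(slope=float(glm.coef[0]), bias=glm.bias, lapse=glm.lapse)


@dataclass(frozen=True)
class ChangeOfMindEvent:
    trial: int
    time: float  # s, crossing time on the model grid
    direction: str  # "L->R" or "R->L"


def detect_com(
    mean_trace: np.ndarray,
    dt: float,
    c: float = 0.0,
    trial: int = 0,
    pre: float = 0.05,
    post: float = 0.05,
    magnitude: float = 2.0,
) -> list[ChangeOfMindEvent]:
    """Detect putative change-of-mind events in a posterior-mean trace.

    A crossing of the criterion ``c`` qualifies when the trace stays strictly
    on one side for at least ``pre`` seconds before and on the other side for
    ``post`` seconds after, and ``|trace|`` reaches ``magnitude`` somewhere in
    that window.  Criteria are expressed in seconds, so detections are
    invariant to resampling the trace onto a finer grid.
    """
    m = np.asarray(mean_trace, dtype=float)
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    if m.size < n_pre + n_post:
        log.warning("detect_com: trace shorter than dwell window; no events")
        return []
    sign = np.sign(m - c)
    events: list[ChangeOfMindEvent] = []
    for t in range(1, m.size):
        if sign[t] == 0 or sign[t - 1] == 0 or sign[t] == sign[t - 1]:
            continue
        lo = t - n_pre
        hi = t + n_post  # window [lo, t-1] before, [t, hi-1] after
        if lo < 0 or hi > m.size:
            continue
        if np.any(sign[lo:t] != sign[t - 1]) or np.any(sign[t:hi] != sign[t]):
            continue
        if np.max(np.abs(m[lo:hi])) < magnitude:
            continue
        direction = "L->R" if sign[t] > 0 else "R->L"
        events.append(ChangeOfMindEvent(trial=trial, time=t * dt, direction=direction))
    return events


def participation_ratio(rates: np.ndarray) -> float:
    """Effective dimensionality of a population: (sum lam)^2 / sum lam^2.

    ``rates`` is (samples, neurons) — e.g. filtered single-trial rates
    stacked over trials and time.  The eigenvalues are those of the rate
    covariance matrix; the result lies in [1, n_neurons].
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 3:  # (trials, time, neurons)
        rates = rates.reshape(-1, rates.shape[-1])
    if rates.shape[1] < 2:
        raise ValueError("need at least 2 neurons")
    cov = np.cov(rates, rowvar=False)
    lam = np.linalg.eigvalsh(cov)
    lam = np.maximum(lam, 0.0)
    denom = float(np.sum(lam**2))
    if denom == 0:
        raise ValueError("rank-0 covariance")
    return float(np.sum(lam) ** 2 / denom)


def select_tuned_neurons(
    rates_by_choice: dict[str, tuple[np.ndarray, np.ndarray]], alpha: float = 0.01
) -> list[str]:
    """Keep neurons whose stimulus-period rate differs between choices.

    ``rates_by_choice`` maps neuron id to ``(left_trial_rates,
    right_trial_rates)``; a two-sided two-sample t-test at level ``alpha``
    decides inclusion.
    """
    kept = []
    for nid, (left, right) in rates_by_choice.items():
        if len(left) < 2 or len(right) < 2:
            raise ValueError(f"neuron {nid}: need >= 2 trials per choice class")
        _, p = ttest_ind(left, right, equal_var=False)
        if p < alpha:
            kept.append(nid)
    return kept


def com_latency_regression(event_times: np.ndarray, latencies: np.ndarray):
    """OLS of response latency on event time (relative to stimulus end).

    Returns ``(slope, p_value)`` with a two-sided t-test on the slope.
    """
    x = np.asarray(event_times, dtype=float)
    y = np.asarray(latencies, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 events")
    if np.ptp(x) == 0:
        raise ValueError("constant regressor")
    res = linregress(x, y)
    return float(res.slope), float(res.pvalue)
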