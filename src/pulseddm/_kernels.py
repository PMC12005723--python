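"""Numba-compiled numerical kernels.

Everything here is a plain-array implementation detail; the public API lives
in :mod:`pulseddm.latent_fp`, :mod:`pulseddm.inference` and
:mod:`pulseddm.synthetic`.  Kernels are written for a uniform latent grid
``centers = linspace(-B, B, n)`` whose outer bins are absorbing.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Gaussian spread truncated at +/- 4 SD
_SD_RANGE = 4.0
# intensity floor (Hz) keeping spike log-likelihoods finite
RATE_FLOOR = 1e-6


@njit(cache=True)
def softplus(x):
    if x > 30.0:
        return x
    if x < -30.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


@njit(cache=True)
def _settle_point(col, centers, dx, x, mass):
    """Deposit `mass` at position x onto the two nearest grid bins."""
    n = centers.shape[0]
    if x <= centers[0]:
        col[0] += mass
    elif x >= centers[n - 1]:
        col[n - 1] += mass
    else:
        f = (x - centers[0]) / dx
        k = int(f)
        if k >= n - 1:
            k = n - 2
        w_hi = f - k
        col[k] += mass * (1.0 - w_hi)
        col[k + 1] += mass * w_hi


@njit(cache=True)
def _n_sub(refine):
    """Quadrature size for the Gaussian spread.

    Fixed given ``refine`` (2*refine points per SD over +/-4 SD) so the
    log-likelihood is smooth in the parameters: a variance-dependent count
    would jump discretely and wreck finite-difference gradients.
    """
    return 8 * refine + 1


@njit(cache=True)
def _settle_gaussian(col, centers, dx, mu, var, refine):
    """Deposit a unit Gaussian N(mu, var) onto the grid (bounds absorbing)."""
    n = centers.shape[0]
    for i in range(n):
        col[i] = 0.0
    if var <= 0.0:
        _settle_point(col, centers, dx, mu, 1.0)
        return
    sd = math.sqrt(var)
    m = _n_sub(refine)
    lo = mu - _SD_RANGE * sd
    step = 2.0 * _SD_RANGE * sd / (m - 1)
    # unnormalized Gaussian weights on the refined grid, normalized to sum 1
    total = 0.0
    for j in range(m):
        x = lo + j * step
        z = (x - mu) / sd
        total += math.exp(-0.5 * z * z)
    for j in range(m):
        x = lo + j * step
        z = (x - mu) / sd
        _settle_point(col, centers, dx, x, math.exp(-0.5 * z * z) / total)


@njit(cache=True)
def drift_gain(lam, dt):
    """(exp(lam*dt) - 1) / (lam*dt), the exact per-bin impulse gain."""
    x = lam * dt
    if abs(x) < 1e-10:
        return 1.0 + 0.5 * x
    return math.expm1(x) / x


@njit(cache=True)
def build_transition(M, centers, dx, lam, dt, delta, tvar, refine):
    """Fill the column-stochastic one-step transition operator.

    Column j holds the destination distribution of mass starting in bin j:
    deterministic linear-ODE update of the bin center followed by a Gaussian
    spread of variance ``tvar``, settled onto the two nearest bins.  The
    outer (absorbing) columns are unit vectors.
    """
    n = centers.shape[0]
    ed = math.exp(lam * dt)
    g = drift_gain(lam, dt)
    for j in range(n):
        for i in range(n):
            M[i, j] = 0.0
    M[0, 0] = 1.0
    M[n - 1, n - 1] = 1.0
    for j in range(1, n - 1):
        mu = centers[j] * ed + delta * g
        _settle_gaussian(M[:, j], centers, dx, mu, tvar, refine)


@njit(cache=True)
def initial_dist(centers, dx, sigma2_i, refine):
    p = np.zeros(centers.shape[0])
    _settle_gaussian(p, centers, dx, 0.0, sigma2_i, refine)
    return p


@njit(cache=True)
def spike_log_weights(counts, exposures, slopes, theta0, centers, disp, use_nb, dt):
    """Per-(time bin, grid bin) log-likelihood of the observed spike counts.

    counts : (N, T+1) int64 spike counts per active neuron
    theta0 : (N, T+1) baseline log-rate argument per neuron and time bin
    slopes : (N,) tuning slopes
    exposures : (T+1,) observation window of each spike bin (s)
    disp : (N,) negative-binomial dispersions (ignored when use_nb is False)

    Returns (T+1, n) array of summed log-likelihoods across neurons.
    """
    N = counts.shape[0]
    T1 = counts.shape[1]
    n = centers.shape[0]
    out = np.zeros((T1, n))
    sc = np.empty((N, n))
    for nn in range(N):
        for i in range(n):
            sc[nn, i] = slopes[nn] * centers[i]
    for t in range(T1):
        e = exposures[t]
        if e <= 0.0:
            continue
        for nn in range(N):
            y = counts[nn, t]
            th0 = theta0[nn, t]
            if not use_nb and y == 0:
                # Poisson zero-count fast path: log pmf is just -mu
                for i in range(n):
                    r = softplus(sc[nn, i] + th0)
                    if r < RATE_FLOOR:
                        r = RATE_FLOOR
                    out[t, i] -= r * e
                continue
            lg = math.lgamma(y + 1.0)
            for i in range(n):
                r = softplus(sc[nn, i] + th0)
                if r < RATE_FLOOR:
                    r = RATE_FLOOR
                mu = r * e
                if use_nb:
                    th = disp[nn]
                    # NB with mean mu, shape th
                    lp = (
                        math.lgamma(y + th)
                        - math.lgamma(th)
                        - lg
                        + th * math.log(th / (mu + th))
                        + y * math.log(mu / (mu + th))
                    )
                else:
                    lp = y * math.log(mu) - mu - lg
                out[t, i] += lp
    return out


@njit(cache=True)
def _spread_template(var, dx, refine):
    """Shared per-step Gaussian quadrature: (offsets, normalized weights).

    The spread applied to every source bin in one time step has the same
    variance, so the sub-point offsets (relative to the post-drift mean) and
    weights are computed once and settled at shifted positions per source.
    """
    sd = math.sqrt(var)
    m = _n_sub(refine)
    offs = np.empty(m)
    w = np.empty(m)
    lo = -_SD_RANGE * sd
    step = 2.0 * _SD_RANGE * sd / (m - 1)
    total = 0.0
    for k in range(m):
        x = lo + k * step
        offs[k] = x
        z = x / sd
        w[k] = math.exp(-0.5 * z * z)
        total += w[k]
    for k in range(m):
        w[k] /= total
    return offs, w


@njit(cache=True)
def _step_direct(p, pnew, centers, dx, ed, g, delta, offs, w, has_var):
    """One transition step applied directly to a distribution (no matrix).

    Sub-point positions within a source's spread are uniformly spaced, so the
    fractional bin coordinate is advanced incrementally (no divisions in the
    inner loop); arithmetic is identical to the matrix construction.
    """
    n = centers.shape[0]
    for i in range(n):
        pnew[i] = 0.0
    pnew[0] = p[0]
    pnew[n - 1] = p[n - 1]
    m = offs.shape[0]
    invdx = 1.0 / dx
    c0 = centers[0]
    top = float(n - 1)
    df = (offs[1] - offs[0]) * invdx if m > 1 else 0.0
    for j in range(1, n - 1):
        pj = p[j]
        if pj <= 1e-300:
            continue
        mu = centers[j] * ed + delta * g
        if not has_var:
            _settle_point(pnew, centers, dx, mu, pj)
        else:
            f = (mu + offs[0] - c0) * invdx
            for k in range(m):
                if f <= 0.0:
                    pnew[0] += pj * w[k]
                elif f >= top:
                    pnew[n - 1] += pj * w[k]
                else:
                    kk = int(f)
                    r = f - kk
                    mass = pj * w[k]
                    pnew[kk] += mass * (1.0 - r)
                    pnew[kk + 1] += mass * r
                f += df


@njit(cache=True)
def forward_filter(
    centers,
    dx,
    p0,
    lam,
    dt,
    var_dt,
    sigma2_s,
    deltas,
    sigmas,
    log_w,
    use_spikes,
    refine,
    M0,
    Ms,
    store_m,
):
    """Forward (filtering) pass over one trial.

    p0 : initial latent distribution (already spike-weighted at t=0 outside
         this kernel when conditioning on spikes; see caller)
    deltas, sigmas : (T,) binned adapted click difference / sum
    log_w : (T+1, n) spike log-weights, used when use_spikes
    M0 : precomputed transition operator for click-free bins
    Ms : (T, n, n) buffer receiving every per-bin operator when store_m

    Returns (loglik, alphas) with alphas (T+1, n) the normalized filtered
    distributions; loglik accumulates the log normalizers (spike factors
    only; the choice factor is applied by the caller).
    """
    n = centers.shape[0]
    T = deltas.shape[0]
    alphas = np.empty((T + 1, n))
    ll = 0.0

    p = p0.copy()
    if use_spikes:
        mx = log_w[0, 0]
        for i in range(1, n):
            if log_w[0, i] > mx:
                mx = log_w[0, i]
        s = 0.0
        for i in range(n):
            p[i] *= math.exp(log_w[0, i] - mx)
            s += p[i]
        ll += math.log(s) + mx
        for i in range(n):
            p[i] /= s
    else:
        s = 0.0
        for i in range(n):
            s += p[i]
        for i in range(n):
            p[i] /= s
    alphas[0] = p

    Mtmp = np.empty((n, n))
    pnew = np.empty(n)
    ed = math.exp(lam * dt)
    g = drift_gain(lam, dt)
    offs0, w0 = _spread_template(var_dt, dx, refine) if var_dt > 0.0 else (
        np.zeros(1), np.ones(1)
    )
    for t in range(T):
        tvar = var_dt + sigma2_s * sigmas[t]
        if store_m:
            if sigmas[t] == 0.0 and deltas[t] == 0.0:
                M = M0
            else:
                build_transition(Mtmp, centers, dx, lam, dt, deltas[t], tvar, refine)
                M = Mtmp
            Ms[t] = M
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += M[i, j] * p[j]
                pnew[i] = acc
        else:
            if sigmas[t] == 0.0:
                offs, w = offs0, w0
            elif tvar > 0.0:
                offs, w = _spread_template(tvar, dx, refine)
            else:
                offs, w = np.zeros(1), np.ones(1)
            _step_direct(p, pnew, centers, dx, ed, g, deltas[t], offs, w, tvar > 0.0)
        if use_spikes:
            mx = log_w[t + 1, 0]
            for i in range(1, n):
                if log_w[t + 1, i] > mx:
                    mx = log_w[t + 1, i]
            s = 0.0
            for i in range(n):
                pnew[i] *= math.exp(log_w[t + 1, i] - mx)
                s += pnew[i]
            ll += math.log(s) + mx
        else:
            s = 0.0
            for i in range(n):
                s += pnew[i]
        for i in range(n):
            p[i] = pnew[i] / s
        alphas[t + 1] = p
    return ll, alphas


@njit(cache=True)
def backward_smooth(alphas, Ms, log_w, use_spikes, beta_T):
    """Backward pass producing smoothed marginals from stored quantities.

    beta_T : terminal weight vector (choice factor, or ones).
    Returns (T+1, n) smoothed distributions, each normalized to 1.
    """
    T1, n = alphas.shape
    T = T1 - 1
    post = np.empty((T1, n))
    beta = beta_T.copy()
    # normalize to guard underflow
    s = beta.sum()
    if s > 0:
        beta = beta / s
    for t in range(T, -1, -1):
        g = alphas[t] * beta
        tot = g.sum()
        post[t] = g / tot
        if t > 0:
            w = np.empty(n)
            if use_spikes:
                mx = log_w[t, 0]
                for i in range(1, n):
                    if log_w[t, i] > mx:
                        mx = log_w[t, i]
                for i in range(n):
                    w[i] = beta[i] * math.exp(log_w[t, i] - mx)
            else:
                for i in range(n):
                    w[i] = beta[i]
            bnew = np.empty(n)
            for j in range(n):
                acc = 0.0
                for i in range(n):
                    acc += Ms[t - 1][i, j] * w[i]
                bnew[j] = acc
            s = bnew.sum()
            beta = bnew / s if s > 0 else bnew
    return post


@njit(cache=True)
def adapt_mags_pooled(times, phi, tau_phi):
    """Pre-jump adaptation state of each click in a pooled, sorted train.

    Clicks sharing a timestamp all receive the same pre-jump state; their
    multiplicative jumps then compound.
    """
    m = times.shape[0]
    mags = np.empty(m)
    c = 1.0
    i = 0
    while i < m:
        if i > 0:
            c = 1.0 - (1.0 - c) * math.exp(-(times[i] - times[i - 1]) / tau_phi)
        j = i
        while j < m and times[j] == times[i]:
            mags[j] = c
            j += 1
        for _ in range(i, j):
            c *= phi
        i = j
    return mags


@njit(cache=True)
def simulate_paths(
    times, sides, mags, duration, step, n_paths,
    sigma2_i, B, lam, sigma2_a, sigma2_s, seeds,
):
    """Euler-Maruyama simulation of the bounded accumulator.

    Clicks are applied at their exact times (magnitude +/- mags[i] with
    Gaussian click noise of variance sigma2_s * mags[i]); the path freezes
    once |a| >= B (sticky bound).  Returns (n_paths, n_steps+1) paths sampled
    every `step` seconds.
    """
    n_steps = int(round(duration / step))
    out = np.empty((n_paths, n_steps + 1))
    sq_a = math.sqrt(sigma2_a * step)
    sq_i = math.sqrt(sigma2_i)
    # integer step index of each click (avoids float bin-edge mismatches)
    cstep = np.empty(times.shape[0], dtype=np.int64)
    for i in range(times.shape[0]):
        ks = int(times[i] / step)
        if ks > n_steps - 1:
            ks = n_steps - 1
        cstep[i] = ks
    for p in range(n_paths):
        np.random.seed(seeds[p])
        a = sq_i * np.random.randn()
        out[p, 0] = a
        ci = 0
        stuck = abs(a) >= B
        for k in range(n_steps):
            if not stuck:
                da = lam * a * step + sq_a * np.random.randn()
                while ci < times.shape[0] and cstep[ci] == k:
                    mg = mags[ci]
                    da += sides[ci] * mg + math.sqrt(sigma2_s * mg) * np.random.randn()
                    ci += 1
                a += da
                if abs(a) >= B:
                    a = B if a > 0 else -B
                    stuck = True
            else:
                while ci < times.shape[0] and cstep[ci] == k:
                    ci += 1
            out[p, k + 1] = a
    return out


@njit(cache=True)
def bin_path_means(path, step, dt, duration):
    """Average a fine-step path within each half-offset spike-bin window."""
    T = max(1, int(math.ceil(duration / dt - 1e-9)))
    n_steps = path.shape[0] - 1
    out = np.zeros(T + 1)
    cnt = np.zeros(T + 1)
    for k in range(n_steps + 1):
        t = k * step
        if t > duration:
            break
        kk = int(math.floor(t / dt + 0.5))
        if kk > T:
            kk = T
        out[kk] += path[k]
        cnt[kk] += 1.0
    for k in range(T + 1):
        if cnt[k] > 0:
            out[k] /= cnt[k]
    return out


@njit(cache=True)
def dataset_spike_logw(
    counts_flat, theta0_flat, row_off, active_flat, act_off,
    exposures_flat, t_off, T_arr, centers, slopes, disps, use_nb,
):
    """Per-neuron-row spike log-weights for a whole packed dataset.

    Returns a flat array laid out like ``counts_flat`` expanded by the grid
    size: row ``r`` (one neuron, one time bin) occupies
    ``logw[r*n : (r+1)*n]``.  This is the transcendental-heavy part of the
    likelihood and depends only on (grid, slopes, dispersions), so callers
    cache it across evaluations that perturb other parameters.
    """
    n = centers.shape[0]
    K = T_arr.shape[0]
    out = np.zeros(counts_flat.shape[0] * n)
    for k in range(K):
        T1 = T_arr[k] + 1
        a0, a1 = act_off[k], act_off[k + 1]
        exposures = exposures_flat[t_off[k] : t_off[k] + T1]
        for a in range(a1 - a0):
            r0 = row_off[k] + a * T1
            nid = active_flat[a0 + a]
            sl = slopes[nid]
            dp = disps[nid]
            for t in range(T1):
                e = exposures[t]
                if e <= 0.0:
                    continue
                y = counts_flat[r0 + t]
                th0 = theta0_flat[r0 + t]
                base = (r0 + t) * n
                if not use_nb and y == 0:
                    for i in range(n):
                        r = softplus(sl * centers[i] + th0)
                        if r < RATE_FLOOR:
                            r = RATE_FLOOR
                        out[base + i] = -r * e
                else:
                    lg = math.lgamma(y + 1.0)
                    for i in range(n):
                        r = softplus(sl * centers[i] + th0)
                        if r < RATE_FLOOR:
                            r = RATE_FLOOR
                        mu = r * e
                        if use_nb:
                            out[base + i] = (
                                math.lgamma(y + dp)
                                - math.lgamma(dp)
                                - lg
                                + dp * math.log(dp / (mu + dp))
                                + y * math.log(mu / (mu + dp))
                            )
                        else:
                            out[base + i] = y * math.log(mu) - mu - lg
    return out


@njit(cache=True)
def dataset_loglik(
    # grid / dynamics
    centers, dx, p0, M0, lam, dt, var_dt, sigma2_s, phi, tau_phi, refine,
    # clicks: flat arrays with per-trial offsets
    click_t, click_s, click_bin, click_off,
    # spikes: flat counts/theta0 (row-major per trial), neuron row offsets
    counts_flat, theta0_flat, row_off, active_flat, act_off,
    exposures_flat, t_off, T_arr,
    # precomputed per-row spike log-weights (see dataset_spike_logw)
    logw_flat,
    # observation / choice parameters
    slopes, disps, use_nb, cw_right, choices,
    use_spikes, independent,
):
    """Log-likelihood of every trial of a packed dataset.

    Layout: trial k owns clicks ``click_off[k]:click_off[k+1]``, spike-bin
    data ``t_off[k]:t_off[k+1]`` (length T_arr[k]+1), active neurons
    ``act_off[k]:act_off[k+1]``, and count/baseline rows starting at
    ``row_off[k]`` (one row of length T_arr[k]+1 per active neuron).
    """
    n = centers.shape[0]
    K = T_arr.shape[0]
    lls = np.empty(K)
    Mbuf = np.empty((1, n, n))
    for k in range(K):
        T = T_arr[k]
        T1 = T + 1
        c0, c1 = click_off[k], click_off[k + 1]
        mags = adapt_mags_pooled(click_t[c0:c1], phi, tau_phi)
        deltas = np.zeros(T)
        sigmas = np.zeros(T)
        for j in range(c1 - c0):
            b = click_bin[c0 + j]
            deltas[b] += click_s[c0 + j] * mags[j]
            sigmas[b] += mags[j]
        exposures = exposures_flat[t_off[k] : t_off[k] + T1]
        a0, a1 = act_off[k], act_off[k + 1]
        n_act = a1 - a0
        fvec = np.empty(n)
        if choices[k] == 1:
            for i in range(n):
                fvec[i] = cw_right[i]
        else:
            for i in range(n):
                fvec[i] = 1.0 - cw_right[i]
        if use_spikes and n_act > 0 and independent and n_act > 1:
            ll = 0.0
            pr_sum = 0.0
            for a in range(n_act):
                r0 = row_off[k] + a * T1
                logw = logw_flat[r0 * n : (r0 + T1) * n].reshape(T1, n)
                lli, alphas = forward_filter(
                    centers, dx, p0, lam, dt, var_dt, sigma2_s,
                    deltas, sigmas, logw, True, refine, M0, Mbuf, False,
                )
                ll += lli
                acc = 0.0
                for i in range(n):
                    acc += alphas[T, i] * fvec[i]
                pr_sum += acc
            p_mean = pr_sum / n_act
            if p_mean < 1e-300:
                p_mean = 1e-300
            lls[k] = ll + math.log(p_mean)
        else:
            sp = use_spikes and n_act > 0
            if sp:
                r0 = row_off[k]
                logw = np.zeros((T1, n))
                for a in range(n_act):
                    base = (r0 + a * T1) * n
                    for t in range(T1):
                        for i in range(n):
                            logw[t, i] += logw_flat[base + t * n + i]
            else:
                logw = np.zeros((1, n))
            ll, alphas = forward_filter(
                centers, dx, p0, lam, dt, var_dt, sigma2_s,
                deltas, sigmas, logw, sp, refine, M0, Mbuf, False,
            )
            acc = 0.0
            for i in range(n):
                acc += alphas[T, i] * fvec[i]
            if acc < 1e-300:
                acc = 1e-300
            lls[k] = ll + math.log(acc)
    return lls


@njit(cache=True)
def simulate_terminal(
    times, sides, mags, duration, step, n_paths,
    sigma2_i, B, lam, sigma2_a, sigma2_s, seeds,
):
    """Terminal accumulator values of Euler-Maruyama paths (memory-light)."""
    n_steps = int(round(duration / step))
    out = np.empty(n_paths)
    sq_a = math.sqrt(sigma2_a * step)
    sq_i = math.sqrt(sigma2_i)
    cstep = np.empty(times.shape[0], dtype=np.int64)
    for i in range(times.shape[0]):
        ks = int(times[i] / step)
        if ks > n_steps - 1:
            ks = n_steps - 1
        cstep[i] = ks
    for p in range(n_paths):
        np.random.seed(seeds[p])
        a = sq_i * np.random.randn()
        ci = 0
        stuck = abs(a) >= B
        for k in range(n_steps):
            if stuck:
                break
            da = lam * a * step + sq_a * np.random.randn()
            while ci < times.shape[0] and cstep[ci] == k:
                mg = mags[ci]
                da += sides[ci] * mg + math.sqrt(sigma2_s * mg) * np.random.randn()
                ci += 1
            a += da
            if abs(a) >= B:
                a = B if a > 0 else -B
                stuck = True
        out[p] = a
    return out
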