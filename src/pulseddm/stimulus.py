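"""Click stimuli, sensory adaptation, and relative binning of clicks and spikes.

The accumulator model is driven by brief auditory pulses ("clicks") delivered
on a left and a right channel.  The effective magnitude of each click is
depressed by recent clicks (sensory adaptation) before being accumulated.
Clicks and spikes are binned onto a common time grid of width ``dt``, with the
spike bins offset by ``dt/2`` relative to the click bins so that the spike bin
centered at ``k*dt`` surrounds the forward edge of click bin ``k - 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClickTrain",
    "AdaptedClicks",
    "BinnedStimulus",
    "adapt_clicks",
    "bin_stimulus",
    "bin_spikes",
    "n_time_bins",
    "spike_bin_exposures",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClickTrain:
    """Timing of the left and right click pulses of one trial.

    Parameters
    ----------
    left_times, right_times:
        Click times in seconds, ascending, within ``[0, duration]``.
    duration:
        Stimulus period in seconds (strictly positive).
    """

    left_times: np.ndarray
    right_times: np.ndarray
    duration: float

    def __post_init__(self):
        object.__setattr__(self, "left_times", np.asarray(self.left_times, dtype=float))
        object.__setattr__(self, "right_times", np.asarray(self.right_times, dtype=float))
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name, t in (("left_times", self.left_times), ("right_times", self.right_times)):
            if t.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"{name} must be sorted ascending")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(f"{name} must lie within [0, duration]")

    @property
    def n_left(self) -> int:
        return int(self.left_times.size)

    @property
    def n_right(self) -> int:
        return int(self.right_times.size)

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All click times pooled and sorted, with per-click sides (+1 right, -1 left).

        Simultaneous left/right clicks are ordered left-first (ties are
        order-dependent only through shared adaptation, at small magnitude).
        """
        times = np.concatenate([self.left_times, self.right_times])
        sides = np.concatenate(
            [np.full(self.n_left, -1.0), np.full(self.n_right, 1.0)]
        )
        # stable sort keeps left (listed first) ahead of right on exact ties
        order = np.argsort(times, kind="stable")
        t_sorted = times[order]
        if t_sorted.size > 1 and np.any(np.diff(t_sorted) == 0):
            log.debug("simultaneous clicks present; ties processed left-first")
        return t_sorted, sides[order]


@dataclass(frozen=True)
class AdaptedClicks:
    """Adapted (unitless) magnitude of every click of a :class:`ClickTrain`."""

    left_mags: np.ndarray
    right_mags: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "left_mags", np.asarray(self.left_mags, dtype=float))
        object.__setattr__(self, "right_mags", np.asarray(self.right_mags, dtype=float))
        if np.any(self.left_mags < 0) or np.any(self.right_mags < 0):
            raise ValueError("adapted magnitudes must be non-negative")


@dataclass(frozen=True)
class BinnedStimulus:
    """Per-bin adapted click difference and sum on the model time grid.

    ``delta[t]`` is the right-minus-left adapted magnitude in click bin
    ``[t*dt, (t+1)*dt)``; ``sigma[t]`` is the total adapted magnitude.  The
    companion spike bins are offset by ``spike_offset = dt/2``.
    """

    delta: np.ndarray
    sigma: np.ndarray
    dt: float
    duration: float
    spike_offset: float = field(default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma < -1e-12):
            raise ValueError("sigma must be non-negative")
        if np.any(np.abs(self.delta) > self.sigma + 1e-9):
            raise ValueError("|delta| must not exceed sigma")

    @property
    def n_bins(self) -> int:
        return int(self.delta.size)


def n_time_bins(duration: float, dt: float) -> int:
    """Number of click bins needed to cover ``[0, duration)``."""
    return max(1, int(math.ceil(duration / dt - 1e-9)))


def _relax(c: float, gap: float, tau_phi: float) -> float:
    # closed form of dC/dt = (1 - C)/tau_phi over an inter-click gap
    return 1.0 - (1.0 - c) * math.exp(-gap / tau_phi)


def adapt_clicks(
    train: ClickTrain,
    phi: float,
    tau_phi: float,
    cross_side: bool = True,
) -> AdaptedClicks:
    """Apply multiplicative sensory adaptation to a click train.

    The adaptation state ``C`` starts at 1, relaxes toward 1 between clicks
    with timescale ``tau_phi``, and is multiplied by ``phi`` at each click.
    A click's effective magnitude is the state *just before* its own jump, so
    an isolated click always has magnitude 1.

    Parameters
    ----------
    phi:
        Adaptation strength; ``phi < 1`` is depression, ``phi = 1`` identity.
    tau_phi:
        Recovery timescale in seconds.
    cross_side:
        If True (default) left and right clicks share a single adaptation
        state; if False each side adapts independently.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if tau_phi <= 0:
        raise ValueError("tau_phi must be positive")

    def _run(times: np.ndarray) -> np.ndarray:
        # clicks sharing a timestamp all see the same pre-jump state (the
        # impulse ODE evaluates C(t^-) once; their jumps then compound)
        mags = np.empty(times.size)
        c = 1.0
        i = 0
        while i < times.size:
            if i > 0:
                c = _relax(c, times[i] - times[i - 1], tau_phi)
            j = i
            while j < times.size and times[j] == times[i]:
                mags[j] = c
                j += 1
            c *= phi ** (j - i)
            i = j
        return mags

    if cross_side:
        times, sides = train.merged()
        mags = _run(times)
        left = mags[sides < 0]
        right = mags[sides > 0]
        # restore the original per-side ordering (merged() sorts by time,
        # which is already ascending within each side)
        return AdaptedClicks(left_mags=left, right_mags=right)
    return AdaptedClicks(
        left_mags=_run(train.left_times), right_mags=_run(train.right_times)
    )


def bin_stimulus(train: ClickTrain, mags: AdaptedClicks, dt: float) -> BinnedStimulus:
    """Bin adapted click magnitudes into difference and sum per click bin."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mags.left_mags.size != train.n_left or mags.right_mags.size != train.n_right:
        raise ValueError("adapted magnitudes do not match the click train")
    n = n_time_bins(train.duration, dt)
    delta = np.zeros(n)
    sigma = np.zeros(n)
    for times, m, sign in (
        (train.left_times, mags.left_mags, -1.0),
        (train.right_times, mags.right_mags, 1.0),
    ):
        idx = np.minimum((times / dt).astype(int), n - 1)
        np.add.at(delta, idx, sign * m)
        np.add.at(sigma, idx, m)
    return BinnedStimulus(
        delta=delta, sigma=sigma, dt=dt, duration=train.duration, spike_offset=dt / 2
    )


def spike_bin_exposures(duration: float, dt: float) -> np.ndarray:
    """Observation-window length of each spike bin, in seconds.

    Spike bin ``k`` (``k = 0 .. T``) spans ``[k*dt - dt/2, k*dt + dt/2)``
    intersected with the stimulus period ``[0, duration]``; the edge bins are
    therefore partially exposed.
    """
    T = n_time_bins(duration, dt)
    k = np.arange(T + 1)
    lo = np.maximum(k * dt - dt / 2, 0.0)
    hi = np.minimum(k * dt + dt / 2, duration)
    return np.maximum(hi - lo, 0.0)


def bin_spikes(
    spike_times: np.ndarray | list,
    dt: float,
    duration: float,
    latency: float = 0.0,
) -> np.ndarray:
    """Count spikes in half-offset bins, per neuron.

    Spike times are shifted *backward* by the response latency, then counted
    in bins ``[k*dt - dt/2, k*dt + dt/2)`` for ``k = 0 .. T`` where ``T`` is
    the number of click bins.  Shifted times outside ``[0, duration]`` are
    dropped (the drop count is logged).

    Parameters
    ----------
    spike_times:
        Either a single 1-d array of times or a sequence of such arrays
        (one per neuron).
    """
    if latency < 0:
        raise ValueError("latency must be non-negative")
    single = isinstance(spike_times, np.ndarray) and np.asarray(spike_times).ndim == 1
    trains = [np.asarray(spike_times, dtype=float)] if single else [
        np.asarray(s, dtype=float) for s in spike_times
    ]
    T = n_time_bins(duration, dt)
    edges = np.arange(T + 2) * dt - dt / 2
    counts = np.zeros((len(trains), T + 1), dtype=np.int64)
    dropped = 0
    for i, t in enumerate(trains):
        t = t - latency
        keep = (t >= 0.0) & (t <= duration)
        dropped += int(t.size - keep.sum())
        counts[i] = np.histogram(t[keep], bins=edges)[0]
    if dropped:
        log.debug("bin_spikes: dropped %d spikes outside [0, duration]", dropped)
    return counts[0] if single else counts
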