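"""Cell-attached single-channel analysis.

A patch contains k identical channels, each an independent two-state
(closed/open) continuous-time Markov chain.  Simulated sweeps superpose
the k gating trajectories, scale by the unitary current (negative for
inward Ba2+ current), pass the signal through a 4-pole low-pass Bessel
filter (2 kHz on 10 kHz samples by default, matching patch-clamp
acquisition) and add Gaussian instrumentation noise.

Analysis follows the classic event-based workflow: half-amplitude
idealization assigns an integer open level per sample using thresholds
at (m - 1/2) times the unitary current, merges events shorter than the
filter risetime (0.3321 / f_c), estimates the channel count k as the
maximum number of simultaneous openings ever observed (a reliable
estimator for k < 4), and converts the time-averaged open level NP_o to
the per-channel open probability P_o = NP_o / k.  No missed-event
correction beyond minimum-duration merging is applied; at low
signal-to-noise this is a known source of bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal

__all__ = [
    "GatingModel",
    "SweepSet",
    "EventList",
    "simulate_sweeps",
    "idealize_half_height",
    "estimate_channel_count",
    "open_probability",
    "mean_ensemble_average",
    "filter_risetime",
]

#: Risetime constant of a 4-pole Bessel low-pass: t_r = 0.3321 / f_c.
BESSEL_RISETIME_CONST = 0.3321


@dataclass(frozen=True)
class GatingModel:
    """Two-state gating of k identical channels.

    ``open_rate`` (closed->open) and ``close_rate`` (open->closed) in
    s^-1; equilibrium P_o = open_rate / (open_rate + close_rate).
    """

    open_rate: float
    close_rate: float
    unitary_current: float  # pA, negative for inward
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.open_rate <= 0 or self.close_rate <= 0:
            raise ValueError("rates must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")

    @property
    def p_open(self) -> float:
        return self.open_rate / (self.open_rate + self.close_rate)

    @classmethod
    def from_po(cls, p_open: float, close_rate: float, unitary_current: float,
                n_channels: int = 1) -> "GatingModel":
        """Build a model with a target equilibrium P_o at a given close rate."""
        if not 0 < p_open < 1:
            raise ValueError("p_open must lie in (0, 1)")
        return cls(close_rate * p_open / (1.0 - p_open), close_rate,
                   unitary_current, n_channels)


@dataclass(frozen=True)
class SweepSet:
    """Equal-length current sweeps with their acquisition settings."""

    sweeps: np.ndarray  # (n_sweeps, n_samples), pA
    sampling_rate: float  # Hz
    sweep_duration: float  # s
    filter_cutoff: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "sweeps", np.atleast_2d(np.asarray(self.sweeps, float)))
        if self.sampling_rate < 2.0 * self.filter_cutoff:
            raise ValueError("sampling_rate must be at least twice the filter cutoff")


@dataclass(frozen=True)
class EventList:
    """Per-sweep (level, start_s, duration_s) events tiling each sweep."""

    events: List[List[Tuple[int, float, float]]]
    sweep_duration: float

    def max_level(self) -> int:
        levels = [lv for sweep in self.events for (lv, _, _) in sweep]
        return max(levels) if levels else 0


def filter_risetime(filter_cutoff: float) -> float:
    return BESSEL_RISETIME_CONST / filter_cutoff


def _dwell_levels(rng: np.random.Generator, open_rate: float, close_rate: float,
                  n_samples: int, dt: float) -> np.ndarray:
    """One channel's 0/1 occupancy on the sample grid, exact exponential dwells."""
    p_open = open_rate / (open_rate + close_rate)
    state = int(rng.random() < p_open)  # stationary start
    out = np.zeros(n_samples, dtype=np.int8)
    t = 0.0
    total = n_samples * dt
    while t < total:
        rate = close_rate if state else open_rate
        dwell = rng.exponential(1.0 / rate)
        if state:
            i0 = int(np.ceil(t / dt - 1e-12))
            i1 = min(int(np.ceil((t + dwell) / dt - 1e-12)), n_samples)
            out[i0:i1] = 1
        t += dwell
        state ^= 1
    return out


def simulate_sweeps(
    model: GatingModel,
    n_sweeps: int,
    duration: float,
    sampling_rate: float = 10_000.0,
    noise_sd: float = 0.2,
    filter_cutoff: float = 2_000.0,
    seed: Optional[int] = None,
) -> SweepSet:
    """Simulate filtered, noisy sweeps of k superposed two-state channels."""
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate
    levels = np.zeros((n_sweeps, n_samples), dtype=np.int16)
    for s in range(n_sweeps):
        for _ in range(model.n_channels):
            levels[s] += _dwell_levels(rng, model.open_rate, model.close_rate,
                                       n_samples, dt)
    traces = levels.astype(float) * model.unitary_current

    sos = signal.bessel(4, filter_cutoff, btype="low", fs=sampling_rate, output="sos")
    zi = signal.sosfilt_zi(sos)
    filtered = np.empty_like(traces)
    for s in range(n_sweeps):
        # steady-state initial conditions avoid a startup transient
        filtered[s], _ = signal.sosfilt(sos, traces[s], zi=zi * traces[s, 0])
    if noise_sd > 0:
        filtered += rng.normal(0.0, noise_sd, size=filtered.shape)
    return SweepSet(filtered, sampling_rate, duration, filter_cutoff)


def _merge_short_runs(levels: np.ndarray, min_samples: int) -> np.ndarray:
    """Absorb runs shorter than ``min_samples`` into their longer neighbour."""
    if min_samples <= 1:
        return levels
    lv = levels.copy()
    for _ in range(20):  # merging can cascade; loop to a fixed point
        change = np.flatnonzero(np.diff(lv)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lv.size]))
        lengths = ends - starts
        short = np.flatnonzero(lengths < min_samples)
        if short.size == 0 or starts.size == 1:
            break
        for r in short:
            if lengths[r] >= min_samples:
                continue
            left_len = lengths[r - 1] if r > 0 else -1
            right_len = lengths[r + 1] if r < starts.size - 1 else -1
            src = r - 1 if left_len >= right_len else r + 1
            lv[starts[r]:ends[r]] = lv[starts[src]]
    return lv


def idealize_half_height(
    sweeps: SweepSet,
    unitary_current: float,
    k_max: int = 5,
    smoothing_samples: Optional[int] = None,
) -> EventList:
    """Half-amplitude idealization into integer open levels.

    Sample j is assigned level m when the current lies between
    (m - 1/2) and (m + 1/2) unitary currents (threshold crossings at the
    half amplitudes), clipped to [0, k_max]; events shorter than the
    filter risetime are merged into their neighbours.  Polarity follows
    ``unitary_current``, so the idealization is invariant to flipping
    both trace and unitary current.

    Before thresholding, the trace is conditioned with a centred boxcar
    of odd length ``smoothing_samples`` (default: ~2.5 filter risetimes,
    5 samples at 2 kHz / 10 kHz), the digital smoothing conventionally
    applied ahead of event detection.  A centred odd boxcar leaves the
    half-amplitude crossing samples of isolated square events in place
    while suppressing white-noise excursions past the next half-level,
    which would otherwise fabricate brief simultaneous-opening events.
    """
    if unitary_current == 0:
        raise ValueError("unitary current must be non-zero")
    # median |first difference| of Gaussian noise is 0.6745 * sqrt(2) * sd
    noise_est = float(np.median(np.abs(np.diff(sweeps.sweeps, axis=1))) / 0.9539)
    if abs(unitary_current) < 3.0 * noise_est:
        warnings.warn("unitary current below 3x estimated noise SD; idealization unreliable")
    rise_samples = filter_risetime(sweeps.filter_cutoff) * sweeps.sampling_rate
    if smoothing_samples is None:
        smoothing_samples = int(np.ceil(2.5 * rise_samples)) | 1
    if smoothing_samples % 2 == 0:
        raise ValueError("smoothing_samples must be odd (centred window)")
    min_samples = max(1, int(round(rise_samples)))
    dt = 1.0 / sweeps.sampling_rate
    kernel = np.ones(smoothing_samples) / smoothing_samples
    events: List[List[Tuple[int, float, float]]] = []
    for trace in sweeps.sweeps:
        if smoothing_samples > 1:
            half = smoothing_samples // 2
            padded = np.concatenate((np.full(half, trace[0]), trace, np.full(half, trace[-1])))
            trace = np.convolve(padded, kernel, mode="valid")
        lv = np.clip(np.floor(trace / unitary_current + 0.5).astype(int), 0, k_max)
        lv = _merge_short_runs(lv, min_samples)
        change = np.flatnonzero(np.diff(lv)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lv.size]))
        events.append([(int(lv[s]), s * dt, (e - s) * dt) for s, e in zip(starts, ends)])
    return EventList(events, sweeps.sweep_duration)


def estimate_channel_count(events: EventList) -> int:
    """k = maximum simultaneous open level ever observed (P_MAX).

    An undercount is possible when simultaneous openings are rare; the
    estimator is considered precise only for k < 4.
    """
    if not events.events or all(len(sw) == 0 for sw in events.events):
        raise ValueError("empty event list")
    k = events.max_level()
    if k >= 4:
        warnings.warn("k >= 4 estimated from simultaneous openings is imprecise")
    return max(k, 1)


def open_probability(events: EventList, k: int, sweep_duration: Optional[float] = None
                     ) -> tuple[float, float]:
    """(NP_o, P_o): time-averaged open level and its per-channel correction."""
    if k < 1:
        raise ValueError("channel count k must be >= 1")
    dur = sweep_duration if sweep_duration is not None else events.sweep_duration
    total_time = dur * len(events.events)
    open_time = sum(lv * d for sweep in events.events for (lv, _, d) in sweep)
    npo = open_time / total_time
    return npo, npo / k


def mean_ensemble_average(sweeps: SweepSet) -> np.ndarray:
    """Pointwise mean current across sweeps (pA).

    For stationary gating the plateau converges to k * P_o * i.
    """
    if sweeps.sweeps.size == 0:
        raise ValueError("no sweeps")
    return sweeps.sweeps.mean(axis=0)
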