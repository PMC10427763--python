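"""Twitch kinetics from single-cell displacement traces.

A displacement trace (distance of a tracked nucleus from its resting
position) is dissected into contraction cycles: local minima and maxima are
detected with a relative prominence criterion, forced to alternate, and each
min → max → min triple becomes one twitch with an amplitude, an acceleration
(rise) time and a relaxation (fall) time.  The dominant pacing frequency is
the largest non-DC peak of the zero-padded FFT of the trace, and fatigue
under continuous stimulation is the first instant the rolling RMS velocity
drops to the pre-stimulation baseline level for a sustained interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .piv import DisplacementTrace

__all__ = [
    "TwitchEvent",
    "KineticsSummary",
    "detect_extrema",
    "dissect_twitches",
    "dominant_frequency",
    "contraction_velocity",
    "fatigue_time",
    "summarize",
]


@dataclass(frozen=True)
class TwitchEvent:
    """One contraction cycle delimited by two minima around a peak."""

    start_min_index: int
    peak_index: int
    end_min_index: int
    amplitude: float  # µm, peak − preceding minimum
    acceleration_time: float  # s
    relaxation_time: float  # s


@dataclass(frozen=True)
class KineticsSummary:
    contraction_velocity: float  # µm/s, mean instantaneous speed
    dominant_frequency: float  # Hz
    period: float  # s (1/frequency; nan when frequency is 0)
    mean_acceleration_time: float  # s
    mean_relaxation_time: float  # s
    mean_amplitude: float  # µm
    n_twitches: int
    fatigue_time: float | None = None  # s from stimulation onset


def _trace_values(trace) -> np.ndarray:
    if isinstance(trace, DisplacementTrace):
        return np.asarray(trace.displacement, dtype=float)
    return np.asarray(trace, dtype=float)


def detect_extrema(
    trace, prominence_fraction: float = 0.1, smooth_window: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating local minima and maxima of a displacement trace.

    Extrema must have a prominence of at least ``prominence_fraction`` times
    the global range of the trace; where two extrema of the same kind would
    be adjacent, only the more extreme one is kept.  Detection runs on a
    lightly Savitzky–Golay-smoothed copy (``smooth_window`` samples,
    quadratic; 0 disables) so single-sample noise dips do not masquerade as
    twitch boundaries; on noise-free traces the smoothed extrema coincide
    with the raw ones.  A leading minimum/maximum is admitted at the start
    of the trace when the first detected extremum needs one (traces start at
    rest); a trailing minimum is admitted only where the trace demonstrably
    settles before its end, so a truncated final cycle yields no event.
    Returns ``(minima, maxima)`` index arrays; both empty for a flat trace.
    """
    y = _trace_values(trace)
    if y.size < 3:
        raise ValueError("trace needs at least 3 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite samples")
    rng = float(y.max() - y.min())
    if rng == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    smooth = y
    radius = 0
    if smooth_window and smooth_window > 2 and y.size > smooth_window:
        w = smooth_window + (smooth_window % 2 == 0)  # odd
        smooth = signal.savgol_filter(y, w, 2)
        radius = w // 2
    prom = prominence_fraction * rng
    maxima = signal.find_peaks(smooth, prominence=prom)[0]
    minima = signal.find_peaks(-smooth, prominence=prom)[0]

    cand = [(int(i), +1) for i in maxima] + [(int(i), -1) for i in minima]
    # candidates were located on the smoothed curve; snap each to the raw
    # extremum within the smoothing radius so timings stay unbiased
    if radius:
        snapped = []
        for i, kind in cand:
            lo, hi = max(0, i - radius), min(y.size, i + radius + 1)
            seg = y[lo:hi]
            j = lo + int(np.argmax(seg) if kind == +1 else np.argmin(seg))
            snapped.append((j, kind))
        cand = snapped
    cand.sort()
    if cand:
        # leading extremum: the segment before the first detected extremum
        # contains the true cycle boundary (e.g. the rest position a twitch
        # starts from); take its extreme sample, preferring the latest tie
        i0, k0 = cand[0]
        seg = y[: i0 + 1]
        if k0 == +1 and y[i0] - seg.min() >= prom / 2:
            j = int(len(seg) - 1 - np.argmin(seg[::-1]))
            if j < i0:
                cand.insert(0, (j, -1))
        elif k0 == -1 and seg.max() - y[i0] >= prom / 2:
            j = int(len(seg) - 1 - np.argmax(seg[::-1]))
            if j < i0:
                cand.insert(0, (j, +1))
        # trailing minimum: only if the post-peak segment reaches its
        # minimum strictly before the last sample (the trace has settled);
        # a still-falling tail is a truncated cycle and yields nothing
        i1, k1 = cand[-1]
        if k1 == +1 and i1 < y.size - 1:
            seg = y[i1 + 1 :]
            j = i1 + 1 + int(np.argmin(seg))
            if j < y.size - 1 and y[i1] - y[j] >= prom / 2:
                cand.append((j, -1))

    # enforce strict alternation: of two same-kind neighbours keep the extremer
    out: list[tuple[int, int]] = []
    for idx, kind in cand:
        if out and out[-1][1] == kind:
            prev_idx = out[-1][0]
            better = y[idx] > y[prev_idx] if kind == +1 else y[idx] < y[prev_idx]
            if better:
                out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    mins = np.array([i for i, k in out if k == -1], dtype=int)
    maxs = np.array([i for i, k in out if k == +1], dtype=int)
    return mins, maxs


def dissect_twitches(trace, extrema=None, dt: float | None = None) -> list[TwitchEvent]:
    """Split a trace into twitch events, one per min → max → min triple.

    A partial cycle at either end of the trace (a peak without a closing
    minimum, or vice versa) yields no event.
    """
    y = _trace_values(trace)
    if dt is None:
        if not isinstance(trace, DisplacementTrace):
            raise ValueError("dt is required when trace is a bare array")
        dt = trace.dt
    if extrema is None:
        extrema = detect_extrema(trace)
    minima, maxima = extrema
    merged = sorted(
        [(int(i), -1) for i in minima] + [(int(i), +1) for i in maxima]
    )
    for (ia, ka), (ib, kb) in zip(merged, merged[1:]):
        if ka == kb:
            raise ValueError("extrema must alternate")
    events = []
    for j in range(1, len(merged) - 1):
        idx, kind = merged[j]
        if kind != +1:
            continue
        i_start, k_start = merged[j - 1]
        i_end, k_end = merged[j + 1]
        if k_start != -1 or k_end != -1:
            continue
        amp = float(y[idx] - y[i_start])
        if amp <= 0:
            continue
        events.append(
            TwitchEvent(
                start_min_index=i_start,
                peak_index=idx,
                end_min_index=i_end,
                amplitude=amp,
                acceleration_time=(idx - i_start) * dt,
                relaxation_time=(i_end - idx) * dt,
            )
        )
    return events


def dominant_frequency(
    trace,
    dt: float | None = None,
    pad_factor: int = 4,
    noise_floor_factor: float = 5.0,
) -> float:
    """Frequency (Hz) of the representative sine of the trace.

    The mean-subtracted trace is zero-padded ``pad_factor``-fold and the
    largest non-DC amplitude of its FFT is located; 0 is returned when no bin
    exceeds ``noise_floor_factor`` times the median spectral amplitude (no
    periodic motion above the noise floor).
    """
    if isinstance(trace, DisplacementTrace):
        times = trace.times
        if times.size >= 3:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("dominant_frequency requires uniform sampling")
        dt = trace.dt
    elif dt is None:
        raise ValueError("dt is required when trace is a bare array")
    y = _trace_values(trace)
    if y.size < 8:
        raise ValueError("trace needs at least 8 samples for a spectrum")
    x = y - y.mean()
    nfft = pad_factor * y.size
    amp = np.abs(np.fft.rfft(x, nfft))
    amp[0] = 0.0
    k = int(np.argmax(amp))
    floor = noise_floor_factor * float(np.median(amp[1:]))
    if amp[k] <= floor:
        return 0.0
    return k / (nfft * dt)


def _speeds(trace, dt: float | None):
    """Per-interval instantaneous speeds (µm/s) and the sample interval."""
    if isinstance(trace, DisplacementTrace):
        dt = trace.dt
        if trace.velocity.size:
            return np.asarray(trace.velocity, dtype=float), dt
        y = trace.displacement
    else:
        if dt is None:
            raise ValueError("dt is required when trace is a bare array")
        y = _trace_values(trace)
    return np.abs(np.diff(y)) / dt, dt


def contraction_velocity(trace, window: float = 2.0, dt: float | None = None) -> float:
    """Mean instantaneous speed (µm/s) over the first ``window`` seconds."""
    speeds, dt = _speeds(trace, dt)
    k = int(round(window / dt))
    if k < 1 or k > speeds.size:
        raise ValueError(
            f"trace spans {speeds.size * dt:.3g} s < window {window:.3g} s; "
            "pass an explicit shorter window"
        )
    return float(speeds[:k].mean())


def fatigue_time(
    trace,
    baseline_window: float,
    stop_threshold_factor: float = 2.0,
    sustain: float = 1.0,
    dt: float | None = None,
) -> float | None:
    """Time (s from stimulation onset) at which contraction ceases.

    The first ``baseline_window`` seconds are the pre-stimulation baseline;
    its RMS velocity, times ``stop_threshold_factor``, is the cessation
    threshold.  Fatigue is the first instant from which the rolling RMS
    velocity over the following ``sustain`` seconds is below the threshold
    (motion statistically indistinguishable from baseline, sustained).
    Returns ``None`` if motion never ceases.
    """
    speeds, dt = _speeds(trace, dt)
    nb = int(round(baseline_window / dt))
    if nb < 1 or nb >= speeds.size:
        raise ValueError("trace lacks a pre-stimulation baseline of the requested length")
    baseline_rms = float(np.sqrt(np.mean(speeds[:nb] ** 2)))
    thr = stop_threshold_factor * baseline_rms

    ns = max(1, int(round(sustain / dt)))
    sq = speeds**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    onset = nb
    idx = np.arange(onset, speeds.size)
    hi = np.minimum(idx + ns, speeds.size)
    ok = hi - idx >= max(1, ns // 2)  # need enough tail for a meaningful RMS
    idx, hi = idx[ok], hi[ok]
    if idx.size == 0:
        return None
    rms = np.sqrt((csum[hi] - csum[idx]) / (hi - idx))
    # first-crossing of a noisy series triggers on downward fluctuations;
    # a centered moving average over the sustain scale removes that bias
    if ns > 1 and rms.size > ns:
        kernel = np.ones(min(ns, rms.size)) / min(ns, rms.size)
        pad = len(kernel) // 2
        padded = np.concatenate([np.full(pad, rms[0]), rms, np.full(pad, rms[-1])])
        rms = np.convolve(padded, kernel, mode="valid")[: idx.size]
    below = (rms <= thr) if thr == 0 else (rms < thr)
    hits = np.nonzero(below)[0]
    if hits.size == 0:
        return None
    return float((idx[hits[0]] - onset) * dt)


def summarize(
    trace,
    window: float = 2.0,
    prominence_fraction: float = 0.1,
    baseline_window: float | None = None,
    dt: float | None = None,
) -> KineticsSummary:
    """Full kinetics summary of one trace (Fig-style per-cell readout)."""
    if isinstance(trace, DisplacementTrace):
        dt = trace.dt
    elif dt is None:
        raise ValueError("dt is required when trace is a bare array")
    y = _trace_values(trace)
    extrema = detect_extrema(y, prominence_fraction)
    events = dissect_twitches(y, extrema, dt=dt)
    freq = dominant_frequency(trace, dt=dt) if y.size >= 8 else 0.0
    span = (y.size - 1) * dt
    vel = contraction_velocity(trace, window=min(window, span), dt=dt)
    ft = (
        fatigue_time(trace, baseline_window, dt=dt)
        if baseline_window is not None
        else None
    )
    return KineticsSummary(
        contraction_velocity=vel,
        dominant_frequency=freq,
        period=(1.0 / freq) if freq > 0 else math.nan,
        mean_acceleration_time=(
            float(np.mean([e.acceleration_time for e in events])) if events else math.nan
        ),
        mean_relaxation_time=(
            float(np.mean([e.relaxation_time for e in events])) if events else math.nan
        ),
        mean_amplitude=float(np.mean([e.amplitude for e in events])) if events else math.nan,
        n_twitches=len(events),
        fatigue_time=ft,
    )
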