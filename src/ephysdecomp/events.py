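"""Template-matching detection of spontaneous synaptic events.

Sliding scaled-template detection in the Clements-Bekkers style: at every
sample a bi-exponential template is fitted to the following window by least
squares with free offset and scale; the detection score is the fitted scale
divided by the standard deviation of the fit residuals.  Events are local
score maxima above the criterion, separated by at least the template rise
time.  On voltage traces, epochs around detected action potentials are
excluded so APs are not counted as synaptic events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, find_peaks

from .protocol import CURRENT_CLAMP, Trace
from .simulate import biexp_kernel
from .spikes import detect_spikes

__all__ = ["EventTrain", "detect_events", "event_stats", "DEFAULT_CRITERION"]

DEFAULT_CRITERION = 3.5
#: spikes are excluded from this long before the AP onset (ms) ...
AP_EXCLUDE_PRE_MS = 2.0
#: ... to this long after it (ms)
AP_EXCLUDE_POST_MS = 20.0
#: recordings shorter than this trigger a duration warning (s)
MIN_RECOMMENDED_DURATION_S = 120.0


@dataclass
class EventTrain:
    """Detected events: times (s), signed amplitudes (fitted template
    scales, pA or mV), detection scores, and excluded epochs (s)."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    scores: np.ndarray
    excluded_epochs_s: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def excluded_time_s(self) -> float:
        return float(sum(e - s for s, e in self.excluded_epochs_s))


def _sliding_template_score(y: np.ndarray, w: np.ndarray):
    """Per-position fitted scale and score for template w on signal y."""
    L = w.size
    ones = np.ones(L)
    Sw = float(w.sum())
    Sww = float((w * w).sum())
    denom = Sww - Sw * Sw / L
    Sy = fftconvolve(y, ones, mode="valid")
    Syy = fftconvolve(y * y, ones, mode="valid")
    Swy = fftconvolve(y, w[::-1], mode="valid")
    scale = (Swy - Sw * Sy / L) / denom
    offset = (Sy - scale * Sw) / L
    sse = np.maximum(Syy - offset * Sy - scale * Swy, 1e-30)
    sd = np.sqrt(sse / (L - 1))
    return scale, scale / sd


def detect_events(
    trace: Trace,
    rise_tau_ms: float,
    decay_tau_ms: float,
    template_length_ms: float | None = None,
    criterion: float = DEFAULT_CRITERION,
    polarity: str = "inward",
    exclude_aps: bool | None = None,
) -> EventTrain:
    """Detect synaptic events by sliding scaled-template matching.

    ``polarity``: 'inward' for downward currents (sEPSC under voltage
    clamp), 'upward' for depolarizing potentials (sEPSP).  ``criterion`` is
    the minimum detection score (fitted scale / residual SD).  On
    current-clamp traces AP epochs are excluded by default.
    """
    if criterion <= 0:
        raise ValueError("criterion must be positive")
    if polarity not in ("inward", "upward"):
        raise ValueError("polarity must be 'inward' or 'upward'")
    dt = trace.dt_ms
    kernel = biexp_kernel(rise_tau_ms, decay_tau_ms, dt, template_length_ms)
    if kernel.size >= trace.signal.size:
        raise ValueError("template longer than the trace")
    if trace.duration_ms / 1000.0 < MIN_RECOMMENDED_DURATION_S:
        warnings.warn(
            f"recording shorter than {MIN_RECOMMENDED_DURATION_S:.0f} s; "
            "frequency estimates may be unreliable",
            stacklevel=2,
        )

    sign = -1.0 if polarity == "inward" else 1.0
    y = sign * trace.signal

    if exclude_aps is None:
        exclude_aps = trace.mode == CURRENT_CLAMP
    excluded: list[tuple[float, float]] = []
    if exclude_aps and trace.mode == CURRENT_CLAMP:
        for onset in detect_spikes(trace):
            t_on = onset * dt
            excluded.append(
                (
                    max(0.0, (t_on - AP_EXCLUDE_PRE_MS)) / 1000.0,
                    min(trace.duration_ms, t_on + AP_EXCLUDE_POST_MS) / 1000.0,
                )
            )

    scale, score = _sliding_template_score(y, kernel)
    # one event per contiguous supra-criterion run of the score, at the run's
    # score maximum; runs long enough to hold several events are split at
    # prominent interior peaks separated by at least the template rise time
    min_sep = max(1, int(round(rise_tau_ms / dt)))
    above = score >= criterion
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    run_starts = edges[::2] + 1 if not above[0] else np.concatenate(([0], edges[1::2] + 1))
    run_ends = edges[1::2] + 1 if not above[0] else edges[::2] + 1
    if above[-1]:
        run_ends = np.concatenate((run_ends, [score.size]))
    peaks_list = []
    for r0, r1 in zip(run_starts, run_ends):
        seg = score[r0:r1]
        p, props = find_peaks(seg, distance=min_sep, prominence=criterion / 2)
        if p.size == 0:
            p = np.array([int(np.argmax(seg))])
        peaks_list.append(p + r0)
    peaks = np.concatenate(peaks_list) if peaks_list else np.array([], dtype=int)

    times = peaks * dt / 1000.0
    amps = sign * scale[peaks]
    scores = score[peaks]
    if excluded:
        keep = np.ones(times.size, dtype=bool)
        for s, e in excluded:
            keep &= ~((times >= s) & (times < e))
        times, amps, scores = times[keep], amps[keep], scores[keep]
    return EventTrain(times, amps, scores, excluded)


def event_stats(train: EventTrain, duration_s: float):
    """(frequency Hz, mean amplitude, amplitude SD) with the excluded time
    removed from the effective duration.  Amplitude statistics are NaN for
    an empty train."""
    effective = duration_s - train.excluded_time_s
    if effective <= 0:
        raise ValueError("non-positive effective duration after exclusions")
    n = train.times_s.size
    freq = n / effective
    if n == 0:
        return freq, float("nan"), float("nan")
    return freq, float(np.mean(train.amplitudes)), float(np.std(train.amplitudes, ddof=1)) if n > 1 else 0.0
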